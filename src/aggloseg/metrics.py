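"""Region-based segmentation metrics.

All metrics operate on the contingency table — the joint pixel-count matrix
of a candidate segmentation S against a reference segmentation U.

The central metric is the variation of information (VI),

    VI(S, U) = H(S | U) + H(U | S)   [bits],

a true metric on partitions.  ``H(S|U)`` is the oversegmentation /
false-split term (given the true segment, how uncertain is the candidate
label) and ``H(U|S)`` the undersegmentation / false-merge term.  Because it
is measured in bits it has a direct reading: a VI of 1 with all error in the
over term means each reference segment is on average split into two
equal-sized fragments.  The split-VI curve plots the two terms against each
other across agglomeration thresholds, and the VI breakdown decomposes each
term into per-segment contributions p(segment) * H(conditional).

Also provided: Rand index, Hubert–Arabie adjusted Rand index, the
pair-counting Rand F-score error used by EM segmentation challenges,
segmentation covering, and ODS/OIS threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

__all__ = [
    "ContingencyTable",
    "VIReport",
    "contingency",
    "vi",
    "vi_from_labels",
    "vi_breakdown",
    "split_vi_curve",
    "rand_index",
    "adjusted_rand_index",
    "adjusted_rand_error",
    "covering",
    "ods_ois",
]


@dataclass
class ContingencyTable:
    """Joint pixel counts: rows are candidate segments, columns reference."""

    matrix: np.ndarray  # (n_candidate_segments, n_reference_segments)
    candidate_ids: np.ndarray
    reference_ids: np.ndarray
    n: int

    def joint(self) -> np.ndarray:
        return self.matrix / self.n


def contingency(
    candidate: np.ndarray,
    reference: np.ndarray,
    ignore_reference: tuple[int, ...] = (0,),
    ignore_candidate: tuple[int, ...] = (),
) -> ContingencyTable:
    """Exact joint counts of two label volumes.

    Pixels whose reference label is in ``ignore_reference`` (default: 0,
    i.e. unlabelled reference regions must not count as errors) are excluded
    entirely.  Candidate label 0 is a real segment unless listed in
    ``ignore_candidate``.
    """
    candidate = np.asarray(candidate)
    reference = np.asarray(reference)
    if candidate.shape != reference.shape:
        raise InputError(
            f"shape mismatch: candidate {candidate.shape} vs reference {reference.shape}"
        )
    s = candidate.ravel()
    u = reference.ravel()
    mask = ~np.isin(u, ignore_reference)
    if ignore_candidate:
        mask &= ~np.isin(s, ignore_candidate)
    s, u = s[mask], u[mask]
    if s.size == 0:
        raise InputError("no pixels left after label exclusion")
    s_ids, s_inv = np.unique(s, return_inverse=True)
    u_ids, u_inv = np.unique(u, return_inverse=True)
    matrix = np.bincount(
        s_inv * len(u_ids) + u_inv, minlength=len(s_ids) * len(u_ids)
    ).reshape(len(s_ids), len(u_ids))
    return ContingencyTable(
        matrix=matrix.astype(np.float64),
        candidate_ids=s_ids,
        reference_ids=u_ids,
        n=int(s.size),
    )


def _cond_entropy_bits(joint: np.ndarray, marginal: np.ndarray) -> np.ndarray:
    """Row-wise H(col | row) in bits for each row; 0*log0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / marginal[:, None]
        terms = np.where(joint > 0, ratio * np.log2(ratio), 0.0)
    return -terms.sum(axis=1)


@dataclass
class VIReport:
    """VI in bits, split into terms, with per-segment breakdowns.

    ``under`` is H(U|S), the false-merge term; ``over`` is H(S|U), the
    false-split term; ``total`` is their sum.  Breakdown lists hold
    (segment id, probability mass p, conditional entropy H) sorted by
    contribution p*H descending.
    """

    under: float
    over: float
    total: float
    reference_breakdown: list[tuple[int, float, float]]
    candidate_breakdown: list[tuple[int, float, float]]


def vi(table: ContingencyTable) -> VIReport:
    """Variation of information of a contingency table, in bits."""
    p = table.joint()
    p_s = p.sum(axis=1)  # candidate marginal
    p_u = p.sum(axis=0)  # reference marginal
    h_u_given_s = _cond_entropy_bits(p, p_s)  # per candidate segment
    h_s_given_u = _cond_entropy_bits(p.T, p_u)  # per reference segment
    under = float(np.dot(p_s, h_u_given_s))
    over = float(np.dot(p_u, h_s_given_u))
    ref_break = sorted(
        zip(
            (int(i) for i in table.reference_ids),
            (float(x) for x in p_u),
            (float(h) for h in h_s_given_u),
        ),
        key=lambda t: -(t[1] * t[2]),
    )
    cand_break = sorted(
        zip(
            (int(i) for i in table.candidate_ids),
            (float(x) for x in p_s),
            (float(h) for h in h_u_given_s),
        ),
        key=lambda t: -(t[1] * t[2]),
    )
    return VIReport(
        under=under,
        over=over,
        total=under + over,
        reference_breakdown=ref_break,
        candidate_breakdown=cand_break,
    )


def vi_from_labels(
    candidate: np.ndarray,
    reference: np.ndarray,
    ignore_reference: tuple[int, ...] = (0,),
) -> VIReport:
    """Convenience: VI directly from two label volumes."""
    return vi(contingency(candidate, reference, ignore_reference=ignore_reference))


def vi_breakdown(
    table: ContingencyTable,
) -> tuple[list[tuple[int, float, float]], list[tuple[int, float, float]]]:
    """Per-segment (id, p, H) lists: (reference side, candidate side).

    The reference-side entries decompose the over term (each reference
    segment's splitting), the candidate-side entries the under term.
    """
    report = vi(table)
    return report.reference_breakdown, report.candidate_breakdown


def split_vi_curve(history, superpixels, gold, thresholds) -> list[tuple[float, float]]:
    """(false-merge, false-split) = (under, over) point per threshold.

    Cuts the recorded merge history at each threshold and evaluates against
    the gold standard.  Thresholds must be sorted ascending.
    """
    from .agglom import cut_history

    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise InputError("thresholds must be sorted ascending")
    points = []
    for t in thresholds:
        seg = cut_history(history, superpixels, t)
        report = vi_from_labels(seg, gold)
        points.append((report.under, report.over))
    return points


# ------------------------------------------------------------------ pair counts


def _pair_counts(table: ContingencyTable) -> tuple[float, float, float, float]:
    """(pairs total, same-in-candidate, same-in-reference, same-in-both)."""
    if table.n < 2:
        raise InputError("pair-counting metrics require at least 2 pixels")

    def c2(x):
        return float((x * (x - 1) / 2).sum())

    m = table.matrix
    return c2(np.array([table.n])), c2(m.sum(axis=1)), c2(m.sum(axis=0)), c2(m)


def rand_index(table: ContingencyTable) -> float:
    """Fraction of pixel pairs on which the two partitions agree."""
    total, same_s, same_u, same_both = _pair_counts(table)
    agreements = total - same_s - same_u + 2 * same_both
    return agreements / total


def adjusted_rand_index(table: ContingencyTable) -> float:
    """Hubert–Arabie chance-corrected Rand index (permutation model)."""
    total, same_s, same_u, same_both = _pair_counts(table)
    expected = same_s * same_u / total
    maximum = 0.5 * (same_s + same_u)
    if maximum == expected:  # single segment on both sides: identical
        return 1.0
    return (same_both - expected) / (maximum - expected)


def adjusted_rand_error(table: ContingencyTable) -> float:
    """Rand F-score error: 1 - harmonic mean of pair precision and recall.

    Precision = same-in-both pairs / same-in-candidate pairs; recall uses
    the reference pairs.  This is the pair-counting error used to rank EM
    segmentation challenge entries; 0 for identical partitions.  Degenerate
    cases with no same-segment pairs on either side score 0 by convention.
    """
    _, same_s, same_u, same_both = _pair_counts(table)
    if same_s == 0 and same_u == 0:  # all singletons on both sides: identical
        return 0.0
    if same_s == 0 or same_u == 0 or same_both == 0:
        return 1.0
    precision = same_both / same_s
    recall = same_both / same_u
    return 1.0 - 2.0 * precision * recall / (precision + recall)


def covering(table: ContingencyTable, direction: str = "reference") -> float:
    """Size-weighted mean best intersection-over-union between segments.

    ``direction="reference"``: each reference segment is matched with its
    best-overlapping candidate segment (the usual gold-standard covering);
    ``"candidate"`` is the transpose.
    """
    m = table.matrix
    areas_s = m.sum(axis=1)
    areas_u = m.sum(axis=0)
    union = areas_s[:, None] + areas_u[None, :] - m
    with np.errstate(invalid="ignore"):
        iou = np.where(m > 0, m / union, 0.0)
    if direction == "reference":
        return float(np.dot(areas_u / table.n, iou.max(axis=0)))
    if direction == "candidate":
        return float(np.dot(areas_s / table.n, iou.max(axis=1)))
    raise InputError(f"unknown covering direction {direction!r}")


def ods_ois(
    per_image_curves: list[dict[float, float]],
    maximize: bool = False,
) -> tuple[float, float, float]:
    """Optimal dataset scale and optimal image scale from threshold curves.

    Each curve maps threshold -> score on one image; all curves must share
    the threshold grid.  ODS picks the single threshold optimizing the mean
    score (ties: smallest threshold); OIS averages each image's own optimum.
    ``maximize=False`` suits VI (lower is better), ``True`` suits covering
    and Rand.  Returns (ods_threshold, ods_score, ois_score).
    """
    if not per_image_curves:
        raise InputError("need at least one threshold curve")
    grid = sorted(per_image_curves[0])
    for curve in per_image_curves:
        if sorted(curve) != grid:
            raise InputError("all curves must share the same threshold grid")
    scores = np.array([[curve[t] for t in grid] for curve in per_image_curves])
    means = scores.mean(axis=0)
    best = np.argmax(means) if maximize else np.argmin(means)
    # ties: smallest threshold
    tied = np.flatnonzero(means == means[best])
    best = tied[0]
    per_image_best = scores.max(axis=1) if maximize else scores.min(axis=1)
    return float(grid[best]), float(means[best]), float(per_image_best.mean())
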