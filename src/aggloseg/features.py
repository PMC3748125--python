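"""Feature vectors for candidate merges.

A merge priority policy decomposes into a feature map and a classifier.
This module is the feature map: given a region adjacency graph and an edge
(u, v), it assembles a fixed-length vector from the cached statistics of the
boundary, of each region, and of their relationship, per cue channel:

* approximate quantiles of the value histogram (linear interpolation of the
  cumulative bin mass), pixel count, mean, and central moments 2..4 — for
  the boundary and for each region;
* absolute differences between the two regions' means/central moments;
* the Jensen–Shannon divergence between the regions' normalized histograms
  (log base 2, so the value is in [0, 1] bits).

In 2D, optional mid-level features add relative orientation angles (from the
regions' second-moment matrices) and convexity ratios (region area over
convex-hull area, for each region and their union).

The vector is symmetric under swapping u and v: the two region blocks are
ordered smaller-region-first (ties by node id) and differences are absolute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

from .errors import InputError, SchemaError
from .rag import NodeStats, Rag, Stats

__all__ = [
    "FeatureConfig",
    "histogram_features",
    "pair_features",
    "orientation_features",
    "convex_hull_features",
    "jensen_shannon",
]

#: sentinel angle for degenerate orientation comparisons (isotropic or
#: single-pixel regions, coincident centroids): the midpoint of [0, pi/2].
DEGENERATE_ANGLE = np.pi / 4


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration fixing the feature schema.

    ``n_quantiles`` of 3 gives quartiles {0.25, 0.5, 0.75}; 9 gives deciles.
    Other counts are evenly spaced in (0, 1).  ``channels`` restricts the cue
    channels used (``None`` = all channels of the graph).
    """

    bins: int = 25
    n_quantiles: int = 3
    use_moments: bool = True
    use_jsd: bool = True
    use_midlevel_2d: bool = False
    channels: tuple[int, ...] | None = None

    def quantile_fractions(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_quantiles + 2)[1:-1]

    def fragment_names(self) -> list[str]:
        qs = [f"q{f:.2f}" for f in self.quantile_fractions()]
        return qs + ["count", "mean", "moment2", "moment3", "moment4"]

    def schema(self, n_channels: int) -> list[tuple[str, int | None, str]]:
        """Ordered (feature-name, channel, source) triples."""
        channels = self.channels if self.channels is not None else range(n_channels)
        out: list[tuple[str, int | None, str]] = []
        for c in channels:
            for source in ("edge", "region_small", "region_large"):
                out += [(name, c, source) for name in self.fragment_names()]
            if self.use_moments:
                out += [
                    (f"abs_diff_{m}", c, "pair")
                    for m in ("mean", "moment2", "moment3", "moment4")
                ]
            if self.use_jsd:
                out.append(("jsd", c, "pair"))
        if self.use_midlevel_2d:
            out += [
                ("angle_between_orientations", None, "pair"),
                ("angle_small_to_centroid_line", None, "pair"),
                ("angle_large_to_centroid_line", None, "pair"),
                ("convexity_small", None, "region_small"),
                ("convexity_large", None, "region_large"),
                ("convexity_union", None, "pair"),
            ]
        return out

    def n_features(self, n_channels: int) -> int:
        return len(self.schema(n_channels))


def histogram_quantiles(hist: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Approximate quantiles by linear interpolation of cumulative bin mass."""
    bins = len(hist)
    total = hist.sum()
    if total == 0:
        raise InputError("cannot take quantiles of an empty histogram")
    edges = np.linspace(0.0, 1.0, bins + 1)
    cdf = np.concatenate([[0.0], np.cumsum(hist) / total])
    return np.interp(fractions, cdf, edges)


def histogram_features(stats: Stats, channel: int, cfg: FeatureConfig) -> np.ndarray:
    """Per-channel fragment: quantiles, pixel count, mean, central moments 2..4."""
    if stats.n == 0:
        raise InputError("cannot compute features of empty statistics")
    q = histogram_quantiles(stats.hist[channel], cfg.quantile_fractions())
    mean = stats.mean[channel]
    moments = stats.central_moments()[channel]
    return np.concatenate([q, [stats.n, mean], moments])


def jensen_shannon(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence of two discrete distributions, in bits."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return max(0.0, 0.5 * kl(p, m) + 0.5 * kl(q, m))


def _ordered_regions(rag: Rag, u: int, v: int) -> tuple[int, int]:
    """Smaller region first; ties broken by node id."""
    ku = (rag.nodes[u].n, u)
    kv = (rag.nodes[v].n, v)
    return (u, v) if ku <= kv else (v, u)


def pair_features(rag: Rag, u: int, v: int, cfg: FeatureConfig) -> np.ndarray:
    """Feature vector for the candidate merge of regions u and v."""
    if cfg.bins != rag.bins:
        raise SchemaError(
            f"feature config expects {cfg.bins} histogram bins, graph has {rag.bins}"
        )
    rag._edge_data(u, v)  # raises MissingEdgeError if absent
    a, b = _ordered_regions(rag, u, v)
    estats = rag.edge_stats(u, v)
    astats, bstats = rag.nodes[a], rag.nodes[b]
    channels = cfg.channels if cfg.channels is not None else range(rag.n_channels)
    parts: list[np.ndarray] = []
    for c in channels:
        if c >= rag.n_channels:
            raise SchemaError(f"channel {c} not present (graph has {rag.n_channels})")
        parts.append(histogram_features(estats, c, cfg))
        parts.append(histogram_features(astats, c, cfg))
        parts.append(histogram_features(bstats, c, cfg))
        if cfg.use_moments:
            ma = np.concatenate([[astats.mean[c]], astats.central_moments()[c]])
            mb = np.concatenate([[bstats.mean[c]], bstats.central_moments()[c]])
            parts.append(np.abs(ma - mb))
        if cfg.use_jsd:
            parts.append([jensen_shannon(astats.hist[c], bstats.hist[c])])
    if cfg.use_midlevel_2d:
        if rag.ndim != 2 or not rag.midlevel_2d:
            raise SchemaError(
                "mid-level features require a 2D graph built with midlevel_2d=True"
            )
        parts.append(orientation_features(rag, a, b))
        parts.append(convex_hull_features(rag, a, b))
    vec = np.concatenate([np.asarray(p, dtype=np.float64) for p in parts])
    if not np.all(np.isfinite(vec)):
        raise InputError("non-finite feature value encountered")
    return vec


# --------------------------------------------------------------- mid-level 2D


def _principal_axis(stats: NodeStats) -> np.ndarray | None:
    """Unit principal axis of a region from its second-moment matrix.

    Returns ``None`` for degenerate (single-pixel or isotropic) regions.
    """
    n = stats.n
    if n < 2 or stats.sq_sum is None:
        return None
    cy, cx = stats.coord_sum / n
    syy = stats.sq_sum[0] / n - cy * cy
    sxx = stats.sq_sum[1] / n - cx * cx
    syx = stats.sq_sum[2] / n - cy * cx
    cov = np.array([[syy, syx], [syx, sxx]])
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= 1e-12 * max(evals[1], 1e-12):
        return None
    return evecs[:, 1]


def _acute_angle(a: np.ndarray, b: np.ndarray) -> float:
    cosang = abs(float(np.dot(a, b))) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cosang, 0.0, 1.0)))


def orientation_features(rag: Rag, u: int, v: int) -> np.ndarray:
    """Three relative angles in [0, pi/2] describing mutual orientation.

    The angle between the two principal orientations, and between each
    orientation and the segment connecting the two centroids.  Degenerate
    comparisons fall back to the pi/4 sentinel.
    """
    if rag.ndim != 2 or not rag.midlevel_2d:
        raise SchemaError("orientation features require 2D data with midlevel_2d=True")
    a, b = _ordered_regions(rag, u, v)
    sa, sb = rag.nodes[a], rag.nodes[b]
    axis_a, axis_b = _principal_axis(sa), _principal_axis(sb)
    centroid_a = sa.coord_sum / sa.n
    centroid_b = sb.coord_sum / sb.n
    d = centroid_b - centroid_a
    d = d if np.linalg.norm(d) > 1e-12 else None

    def ang(x, y):
        return _acute_angle(x, y) if x is not None and y is not None else DEGENERATE_ANGLE

    return np.array([ang(axis_a, axis_b), ang(axis_a, d), ang(axis_b, d)])


def _hull_area(points: np.ndarray | None) -> float | None:
    if points is None or len(points) < 3:
        return None
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return None


def convex_hull_features(rag: Rag, u: int, v: int) -> np.ndarray:
    """Convexity ratios: region area / convex-hull area, for u, v and u∪v.

    Pixels count as unit squares, so a solid rectangle has ratio exactly 1.
    Undefined hulls (collinear corner clouds cannot occur for non-empty
    regions, but guard anyway) fall back to ratio 1.
    """
    if rag.ndim != 2 or not rag.midlevel_2d:
        raise SchemaError("hull features require 2D data with midlevel_2d=True")
    a, b = _ordered_regions(rag, u, v)
    sa, sb = rag.nodes[a], rag.nodes[b]
    area_a = _hull_area(sa.hull_points)
    area_b = _hull_area(sb.hull_points)
    area_ab = _hull_area(np.vstack([sa.hull_points, sb.hull_points]))
    ratio_a = sa.n / area_a if area_a else 1.0
    ratio_b = sb.n / area_b if area_b else 1.0
    ratio_ab = (sa.n + sb.n) / area_ab if area_ab else 1.0
    return np.array([ratio_a, ratio_b, ratio_ab])
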