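"""Hierarchical agglomeration driven by a merge priority policy.

Agglomeration repeatedly merges the edge with the lowest priority score
(scores live in [0, 1] and behave like a boundary probability: low means
"merge first") while that score is below a threshold.  The queue uses lazy
invalidation: entries carry the version stamps of their endpoint nodes and
stale entries are discarded at pop time; after a merge only the edges
incident to the merged node are re-scored, which is exact for the local
policies used here.

The merge history is a dendrogram: an ordered list of (step, a, b, merged,
score) records that can be cut at any threshold without re-running the
agglomeration.  Recorded scores are merge-time values and need not be
globally monotone (re-evaluation after a merge can lower a neighbour's
score); ``monotone=True`` clamps each recorded score to the running maximum
for strict hierarchy cuts.
"""

from __future__ import annotations

import csv
import heapq
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .policy import MeanBoundaryPolicy, Policy
from .rag import Rag

__all__ = [
    "MergeRecord",
    "MergeHistory",
    "agglomerate",
    "mean_boundary_policy",
    "cut_history",
]


@dataclass(frozen=True)
class MergeRecord:
    step: int
    node_a: int
    node_b: int
    merged: int
    score: float


@dataclass
class MergeHistory:
    """Ordered record of merges; a dendrogram cuttable at any threshold."""

    n_initial: int
    records: list[MergeRecord] = field(default_factory=list)

    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records])

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["step", "node_a", "node_b", "merged", "score"])
            for r in self.records:
                writer.writerow([r.step, r.node_a, r.node_b, r.merged, r.score])

    def summary(self) -> dict:
        s = self.scores()
        return {
            "n_initial": self.n_initial,
            "n_merges": len(self.records),
            "score_min": float(s.min()) if len(s) else None,
            "score_max": float(s.max()) if len(s) else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


class MergeQueue:
    """Min-heap of (score, u, v) with version-stamped lazy invalidation.

    Ties among equal scores resolve to the smallest (u, v) id pair through
    tuple ordering, making runs reproducible.
    """

    def __init__(self, rag: Rag):
        self.rag = rag
        self._heap: list[tuple[float, int, int, int, int]] = []

    def push_edges(self, policy: Policy, pairs) -> None:
        pairs = [tuple(sorted(p)) for p in pairs]
        if not pairs:
            return
        scores = policy.score_edges(self.rag, pairs)
        for (u, v), s in zip(pairs, scores):
            heapq.heappush(
                self._heap,
                (float(s), u, v, self.rag.node_version[u], self.rag.node_version[v]),
            )

    def pop_valid(self):
        """Next live (score, u, v) entry, or None when exhausted."""
        rag = self.rag
        while self._heap:
            s, u, v, vu, vv = heapq.heappop(self._heap)
            if (
                rag.node_version.get(u) == vu
                and rag.node_version.get(v) == vv
                and rag.has_edge(u, v)
            ):
                return s, u, v
        return None


def agglomerate(
    rag: Rag,
    policy: Policy,
    threshold: float,
    *,
    monotone: bool = False,
) -> tuple[np.ndarray, MergeHistory]:
    """Merge lowest-score edges while the score is below ``threshold``.

    The strict inequality makes threshold 0 a no-op.  Returns the final
    segmentation (superpixels relabelled with surviving node ids) and the
    merge history.  The graph is modified in place.
    """
    policy.validate(rag)
    history = MergeHistory(n_initial=len(rag))
    queue = MergeQueue(rag)
    queue.push_edges(policy, rag.edge_list())
    step = 0
    running_max = 0.0
    while True:
        entry = queue.pop_valid()
        if entry is None:
            break
        score, u, v = entry
        if score >= threshold:
            break
        merged = rag.merge_nodes(u, v)
        running_max = max(running_max, score)
        history.records.append(
            MergeRecord(
                step=step,
                node_a=u,
                node_b=v,
                merged=merged,
                score=running_max if monotone else score,
            )
        )
        step += 1
        queue.push_edges(policy, [(merged, w) for w in rag.adjacency[merged]])
    return rag.current_segmentation(), history


def mean_boundary_policy(channel: int = 0) -> MeanBoundaryPolicy:
    """Baseline policy: score = mean boundary-cue value over the edge."""
    return MeanBoundaryPolicy(channel=channel)


def cut_history(
    history: MergeHistory, superpixels: np.ndarray, threshold: float
) -> np.ndarray:
    """Replay merges recorded with score < threshold, in recorded order.

    For monotone histories this equals a fresh agglomeration at the same
    threshold; for non-monotone ones it is the dendrogram cut.  Because the
    surviving node id is always the smaller one, record endpoints are
    original superpixel ids and the replay is a union-find pass.
    """
    if not 0.0 <= threshold <= 1.0:
        raise InputError("threshold must lie in [0, 1]")
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:  # path compression
            parent[x], x = root, parent[x]
        return root

    for rec in history.records:
        if rec.score < threshold:
            ra, rb = find(rec.node_a), find(rec.node_b)
            if ra != rb:
                keep, drop = (ra, rb) if ra < rb else (rb, ra)
                parent[drop] = keep
    ids = np.unique(superpixels)
    ids = ids[ids > 0]
    lut = np.zeros(int(ids.max()) + 1, dtype=superpixels.dtype)
    for sp in ids:
        lut[sp] = find(int(sp))
    return lut[superpixels]
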