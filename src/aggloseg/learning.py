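"""Learning the merge priority function.

The key idea: instead of training a merge classifier only on the edges of
the initial superpixel graph ("flat learning"), run the agglomeration
*during* training, guided by the current policy, and label every proposed
merge against the best agglomeration A* derivable from the gold standard.
True merges proceed, false ones are recorded but refused, and the epoch
terminates exactly when the graph's grouping matches A*.  This yields
training examples at every scale of agglomeration — matching the feature
statistics the policy will actually see at test time — and, empirically,
calibrates the classifier so the minimum-VI threshold sits near 0.5.

A* assigns each superpixel to the gold segment with which it shares the
most overlap; the superpixels mapped to one gold segment form one group.
Labels: +1 ("should merge") when both regions lie in one group, -1 ("don't
merge") when each lies wholly in a different group, 0 ("don't know") when a
region mixes groups.  With labels taken against A*, 0 never occurs during
an epoch because only +1 merges are executed, so every region stays pure.

The LASH variant follows the policy to completion (merges always proceed)
and labels each merge by the sign of the Rand-index change it causes; only
the last epoch's data feeds the final fit.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ConsistencyError, DegenerateTrainingError, InputError
from .features import FeatureConfig, pair_features
from .policy import ClassifierPolicy, MeanBoundaryPolicy, Policy, RandomPolicy
from .rag import Rag

logger = logging.getLogger(__name__)

__all__ = [
    "BestAgglomeration",
    "GoldReference",
    "TrainingSet",
    "best_agglomeration",
    "merge_label",
    "flat_learning",
    "gala_epoch",
    "gala_train",
    "lash_epoch",
    "lash_train",
    "fit_policy",
]


@dataclass
class BestAgglomeration:
    """Best achievable grouping of superpixels given a gold standard.

    ``assignment`` maps every superpixel id to a group id; ``groups`` is the
    inverse partition.  Group ids coincide with gold segment ids except for
    groups created by connectivity refinement or for unassigned superpixels.
    """

    assignment: dict[int, int]
    groups: dict[int, set[int]]


@dataclass
class GoldReference:
    """Per-superpixel purity against the raw gold standard.

    ``pure`` maps superpixel id -> gold segment id when the superpixel lies
    wholly inside one (non-zero) gold segment, else ``None``.  Used for the
    literal label definition (label source "gold"), which can produce
    0-labelled "don't know" examples.
    """

    pure: dict[int, int | None]


def _superpixel_adjacency(superpixels: np.ndarray) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {}
    for axis in range(superpixels.ndim):
        sl1 = [slice(None)] * superpixels.ndim
        sl2 = [slice(None)] * superpixels.ndim
        sl1[axis] = slice(None, -1)
        sl2[axis] = slice(1, None)
        a = superpixels[tuple(sl1)].ravel()
        b = superpixels[tuple(sl2)].ravel()
        mask = (a != b) & (a > 0) & (b > 0)
        for la, lb in zip(a[mask], b[mask]):
            adj.setdefault(int(la), set()).add(int(lb))
            adj.setdefault(int(lb), set()).add(int(la))
    return adj


def best_agglomeration(
    superpixels: np.ndarray,
    gold: np.ndarray,
    *,
    split_disconnected: bool = True,
) -> BestAgglomeration:
    """Assign each superpixel to the gold segment of maximal overlap.

    Ties break to the smallest gold id.  Superpixels overlapping only
    unlabelled (gold 0) pixels go to a dedicated "unassigned" group and a
    warning is emitted.

    With ``split_disconnected=True`` (default) each group is refined into
    its connected components in the superpixel adjacency graph, so the
    result is achievable by adjacency-constrained merging — the training
    epoch can then terminate with the graph grouping exactly equal to A*.
    """
    superpixels = np.asarray(superpixels)
    gold = np.asarray(gold)
    if superpixels.shape != gold.shape:
        raise InputError(
            f"shape mismatch: superpixels {superpixels.shape} vs gold {gold.shape}"
        )
    if not (gold > 0).any():
        raise InputError("gold standard has no non-zero segment")
    sp = superpixels.ravel()
    g = gold.ravel()
    mask = sp > 0
    sp_ids = np.unique(sp[mask])

    overlap_mask = mask & (g > 0)
    pairs, counts = np.unique(
        np.stack([sp[overlap_mask], g[overlap_mask]]), axis=1, return_counts=True
    )
    # sort so that for each superpixel the (max count, min gold id) wins last-to-first
    order = np.lexsort((pairs[1], -counts, pairs[0]))
    assignment: dict[int, int] = {}
    for idx in order:
        s = int(pairs[0, idx])
        if s not in assignment:
            assignment[s] = int(pairs[1, idx])

    unassigned = [int(s) for s in sp_ids if int(s) not in assignment]
    if unassigned:
        unassigned_group = int(gold.max()) + 1
        warnings.warn(
            f"{len(unassigned)} superpixel(s) overlap only unlabelled gold "
            f"pixels; assigned to dedicated group {unassigned_group}",
            stacklevel=2,
        )
        for s in unassigned:
            assignment[s] = unassigned_group

    if split_disconnected:
        assignment = _split_disconnected_groups(superpixels, assignment)

    groups: dict[int, set[int]] = {}
    for s, grp in assignment.items():
        groups.setdefault(grp, set()).add(s)
    return BestAgglomeration(assignment=assignment, groups=groups)


def _split_disconnected_groups(
    superpixels: np.ndarray, assignment: dict[int, int]
) -> dict[int, int]:
    """Refine groups into adjacency-connected components.

    The first component (smallest member id) keeps the original group id;
    further components get fresh ids above the current maximum.
    """
    adj = _superpixel_adjacency(superpixels)
    next_id = max(assignment.values()) + 1
    refined: dict[int, int] = {}
    seen: set[int] = set()
    by_group: dict[int, list[int]] = {}
    for s, grp in assignment.items():
        by_group.setdefault(grp, []).append(s)
    for grp in sorted(by_group):
        members = sorted(by_group[grp])
        member_set = set(members)
        first_component = True
        for start in members:
            if start in seen:
                continue
            component = {start}
            stack = [start]
            while stack:
                node = stack.pop()
                for nb in adj.get(node, ()):
                    if nb in member_set and nb not in component:
                        component.add(nb)
                        stack.append(nb)
            seen |= component
            if first_component:
                comp_id = grp
                first_component = False
            else:
                comp_id = next_id
                next_id += 1
                logger.info(
                    "group %d disconnected; component of %d superpixel(s) "
                    "re-labelled as group %d",
                    grp,
                    len(component),
                    comp_id,
                )
            for s in component:
                refined[s] = comp_id
    return refined


def make_gold_reference(superpixels: np.ndarray, gold: np.ndarray) -> GoldReference:
    """Per-superpixel purity map for the literal gold-standard labels."""
    sp = superpixels.ravel()
    g = gold.ravel()
    mask = sp > 0
    pure: dict[int, int | None] = {}
    pairs = np.unique(np.stack([sp[mask], g[mask]]), axis=1)
    touched: dict[int, set[int]] = {}
    for s, gl in pairs.T:
        touched.setdefault(int(s), set()).add(int(gl))
    for s, gls in touched.items():
        nonzero = gls - {0}
        pure[s] = nonzero.pop() if len(nonzero) == 1 else None
    return GoldReference(pure=pure)


def merge_label(rag: Rag, u: int, v: int, ref) -> int:
    """+1 should merge, -1 don't merge, 0 don't know (region mixes groups)."""
    rag._edge_data(u, v)  # raises MissingEdgeError if absent
    if isinstance(ref, BestAgglomeration):
        gu = {ref.assignment[s] for s in rag.nodes[u].superpixels}
        gv = {ref.assignment[s] for s in rag.nodes[v].superpixels}
    elif isinstance(ref, GoldReference):
        gu = {ref.pure[s] for s in rag.nodes[u].superpixels}
        gv = {ref.pure[s] for s in rag.nodes[v].superpixels}
        if None in gu or None in gv:
            return 0
    else:
        raise InputError(f"unsupported reference type {type(ref).__name__}")
    if len(gu) > 1 or len(gv) > 1:
        return 0
    return 1 if gu == gv else -1


@dataclass
class TrainingSet:
    """Accumulated (feature vector, label) pairs with provenance.

    ``features`` and ``labels`` hold only the usable +/-1 examples;
    0-labelled "don't know" examples are recorded in ``skipped``.
    Provenance entries are (epoch, edge, label, source) with source in
    {"flat", "epoch", "lash"}.
    """

    features: list[np.ndarray] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    weights: list[float] | None = None
    provenance: list[tuple[int, tuple[int, int], int, str]] = field(default_factory=list)
    skipped: list[tuple[int, tuple[int, int], int, str]] = field(default_factory=list)

    def add(self, feats: np.ndarray, label: int, epoch: int, edge, source: str) -> None:
        edge = tuple(sorted(edge))
        if label == 0:
            self.skipped.append((epoch, edge, 0, source))
        else:
            self.features.append(feats)
            self.labels.append(int(label))
            self.provenance.append((epoch, edge, int(label), source))

    def extend(self, other: "TrainingSet") -> None:
        self.features.extend(other.features)
        self.labels.extend(other.labels)
        self.provenance.extend(other.provenance)
        self.skipped.extend(other.skipped)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array(self.features), np.array(self.labels)

    def class_counts(self) -> dict[int, int]:
        return dict(Counter(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


def flat_learning(rag: Rag, ref, cfg: FeatureConfig, *, epoch: int = 0) -> TrainingSet:
    """One example per labelled edge of the initial graph; no merges."""
    ts = TrainingSet()
    for u, v in rag.edge_list():
        label = merge_label(rag, u, v, ref)
        feats = pair_features(rag, u, v, cfg)
        ts.add(feats, label, epoch, (u, v), "flat")
    if not ts.labels:
        raise DegenerateTrainingError(
            "no +/-1 labelled edges in the initial graph (degenerate volume)"
        )
    return ts


def _node_group(rag: Rag, node: int, astar: BestAgglomeration) -> int:
    groups = {astar.assignment[s] for s in rag.nodes[node].superpixels}
    if len(groups) != 1:
        raise ConsistencyError(f"node {node} mixes best-agglomeration groups {groups}")
    return groups.pop()


def gala_epoch(
    rag: Rag,
    ref,
    policy: Policy,
    *,
    termination_ref: BestAgglomeration | None = None,
    cfg: FeatureConfig | None = None,
    epoch: int = 1,
) -> TrainingSet:
    """One active training epoch on a freshly built graph.

    Pops the policy's best remaining edge, records (pop-time features,
    label), merges only on +1, and terminates exactly when the grouping
    equals the best agglomeration.  A refused (-1 or 0) edge is not
    re-queued until one of its endpoints changes.  ``termination_ref`` must
    be the best agglomeration when ``ref`` is a :class:`GoldReference`.
    """
    cfg = cfg or FeatureConfig(bins=rag.bins)
    astar = termination_ref if termination_ref is not None else ref
    if not isinstance(astar, BestAgglomeration):
        raise InputError(
            "termination requires a BestAgglomeration (pass termination_ref "
            "when labelling against the raw gold standard)"
        )
    group_nodes = Counter(_node_group(rag, n, astar) for n in rag.nodes)
    remaining = sum(c - 1 for c in group_nodes.values())

    ts = TrainingSet()
    heap: list[tuple[float, int, int, int, int]] = []

    def push(pairs):
        pairs = [tuple(sorted(p)) for p in pairs]
        if not pairs:
            return
        scores = policy.score_edges(rag, pairs)
        for (u, v), s in zip(pairs, scores):
            heapq.heappush(
                heap,
                (float(s), u, v, rag.node_version[u], rag.node_version[v]),
            )

    push(rag.edge_list())
    while remaining > 0:
        if not heap:
            raise ConsistencyError(
                f"queue exhausted with {remaining} pending merge(s); "
                f"{len(rag)} nodes for {len(astar.groups)} groups — the "
                "reference is not achievable from this graph"
            )
        s, u, v, vu, vv = heapq.heappop(heap)
        if (
            rag.node_version.get(u) != vu
            or rag.node_version.get(v) != vv
            or not rag.has_edge(u, v)
        ):
            continue
        feats = pair_features(rag, u, v, cfg)
        label = merge_label(rag, u, v, ref)
        # with a gold-standard reference, a +1 edge may still cross two
        # achievable groups (e.g. a gold segment disconnected at superpixel
        # resolution); the merge is then refused to preserve termination
        same_group = _node_group(rag, u, astar) == _node_group(rag, v, astar)
        ts.add(feats, label, epoch, (u, v), "epoch")
        if label == 1 and same_group:
            grp = _node_group(rag, u, astar)
            merged = rag.merge_nodes(u, v)
            group_nodes[grp] -= 1
            remaining -= 1
            if remaining == 0:
                break
            push((merged, w) for w in rag.adjacency[merged])
    return ts


def default_classifier(seed: int, y=None):
    """Seeded random forest with sigmoid-calibrated probability output.

    Agglomeration thresholds the policy's probabilities (canonically at
    0.5), so their scale matters, not just their order.  Raw vote fractions
    inherit the class prior of the training protocol — which for the active
    loop is heavily tilted towards "merge", since every spanning merge
    contributes a positive example — so the forest is wrapped in a sigmoid
    (Platt) calibration fitted by cross-validation.  ``min_samples_leaf``
    smooths the vote fractions the calibrator sees.  Falls back to the bare
    forest when a class is too rare to cross-validate.
    """
    from sklearn.calibration import CalibratedClassifierCV

    forest = RandomForestClassifier(
        n_estimators=100,
        min_samples_leaf=5,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    if y is not None and min(np.bincount((np.asarray(y) > 0).astype(int))) < 3:
        return forest
    return CalibratedClassifierCV(forest, method="sigmoid", cv=3)


def fit_policy(
    train: TrainingSet,
    classifier_factory=None,
    *,
    seed: int = 0,
    cfg: FeatureConfig | None = None,
) -> ClassifierPolicy:
    """Fit the merge classifier; returns a policy scoring P(boundary).

    The default classifier is a seeded random forest with probability
    averaging; any estimator with fit/predict_proba works via
    ``classifier_factory(seed)``.
    """
    X, y = train.to_arrays()
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            "training set contains a single class; provide a volume with both "
            "true and false merge candidates"
        )
    if classifier_factory is None:
        clf = default_classifier(seed, y)
    else:
        clf = classifier_factory(seed)
    clf.fit(X, y)
    return ClassifierPolicy(cfg or FeatureConfig(), clf)


def _initial_policy(name: str, flat_ts: TrainingSet, cfg, classifier_factory, seed):
    if name == "flat":
        return fit_policy(flat_ts, classifier_factory, seed=seed, cfg=cfg)
    if name == "mean":
        return MeanBoundaryPolicy()
    if name == "random":
        return RandomPolicy(seed=seed)
    raise InputError(f"unknown init_policy {name!r}")


def gala_train(
    superpixels: np.ndarray,
    cues,
    gold: np.ndarray,
    *,
    epochs: int = 5,
    cfg: FeatureConfig | None = None,
    classifier_factory=None,
    seed: int = 0,
    label_source: str = "astar",
    init_policy: str = "flat",
    keep_flat: bool = True,
    rag_kwargs: dict | None = None,
) -> tuple[ClassifierPolicy, TrainingSet]:
    """Full active agglomerative training.

    Bootstraps with flat learning, then runs ``epochs`` active epochs, each
    guided by the policy trained on all data accumulated so far (flat
    included unless ``keep_flat=False``).  ``epochs=0`` is flat learning
    with a single fit.  ``label_source="gold"`` labels edges literally
    against the gold standard (0-labelled examples recorded but excluded
    from fitting); the default "astar" labels against the best
    agglomeration, which is 0-free.
    """
    if epochs < 0:
        raise InputError("epochs must be >= 0")
    cfg = cfg or FeatureConfig()
    rag_kwargs = dict(rag_kwargs or {})
    rag_kwargs.setdefault("bins", cfg.bins)
    rag_kwargs.setdefault("midlevel_2d", cfg.use_midlevel_2d)

    astar = best_agglomeration(superpixels, gold)
    ref = astar if label_source == "astar" else make_gold_reference(superpixels, gold)
    if label_source not in ("astar", "gold"):
        raise InputError(f"unknown label_source {label_source!r}")

    rag = Rag(superpixels, cues, **rag_kwargs)
    flat_ts = flat_learning(rag, ref, cfg)
    logger.info("flat learning: %d examples %s", len(flat_ts), flat_ts.class_counts())
    policy = _initial_policy(init_policy, flat_ts, cfg, classifier_factory, seed)
    if epochs == 0:
        if not isinstance(policy, ClassifierPolicy):
            policy = fit_policy(flat_ts, classifier_factory, seed=seed, cfg=cfg)
        return policy, flat_ts

    total = TrainingSet()
    if keep_flat:
        total.extend(flat_ts)
    for e in range(1, epochs + 1):
        rag = Rag(superpixels, cues, **rag_kwargs)
        ts_e = gala_epoch(rag, ref, policy, termination_ref=astar, cfg=cfg, epoch=e)
        total.extend(ts_e)
        logger.info(
            "epoch %d: %d examples %s (cumulative %d)",
            e,
            len(ts_e),
            ts_e.class_counts(),
            len(total),
        )
        policy = fit_policy(total, classifier_factory, seed=seed, cfg=cfg)
    return policy, total


# ------------------------------------------------------------------------ LASH


def _superpixel_gold_overlaps(
    superpixels: np.ndarray, gold: np.ndarray
) -> dict[int, Counter]:
    sp = superpixels.ravel()
    g = gold.ravel()
    mask = (sp > 0) & (g > 0)
    pairs, counts = np.unique(
        np.stack([sp[mask], g[mask]]), axis=1, return_counts=True
    )
    out: dict[int, Counter] = {}
    for (s, gl), c in zip(pairs.T, counts):
        out.setdefault(int(s), Counter())[int(gl)] = int(c)
    return out


def lash_epoch(
    rag: Rag,
    gold: np.ndarray,
    policy: Policy,
    *,
    cfg: FeatureConfig | None = None,
    epoch: int = 1,
) -> TrainingSet:
    """One LASH epoch: merges always proceed, labels are sign(delta RI).

    Follows the policy to completion (single node or exhausted queue).  The
    Rand-index change of merging u and v against the gold standard has the
    sign of ``2 * sum_g c_u(g) c_v(g) - |u||v|`` where ``c_.(g)`` are
    gold-overlap counts (gold-0 pixels excluded); zero-change merges are
    recorded as skipped.
    """
    cfg = cfg or FeatureConfig(bins=rag.bins)
    sp_overlaps = _superpixel_gold_overlaps(rag.labels, gold)
    node_overlap: dict[int, Counter] = {}
    for n, stats in rag.nodes.items():
        c: Counter = Counter()
        for s in stats.superpixels:
            c.update(sp_overlaps.get(s, {}))
        node_overlap[n] = c

    ts = TrainingSet()
    heap: list[tuple[float, int, int, int, int]] = []

    def push(pairs):
        pairs = [tuple(sorted(p)) for p in pairs]
        if not pairs:
            return
        scores = policy.score_edges(rag, pairs)
        for (u, v), s in zip(pairs, scores):
            heapq.heappush(
                heap, (float(s), u, v, rag.node_version[u], rag.node_version[v])
            )

    push(rag.edge_list())
    while heap:
        s, u, v, vu, vv = heapq.heappop(heap)
        if (
            rag.node_version.get(u) != vu
            or rag.node_version.get(v) != vv
            or not rag.has_edge(u, v)
        ):
            continue
        feats = pair_features(rag, u, v, cfg)
        cu, cv = node_overlap[u], node_overlap[v]
        nu, nv = sum(cu.values()), sum(cv.values())
        cross = sum(cu[g] * cv[g] for g in cu if g in cv)
        delta = 2 * cross - nu * nv
        label = 1 if delta > 0 else (-1 if delta < 0 else 0)
        ts.add(feats, label, epoch, (u, v), "lash")
        merged = rag.merge_nodes(u, v)
        dead = u + v - merged
        node_overlap[merged] = cu + cv
        node_overlap.pop(dead, None)
        push((merged, w) for w in rag.adjacency[merged])
    return ts


def lash_train(
    superpixels: np.ndarray,
    cues,
    gold: np.ndarray,
    *,
    epochs: int = 5,
    cfg: FeatureConfig | None = None,
    classifier_factory=None,
    seed: int = 0,
    init_policy: str = "flat",
    rag_kwargs: dict | None = None,
) -> tuple[ClassifierPolicy, TrainingSet]:
    """LASH training: per the protocol, only the last epoch's data is fitted."""
    if epochs < 1:
        raise InputError("lash_train requires epochs >= 1")
    cfg = cfg or FeatureConfig()
    rag_kwargs = dict(rag_kwargs or {})
    rag_kwargs.setdefault("bins", cfg.bins)
    rag_kwargs.setdefault("midlevel_2d", cfg.use_midlevel_2d)

    rag = Rag(superpixels, cues, **rag_kwargs)
    astar = best_agglomeration(superpixels, gold)
    flat_ts = flat_learning(rag, astar, cfg)
    policy = _initial_policy(init_policy, flat_ts, cfg, classifier_factory, seed)
    ts_e = flat_ts
    for e in range(1, epochs + 1):
        rag = Rag(superpixels, cues, **rag_kwargs)
        ts_e = lash_epoch(rag, gold, policy, cfg=cfg, epoch=e)
        policy = fit_policy(ts_e, classifier_factory, seed=seed, cfg=cfg)
    return policy, ts_e
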