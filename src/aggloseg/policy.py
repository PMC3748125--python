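"""Merge priority policies.

A policy assigns every RAG edge a score in [0, 1] interpreted as a merge
priority: low scores merge first, and agglomeration stops at a threshold.
The score behaves like the probability that the edge is a true boundary
(for a trained classifier it is exactly ``1 - P(merge)``), which makes the
mean-boundary baseline, the learned policies and the canonical 0.5
operating point directly comparable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import joblib
import numpy as np

from .errors import SchemaError
from .features import FeatureConfig, pair_features
from .rag import Rag

__all__ = [
    "Policy",
    "MeanBoundaryPolicy",
    "RandomPolicy",
    "ClassifierPolicy",
    "save_policy",
    "load_policy",
]

MODEL_FORMAT_VERSION = 1


class Policy:
    """Interface: score edges of a RAG; low score = merge first."""

    def score(self, rag: Rag, u: int, v: int) -> float:
        return float(self.score_edges(rag, [(u, v)])[0])

    def score_edges(self, rag: Rag, pairs) -> np.ndarray:
        raise NotImplementedError

    def validate(self, rag: Rag) -> None:
        """Raise SchemaError if the policy cannot score this graph."""


@dataclass
class MeanBoundaryPolicy(Policy):
    """Score = mean value of the designated boundary cue over the edge."""

    channel: int = 0

    def score_edges(self, rag: Rag, pairs) -> np.ndarray:
        return np.array(
            [rag.edge_stats(u, v).mean[self.channel] for u, v in pairs]
        )

    def validate(self, rag: Rag) -> None:
        if not 0 <= self.channel < rag.n_channels:
            raise SchemaError(
                f"boundary channel {self.channel} not in graph with "
                f"{rag.n_channels} channel(s)"
            )


@dataclass
class RandomPolicy(Policy):
    """Deterministic pseudo-random scores, keyed by (seed, edge).

    Useful as the initial policy of the first training epoch: any ordering
    works because labels come from the reference, not from the scores.
    """

    seed: int = 0

    def score_edges(self, rag: Rag, pairs) -> np.ndarray:
        return np.array(
            [
                np.random.default_rng([self.seed, u, v]).random()
                for u, v in (sorted(p) for p in pairs)
            ]
        )


class ClassifierPolicy(Policy):
    """Feature map + fitted probabilistic classifier.

    ``classifier`` must expose ``predict_proba`` over the feature vectors of
    :func:`aggloseg.features.pair_features`; training labels are +1 (merge)
    and -1 (boundary).  ``score`` returns P(-1), the boundary probability.
    """

    def __init__(self, feature_config: FeatureConfig, classifier, *, version: int = MODEL_FORMAT_VERSION):
        self.feature_config = feature_config
        self.classifier = classifier
        self.version = version
        classes = list(getattr(classifier, "classes_", []))
        if sorted(classes) != [-1, 1]:
            raise SchemaError(f"classifier must be fitted on classes -1/+1, got {classes}")
        self._boundary_col = classes.index(-1)

    def features(self, rag: Rag, pairs) -> np.ndarray:
        return np.array([pair_features(rag, u, v, self.feature_config) for u, v in pairs])

    def score_edges(self, rag: Rag, pairs) -> np.ndarray:
        X = self.features(rag, pairs)
        proba = self.classifier.predict_proba(X)
        return proba[:, self._boundary_col]

    def predict_merge_proba(self, rag: Rag, pairs) -> np.ndarray:
        return 1.0 - self.score_edges(rag, pairs)

    def validate(self, rag: Rag) -> None:
        cfg = self.feature_config
        if cfg.bins != rag.bins:
            raise SchemaError(
                f"model expects {cfg.bins} histogram bins, graph has {rag.bins}"
            )
        channels = cfg.channels if cfg.channels is not None else range(rag.n_channels)
        bad = [c for c in channels if c >= rag.n_channels]
        if bad or (cfg.channels is None and rag.n_channels == 0):
            raise SchemaError(
                f"model channels {list(channels)} exceed graph channels "
                f"{rag.n_channels}"
            )
        if cfg.use_midlevel_2d and (rag.ndim != 2 or not rag.midlevel_2d):
            raise SchemaError("model uses 2D mid-level features; graph does not")


def save_policy(policy: ClassifierPolicy, path, *, metadata: dict | None = None) -> None:
    """Persist a trained policy: classifier, feature schema, provenance."""
    payload = {
        "format_version": policy.version,
        "feature_config": asdict(policy.feature_config),
        "classifier": policy.classifier,
        "metadata": metadata or {},
    }
    joblib.dump(payload, path)


def load_policy(path) -> ClassifierPolicy:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise SchemaError(
            f"unsupported model format version {payload.get('format_version')}"
        )
    cfg = payload["feature_config"]
    cfg["channels"] = tuple(cfg["channels"]) if cfg["channels"] is not None else None
    return ClassifierPolicy(FeatureConfig(**cfg), payload["classifier"])
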