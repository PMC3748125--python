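"""Region adjacency graph (RAG) over a superpixel label volume.

The RAG is the central data structure of agglomerative segmentation: one node
per current region (initially one per superpixel), and an edge between two
nodes whenever their regions touch.  Every node and edge carries cached
summary statistics of one or more real-valued pixel "cue" maps (boundary
probability, cytoplasm/texture channels, ...) so that merge features can be
computed in time independent of region size.

Conventions
-----------
* Arrays are indexed ``(z, )y, x`` with 0-based coordinates; dimension is 2
  or 3.
* Label 0, if present, is reserved background / watershed-line and owns no
  region.
* Adjacency is face connectivity only: 4-connectivity in 2D, 6-connectivity
  in 3D.  Diagonal contact does not create an edge.
* The boundary of an edge ``(u, v)`` is two-sided ("thick"): the pixels of
  either region with a face neighbour in the other region.  For superpixel
  maps with 0-labelled watershed lines, ``boundary_mode="ridge"`` instead
  samples the 0-pixels adjacent to both regions (and also connects regions
  that only touch through such a line).
* A merged node keeps the smaller of the two ids, so node ids are always
  drawn from the original superpixel ids and merge histories are
  reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial._qhull import QhullError

from .errors import ConsistencyError, InputError, MissingEdgeError

__all__ = [
    "Rag",
    "Stats",
    "NodeStats",
    "build_rag",
    "boundary_pixels",
    "merge_nodes",
    "current_segmentation",
]


def _edge_key(u: int, v: int) -> tuple[int, int]:
    return (u, v) if u < v else (v, u)


@dataclass
class Stats:
    """Cue statistics of a pixel set: histogram and raw power sums.

    ``hist`` has shape (n_channels, bins) over the fixed range [0, 1];
    ``pow_sums`` has shape (n_channels, 4) holding sums of v, v^2, v^3, v^4.
    Central moments are derived on demand, so combining two disjoint pixel
    sets is plain addition.
    """

    n: int
    hist: np.ndarray
    pow_sums: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.pow_sums[:, 0] / self.n

    def central_moments(self) -> np.ndarray:
        """Central moments 2..4 per channel, shape (n_channels, 3)."""
        n = self.n
        s1, s2, s3, s4 = (self.pow_sums[:, k] for k in range(4))
        m = s1 / n
        m2 = s2 / n - m**2
        m3 = s3 / n - 3 * m * s2 / n + 2 * m**3
        m4 = s4 / n - 4 * m * s3 / n + 6 * m**2 * s2 / n - 3 * m**4
        return np.stack([m2, m3, m4], axis=1)

    def normalized_hist(self) -> np.ndarray:
        return self.hist / self.n

    def add_(self, other: "Stats") -> None:
        self.n += other.n
        self.hist += other.hist
        self.pow_sums += other.pow_sums


@dataclass
class NodeStats(Stats):
    """Region statistics: cue stats plus spatial accumulators.

    ``coord_sum`` accumulates pixel coordinates for the centroid.  The
    second-moment accumulators and convex-hull vertices are maintained only
    in 2D when mid-level features are enabled (they are the memory-heavy
    part and irrelevant for the 3D EM-style feature set).
    """

    superpixels: set[int] = field(default_factory=set)
    coord_sum: np.ndarray | None = None
    sq_sum: np.ndarray | None = None  # 2D only: sums of y^2, x^2, y*x
    hull_points: np.ndarray | None = None  # 2D only: hull vertex coords

    def merge_node_(self, other: "NodeStats") -> None:
        self.add_(other)
        self.superpixels |= other.superpixels
        self.coord_sum = self.coord_sum + other.coord_sum
        if self.sq_sum is not None:
            self.sq_sum = self.sq_sum + other.sq_sum
        if self.hull_points is not None:
            pts = np.vstack([self.hull_points, other.hull_points])
            self.hull_points = _hull_vertices(pts)


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of a 2D point cloud (fallback: the points)."""
    if len(points) < 3:
        return points
    try:
        hull = ConvexHull(points)
    except QhullError:
        return points
    return points[hull.vertices]


def _pixel_corner_points(coords: np.ndarray) -> np.ndarray:
    """Corner points of unit-square pixels centred on integer coords."""
    offsets = np.array(list(itertools.product((-0.5, 0.5), repeat=2)))
    return (coords[:, None, :] + offsets[None, :, :]).reshape(-1, 2)


@dataclass
class _EdgeData:
    """Boundary bookkeeping for one edge.

    ``pixels`` is the set of flat indices forming the edge's boundary
    (two-sided contact pixels in ``thick`` mode, shared 0-pixels in
    ``ridge`` mode).  Cue statistics over the set are computed lazily and
    cached; merging two edges unions the pixel sets (a pixel adjacent to
    both merged partners must count once), which keeps the cached stats
    exactly equal to a from-scratch recomputation.
    """

    pixels: set[int]
    _stats: Stats | None = None

    def invalidate(self) -> None:
        self._stats = None


class Rag:
    """Region adjacency graph with cached region/boundary statistics.

    Parameters
    ----------
    superpixels : ndarray of non-negative int, 2D or 3D
        Initial oversegmentation. 0 is background/boundary and owns no node.
    cues : array or list of arrays in [0, 1], same shape as ``superpixels``
        Pixel-level cue maps; the first is conventionally the boundary
        probability.
    bins : int
        Histogram bin count over [0, 1] (10 or 25 are the standard choices).
    boundary_mode : {"thick", "ridge"}
        Edge-boundary convention, see module docstring.
    midlevel_2d : bool
        Maintain second-moment accumulators and hull vertices (2D only).
    clamp_cues : bool
        Clamp out-of-range cue values into [0, 1] instead of raising.
    """

    def __init__(
        self,
        superpixels: np.ndarray,
        cues,
        *,
        bins: int = 25,
        boundary_mode: str = "thick",
        midlevel_2d: bool = False,
        clamp_cues: bool = False,
    ):
        superpixels = np.asarray(superpixels)
        if superpixels.ndim not in (2, 3):
            raise InputError(f"label volume must be 2D or 3D, got {superpixels.ndim}D")
        if not np.issubdtype(superpixels.dtype, np.integer):
            raise InputError("label volume must have an integer dtype")
        if superpixels.min() < 0:
            raise InputError("label volume must be non-negative")
        if boundary_mode not in ("thick", "ridge"):
            raise InputError(f"unknown boundary_mode {boundary_mode!r}")
        if isinstance(cues, np.ndarray) and cues.shape == superpixels.shape:
            cues = [cues]
        cues = [np.asarray(c, dtype=np.float64) for c in cues]
        if not cues:
            raise InputError("at least one cue map is required")
        for c in cues:
            if c.shape != superpixels.shape:
                raise InputError(
                    f"cue shape {c.shape} does not match labels {superpixels.shape}"
                )
        cue_flat = np.stack([c.ravel() for c in cues])
        if clamp_cues:
            np.clip(cue_flat, 0.0, 1.0, out=cue_flat)
        elif cue_flat.min() < 0.0 or cue_flat.max() > 1.0:
            raise InputError("cue values outside [0, 1]; pass clamp_cues=True to clamp")

        self.labels = superpixels
        self.shape = superpixels.shape
        self.ndim = superpixels.ndim
        self.cue_flat = cue_flat  # (n_channels, n_pixels)
        self.n_channels = len(cues)
        self.bins = int(bins)
        self.boundary_mode = boundary_mode
        self.midlevel_2d = bool(midlevel_2d) and superpixels.ndim == 2

        self.nodes: dict[int, NodeStats] = {}
        self.edges: dict[tuple[int, int], _EdgeData] = {}
        self.adjacency: dict[int, set[int]] = {}
        self.superpixel_to_node: dict[int, int] = {}
        self.node_version: dict[int, int] = {}

        self._build_nodes()
        self._build_edges()

    # ------------------------------------------------------------------ build

    def _build_nodes(self) -> None:
        lab = self.labels.ravel()
        nz = np.flatnonzero(lab)
        if nz.size == 0:
            raise InputError("label volume contains no non-zero superpixels")
        ids, inv = np.unique(lab[nz], return_inverse=True)
        k = len(ids)
        bins = self.bins
        counts = np.bincount(inv, minlength=k)
        hists = np.zeros((k, self.n_channels, bins))
        pows = np.zeros((k, self.n_channels, 4))
        for c in range(self.n_channels):
            v = self.cue_flat[c, nz]
            bin_idx = np.minimum((v * bins).astype(np.intp), bins - 1)
            hists[:, c, :] = np.bincount(
                inv * bins + bin_idx, minlength=k * bins
            ).reshape(k, bins)
            vp = v.copy()
            for p in range(4):
                pows[:, c, p] = np.bincount(inv, weights=vp, minlength=k)
                if p < 3:
                    vp *= v
        coords = np.stack(np.unravel_index(nz, self.shape), axis=1).astype(np.float64)
        coord_sums = np.stack(
            [np.bincount(inv, weights=coords[:, d], minlength=k) for d in range(self.ndim)],
            axis=1,
        )
        sq_sums = None
        if self.midlevel_2d:
            y, x = coords[:, 0], coords[:, 1]
            sq_sums = np.stack(
                [
                    np.bincount(inv, weights=y * y, minlength=k),
                    np.bincount(inv, weights=x * x, minlength=k),
                    np.bincount(inv, weights=y * x, minlength=k),
                ],
                axis=1,
            )
            order = np.argsort(inv, kind="stable")
            splits = np.cumsum(counts)[:-1]
            coord_groups = np.split(coords[order], splits)
        for i, sp in enumerate(ids):
            sp = int(sp)
            node = NodeStats(
                n=int(counts[i]),
                hist=hists[i],
                pow_sums=pows[i],
                superpixels={sp},
                coord_sum=coord_sums[i],
            )
            if self.midlevel_2d:
                node.sq_sum = sq_sums[i]
                node.hull_points = _hull_vertices(_pixel_corner_points(coord_groups[i]))
            self.nodes[sp] = node
            self.adjacency[sp] = set()
            self.superpixel_to_node[sp] = sp
            self.node_version[sp] = 0

    def _face_pairs(self):
        """Yield (labels_a, labels_b, flat_a, flat_b) for every face contact."""
        lab = self.labels
        flat_index = np.arange(lab.size).reshape(self.shape)
        for axis in range(self.ndim):
            sl1 = [slice(None)] * self.ndim
            sl2 = [slice(None)] * self.ndim
            sl1[axis] = slice(None, -1)
            sl2[axis] = slice(1, None)
            a, b = lab[tuple(sl1)], lab[tuple(sl2)]
            ia, ib = flat_index[tuple(sl1)], flat_index[tuple(sl2)]
            yield a.ravel(), b.ravel(), ia.ravel(), ib.ravel()

    def _build_edges(self) -> None:
        edge_pixels: dict[tuple[int, int], set[int]] = {}
        zero_contacts: dict[tuple[int, int], set[int]] = {}
        zero_neighbors: dict[int, set[int]] = {}
        for a, b, ia, ib in self._face_pairs():
            contact = (a != b) & (a > 0) & (b > 0)
            for la, lb, pa, pb in zip(a[contact], b[contact], ia[contact], ib[contact]):
                key = _edge_key(int(la), int(lb))
                s = edge_pixels.setdefault(key, set())
                s.add(int(pa))
                s.add(int(pb))
            if self.boundary_mode == "ridge":
                za = (a == 0) & (b > 0)
                for pz, lb in zip(ia[za], b[za]):
                    zero_neighbors.setdefault(int(pz), set()).add(int(lb))
                zb = (b == 0) & (a > 0)
                for pz, la in zip(ib[zb], a[zb]):
                    zero_neighbors.setdefault(int(pz), set()).add(int(la))
        if self.boundary_mode == "ridge":
            for pz, labs in zero_neighbors.items():
                for u, v in itertools.combinations(sorted(labs), 2):
                    zero_contacts.setdefault((u, v), set()).add(pz)
            # ridge pixels define the boundary where available; direct-contact
            # pixels are the fallback so every edge has a non-empty boundary
            keys = set(edge_pixels) | set(zero_contacts)
            merged: dict[tuple[int, int], set[int]] = {}
            for key in keys:
                merged[key] = zero_contacts.get(key) or edge_pixels.get(key) or set()
            edge_pixels = merged
        for (u, v), pixels in edge_pixels.items():
            self.edges[(u, v)] = _EdgeData(pixels=pixels)
            self.adjacency[u].add(v)
            self.adjacency[v].add(u)

    # ------------------------------------------------------------------ stats

    def _stats_from_flat(self, flat_idx: np.ndarray) -> Stats:
        bins = self.bins
        hist = np.zeros((self.n_channels, bins))
        pows = np.zeros((self.n_channels, 4))
        for c in range(self.n_channels):
            v = self.cue_flat[c, flat_idx]
            bin_idx = np.minimum((v * bins).astype(np.intp), bins - 1)
            hist[c] = np.bincount(bin_idx, minlength=bins)
            pows[c] = [v.sum(), (v**2).sum(), (v**3).sum(), (v**4).sum()]
        return Stats(n=len(flat_idx), hist=hist, pow_sums=pows)

    def edge_stats(self, u: int, v: int) -> Stats:
        """Cue statistics over the boundary pixels of edge (u, v)."""
        data = self._edge_data(u, v)
        if data._stats is None:
            idx = np.fromiter(data.pixels, dtype=np.intp, count=len(data.pixels))
            idx.sort()
            data._stats = self._stats_from_flat(idx)
        return data._stats

    def _edge_data(self, u: int, v: int) -> _EdgeData:
        try:
            return self.edges[_edge_key(u, v)]
        except KeyError:
            raise MissingEdgeError(f"no edge between nodes {u} and {v}") from None

    def has_edge(self, u: int, v: int) -> bool:
        return _edge_key(u, v) in self.edges

    def boundary_pixels(self, u: int, v: int) -> set[tuple[int, ...]]:
        """Coordinates of the boundary pixels of edge (u, v)."""
        data = self._edge_data(u, v)
        return {
            tuple(int(c) for c in np.unravel_index(p, self.shape)) for p in data.pixels
        }

    def boundary_pixel_count(self, u: int, v: int) -> int:
        return len(self._edge_data(u, v).pixels)

    # ------------------------------------------------------------------ merge

    def merge_nodes(self, u: int, v: int) -> int:
        """Merge regions u and v; the smaller id survives and is returned.

        Node statistics add; the (u, v) boundary is absorbed into the merged
        interior; edges to a common neighbour w are unioned.
        """
        if u == v:
            raise InputError(f"cannot merge node {u} with itself")
        self._edge_data(u, v)  # raises MissingEdgeError if absent
        survivor, dead = (u, v) if u < v else (v, u)

        self.edges.pop((survivor, dead))
        self.adjacency[survivor].discard(dead)
        self.adjacency[dead].discard(survivor)

        for w in list(self.adjacency[dead]):
            old = self.edges.pop(_edge_key(dead, w))
            self.adjacency[w].discard(dead)
            new_key = _edge_key(survivor, w)
            if new_key in self.edges:
                kept = self.edges[new_key]
                kept.pixels |= old.pixels
                kept.invalidate()
            else:
                old.invalidate()
                self.edges[new_key] = old
                self.adjacency[survivor].add(w)
                self.adjacency[w].add(survivor)

        self.nodes[survivor].merge_node_(self.nodes[dead])
        for sp in self.nodes[dead].superpixels:
            self.superpixel_to_node[sp] = survivor
        del self.nodes[dead]
        del self.adjacency[dead]
        del self.node_version[dead]
        self.node_version[survivor] += 1
        return survivor

    # ---------------------------------------------------------------- outputs

    def current_segmentation(self, original: np.ndarray | None = None) -> np.ndarray:
        """Relabel the (original) superpixel volume with current node ids.

        Pixels labelled 0 in the input stay 0.
        """
        if original is None:
            original = self.labels
        present = np.unique(original)
        present = present[present > 0]
        missing = [int(s) for s in present if int(s) not in self.superpixel_to_node]
        if missing:
            raise ConsistencyError(
                f"superpixel ids {missing[:5]} absent from the graph"
            )
        lut = np.zeros(int(present.max()) + 1, dtype=original.dtype)
        for sp, node in self.superpixel_to_node.items():
            if sp <= present.max():
                lut[sp] = node
        return lut[original]

    def grouping(self) -> dict[int, frozenset[int]]:
        """Current node -> member-superpixel partition."""
        return {n: frozenset(st.superpixels) for n, st in self.nodes.items()}

    def edge_list(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def __len__(self) -> int:
        return len(self.nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Rag(nodes={len(self.nodes)}, edges={len(self.edges)}, "
            f"channels={self.n_channels}, shape={self.shape})"
        )


# Functional aliases mirroring the operation-style API.


def build_rag(superpixels: np.ndarray, cues, **kwargs) -> Rag:
    """Build a region adjacency graph; see :class:`Rag`."""
    return Rag(superpixels, cues, **kwargs)


def boundary_pixels(rag: Rag, u: int, v: int) -> set[tuple[int, ...]]:
    return rag.boundary_pixels(u, v)


def merge_nodes(rag: Rag, u: int, v: int) -> int:
    return rag.merge_nodes(u, v)


def current_segmentation(rag: Rag, original: np.ndarray | None = None) -> np.ndarray:
    return rag.current_segmentation(original)
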