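"""Expression signals at cell, niche and territory scale.

The mapping cost compares cells through expression "signals" extracted at
three spatial scales.  The cell-scale signal is the (normalised) expression
profile of the cell itself, usually restricted to highly variable genes or
replaced by an embedding.  The niche-scale signal replaces each cell's
profile with the mean profile of its spatial neighbourhood, and the
territory-scale signal with the mean profile over the larger spatial domain
the cell sits in.

Niches can be defined by k-nearest neighbours, by graph depth on the
Delaunay triangulation (the dual of the Voronoi tessellation), or by a
radius in coordinate units.
"""

from __future__ import annotations

from collections import deque
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .datasets import NicheAssignment, SignalMatrix, SpatialDataset

__all__ = [
    "normalize_counts",
    "select_variable_features",
    "expression_signal",
    "compute_embedding",
    "extract_niches",
    "niche_signal",
    "assign_territories",
    "territory_signal",
    "delaunay_adjacency",
]


# ---------------------------------------------------------------------------
# normalisation and feature selection
# ---------------------------------------------------------------------------

def normalize_counts(d: SpatialDataset, method: str = "lognorm") -> SpatialDataset:
    """Attach a normalised layer to the dataset.

    ``lognorm`` scales every cell to the median library size and applies
    log1p.  ``tfidf`` computes term-frequency × inverse-document-frequency
    with genes as terms and cells as documents.
    """
    counts = d.counts_dense()
    libsize = counts.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if len(zero):
        raise ValueError(
            f"cells with zero total counts cannot be normalised: "
            f"{d.barcodes[zero][:5].tolist()}"
        )
    if method == "lognorm":
        target = float(np.median(libsize))
        normalized = np.log1p(counts / libsize * target)
    elif method == "tfidf":
        tf = counts / libsize
        n_cells = d.n_cells
        df = (counts > 0).sum(axis=1)
        idf = np.log(1.0 + n_cells / (1.0 + df))
        normalized = tf * idf[:, None]
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    return d.with_(normalized=normalized)


def select_variable_features(d: SpatialDataset, n: int = 2000) -> np.ndarray:
    """Top-``n`` genes ranked by dispersion (variance / mean) of the
    normalised layer.  Deterministic: ties broken by gene order."""
    if d.normalized is None:
        raise ValueError("normalise counts before selecting variable features")
    if n > d.n_genes:
        raise ValueError(f"requested {n} features but only {d.n_genes} genes present")
    values = d.normalized
    mean = values.mean(axis=1)
    var = values.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(-dispersion, kind="stable")
    return d.genes[order[:n]]


def expression_signal(
    d: SpatialDataset, features: Optional[Sequence[str]] = None
) -> SignalMatrix:
    """Cell-scale signal: normalised expression restricted to ``features``."""
    if d.normalized is None:
        raise ValueError("normalise counts before extracting a signal")
    feats = np.asarray(list(features), dtype=object) if features is not None else d.genes
    idx = {g: i for i, g in enumerate(d.genes)}
    missing = [f for f in feats if f not in idx]
    if missing:
        raise KeyError(f"features absent from dataset: {missing[:5]}")
    rows = np.array([idx[f] for f in feats], dtype=int)
    return SignalMatrix(
        level="cell", values=d.normalized[rows], feature_ids=feats, barcodes=d.barcodes
    )


def compute_embedding(
    d: SpatialDataset,
    method: str = "pca",
    dims: int = 30,
    features: Optional[Sequence[str]] = None,
    random_state: int = 0,
) -> SignalMatrix:
    """Principal-component scores on centred (normalised) features.

    Returns a dims × cells cell-level signal whose feature ids are PC names.
    """
    if method != "pca":
        raise ValueError(f"unknown embedding method {method!r}")
    base = expression_signal(d, features)
    n_feat, n_cells = base.values.shape
    if dims > min(n_feat, n_cells):
        raise ValueError(
            f"dims={dims} exceeds min(n_features={n_feat}, n_cells={n_cells})"
        )
    model = PCA(n_components=dims, svd_solver="full", random_state=random_state)
    scores = model.fit_transform(base.values.T)  # cells × dims
    names = np.asarray([f"PC{i + 1}" for i in range(dims)], dtype=object)
    return SignalMatrix(
        level="cell", values=scores.T, feature_ids=names, barcodes=d.barcodes
    )


# ---------------------------------------------------------------------------
# niches
# ---------------------------------------------------------------------------

def delaunay_adjacency(
    coords: np.ndarray, prune_quantile: float = 0.99
) -> sp.csr_matrix:
    """Symmetric adjacency of the Delaunay triangulation (Voronoi dual).

    Edges longer than the given quantile of all edge lengths are removed to
    avoid spurious long-range adjacency along the convex hull.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 4:
        raise ValueError("Delaunay adjacency requires at least 4 points")
    tri = Delaunay(coords)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    edges = np.array(sorted(edges), dtype=int)
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    if prune_quantile is not None and len(lengths) > 1:
        cutoff = np.quantile(lengths, prune_quantile)
        edges = edges[lengths <= cutoff]
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.ones(len(rows), dtype=np.int8)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def _graph_depth_neighbors(adj: sp.csr_matrix, depth: int) -> list:
    """Breadth-first neighbourhoods to the given depth (centre excluded)."""
    indptr, indices = adj.indptr, adj.indices
    n = adj.shape[0]
    out = []
    for start in range(n):
        seen = {start}
        frontier = deque([(start, 0)])
        members = []
        while frontier:
            node, dist = frontier.popleft()
            if dist == depth:
                continue
            for nb in indices[indptr[node] : indptr[node + 1]]:
                if nb not in seen:
                    seen.add(nb)
                    members.append(nb)
                    frontier.append((nb, dist + 1))
        out.append(np.asarray(sorted(members), dtype=int))
    return out


def extract_niches(
    d: SpatialDataset,
    method: str = "knn",
    k: int = 6,
    depth: int = 1,
    radius: float = None,
    include_center: bool = True,
    prune_quantile: float = 0.99,
) -> NicheAssignment:
    """Spatial neighbourhoods per cell.

    ``knn``: the k nearest cells (centre excluded from the k).
    ``graph``: all cells within the given depth on the Delaunay graph.
    ``radius``: all other cells within ``radius`` of the centre.
    """
    n = d.n_cells
    if method == "knn":
        if not 1 <= k < n:
            raise ValueError(f"knn requires 1 <= k < n_cells; got k={k}, n={n}")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(d.coords)
        _, idx = nn.kneighbors(d.coords)
        neighbors = [row[row != i][:k] for i, row in enumerate(idx)]
        parameter = float(k)
    elif method == "graph":
        if depth < 1:
            raise ValueError("graph depth must be >= 1")
        adj = delaunay_adjacency(d.coords, prune_quantile=prune_quantile)
        neighbors = _graph_depth_neighbors(adj, depth)
        parameter = float(depth)
    elif method == "radius":
        if radius is None or radius <= 0:
            raise ValueError("radius must be positive")
        tree = cKDTree(d.coords)
        balls = tree.query_ball_point(d.coords, r=radius)
        neighbors = [
            np.asarray(sorted(set(b) - {i}), dtype=int) for i, b in enumerate(balls)
        ]
        parameter = float(radius)
    else:
        raise ValueError(f"unknown niche method {method!r}")
    return NicheAssignment(
        method=method, parameter=parameter, neighbors=neighbors, include_center=include_center
    )


def niche_signal(
    d: SpatialDataset,
    niches: NicheAssignment,
    base: SignalMatrix,
    fallback_to_cell: bool = False,
) -> SignalMatrix:
    """Niche-scale signal: column c = mean of base columns over the niche of c."""
    if base.level != "cell":
        raise ValueError("niche_signal requires a cell-level base signal")
    if niches.n_cells != base.n_cells:
        raise ValueError("niche assignment and signal cover different cell sets")
    values = np.empty_like(base.values)
    for i in range(niches.n_cells):
        members = niches.members(i)
        if len(members) == 0:
            if fallback_to_cell:
                members = np.array([i])
            else:
                raise ValueError(
                    f"cell {base.barcodes[i]!r} has an empty niche; "
                    "set fallback_to_cell=True or include the centre"
                )
        values[:, i] = base.values[:, members].mean(axis=1)
    return SignalMatrix(
        level="niche", values=values, feature_ids=base.feature_ids, barcodes=base.barcodes
    )


# ---------------------------------------------------------------------------
# territories
# ---------------------------------------------------------------------------

def assign_territories(
    d: SpatialDataset,
    source: str = "provided",
    embedding: Optional[SignalMatrix] = None,
    k: int = 5,
    random_state: int = 0,
    prune_quantile: float = 0.99,
) -> SpatialDataset:
    """Attach territory labels to every cell.

    ``provided`` passes through labels already on the dataset.  ``fallback``
    runs k-means on the embedding and then splits each expression cluster
    into spatially connected components on the Delaunay graph, so a single
    territory label never spans disconnected regions.  The fallback is an
    approximation to image-based territory segmentation, intended for data
    without curated domain annotations.
    """
    if source == "provided":
        if d.territory_labels is None:
            raise ValueError("source='provided' but dataset has no territory labels")
        return d
    if source != "fallback":
        raise ValueError(f"unknown territory source {source!r}")
    if embedding is None:
        raise ValueError("fallback territory detection requires an embedding")
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    clusters = km.fit_predict(embedding.values.T)
    adj = delaunay_adjacency(d.coords, prune_quantile=prune_quantile)
    labels = np.empty(d.n_cells, dtype=object)
    for c in np.unique(clusters):
        mask = clusters == c
        sub = adj[mask][:, mask]
        n_comp, comp = connected_components(sub, directed=False)
        idx = np.flatnonzero(mask)
        for j, cell in enumerate(idx):
            labels[cell] = f"{c}.{comp[j]}" if n_comp > 1 else str(c)
    return d.with_(territory_labels=labels)


def territory_signal(d: SpatialDataset, base: SignalMatrix) -> SignalMatrix:
    """Territory-scale signal: column c = mean base column over c's territory."""
    if d.territory_labels is None:
        raise ValueError("dataset has no territory labels")
    if base.n_cells != d.n_cells:
        raise ValueError("signal and dataset cover different cell sets")
    values = np.empty_like(base.values)
    labels = d.territory_labels.astype(str)
    for t in np.unique(labels):
        mask = labels == t
        values[:, mask] = base.values[:, mask].mean(axis=1, keepdims=True)
    return SignalMatrix(
        level="territory",
        values=values,
        feature_ids=base.feature_ids,
        barcodes=base.barcodes,
    )
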