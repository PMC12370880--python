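"""Core in-memory containers for spatial omics samples and derived signals.

A :class:`SpatialDataset` bundles a genes × cells count matrix with 2-D cell
coordinates and optional per-cell annotation tracks (cell type, territory,
interaction labels).  Coordinates are treated as continuous points in
arbitrary units — no grid assumption is made, so spot-, bin- and
cell-resolved assays are all representable.

:class:`SignalMatrix` holds an expression "signal" at one of three spatial
scales (cell, niche, territory): a features × cells real matrix whose columns
are compared across samples via Pearson correlation when building mapping
costs.  :class:`NicheAssignment` records, for every cell, the set of spatial
neighbours under a stated method (k-nearest neighbours, Delaunay-graph depth,
or radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["SpatialDataset", "SignalMatrix", "NicheAssignment"]

SIGNAL_LEVELS = ("cell", "niche", "territory")
NICHE_METHODS = ("knn", "graph", "radius")


def _as_str_array(values: Sequence) -> np.ndarray:
    return np.asarray(values, dtype=object)


@dataclass
class SpatialDataset:
    """One spatial sample: counts, coordinates and optional label tracks.

    Parameters
    ----------
    sample_id : str
        Identifier for the sample.
    barcodes : array of str, shape (n_cells,)
        Unique cell identifiers; column order of ``counts``.
    coords : array, shape (n_cells, 2)
        Per-cell (x, y) coordinates in arbitrary units.
    counts : genes × cells matrix (dense ndarray or scipy sparse)
        Non-negative integer counts.
    genes : array of str, shape (n_genes,)
        Gene identifiers; row order of ``counts``.
    normalized : optional genes × cells real matrix
        Normalised expression layer (same shape/order as ``counts``).
    cell_labels, interaction_labels, territory_labels : optional arrays
        Per-cell categories aligned with ``barcodes``.
    """

    sample_id: str
    barcodes: np.ndarray
    coords: np.ndarray
    counts: "sp.spmatrix | np.ndarray"
    genes: np.ndarray
    normalized: Optional[np.ndarray] = None
    cell_labels: Optional[np.ndarray] = None
    interaction_labels: Optional[np.ndarray] = None
    territory_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.barcodes = _as_str_array(self.barcodes)
        self.genes = _as_str_array(self.genes)
        self.coords = np.asarray(self.coords, dtype=float)
        for name in ("cell_labels", "interaction_labels", "territory_labels"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, _as_str_array(val))
        self.validate()

    # -- basic facts ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        n = self.n_cells
        uniq, counts = np.unique(self.barcodes.astype(str), return_counts=True)
        if (counts > 1).any():
            dupes = uniq[counts > 1][:5].tolist()
            raise ValueError(f"duplicate barcodes in sample {self.sample_id!r}: {dupes}")
        if self.coords.ndim != 2 or self.coords.shape != (n, 2):
            raise ValueError(
                f"coords must be (n_cells, 2); got {self.coords.shape} for {n} cells"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("coords contain non-finite values")
        if self.counts.shape != (self.n_genes, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"({self.n_genes} genes, {n} cells)"
            )
        cmin = self.counts.min() if not sp.issparse(self.counts) else self.counts.min()
        if cmin < 0:
            raise ValueError("counts must be non-negative")
        for name in ("cell_labels", "interaction_labels", "territory_labels"):
            val = getattr(self, name)
            if val is not None and len(val) != n:
                raise ValueError(f"{name} length {len(val)} != n_cells {n}")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValueError("normalized layer shape must match counts")

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def with_(self, **changes) -> "SpatialDataset":
        """Shallow-copied dataset with the given fields replaced."""
        return replace(self, **changes)

    def barcode_index(self) -> dict:
        return {b: i for i, b in enumerate(self.barcodes)}

    def rescale_coords(self) -> "SpatialDataset":
        """Translate coordinates so that min x and min y both equal 1.

        Mapping itself is translation-invariant; this only matters for
        radius-based niches where units carry meaning.
        """
        shifted = self.coords - self.coords.min(axis=0) + 1.0
        return self.with_(coords=shifted)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tracks = [
            t
            for t in ("cell_labels", "interaction_labels", "territory_labels")
            if getattr(self, t) is not None
        ]
        return (
            f"SpatialDataset({self.sample_id!r}, {self.n_genes} genes × "
            f"{self.n_cells} cells, tracks={tracks})"
        )


@dataclass
class SignalMatrix:
    """Expression signal at one spatial scale: features × cells."""

    level: str
    values: np.ndarray
    feature_ids: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        if self.level not in SIGNAL_LEVELS:
            raise ValueError(f"level must be one of {SIGNAL_LEVELS}, got {self.level!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = _as_str_array(self.feature_ids)
        self.barcodes = _as_str_array(self.barcodes)
        if self.values.shape != (len(self.feature_ids), len(self.barcodes)):
            raise ValueError("values shape must be (n_features, n_cells)")
        if not np.isfinite(self.values).all():
            raise ValueError("signal matrix contains non-finite values")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def restrict_features(self, feature_ids: Sequence[str]) -> "SignalMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in feature_ids]
        return SignalMatrix(
            level=self.level,
            values=self.values[rows],
            feature_ids=np.asarray(list(feature_ids), dtype=object),
            barcodes=self.barcodes,
        )


@dataclass
class NicheAssignment:
    """Per-cell spatial neighbourhoods under one method/parameter.

    ``neighbors[i]`` lists the neighbour *indices* of cell ``i`` excluding the
    centre cell itself; whether the centre joins its own niche when signals or
    compositions are computed is controlled by ``include_center``.
    """

    method: str
    parameter: float
    neighbors: list
    include_center: bool = True

    def __post_init__(self) -> None:
        if self.method not in NICHE_METHODS:
            raise ValueError(f"method must be one of {NICHE_METHODS}, got {self.method!r}")
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]

    @property
    def n_cells(self) -> int:
        return len(self.neighbors)

    def members(self, i: int) -> np.ndarray:
        """Niche membership of cell ``i`` (centre included per flag)."""
        nb = self.neighbors[i]
        if self.include_center:
            return np.concatenate(([i], nb))
        return nb
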