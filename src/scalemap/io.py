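"""Reading and writing spatial datasets and mapping tables.

Counts are accepted either as MatrixMarket coordinate files (``.mtx``) with
one-identifier-per-line gene/barcode sidecar files, or as dense delimited
text with a header row of barcodes and a first column of gene identifiers.
The cell table is whitespace- or comma-delimited text with at least
``barcode``, ``x`` and ``y`` columns; optional columns ``cell_labels``,
``interactions``, ``territory`` and ``sample`` are picked up automatically.
Barcode order in the counts and the cell table is reconciled by identifier,
never by position.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datasets import SpatialDataset

__all__ = [
    "load_spatial_dataset",
    "write_spatial_dataset",
    "write_mapping",
    "read_mapping",
]

_CELL_COLUMN_MAP = {
    "cell_labels": "cell_labels",
    "cell_label": "cell_labels",
    "interactions": "interaction_labels",
    "interaction_labels": "interaction_labels",
    "territory": "territory_labels",
    "territory_labels": "territory_labels",
}


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else None
    # sep=None sniffs the delimiter (tab or whitespace) with the python engine
    return pd.read_csv(path, sep=sep, engine="python")


def _sidecar_paths(counts_path: Path):
    stem = counts_path.with_suffix("")
    return Path(f"{stem}_genes.tsv"), Path(f"{stem}_barcodes.tsv")


def _load_counts(counts_path: Path, genes_path=None, barcodes_path=None):
    if counts_path.suffix.lower() == ".mtx":
        default_genes, default_barcodes = _sidecar_paths(counts_path)
        genes_path = Path(genes_path) if genes_path else default_genes
        barcodes_path = Path(barcodes_path) if barcodes_path else default_barcodes
        for p in (genes_path, barcodes_path):
            if not p.exists():
                raise FileNotFoundError(f"missing MTX sidecar file: {p}")
        counts = sp.csr_matrix(scipy.io.mmread(counts_path))
        genes = np.loadtxt(genes_path, dtype=str, ndmin=1)
        barcodes = np.loadtxt(barcodes_path, dtype=str, ndmin=1)
        if counts.shape != (len(genes), len(barcodes)):
            raise ValueError(
                f"MTX shape {counts.shape} does not match sidecars "
                f"({len(genes)} genes, {len(barcodes)} barcodes)"
            )
        return counts, genes, barcodes
    table = _read_table(counts_path)
    genes = table.iloc[:, 0].astype(str).to_numpy()
    barcodes = np.asarray(table.columns[1:], dtype=str)
    values = table.iloc[:, 1:].to_numpy()
    return np.asarray(values), genes, barcodes


def load_spatial_dataset(
    counts_path,
    cells_path,
    sample_id: Optional[str] = None,
    genes_path=None,
    barcodes_path=None,
    rescale: bool = False,
) -> SpatialDataset:
    """Load one spatial sample from a counts file and a cell table.

    Parameters
    ----------
    counts_path : path
        ``.mtx`` (with sidecars) or dense delimited text (genes × cells).
    cells_path : path
        Delimited text with columns ``barcode``, ``x``, ``y`` and optional
        label columns.
    sample_id : str, optional
        Defaults to the ``sample`` column (if single-valued) or the counts
        file stem.
    rescale : bool
        If True, translate coordinates so min x and min y equal 1.
    """
    counts_path = Path(counts_path)
    counts, genes, count_barcodes = _load_counts(counts_path, genes_path, barcodes_path)
    cells = _read_table(cells_path)
    if "barcode" not in cells.columns:
        # accept a conventional first-column barcode under other names
        first = cells.columns[0]
        if first.lower() in ("barcodes", "cell", "cell_id"):
            cells = cells.rename(columns={first: "barcode"})
        else:
            raise ValueError("cell table must contain a 'barcode' column")
    for col in ("x", "y"):
        if col not in cells.columns:
            raise ValueError(f"cell table must contain an {col!r} column")

    table_barcodes = cells["barcode"].astype(str).to_numpy()
    dupes = pd.Series(table_barcodes).value_counts()
    dupes = dupes[dupes > 1]
    if len(dupes):
        raise ValueError(f"duplicate barcodes in cell table: {dupes.index[:5].tolist()}")

    count_set = set(map(str, count_barcodes))
    table_set = set(table_barcodes)
    missing = sorted(table_set - count_set)
    extra = sorted(count_set - table_set)
    if missing or extra:
        msg = []
        if missing:
            msg.append(f"barcodes in cell table but not counts: {missing[:5]}")
        if extra:
            msg.append(f"barcodes in counts but not cell table: {extra[:5]}")
        raise ValueError("; ".join(msg))

    coords = cells[["x", "y"]].to_numpy()
    try:
        coords = coords.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric coordinates in cell table: {err}") from None
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates in cell table")

    # reorder count columns to the cell-table order, by identifier
    order = {str(b): i for i, b in enumerate(count_barcodes)}
    col_idx = np.array([order[b] for b in table_barcodes], dtype=int)
    counts = counts[:, col_idx]

    tracks = {}
    for col, attr in _CELL_COLUMN_MAP.items():
        if col in cells.columns and attr not in tracks:
            tracks[attr] = cells[col].astype(str).to_numpy()

    if sample_id is None:
        if "sample" in cells.columns and cells["sample"].nunique() == 1:
            sample_id = str(cells["sample"].iloc[0])
        else:
            sample_id = counts_path.stem

    d = SpatialDataset(
        sample_id=sample_id,
        barcodes=table_barcodes,
        coords=coords,
        counts=counts,
        genes=genes,
        **tracks,
    )
    return d.rescale_coords() if rescale else d


def write_spatial_dataset(d: SpatialDataset, out_dir, prefix: Optional[str] = None):
    """Write a sample as MTX counts + sidecars and a cells TSV.

    Returns the (counts_path, cells_path) pair, re-readable with
    :func:`load_spatial_dataset`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or d.sample_id
    counts_path = out_dir / f"{prefix}_counts.mtx"
    genes_path, barcodes_path = _sidecar_paths(counts_path)
    cells_path = out_dir / f"{prefix}_cells.tsv"

    counts = d.counts if sp.issparse(d.counts) else sp.coo_matrix(d.counts)
    scipy.io.mmwrite(str(counts_path), counts, field="integer")
    np.savetxt(genes_path, d.genes.astype(str), fmt="%s")
    np.savetxt(barcodes_path, d.barcodes.astype(str), fmt="%s")

    table = pd.DataFrame(
        {
            "barcode": d.barcodes.astype(str),
            "x": d.coords[:, 0],
            "y": d.coords[:, 1],
            "sample": d.sample_id,
        }
    )
    if d.cell_labels is not None:
        table["cell_labels"] = d.cell_labels.astype(str)
    if d.interaction_labels is not None:
        table["interactions"] = d.interaction_labels.astype(str)
    if d.territory_labels is not None:
        table["territory"] = d.territory_labels.astype(str)
    table.to_csv(cells_path, sep="\t", index=False)
    return counts_path, cells_path


def write_mapping(result, path) -> None:
    """Write a mapping result as a TSV of cell pairs.

    Columns: ``query_barcode``, ``ref_barcode``, ``total_cost``, ``epoch``
    and one ``score_<metric>`` column per similarity metric in the stack.
    """
    pairs = result if isinstance(result, pd.DataFrame) else result.pairs
    if pairs is None or len(pairs) == 0:
        raise ValueError("refusing to write an empty mapping result")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        pairs.to_csv(path, sep="\t", index=False, float_format="%.12g")
    except OSError as err:  # pragma: no cover - environment dependent
        raise OSError(f"cannot write mapping to {path}: {err}") from err


def read_mapping(path) -> pd.DataFrame:
    """Read a mapping TSV back into a pairs table."""
    table = pd.read_csv(path, sep="\t")
    required = {"query_barcode", "ref_barcode", "total_cost", "epoch"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"mapping file {path} missing columns: {sorted(missing)}")
    return table
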