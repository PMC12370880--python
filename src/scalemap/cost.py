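"""Similarity matrices between query and reference cells, and the total cost.

The total mapping cost for a query cell *i* and a reference cell *j* is the
unweighted sum of reciprocals over the active similarity matrices:

    C_ij = sum_k (1 - S_ij^(k))

Continuous metrics (cell/"feature", niche, territory) score pairs by the
Pearson correlation of their expression signals over the shared feature set,
so a correlation metric can contribute up to 2 to the cost; scores are used
raw, never rescaled.  Categorical metrics are a frequency-aware Jaccard
index on niche cell-type composition and a 0/1 indicator on the cell-type
label itself.  Metrics are addressed by single letters — f (feature/cell),
n (niche), t (territory), c (composition), y (cell-type label) — so a
configuration string like ``"fnct"`` names one cost-stack combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import NicheAssignment, SignalMatrix, SpatialDataset

__all__ = [
    "SimilarityMatrix",
    "CostStack",
    "METRIC_LETTERS",
    "parse_metrics",
    "feature_similarity",
    "niche_similarity",
    "territory_similarity",
    "composition_similarity",
    "label_similarity",
    "custom_similarity",
    "build_cost_stack",
    "filter_candidates",
    "cost_diagnostics",
    "pair_poc",
    "frequency_aware_jaccard",
]

METRIC_LETTERS = {
    "f": "feature",
    "n": "niche",
    "t": "territory",
    "c": "composition",
    "y": "label",
}
CORRELATION_METRICS = {"feature", "niche", "territory"}
#: metrics the user-defined score threshold applies to (the label indicator
#: has its own dedicated filter)
THRESHOLDED_METRICS = CORRELATION_METRICS | {"composition", "custom"}


def parse_metrics(letters: str) -> List[str]:
    """Expand a letter string like ``"fnc"`` into metric names."""
    out = []
    for ch in letters:
        if ch not in METRIC_LETTERS:
            raise ValueError(
                f"unknown metric letter {ch!r}; valid letters: {sorted(METRIC_LETTERS)}"
            )
        name = METRIC_LETTERS[ch]
        if name in out:
            raise ValueError(f"metric {name!r} listed twice in {letters!r}")
        out.append(name)
    if not out:
        raise ValueError("at least one metric letter is required")
    return out


@dataclass
class SimilarityMatrix:
    """One named query × reference similarity matrix."""

    metric: str
    scores: np.ndarray
    declared_range: tuple

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D query × reference matrix")
        if np.isnan(self.scores).any():
            raise ValueError(f"{self.metric} similarity contains NaN")
        lo, hi = self.declared_range
        # tiny numerical excursions from BLAS correlation products are clipped
        self.scores = np.clip(self.scores, lo, hi)

    @property
    def shape(self):
        return self.scores.shape


@dataclass
class CostStack:
    """Named similarity matrices plus their summed total cost.

    ``active_query`` lists the query indices that survived candidate
    filtering; all matrices keep full query × reference shape.
    """

    matrices: Dict[str, SimilarityMatrix]
    total_cost: np.ndarray
    query_barcodes: np.ndarray
    ref_barcodes: np.ndarray
    active_query: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.active_query is None:
            self.active_query = np.arange(len(self.query_barcodes))
        self.active_query = np.asarray(self.active_query, dtype=int)

    @property
    def metrics(self) -> List[str]:
        return list(self.matrices)

    @property
    def shape(self):
        return self.total_cost.shape


# ---------------------------------------------------------------------------
# continuous metrics: Pearson correlation of signals
# ---------------------------------------------------------------------------

def _standardize_columns(values: np.ndarray):
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    z = (values - mu) / sd_safe
    z[:, degenerate] = 0.0
    return z, degenerate


def _pearson_matrix(q: np.ndarray, r: np.ndarray, metric: str) -> np.ndarray:
    zq, dq = _standardize_columns(q)
    zr, dr = _standardize_columns(r)
    if dq.any() or dr.any():
        warnings.warn(
            f"{metric} similarity: {int(dq.sum())} query / {int(dr.sum())} reference "
            "constant signal columns scored 0",
            RuntimeWarning,
            stacklevel=3,
        )
    m = q.shape[0]
    return (zq.T @ zr) / m


def _correlation_similarity(
    q: SignalMatrix, r: SignalMatrix, metric: str
) -> SimilarityMatrix:
    shared = [f for f in q.feature_ids if f in set(r.feature_ids)]
    if len(shared) < 2:
        raise ValueError(
            f"{metric} similarity needs >= 2 shared features; got {len(shared)}"
        )
    qv = q.restrict_features(shared).values
    rv = r.restrict_features(shared).values
    scores = _pearson_matrix(qv, rv, metric)
    return SimilarityMatrix(metric=metric, scores=scores, declared_range=(-1.0, 1.0))


def feature_similarity(q: SignalMatrix, r: SignalMatrix) -> SimilarityMatrix:
    """Pearson correlation between cell-scale expression signals, over the
    intersection of feature ids."""
    return _correlation_similarity(q, r, "feature")


def niche_similarity(qn: SignalMatrix, rn: SignalMatrix) -> SimilarityMatrix:
    """Pearson correlation between niche-scale signals."""
    return _correlation_similarity(qn, rn, "niche")


def territory_similarity(qt: SignalMatrix, rt: SignalMatrix) -> SimilarityMatrix:
    """Pearson correlation between territory-scale signals (block-constant
    over territory pairs by construction)."""
    return _correlation_similarity(qt, rt, "territory")


# ---------------------------------------------------------------------------
# categorical metrics
# ---------------------------------------------------------------------------

def frequency_aware_jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    """Jaccard index between label multisets under occurrence uniquification.

    Repeat occurrences of a label are suffixed (A, A.1, A.2, ...) before the
    set operations, which makes the index equal to multiset intersection
    over multiset union: sum of per-label minimum counts over maximum counts.
    """
    if len(a) == 0 and len(b) == 0:
        return 0.0
    labels_a = pd.Series(list(a)).value_counts()
    labels_b = pd.Series(list(b)).value_counts()
    vocab = labels_a.index.union(labels_b.index)
    ca = labels_a.reindex(vocab, fill_value=0).to_numpy()
    cb = labels_b.reindex(vocab, fill_value=0).to_numpy()
    union = np.maximum(ca, cb).sum()
    if union == 0:
        return 0.0
    return float(np.minimum(ca, cb).sum() / union)


def _niche_label_counts(d: SpatialDataset, niches: NicheAssignment, vocab: dict):
    counts = np.zeros((d.n_cells, len(vocab)), dtype=np.int64)
    labels = d.cell_labels.astype(str)
    for i in range(d.n_cells):
        for m in niches.members(i):
            counts[i, vocab[labels[m]]] += 1
    return counts


def composition_similarity(
    q: SpatialDataset,
    r: SpatialDataset,
    qn: NicheAssignment,
    rn: NicheAssignment,
) -> SimilarityMatrix:
    """Frequency-aware Jaccard index between niche cell-type compositions."""
    for d in (q, r):
        if d.cell_labels is None:
            raise ValueError(f"sample {d.sample_id!r} has no cell labels")
    vocab_labels = sorted(
        set(q.cell_labels.astype(str)) | set(r.cell_labels.astype(str))
    )
    vocab = {lab: i for i, lab in enumerate(vocab_labels)}
    cq = _niche_label_counts(q, qn, vocab)
    cr = _niche_label_counts(r, rn, vocab)
    inter = np.zeros((q.n_cells, r.n_cells), dtype=float)
    union = np.zeros_like(inter)
    for l in range(len(vocab)):
        a = cq[:, l][:, None]
        b = cr[:, l][None, :]
        inter += np.minimum(a, b)
        union += np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(union > 0, inter / union, 0.0)
    return SimilarityMatrix(
        metric="composition", scores=scores, declared_range=(0.0, 1.0)
    )


def label_similarity(q: SpatialDataset, r: SpatialDataset) -> SimilarityMatrix:
    """0/1 indicator of cell-type label agreement."""
    for d in (q, r):
        if d.cell_labels is None:
            raise ValueError(f"sample {d.sample_id!r} has no cell labels")
    scores = (
        q.cell_labels.astype(str)[:, None] == r.cell_labels.astype(str)[None, :]
    ).astype(float)
    return SimilarityMatrix(metric="label", scores=scores, declared_range=(0.0, 1.0))


def custom_similarity(
    scores: np.ndarray, declared_range=(0.0, 1.0), metric: str = "custom"
) -> SimilarityMatrix:
    """Entry point for user-defined similarity matrices (identity pass-through)."""
    return SimilarityMatrix(metric=metric, scores=scores, declared_range=declared_range)


# ---------------------------------------------------------------------------
# stacking, filtering, diagnostics
# ---------------------------------------------------------------------------

def build_cost_stack(
    matrices: Sequence[SimilarityMatrix],
    query_barcodes: np.ndarray,
    ref_barcodes: np.ndarray,
) -> CostStack:
    """Sum the reciprocals of the given similarity matrices, unweighted."""
    if len(matrices) == 0:
        raise ValueError("at least one similarity matrix is required")
    shape = matrices[0].shape
    for m in matrices:
        if m.shape != shape:
            raise ValueError(
                f"similarity matrix {m.metric!r} shape {m.shape} != {shape}"
            )
    if shape != (len(query_barcodes), len(ref_barcodes)):
        raise ValueError("matrix shape does not match barcode lists")
    total = np.zeros(shape)
    named = {}
    for m in matrices:
        if m.metric in named:
            raise ValueError(f"duplicate metric {m.metric!r} in stack")
        named[m.metric] = m
        total += 1.0 - m.scores
    return CostStack(
        matrices=named,
        total_cost=total,
        query_barcodes=np.asarray(query_barcodes, dtype=object),
        ref_barcodes=np.asarray(ref_barcodes, dtype=object),
    )


def filter_candidates(
    stack: CostStack, threshold: float = 0.9, use_label_filter: bool = False
) -> CostStack:
    """Drop query cells unlikely to have any acceptable match.

    A query cell survives the score filter if *at least one* reference cell
    scores above ``threshold`` in *any* correlation/Jaccard matrix.  With
    ``use_label_filter``, query cells whose cell-type label matches no
    reference cell are additionally dropped.
    """
    keep = np.ones(len(stack.query_barcodes), dtype=bool)
    scored = [m for name, m in stack.matrices.items() if name in THRESHOLDED_METRICS]
    if threshold is not None and scored:
        any_above = np.zeros(len(keep), dtype=bool)
        for m in scored:
            any_above |= (m.scores > threshold).any(axis=1)
        keep &= any_above
    if use_label_filter:
        if "label" not in stack.matrices:
            raise ValueError("label filtering requested but no label matrix in stack")
        keep &= stack.matrices["label"].scores.sum(axis=1) > 0
    active = np.intersect1d(stack.active_query, np.flatnonzero(keep))
    if len(active) == 0:
        raise ValueError("candidate filtering removed every query cell")
    return CostStack(
        matrices=stack.matrices,
        total_cost=stack.total_cost,
        query_barcodes=stack.query_barcodes,
        ref_barcodes=stack.ref_barcodes,
        active_query=active,
    )


def cost_diagnostics(stack: CostStack, result) -> pd.DataFrame:
    """Interpretability diagnostics per metric: CV and mean POC.

    CV is sd/mean of the metric's cost contribution (1 - S) over all active
    query × reference pairs — a measure of how strongly the metric can
    discriminate candidate matches.  POC (proportion of contribution) is,
    per mapped pair, the metric's share of the total cost; pairs with zero
    total cost have undefined POC and are excluded (their count is
    reported in the ``n_zero_cost_excluded`` column).
    """
    pairs = result if isinstance(result, pd.DataFrame) else result.pairs
    qidx = {b: i for i, b in enumerate(stack.query_barcodes)}
    ridx = {b: i for i, b in enumerate(stack.ref_barcodes)}
    qi = np.array([qidx[b] for b in pairs["query_barcode"]], dtype=int)
    rj = np.array([ridx[b] for b in pairs["ref_barcode"]], dtype=int)
    total = stack.total_cost[qi, rj]
    positive = total > 0
    n_excluded = int((~positive).sum())
    rows = []
    for name, m in stack.matrices.items():
        contrib_all = 1.0 - m.scores[stack.active_query]
        mean_contrib = contrib_all.mean()
        cv = contrib_all.std() / mean_contrib if mean_contrib != 0 else np.nan
        contrib_pairs = 1.0 - m.scores[qi, rj]
        poc = contrib_pairs[positive] / total[positive] if positive.any() else np.array([])
        rows.append(
            {
                "metric": name,
                "cv": float(cv),
                "mean_contribution": float(contrib_pairs.mean()),
                "mean_poc": float(poc.mean()) if len(poc) else np.nan,
                "n_pairs": int(positive.sum()),
                "n_zero_cost_excluded": n_excluded,
            }
        )
    return pd.DataFrame(rows)


def pair_poc(stack: CostStack, result) -> pd.DataFrame:
    """Per-pair proportion of contribution for every metric in the stack.

    Rows are mapped pairs with positive total cost; columns ``poc_<metric>``
    sum to 1 across metrics for every row.
    """
    pairs = result if isinstance(result, pd.DataFrame) else result.pairs
    qidx = {b: i for i, b in enumerate(stack.query_barcodes)}
    ridx = {b: i for i, b in enumerate(stack.ref_barcodes)}
    qi = np.array([qidx[b] for b in pairs["query_barcode"]], dtype=int)
    rj = np.array([ridx[b] for b in pairs["ref_barcode"]], dtype=int)
    total = stack.total_cost[qi, rj]
    positive = total > 0
    out = pd.DataFrame(
        {
            "query_barcode": np.asarray(pairs["query_barcode"])[positive],
            "ref_barcode": np.asarray(pairs["ref_barcode"])[positive],
            "total_cost": total[positive],
        }
    )
    for name, m in stack.matrices.items():
        contrib = 1.0 - m.scores[qi, rj]
        out[f"poc_{name}"] = contrib[positive] / total[positive]
    return out
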