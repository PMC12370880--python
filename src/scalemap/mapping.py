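"""Batched linear-assignment cell mapping across spatial samples.

Mapping is phrased as a Linear Assignment Problem: query cells are "workers",
reference cells are "tasks", and the optimal one-to-one assignment of a batch
minimises the summed total cost.  Because the assignment depends on which
cells land in a batch together, batching and solving are repeated over
epochs; a query cell's retained match is replaced only when a new epoch finds
a strictly cheaper pair.  Reference cells may be won by several query cells
across batches and epochs, so the raw output is a many-to-many mapping; an
optional greedy pass reduces it to one-to-one.

The user-facing surface is the :class:`CellMapper` model — construct it from
two :class:`~scalemap.datasets.SpatialDataset` objects and a metric string,
call :meth:`CellMapper.fit`, and work with the returned
:class:`MappingResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import cost as cost_mod
from . import preprocessing as pp
from .cost import CostStack, SimilarityMatrix, build_cost_stack, parse_metrics
from .datasets import SignalMatrix, SpatialDataset

__all__ = [
    "MappingConfig",
    "CellMapper",
    "MappingResults",
    "solve_lap",
    "make_batches",
    "map_cells",
    "filter_one_to_one",
]


@dataclass
class MappingConfig:
    """Batching and refinement parameters.

    Defaults follow the synthetic benchmarking protocol: batches of 1000
    cells refined across 25 epochs, candidate score threshold 0.9.
    """

    batch_size: int = 1000
    epochs: int = 25
    seed: int = 42
    one_to_one: bool = False
    cost_metrics: str = "fn"
    threshold: Optional[float] = 0.9
    filter_labels: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def solve_lap(cost: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Optimal one-to-one assignment of rows to columns (rows <= columns).

    Thin wrapper over the shortest-augmenting-path solver in scipy (the
    Jonker-Volgenant family); returns (row_indices, column_indices).
    """
    cost = np.asarray(cost, dtype=float)
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix contains non-finite entries")
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if cost.shape[0] > cost.shape[1]:
        raise ValueError(
            f"cost matrix has more rows than columns {cost.shape}; pad first"
        )
    return linear_sum_assignment(cost)


def make_batches(
    n_query: int,
    n_ref: int,
    batch_size: int,
    rng: np.random.Generator,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Random batches of matched size for one epoch.

    The query set is shuffled and partitioned into consecutive batches of at
    most ``batch_size`` cells, so every query cell appears exactly once per
    epoch.  Reference cells are drawn without replacement from a shuffled
    pool; when the pool runs dry it is refilled with a freshly shuffled copy
    (cyclic duplication padding), so reference ids may repeat but are never
    invented.  Deterministic given the generator state.
    """
    if n_query < 1 or n_ref < 1:
        raise ValueError("both cell sets must be non-empty")
    qperm = rng.permutation(n_query)
    pool = list(rng.permutation(n_ref))
    batches = []
    for start in range(0, n_query, batch_size):
        qb = qperm[start : start + batch_size]
        rb = []
        while len(rb) < len(qb):
            if not pool:
                pool = list(rng.permutation(n_ref))
            need = len(qb) - len(rb)
            take, pool = pool[:need], pool[need:]
            rb.extend(take)
        batches.append((qb, np.asarray(rb, dtype=int)))
    return batches


def map_cells(
    stack: CostStack,
    config: MappingConfig,
    keep_history: bool = False,
) -> "MappingResults":
    """Run the batched epoch-refined assignment on a precomputed cost stack.

    Per-batch cost submatrices are sliced from the full stack (scores do not
    depend on batching, so this is exact).  Within a batch a padded
    duplicate of a reference cell is just the same column index appearing
    twice; assignments to duplicates therefore map back to the original id,
    which is how many-to-one matches arise.
    """
    active = stack.active_query
    if len(active) == 0:
        raise ValueError("no active query cells to map")
    n_ref = len(stack.ref_barcodes)
    cost_active = stack.total_cost[active]

    best_cost = np.full(len(active), np.inf)
    best_ref = np.full(len(active), -1, dtype=int)
    best_epoch = np.zeros(len(active), dtype=int)
    history = []

    for epoch in range(1, config.epochs + 1):
        # epoch e draws its own deterministic stream from seed + e
        rng = np.random.default_rng(config.seed + epoch)
        for qb, rb in make_batches(len(active), n_ref, config.batch_size, rng):
            sub = cost_active[np.ix_(qb, rb)]
            rows, cols = solve_lap(sub)
            for r, c in zip(rows, cols):
                qi = qb[r]
                pair_cost = sub[r, c]
                # strict inequality: ties keep the earlier epoch's pair
                if pair_cost < best_cost[qi]:
                    best_cost[qi] = pair_cost
                    best_ref[qi] = rb[c]
                    best_epoch[qi] = epoch
        if keep_history:
            history.append(best_cost.copy())

    pairs = pd.DataFrame(
        {
            "query_barcode": stack.query_barcodes[active],
            "ref_barcode": stack.ref_barcodes[best_ref],
            "total_cost": best_cost,
            "epoch": best_epoch,
        }
    )
    for name, m in stack.matrices.items():
        pairs[f"score_{name}"] = m.scores[active, best_ref]

    result = MappingResults(
        pairs=pairs,
        config=config,
        stack=stack,
        epoch_cost_history=np.asarray(history) if keep_history else None,
    )
    if config.one_to_one:
        result = filter_one_to_one(result)
    return result


def filter_one_to_one(result: "MappingResults") -> "MappingResults":
    """Greedy reduction to a one-to-one mapping by ascending cost."""
    pairs = result.pairs
    if len(pairs) == 0:
        raise ValueError("cannot filter an empty mapping result")
    order = np.argsort(pairs["total_cost"].to_numpy(), kind="stable")
    used_q, used_r = set(), set()
    keep = []
    for i in order:
        q = pairs["query_barcode"].iloc[i]
        r = pairs["ref_barcode"].iloc[i]
        if q in used_q or r in used_r:
            continue
        used_q.add(q)
        used_r.add(r)
        keep.append(i)
    kept = pairs.iloc[sorted(keep)].reset_index(drop=True)
    return MappingResults(
        pairs=kept,
        config=result.config,
        stack=result.stack,
        epoch_cost_history=result.epoch_cost_history,
    )


# ---------------------------------------------------------------------------
# the Model / Results surface
# ---------------------------------------------------------------------------

class CellMapper:
    """Map query cells onto reference cells via multi-scale similarity.

    Parameters
    ----------
    query, reference : SpatialDataset
        The sample to map and the sample to map onto.
    metrics : str
        Cost-stack configuration as a letter string over
        f (cell), n (niche), t (territory), c (composition), y (label);
        e.g. ``"fn"`` (the default) or ``"fncty"``.
    n_features : int
        Number of highly variable genes per sample; the two HVG sets are
        intersected before correlation.
    signal : {"hvg", "pca"}
        Use log-normalised HVG expression directly (default) or a PCA
        embedding of it as the continuous signal.
    embedding_dims : int
        Number of principal components when ``signal="pca"``.
    niche_method : {"knn", "graph", "radius"} with niche_k / niche_depth /
        niche_radius
        Niche definition for the n and c metrics.
    territory_source : {"provided", "fallback"}
        Where territory labels come from when the t metric is active.
    threshold : float or None
        Candidate score filter applied before solving (None disables).
    filter_labels : bool
        Drop query cells whose cell-type label matches no reference cell.

    Examples
    --------
    >>> mapper = CellMapper(query, reference, metrics="fnc")
    >>> res = mapper.fit(batch_size=500, epochs=10, seed=7)
    >>> res.pairs.head()
    """

    def __init__(
        self,
        query: SpatialDataset,
        reference: SpatialDataset,
        metrics: str = "fn",
        *,
        n_features: int = 2000,
        signal: str = "hvg",
        embedding_dims: int = 30,
        niche_method: str = "knn",
        niche_k: int = 6,
        niche_depth: int = 1,
        niche_radius: Optional[float] = None,
        include_center: bool = True,
        territory_source: str = "provided",
        territory_k: int = 5,
        normalization: str = "lognorm",
        threshold: Optional[float] = 0.9,
        filter_labels: bool = False,
        custom_matrices: Optional[Sequence[SimilarityMatrix]] = None,
    ) -> None:
        self.query = query
        self.reference = reference
        self.metric_names = parse_metrics(metrics)
        self.metrics = metrics
        self.n_features = n_features
        self.signal = signal
        self.embedding_dims = embedding_dims
        self.niche_method = niche_method
        self.niche_k = niche_k
        self.niche_depth = niche_depth
        self.niche_radius = niche_radius
        self.include_center = include_center
        self.territory_source = territory_source
        self.territory_k = territory_k
        self.normalization = normalization
        self.threshold = threshold
        self.filter_labels = filter_labels
        self.custom_matrices = list(custom_matrices or [])
        self._stack: Optional[CostStack] = None

    # -- preprocessing ----------------------------------------------------
    def _prepare(self, d: SpatialDataset) -> Dict[str, object]:
        if d.normalized is None:
            d = pp.normalize_counts(d, self.normalization)
        n_feat = min(self.n_features, d.n_genes)
        hvg = pp.select_variable_features(d, n_feat)
        state: Dict[str, object] = {"dataset": d, "hvg": hvg}
        if self.signal == "pca":
            state["signal"] = pp.compute_embedding(
                d, dims=self.embedding_dims, features=hvg
            )
        else:
            state["signal"] = pp.expression_signal(d, hvg)
        needs_niche = {"niche", "composition"} & set(self.metric_names)
        if needs_niche:
            state["niches"] = pp.extract_niches(
                d,
                method=self.niche_method,
                k=self.niche_k,
                depth=self.niche_depth,
                radius=self.niche_radius,
                include_center=self.include_center,
            )
        if "niche" in self.metric_names:
            state["niche_signal"] = pp.niche_signal(d, state["niches"], state["signal"])
        if "territory" in self.metric_names:
            if self.territory_source == "fallback":
                emb = pp.compute_embedding(
                    d, dims=min(self.embedding_dims, len(hvg) - 1, d.n_cells - 1),
                    features=hvg,
                )
                d = pp.assign_territories(
                    d, source="fallback", embedding=emb, k=self.territory_k
                )
                state["dataset"] = d
            else:
                d = pp.assign_territories(d, source="provided")
            state["territory_signal"] = pp.territory_signal(d, state["signal"])
        return state

    def build_cost_stack(self) -> CostStack:
        """Compute (and cache) the full query × reference cost stack."""
        if self._stack is not None:
            return self._stack
        qs = self._prepare(self.query)
        rs = self._prepare(self.reference)
        mats: List[SimilarityMatrix] = []
        for name in self.metric_names:
            if name == "feature":
                mats.append(cost_mod.feature_similarity(qs["signal"], rs["signal"]))
            elif name == "niche":
                mats.append(
                    cost_mod.niche_similarity(qs["niche_signal"], rs["niche_signal"])
                )
            elif name == "territory":
                mats.append(
                    cost_mod.territory_similarity(
                        qs["territory_signal"], rs["territory_signal"]
                    )
                )
            elif name == "composition":
                mats.append(
                    cost_mod.composition_similarity(
                        qs["dataset"], rs["dataset"], qs["niches"], rs["niches"]
                    )
                )
            elif name == "label":
                mats.append(cost_mod.label_similarity(qs["dataset"], rs["dataset"]))
        mats.extend(self.custom_matrices)
        stack = build_cost_stack(mats, self.query.barcodes, self.reference.barcodes)
        if self.threshold is not None or self.filter_labels:
            stack = cost_mod.filter_candidates(
                stack,
                threshold=self.threshold,
                use_label_filter=self.filter_labels,
            )
        self._stack = stack
        return stack

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        batch_size: int = 1000,
        epochs: int = 25,
        seed: int = 42,
        one_to_one: bool = False,
        keep_history: bool = False,
    ) -> "MappingResults":
        """Solve the batched assignment and return the retained pairs."""
        config = MappingConfig(
            batch_size=batch_size,
            epochs=epochs,
            seed=seed,
            one_to_one=one_to_one,
            cost_metrics=self.metrics,
            threshold=self.threshold,
            filter_labels=self.filter_labels,
        )
        stack = self.build_cost_stack()
        return map_cells(stack, config, keep_history=keep_history)


class MappingResults:
    """Retained cell pairs with costs, scores and diagnostics.

    Attributes
    ----------
    pairs : DataFrame
        One row per retained pair: query_barcode, ref_barcode, total_cost,
        epoch (the epoch the pair was retained in) and one score column per
        metric.
    config : MappingConfig
    stack : CostStack
        The cost stack the mapping was solved on.
    epoch_cost_history : ndarray (epochs × active queries) or None
        Retained cost after each epoch when ``keep_history=True``.
    """

    def __init__(self, pairs, config, stack=None, epoch_cost_history=None):
        self.pairs = pairs
        self.config = config
        self.stack = stack
        self.epoch_cost_history = epoch_cost_history

    # -- conveniences -----------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_cost(self) -> float:
        return float(self.pairs["total_cost"].mean())

    def score_columns(self) -> List[str]:
        return [c for c in self.pairs.columns if c.startswith("score_")]

    def diagnostics(self) -> pd.DataFrame:
        if self.stack is None:
            raise ValueError("results carry no cost stack")
        return cost_mod.cost_diagnostics(self.stack, self)

    def pair_poc(self) -> pd.DataFrame:
        if self.stack is None:
            raise ValueError("results carry no cost stack")
        return cost_mod.pair_poc(self.stack, self)

    def filter_one_to_one(self) -> "MappingResults":
        return filter_one_to_one(self)

    def to_tsv(self, path) -> None:
        from .io import write_mapping

        write_mapping(self, path)

    def summary(self) -> str:
        """Plain-text summary table of the fitted mapping."""
        lines = []
        lines.append("Cell mapping results")
        lines.append("=" * 60)
        lines.append(f"metrics:            {self.config.cost_metrics}")
        lines.append(f"batch size:         {self.config.batch_size}")
        lines.append(f"epochs:             {self.config.epochs}")
        lines.append(f"seed:               {self.config.seed}")
        lines.append(f"retained pairs:     {self.n_pairs}")
        lines.append(f"distinct references:{self.pairs['ref_barcode'].nunique():>6}")
        lines.append(f"mean total cost:    {self.mean_cost:.4f}")
        lines.append("-" * 60)
        lines.append("per-metric mean similarity of retained pairs:")
        for col in self.score_columns():
            lines.append(f"  {col[6:]:<12} {self.pairs[col].mean():8.4f}")
        if self.stack is not None:
            diag = self.diagnostics()
            lines.append("-" * 60)
            lines.append("cost diagnostics (CV of contribution, mean POC):")
            for _, row in diag.iterrows():
                lines.append(
                    f"  {row['metric']:<12} cv={row['cv']:7.4f}  "
                    f"poc={row['mean_poc']:6.4f}"
                )
        lines.append("=" * 60)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MappingResults({self.n_pairs} pairs, metrics="
            f"{self.config.cost_metrics!r}, mean_cost={self.mean_cost:.4f})"
        )
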