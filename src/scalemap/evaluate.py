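"""Evaluation of mappings and downstream clustering.

Mapping quality is judged two ways: an Adjusted Rand Index between the
cell-type labels of mapped pairs (did we find the right *kind* of cell?) and
a frequency-aware Jaccard index between the k-NN interaction neighbourhoods
of mapped cells (did we preserve the *spatial context*?).

Two clustering views build on the mapping machinery: query cells cluster by
which reference cells they tend to co-map to (Jaccard over top-n candidate
sets, 1 − J as the distance), and whole samples cluster by the mean
mapping cost between them.
"""

from __future__ import annotations

from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .cost import frequency_aware_jaccard
from .datasets import SpatialDataset

__all__ = [
    "cost_combinations",
    "mapping_events",
    "adjusted_rand_index",
    "interaction_jaccard",
    "co_mapping_clusters",
    "cluster_samples",
    "differential_expression",
]

#: the benchmark's 14 cost-matrix combinations, as metric letter strings
COST_COMBINATIONS = [
    "f",          # cell similarity alone
    "n",          # niche
    "t",          # territory
    "c",          # composition
    "fn",
    "fny",
    "fc",
    "ft",
    "nt",
    "nc",
    "fnt",
    "fnc",
    "fnct",
    "fncty",
]


def cost_combinations() -> List[str]:
    """The benchmark list of cost-stack configurations (14 combinations)."""
    return list(COST_COMBINATIONS)


def mapping_events(
    samples: Sequence, include_self: bool = False
) -> List[Tuple[str, str]]:
    """Ordered (query, reference) pairs over a sample collection.

    With self-mapping excluded, n samples yield n·(n−1) events.
    """
    ids = [s.sample_id if isinstance(s, SpatialDataset) else str(s) for s in samples]
    return [
        (q, r) for q in ids for r in ids if include_self or q != r
    ]


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Permutation-model ARI between two labelings of mapped pairs."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label vectors differ in length: {len(labels_a)} vs {len(labels_b)}"
        )
    return float(adjusted_rand_score(labels_a, labels_b))


def mapped_label_ari(result, query: SpatialDataset, reference: SpatialDataset) -> float:
    """ARI between query and reference cell-type labels over mapped pairs."""
    for d in (query, reference):
        if d.cell_labels is None:
            raise ValueError(f"sample {d.sample_id!r} has no cell labels")
    pairs = result if isinstance(result, pd.DataFrame) else result.pairs
    qlab = dict(zip(query.barcodes, query.cell_labels.astype(str)))
    rlab = dict(zip(reference.barcodes, reference.cell_labels.astype(str)))
    a = [qlab[b] for b in pairs["query_barcode"]]
    b = [rlab[b] for b in pairs["ref_barcode"]]
    return adjusted_rand_index(a, b)


def _knn_label_sets(d: SpatialDataset, k: int) -> List[List[str]]:
    if d.cell_labels is None:
        raise ValueError(f"sample {d.sample_id!r} has no cell labels")
    if k >= d.n_cells:
        raise ValueError(f"k={k} must be smaller than n_cells={d.n_cells}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(d.coords)
    _, idx = nn.kneighbors(d.coords)
    labels = d.cell_labels.astype(str)
    return [list(labels[row[row != i][:k]]) for i, row in enumerate(idx)]


def interaction_jaccard(
    result, query: SpatialDataset, reference: SpatialDataset, k: int = 6
) -> pd.DataFrame:
    """Frequency-aware Jaccard between k-NN neighbourhoods of mapped pairs.

    For each mapped pair, the label multiset of the query cell's k nearest
    neighbours (in its own sample) is compared with that of its matched
    reference cell (in the reference sample) under occurrence
    uniquification.  Returns a per-pair table with a ``jaccard`` column.
    """
    pairs = result if isinstance(result, pd.DataFrame) else result.pairs
    q_sets = _knn_label_sets(query, k)
    r_sets = _knn_label_sets(reference, k)
    qidx = query.barcode_index()
    ridx = reference.barcode_index()
    scores = [
        frequency_aware_jaccard(q_sets[qidx[qb]], r_sets[ridx[rb]])
        for qb, rb in zip(pairs["query_barcode"], pairs["ref_barcode"])
    ]
    return pd.DataFrame(
        {
            "query_barcode": pairs["query_barcode"],
            "ref_barcode": pairs["ref_barcode"],
            "jaccard": scores,
        }
    )


# ---------------------------------------------------------------------------
# co-mapping clustering of query cells
# ---------------------------------------------------------------------------

def _top_sets_from_stack(stack, top_n: int) -> Dict[str, frozenset]:
    """Per active query cell, the top-n lowest-cost reference ids."""
    out = {}
    for qi in stack.active_query:
        order = np.argsort(stack.total_cost[qi], kind="stable")[:top_n]
        out[stack.query_barcodes[qi]] = frozenset(stack.ref_barcodes[order])
    return out


def co_mapping_clusters(
    result,
    stack=None,
    top_n: int = 30,
    method: str = "hierarchical",
    n_clusters: Optional[int] = None,
    height: Optional[float] = None,
    linkage: str = "average",
) -> pd.DataFrame:
    """Cluster query cells by the reference cells they preferentially map to.

    Candidates per query are ranked by ascending mapping cost (best match
    first) and the top-n reference ids kept; queries are compared by the
    Jaccard index of these sets, with 1 − J as the clustering distance.
    Cut the average-linkage tree either at ``n_clusters`` or at ``height``.
    """
    if stack is not None:
        top_sets = _top_sets_from_stack(stack, top_n)
        queries = list(top_sets)
    else:
        pairs = result if isinstance(result, pd.DataFrame) else result.pairs
        grouped = pairs.sort_values("total_cost", kind="stable").groupby(
            "query_barcode", sort=False
        )
        top_sets = {
            q: frozenset(g["ref_barcode"].head(top_n)) for q, g in grouped
        }
        queries = list(top_sets)
    n = len(queries)
    if n < 2:
        raise ValueError("co-mapping clustering needs at least 2 query cells")
    dist = np.zeros((n, n))
    sets = [top_sets[q] for q in queries]
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            jac = inter / union if union else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    if method == "hierarchical":
        link = sch.linkage(squareform(dist, checks=False), method=linkage)
        if n_clusters is not None:
            labels = sch.fcluster(link, t=n_clusters, criterion="maxclust")
        elif height is not None:
            labels = sch.fcluster(link, t=height, criterion="distance")
        else:
            raise ValueError("provide n_clusters or height to cut the tree")
    elif method in ("leiden", "louvain"):
        labels = _community_labels(dist, method)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return pd.DataFrame({"query_barcode": queries, "cluster": labels})


def _community_labels(dist: np.ndarray, method: str) -> np.ndarray:
    """Community detection on the similarity graph implied by 1 − distance."""
    import igraph as ig

    sim = 1.0 - dist
    np.fill_diagonal(sim, 0.0)
    src, dst = np.nonzero(np.triu(sim > 0, k=1))
    g = ig.Graph(
        n=dist.shape[0],
        edges=list(zip(src.tolist(), dst.tolist())),
        edge_attrs={"weight": sim[src, dst].tolist()},
    )
    if method == "leiden":
        import leidenalg

        part = leidenalg.find_partition(
            g, leidenalg.ModularityVertexPartition, weights="weight", seed=0
        )
    else:
        part = g.community_multilevel(weights="weight")
    labels = np.empty(dist.shape[0], dtype=int)
    for ci, members in enumerate(part):
        labels[list(members)] = ci + 1
    return labels


def cluster_samples(
    cost_matrix, height: float = 0.5, linkage: str = "average"
) -> pd.DataFrame:
    """Cluster samples by their pairwise mean mapping costs.

    ``cost_matrix`` is a square DataFrame/array over samples where entry
    (i, j) is the mean cost of mapping sample i onto sample j; it is
    symmetrised as the mean of (i→j) and (j→i), the diagonal (self-mapping)
    is ignored, and the average-linkage tree is cut at ``height``.
    """
    if isinstance(cost_matrix, pd.DataFrame):
        names = list(cost_matrix.index)
        values = cost_matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(cost_matrix, dtype=float)
        names = [f"sample_{i}" for i in range(values.shape[0])]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"cost matrix must be square; got {values.shape}")
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    link = sch.linkage(squareform(sym, checks=False), method=linkage)
    labels = sch.fcluster(link, t=height, criterion="distance")
    return pd.DataFrame({"sample": names, "cluster": labels})


# ---------------------------------------------------------------------------
# differential expression between mapped groups
# ---------------------------------------------------------------------------

def differential_expression(
    d: SpatialDataset,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Runs on the normalised layer; p-values are Benjamini–Hochberg adjusted
    and genes flagged significant at adjusted p < ``alpha``.
    """
    if d.normalized is None:
        raise ValueError("normalise counts before differential expression")
    idx = d.barcode_index()
    ia = np.asarray([idx[b] for b in group_a], dtype=int)
    ib = np.asarray([idx[b] for b in group_b], dtype=int)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need at least 2 cells")
    a = d.normalized[:, ia]
    b = d.normalized[:, ib]
    stat, pval = mannwhitneyu(a, b, axis=1, alternative="two-sided")
    _, p_adj, _, _ = multipletests(pval, method="fdr_bh")
    table = pd.DataFrame(
        {
            "gene": d.genes,
            "statistic": stat,
            "p_value": pval,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
    return table.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
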