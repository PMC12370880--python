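"""Synthetic spatial regimes with ground-truth labels and simulated counts.

Five regime families emulate tissues of increasing organisational
complexity, each sample being a set of uniform points in the unit square
partitioned into a background and territory/layer regions:

* ``circle`` — 5 circular territories of random size placed at random in a
  background; every territory holds 2 cell types and is guaranteed present
  in every sample.
* ``layer`` — one circular territory divided into 5 concentric layers;
  background and each layer hold 2 cell types.
* ``dropped`` — 2 circular territories, each split into 1–3 layers chosen
  per sample, with 1–2 cell types per region, so regions are not
  necessarily shared across samples.
* ``random_one`` / ``random_two`` — 1–3 territories of random shape
  (circle, rod/capsule, or a bounded chaotic-map point cloud) with 0–4
  layers, holding at most one (resp. up to two) cell types per region.

Counts follow a gamma-Poisson (negative-binomial) model: gene-wise baseline
means are log-normal, and each cell type carries a fold-change vector whose
genes are flagged differentially expressed with probability 0.5 between
territories/cell types and 0.05 between layers.  The per-type model is
drawn once per regime and shared by all samples, so cells of the same type
are exchangeable across samples.

Ground-truth spatial context is captured by "interaction" labels: the
lexicographically sorted cell-type labels of each cell's k nearest
neighbours joined with ``@``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from .datasets import SpatialDataset

__all__ = [
    "RegimeConfig",
    "CellTypeModel",
    "generate_layout",
    "simulate_counts",
    "make_sample",
    "generate_regime",
    "add_interactions",
]

REGIMES = ("circle", "layer", "dropped", "random_one", "random_two")


@dataclass
class RegimeConfig:
    """Parameters of one synthetic regime run.

    Defaults are the benchmark conditions: 12 samples of 5000 cells and
    2000 genes, differential-expression probability 0.5 between
    territories/cell types and 0.05 between layers.
    """

    regime: str = "circle"
    n_samples: int = 12
    n_cells: int = 5000
    n_genes: int = 2000
    de_prob_territory: float = 0.5
    de_prob_layer: float = 0.05
    seed: int = 0
    # geometry defaults (package choices; see docs/methods.md)
    circle_radius: Tuple[float, float] = (0.05, 0.2)
    layer_radius: Tuple[float, float] = (0.2, 0.4)
    # count model stand-in parameters
    mean_log_mu: float = np.log(0.5)
    mean_log_sd: float = 1.0
    dispersion: float = 0.3
    de_fc_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        for p in (self.de_prob_territory, self.de_prob_layer):
            if not 0.0 <= p <= 1.0:
                raise ValueError("DE probabilities must lie in [0, 1]")
        for c in (self.n_samples, self.n_cells, self.n_genes):
            if c < 1:
                raise ValueError("counts must be >= 1")


@dataclass
class CellTypeModel:
    """Shared count model: baseline gene means plus per-type fold changes."""

    base_mean: np.ndarray
    fold_changes: Dict[str, np.ndarray]
    dispersion: float

    def mean_for(self, cell_type: str) -> np.ndarray:
        return self.base_mean * self.fold_changes[cell_type]


@dataclass
class Layout:
    """Geometry of one sample: coordinates plus per-cell region labels.

    ``meta`` records the drawn geometry (circle centres/radii, …) so that
    region membership can be audited against the coordinates.
    """

    coords: np.ndarray
    cell_type: np.ndarray
    territory: np.ndarray
    layer: np.ndarray
    meta: dict = field(default_factory=dict)


def _rng_for(cfg: RegimeConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *keys])


# ---------------------------------------------------------------------------
# region vocabularies: canonical per regime so the count model is shared
# ---------------------------------------------------------------------------

def _type_name(territory: str, layer: int, variant: int) -> str:
    if territory == "background":
        return f"bg_{chr(65 + variant)}"
    return f"{territory}_L{layer}_{chr(65 + variant)}"


def regime_type_vocabulary(cfg: RegimeConfig) -> List[str]:
    """Every cell-type label the regime can emit, in canonical order."""
    regime = cfg.regime
    vocab: List[str] = []
    if regime == "circle":
        vocab = ["bg_A"] + [
            _type_name(f"T{t}", 0, v) for t in range(1, 6) for v in range(2)
        ]
    elif regime == "layer":
        vocab = ["bg_A", "bg_B"] + [
            _type_name("T1", l, v) for l in range(5) for v in range(2)
        ]
    elif regime == "dropped":
        vocab = ["bg_A", "bg_B"] + [
            _type_name(f"T{t}", l, v)
            for t in range(1, 3)
            for l in range(3)
            for v in range(2)
        ]
    else:  # random_one / random_two
        vocab = ["bg_A", "bg_B"] + [
            _type_name(f"T{t}", l, v)
            for t in range(1, 4)
            for l in range(5)
            for v in range(2)
        ]
    return vocab


def _layer_membership(regime_dist: np.ndarray, max_dist: float, n_layers: int):
    """Equal-width distance bands, innermost band = layer 0."""
    if n_layers <= 1:
        return np.zeros(len(regime_dist), dtype=int)
    edges = np.linspace(0.0, max_dist, n_layers + 1)
    return np.clip(np.searchsorted(edges, regime_dist, side="right") - 1, 0, n_layers - 1)


# ---------------------------------------------------------------------------
# shapes for the random regimes
# ---------------------------------------------------------------------------

def _capsule_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray):
    """Distance from each point to the segment p0→p1."""
    seg = p1 - p0
    denom = float(seg @ seg)
    t = np.clip(((points - p0) @ seg) / denom, 0.0, 1.0) if denom > 0 else 0.0
    proj = p0 + np.outer(np.atleast_1d(t), seg)
    return np.linalg.norm(points - proj, axis=1)


def _clifford_points(rng: np.random.Generator, n: int = 4000) -> np.ndarray:
    """Point cloud on a bounded 2-D quadratic (Clifford-type) attractor."""
    a, b = rng.uniform(-2.0, 2.0, 2)
    c, d = rng.uniform(0.5, 1.5, 2)
    x, y = 0.1, 0.0
    pts = np.empty((n, 2))
    for i in range(n + 100):
        x, y = np.sin(a * y) + c * np.cos(a * x), np.sin(b * x) + d * np.cos(b * y)
        if i >= 100:  # discard transient
            pts[i - 100] = (x, y)
    return pts


# ---------------------------------------------------------------------------
# layouts per regime
# ---------------------------------------------------------------------------

def _circle_layout(cfg: RegimeConfig, rng: np.random.Generator) -> Layout:
    n = cfg.n_cells
    for _ in range(200):
        coords = rng.uniform(0.0, 1.0, (n, 2))
        radii = rng.uniform(*cfg.circle_radius, 5)
        centers = np.column_stack(
            [rng.uniform(radii, 1 - radii), rng.uniform(radii, 1 - radii)]
        )
        territory = np.zeros(n, dtype=int)  # 0 = background
        for t in range(5):  # later-drawn circles take precedence on overlap
            dist = np.linalg.norm(coords - centers[t], axis=1)
            territory[dist <= radii[t]] = t + 1
        present = all((territory == t).sum() >= 2 for t in range(1, 6))
        if present:
            break
    else:  # pragma: no cover - practically unreachable at benchmark sizes
        raise RuntimeError("could not place all 5 circle territories")
    cell_type = np.empty(n, dtype=object)
    layer = np.zeros(n, dtype=int)
    cell_type[territory == 0] = "bg_A"
    for t in range(1, 6):
        mask = territory == t
        variants = rng.integers(0, 2, mask.sum())
        cell_type[mask] = [_type_name(f"T{t}", 0, v) for v in variants]
    terr_labels = np.where(territory == 0, "background", np.char.add("T", territory.astype(str)))
    meta = {"centers": centers, "radii": radii}
    return Layout(coords, cell_type, terr_labels.astype(object), layer, meta)


def _layer_layout(cfg: RegimeConfig, rng: np.random.Generator) -> Layout:
    n = cfg.n_cells
    radius = rng.uniform(*cfg.layer_radius)
    center = rng.uniform(radius, 1 - radius, 2)
    coords = rng.uniform(0.0, 1.0, (n, 2))
    dist = np.linalg.norm(coords - center, axis=1)
    inside = dist <= radius
    layer = np.full(n, -1, dtype=int)
    layer[inside] = _layer_membership(dist[inside], radius, 5)
    cell_type = np.empty(n, dtype=object)
    bg = ~inside
    cell_type[bg] = [_type_name("background", 0, v) for v in rng.integers(0, 2, bg.sum())]
    for l in range(5):
        mask = layer == l
        cell_type[mask] = [
            _type_name("T1", l, v) for v in rng.integers(0, 2, mask.sum())
        ]
    territory = np.where(inside, "T1", "background").astype(object)
    return Layout(coords, cell_type, territory, layer, {"center": center, "radius": radius})


def _dropped_layout(cfg: RegimeConfig, rng: np.random.Generator) -> Layout:
    n = cfg.n_cells
    coords = rng.uniform(0.0, 1.0, (n, 2))
    territory = np.zeros(n, dtype=int)
    dist_to_center = np.zeros(n)
    radii = rng.uniform(0.1, 0.25, 2)
    centers = np.column_stack([rng.uniform(radii, 1 - radii), rng.uniform(radii, 1 - radii)])
    for t in range(2):
        dist = np.linalg.norm(coords - centers[t], axis=1)
        mask = dist <= radii[t]
        territory[mask] = t + 1
        dist_to_center[mask] = dist[mask]
    layer = np.full(n, -1, dtype=int)
    cell_type = np.empty(n, dtype=object)
    n_bg_types = rng.integers(1, 3)
    bg = territory == 0
    cell_type[bg] = [_type_name("background", 0, v) for v in rng.integers(0, n_bg_types, bg.sum())]
    for t in range(1, 3):
        mask = territory == t
        if not mask.any():
            continue
        n_layers = int(rng.integers(1, 4))
        lay = _layer_membership(dist_to_center[mask], radii[t - 1], n_layers)
        layer[mask] = lay
        for l in range(n_layers):
            lmask = np.flatnonzero(mask)[lay == l]
            n_types = rng.integers(1, 3)
            cell_type[lmask] = [
                _type_name(f"T{t}", l, v) for v in rng.integers(0, n_types, len(lmask))
            ]
    terr_labels = np.where(
        territory == 0, "background", np.char.add("T", territory.astype(str))
    ).astype(object)
    return Layout(coords, cell_type, terr_labels, layer, {"centers": centers, "radii": radii})


def _random_layout(cfg: RegimeConfig, rng: np.random.Generator, max_types: int) -> Layout:
    n = cfg.n_cells
    coords = rng.uniform(0.0, 1.0, (n, 2))
    territory = np.zeros(n, dtype=int)
    region_dist = np.zeros(n)
    region_scale = np.ones(n)
    n_terr = int(rng.integers(1, 4))
    for t in range(1, n_terr + 1):
        shape = rng.choice(["circle", "rod", "chaos"])
        if shape == "circle":
            r = rng.uniform(0.08, 0.25)
            c = rng.uniform(r, 1 - r, 2)
            dist = np.linalg.norm(coords - c, axis=1)
            mask = dist <= r
            scale = r
        elif shape == "rod":
            w = rng.uniform(0.03, 0.08)
            p0 = rng.uniform(0.15, 0.85, 2)
            angle = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(0.2, 0.5)
            p1 = np.clip(p0 + length * np.array([np.cos(angle), np.sin(angle)]), 0.02, 0.98)
            dist = _capsule_distance(coords, p0, p1)
            mask = dist <= w
            scale = w
        else:  # chaos-map point cloud
            pts = _clifford_points(rng)
            lo, hi = pts.min(axis=0), pts.max(axis=0)
            span = np.where(hi - lo > 0, hi - lo, 1.0)
            box0 = rng.uniform(0.0, 0.4, 2)
            box1 = box0 + rng.uniform(0.4, 0.6, 2)
            pts = (pts - lo) / span * (box1 - box0) + box0
            h = 0.03
            dist, _ = cKDTree(pts).query(coords, k=1)
            mask = dist <= h
            scale = h
        territory[mask] = t  # later territories take precedence on overlap
        region_dist[mask] = dist[mask]
        region_scale[mask] = scale
    layer = np.full(n, -1, dtype=int)
    cell_type = np.empty(n, dtype=object)
    bg = territory == 0
    n_bg = 1 if max_types == 1 else int(rng.integers(1, 3))
    cell_type[bg] = [_type_name("background", 0, v) for v in rng.integers(0, n_bg, bg.sum())]
    for t in range(1, n_terr + 1):
        mask = territory == t
        if not mask.any():
            continue
        n_layers = int(rng.integers(0, 5))
        if n_layers >= 1:
            lay = _layer_membership(region_dist[mask], region_scale[mask].max(), n_layers)
        else:
            lay = np.zeros(mask.sum(), dtype=int)
        layer[mask] = lay
        for l in np.unique(lay):
            lmask = np.flatnonzero(mask)[lay == l]
            n_types = 1 if max_types == 1 else int(rng.integers(1, 3))
            cell_type[lmask] = [
                _type_name(f"T{t}", l, v) for v in rng.integers(0, n_types, len(lmask))
            ]
    terr_labels = np.where(
        territory == 0, "background", np.char.add("T", territory.astype(str))
    ).astype(object)
    return Layout(coords, cell_type, terr_labels, layer)


def generate_layout(cfg: RegimeConfig, sample_index: int) -> Layout:
    """Coordinates plus territory/layer/cell-type labels for one sample."""
    rng = _rng_for(cfg, 1, sample_index)
    if cfg.regime == "circle":
        return _circle_layout(cfg, rng)
    if cfg.regime == "layer":
        return _layer_layout(cfg, rng)
    if cfg.regime == "dropped":
        return _dropped_layout(cfg, rng)
    if cfg.regime == "random_one":
        return _random_layout(cfg, rng, max_types=1)
    return _random_layout(cfg, rng, max_types=2)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _de_fold_change(rng: np.random.Generator, n_genes: int, p: float, log_sd: float):
    fc = np.ones(n_genes)
    de = rng.random(n_genes) < p
    fc[de] = np.exp(rng.normal(0.0, log_sd, de.sum()))
    return fc


def build_cell_type_model(cfg: RegimeConfig) -> CellTypeModel:
    """Draw the regime-wide count model once, from the regime seed.

    Fold changes compose hierarchically: a territory-level factor (DE
    probability ``de_prob_territory``) shared by everything in a territory,
    a layer-level factor (``de_prob_layer``) per layer, and a within-region
    variant factor distinguishing the second cell type of a region.  In the
    circle regime each territory cell type draws its own independent
    territory-level factor (DE between cell types at p = 0.5); background
    types are the baseline.
    """
    rng = _rng_for(cfg, 2)
    g = cfg.n_genes
    base_mean = np.exp(rng.normal(cfg.mean_log_mu, cfg.mean_log_sd, g))
    pt, pl, sd = cfg.de_prob_territory, cfg.de_prob_layer, cfg.de_fc_log_sd
    fold_changes: Dict[str, np.ndarray] = {}
    territory_factor: Dict[str, np.ndarray] = {}
    layer_factor: Dict[Tuple[str, int], np.ndarray] = {}
    for name in regime_type_vocabulary(cfg):
        if name.startswith("bg_"):
            variant = name[3:]
            if variant == "A":
                fold_changes[name] = np.ones(g)
            else:  # second background type differs at layer-level probability
                fold_changes[name] = _de_fold_change(rng, g, pl, sd)
            continue
        terr, lay, variant = name.split("_")
        lay_idx = int(lay[1:])
        if cfg.regime == "circle":
            # DE between cell types at territory probability, independent per type
            fold_changes[name] = _de_fold_change(rng, g, pt, sd)
            continue
        if terr not in territory_factor:
            territory_factor[terr] = _de_fold_change(rng, g, pt, sd)
        if (terr, lay_idx) not in layer_factor:
            layer_factor[(terr, lay_idx)] = _de_fold_change(rng, g, pl, sd)
        fc = territory_factor[terr] * layer_factor[(terr, lay_idx)]
        if variant != "A":
            fc = fc * _de_fold_change(rng, g, pl, sd)
        fold_changes[name] = fc
    return CellTypeModel(
        base_mean=base_mean, fold_changes=fold_changes, dispersion=cfg.dispersion
    )


def simulate_counts(
    layout: Layout, cfg: RegimeConfig, model: CellTypeModel, sample_index: int = 0
) -> sp.csr_matrix:
    """Gamma-Poisson counts (genes × cells) under the shared type model."""
    rng = _rng_for(cfg, 3, sample_index)
    n = len(layout.cell_type)
    g = cfg.n_genes
    shape = 1.0 / model.dispersion
    counts = np.zeros((g, n), dtype=np.int64)
    for cell_type in np.unique(layout.cell_type.astype(str)):
        cols = np.flatnonzero(layout.cell_type.astype(str) == cell_type)
        mean = model.mean_for(cell_type)
        lam = rng.gamma(shape, (mean / shape)[:, None], size=(g, len(cols)))
        counts[:, cols] = rng.poisson(lam)
    return sp.csr_matrix(counts)


def add_interactions(d: SpatialDataset, k: int = 6) -> SpatialDataset:
    """Attach k-NN interaction labels: sorted neighbour types joined by '@'."""
    if d.cell_labels is None:
        raise ValueError("interaction labels require cell labels")
    if k >= d.n_cells:
        raise ValueError(f"k={k} must be smaller than n_cells={d.n_cells}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(d.coords)
    _, idx = nn.kneighbors(d.coords)
    labels = d.cell_labels.astype(str)
    interactions = np.empty(d.n_cells, dtype=object)
    for i, row in enumerate(idx):
        neighbors = row[row != i][:k]
        interactions[i] = "@".join(sorted(labels[neighbors]))
    return d.with_(interaction_labels=interactions)


def make_sample(
    cfg: RegimeConfig,
    sample_index: int,
    model: Optional[CellTypeModel] = None,
    interactions_k: Optional[int] = 6,
) -> SpatialDataset:
    """Generate one full sample: layout, counts and interaction labels."""
    if model is None:
        model = build_cell_type_model(cfg)
    layout = generate_layout(cfg, sample_index)
    counts = simulate_counts(layout, cfg, model, sample_index)
    genes = np.asarray([f"gene_{i + 1}" for i in range(cfg.n_genes)], dtype=object)
    barcodes = np.asarray(
        [f"s{sample_index}_cell_{i + 1}" for i in range(cfg.n_cells)], dtype=object
    )
    d = SpatialDataset(
        sample_id=f"{cfg.regime}_{sample_index}",
        barcodes=barcodes,
        coords=layout.coords,
        counts=counts,
        genes=genes,
        cell_labels=layout.cell_type,
        territory_labels=layout.territory,
    )
    if interactions_k is not None:
        d = add_interactions(d, k=interactions_k)
    return d


def generate_regime(cfg: RegimeConfig, interactions_k: Optional[int] = 6):
    """All ``cfg.n_samples`` samples of a regime, sharing one count model."""
    model = build_cell_type_model(cfg)
    return [
        make_sample(cfg, i, model=model, interactions_k=interactions_k)
        for i in range(cfg.n_samples)
    ]
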