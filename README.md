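# scalemap

Interpretable cell mapping across heterogeneous spatial-omics samples.

Spatial transcriptomics and spatial proteomics samples taken from different
sections, time points, technologies or patients rarely share enough
structure for alignment tools to deform one onto the other. `scalemap`
instead *matches cells*: it solves a Linear Assignment Problem (LAP) in
which query cells are assigned to reference cells so as to minimise a total
cost

    C_ij = Σ_k (1 − S_ij^(k)),

the unweighted sum of reciprocals of similarity matrices computed at
several biological scales — the cell's own expression (Pearson r, letter
`f`), its niche's mean expression (`n`), its tissue territory's mean
expression (`t`), the cell-type composition of its niche (frequency-aware
Jaccard, `c`) and its cell-type label (0/1 indicator, `y`). Any subset
("`fnc`", "`fncty`", …) forms a cost stack, and because each matrix keeps
its identity, every mapped pair can be decomposed into per-metric scores
and proportions of contribution — the mapping stays interpretable.

Batches of cells (default 1000) are assigned with scipy's Jonker–Volgenant
family LAP solver and refined over epochs (default 25); a query cell's
retained match is replaced only by a strictly cheaper one, yielding a
many-to-many mapping with per-pair cost, scores and retention epoch, plus
an optional greedy one-to-one reduction.

The package also ships the synthetic spatial regimes used to validate the
approach (circle / layer / dropped / random territory layouts with
gamma-Poisson counts and k-NN "interaction" ground truth), evaluation
metrics (label ARI, interaction Jaccard), co-mapping clustering of query
cells, cost-based clustering of whole samples, and rank-sum differential
expression. It is aimed at computational biologists comparing spatial
samples where structural alignment is impossible.

## Worked example

```python
import scalemap as sm

# two synthetic samples from the "circle" regime: 5 circular territories,
# 2 cell types each, in a background; shared count model across samples
cfg = sm.RegimeConfig(regime="circle", n_samples=3, n_cells=1000,
                      n_genes=500, seed=11)
samples = sm.generate_regime(cfg)
query, ref = samples[0], samples[1]

mapper = sm.CellMapper(query, ref, metrics="fnc", n_features=500,
                       threshold=None)
result = mapper.fit(batch_size=250, epochs=10, seed=3)
print(result.summary())
```

```
Cell mapping results
============================================================
metrics:            fnc
batch size:         250
epochs:             10
seed:               3
retained pairs:     1000
distinct references:   505
mean total cost:    0.7744
------------------------------------------------------------
per-metric mean similarity of retained pairs:
  feature        0.4533
  niche          0.8194
  composition    0.9530
------------------------------------------------------------
cost diagnostics (CV of contribution, mean POC):
  feature      cv= 0.0698  poc=0.7199
  niche        cv= 0.0999  poc=0.2385
  composition  cv= 0.6762  poc=0.0416
============================================================
```

Every query cell retained its cheapest pair across the 10 epochs; the
niche-composition metric is by far the most discriminative (highest CV of
its cost contribution) while carrying the least of the total cost (lowest
POC) — the categorical context signal sharpens the assignment without
drowning the expression similarities. Evaluating against the generator's
ground truth:

```python
ji = sm.interaction_jaccard(result, query, ref, k=6)["jaccard"].mean()
ari = sm.mapped_label_ari(result, query, ref)
print(f"interaction JI {ji:.3f}   cell-label ARI {ari:.3f}")
```

```
interaction JI 0.935   cell-label ARI 0.878
```

With cell similarity alone (`metrics="f"`) the same event scores a mean
interaction JI of about 0.53: the niche and composition scales are what
preserve each cell's spatial context through the mapping.

The same pipeline is scriptable from the shell:

```bash
scalemap simulate --regime circle --samples 3 --cells 1000 --genes 500 --seed 11 --out data/
scalemap map --ref-counts data/circle_1_counts.mtx --ref-cells data/circle_1_cells.tsv \
             --query-counts data/circle_0_counts.mtx --query-cells data/circle_0_cells.tsv \
             --cost fnc --batch-size 250 --epochs 10 --seed 3 --no-threshold --out map.tsv
scalemap evaluate --mapping map.tsv --ref-counts ... --query-counts ... --k 6
```

See `docs/methods.md` for the model, the synthetic regimes and all
numerical choices.

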