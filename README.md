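# c3mi

Benchmarking discrete mutual-information estimators and discretization
methods as components of C3NET gene-regulatory-network inference, on
simulated ensemble gene-expression data.

## What this is for

Mutual information (MI) is the standard dependence measure behind a
family of expression-based network-inference algorithms. In practice MI
is computed by the histogram approach — discretize two gene profiles,
cross-tabulate, estimate entropies — so every inference result silently
depends on (a) the entropy estimator and (b) the discretization method.
This package lets you measure that dependence for C3NET, the
conservative-causal-core algorithm that keeps, per gene, only its single
most significant maximal-MI link.

It provides, as importable library code under `src/c3mi`:

* four entropy estimators on contingency tables — **empirical**,
  **Miller–Madow**, **shrink** (James–Stein towards uniform), and
  **Schürmann–Grassberger** (Dirichlet posterior mean) — and
  MI = H(X) + H(Y) − H(X,Y) in bits;
* three discretizations — **equal frequency**, **equal width**,
  **global equal width** — with the B = round(√N) bin rule;
* **C3NET** inference with a pooled permutation null and
  multiple-testing correction;
* evaluation: all-pairs **AUC-PR** against the true network, ensemble
  aggregation into per-edge TPR weights, and the **Class I / Class II**
  split of edges by the degree score D = deg(i) + deg(j);
* **heterogeneity diagnostics**: Anderson–Darling normality audit,
  Stouffer-combined pair p-values, two-sample KS pair tests, and the
  TP/FP rank-accumulation analysis (R_TP vs R_FP ecdfs);
* a **synthetic-data generator**: sparse Erdős–Rényi topologies,
  acyclic orientation, Hill-type nonlinear regulation with mixed
  activation/repression, Uniform(0,1) roots and Gaussian noise, and
  seeded ensembles of datasets from one network.

The numbered scripts under `analysis/` run the study end to end and
write their tables under `results/`; `docs/methods.md` documents the
model and all defaults.

## Worked example

```python
import numpy as np
import c3mi as m

# one ensemble: a 30-gene network at edge density 0.05, 10 datasets
cfg = m.SimulationConfig(n_genes=30, edge_density=0.05, n_samples=200,
                         n_datasets=10, seed=42)
network, datasets = m.generate_ensemble(cfg)
scheme = m.scheme_for("equal_width", 200)     # B = round(sqrt(200)) = 14

# global score of the first dataset's MI ranking
mi = m.mi_matrix(datasets[0], "miller_madow", scheme)
curve = m.precision_recall_curve(m.mi_scored_pairs(mi), network)
print(f"AUC-PR: {curve.auc:.3f}")

# C3NET inference and local edge-class TPRs over the ensemble
inferred = []
for ds in datasets:
    mm = m.mi_matrix(ds, "miller_madow", scheme)
    null = m.permutation_null(ds, "miller_madow", scheme, 1000, seed=ds.seed)
    sig = m.edge_significance(mm, null, alpha=0.05)
    inferred.append(m.c3net_infer(mm, sig))
weighted = m.ensemble_network(inferred)
classes = m.degree_scores_and_classes(network, d_max=4)
tpr1, tpr2 = m.classwise_tpr(weighted, network, classes)
print(f"median TPR  chain-like (I): {np.median(tpr1):.2f}  "
      f"hub-attached (II): {np.median(tpr2):.2f}")
```

Output:

```
AUC-PR: 0.720
median TPR  chain-like (I): 1.00  hub-attached (II): 0.20
```

The MI ranking recovers the 20-edge network far above the random-ranking
baseline (prevalence |E|/#pairs ≈ 0.046), and chain-like edges (both
endpoint degrees ≤ 2) are recovered by essentially every ensemble member
while the median hub-attached edge is found in only 20% — the local
structure dependence that a global score alone would hide.

A `c3mi` command-line tool wraps the same stages
(`c3mi simulate|mi|infer|evaluate|heterogeneity|benchmark|summarize`);
`configs/benchmark_example.yaml` is a complete grid configuration for
`c3mi benchmark`.

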