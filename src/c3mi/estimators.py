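"""Discrete entropy estimators and mutual information in bits.

Four classical histogram estimators of the Shannon entropy of a binned
distribution, all operating on raw cell counts:

* **empirical** — plug-in maximum-likelihood estimate from observed
  frequencies; known to underestimate the true entropy when cells are
  undersampled.
* **miller_madow** — empirical plus the first-order bias correction
  (B̂ − 1)/(2N) (in nats; converted to bits), with B̂ the number of
  occupied cells by default.
* **shrink** — James–Stein-type shrinkage of the cell frequencies towards
  the uniform distribution, with the closed-form MSE-optimal intensity λ*.
* **schurmann_grassberger** — Bayesian posterior-mean cell probabilities
  under a symmetric Dirichlet prior with concentration 1/#cells, i.e. one
  pseudocount added to the total sample count.

Mutual information is assembled from entropies, I = H(X) + H(Y) − H(X,Y),
with the marginal tables taken as the margins of the joint table so the
decomposition is internally consistent. Logarithms are base 2 throughout.
Bias-corrected MI values can come out slightly negative; they are reported
as computed (ranking, the downstream consumer, is unaffected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .discretize import BinningScheme, ContingencyTable, PairLabeller, joint_counts

ESTIMATORS = ("empirical", "miller_madow", "shrink", "schurmann_grassberger")

_LOG2E = float(np.log2(np.e))


def _counts_array(table) -> np.ndarray:
    c = np.asarray(getattr(table, "counts", table), dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    return c


def _plugin_entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def entropy_empirical(table) -> float:
    """Plug-in entropy −Σ (n_k/N) log2(n_k/N) over occupied cells."""
    c = _counts_array(table)
    n = c.sum()
    if n <= 0:
        raise ValueError("table must contain at least one count")
    return _plugin_entropy(c.ravel() / n)


def entropy_miller_madow(table, occupied: bool = True) -> float:
    """Empirical entropy plus the Miller–Madow bias correction.

    The correction is (B̂ − 1)/(2N)·log2(e) with B̂ the number of occupied
    cells; set ``occupied=False`` to use the nominal cell count instead.
    """
    c = _counts_array(table)
    n = c.sum()
    if n <= 0:
        raise ValueError("table must contain at least one count")
    b = int((c > 0).sum()) if occupied else c.size
    return entropy_empirical(c) + (b - 1) / (2.0 * n) * _LOG2E


def shrink_lambda(table) -> float:
    """MSE-optimal shrinkage intensity towards the uniform target, in [0,1]."""
    c = _counts_array(table).ravel()
    n = c.sum()
    if n <= 1:
        raise ValueError("shrinkage needs at least two observations")
    p_hat = c / n
    t = 1.0 / c.size
    denom = (n - 1.0) * float(((t - p_hat) ** 2).sum())
    if denom == 0.0:
        return 1.0
    lam = (1.0 - float((p_hat**2).sum())) / denom
    return float(np.clip(lam, 0.0, 1.0))


def entropy_shrink(table) -> tuple[float, float]:
    """Entropy of the shrinkage-regularized cell distribution; returns (H, λ)."""
    c = _counts_array(table).ravel()
    n = c.sum()
    if n <= 1:
        raise ValueError("shrinkage needs at least two observations")
    lam = shrink_lambda(c)
    p = lam / c.size + (1.0 - lam) * c / n
    return _plugin_entropy(p), lam


def entropy_sg(table) -> float:
    """Schürmann–Grassberger entropy from Dirichlet posterior-mean cell
    probabilities p_k = (n_k + 1/#cells)/(N + 1)."""
    c = _counts_array(table).ravel()
    n = c.sum()
    if n <= 0:
        raise ValueError("table must contain at least one count")
    p = (c + 1.0 / c.size) / (n + 1.0)
    return _plugin_entropy(p)


def entropy(table, estimator: str) -> float:
    """Dispatch on estimator name; shrink returns the entropy only."""
    if estimator == "empirical":
        return entropy_empirical(table)
    if estimator == "miller_madow":
        return entropy_miller_madow(table)
    if estimator == "shrink":
        return entropy_shrink(table)[0]
    if estimator == "schurmann_grassberger":
        return entropy_sg(table)
    raise ValueError(f"unknown estimator {estimator!r}")


def mi_from_table(table: ContingencyTable, estimator: str) -> float:
    """I = H(X) + H(Y) − H(X,Y) from a joint table and its margins."""
    c = np.asarray(getattr(table, "counts", table))
    if c.ndim != 2:
        raise ValueError("joint table must be 2-dimensional")
    hx = entropy(c.sum(axis=1), estimator)
    hy = entropy(c.sum(axis=0), estimator)
    hxy = entropy(c.ravel(), estimator)
    return hx + hy - hxy


def mutual_information(
    x: np.ndarray, y: np.ndarray, estimator: str, scheme: BinningScheme
) -> float:
    """Discretize a pair of profiles and estimate their MI in bits."""
    from .discretize import discretize_pair

    lx, ly = discretize_pair(np.asarray(x, float), np.asarray(y, float), scheme)
    table = joint_counts(lx, ly, scheme.n_bins, scheme.n_bins)
    return mi_from_table(table, estimator)


@dataclass(frozen=True)
class MIMatrix:
    """Symmetric matrix of pairwise MI estimates (bits), diagonal 0."""

    gene_ids: tuple[str, ...]
    values: np.ndarray
    estimator: str
    scheme: BinningScheme

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids),) * 2:
            raise ValueError("MI matrix shape must be (n_genes, n_genes)")
        object.__setattr__(self, "values", v)

    def pair_value(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.gene_ids)
        ).to_csv(path, sep="\t", index_label="gene")


def mi_matrix(
    dataset: ExpressionDataset, estimator: str, scheme: BinningScheme
) -> MIMatrix:
    """All-pairs MI matrix for one dataset (upper triangle mirrored)."""
    if dataset.n_samples < scheme.n_bins:
        raise ValueError("need at least as many samples as bins")
    labeller = PairLabeller(dataset.values, scheme)
    g = dataset.n_genes
    b = scheme.n_bins
    out = np.zeros((g, g), dtype=float)
    for i in range(g):
        for j in range(i + 1, g):
            lx, ly = labeller.pair(i, j)
            out[i, j] = out[j, i] = mi_from_table(
                joint_counts(lx, ly, b, b), estimator
            )
    return MIMatrix(dataset.gene_ids, out, estimator, scheme)
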