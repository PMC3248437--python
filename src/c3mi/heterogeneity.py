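"""Data-heterogeneity diagnostics: normality audit, pairwise distribution
tests, and the TP/FP rank-accumulation analysis.

Expression data simulated from (or measured on) a regulatory network are
heterogeneous: different gene pairs follow different joint distributions,
so no single "the" distribution exists to study an MI estimator against.
This module quantifies that heterogeneity three ways:

1. per-gene Anderson–Darling normality tests (composite null: mean and
   variance estimated), with a corrected rejection fraction;
2. two-sample Kolmogorov–Smirnov tests comparing the two profiles of each
   gene pair — a homogeneous dataset (all genes i.i.d. from one
   distribution) would reject at about the nominal rate only;
3. rank accumulation: per dataset of an ensemble, gene-pair p-values
   (Stouffer combination of the two genes' normality p-values) are ranked
   ascending; the ranks of the l_k = min(|TP|, |FP|) best TP and FP edges
   of the C3NET inference are accumulated over datasets into count vectors
   R_TP and R_FP, whose ecdfs reveal whether true-positive edges sit on
   more strongly non-normal genes than false positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset
from .networks import GeneNetwork, canonical_pair

_DEGENERATE_P = 1e-300

_SM_METHOD = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}


def gene_normality_pvalues(dataset: ExpressionDataset) -> np.ndarray:
    """Anderson–Darling composite-normality p-value for every gene profile.

    Constant profiles are degenerate for the test; they are reported at the
    minimum representable p-value with a warning, since a constant profile
    is certainly not a normal sample.
    """
    if dataset.n_samples < 8:
        raise ValueError("need at least 8 samples for the normality test")
    out = np.empty(dataset.n_genes, dtype=float)
    for i, row in enumerate(dataset.values):
        if np.ptp(row) == 0.0:
            warnings.warn(
                f"constant profile for gene {dataset.gene_ids[i]!r}; "
                "reporting the degenerate minimum p-value",
                stacklevel=2,
            )
            out[i] = _DEGENERATE_P
        else:
            out[i] = normal_ad(row)[1]
    return out


def rejection_fraction(
    p_values: np.ndarray, alpha: float, correction: str = "bonferroni"
) -> float:
    """Fraction of hypotheses rejected after multiple-testing correction."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if correction == "none":
        reject = p <= alpha
    elif correction in _SM_METHOD:
        reject = multipletests(p, alpha=alpha, method=_SM_METHOD[correction])[0]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(reject.mean())


def combine_pair_pvalues(p_i: float, p_j: float) -> float:
    """Stouffer combination of two one-sided p-values.

    Each p maps to z = Φ⁻¹(1 − p); the combined z = (z_i + z_j)/√2 maps
    back to p = 1 − Φ(z). Small inputs (strong deviation) give a small
    combined p. Inputs at 0 or 1 are clipped with a warning.
    """
    eps = np.finfo(float).tiny
    p = np.array([p_i, p_j], dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        warnings.warn("p-values clipped away from {0, 1} for Stouffer", stacklevel=2)
        p = np.clip(p, eps, 1.0 - 1e-16)
    z = stats.norm.isf(p)
    return float(stats.norm.sf(z.sum() / np.sqrt(2.0)))


def pair_combined_pvalues(
    gene_pvalues: np.ndarray,
    gene_ids: Sequence[str],
    pairs: Sequence[tuple[str, str]],
) -> np.ndarray:
    """Stouffer-combined normality p-value for each listed gene pair."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    return np.array(
        [combine_pair_pvalues(gene_pvalues[idx[a]], gene_pvalues[idx[b]]) for a, b in pairs]
    )


def pair_distribution_pvalues(
    dataset: ExpressionDataset, pairs: Sequence[tuple[str, str]]
) -> np.ndarray:
    """Two-sample KS p-value per pair, comparing the two genes' profiles."""
    idx = {g: i for i, g in enumerate(dataset.gene_ids)}
    out = np.empty(len(pairs), dtype=float)
    for k, (a, b) in enumerate(pairs):
        out[k] = stats.ks_2samp(
            dataset.values[idx[a]], dataset.values[idx[b]], method="asymp"
        ).pvalue
    return out


@dataclass(frozen=True)
class RankAccumulation:
    """Accumulated rank-position counts for TP and FP edges over an ensemble.

    ``r_tp[r-1]`` counts how often, across datasets, a TP edge (among each
    dataset's l_k best-ranked) occupied rank position r of the ascending
    pair-p-value ranking; ``r_fp`` analogously. By the common-length
    construction both vectors sum to Σ_k l_k.
    """

    r_tp: np.ndarray
    r_fp: np.ndarray
    common_lengths: tuple[int, ...]
    n_datasets: int


def _stable_ranks(values: np.ndarray) -> np.ndarray:
    """Integer ranks 1..M, ascending, ties broken by first occurrence."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(values.size, dtype=np.int64)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def tp_fp_rank_accumulate(
    ensemble_pair_pvalues: Sequence[np.ndarray],
    tp_sets: Sequence[set],
    fp_sets: Sequence[set],
    pairs: Sequence[tuple[str, str]],
) -> RankAccumulation:
    """Accumulate TP/FP rank positions over the datasets of an ensemble.

    For dataset k the M pair p-values (in the canonical ``pairs`` order)
    are ranked ascending; with l_k = min(|TP_k|, |FP_k|), the l_k
    lowest-ranked TP pairs and l_k lowest-ranked FP pairs increment R_TP
    respectively R_FP at their rank positions. Datasets with l_k = 0
    contribute nothing.
    """
    m = len(pairs)
    pair_index = {canonical_pair(*p): i for i, p in enumerate(pairs)}
    if not (len(ensemble_pair_pvalues) == len(tp_sets) == len(fp_sets)):
        raise ValueError("per-dataset inputs must have equal length")
    r_tp = np.zeros(m, dtype=np.int64)
    r_fp = np.zeros(m, dtype=np.int64)
    lengths = []
    for pvals, tp, fp in zip(ensemble_pair_pvalues, tp_sets, fp_sets):
        pvals = np.asarray(pvals, dtype=float)
        if pvals.size != m:
            raise ValueError("p-value vector length must equal the pair count")
        tp_idx = {pair_index[canonical_pair(*p)] for p in tp}
        fp_idx = {pair_index[canonical_pair(*p)] for p in fp}
        if tp_idx & fp_idx:
            raise ValueError("TP and FP sets overlap within a dataset")
        l_k = min(len(tp_idx), len(fp_idx))
        lengths.append(l_k)
        if l_k == 0:
            continue
        ranks = _stable_ranks(pvals)
        tp_ranks = np.sort(ranks[sorted(tp_idx)])[:l_k]
        fp_ranks = np.sort(ranks[sorted(fp_idx)])[:l_k]
        r_tp[tp_ranks - 1] += 1
        r_fp[fp_ranks - 1] += 1
    return RankAccumulation(r_tp, r_fp, tuple(lengths), len(lengths))


def ecdf_points(counts: np.ndarray) -> list[tuple[int, float]]:
    """Empirical cdf over rank positions: (rank, cumulative fraction)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    frac = np.cumsum(c) / total
    return [(r + 1, float(f)) for r, f in enumerate(frac)]


@dataclass(frozen=True)
class HeterogeneitySummary:
    """Flat summary of the heterogeneity diagnostics for one dataset."""

    gene_pvalues: np.ndarray
    normality_rejection_fraction: float
    pairwise_rejection_fraction: float
    alpha: float
    correction: str


def summarize_heterogeneity(
    dataset: ExpressionDataset,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> HeterogeneitySummary:
    """Normality and pairwise-distribution rejection fractions for a dataset.

    For homogeneous data (all genes i.i.d. from one distribution) the
    pairwise KS rejection fraction stays near the nominal level — the
    degenerate one-distribution case; materially larger fractions indicate
    heterogeneity.
    """
    gene_p = gene_normality_pvalues(dataset)
    norm_frac = rejection_fraction(gene_p, alpha, correction)
    pair_p = pair_distribution_pvalues(dataset, pairs)
    pair_frac = rejection_fraction(pair_p, alpha, correction)
    return HeterogeneitySummary(gene_p, norm_frac, pair_frac, alpha, correction)
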