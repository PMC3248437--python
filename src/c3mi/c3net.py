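"""Conservative causal core (C3NET) network inference from an MI matrix.

Three steps: (1) pairwise MI estimation (module :mod:`c3mi.estimators`);
(2) per gene, pick the single neighbour with maximal MI; (3) keep only
picks whose MI is significant against a permutation null after multiple-
testing correction. Because every gene contributes at most one edge, the
inferred network has at most as many edges as genes — the conservative
core of the regulatory network. Output is undirected and unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset
from .discretize import BinningScheme, PairLabeller, joint_counts
from .estimators import MIMatrix, mi_from_table
from .networks import GeneNetwork, canonical_pair

CORRECTIONS = ("bonferroni", "benjamini_hochberg", "none")

_SM_METHOD = {"bonferroni": "bonferroni", "benjamini_hochberg": "fdr_bh"}


@dataclass(frozen=True)
class SignificanceResult:
    """Per-pair permutation p-values and the corrected significance mask."""

    p_values: np.ndarray
    alpha: float
    correction: str
    mask: np.ndarray
    n_permutations: int
    seed: int


def permutation_null(
    dataset: ExpressionDataset,
    estimator: str,
    scheme: BinningScheme,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Pooled permutation null for pairwise MI.

    Each draw picks a random gene pair, permutes the sample order of one
    profile (which destroys any dependence while keeping both marginals),
    and records the resulting MI. Pooling across pairs gives one null
    sample shared by all pairs, so the test cost stays linear rather than
    quadratic in the number of genes.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if dataset.n_samples < scheme.n_bins:
        raise ValueError("need at least as many samples as bins")
    if dataset.n_genes < 2:
        raise ValueError("need at least two genes")
    rng = np.random.default_rng(seed)
    labeller = PairLabeller(dataset.values, scheme)
    b = scheme.n_bins
    null = np.empty(n_permutations, dtype=float)
    for t in range(n_permutations):
        i, j = rng.choice(dataset.n_genes, size=2, replace=False)
        lx, ly = labeller.pair(int(i), int(j))
        ly = ly[rng.permutation(ly.size)]
        null[t] = mi_from_table(joint_counts(lx, ly, b, b), estimator)
    return null


def edge_significance(
    mi: MIMatrix,
    null_samples: np.ndarray,
    alpha: float = 0.05,
    correction: str = "benjamini_hochberg",
) -> SignificanceResult:
    """Permutation p-values per pair, corrected over all n(n−1)/2 tests.

    p = (1 + #{null ≥ observed}) / (1 + n_permutations) — the +1 convention
    keeps p strictly positive. The mask marks pairs whose corrected p-value
    is ≤ alpha.
    """
    null = np.sort(np.asarray(null_samples, dtype=float))
    if null.size == 0:
        raise ValueError("null sample is empty")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    g = len(mi.gene_ids)
    iu, ju = np.triu_indices(g, k=1)
    obs = mi.values[iu, ju]
    # count of null values >= obs via position in the sorted null
    n_ge = null.size - np.searchsorted(null, obs, side="left")
    p_flat = (1.0 + n_ge) / (1.0 + null.size)
    if correction == "none":
        reject = p_flat <= alpha
    else:
        reject, _, _, _ = multipletests(
            p_flat, alpha=alpha, method=_SM_METHOD[correction]
        )[:4]
    p = np.zeros((g, g), dtype=float)
    mask = np.zeros((g, g), dtype=bool)
    p[iu, ju] = p_flat
    p[ju, iu] = p_flat
    mask[iu, ju] = reject
    mask[ju, iu] = reject
    return SignificanceResult(p, alpha, correction, mask, null.size, -1)


def c3net_infer(mi: MIMatrix, sig: SignificanceResult) -> GeneNetwork:
    """Per gene, keep its maximal-MI significant pair; collapse duplicates.

    Ties within a gene are broken towards the lexicographically smallest
    partner id, so the result does not depend on gene ordering. Genes with
    no significant pair contribute nothing; the edge count never exceeds
    the gene count.
    """
    g = len(mi.gene_ids)
    if sig.mask.shape != (g, g):
        raise ValueError("significance mask does not match the MI matrix")
    edges: set[tuple[str, str]] = set()
    order = np.argsort(np.array(mi.gene_ids))  # partner scan in id order
    for i in range(g):
        best_j = -1
        best_mi = -np.inf
        for j in order:
            if j == i or not sig.mask[i, j]:
                continue
            if mi.values[i, j] > best_mi:
                best_mi = mi.values[i, j]
                best_j = int(j)
        if best_j >= 0:
            edges.add(canonical_pair(mi.gene_ids[i], mi.gene_ids[best_j]))
    return GeneNetwork.from_edges(mi.gene_ids, edges)
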