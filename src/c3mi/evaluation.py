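"""Global (AUC-PR) and local (edge-class TPR) evaluation against a reference.

The global measure ranks candidate gene pairs by a score (here: MI) and
sweeps a threshold θ over the distinct scores; at each θ the predicted
edge set is {pairs with score ≥ θ} and precision/recall follow from the
confusion table against the reference network. The area under the
precision–recall curve is a trapezoidal integral over recall.

The local measure works on ensembles: K networks inferred from K datasets
of the same underlying network are aggregated into a weighted network
whose edge weights are occurrence fractions — the empirical true-positive
rate of each edge. Reference edges are split by the degree score
D = deg(i) + deg(j) into chain-like Class I (D ≤ D_max) and hub-attached
Class II edges, whose TPR distributions are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .networks import GeneNetwork, canonical_pair


@dataclass(frozen=True)
class PRCurve:
    """One (recall, precision) point per distinct score threshold."""

    recalls: np.ndarray
    precisions: np.ndarray
    thresholds: np.ndarray
    auc: float


def precision_recall_curve(
    scored_pairs: Sequence[tuple[tuple[str, str], float]],
    reference: GeneNetwork,
) -> PRCurve:
    """PR curve of a scored candidate-pair ranking against the reference.

    Recall = TP / |E_ref| (reference edges missing from the candidate list
    count as misses), precision = TP / (TP + FP).
    """
    if reference.n_edges == 0:
        raise ValueError("reference network has no edges")
    scores = np.array([s for _, s in scored_pairs], dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    truth = np.array(
        [canonical_pair(*p) in reference.edges for p, _ in scored_pairs], dtype=bool
    )
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    truth = truth[order]
    tp = np.cumsum(truth)
    fp = np.cumsum(~truth)
    # one point per distinct threshold: take the last index of each score run
    last = np.flatnonzero(np.diff(scores, append=np.nan) != 0)
    thresholds = scores[last]
    recall = tp[last] / reference.n_edges
    precision = tp[last] / (tp[last] + fp[last])
    curve = PRCurve(recall, precision, thresholds, 0.0)
    return PRCurve(recall, precision, thresholds, auc_pr(curve))


def auc_pr(curve: PRCurve) -> float:
    """Trapezoidal area under precision over recall.

    The curve is anchored at recall 0 with the first point's precision, the
    standard convention that avoids the undefined 0/0 corner.
    """
    if curve.recalls.size == 0:
        raise ValueError("curve has no points")
    r = np.concatenate(([0.0], curve.recalls))
    p = np.concatenate(([curve.precisions[0]], curve.precisions))
    return float(np.trapezoid(p, r))


def mi_scored_pairs(mi) -> list[tuple[tuple[str, str], float]]:
    """All unordered gene pairs of an MI matrix with their MI scores."""
    gene_ids = mi.gene_ids
    out = []
    for i in range(len(gene_ids)):
        for j in range(i + 1, len(gene_ids)):
            out.append((canonical_pair(gene_ids[i], gene_ids[j]), float(mi.values[i, j])))
    return out


@dataclass(frozen=True)
class WeightedNetwork:
    """Probabilistic network: weight(i,j) = fraction of ensemble members
    containing edge (i,j), i.e. the empirical per-edge TPR."""

    gene_ids: tuple[str, ...]
    weights: np.ndarray
    ensemble_size: int

    def pair_weight(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.weights[i, j])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            g = len(self.gene_ids)
            for i in range(g):
                for j in range(i + 1, g):
                    w = self.weights[i, j]
                    if w > 0:
                        fh.write(f"{self.gene_ids[i]}\t{self.gene_ids[j]}\t{w:.10g}\n")


def ensemble_network(networks: Sequence[GeneNetwork]) -> WeightedNetwork:
    """Aggregate an ensemble of inferred networks into occurrence fractions."""
    if not networks:
        raise ValueError("ensemble is empty")
    gene_ids = networks[0].gene_ids
    if any(n.gene_ids != gene_ids for n in networks):
        raise ValueError("all networks must share the same gene universe")
    idx = {g: i for i, g in enumerate(gene_ids)}
    counts = np.zeros((len(gene_ids),) * 2, dtype=float)
    for net in networks:
        for a, b in net.edges:
            counts[idx[a], idx[b]] += 1
            counts[idx[b], idx[a]] += 1
    return WeightedNetwork(gene_ids, counts / len(networks), len(networks))


@dataclass(frozen=True)
class EdgeClassification:
    """Degree score D and Class I/II label for every reference edge."""

    edges: tuple[tuple[str, str], ...]
    d_scores: tuple[int, ...]
    classes: tuple[str, ...]
    d_max: int


def degree_scores_and_classes(
    reference: GeneNetwork, d_max: int = 4
) -> EdgeClassification:
    """Score each reference edge by D = deg(i) + deg(j); Class I iff D ≤ D_max.

    The minimum possible D for a real edge is 2 (an isolated pair); with the
    default D_max = 4 both endpoints must have degree ≤ 2 for Class I, so
    Class I edges sit on chains and Class II edges attach to hubs.
    """
    deg = reference.degrees()
    edges = tuple(sorted(reference.edges))
    d = tuple(deg[a] + deg[b] for a, b in edges)
    cls = tuple("I" if s <= d_max else "II" for s in d)
    return EdgeClassification(edges, d, cls, d_max)


def classwise_tpr(
    weighted: WeightedNetwork,
    reference: GeneNetwork,
    classes: EdgeClassification,
) -> tuple[np.ndarray, np.ndarray]:
    """Split reference-edge TPRs (ensemble weights) by edge class.

    Returns the Class I and Class II weight vectors; together they cover
    every reference edge exactly once.
    """
    if weighted.gene_ids != reference.gene_ids:
        raise ValueError("weighted network and reference gene universes differ")
    tpr_1, tpr_2 = [], []
    for edge, cls in zip(classes.edges, classes.classes):
        w = weighted.pair_weight(*edge)
        (tpr_1 if cls == "I" else tpr_2).append(w)
    return np.array(tpr_1), np.array(tpr_2)
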