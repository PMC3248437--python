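"""Synthetic steady-state expression ensembles from Erdős–Rényi networks.

The generator emulates the qualitative features that matter for benchmarking
mutual-information-based network inference, without an external simulator:

* a sparse random (Erdős–Rényi) regulatory topology, with unconnected genes
  kept as pure-noise "non-expressed" genes;
* nonlinear regulator→target coupling — each target is a Hill-type
  saturating function of the (signed) mean of its regulators' activities;
* mixed activation/repression, drawn per regulatory arc;
* per-observation Gaussian measurement noise;
* ensembles: many independent datasets simulated from one fixed network.

Root genes (no regulators) and unconnected genes draw i.i.d. Uniform(0,1)
activities per sample: bounded and deliberately non-Gaussian, so the
normality audit of the heterogeneity analysis has something to detect.
Cycles are avoided by construction — edges are oriented along a random
total order — which makes a single topological sweep a valid steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .networks import DirectedGeneNetwork, GeneNetwork

#: Hill exponent and half-saturation constant of the target response
HILL_M = 2.0
HILL_K = 0.5

DEFAULT_NOISE_SD = 0.05
DEFAULT_INTERACTION_STRENGTH = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition bundle for one ensemble.

    ``edge_density`` is the Erdős–Rényi probability p that any unordered
    gene pair carries an edge; ``noise_sd`` is the additive Gaussian noise
    standard deviation on the [0, 1] activity scale.
    """

    n_genes: int
    edge_density: float
    n_samples: int
    n_datasets: int = 30
    noise_sd: float = DEFAULT_NOISE_SD
    interaction_strength: float = DEFAULT_INTERACTION_STRENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1 or self.n_datasets < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _gene_names(n_genes: int) -> tuple[str, ...]:
    width = len(str(n_genes))
    return tuple(f"G{str(i + 1).zfill(width)}" for i in range(n_genes))


def generate_er_network(n_genes: int, edge_density: float, seed: int) -> GeneNetwork:
    """Draw a G(n, p) network: each unordered pair is an edge w.p. ``edge_density``.

    Unconnected genes stay in the gene universe (they model non-expressed
    genes). Same seed, same arguments → identical network.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    genes = _gene_names(n_genes)
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_genes, k=1)
    mask = rng.random(iu.size) < edge_density
    edges = [(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])]
    return GeneNetwork.from_edges(genes, edges)


def orient_for_simulation(network: GeneNetwork, seed: int) -> DirectedGeneNetwork:
    """Orient edges along a random total order and draw per-arc signs.

    A uniform random permutation of the genes serves as topological order;
    each undirected edge becomes an arc from its earlier to its later
    endpoint, so the result is acyclic by construction. Each arc is an
    activator or a repressor with probability 1/2.
    """
    rng = np.random.default_rng(seed)
    order = tuple(network.gene_ids[i] for i in rng.permutation(network.n_genes))
    pos = {g: i for i, g in enumerate(order)}
    arcs = []
    for a, b in sorted(network.edges):
        arcs.append((a, b) if pos[a] < pos[b] else (b, a))
    signs = {arc: (1 if rng.random() < 0.5 else -1) for arc in arcs}
    return DirectedGeneNetwork(network.gene_ids, tuple(arcs), order, signs)


def _hill(u: np.ndarray) -> np.ndarray:
    um = np.power(u, HILL_M)
    return um / (um + HILL_K**HILL_M)


def simulate_expression(
    dnet: DirectedGeneNetwork,
    n_samples: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    interaction_strength: float = DEFAULT_INTERACTION_STRENGTH,
    seed: int = 0,
) -> ExpressionDataset:
    """Simulate one steady-state dataset from an oriented network.

    Per sample: root genes (in-degree 0) draw Uniform(0,1) activities; each
    regulated gene evaluates, in topological order,

        x_t = h(s · mean_r c_r) + ε,   h(u) = u^m / (u^m + k^m)

    where c_r is the regulator's activity clipped to [0,1] for an activator
    and one minus that for a repressor, s is ``interaction_strength``, and
    ε ~ N(0, noise_sd²). Same seed → bit-identical matrix.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    parents = dnet.parents()
    idx = {g: i for i, g in enumerate(dnet.gene_ids)}
    values = np.empty((dnet.n_genes, n_samples), dtype=float)
    for g in dnet.order:
        regs = parents[g]
        if not regs:
            x = rng.uniform(0.0, 1.0, size=n_samples)
        else:
            contrib = np.empty((len(regs), n_samples))
            for r, (reg, sign) in enumerate(regs):
                c = np.clip(values[idx[reg]], 0.0, 1.0)
                contrib[r] = c if sign > 0 else 1.0 - c
            u = interaction_strength * contrib.mean(axis=0)
            x = _hill(u) + rng.normal(0.0, noise_sd, size=n_samples)
        values[idx[g]] = x
    return ExpressionDataset(dnet.gene_ids, values, seed=seed)


def generate_ensemble(
    config: SimulationConfig,
) -> tuple[GeneNetwork, list[ExpressionDataset]]:
    """One network, many datasets: the ensemble unit of the whole study.

    The network and its orientation are drawn once from ``config.seed``;
    dataset i (1-based) is simulated with seed ``config.seed + i``, so any
    single ensemble member can be regenerated without the rest.
    """
    net = generate_er_network(config.n_genes, config.edge_density, config.seed)
    dnet = orient_for_simulation(net, config.seed)
    datasets = [
        simulate_expression(
            dnet,
            config.n_samples,
            noise_sd=config.noise_sd,
            interaction_strength=config.interaction_strength,
            seed=config.seed + i,
        )
        for i in range(1, config.n_datasets + 1)
    ]
    return net, datasets
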