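"""Undirected and directed gene-network containers with edge-list TSV I/O.

Networks are small (hundreds of genes) and sparse, so edges are kept as a
frozenset of canonical ``(a, b)`` gene-id pairs rather than an adjacency
structure. Unconnected genes are first-class citizens: they model
non-expressed (pure-noise) genes and must survive file round-trips, hence
the separate gene-universe file next to the edge list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` in its canonical (sorted) form."""
    if a == b:
        raise ValueError(f"self-pair {a!r} is not a valid edge")
    return (a, b) if a < b else (b, a)


def all_pairs(gene_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs in the canonical study order (i < j by index).

    This ordering is the tie-break and vectorisation order used throughout:
    significance testing, PR scoring and the rank-accumulation analysis all
    enumerate pairs this way.
    """
    return [
        canonical_pair(gene_ids[i], gene_ids[j])
        for i in range(len(gene_ids))
        for j in range(i + 1, len(gene_ids))
    ]


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected, unweighted gene network.

    Parameters
    ----------
    gene_ids
        Ordered gene universe; genes without any edge are retained.
    edges
        Unordered gene-id pairs, stored once each in canonical order.
    """

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        known = set(self.gene_ids)
        if len(known) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if a > b:
                raise ValueError(f"edge ({a!r}, {b!r}) not in canonical order")
            if a not in known or b not in known:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown gene")

    @classmethod
    def from_edges(
        cls, gene_ids: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "GeneNetwork":
        return cls(tuple(gene_ids), frozenset(canonical_pair(a, b) for a, b in edges))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def degrees(self) -> dict[str, int]:
        deg = {g: 0 for g in self.gene_ids}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def write(self, edge_path: str | Path, genes_path: str | Path) -> None:
        """Write a two-column TSV edge list plus a one-column gene universe."""
        with open(edge_path, "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")
        with open(genes_path, "w") as fh:
            for g in self.gene_ids:
                fh.write(f"{g}\n")

    @classmethod
    def read(cls, edge_path: str | Path, genes_path: str | Path) -> "GeneNetwork":
        gene_ids = [ln.strip() for ln in open(genes_path) if ln.strip()]
        edges = []
        for ln in open(edge_path):
            ln = ln.strip()
            if not ln:
                continue
            a, b = ln.split("\t")
            edges.append((a, b))
        return cls.from_edges(gene_ids, edges)


@dataclass(frozen=True)
class DirectedGeneNetwork:
    """Acyclic regulator→target orientation of a :class:`GeneNetwork`.

    Only the simulator needs direction; evaluation ignores it. Acyclicity is
    guaranteed by construction: every arc must go forward in ``order``, a
    total order over the genes.

    ``signs`` maps each arc to +1 (activator) or -1 (repressor).
    """

    gene_ids: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...]
    order: tuple[str, ...]
    signs: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = {g: i for i, g in enumerate(self.order)}
        if set(self.order) != set(self.gene_ids):
            raise ValueError("order must be a permutation of gene_ids")
        for reg, tgt in self.arcs:
            if pos[reg] >= pos[tgt]:
                raise ValueError(f"arc {reg!r}->{tgt!r} violates topological order")
        for arc, s in self.signs.items():
            if s not in (-1, 1):
                raise ValueError(f"sign of arc {arc} must be +/-1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def parents(self) -> dict[str, list[tuple[str, int]]]:
        """Map each gene to its ``(regulator, sign)`` list (sign defaults +1)."""
        par: dict[str, list[tuple[str, int]]] = {g: [] for g in self.gene_ids}
        for reg, tgt in self.arcs:
            par[tgt].append((reg, self.signs.get((reg, tgt), 1)))
        return par

    def undirected(self) -> GeneNetwork:
        return GeneNetwork.from_edges(self.gene_ids, self.arcs)
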