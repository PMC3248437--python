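"""Expression-matrix container and TSV round-trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes × samples real-valued expression matrix.

    ``seed`` is a provenance tag recording the RNG seed the matrix was
    simulated with (-1 for data read from file).
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    seed: int = -1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"values must be ({len(self.gene_ids)}, n_samples), got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def to_tsv(self, path: str | Path) -> None:
        """Write TSV: first column gene id, header row of sample ids."""
        df = pd.DataFrame(
            self.values,
            index=list(self.gene_ids),
            columns=[f"S{j + 1}" for j in range(self.n_samples)],
        )
        df.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(g) for g in df.index), df.to_numpy(dtype=float))
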