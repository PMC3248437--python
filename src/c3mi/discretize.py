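"""Histogram discretization of expression pairs and joint-count tables.

Three binning schemes are supported, matching the standard vocabulary:

* ``equal_frequency`` — per-variable quantile bins (≈ same occupancy);
* ``equal_width``     — per-variable range split into B equal intervals;
* ``global_equal_width`` — one pooled range over both variables of the
  pair, split into B equal intervals shared by x and y.

Intervals are left-open right-closed, except the first which is closed on
both sides, so every finite value lands in exactly one bin 1..B. The bin
count follows the proportional k-interval rule B = round(sqrt(N)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METHODS = ("equal_frequency", "equal_width", "global_equal_width")


@dataclass(frozen=True)
class BinningScheme:
    method: str
    n_bins: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def choose_bin_count(n_samples: int) -> int:
    """Proportional k-interval bin rule: B = round(sqrt(N)), at least 2."""
    if n_samples < 4:
        raise ValueError("need at least 4 samples to discretize")
    return max(2, round(np.sqrt(n_samples).item()))


def scheme_for(method: str, n_samples: int) -> BinningScheme:
    return BinningScheme(method, choose_bin_count(n_samples))


def _uniform_labels(v: np.ndarray, lo: float, hi: float, n_bins: int) -> np.ndarray:
    """Labels 1..B for B equal-width intervals over [lo, hi], right-closed."""
    if hi <= lo:  # constant data: everything in the first bin
        return np.ones(v.shape, dtype=np.int64)
    width = (hi - lo) / n_bins
    inner = lo + width * np.arange(1, n_bins)
    lab = np.searchsorted(inner, v, side="left") + 1
    return np.clip(lab, 1, n_bins).astype(np.int64)


def _quantile_labels(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency labels 1..B; tied values never split across bins.

    Positions in the stable sort order are assigned bins floor(pos·B/N);
    a run of equal values takes the bin of its first (lowest) position,
    i.e. ties are first-fit to the lower bin.
    """
    n = v.size
    order = np.argsort(v, kind="stable")
    sv = v[order]
    pos_bin = (np.arange(n, dtype=np.int64) * n_bins) // n
    first = np.searchsorted(sv, sv, side="left")
    lab = np.empty(n, dtype=np.int64)
    lab[order] = pos_bin[first] + 1
    return lab


def discretize_vector(v: np.ndarray, method: str, n_bins: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    if method == "equal_frequency":
        return _quantile_labels(v, n_bins)
    if method == "equal_width":
        return _uniform_labels(v, v.min(), v.max(), n_bins)
    raise ValueError(f"method {method!r} is not a per-variable scheme")


def discretize_pair(
    x: np.ndarray, y: np.ndarray, scheme: BinningScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a pair of profiles into labels 1..B under ``scheme``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < scheme.n_bins:
        raise ValueError("need at least as many samples as bins")
    if scheme.method == "global_equal_width":
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        return (
            _uniform_labels(x, lo, hi, scheme.n_bins),
            _uniform_labels(y, lo, hi, scheme.n_bins),
        )
    return (
        discretize_vector(x, scheme.method, scheme.n_bins),
        discretize_vector(y, scheme.method, scheme.n_bins),
    )


@dataclass(frozen=True)
class ContingencyTable:
    """Joint bin counts n_k of a discretized pair; the estimator substrate."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def marginal_x(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def joint_counts(
    labels_x: np.ndarray, labels_y: np.ndarray, bx: int, by: int
) -> ContingencyTable:
    """Cross-tabulate two label vectors (labels 1..B) into a B_x × B_y table."""
    lx = np.asarray(labels_x, dtype=np.int64)
    ly = np.asarray(labels_y, dtype=np.int64)
    if lx.shape != ly.shape:
        raise ValueError("label vectors must have equal length")
    if lx.min(initial=1) < 1 or lx.max(initial=1) > bx:
        raise ValueError("labels_x out of range 1..B_x")
    if ly.min(initial=1) < 1 or ly.max(initial=1) > by:
        raise ValueError("labels_y out of range 1..B_y")
    flat = np.bincount((lx - 1) * by + (ly - 1), minlength=bx * by)
    return ContingencyTable(flat.reshape(bx, by))


class PairLabeller:
    """Cached per-gene labels for a whole expression matrix.

    For the per-variable schemes every gene is discretized once up front;
    for ``global_equal_width`` the bin edges depend on the pooled range of
    the pair, so labels are computed per request from cached row extrema.
    """

    def __init__(self, values: np.ndarray, scheme: BinningScheme) -> None:
        self.values = np.asarray(values, dtype=float)
        self.scheme = scheme
        if scheme.method == "global_equal_width":
            self._lo = self.values.min(axis=1)
            self._hi = self.values.max(axis=1)
            self._labels = None
        else:
            self._labels = np.vstack(
                [
                    discretize_vector(row, scheme.method, scheme.n_bins)
                    for row in self.values
                ]
            )

    def pair(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        if self._labels is not None:
            return self._labels[i], self._labels[j]
        lo = min(self._lo[i], self._lo[j])
        hi = max(self._hi[i], self._hi[j])
        b = self.scheme.n_bins
        return (
            _uniform_labels(self.values[i], lo, hi, b),
            _uniform_labels(self.values[j], lo, hi, b),
        )
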