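"""Pairwise correlation matrices: blocked Pearson r and bit-packed tetrachoric r_t.

Two estimators of the V x V correlation structure are provided, both
storing only the upper triangle (i < j) in linear memory:

* :func:`pearson_matrix` — Pearson's r on the continuous series, with
  per-voxel means and norms precomputed once and the pairwise products
  evaluated in configurable blocks.  Blocking changes the memory schedule
  only; the resulting triangle is identical (to floating tolerance) for
  every block size.

* :func:`tetrachoric_matrix` — the tetrachoric correlation of the
  median-dichotomized series.  Because a median split fixes both marginals
  of the 2x2 contingency table at 1/2, the estimator has the closed form

      r_t = -cos(2 * pi * n11 / T),

  where n11 counts time points at which both binary series are 1.  n11 is
  obtained by bitwise AND + popcount over the packed words, and r_t is
  read from a lookup table indexed by n11 — the cosine is never evaluated
  per pair.  Consequently r_t can only attain the discrete values
  {-cos(2*pi*n/T) : n attainable}; the attainable n11 under tie-free
  median splits are 0..T/2 (T even) or 1..(T+1)/2 (T odd).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dichotomize import PackedBinaryMatrix

__all__ = [
    "TriangularCorrelationMatrix",
    "TetrachoricLookupTable",
    "triangular_index",
    "pearson_pair",
    "pearson_matrix",
    "n11_pair",
    "tetrachoric_from_n11",
    "tetrachoric_matrix",
]


def triangular_index(i, j, V: int):
    """Linear position of pair (i, j) in the row-major upper triangle.

    Bijection between {(i, j) : 0 <= i < j < V} and {0, ..., V(V-1)/2 - 1};
    symmetric in its arguments.  Accepts scalars or arrays.
    """
    i = np.asarray(i)
    j = np.asarray(j)
    if np.any(i == j):
        raise ValueError("self-pairs (i == j) are not stored")
    if np.any(i >= V) or np.any(j >= V) or np.any(i < 0) or np.any(j < 0):
        raise ValueError("node index out of range")
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    idx = lo * (2 * V - lo - 1) // 2 + (hi - lo - 1)
    return idx if idx.ndim else int(idx)


@dataclass
class TriangularCorrelationMatrix:
    """Upper-triangular pairwise correlations in linear storage.

    Attributes
    ----------
    values : ndarray of float64, shape (V*(V-1)/2,)
        Entry for pair (i, j), i < j, at :func:`triangular_index`(i, j, V).
        Missing (degenerate-pair) entries hold NaN.
    V : int
        Node count.
    estimator : str
        ``"r"`` (Pearson) or ``"r_t"`` (tetrachoric).
    T : int
        Length of the source series.
    missing : ndarray of bool
        Mask over ``values``; True where the pair involves a degenerate node.
    """

    values: np.ndarray
    V: int
    estimator: str
    T: int = 0
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        n_pairs = self.V * (self.V - 1) // 2
        if self.values.shape != (n_pairs,):
            raise ValueError("values length must be V*(V-1)/2")
        if self.missing is None:
            self.missing = np.isnan(self.values)

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    @property
    def missing_count(self) -> int:
        return int(self.missing.sum())

    def lookup(self, i: int, j: int) -> float:
        """Correlation of nodes i and j (order-free)."""
        return float(self.values[triangular_index(i, j, self.V)])

    def to_dense(self, diag: float = 1.0) -> np.ndarray:
        """Expand to a dense symmetric V x V matrix."""
        out = np.full((self.V, self.V), diag, dtype=np.float64)
        iu, ju = np.triu_indices(self.V, k=1)
        out[iu, ju] = self.values
        out[ju, iu] = self.values
        return out

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.bin`` (flat float64 triangle) + ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        self.values.astype(np.float64).tofile(prefix.with_suffix(".bin"))
        sidecar = {
            "V": self.V,
            "T": self.T,
            "estimator": self.estimator,
            "layout": "row-major-upper-triangle",
            "dtype": "float64",
            "missing_count": self.missing_count,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, prefix: str | Path) -> "TriangularCorrelationMatrix":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        values = np.fromfile(prefix.with_suffix(".bin"), dtype=np.float64)
        return cls(values=values, V=meta["V"], estimator=meta["estimator"], T=meta["T"])


def pearson_pair(s_v: np.ndarray, s_w: np.ndarray) -> float:
    """Pearson's sample correlation of two series.

    Returns NaN (with a warning) for constant input, where r is undefined.
    """
    x = np.asarray(s_v, dtype=np.float64)
    y = np.asarray(s_w, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("series must share a length T >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt(xc @ xc)
    ny = np.sqrt(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        warnings.warn("constant series: Pearson r undefined", stacklevel=2)
        return float("nan")
    return float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))


def pearson_matrix(
    data: np.ndarray, block: int = 256, degenerate: np.ndarray | None = None
) -> TriangularCorrelationMatrix:
    """Upper-triangular Pearson correlation matrix of V x T data, blocked.

    Per-voxel subexpressions (mean, centered norm) are computed once; the
    cross-products are then evaluated block by block so only
    ``block x block`` submatrices are materialized at a time.  The result
    is independent of ``block`` up to floating-point summation order.

    Parameters
    ----------
    data : ndarray, shape (V, T)
    block : int
        Row/column block size (>= 1).  Purely a memory/cache knob.
    degenerate : ndarray of bool, optional
        Extra rows to force missing (e.g. flags from dichotomization).
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be V x T with V >= 2")
    if block < 1:
        raise ValueError("block must be >= 1")
    V, T = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    bad = norms == 0.0
    if degenerate is not None:
        bad = bad | np.asarray(degenerate, dtype=bool)
    safe = np.where(norms == 0.0, 1.0, norms)
    z = xc / safe[:, None]

    n_pairs = V * (V - 1) // 2
    values = np.empty(n_pairs, dtype=np.float64)
    for bi in range(0, V, block):
        zi = z[bi : bi + block]
        for bj in range(bi, V, block):
            prod = zi @ z[bj : bj + block].T
            for ii in range(zi.shape[0]):
                gi = bi + ii
                j0 = max(bj, gi + 1)
                if j0 >= bj + prod.shape[1]:
                    continue
                row = prod[ii, j0 - bj :]
                start = triangular_index(gi, j0, V)
                values[start : start + row.shape[0]] = row
    np.clip(values, -1.0, 1.0, out=values)

    missing = np.zeros(n_pairs, dtype=bool)
    if bad.any():
        iu, ju = np.triu_indices(V, k=1)
        missing = bad[iu] | bad[ju]
        values[missing] = np.nan
    return TriangularCorrelationMatrix(
        values=values, V=V, estimator="r", T=T, missing=missing
    )


@dataclass(frozen=True)
class TetrachoricLookupTable:
    """Precomputed r_t = -cos(2*pi*n/T) indexed by n11.

    The table covers the full range 0..T so tied data can never index out
    of bounds, although only 0..T/2 (T even) or 1..(T+1)/2 (T odd) is
    attainable under tie-free median splits.
    """

    T: int
    table: np.ndarray

    @classmethod
    def build(cls, T: int) -> "TetrachoricLookupTable":
        if T < 2:
            raise ValueError("T must be >= 2")
        n = np.arange(T + 1)
        return cls(T=T, table=-np.cos(2.0 * np.pi * n / T))

    @property
    def attainable_n11(self) -> np.ndarray:
        """n11 values reachable under a tie-free median split."""
        if self.T % 2 == 0:
            return np.arange(0, self.T // 2 + 1)
        return np.arange(1, (self.T + 1) // 2 + 1)

    @property
    def attainable_values(self) -> np.ndarray:
        return self.table[self.attainable_n11]


def n11_pair(p_v: np.ndarray, p_w: np.ndarray) -> int:
    """Joint-ones count of two packed rows: popcount of their bitwise AND."""
    p_v = np.asarray(p_v)
    p_w = np.asarray(p_w)
    if p_v.shape != p_w.shape or p_v.dtype != p_w.dtype:
        raise ValueError("packed rows must share length and word width")
    return int(np.bitwise_count(p_v & p_w).sum())


def tetrachoric_from_n11(n11: int, T: int) -> float:
    """Closed-form tetrachoric correlation from the joint-ones count.

    r_t = -cos(2*pi*n11/T); monotone increasing in n11 on [0, T/2].
    Values above the tie-free attainable maximum ceil(T/2) are still
    computed (tied data can produce them) but trigger a warning.
    """
    if not 0 <= n11 <= T:
        raise ValueError("n11 must lie in [0, T]")
    if n11 > -(-T // 2):
        warnings.warn(
            f"n11={n11} exceeds the tie-free attainable maximum {-(-T // 2)}",
            stacklevel=2,
        )
    return float(-np.cos(2.0 * np.pi * n11 / T))


def tetrachoric_matrix(pb: PackedBinaryMatrix) -> TriangularCorrelationMatrix:
    """Upper-triangular tetrachoric correlation matrix from packed binary data.

    For every pair i < j: AND the packed rows, popcount to get n11, and
    read r_t from the lookup table.  Pairs involving degenerate-flagged
    rows are reported missing (NaN).
    """
    V, T = pb.V, pb.T
    if V < 2:
        raise ValueError("need at least two nodes")
    lut = TetrachoricLookupTable.build(T)
    n_pairs = V * (V - 1) // 2
    values = np.empty(n_pairs, dtype=np.float64)
    max_n11 = 0
    for i in range(V - 1):
        anded = pb.words[i] & pb.words[i + 1 :]
        n11 = np.bitwise_count(anded).sum(axis=1)
        if n11.size:
            max_n11 = max(max_n11, int(n11.max()))
        start = triangular_index(i, i + 1, V)
        values[start : start + n11.shape[0]] = lut.table[n11]
    if max_n11 > -(-T // 2):
        warnings.warn(
            f"n11={max_n11} exceeds the tie-free attainable maximum {-(-T // 2)}; "
            "input likely contains ties at the median",
            stacklevel=2,
        )
    missing = np.zeros(n_pairs, dtype=bool)
    if pb.degenerate.any():
        iu, ju = np.triu_indices(V, k=1)
        missing = pb.degenerate[iu] | pb.degenerate[ju]
        values[missing] = np.nan
    return TriangularCorrelationMatrix(
        values=values, V=V, estimator="r_t", T=T, missing=missing
    )
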