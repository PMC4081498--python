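"""Median dichotomization of voxel time series and bit-packing.

Each continuous time series is binarized at its own sample median: time
point ``k`` becomes 1 iff the signal value is at least the median.  For
tie-free data this yields balanced binary series (exactly T/2 ones for
even T, (T+1)/2 for odd T), which is the precondition for the closed-form
tetrachoric correlation used downstream.  Binary series are bit-packed
into fixed-width unsigned words so that a joint-ones count between two
series reduces to bitwise AND plus popcount over ceil(T/word_width) words.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinarySeries",
    "PackedBinaryMatrix",
    "DegenerateSeriesWarning",
    "median_dichotomize",
    "dichotomize_matrix",
    "pack",
    "unpack",
]

_WORD_DTYPES = {8: np.uint8, 32: np.uint32, 64: np.uint64}


class DegenerateSeriesWarning(UserWarning):
    """A constant (zero-variance) series was dichotomized.

    The result is all ones (every value equals, hence "is at least", the
    median) but no correlation estimator is defined against such a node;
    downstream code reports correlations with flagged nodes as missing.
    """


@dataclass(frozen=True)
class BinarySeries:
    """A median-dichotomized time series.

    Attributes
    ----------
    bits : ndarray of uint8, shape (T,)
        Binary values in time order.
    degenerate : bool
        True when the source series was constant.
    """

    bits: np.ndarray
    degenerate: bool = False

    @property
    def T(self) -> int:
        return self.bits.shape[0]

    @property
    def ones_count(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class PackedBinaryMatrix:
    """V binary series of length T packed into V x W unsigned words.

    Bit order is little-endian within a word: time index ``k`` occupies
    bit ``k % word_width`` of word ``k // word_width``.  Padding bits
    beyond position T are zero, so popcounts over whole rows equal the
    ones-counts of the unpacked series.

    Attributes
    ----------
    words : ndarray, shape (V, W)
        Packed rows; ``W == ceil(T / word_width)``.
    T : int
        Number of time points (scans).
    word_width : int
        Bits per word; one of 8, 32, 64.
    degenerate : ndarray of bool, shape (V,)
        Rows flagged as constant before dichotomization.
    """

    words: np.ndarray
    T: int
    word_width: int
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.degenerate is None:
            object.__setattr__(
                self, "degenerate", np.zeros(self.words.shape[0], dtype=bool)
            )

    @property
    def V(self) -> int:
        return self.words.shape[0]

    @property
    def W(self) -> int:
        return self.words.shape[1]

    def popcounts(self) -> np.ndarray:
        """Per-row ones-counts via word-wise popcount."""
        return np.bitwise_count(self.words).sum(axis=1).astype(np.int64)


def median_dichotomize(series: np.ndarray) -> BinarySeries:
    """Binarize a series at its sample median (ties map to 1).

    Bit ``k`` is 1 iff ``series[k] >= median(series)`` with the standard
    sample median (mean of the two central order statistics for even T).

    Parameters
    ----------
    series : array-like, shape (T,)
        Continuous series, T >= 2, all values finite.

    Returns
    -------
    BinarySeries
        With ``degenerate=True`` (and a :class:`DegenerateSeriesWarning`)
        when the input is constant.
    """
    s = np.asarray(series, dtype=np.float64)
    if s.ndim != 1 or s.shape[0] < 2:
        raise ValueError("series must be one-dimensional with T >= 2")
    if not np.all(np.isfinite(s)):
        raise ValueError("series contains non-finite values")
    degenerate = bool(s.min() == s.max())
    if degenerate:
        warnings.warn(
            "constant series: all bits set, correlations undefined",
            DegenerateSeriesWarning,
            stacklevel=2,
        )
    bits = (s >= np.median(s)).astype(np.uint8)
    return BinarySeries(bits=bits, degenerate=degenerate)


def dichotomize_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise median dichotomization of a V x T matrix.

    Returns
    -------
    bits : ndarray of uint8, shape (V, T)
    degenerate : ndarray of bool, shape (V,)
        Rows that were constant (their bits are all 1).
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("data must be V x T with T >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("data contains non-finite values")
    med = np.median(x, axis=1, keepdims=True)
    bits = (x >= med).astype(np.uint8)
    degenerate = x.min(axis=1) == x.max(axis=1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant series flagged as degenerate",
            DegenerateSeriesWarning,
            stacklevel=2,
        )
    return bits, degenerate


def pack(
    bits: np.ndarray,
    word_width: int = 64,
    degenerate: np.ndarray | None = None,
) -> PackedBinaryMatrix:
    """Bit-pack a V x T binary matrix into fixed-width words.

    Parameters
    ----------
    bits : ndarray, shape (V, T)
        Strictly 0/1 values.
    word_width : {8, 32, 64}
        Word size in bits.
    degenerate : ndarray of bool, shape (V,), optional
        Degeneracy flags carried through from dichotomization.
    """
    if word_width not in _WORD_DTYPES:
        raise ValueError(f"word_width must be one of {sorted(_WORD_DTYPES)}")
    b = np.asarray(bits)
    if b.ndim != 2 or b.shape[1] == 0:
        raise ValueError("bits must be a non-empty V x T matrix")
    if not np.isin(b, (0, 1)).all():
        raise ValueError("bits must contain only 0 and 1")
    V, T = b.shape
    W = -(-T // word_width)  # ceil
    # packbits fills trailing byte padding with zeros; pad bytes to W words
    packed_bytes = np.packbits(b.astype(np.uint8), axis=1, bitorder="little")
    n_bytes = W * (word_width // 8)
    if packed_bytes.shape[1] < n_bytes:
        pad = np.zeros((V, n_bytes - packed_bytes.shape[1]), dtype=np.uint8)
        packed_bytes = np.hstack([packed_bytes, pad])
    words = packed_bytes.view(_WORD_DTYPES[word_width])
    if degenerate is None:
        degenerate = np.zeros(V, dtype=bool)
    return PackedBinaryMatrix(
        words=words, T=T, word_width=word_width, degenerate=np.asarray(degenerate)
    )


def unpack(pb: PackedBinaryMatrix) -> np.ndarray:
    """Recover the V x T binary matrix from its packed form (exact round-trip)."""
    as_bytes = pb.words.view(np.uint8).reshape(pb.V, -1)
    bits = np.unpackbits(as_bytes, axis=1, bitorder="little")
    return bits[:, : pb.T]
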