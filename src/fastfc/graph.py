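"""Density-thresholded binary graphs and degree-based node statistics.

A functional-connectivity graph is obtained by thresholding the pairwise
correlation matrix.  Rather than fixing the correlation cutoff theta,
which would yield graphs of different sizes across subjects, the cutoff is
chosen per matrix so that all graphs share a target density

    kappa = 2|E| / (V(V-1)),

the fraction of potential edges that exist.  Edges are the top
round(kappa * V(V-1)/2) correlations; ties are broken deterministically by
(i, j) lexicographic order, and the reported theta is the smallest
correlation included.  Node importance is summarized by the degree
k_i (incident-edge count), z-scored per subject for comparable scaling,
and group maps are voxel-wise averages over the subjects whose mask
covers each voxel, dropping voxels supported by fewer than a set fraction
of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .correlation import TriangularCorrelationMatrix

__all__ = [
    "BinaryGraph",
    "DegreeMap",
    "GroupKMap",
    "density_threshold",
    "degree",
    "standardize_degrees",
    "group_average",
]


@dataclass
class BinaryGraph:
    """Undirected binary graph from density thresholding.

    Attributes
    ----------
    V : int
        Node count.
    edges : ndarray of int64, shape (|E|, 2)
        Unordered pairs stored once with i < j, sorted lexicographically.
    theta : float
        Correlation threshold realized (smallest included correlation).
    """

    V: int
    edges: np.ndarray
    theta: float = float("nan")

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def kappa(self) -> float:
        """Realized density 2|E| / (V(V-1))."""
        return 2.0 * self.n_edges / (self.V * (self.V - 1))

    def adjacency(self) -> np.ndarray:
        out = np.zeros((self.V, self.V), dtype=np.uint8)
        if self.n_edges:
            out[self.edges[:, 0], self.edges[:, 1]] = 1
            out[self.edges[:, 1], self.edges[:, 0]] = 1
        return out

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def save_edgelist(self, path: str | Path) -> None:
        """Write one `i<TAB>j` line per edge (0-based)."""
        np.savetxt(path, self.edges, fmt="%d", delimiter="\t")

    @classmethod
    def load_edgelist(cls, path: str | Path, V: int) -> "BinaryGraph":
        edges = np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2)
        if edges.size == 0:
            edges = np.empty((0, 2), dtype=np.int64)
        return cls(V=V, edges=edges)


@dataclass
class DegreeMap:
    """Raw and standardized node degrees, optionally tied to voxel coordinates."""

    k: np.ndarray
    z: np.ndarray | None = None
    coords: np.ndarray | None = None


@dataclass
class GroupKMap:
    """Group-average standardized-degree map on a shared 3D grid.

    Voxels supported by fewer than ``support_fraction`` of subjects hold NaN.
    """

    mean: np.ndarray
    support: np.ndarray
    support_fraction: float
    n_subjects: int = 0
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.kept is None:
            self.kept = ~np.isnan(self.mean)


def density_threshold(
    C: TriangularCorrelationMatrix, kappa: float
) -> tuple[float, BinaryGraph]:
    """Threshold a correlation triangle at a target density.

    Selects the round(kappa * V(V-1)/2) largest non-missing correlations
    as edges, breaking ties by (i, j) lexicographic order, and reports
    theta as the smallest correlation included.  Missing (degenerate)
    entries can never become edges.

    Returns
    -------
    (theta, BinaryGraph)

    Raises
    ------
    ValueError
        If kappa is outside (0, 1) or missing entries make the target
        edge count infeasible.
    """
    if not 0.0 < kappa < 1.0:
        raise ValueError("kappa must lie in (0, 1)")
    n_pairs = C.n_pairs
    n_valid = n_pairs - C.missing_count
    if n_valid < 1:
        raise ValueError("correlation matrix has no non-missing entries")
    m = int(round(kappa * n_pairs))
    if m > n_valid:
        raise ValueError(
            f"target density needs {m} edges but only {n_valid} non-missing pairs exist"
        )
    iu, ju = np.triu_indices(C.V, k=1)
    vals = np.where(C.missing, -np.inf, C.values)
    # stable deterministic order: descending value, then (i, j) lexicographic
    order = np.lexsort((ju, iu, -vals))
    chosen = order[:m]
    theta = float(vals[chosen[-1]]) if m > 0 else float("inf")
    edges = np.stack([iu[chosen], ju[chosen]], axis=1).astype(np.int64)
    edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
    return theta, BinaryGraph(V=C.V, edges=edges, theta=theta)


def degree(G: BinaryGraph, coords: np.ndarray | None = None) -> DegreeMap:
    """Raw node degrees k_i = number of incident edges; sum(k) == 2|E|."""
    k = np.bincount(G.edges.ravel(), minlength=G.V).astype(np.int64)
    return DegreeMap(k=k, coords=coords)


def standardize_degrees(k: np.ndarray) -> np.ndarray:
    """z-score degrees with the population (n-denominator) standard deviation.

    Raises
    ------
    ValueError
        For fewer than two nodes or zero degree variance.
    """
    k = np.asarray(k, dtype=np.float64)
    if k.shape[0] < 2:
        raise ValueError("need at least two nodes")
    sd = k.std()
    if sd == 0.0:
        raise ValueError("zero degree variance: standardization undefined")
    return (k - k.mean()) / sd


def group_average(
    kmaps: list[np.ndarray], support_fraction: float = 0.2
) -> GroupKMap:
    """Voxel-wise average of per-subject standardized-degree maps.

    Each map is a 3D array with NaN at voxels outside the subject's mask.
    A voxel's average is taken over the subjects that support it (non-NaN);
    voxels supported by fewer than ``support_fraction`` of all subjects
    are discarded (NaN in the output).
    """
    if not kmaps:
        raise ValueError("empty subject list")
    if not 0.0 < support_fraction <= 1.0:
        raise ValueError("support_fraction must lie in (0, 1]")
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in kmaps])
    if any(m.shape != stack.shape[1:] for m in kmaps):
        raise ValueError("all maps must share one grid")
    support = (~np.isnan(stack)).sum(axis=0)
    totals = np.nansum(stack, axis=0)
    mean = np.divide(
        totals, support, out=np.full(support.shape, np.nan), where=support > 0
    )
    n = stack.shape[0]
    mean[support < support_fraction * n] = np.nan
    return GroupKMap(
        mean=mean,
        support=support,
        support_fraction=support_fraction,
        n_subjects=n,
    )
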