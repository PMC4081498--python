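"""Reading fMRI-like datasets, gray-matter masking and band-pass preprocessing.

Nodes of a voxel-level graph are the voxels whose gray-matter (GM)
probability reaches a threshold (0.2 by default).  :func:`load_dataset`
extracts one time series per supra-threshold voxel from a 4D NIfTI volume,
in deterministic C-order over the grid, so node indices map back to voxel
coordinates reproducibly.  :func:`bandpass` applies the customary
resting-state band-pass (0.01-0.1 Hz) with a zero-phase Butterworth
filter; it removes slow scanner drifts and high-frequency noise while
leaving the pass band essentially untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import signal

__all__ = [
    "TimeSeriesMatrix",
    "VoxelMask",
    "load_dataset",
    "bandpass",
    "degree_map_to_nifti",
]

DEFAULT_GM_THRESHOLD = 0.2
DEFAULT_BAND = (0.01, 0.1)  # Hz


@dataclass
class TimeSeriesMatrix:
    """V continuous voxel time series of length T.

    Attributes
    ----------
    data : ndarray, shape (V, T)
    coords : ndarray of int, shape (V, 3), optional
        Voxel coordinate of each node (grid indices); None for headless
        matrices loaded from plain text.
    tr : float, optional
        Repetition time in seconds (sampling interval).
    """

    data: np.ndarray
    coords: np.ndarray | None = None
    tr: float | None = None

    @property
    def V(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1]

    def save_tsv(self, path: str | Path) -> None:
        np.savetxt(path, self.data, delimiter="\t")

    @classmethod
    def load_tsv(cls, path: str | Path, tr: float | None = None) -> "TimeSeriesMatrix":
        data = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(data=data, tr=tr)


@dataclass
class VoxelMask:
    """Boolean node mask over a 3D grid with the node -> voxel mapping.

    Node order is the C-order linear scan of the grid, making the mapping
    deterministic and invertible.
    """

    mask: np.ndarray
    coords: np.ndarray
    gm_threshold: float

    @property
    def V(self) -> int:
        return self.coords.shape[0]

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-node values back onto the 3D grid."""
        if values.shape[0] != self.V:
            raise ValueError("one value per node required")
        out = np.full(self.mask.shape, fill, dtype=np.float64)
        out[tuple(self.coords.T)] = values
        return out


def load_dataset(
    functional: str | Path,
    gm_map: str | Path,
    theta_gm: float = DEFAULT_GM_THRESHOLD,
) -> tuple[TimeSeriesMatrix, VoxelMask]:
    """Extract masked voxel time series from a 4D volume + 3D GM probability map.

    A voxel becomes a node iff its GM probability is >= ``theta_gm``.

    Raises
    ------
    ValueError
        On spatial grid mismatch or when no voxel passes the threshold.
    """
    func_img = nib.load(str(functional))
    gm_img = nib.load(str(gm_map))
    func = np.asarray(func_img.dataobj, dtype=np.float64)
    gm = np.asarray(gm_img.dataobj, dtype=np.float64)
    if func.ndim != 4:
        raise ValueError("functional image must be 4D")
    if gm.shape != func.shape[:3]:
        raise ValueError(
            f"grid mismatch: functional {func.shape[:3]} vs GM map {gm.shape}"
        )
    mask = gm >= theta_gm
    coords = np.argwhere(mask)  # C-order scan: deterministic node order
    if coords.shape[0] == 0:
        raise ValueError(f"no voxel reaches GM threshold {theta_gm}")
    data = func[mask]  # (V, T), same C-order as argwhere
    tr = float(func_img.header.get_zooms()[3]) if len(func_img.header.get_zooms()) > 3 else None
    ts = TimeSeriesMatrix(data=data, coords=coords, tr=tr)
    return ts, VoxelMask(mask=mask, coords=coords, gm_threshold=theta_gm)


def bandpass(
    ts: TimeSeriesMatrix,
    tr: float | None = None,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass of every node's time series.

    Frequencies below ``low`` and above ``high`` (Hz) are attenuated; the
    filter is applied forward and backward (filtfilt) so no phase shift is
    introduced and the output length equals T.  The DC component falls in
    the stop band and is removed.

    Parameters
    ----------
    tr : float
        Repetition time in seconds; taken from ``ts.tr`` when omitted.
    """
    tr = tr if tr is not None else ts.tr
    if tr is None or tr <= 0:
        raise ValueError("a positive TR (seconds) is required")
    nyquist = 0.5 / tr
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high")
    if high > nyquist:
        raise ValueError(
            f"high cutoff {high} Hz exceeds the Nyquist frequency {nyquist:.4g} Hz "
            f"for TR={tr} s"
        )
    sos = signal.butter(
        order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=1)
    return TimeSeriesMatrix(data=filtered, coords=ts.coords, tr=tr)


def degree_map_to_nifti(
    values: np.ndarray,
    mask: VoxelMask,
    path: str | Path,
    affine: np.ndarray | None = None,
) -> None:
    """Write per-node values as a 3D NIfTI volume on the mask's grid.

    Unmasked voxels hold NaN, so downstream group averaging can tell
    unsupported voxels apart from genuine zeros.
    """
    vol = mask.embed(values)
    img = nib.Nifti1Image(vol.astype(np.float64), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
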