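"""Synthetic datasets with planted correlation structure.

Real resting-state data are not required anywhere in this package: this
module generates (a) V x T voxel time-series matrices in which chosen
clusters of voxels share a latent signal, giving an exact expected
pairwise correlation within each cluster, and (b) small 4D NIfTI volumes
plus 3D gray-matter probability maps that round-trip through the loader,
with a JSON ground-truth sidecar.  The latent-factor construction

    voxel = sqrt(rho) * shared + sqrt(1 - rho) * idiosyncratic

with standard-normal components yields unit-variance series whose
within-cluster pairwise correlation is exactly rho in expectation, so
cluster-recovery tests have a closed-form target.

Defaults mirror a typical resting-state acquisition: T=275 scans at
TR=1.5 s (a common high-sampling protocol; the slower TR=3 s, T=119
regime is equally representable by changing the spec).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .io import TimeSeriesMatrix, bandpass

__all__ = ["PlantedStructureSpec", "make_timeseries", "make_nifti_dataset"]


@dataclass(frozen=True)
class PlantedStructureSpec:
    """Parameters of a synthetic voxel-time-series dataset.

    Attributes
    ----------
    V : int
        Total number of voxels (nodes).
    T : int
        Number of scans per voxel.
    clusters : tuple of (size, rho)
        Planted clusters; each of ``size`` voxels shares a latent signal
        scaled so that the expected pairwise correlation within the
        cluster is ``rho`` (0 < rho < 1).  Sizes must sum to <= V;
        remaining voxels are independent noise.
    tr : float
        Repetition time in seconds.
    apply_bandpass : bool
        Pass the series through the 0.01-0.1 Hz band-pass to emulate
        preprocessed data spectra (default off: keeps unit tests analytic).
    seed : int
        Seed for the dataset's generator.
    """

    V: int = 200
    T: int = 275
    clusters: tuple[tuple[int, float], ...] = ((20, 0.7),)
    tr: float = 1.5
    apply_bandpass: bool = False
    seed: int = 0

    def __post_init__(self):
        if sum(size for size, _ in self.clusters) > self.V:
            raise ValueError("cluster sizes must sum to <= V")
        for size, rho in self.clusters:
            if not 0.0 < rho < 1.0:
                raise ValueError("within-cluster correlation must lie in (0, 1)")
            if size < 2:
                raise ValueError("clusters need at least two voxels")


def make_timeseries(
    spec: PlantedStructureSpec,
) -> tuple[TimeSeriesMatrix, np.ndarray]:
    """Generate the V x T matrix and the ground-truth cluster labels.

    Returns
    -------
    ts : TimeSeriesMatrix
    labels : ndarray of int, shape (V,)
        Cluster index per voxel, -1 for background-noise voxels.
        Cluster voxels occupy the leading rows in cluster order.
    """
    rng = np.random.default_rng(spec.seed)
    data = rng.standard_normal((spec.V, spec.T))
    labels = np.full(spec.V, -1, dtype=np.int64)
    start = 0
    for ci, (size, rho) in enumerate(spec.clusters):
        shared = rng.standard_normal(spec.T)
        block = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * data[start : start + size]
        data[start : start + size] = block
        labels[start : start + size] = ci
        start += size
    ts = TimeSeriesMatrix(data=data, tr=spec.tr)
    if spec.apply_bandpass:
        ts = bandpass(ts)
    return ts, labels


def make_nifti_dataset(
    spec: PlantedStructureSpec,
    grid_shape: tuple[int, int, int],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a synthetic 4D functional volume + 3D GM probability map to disk.

    The spec's V voxels are placed at the first V grid positions in
    C-order and given GM probability 0.9 (>= the 0.2 threshold); all other
    voxels get probability 0.05 and pure noise time series.  A JSON
    sidecar records the ground truth (node coordinates, cluster labels,
    seed).

    Returns
    -------
    dict with paths: ``functional``, ``gm_map``, ``truth``.
    """
    nx, ny, nz = grid_shape
    n_grid = nx * ny * nz
    if n_grid < spec.V:
        raise ValueError(f"grid {grid_shape} too small for V={spec.V} voxels")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ts, labels = make_timeseries(spec)
    rng = np.random.default_rng(spec.seed + 1)

    func = rng.standard_normal((nx, ny, nz, spec.T)) * 0.5
    gm = np.full((nx, ny, nz), 0.05)
    flat_coords = np.stack(
        np.unravel_index(np.arange(spec.V), grid_shape), axis=1
    )
    func[tuple(flat_coords.T)] = ts.data
    gm[tuple(flat_coords.T)] = 0.9

    affine = np.eye(4)
    func_img = nib.Nifti1Image(func.astype(np.float32), affine)
    func_img.header.set_zooms((1.0, 1.0, 1.0, spec.tr))
    gm_img = nib.Nifti1Image(gm.astype(np.float32), affine)

    paths = {
        "functional": out / "functional.nii.gz",
        "gm_map": out / "gm_map.nii.gz",
        "truth": out / "ground_truth.json",
    }
    nib.save(func_img, str(paths["functional"]))
    nib.save(gm_img, str(paths["gm_map"]))
    truth = {
        "V": spec.V,
        "T": spec.T,
        "tr": spec.tr,
        "seed": spec.seed,
        "grid_shape": list(grid_shape),
        "coords": flat_coords.tolist(),
        "labels": labels.tolist(),
        "clusters": [list(c) for c in spec.clusters],
    }
    paths["truth"].write_text(json.dumps(truth))
    return paths
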