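"""Sphere-mask ROI extraction and per-subject analysis-matrix assembly.

Five regions of interest (bilateral putamen, bilateral insula, right cingulate) are
defined by MNI-mm centers with 5-mm-radius spheres ("10 mm diameter"; some sphere tools
read such a value as a radius, so the radius is configurable).  A voxel belongs to a
sphere iff the Euclidean distance from its center to the sphere center is <= the radius
(boundary ties included).  The analysis matrix per subject is T rows x 7 columns: the
five ROI mean series in fixed order plus the binary specific/general task-onset vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edges import INPUT_NAMES, ROI_ORDER

__all__ = [
    "ROISpec",
    "GridSpec",
    "ROIError",
    "EmptyMaskError",
    "default_roi_specs",
    "sphere_mask",
    "sphere_extends_outside",
    "mean_timeseries",
    "build_inputs",
    "assemble_matrix",
    "write_subject_matrix",
    "read_subject_matrix",
]


class ROIError(ValueError):
    """Invalid ROI specification or extraction input."""


class EmptyMaskError(ROIError):
    """A sphere mask contains no voxels."""


@dataclass(frozen=True)
class ROISpec:
    """A spherical ROI: name, hemisphere, MNI-mm center and radius."""

    name: str
    hemisphere: str
    center_mni: tuple[float, float, float]
    radius_mm: float = 5.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ROIError("radius_mm must be positive")
        if self.hemisphere not in ("L", "R"):
            raise ROIError("hemisphere must be 'L' or 'R'")


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid: array shape and a 4x4 affine mapping voxel indices to MNI mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        aff = np.asarray(self.affine, float)
        if aff.shape != (4, 4):
            raise ROIError("affine must be 4 x 4")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def centered(cls, shape=(40, 48, 30), voxel_mm=(3.0, 3.0, 4.0)) -> "GridSpec":
        """A grid whose center voxel sits near MNI (0, 0, 0)."""
        aff = np.diag(list(voxel_mm) + [1.0])
        aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * np.asarray(voxel_mm)
        return cls(tuple(int(s) for s in shape), aff)


def default_roi_specs(radius_mm: float = 5.0) -> list[ROISpec]:
    """The five study ROIs (MNI mm), in the fixed analysis column order."""
    coords = {
        "putamen_l": ("L", (-23.0, 7.0, 4.0)),
        "putamen_r": ("R", (18.0, 10.0, 0.0)),
        "insula_l": ("L", (-42.0, 6.0, 0.0)),
        "insula_r": ("R", (37.0, 4.0, 3.0)),
        "cingulate_r": ("R", (2.0, 11.0, 46.0)),
    }
    return [ROISpec(name, hemi, xyz, radius_mm) for name, (hemi, xyz) in coords.items()]


def _voxel_centers_mm(grid: GridSpec) -> np.ndarray:
    """(nx, ny, nz, 3) array of voxel-center MNI coordinates."""
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
    return np.einsum("ab,ijkb->ijka", grid.affine, vox)[..., :3]


def sphere_mask(spec: ROISpec, grid: GridSpec) -> list[tuple[int, int, int]]:
    """Voxel indices whose centers lie within ``radius_mm`` of the sphere center."""
    centers = _voxel_centers_mm(grid)
    d2 = np.sum((centers - np.asarray(spec.center_mni)) ** 2, axis=-1)
    idx = np.argwhere(d2 <= spec.radius_mm**2 + 1e-9)
    if len(idx) == 0:
        raise EmptyMaskError(
            f"sphere mask for {spec.name!r} (radius {spec.radius_mm} mm) contains no voxels"
        )
    return [tuple(int(v) for v in row) for row in sorted(map(tuple, idx))]


def sphere_extends_outside(spec: ROISpec, grid: GridSpec) -> bool:
    """True if the sphere's bounding box reaches beyond the voxel grid."""
    centers = _voxel_centers_mm(grid)
    lo = centers.reshape(-1, 3).min(axis=0)
    hi = centers.reshape(-1, 3).max(axis=0)
    c = np.asarray(spec.center_mni)
    return bool(np.any(c - spec.radius_mm < lo) or np.any(c + spec.radius_mm > hi))


def mean_timeseries(volume, mask: list[tuple[int, int, int]]) -> np.ndarray:
    """Unweighted mean series across the mask voxels of a 4-D volume (array or NIfTI)."""
    data = volume.get_fdata() if hasattr(volume, "get_fdata") else np.asarray(volume, float)
    if data.ndim != 4:
        raise ROIError("volume must be 4-D (x, y, z, t)")
    if not mask:
        raise EmptyMaskError("mask is empty")
    for vox in mask:
        if any(v < 0 or v >= s for v, s in zip(vox, data.shape[:3])):
            raise ROIError(f"mask voxel {vox} is outside the volume bounds {data.shape[:3]}")
    return np.mean([data[vox] for vox in mask], axis=0)


def build_inputs(schedule: pd.DataFrame, tr_s: float, n_trs: int):
    """Binary TR-bin onset vectors from a transfer schedule.

    ``specific`` marks bins containing a CS1 or CS2 onset, ``general`` marks CS3 onsets;
    CS4/CS5 contribute to neither.  An onset at time t belongs to bin floor(t / TR).
    """
    from .task import PhaseMismatchError

    if "phase" in schedule.columns and len(schedule):
        if not (schedule["phase"] == "transfer").all():
            raise PhaseMismatchError("input vectors are built from transfer-phase schedules")
    specific = np.zeros(n_trs)
    general = np.zeros(n_trs)
    for row in schedule.itertuples(index=False):
        if row.trial_type in ("CS1", "CS2", "CS3"):
            b = int(np.floor(row.onset / tr_s))
            if b >= n_trs:
                raise ROIError(
                    f"onset {row.onset:.2f}s falls beyond the series span {n_trs * tr_s:.0f}s"
                )
            if row.trial_type == "CS3":
                general[b] += 1.0
            else:
                specific[b] += 1.0
    return specific, general


def assemble_matrix(roi_series: dict[str, np.ndarray], inputs) -> pd.DataFrame:
    """Stack the five ROI series and the two input vectors into the analysis matrix.

    ``inputs`` is a (specific, general) pair or a DataFrame with those columns.  Column
    order is fixed: putamen_l, putamen_r, insula_l, insula_r, cingulate_r, specific,
    general.
    """
    if isinstance(inputs, pd.DataFrame):
        specific = inputs["specific"].to_numpy()
        general = inputs["general"].to_numpy()
    else:
        specific, general = (np.asarray(v, float) for v in inputs)
    missing = [r for r in ROI_ORDER if r not in roi_series]
    if missing:
        raise ROIError(f"missing ROI series for {missing}")
    lengths = {len(np.asarray(roi_series[r])) for r in ROI_ORDER} | {len(specific), len(general)}
    if len(lengths) != 1:
        raise ROIError(f"series length mismatch: {sorted(lengths)}")
    T = lengths.pop()
    if T == 0:
        raise ROIError("cannot assemble an empty (T = 0) matrix")
    if np.any(specific < 0) or np.any(general < 0):
        raise ROIError("input columns must be non-negative")
    data = {r: np.asarray(roi_series[r], float) for r in ROI_ORDER}
    data["specific"] = specific
    data["general"] = general
    return pd.DataFrame(data, columns=list(ROI_ORDER) + list(INPUT_NAMES))


def write_subject_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_subject_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in list(ROI_ORDER) + list(INPUT_NAMES) if c not in df.columns]
    if missing:
        raise ROIError(f"subject matrix missing columns {missing}")
    if df.isna().any().any():
        raise ROIError("subject matrix contains missing values")
    return df
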