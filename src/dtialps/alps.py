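"""ALPS index: diffusivity along the perivascular space from fiber-ROI tensors.

At the level of the lateral ventricle body the perivascular spaces of the
deep medullary veins run right-left (x), nearly perpendicular both to the
corticofugal projection fibers (principal axis craniocaudal, z) and to the
superior-longitudinal-fasciculus association fibers (principal axis
anterior-posterior, y). The index contrasts the x-axis diffusivity inside
both fiber ROIs against the diffusivity perpendicular to x and to each
fiber tract:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

An isotropic medium gives exactly 1; water movement along the
perivascular (x) direction pushes the index above 1.

ROI means of the tensor diagonal elements are taken first and one index is
computed from them (not per-voxel indices averaged), and "x-axis
diffusivity" is the diagonal tensor element in image coordinates.
Per-subject indices are the mean of two observers' independent
measurements.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .tensor import TensorField

__all__ = [
    "RoiMask",
    "AxisDiffusivities",
    "AlpsResult",
    "extract_axis_diffusivities",
    "compute_alps",
    "single_observer_result",
    "average_observers",
]

FIBER_KINDS = ("projection", "association")
HEMISPHERES = ("right", "left")


@dataclass(frozen=True)
class RoiMask:
    """Voxel set of one fiber ROI on a single axial slice.

    ``voxels`` holds integer (x, y, z) indices; all voxels must share one z
    index, matching single-slice ROI placement at the lateral ventricle
    body.
    """

    voxels: np.ndarray  # (k, 3) int
    fiber_kind: str
    hemisphere: str

    def __post_init__(self) -> None:
        vox = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        if vox.size == 0:
            raise ValueError("ROI mask is empty")
        if vox.ndim != 2 or vox.shape[1] != 3:
            raise ValueError("ROI voxels must have shape (k, 3)")
        if np.unique(vox[:, 2]).size != 1:
            raise ValueError("ROI must lie on a single axial slice (one z index)")
        if self.fiber_kind not in FIBER_KINDS:
            raise ValueError(f"fiber_kind must be one of {FIBER_KINDS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_index(self) -> int:
        return int(self.voxels[0, 2])

    def area_mm2(self, voxel_size) -> float:
        """In-plane ROI size in mm^2 given the voxel geometry."""
        return self.n_voxels * float(voxel_size[0]) * float(voxel_size[1])

    @classmethod
    def from_label_volume(cls, labels: np.ndarray, value: int, fiber_kind: str,
                          hemisphere: str, slice_index: int | None = None
                          ) -> "RoiMask":
        """Build an ROI from a label volume, restricted to one axial slice.

        If ``slice_index`` is None the median z index of the labelled voxels
        is used (the middle of the labelled slab).
        """
        idx = np.argwhere(np.asarray(labels) == value)
        if idx.size == 0:
            raise ValueError(f"label value {value} not present in volume")
        if slice_index is None:
            slice_index = int(np.median(idx[:, 2]))
        sel = idx[idx[:, 2] == slice_index]
        if sel.size == 0:
            raise ValueError(f"label value {value} absent from slice {slice_index}")
        return cls(voxels=sel, fiber_kind=fiber_kind, hemisphere=hemisphere)

    @classmethod
    def from_json(cls, path) -> "RoiMask":
        """Read an ROI from a JSON voxel list
        (``{"fiber_kind":..., "hemisphere":..., "voxels": [[x,y,z],...]}``)."""
        with open(path) as fh:
            doc = json.load(fh)
        return cls(voxels=np.asarray(doc["voxels"], dtype=int),
                   fiber_kind=doc["fiber_kind"], hemisphere=doc["hemisphere"])


@dataclass(frozen=True)
class AxisDiffusivities:
    """The four ROI-mean diagonal diffusivities entering the index (mm^2/s)."""

    d_xproj: float
    d_yproj: float
    d_xassoc: float
    d_zassoc: float

    def __post_init__(self) -> None:
        for name in ("d_xproj", "d_yproj", "d_xassoc", "d_zassoc"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _roi_diagonal(field: TensorField, roi: RoiMask) -> np.ndarray:
    grid = np.asarray(field.grid_shape)
    vox = roi.voxels
    if np.any(vox < 0) or np.any(vox >= grid):
        raise ValueError("ROI references voxels outside the tensor field grid")
    ix, iy, iz = vox[:, 0], vox[:, 1], vox[:, 2]
    if np.any(field.invalid[ix, iy, iz]):
        raise ValueError("ROI contains voxels where no tensor could be fitted")
    if np.any(field.clipped[ix, iy, iz]):
        warnings.warn(
            "ROI contains voxels with clipped (originally non-positive) "
            "eigenvalues; diffusivity means may be biased",
            RuntimeWarning,
            stacklevel=3,
        )
    return field.diagonal()[ix, iy, iz]  # (k, 3)


def extract_axis_diffusivities(field: TensorField, proj_roi: RoiMask,
                               assoc_roi: RoiMask) -> AxisDiffusivities:
    """ROI-mean diagonal diffusivities for one hemisphere.

    ``d_xproj``/``d_yproj`` are the means of Dxx/Dyy over the projection
    ROI, ``d_xassoc``/``d_zassoc`` the means of Dxx/Dzz over the association
    ROI.
    """
    if proj_roi.fiber_kind != "projection":
        raise ValueError("proj_roi must be a projection-fiber ROI")
    if assoc_roi.fiber_kind != "association":
        raise ValueError("assoc_roi must be an association-fiber ROI")
    if proj_roi.hemisphere != assoc_roi.hemisphere:
        raise ValueError("projection and association ROIs must share a hemisphere")
    proj = _roi_diagonal(field, proj_roi)
    assoc = _roi_diagonal(field, assoc_roi)
    return AxisDiffusivities(
        d_xproj=float(proj[:, 0].mean()),
        d_yproj=float(proj[:, 1].mean()),
        d_xassoc=float(assoc[:, 0].mean()),
        d_zassoc=float(assoc[:, 2].mean()),
    )


def compute_alps(d: AxisDiffusivities) -> float:
    """ALPS index: mean(d_xproj, d_xassoc) / mean(d_yproj, d_zassoc)."""
    return (d.d_xproj + d.d_xassoc) / (d.d_yproj + d.d_zassoc)


@dataclass(frozen=True)
class AlpsResult:
    """Per-hemisphere ALPS measurement, possibly multi-observer.

    ``index`` is the arithmetic mean of the per-observer indices.
    """

    subject_id: str
    hemisphere: str
    observer_diffusivities: tuple[AxisDiffusivities, ...]
    observer_indices: tuple[float, ...]
    index: float

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")
        if len(self.observer_indices) != len(self.observer_diffusivities):
            raise ValueError("per-observer indices and diffusivities differ in length")
        if not self.index > 0:
            raise ValueError("ALPS index must be positive")
        mean_idx = float(np.mean(self.observer_indices))
        if abs(self.index - mean_idx) > 1e-12 * max(1.0, abs(mean_idx)):
            raise ValueError("final index must equal the mean of observer indices")


def single_observer_result(subject_id: str, hemisphere: str,
                           d: AxisDiffusivities) -> AlpsResult:
    """Wrap one observer's diffusivities into an :class:`AlpsResult`."""
    idx = compute_alps(d)
    return AlpsResult(subject_id=subject_id, hemisphere=hemisphere,
                      observer_diffusivities=(d,), observer_indices=(idx,),
                      index=idx)


def average_observers(a: AlpsResult, b: AlpsResult) -> AlpsResult:
    """Combine two observers' measurements of the same subject and hemisphere."""
    if a.subject_id != b.subject_id:
        raise ValueError("observer results belong to different subjects")
    if a.hemisphere != b.hemisphere:
        raise ValueError("observer results belong to different hemispheres")
    indices = a.observer_indices + b.observer_indices
    return AlpsResult(
        subject_id=a.subject_id,
        hemisphere=a.hemisphere,
        observer_diffusivities=a.observer_diffusivities + b.observer_diffusivities,
        observer_indices=indices,
        index=float(np.mean(indices)),
    )
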