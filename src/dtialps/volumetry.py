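"""Tumor and peritumoral-edema volumetry from planar polygonal ROI stacks.

Volumes follow the planimetric convention: each manually drawn polygon
contributes (in-plane area) x (slice thickness), with no inter-slice
interpolation, and multiple lesions are measured separately and summed.
Exclusion rules (dural tails, necrosis, presumed calcification) are the
responsibility of whoever draws the ROIs; this module only measures them.
Edema absent is encoded as a volume of exactly 0 cm^3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Polygon as _ShapelyPolygon

__all__ = [
    "PlanarPolygon",
    "RoiStack",
    "polygon_area",
    "stack_volume",
    "lesion_volumes",
    "mask_volume",
    "stack_from_json",
    "stack_to_json",
]


@dataclass(frozen=True)
class PlanarPolygon:
    """One in-plane polygonal ROI: ordered vertices in mm on a given slice."""

    vertices: np.ndarray  # (k, 2) mm
    slice_index: int
    lesion_id: int | str = 0

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise ValueError("vertices must have shape (k, 2)")
        if verts.shape[0] < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if not np.all(np.isfinite(verts)):
            raise ValueError("polygon vertices must be finite")
        ring = LinearRing(verts)
        if not ring.is_simple:
            raise ValueError("polygon is self-intersecting")
        if _ShapelyPolygon(verts).area <= 0.0:
            raise ValueError("polygon is degenerate (zero area)")
        object.__setattr__(self, "vertices", verts)


def polygon_area(p: PlanarPolygon) -> float:
    """Absolute (orientation-independent) polygon area in mm^2."""
    return float(_ShapelyPolygon(p.vertices).area)


@dataclass(frozen=True)
class RoiStack:
    """Polygons of one structure (tumor or edema), grouped by lesion.

    Slices within a lesion need not be contiguous, but one lesion may
    contribute at most one polygon per slice; overlapping drawings on a
    slice must belong to distinct lesions.
    """

    polygons: tuple[PlanarPolygon, ...]
    slice_thickness: float  # mm
    kind: str = "tumor"     # "tumor" or "ptbe"

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be > 0")
        if self.kind not in ("tumor", "ptbe"):
            raise ValueError("kind must be 'tumor' or 'ptbe'")
        seen = set()
        for p in self.polygons:
            key = (p.lesion_id, p.slice_index)
            if key in seen:
                raise ValueError(
                    f"lesion {p.lesion_id!r} has duplicate polygons on slice "
                    f"{p.slice_index}; duplicates on one slice must belong to "
                    "distinct lesions"
                )
            seen.add(key)
        object.__setattr__(self, "polygons", tuple(self.polygons))

    @property
    def lesion_ids(self) -> tuple:
        out: list = []
        for p in self.polygons:
            if p.lesion_id not in out:
                out.append(p.lesion_id)
        return tuple(out)


def lesion_volumes(s: RoiStack) -> dict:
    """Per-lesion volumes in cm^3 (area x slice thickness, summed over slices)."""
    vols: dict = {lid: 0.0 for lid in s.lesion_ids}
    for p in s.polygons:
        vols[p.lesion_id] += polygon_area(p) * s.slice_thickness / 1000.0
    return vols


def stack_volume(s: RoiStack) -> float:
    """Total volume in cm^3, summed across all lesions of the stack."""
    if not s.polygons:
        warnings.warn(f"empty {s.kind} ROI stack: volume is 0 cm^3",
                      RuntimeWarning, stacklevel=2)
        return 0.0
    return float(sum(lesion_volumes(s).values()))


def mask_volume(mask: np.ndarray, voxel_size) -> float:
    """Volume of a binary mask in cm^3 (voxel count x voxel volume)."""
    mask = np.asarray(mask)
    voxel_mm3 = float(np.prod([float(v) for v in voxel_size]))
    return float(np.count_nonzero(mask) * voxel_mm3 / 1000.0)


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------

def stack_from_json(source) -> RoiStack:
    """Read an ROI stack from JSON.

    Expected layout::

        {"kind": "tumor", "slice_thickness_mm": 2.0,
         "lesions": {"1": [{"slice": 3, "vertices": [[x, y], ...]}, ...]}}
    """
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    polys = [
        PlanarPolygon(vertices=np.asarray(entry["vertices"], dtype=float),
                      slice_index=int(entry["slice"]), lesion_id=lid)
        for lid, entries in doc["lesions"].items()
        for entry in entries
    ]
    return RoiStack(polygons=tuple(polys),
                    slice_thickness=float(doc["slice_thickness_mm"]),
                    kind=doc.get("kind", "tumor"))


def stack_to_json(s: RoiStack, path=None) -> dict:
    lesions: dict = {}
    for p in s.polygons:
        lesions.setdefault(str(p.lesion_id), []).append(
            {"slice": int(p.slice_index), "vertices": p.vertices.tolist()})
    doc = {"kind": s.kind, "slice_thickness_mm": s.slice_thickness,
           "lesions": lesions}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
    return doc
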