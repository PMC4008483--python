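"""Label the four brain-feeding arteries among thresholded connected objects.

The brain is supplied by the left/right internal carotid arteries (ICA) and
the left/right vertebral arteries (VA).  After adaptive thresholding of the
TOF angiogram the arteries appear as bright connected objects; this module
identifies which object is which using the middle axial slice:

* the VAs are the most posterior cross-sections and have no branches
  (exactly one cross-section per object at the middle slice);
* the carotids are the two largest remaining objects, one per left/right
  half; the common carotid bifurcates into ICA and external carotid (ECA),
  so a carotid object can show two cross-sections — the one closest to the
  in-plane image centre is the ICA.

If fewer than three arteries (or no VA) can be labeled the pipeline aborts:
at least one VA is needed downstream to fix the z level of the skull entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask3D, Volume3D

__all__ = [
    "ConnectedObject",
    "CrossSection",
    "ArteryLabeling",
    "ARTERY_LABELS",
    "connected_components",
    "select_candidates",
    "middle_slice_sections",
    "label_arteries",
]

ARTERY_LABELS = ("LICA", "RICA", "LVA", "RVA")

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class ConnectedObject:
    """One 26-connected component of the artery mask."""

    label: int
    voxels: np.ndarray  # (N, 3) int voxel indices
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3 or len(self.voxels) < 1:
            raise ValueError("object needs a non-empty (N, 3) voxel index array")

    @property
    def count(self) -> int:
        return len(self.voxels)

    @property
    def z_min(self) -> int:
        return int(self.voxels[:, 2].min())

    @property
    def z_max(self) -> int:
        return int(self.voxels[:, 2].max())

    @property
    def z_extent(self) -> int:
        """Number of axial slices spanned, inclusive."""
        return self.z_max - self.z_min + 1


@dataclass
class CrossSection:
    """One 8-connected 2-D region of an object at the middle axial slice."""

    parent_label: int
    voxels_xy: np.ndarray  # (N, 2) int in-plane voxel indices
    centroid_mm: tuple[float, float]  # (x, y) mm

    def __post_init__(self) -> None:
        self.voxels_xy = np.asarray(self.voxels_xy, dtype=np.intp)
        if len(self.voxels_xy) < 1:
            raise ValueError("cross-section region must be non-empty")


@dataclass
class ArteryLabeling:
    """Assignment of {LICA, RICA, LVA, RVA} to connected objects."""

    arteries: dict  # label -> (ConnectedObject, CrossSection)
    status: dict  # label -> "found" | "not found"
    overall: str  # "ok" | "aborted"
    reason: str = ""

    def found(self, label: str) -> bool:
        return self.status.get(label) == "found"

    @property
    def n_found(self) -> int:
        return sum(1 for s in self.status.values() if s == "found")


def connected_components(mask: BinaryMask3D) -> list[ConnectedObject]:
    """All maximal 26-connected components, largest first.

    Ties in voxel count are broken by smaller minimal z, then by the raw
    scan-order label, so the output ordering is deterministic.
    """
    labeled, n = ndimage.label(mask.data, structure=_STRUCT_26)
    if n == 0:
        return []
    objects = []
    slices = ndimage.find_objects(labeled)
    for raw in range(1, n + 1):
        sl = slices[raw - 1]
        local = np.argwhere(labeled[sl] == raw)
        local += np.array([s.start for s in sl])
        objects.append((raw, local))
    objects.sort(key=lambda t: (-len(t[1]), int(t[1][:, 2].min()), t[0]))
    return [
        ConnectedObject(label=i + 1, voxels=vox, spacing=mask.spacing, origin=mask.origin)
        for i, (_, vox) in enumerate(objects)
    ]


def select_candidates(objects: list[ConnectedObject], k: int = 8) -> list[ConnectedObject]:
    """The up-to-*k* largest objects (the artery candidates)."""
    ordered = sorted(objects, key=lambda o: (-o.count, o.z_min, o.label))
    return ordered[:k]


def middle_slice_sections(
    objects: list[ConnectedObject], volume_shape: tuple[int, int, int]
) -> list[CrossSection]:
    """Every 2-D 8-connected cross-section of *objects* at the middle slice.

    An object absent from the middle axial slice contributes no section; an
    object whose branches have not merged below the middle slice contributes
    one section per branch.
    """
    mid = volume_shape[2] // 2
    sections: list[CrossSection] = []
    for obj in objects:
        at_mid = obj.voxels[obj.voxels[:, 2] == mid]
        if len(at_mid) == 0:
            continue
        plane = np.zeros(volume_shape[:2], dtype=bool)
        plane[at_mid[:, 0], at_mid[:, 1]] = True
        labeled, n = ndimage.label(plane, structure=_STRUCT_8)
        for region in range(1, n + 1):
            xy = np.argwhere(labeled == region)
            cen = xy.mean(axis=0)
            centroid_mm = (
                float(obj.origin[0] + cen[0] * obj.spacing[0]),
                float(obj.origin[1] + cen[1] * obj.spacing[1]),
            )
            sections.append(
                CrossSection(parent_label=obj.label, voxels_xy=xy, centroid_mm=centroid_mm)
            )
    return sections


def label_arteries(
    candidates: list[ConnectedObject],
    sections: list[CrossSection],
    volume: Volume3D,
) -> ArteryLabeling:
    """Identify LICA, RICA, LVA, RVA among the candidate objects.

    VAs: objects with exactly one middle-slice section; per left/right half,
    the most posterior centroid.  Carotids: the two largest remaining
    sectioned objects, one per half; the section closest to the in-plane
    image centre seeds the ICA (the other branch is the ECA).  Failures are
    statuses, never exceptions.
    """
    nx, ny, _ = volume.shape
    cx = volume.origin[0] + (nx - 1) / 2.0 * volume.spacing[0]
    cy = volume.origin[1] + (ny - 1) / 2.0 * volume.spacing[1]

    by_parent: dict[int, list[CrossSection]] = {}
    for sec in sections:
        by_parent.setdefault(sec.parent_label, []).append(sec)
    obj_by_label = {o.label: o for o in candidates}

    arteries: dict = {}
    status = {lbl: "not found" for lbl in ARTERY_LABELS}

    # --- vertebral arteries: single-section objects, most posterior per half
    va_cands = [
        (obj_by_label[lbl], secs[0])
        for lbl, secs in by_parent.items()
        if len(secs) == 1 and lbl in obj_by_label
    ]
    taken: set[int] = set()
    for side, keep in (("LVA", lambda x: x < cx), ("RVA", lambda x: x > cx)):
        side_cands = [(o, s) for o, s in va_cands if keep(s.centroid_mm[0])]
        if side_cands:
            obj, sec = max(side_cands, key=lambda t: t[1].centroid_mm[1])
            arteries[side] = (obj, sec)
            status[side] = "found"
            taken.add(obj.label)

    # --- carotids: largest remaining sectioned object per half
    remaining = [
        obj_by_label[lbl]
        for lbl in by_parent
        if lbl in obj_by_label and lbl not in taken
    ]
    for side, keep in (("LICA", lambda x: x < cx), ("RICA", lambda x: x > cx)):
        side_objs = [
            o
            for o in remaining
            if keep(float(np.mean([s.centroid_mm[0] for s in by_parent[o.label]])))
        ]
        if not side_objs:
            continue
        obj = max(side_objs, key=lambda o: (o.count, -o.label))
        # among this object's branches the ICA runs closest to the image centre
        sec = min(
            by_parent[obj.label],
            key=lambda s: (s.centroid_mm[0] - cx) ** 2 + (s.centroid_mm[1] - cy) ** 2,
        )
        arteries[side] = (obj, sec)
        status[side] = "found"
        taken.add(obj.label)

    n_found = sum(1 for s in status.values() if s == "found")
    n_va = sum(1 for lbl in ("LVA", "RVA") if status[lbl] == "found")
    if n_found >= 3 and n_va >= 1:
        overall, reason = "ok", ""
    else:
        overall = "aborted"
        reason = (
            f"fewer than three arteries identified ({n_found})"
            if n_found < 3
            else "no vertebral artery identified"
        )
    return ArteryLabeling(arteries=arteries, status=status, overall=overall, reason=reason)
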