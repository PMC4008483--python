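"""Skeleton curves of segmented arteries and their 1-D derivative profiles.

The artery object is treated as a voxel graph (26-connectivity, edges
weighted by the physical step length).  Geodesic distance from the
inferior-most voxel is computed with Dijkstra's algorithm and binned into
level sets; the centroid of each level set, restricted to the branch that
passes through a seed cross-section, traces the skeleton polyline from
inferior to superior.  This reproduces the centres-of-level-curves
construction without surface meshing.

The vertebral-artery bends are then summarized by a 1-D *derivative
profile*: the centerline's transverse coordinate (anterior–posterior by
default) resampled at uniform z steps and differentiated with respect to z.
The two bends appear as changepoints of that profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .artery_id import ConnectedObject, CrossSection
from .volume_io import Volume3D

__all__ = [
    "Centerline",
    "DerivativeProfile",
    "LabeledProfile",
    "extract_centerline",
    "derivative_profile",
]

# the 13 "positive" half-space neighbour offsets of 26-connectivity
_OFFSETS = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) > (0, 0, 0)
    ],
    dtype=np.intp,
)


class CenterlineError(RuntimeError):
    """Raised when an object is too short or degenerate for skeletonization."""


@dataclass
class Centerline:
    """Ordered 3-D polyline of an artery, inferior to superior, in mm."""

    label: str
    points: np.ndarray  # (N, 3) mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be (N, 3)")
        if len(self.points) < 5:
            raise CenterlineError(f"artery too short: {len(self.points)} centerline points")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length (mm), starting at 0."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def translated(self, offset) -> "Centerline":
        return Centerline(self.label, self.points + np.asarray(offset, dtype=float))


@dataclass
class DerivativeProfile:
    """Uniformly z-sampled slope of a centerline's transverse coordinate."""

    values: np.ndarray  # dimensionless d(transverse)/dz
    dz: float  # mm sampling interval
    z0: float  # mm z of the first sample
    axis: str = "AP"  # "AP" or "LR"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 10:
            raise ValueError(f"profile needs >= 10 samples, got {len(self.values)}")
        if self.dz <= 0:
            raise ValueError("dz must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def z_of(self, index) -> np.ndarray:
        return self.z0 + np.asarray(index, dtype=float) * self.dz


@dataclass
class LabeledProfile:
    """A derivative profile with its annotated true turning-point indices."""

    profile: DerivativeProfile
    turn_lower: int
    turn_upper: int

    def __post_init__(self) -> None:
        if not 0 <= self.turn_lower < self.turn_upper < len(self.profile):
            raise ValueError("turning indices must satisfy 0 <= lower < upper < n")


def _build_graph(voxels: np.ndarray, spacing) -> "coo_matrix":
    """Weighted 26-connectivity adjacency of an object's voxel set."""
    n = len(voxels)
    span = voxels.max(axis=0) - voxels.min(axis=0) + 3
    base = voxels - voxels.min(axis=0) + 1
    rav = np.ravel_multi_index(base.T, span)
    order = np.argsort(rav)
    rav_sorted = rav[order]
    spacing = np.asarray(spacing, dtype=float)
    rows, cols, weights = [], [], []
    for off in _OFFSETS:
        nb = np.ravel_multi_index((base + off).T, span, mode="clip")
        pos = np.searchsorted(rav_sorted, nb)
        pos_c = np.clip(pos, 0, n - 1)
        hit = rav_sorted[pos_c] == nb
        w = float(np.linalg.norm(off * spacing))
        rows.append(np.nonzero(hit)[0])
        cols.append(order[pos_c[hit]])
        weights.append(np.full(int(hit.sum()), w))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    weights = np.concatenate(weights)
    return coo_matrix((weights, (rows, cols)), shape=(n, n))


def extract_centerline(
    obj: ConnectedObject, seed: CrossSection, volume: Volume3D, label: str = ""
) -> Centerline:
    """Skeleton polyline of *obj* following the branch through *seed*.

    Geodesic distance from the inferior-most voxel is binned into level sets
    of width ``max(spacing)``; per bin, the 26-connected cluster(s) touching
    the seed's branch (ancestors or descendants of the seed section in the
    shortest-path tree) are kept and their centroid appended.  The polyline
    is smoothed with a 3-point moving average.
    """
    voxels = obj.voxels
    spacing = np.asarray(volume.spacing, dtype=float)
    graph = _build_graph(voxels, spacing)

    # source: inferior-most voxel; ties resolved toward the seed centroid
    zmin = voxels[:, 2].min()
    bottom = np.nonzero(voxels[:, 2] == zmin)[0]
    seed_c = np.asarray(seed.centroid_mm)
    xy_mm = voxels[bottom, :2] * spacing[:2] + np.asarray(volume.origin[:2])
    source = int(bottom[np.lexsort((voxels[bottom, 1], voxels[bottom, 0],
                                    np.linalg.norm(xy_mm - seed_c, axis=1)))[0]])

    dist, pred = dijkstra(
        graph, directed=False, indices=source, return_predecessors=True
    )
    if not np.all(np.isfinite(dist)):
        raise CenterlineError("object voxel graph is not connected")

    # seed voxel rows: object voxels lying in the seed's 2-D region
    mid = volume.shape[2] // 2
    seed_xy = {tuple(v) for v in seed.voxels_xy}
    seed_rows = np.array(
        [
            i
            for i, v in enumerate(voxels)
            if v[2] == mid and (v[0], v[1]) in seed_xy
        ],
        dtype=np.intp,
    )
    if len(seed_rows) == 0:
        raise CenterlineError("seed cross-section does not intersect the object")

    # branch membership in the shortest-path tree: ancestors of the seed
    # section plus descendants of the seed section only (descendants of the
    # shared trunk would pull in side branches such as the ECA)
    in_branch = np.zeros(len(voxels), dtype=bool)
    in_branch[seed_rows] = True
    for r in seed_rows:  # ancestors: walk predecessors to the source
        node = int(r)
        while node != source and pred[node] >= 0 and not in_branch[pred[node]]:
            node = int(pred[node])
            in_branch[node] = True
    in_branch[source] = True
    desc = np.zeros(len(voxels), dtype=bool)
    desc[seed_rows] = True
    for node in np.argsort(dist):  # propagate outward from the seed only
        p = pred[node]
        if p >= 0 and desc[p]:
            desc[node] = True
    in_branch |= desc

    # level sets of geodesic distance
    width = float(spacing.max())
    bins = np.floor(dist / width).astype(int)
    # cluster within each bin using the object adjacency
    graph_csr = graph.tocsr()
    graph_sym = graph_csr + graph_csr.T
    centers = []
    for b in np.unique(bins):
        members = np.nonzero(bins == b)[0]
        if not np.any(in_branch[members]):
            continue
        if len(members) == 1:
            keep = members
        else:
            from scipy.sparse.csgraph import connected_components as cc

            sub = graph_sym[members][:, members]
            _, comp = cc(sub, directed=False)
            branch_comps = np.unique(comp[in_branch[members]])
            keep = members[np.isin(comp, branch_comps)]
        centers.append(voxels[keep].mean(axis=0))
    if len(centers) < 5:
        raise CenterlineError(f"artery too short: {len(centers)} level sets")

    pts = np.asarray(centers) * spacing + np.asarray(volume.origin)
    # 3-point moving average (ends kept as partial means)
    sm = pts.copy()
    sm[1:-1] = (pts[:-2] + pts[1:-1] + pts[2:]) / 3.0
    return Centerline(label=label, points=sm)


def _monotone_z(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Keep a strictly-z-increasing subsequence for interpolation in z."""
    z = points[:, 2]
    keep = [0]
    for i in range(1, len(z)):
        if z[i] > z[keep[-1]]:
            keep.append(i)
    keep = np.asarray(keep)
    return points[keep, 0], points[keep, 1], z[keep]


def derivative_profile(
    centerline: Centerline, axis: str = "AP", dz: float = 1.5
) -> DerivativeProfile:
    """Uniform-z derivative of the centerline's transverse coordinate.

    The transverse coordinate (y for ``axis="AP"``, x for ``"LR"``) is
    resampled at steps *dz* by linear interpolation and differentiated with
    central finite differences (one-sided at the endpoints).
    """
    if axis not in ("AP", "LR"):
        raise ValueError(f"axis must be 'AP' or 'LR', got {axis!r}")
    x, y, z = _monotone_z(centerline.points)
    span = z[-1] - z[0]
    if span < 10 * dz:
        raise ValueError(f"centerline z-span {span:.1f} mm < 10 * dz = {10 * dz:.1f} mm")
    zs = np.arange(z[0], z[-1] + 1e-9, dz)
    coord = np.interp(zs, z, y if axis == "AP" else x)
    values = np.gradient(coord, dz)
    return DerivativeProfile(values=values, dz=float(dz), z0=float(zs[0]), axis=axis)


def interp_point_at_z(centerline: Centerline, z_target: float) -> np.ndarray:
    """Centerline point at height *z_target*, linearly interpolated.

    Heights outside the centerline's z-span clamp to the nearest endpoint.
    """
    x, y, z = _monotone_z(centerline.points)
    xi = np.interp(z_target, z, x)
    yi = np.interp(z_target, z, y)
    zi = np.clip(z_target, z[0], z[-1])
    return np.array([xi, yi, zi])
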