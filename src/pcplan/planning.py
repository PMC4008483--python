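"""Turning-point detection and scan-plane computation.

The vertebral artery (VA) makes two bends at the C2 and C1 vertebral
levels; the flow-quantification plane belongs midway between them, where
the vessel runs straight.  Detection proceeds in two stages:

1. *Rough localization* — the subject's VA derivative profile is matched
   against a side-specific template (built by averaging a population of
   profiles) with normalized cross-correlation; padding around the
   template's annotated turning points gives a rough region.
2. *Refinement* — within the rough region, the two changepoints ``k1 < k2``
   minimizing the total within-segment variance of the three subregions
   are found exactly by dynamic programming over prefix sums.

The VA plane is centred at the profile-index midpoint of the two turning
points; the internal carotid (ICA) plane at the ICA point level with the
upper VA turn.  Plane normals are the first principal direction of the
centerline in a small window (the best-fitting line's direction), reported
as a unit normal plus two angulation angles about the L-R and A-P axes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import segmentation
from .centerline import (
    Centerline,
    DerivativeProfile,
    LabeledProfile,
    derivative_profile,
    extract_centerline,
    interp_point_at_z,
)
from .volume_io import Volume3D, volume_center_mm

__all__ = [
    "Template",
    "TurningPointPair",
    "ScanPlane",
    "ArteryPlan",
    "PositioningResult",
    "build_template",
    "cross_correlate",
    "rough_region",
    "detect_turning_points",
    "plan_va_plane",
    "plan_ica_plane",
    "plan_all",
    "angles_to_normal",
]


class PlanningError(RuntimeError):
    """A per-artery planning failure (recorded as a status, never fatal)."""


@dataclass
class Template:
    """Averaged VA derivative template with annotated turning indices."""

    values: np.ndarray
    dz: float
    turn_lower: int
    turn_upper: int
    pad: int = 10
    side: str = "L"
    axis: str = "AP"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not 0 <= self.turn_lower < self.turn_upper < len(self.values):
            raise ValueError("template turning indices out of order or range")
        if self.dz <= 0 or self.pad < 0:
            raise ValueError("need dz > 0 and pad >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "values": self.values.tolist(),
                    "dz": self.dz,
                    "turn_lower": self.turn_lower,
                    "turn_upper": self.turn_upper,
                    "pad": self.pad,
                    "side": self.side,
                    "axis": self.axis,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "Template":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TurningPointPair:
    """Indices k1 < k2 minimizing the three-segment variance objective."""

    k1: int
    k2: int
    v_total: float
    points_mm: np.ndarray | None = None  # (2, 3) centerline points, once mapped


@dataclass
class ScanPlane:
    """Scan-positioning output: off-centre (mm), unit normal, angulation (deg).

    ``center`` is the plane centre as offsets from the volume centre along
    (L-R, A-P, F-H).  Angulation is (alpha about L-R, beta about A-P,
    gamma about F-H == 0): rotating (0, 0, 1) by alpha then beta reproduces
    the normal.
    """

    center: np.ndarray
    normal: np.ndarray
    angulation: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")

    def to_dict(self) -> dict:
        return {
            "off_center_mm": self.center.tolist(),
            "normal": self.normal.tolist(),
            "angulation_deg": list(self.angulation),
        }


@dataclass
class ArteryPlan:
    label: str
    status: str  # "ok" | "failed"
    plane: ScanPlane | None = None
    reason: str = ""
    cc_offset: int | None = None
    turning: TurningPointPair | None = None


@dataclass
class PositioningResult:
    arteries: dict  # label -> ArteryPlan
    overall: str  # "ok" | "aborted"
    reason: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def n_planes(self) -> int:
        return sum(1 for a in self.arteries.values() if a.status == "ok")

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "reason": self.reason,
            "provenance": self.provenance,
            "arteries": {
                lbl: {
                    "status": a.status,
                    "reason": a.reason,
                    "plane": a.plane.to_dict() if a.plane else None,
                }
                for lbl, a in self.arteries.items()
            },
        }


def build_template(profiles: list[LabeledProfile], pad: int = 10, side: str = "L") -> Template:
    """Average a population of annotated profiles into a matching template.

    Profiles are aligned on the midpoint of their annotated turning indices,
    cropped to common support, and averaged pointwise; the template turning
    indices are the rounded means of the aligned individual indices.
    """
    if len(profiles) < 2:
        raise ValueError("template needs >= 2 profiles")
    dz = profiles[0].profile.dz
    axis = profiles[0].profile.axis
    for lp in profiles:
        if abs(lp.profile.dz - dz) > 1e-9 or lp.profile.axis != axis:
            raise ValueError("profiles must share dz and transverse axis")
    mids = [round((lp.turn_lower + lp.turn_upper) / 2) for lp in profiles]
    lo = max(-m for m in mids)
    hi = min(len(lp.profile) - 1 - m for lp, m in zip(profiles, mids))
    if hi - lo + 1 < 4:
        raise ValueError("profiles have no usable common support after alignment")
    grid = np.arange(lo, hi + 1)
    stack = np.stack([lp.profile.values[grid + m] for lp, m in zip(profiles, mids)])
    values = stack.mean(axis=0)
    t_lower = round(float(np.mean([lp.turn_lower - m for lp, m in zip(profiles, mids)]))) - lo
    t_upper = round(float(np.mean([lp.turn_upper - m for lp, m in zip(profiles, mids)]))) - lo
    return Template(
        values=values,
        dz=dz,
        turn_lower=int(t_lower),
        turn_upper=int(t_upper),
        pad=pad,
        side=side,
        axis=axis,
    )


def cross_correlate(profile: DerivativeProfile, template: Template) -> tuple[int, float]:
    """Best integer offset of *template* against *profile* and its score.

    Normalized (zero-mean, unit-norm over the overlap) cross-correlation,
    evaluated at every offset with overlap >= 50% of the template length;
    ties go to the smallest offset.  Template sample ``t`` aligns with
    profile sample ``t + m``.
    """
    f = profile.values
    g = template.values
    n_f, n_g = len(f), len(g)
    if n_f < n_g / 2:
        raise ValueError("profile shorter than half the template")
    min_overlap = max(int(math.ceil(n_g / 2)), 2)
    best_m, best_r = None, -np.inf
    for m in range(-(n_g - min_overlap), n_f - min_overlap + 1):
        t0 = max(0, -m)
        t1 = min(n_g, n_f - m)
        if t1 - t0 < min_overlap:
            continue
        a = f[t0 + m : t1 + m]
        b = g[t0:t1]
        a = a - a.mean()
        b = b - b.mean()
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na < 1e-12 or nb < 1e-12:
            continue
        r = float(a @ b) / (na * nb)
        if r > best_r:
            best_m, best_r = m, r
    if best_m is None:
        raise ValueError("degenerate (zero-variance) overlap at every offset")
    return best_m, best_r


def rough_region(
    profile: DerivativeProfile, template: Template, m: int, lmin: int = 2
) -> tuple[int, int]:
    """Inclusive index interval of the rough turning-point region.

    Pads the template's turning indices (shifted by the matching offset *m*)
    by ``template.pad`` samples and clips to the profile range; a clipped
    region shorter than ``3 * lmin`` is a planning failure.
    """
    lo = max(0, template.turn_lower + m - template.pad)
    hi = min(len(profile) - 1, template.turn_upper + m + template.pad)
    if hi - lo + 1 < 3 * lmin:
        raise PlanningError("turning region outside profile")
    return lo, hi


def detect_turning_points(
    segment: np.ndarray, lmin: int = 2, offset: int = 0
) -> TurningPointPair:
    """Optimal three-segment changepoint pair of a 1-D signal.

    Finds ``(k1, k2)`` minimizing ``V1 + V2 + V3`` where each ``V_i`` is the
    within-segment sum of squared deviations from the segment mean, over
    ``[0, k1)``, ``[k1, k2)``, ``[k2, n)`` with every segment at least
    *lmin* samples.  Exact minimization in O(n^2) using prefix sums; ties
    resolve to the lexicographically smallest pair.  *offset* shifts the
    returned indices back into full-profile coordinates.
    """
    x = np.asarray(segment, dtype=float)
    n = len(x)
    if n < 3 * lmin:
        raise ValueError(f"segment of {n} samples cannot hold three segments of {lmin}")
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(a, b):  # sum of squared deviations of x[a:b]; a, b arrays ok
        length = b - a
        s = s1[b] - s1[a]
        return (s2[b] - s2[a]) - s * s / length

    best = (np.inf, -1, -1)
    k2_all = np.arange(2 * lmin, n - lmin + 1)
    for k1 in range(lmin, n - 2 * lmin + 1):
        k2 = k2_all[k2_all >= k1 + lmin]
        totals = cost(0, k1) + cost(np.full_like(k2, k1), k2) + cost(k2, np.full_like(k2, n))
        i = int(np.argmin(totals))
        if totals[i] < best[0]:
            best = (float(totals[i]), k1, int(k2[i]))
    v, k1, k2 = best
    return TurningPointPair(k1=k1 + offset, k2=k2 + offset, v_total=v)


def _normal_to_angles(normal: np.ndarray) -> tuple[float, float, float]:
    alpha = math.degrees(math.asin(float(np.clip(normal[1], -1.0, 1.0))))
    beta = math.degrees(math.atan2(float(normal[0]), float(normal[2])))
    return (alpha, beta, 0.0)


def angles_to_normal(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Unit normal produced by rotating (0,0,1) by alpha about L-R then beta about A-P."""
    a = math.radians(alpha_deg)
    b = math.radians(beta_deg)
    return np.array([math.sin(b) * math.cos(a), math.sin(a), math.cos(b) * math.cos(a)])


def _fit_plane(
    centerline: Centerline, z_center: float, window: int, volume_center
) -> ScanPlane:
    """Plane at height *z_center*: PCA tangent normal over +-window points."""
    pts = centerline.points
    center = interp_point_at_z(centerline, z_center)
    i0 = int(np.argmin(np.abs(pts[:, 2] - center[2])))
    w = window
    lo, hi = i0 - w, i0 + w + 1
    if lo < 0 or hi > len(pts):  # shrink symmetrically, never below 3 points
        w = min(i0, len(pts) - 1 - i0)
        lo, hi = i0 - w, i0 + w + 1
        if hi - lo < 3:
            lo, hi = max(0, i0 - 1), min(len(pts), i0 + 2)
    nb = pts[lo:hi]
    centred = nb - nb.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[0]
    if normal[2] < 0:
        normal = -normal
    normal = normal / np.linalg.norm(normal)
    return ScanPlane(
        center=center - np.asarray(volume_center, dtype=float),
        normal=normal,
        angulation=_normal_to_angles(normal),
    )


def plan_va_plane(
    centerline: Centerline,
    profile: DerivativeProfile,
    turns: TurningPointPair,
    window: int = 5,
    volume_center=(0.0, 0.0, 0.0),
) -> ScanPlane:
    """VA plane at the index midpoint of the two turning points."""
    mid_idx = (turns.k1 + turns.k2) // 2
    z_center = profile.z_of(mid_idx)
    return _fit_plane(centerline, float(z_center), window, volume_center)


def plan_ica_plane(
    ica_centerline: Centerline,
    upper_turn_mm,
    window: int = 5,
    volume_center=(0.0, 0.0, 0.0),
) -> ScanPlane:
    """ICA plane at the ICA point level with the VA's upper turning point."""
    z_star = float(np.asarray(upper_turn_mm, dtype=float)[2])
    return _fit_plane(ica_centerline, z_star, window, volume_center)


def plan_all(
    volume: Volume3D,
    template_left: Template,
    template_right: Template,
    config=None,
) -> PositioningResult:
    """Full pipeline: segment, identify, skeletonize, detect turns, plan.

    Per-artery failures are statuses with reasons; the run is ``"ok"``
    iff at least three planes, including at least one VA plane, exist.
    """
    from .config import RunConfig

    cfg = config or RunConfig()
    templates = {"L": template_left, "R": template_right}
    vc = volume_center_mm(volume)
    dz = cfg.dz if cfg.dz is not None else volume.spacing[2]

    body = segmentation.otsu_body_mask(volume)
    seg = segmentation.adaptive_artery_threshold(
        volume,
        body,
        j_high=cfg.j_high,
        j_low=cfg.j_low,
        length_fraction=cfg.length_fraction,
        n_candidates=cfg.n_candidates,
    )
    labeling = seg.labeling
    provenance = {
        "j": seg.j,
        "threshold": seg.threshold,
        "threshold_status": seg.status,
        "templates": {s: {"side": t.side, "axis": t.axis} for s, t in templates.items()},
    }
    if labeling.overall == "aborted":
        return PositioningResult(
            arteries={}, overall="aborted", reason=labeling.reason, provenance=provenance
        )

    plans: dict[str, ArteryPlan] = {}
    va_upper_turn: dict[str, np.ndarray] = {}
    centerlines: dict[str, Centerline] = {}

    for side in ("L", "R"):
        lbl = side + "VA"
        if not labeling.found(lbl):
            plans[lbl] = ArteryPlan(lbl, "failed", reason="artery not identified")
            continue
        obj, sec = labeling.arteries[lbl]
        try:
            cl = extract_centerline(obj, sec, volume, label=lbl)
            centerlines[lbl] = cl
            prof = derivative_profile(cl, axis=cfg.axis, dz=dz)
            m, _score = cross_correlate(prof, templates[side])
            lo, hi = rough_region(prof, templates[side], m, lmin=cfg.lmin)
            turns = detect_turning_points(
                prof.values[lo : hi + 1], lmin=cfg.lmin, offset=lo
            )
            turns.points_mm = np.vstack(
                [
                    interp_point_at_z(cl, float(prof.z_of(turns.k1))),
                    interp_point_at_z(cl, float(prof.z_of(turns.k2))),
                ]
            )
            plane = plan_va_plane(cl, prof, turns, window=cfg.window, volume_center=vc)
            plans[lbl] = ArteryPlan(
                lbl, "ok", plane=plane, cc_offset=m, turning=turns
            )
            va_upper_turn[side] = turns.points_mm[1]
        except (PlanningError, ValueError, RuntimeError) as exc:
            plans[lbl] = ArteryPlan(lbl, "failed", reason=str(exc))

    for side in ("L", "R"):
        lbl = side + "ICA"
        if not labeling.found(lbl):
            plans[lbl] = ArteryPlan(lbl, "failed", reason="artery not identified")
            continue
        # same-side VA preferred; the other VA's upper turn is the fallback
        turn = va_upper_turn.get(side)
        if turn is None:
            turn = va_upper_turn.get("R" if side == "L" else "L")
        if turn is None:
            plans[lbl] = ArteryPlan(lbl, "failed", reason="no VA turning point available")
            continue
        obj, sec = labeling.arteries[lbl]
        try:
            cl = extract_centerline(obj, sec, volume, label=lbl)
            centerlines[lbl] = cl
            plane = plan_ica_plane(cl, turn, window=cfg.window, volume_center=vc)
            plans[lbl] = ArteryPlan(lbl, "ok", plane=plane)
        except (PlanningError, ValueError, RuntimeError) as exc:
            plans[lbl] = ArteryPlan(lbl, "failed", reason=str(exc))

    n_planes = sum(1 for a in plans.values() if a.status == "ok")
    n_va = sum(1 for s in ("L", "R") if plans.get(s + "VA", ArteryPlan("", "")).status == "ok")
    if n_planes >= 3 and n_va >= 1:
        overall, reason = "ok", ""
    else:
        overall = "aborted"
        reason = (
            f"only {n_planes} planes could be planned"
            if n_planes < 3
            else "no vertebral artery plane"
        )
    return PositioningResult(
        arteries=plans, overall=overall, reason=reason, provenance=provenance
    )
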