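"""Synthetic TOF-like angiogram phantoms with known arterial geometry.

The phantom emulates the neck anatomy the planning algorithm relies on:

* two near-vertical internal carotid arteries (ICA) whose common trunk
  bifurcates into an external carotid (ECA) branch below the middle slice;
* two vertebral arteries (VA) posterior to the carotids, each with two
  smooth bends (at the C2 and C1 vertebral levels) between which the vessel
  shifts posteriorly and medially;
* a dim tissue cylinder with Gaussian texture, air outside, and bright
  tubes at ``tissue_mean + contrast * tissue_sd``.

Every generated volume comes with its ground truth: dense centerline
polylines, the true VA turning points, and the ideal scan plane (centre +
tangent normal) per artery — so each pipeline stage can be scored without
any real MRI data.  Optional degradations (motion blur along y, small VAs,
dropped arteries, intensity taper toward the head) reproduce the failure
modes seen in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .centerline import Centerline, DerivativeProfile, LabeledProfile, derivative_profile
from .volume_io import Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "generate_profile_population",
    "artery_intensity",
]

_CURVE_STEP = 0.25  # mm sampling step of analytic centerlines


@dataclass
class PhantomSpec:
    """Geometry, intensity model and degradations of a synthetic angiogram.

    Defaults: 0.8 x 0.8 x 1.5 mm voxels, 47 axial slices; ICA radius 2.2 mm,
    VA radius 1.4 mm; VA bends at 35% and 60% of the z extent; artery
    contrast 8 tissue SDs above tissue mean.
    """

    shape: tuple[int, int, int] = (80, 80, 47)
    spacing: tuple[float, float, float] = (0.8, 0.8, 1.5)
    ica_radius: float = 2.2
    va_radius: float = 1.4
    # VA bend heights as fractions of the z extent (lower ~C2, upper ~C1)
    turn_lower_frac: float = 0.35
    turn_upper_frac: float = 0.60
    va_posterior_shift: float = 4.0  # mm shift between the bends, toward P
    va_medial_shift: float = 3.0  # mm shift between the bends, toward midline
    bend_halfwidth: float = 2.5  # mm C1 smoothing of each bend
    ica_offset_x: float = 13.0  # mm of ICA from midline
    ica_offset_y: float = -8.0  # mm of ICA from in-plane centre (A of centre)
    ica_sway: float = 1.0  # mm gentle lateral curvature amplitude
    va_offset_x: float = 9.0  # mm of VA from midline (below the bends)
    va_offset_y: float = 8.0  # mm of VA from centre (P of centre)
    eca_bifurcation_frac: float = 0.35  # z fraction of the carotid bifurcation
    eca_lateral_offset: float = 8.0  # mm of ECA lateral to the ICA
    tissue_mean: float = 100.0
    tissue_sd: float = 10.0
    contrast: float = 8.0  # artery = tissue_mean + contrast * tissue_sd
    noise_sd: float = 2.0  # additive Gaussian noise everywhere
    taper_top_fraction: float = 0.0  # fractional contrast loss at the top slice
    blur_sigma_y: float = 0.0  # mm, motion-blur degradation along A-P
    small_va_scale: float = 1.0  # multiplies the VA radius
    drop_arteries: tuple = ()  # subset of {"LICA","RICA","LVA","RVA"}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.turn_lower_frac < self.turn_upper_frac < 1:
            raise ValueError("need 0 < turn_lower_frac < turn_upper_frac < 1")
        if self.ica_radius <= 0 or self.va_radius <= 0 or self.small_va_scale <= 0:
            raise ValueError("radii must be positive")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        bad = set(self.drop_arteries) - {"LICA", "RICA", "LVA", "RVA"}
        if bad:
            raise ValueError(f"unknown arteries in drop_arteries: {sorted(bad)}")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def z_extent(self) -> float:
        return float(self.extent[2])

    @property
    def z_turn_lower(self) -> float:
        return self.turn_lower_frac * self.z_extent

    @property
    def z_turn_upper(self) -> float:
        return self.turn_upper_frac * self.z_extent


@dataclass
class PhantomGroundTruth:
    """Analytic truth of a generated phantom, all coordinates in mm."""

    centerlines: dict  # label -> (N, 3) polyline, incl. "LECA"/"RECA"
    tangents: dict  # label -> (N, 3) unit tangents along the polyline
    turning_points: dict  # VA label -> (2, 3): lower then upper bend
    ideal_planes: dict  # label -> {"center": (3,), "normal": (3,)}
    radii: dict  # label -> tube radius mm
    volume_center: np.ndarray

    def tangent_at(self, label: str, point) -> np.ndarray:
        """Unit tangent of the labeled centerline nearest to *point*."""
        pts = self.centerlines[label]
        i = int(np.argmin(np.linalg.norm(pts - np.asarray(point), axis=1)))
        return self.tangents[label][i]

    def to_json(self, path) -> None:
        def enc(x):
            return np.asarray(x).tolist()

        payload = {
            "centerlines": {k: enc(v) for k, v in self.centerlines.items()},
            "tangents": {k: enc(v) for k, v in self.tangents.items()},
            "turning_points": {k: enc(v) for k, v in self.turning_points.items()},
            "ideal_planes": {
                k: {"center": enc(v["center"]), "normal": enc(v["normal"])}
                for k, v in self.ideal_planes.items()
            },
            "radii": self.radii,
            "volume_center": enc(self.volume_center),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _smooth_ramp(z: np.ndarray, z_lo: float, z_hi: float, half: float) -> tuple[np.ndarray, np.ndarray]:
    """C1 ramp 0→1 between the two bend heights, and its derivative.

    The slope turns on/off over a cosine-tapered window of half-width *half*
    around each bend, so the curve is an arc-like C1 blend rather than a
    sharp corner and the tangent is well defined everywhere.
    """
    slope = 1.0 / (z_hi - z_lo)

    def gate(u):  # cosine taper from 0 to 1 over [-half, half]
        t = np.clip((u + half) / (2 * half), 0.0, 1.0)
        return 0.5 - 0.5 * np.cos(np.pi * t)

    rate = slope * gate(z - z_lo) * gate(z_hi - z)
    ramp = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2 * np.diff(z))])
    if ramp[-1] > 0:  # normalize so the full displacement is exactly 1
        scale = 1.0 / ramp[-1] if z[-1] >= z_hi + half else 1.0
        # only rescale when the ramp completes inside the volume
        if z[-1] >= z_hi + half:
            ramp = ramp * scale
            rate = rate * scale
    return ramp, rate


def _analytic_curves(spec: PhantomSpec) -> tuple[dict, dict]:
    """Dense centerline polylines and unit tangents for every tube."""
    ext = spec.extent
    cx, cy = ext[0] / 2.0, ext[1] / 2.0
    z = np.arange(0.0, spec.z_extent + 1e-9, _CURVE_STEP)
    curves: dict[str, np.ndarray] = {}
    tangents: dict[str, np.ndarray] = {}

    def add(label, x, y, dxdz, dydz):
        pts = np.column_stack([x, y, z])
        t = np.column_stack([dxdz, dydz, np.ones_like(z)])
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        curves[label] = pts
        tangents[label] = t

    ramp, rate = _smooth_ramp(z, spec.z_turn_lower, spec.z_turn_upper, spec.bend_halfwidth)
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        # vertebral artery: vertical, shifting posteriorly and medially
        x0 = cx + sgn * spec.va_offset_x
        x = x0 - sgn * spec.va_medial_shift * ramp
        y = cy + spec.va_offset_y + spec.va_posterior_shift * ramp
        add(side + "VA", x, y, -sgn * spec.va_medial_shift * rate, spec.va_posterior_shift * rate)

        # internal carotid: near-vertical with a gentle lateral sway
        xi0 = cx + sgn * spec.ica_offset_x
        sway = spec.ica_sway * np.sin(np.pi * z / spec.z_extent)
        dsway = spec.ica_sway * np.pi / spec.z_extent * np.cos(np.pi * z / spec.z_extent)
        x = xi0 + sgn * sway
        y = np.full_like(z, cy + spec.ica_offset_y)
        add(side + "ICA", x, y, sgn * dsway, np.zeros_like(z))

        # external carotid: departs from the ICA above the bifurcation
        zb = spec.eca_bifurcation_frac * spec.z_extent
        dep, ddep = _smooth_ramp(z, zb, zb + 8.0, 2.0)
        mask = z >= zb - 1e-9
        ex = x + sgn * spec.eca_lateral_offset * dep
        ey = y - 3.0 * dep
        pts = np.column_stack([ex, ey, z])[mask]
        t = np.column_stack(
            [sgn * (dsway + spec.eca_lateral_offset * ddep), -3.0 * ddep, np.ones_like(z)]
        )[mask]
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        curves[side + "ECA"] = pts
        tangents[side + "ECA"] = t
    return curves, tangents


def _ground_truth(spec: PhantomSpec, curves: dict, tangents: dict) -> PhantomGroundTruth:
    turning, planes, radii = {}, {}, {}
    z_mid = (spec.z_turn_lower + spec.z_turn_upper) / 2.0

    def at_z(label, z_target):
        pts = curves[label]
        i = int(np.argmin(np.abs(pts[:, 2] - z_target)))
        return pts[i], tangents[label][i]

    for side in ("L", "R"):
        va = side + "VA"
        if va in curves:
            lo, _ = at_z(va, spec.z_turn_lower)
            hi, _ = at_z(va, spec.z_turn_upper)
            turning[va] = np.vstack([lo, hi])
            center, normal = at_z(va, z_mid)
            planes[va] = {"center": center, "normal": normal}
            radii[va] = spec.va_radius * spec.small_va_scale
        ica = side + "ICA"
        if ica in curves:
            center, normal = at_z(ica, spec.z_turn_upper)
            planes[ica] = {"center": center, "normal": normal}
            radii[ica] = spec.ica_radius
            radii[side + "ECA"] = spec.ica_radius * 0.8
    vol_center = (np.asarray(spec.shape, dtype=float) - 1) / 2.0 * np.asarray(spec.spacing)
    return PhantomGroundTruth(
        centerlines=curves,
        tangents=tangents,
        turning_points=turning,
        ideal_planes=planes,
        radii=radii,
        volume_center=vol_center,
    )


def artery_intensity(spec: PhantomSpec, z_mm: float | np.ndarray):
    """Analytic tube intensity at height z (taper reduces contrast upward)."""
    c = spec.contrast * (1.0 - spec.taper_top_fraction * np.asarray(z_mm) / spec.z_extent)
    return spec.tissue_mean + c * spec.tissue_sd


def _rasterize_tube(flags: np.ndarray, spec: PhantomSpec, curve: np.ndarray, radius: float) -> None:
    """Mark voxels whose centre lies within *radius* of the curve."""
    spacing = np.asarray(spec.spacing)
    lo = np.maximum(np.floor((curve.min(axis=0) - radius) / spacing).astype(int), 0)
    hi = np.minimum(
        np.ceil((curve.max(axis=0) + radius) / spacing).astype(int) + 1,
        np.asarray(spec.shape),
    )
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = idx * spacing
    tree = cKDTree(curve)
    dist, _ = tree.query(centers, workers=1)
    inside = idx[dist < radius]
    flags[inside[:, 0], inside[:, 1], inside[:, 2]] = True


def generate_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomGroundTruth]:
    """Rasterize a phantom angiogram and return it with its ground truth.

    Fixed seed implies bit-for-bit reproducible output.
    """
    curves, tangents = _analytic_curves(spec)
    dropped = set(spec.drop_arteries)
    for lbl in dropped:
        curves.pop(lbl, None)
        tangents.pop(lbl, None)
        if lbl.endswith("ICA"):  # the ECA branch belongs to the carotid trunk
            curves.pop(lbl[0] + "ECA", None)
            tangents.pop(lbl[0] + "ECA", None)
    truth = _ground_truth(spec, curves, tangents)

    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    ext = spec.extent

    # tissue: elliptical cylinder with Gaussian texture, air outside
    xi = np.arange(nx) * spec.spacing[0]
    yi = np.arange(ny) * spec.spacing[1]
    ex, ey = 0.45 * ext[0], 0.45 * ext[1]
    body2d = ((xi[:, None] - ext[0] / 2) / ex) ** 2 + ((yi[None, :] - ext[1] / 2) / ey) ** 2 <= 1.0
    body = np.repeat(body2d[:, :, None], nz, axis=2)
    data = np.zeros(spec.shape, dtype=float)
    data[body] = spec.tissue_mean + spec.tissue_sd * rng.standard_normal(int(body.sum()))

    # arteries: constant contrast, optionally tapering toward the head
    artery = np.zeros(spec.shape, dtype=bool)
    for lbl, curve in curves.items():
        _rasterize_tube(artery, spec, curve, truth.radii[lbl])
    zi = np.arange(nz) * spec.spacing[2]
    intensity = artery_intensity(spec, zi)  # (nz,)
    data[artery] = np.broadcast_to(intensity, spec.shape)[artery]

    if spec.blur_sigma_y > 0:
        data = gaussian_filter1d(data, spec.blur_sigma_y / spec.spacing[1], axis=1)
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(spec.shape)
    data = np.clip(data, 0.0, None)

    volume = Volume3D(data=data, spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    return volume, truth


def generate_profile_population(
    n: int,
    spec: PhantomSpec | None = None,
    side: str = "L",
    turn_height_jitter: float = 3.0,
    shift_jitter: float = 1.0,
    profile_noise_sd: float = 0.02,
    dz: float | None = None,
    axis: str = "AP",
    seed: int = 0,
) -> list[LabeledProfile]:
    """VA derivative profiles from *n* phantoms with jittered bend geometry.

    Emulates the subject population a matching template is averaged from:
    each profile comes from a phantom whose bend heights and displacements
    are perturbed (SDs in mm), with the true turning indices annotated.
    """
    if n < 2:
        raise ValueError("population needs n >= 2")
    spec = spec or PhantomSpec()
    if dz is None:
        dz = spec.spacing[2]
    rng = np.random.default_rng(seed)
    out: list[LabeledProfile] = []
    for _ in range(n):
        zext = spec.z_extent
        lo = spec.z_turn_lower + turn_height_jitter * rng.standard_normal()
        hi = spec.z_turn_upper + turn_height_jitter * rng.standard_normal()
        lo = float(np.clip(lo, 0.1 * zext, 0.55 * zext))
        hi = float(np.clip(hi, lo + 6 * spec.bend_halfwidth, 0.9 * zext))
        jspec = replace(
            spec,
            turn_lower_frac=lo / zext,
            turn_upper_frac=hi / zext,
            va_posterior_shift=max(
                0.5, spec.va_posterior_shift + shift_jitter * rng.standard_normal()
            ),
            va_medial_shift=max(
                0.0, spec.va_medial_shift + shift_jitter * rng.standard_normal()
            ),
        )
        curves, _ = _analytic_curves(jspec)
        cl = Centerline(side + "VA", curves[side + "VA"])
        prof = derivative_profile(cl, axis=axis, dz=dz)
        if profile_noise_sd > 0:
            prof = DerivativeProfile(
                values=prof.values + profile_noise_sd * rng.standard_normal(len(prof)),
                dz=prof.dz,
                z0=prof.z0,
                axis=prof.axis,
            )
        i_lo = int(np.clip(round((lo - prof.z0) / dz), 0, len(prof) - 2))
        i_hi = int(np.clip(round((hi - prof.z0) / dz), i_lo + 1, len(prof) - 1))
        out.append(LabeledProfile(profile=prof, turn_lower=i_lo, turn_upper=i_hi))
    return out
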