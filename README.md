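# pcplan

Automatic scan-plane positioning for phase-contrast MRI (PC-MRI)
quantification of global cerebral blood flow.

## The problem

Whole-brain cerebral blood flow can be measured by summing PC-MRI flow flux
over the four brain-feeding arteries — the left/right internal carotid
arteries (ICA) and the left/right vertebral arteries (VA). Accurate flux
needs each single-slice PC-MRI scan placed perpendicular to its artery near
the skull entry, which traditionally requires an experienced operator
reading a time-of-flight (TOF) angiogram. `pcplan` computes those slice
prescriptions automatically: given a 3-D TOF angiogram of the neck it emits,
per artery, the six numbers an operator types into the console — three
off-centre offsets (mm along L–R, A–P, F–H) and three angulation angles
(degrees).

## The algorithm

1. **Body mask** — Otsu's threshold (256-bin histogram) separates the body
   region *O* from air.
2. **Adaptive artery threshold** — arteries are voxels above
   `T_j = μ_O + j·σ_O`. Searching `j = 5, 4, 3` in descending order, the
   first `j` at which all four identified arteries span ≥ 60 % of the z
   range is accepted.
3. **Artery identification** — among the eight largest 26-connected
   objects, VAs are the most posterior branch-free cross-sections at the
   middle axial slice (one per left/right half); the carotids are the two
   largest remaining objects, with the middle-slice branch closest to the
   image centre seeding the ICA (the other branch being the external
   carotid).
4. **Centerline** — centres of geodesic-distance level sets on the object's
   voxel graph, restricted to the branch through the seed section.
5. **VA turning points** — the VA bends twice between the C2 and C1
   vertebral levels. Its derivative profile `f` (slope of the A–P
   coordinate vs height) is matched to a population-averaged template `g`
   by normalized cross-correlation `R(m)`; padding around the template's
   annotated turns gives a rough region; within it, dynamic programming
   finds the changepoints `k1 < k2` minimizing the total within-segment
   variance `V1 + V2 + V3` of the three subregions.
6. **Planes** — the VA plane sits at the index midpoint of the two turning
   points; each ICA plane at the ICA point level with the upper VA turn
   (cross-side fallback if a VA is missing). Normals are the principal
   direction of the centerline in a ±5-point window; the run aborts unless
   at least three planes, including one VA, succeed.

A synthetic phantom module generates TOF-like volumes (bright tubes for the
four arteries with an ECA branch and the double VA bend, noisy tissue
cylinder, air background) with exact ground truth, so the whole pipeline is
testable without any scanner data. Evaluation statistics used for such
pipelines — ROI flux, two-replicate inter-session coefficient of variation,
log-scale Bland–Altman agreement, chi-square tests of independence, and
success-rate accounting — live in `pcplan.eval_stats`.

## Worked example

`python examples/plan_phantom_scan.py` prints:

```
phantom: (80, 80, 47) voxels at (0.8, 0.8, 1.5) mm
threshold accepted at j = 5; overall: ok

LICA: off-center [-13.5, -7.6, +9.0] mm  angulation [-0.2, +1.3, +0.0] deg
       normal within 0.45 deg of the true vessel tangent
RICA: off-center [+14.4, -7.6, +7.5] mm  angulation [+0.0, -0.5, +0.0] deg
       normal within 0.23 deg of the true vessel tangent
LVA: off-center [-7.0, +10.7, +0.0] mm  angulation [+12.2, +10.3, +0.0] deg
       normal within 0.77 deg of the true vessel tangent
RVA: off-center [+7.9, +10.6, -1.5] mm  angulation [+12.4, -9.9, +0.0] deg
       normal within 0.33 deg of the true vessel tangent
```

Each line is one slice prescription: the plane centre relative to the
volume centre and the tilt angles about the L–R and A–P axes (`γ ≡ 0`; a
plane has no in-plane orientation). The VA planes tilt ~12° posteriorly
because the plane sits between the two bends, where the vessel still climbs
obliquely; the comparison lines confirm each planned normal is within a
degree of the true vessel tangent at that point.

Other examples: `examples/detect_turning_points.py` (template matching and
changepoint refinement on a single profile) and
`examples/evaluation_statistics.py` (success accounting, chi-square tables,
flux/CoV/Bland–Altman). A thin CLI wraps the same library:
`pcplan phantom`, `pcplan build-template`, `pcplan plan`, `pcplan stats`
(exit codes: 0 ok, 1 usage/I-O error, 2 algorithmic abort).

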