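# Methods

## Coordinate conventions

All computation happens in one anatomical frame: x = left→right,
y = anterior→posterior, z = feet→head, voxel indices 0-based, a voxel's
coordinate referring to its centre. NIfTI-1 input in any axis-aligned
orientation is remapped on read; oblique affines are rejected explicitly
rather than resampled, since slice prescriptions are only meaningful
relative to a rectilinear acquisition frame. PAR/REC and DICOM dialects are
out of scope — convert to NIfTI first.

## Segmentation

The body mask is Otsu's threshold on a 256-bin histogram of the whole
volume. The artery threshold is `T_j = μ_O + j·σ_O` with `μ_O`, `σ_O` the
mean and *population* SD over body voxels (at volume scale the sample/
population distinction is far below intensity noise; the population form is
the simpler contract). `j` is searched from 5 down to 3; each candidate
mask is labeled and the acceptance criterion — every identified artery
spanning at least 60 % of the z range — is evaluated on the four identified
arteries, not on all candidate objects, because the criterion exists to
guarantee the inter-bend portion of the VAs is captured. z-extent is slice
extent `(z_max − z_min + 1)/N_z`, not arc length, matching the criterion's
purpose of covering the scan range. If even `j = 3` fails, segmentation
returns the `j = 3` mask with a lower-bound status and the ≥3-artery rule
downstream decides whether to abort; this mirrors the operational rule that
an artery undetectable at `j = 3` is too weak to be trusted.

## Identification

3-D connectivity is 26, 2-D connectivity 8 — the most permissive standard
choices, keeping thin oblique vessels connected. "Most posterior" means
largest y centroid among single-section candidates; "image centre" is the
in-plane midpoint of the grid. If the two largest remaining objects fall in
the same x half, the largest per half is taken; an empty half leaves that
ICA "not found". If the carotid bifurcation sits exactly at the middle
slice both sections are kept and the centre-closest rule picks the ICA
seed.

## Centerline

Rather than meshing the vessel surface and tracing level curves on it, the
centerline is the sequence of centroids of geodesic-distance level sets on
the object's voxel graph (edge weights = physical step lengths, source =
inferior-most voxel), binned at `max(spacing)`. Side branches are cut by
keeping, per level bin, only the 26-connected cluster(s) containing
ancestors or descendants of the seed cross-section in the shortest-path
tree — descendants are propagated from the seed section only, because
propagating from the shared trunk would readmit the ECA branch. The
polyline is smoothed with a 3-point moving average, chosen to suppress
voxel-quantization jitter without displacing bends by more than one sample.

The derivative profile is the centerline's transverse coordinate resampled
at uniform z steps (default: the slice spacing) and differentiated with
central differences, one-sided at the endpoints. The transverse axis
defaults to A–P — the VA bends are predominantly posterior — and is
configurable to L–R; template and subject profiles record their axis and
sampling so a mismatch is an error, never a silent bias.

## Turning-point detection

Cross-correlation is normalized (zero mean, unit norm over the overlap) so
amplitude and offset differences between subject and template cannot bias
the offset estimate; overlaps shorter than half the template are skipped
and ties go to the smallest offset. The rough region pads the template's
turning indices by `P = 10` samples (15 mm at the default sampling) on each
side — wide enough to absorb several-sample anatomical variation, narrow
enough to exclude the profile ends.

The refinement objective is the total within-segment sum of squared
deviations of the three subregions `[0,k1)`, `[k1,k2)`, `[k2,n)`. With
prefix sums each segment cost is O(1), so exact minimization over all valid
pairs is O(n²) — trivially fast at the n ≈ 30–50 of a rough region, and
verified against an independent exhaustive oracle in the tests. Minimum
segment length is 2 samples so every variance is defined on at least two
points; ties resolve to the lexicographically smallest `(k1, k2)`, making
the constant-segment case deterministic.

The scan-plane centre is the centerline point at profile index
`⌊(k1+k2)/2⌋` — an index midpoint, not an arc-length midpoint; at sampling
equal to the slice spacing the difference is sub-voxel. The normal is the
first principal direction (SVD) of the centerline points within ±5 points
of the centre, sign-fixed to a positive F–H component; the window shrinks
symmetrically (minimum 3 points) near the ends. Angulation is reported as
α about L–R then β about A–P applied to (0,0,1), with γ ≡ 0; the unit
normal is always emitted alongside so the output is convention-proof. When
a same-side VA is missing, the other VA's upper turn supplies the ICA plane
height — one VA is the minimum needed to fix that level, hence the
≥3-artery/≥1-VA abort rule.

## Phantom

The phantom emulates exactly the features the algorithm exploits: four
bright tubes (ICA radius 2.2 mm, VA 1.4 mm) rasterized as
distance-to-curve < radius in a 80×80×47 grid of 0.8×0.8×1.5 mm voxels; a
tissue cylinder of mean 100, SD 10 with arteries at contrast 8 tissue SDs;
additive Gaussian noise SD 2; an ECA branch leaving the carotid at 35 % of
the z extent; VA bends at 35 % and 60 % (≈ C2 and C1 levels) with 4 mm
posterior and 3 mm medial displacement between them, blended by C¹
cosine-tapered ramps so the true tangent is defined everywhere. Degradation
flags reproduce the observed failure modes: motion blur along y, a
small-VA radius scale, dropped arteries, and an intensity taper toward the
head that exercises the descending-j threshold loop. Gaussian rather than
Rician noise is used deliberately: the algorithm only thresholds
high-intensity voxels, where the two are indistinguishable.

`generate_profile_population` jitters bend heights (SD 3 mm) and
displacements (SD 1 mm) and perturbs the analytic profiles with small noise
(SD 0.02), emulating the subject population a template is averaged from.
The defaults are plausible for cervical anatomy but are not claimed to be
population-accurate; they are all exposed on `PhantomSpec`.

What the phantom does **not** model: flow-related signal saturation and
pulsatility, bone/skull structures, partial-volume intensity gradients at
vessel walls, and real anatomical variability of vessel calibre and
tortuosity. Passing the recovery tests therefore shows the pipeline is
correct on geometry it was designed for, not that it attains any particular
success rate on clinical angiograms.

## Evaluation statistics

Two-replicate CoV is `100·|F1 − F2| / mean(F1, F2)`; the alternative
SD-of-pair/mean convention differs by √2, so the choice is stated
prominently. Bland–Altman agreement uses natural-log differences, sample
SD, and 1.96·SD limits of agreement; the geometric mean ratio `exp(mean d)`
is the multiplicative bias. Chi-square independence is the Pearson
statistic without continuity correction (delegated to scipy), `df =
(r−1)(c−1)`. Success accounting derives artery counts from the three
subject performance groups (4, 3 and 0 successes respectively) and reports
exact percentage rates; callers round for display. Cohort CoV is reported
as mean ± SD across per-artery pairs. Phase-to-velocity (venc) scaling is
out of scope: `compute_flux` takes velocity maps in cm/s directly.

## Problem sizes and determinism

The test suite and the acceptance script run everything on the 80×80×47
default grid: 20 seeded noisy phantoms plus their noiseless twins for
recovery scoring, 10-profile populations for templates, 120 random segments
for the changepoint oracle, and 10 000 simulated pairs for the
Bland–Altman coverage check — sizes at which the full pipeline runs in
under a second per phantom while leaving every code path exercised. All
randomness flows from explicit seeds (`PhantomSpec.seed`, generator seeds,
the acceptance script's `--seed`), so identical inputs give bit-identical
volumes and reports.

## Known limitations

* Only axis-aligned NIfTI volumes; no resampling, registration, or 4-D
  series.
* The centerline is voxel-graph based; sub-voxel accuracy comes from level-
  set averaging and smoothing, not from a surface model, and degrades for
  vessels only 1–2 voxels thick.
* Template and subject profiles must share their sampling interval; there
  is no length normalization across subjects with very different neck
  spans.
* The abort rule (≥3 arteries, ≥1 VA) excludes subjects in whom both VAs
  are too small to segment — a property of the method, preserved here.
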