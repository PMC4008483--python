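"""Turning-point detection on a vertebral-artery derivative profile.

The VA bends twice between the C2 and C1 vertebral levels; on the
derivative profile (slope of the A-P coordinate vs height) those bends are
changepoints.  A template matched by normalized cross-correlation brackets
a rough region; dynamic programming then minimizes the total variance of
the three subregions to place the two changepoints exactly.
"""

from pcplan.phantom import PhantomSpec, generate_profile_population
from pcplan.planning import (
    build_template,
    cross_correlate,
    detect_turning_points,
    rough_region,
)

spec = PhantomSpec(seed=0)
population = generate_profile_population(10, spec, side="L", seed=100)
template = build_template(population, pad=10, side="L")
print(
    f"template: {len(template)} samples at dz = {template.dz} mm, "
    f"annotated turns at {template.turn_lower} and {template.turn_upper}"
)

subject = generate_profile_population(2, spec, side="L", seed=999)[0]
m, score = cross_correlate(subject.profile, template)
lo, hi = rough_region(subject.profile, template, m)
turns = detect_turning_points(subject.profile.values[lo : hi + 1], offset=lo)

print(f"best match offset m = {m} (correlation {score:.3f})")
print(f"rough region: samples {lo}..{hi}")
print(
    f"detected turns at samples ({turns.k1}, {turns.k2}); "
    f"true turns at ({subject.turn_lower}, {subject.turn_upper})"
)
mid = (turns.k1 + turns.k2) // 2
print(f"scan plane goes at sample {mid}, z = {subject.profile.z_of(mid):.1f} mm")
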