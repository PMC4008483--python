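"""End-to-end scan planning on a synthetic angiogram.

Generates a phantom neck angiogram with known artery geometry, builds the
left/right vertebral-artery matching templates from a jittered profile
population, runs the full positioning pipeline, and compares the planned
planes against the phantom's ground truth.
"""

import numpy as np

from pcplan.phantom import PhantomSpec, generate_phantom, generate_profile_population
from pcplan.planning import build_template, plan_all

spec = PhantomSpec(seed=1)
volume, truth = generate_phantom(spec)
print(f"phantom: {volume.shape} voxels at {volume.spacing} mm")

templates = {
    side: build_template(
        generate_profile_population(10, spec, side=side, seed=100 + i), side=side
    )
    for i, side in enumerate("LR")
}

result = plan_all(volume, templates["L"], templates["R"])
print(f"threshold accepted at j = {result.provenance['j']}; overall: {result.overall}\n")

for label in ("LICA", "RICA", "LVA", "RVA"):
    art = result.arteries[label]
    p = art.plane
    off = ", ".join(f"{v:+.1f}" for v in p.center)
    ang = ", ".join(f"{v:+.1f}" for v in p.angulation)
    print(f"{label}: off-center [{off}] mm  angulation [{ang}] deg")
    center_abs = p.center + truth.volume_center
    tangent = truth.tangent_at(label, center_abs)
    err = np.degrees(np.arccos(min(abs(p.normal @ tangent), 1.0)))
    print(f"       normal within {err:.2f} deg of the true vessel tangent")

# The six numbers per artery are exactly what an operator would type into
# the scanner console: plane-centre offsets (L-R, A-P, F-H) from the volume
# centre and tilt angles about the L-R and A-P axes (in-plane angle is 0).
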