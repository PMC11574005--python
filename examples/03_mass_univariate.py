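"""Vertex-wise mixed-model group comparison with searchlight FDR.

Simulates a two-group cohort over a small atlas with a planted putamen
thinning, fits the per-vertex linear mixed model (cohort random intercept;
age/sex/ICV nuisance), and corrects with neighborhood-wise
Benjamini-Hochberg.
"""

import numpy as np

from shapestage import (
    DesignSpec,
    EffectSpec,
    StageBump,
    map_effects,
    searchlight_fdr,
    simulate_cohort,
    simulate_thickness,
    summarize_map,
)
from shapestage.mesh import build_atlas

config = [
    {"name": n, "hemisphere": h, "kind": "uv", "rings": 8, "cols": 10,
     "axes": [10.0, 5.0, 4.0], "center": [s * 15.0, 0, 0], "rotate": False}
    for n in ("putamen", "pallidum") for h, s in [("left", -1), ("right", 1)]
]
atlas = build_atlas(config, seed=0)
cohort = simulate_cohort({"control": 120, 2: 120}, n_cohorts=5, seed=1)
spec = EffectSpec(
    bumps=[StageBump("putamen_left", 40, radius=5, amplitude=-0.25, stages=(2.0,))],
    residual_sd=0.2,
)
thickness = simulate_thickness(atlas, cohort, spec, seed=2)

cohort["is_pd"] = (cohort["group"] == "PD").astype(int)
emap = map_effects(thickness, DesignSpec(predictor="is_pd"), cohort)
emap.sig_mask = searchlight_fdr(emap.p, atlas.adjacency, radius_hops=5, q=0.05)
emap.q_level = 0.05

print(summarize_map(emap, atlas).to_string(index=False))
peak = np.argmax(np.abs(emap.beta))
print(f"\npeak |beta| = {emap.beta[peak]:.3f} mm at global vertex {peak}")
# The planted putamen_left bump (amplitude -0.25 mm) should dominate the
# significant vertices; pallidum carries no effect and stays near 0%.
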