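"""Reporter activity profiles along dead-end pores and front extraction.

Plants a sigmoidal quorum-sensing activation front 0.06 mm into each
cavity, renders the GFP channel as biomass × activation, and recovers the
front depth from the biomass-normalized profiles.
"""

import numpy as np

from porecolony.biomass import preprocess_stack
from porecolony.geometry import discretize
from porecolony.reporter import dep_depth_profile, extract_front, normalize_activity
from porecolony.synthetic import (
    GeometryParams,
    generate_biomass_stack,
    generate_geometry,
    generate_reporter_stack,
)

params = GeometryParams(
    domain_size_px=(256, 320), pixel_size=4.0, target_porosity=0.35,
    target_dep_fraction=0.08, mean_pore_size=0.04, mean_dep_depth=0.1,
    cavity_aspect=3.0, seed=1,
)
mask, truth = generate_geometry(params)
lmap, skeleton, disks, _ = discretize(mask)

times = np.arange(3) * 600.0
bstack, btruth = generate_biomass_stack(
    truth.true_label_map, times, np.array([0, 2.0, 2.0]), tp_mean=3000.0, seed=0
)
gfp, _ = generate_reporter_stack(
    truth.true_label_map, bstack, btruth, truth.cavities,
    front_depth_mm=0.06, steepness_um=6.0, seed=0,
)

corr_b = preprocess_stack(bstack, lmap)
corr_g = preprocess_stack(gfp, lmap)
amap = normalize_activity(corr_g.frames[1], corr_b.frames[1], floor=10.0)
profiles = dep_depth_profile(amap, lmap, skeleton, disks, step_px=10)
fronts = [
    extract_front(p).zeta_mm
    for p in profiles
    if not p.single_point and extract_front(p).defined
]
print(f"profiled DEPs        {len(profiles)}")
print(f"median front depth   {np.median(fronts)*1000:.0f} um (planted 60 um)")
print(f"front depth IQR      {np.percentile(fronts, 25)*1000:.0f}"
      f"-{np.percentile(fronts, 75)*1000:.0f} um")
# The 80%-of-maximum front position recovers the planted activation depth
# to within one 10-pixel sampling step.
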