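"""Microvascular density mapping via the skeleton fill factor.

Grows a capillary network with a known skeleton density, converts the
angiogram to a fill-factor density map (w = 60 window, sigma = 3
Gaussian) and reads ROI max/mean densities.
"""

import numpy as np

from vasoreact import density as de
from vasoreact import synth

spec = synth.OctPhantomSpec(
    shape=(1, 240, 240),
    capillary=synth.CapillarySpec(target_fill=0.05), seed=7)
phantom = synth.gen_oct_phantom(spec)
print(f"generated skeleton fill fraction: {phantom.capillary_fill:.4f} "
      f"(target {spec.capillary.target_fill})")

skel = de.repair_skeleton(de.binarize_skeletonize(phantom.angiogram[0]))
dmap = de.smooth_density(de.fill_factor_map(skel, window=60), sigma=3.0)

rois = {}
for i, (y, x) in enumerate([(70, 70), (70, 170), (170, 120)]):
    m = np.zeros((240, 240), dtype=bool)
    m[y - 30:y + 30, x - 30:x + 30] = True
    rois[i] = m
stats = de.roi_density_stats(dmap, rois)
print(stats.to_string(index=False))
print(f"per-animal value = mean over the ROIs: max {stats.ff_max.mean():.4f}, "
      f"mean {stats.ff_mean.mean():.4f}")
print("FF(x,y) counts skeleton pixels in the 60x60 patch over 3600; maps are")
print("displayed on a 0.00-0.15 scale, statistics use unclipped values.")
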