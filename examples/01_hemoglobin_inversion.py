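"""Dual-wavelength Beer-Lambert inversion on a synthetic reflectance stack.

Builds a noiseless two-wavelength (568/630 nm) phantom with artery, vein
and tissue compartments, each dipping after a simulated vasoconstrictive
injection, then inverts the stack back to hemoglobin concentration
changes and reads the per-class Delta[HbT]% nadirs.
"""

import numpy as np

from vasoreact import spectral, synth

spec = synth.default_dwi_phantom_spec(shape=(48, 48), frame_interval_s=2.0)
ext = spectral.default_extinction()
phantom = synth.gen_dwi_stack(spec, ext)

dhbo2, dhbr = spectral.invert_beer_lambert(phantom.stack, ext)
series = spectral.roi_timeseries(dhbo2, dhbr, phantom.rois,
                                 phantom.stack.timestamps_s,
                                 baseline_hbt=spec.baseline_hbt)

err = np.max(np.abs(dhbo2 - phantom.truth_dhbo2)) / np.max(np.abs(phantom.truth_dhbo2))
print(f"round-trip max relative error: {err:.2e}  (noiseless: numerical precision)")
for cls in ("vein", "artery", "tissue"):
    nadir = series.class_mean_pct(cls).min()
    configured = spec.compartments[cls].transient.amplitude_pct
    print(f"{cls:7s} Delta[HbT]% nadir: {nadir:7.2f}  (configured {configured})")

hints = spectral.vessel_class_hint(phantom.stack, phantom.rois)
by_class = {c: np.mean([hints[l] for l in phantom.rois.labels_of(c)])
            for c in ("vein", "artery")}
print(f"630/568 absorbance score - vein {by_class['vein']:.3f} vs "
      f"artery {by_class['artery']:.3f} (veins absorb more red light)")
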