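# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Hemoglobin inversion (spectral)

The two-wavelength modified Beer–Lambert model assumes changes in diffuse
reflectance are dominated by changes in HbO₂ and HbR absorption. Per pixel
and frame the 2×2 extinction system is solved against the log-attenuation
relative to R_λ(0), the temporal mean over the whole baseline window
(robust to noise; a single first frame would be an unnecessarily noisy
reference). The matrix inverse is precomputed once; a condition number
above 10¹² raises rather than silently amplifying noise.

* **Extinction coefficients.** Built-in values are approximate compiled
  hemoglobin spectra: 568 nm is near-isosbestic (ε_HbO₂ = 44480,
  ε_HbR = 41212 M⁻¹cm⁻¹), at 630 nm HbR dominates (610 vs 5148).
  Percentage metrics depend only on the matrix structure, not its absolute
  scale; users can supply any tabulation via `ExtinctionSet`.
* **Pathlengths** default to L = 1 (differential pathlength factors are
  rarely known per preparation), so concentration changes are in the
  inversion's arbitrary units. The Δ[HbT]% normalization divides by a
  configurable `baseline_hbt`; the default phantom works in molar units
  with a 100 μM baseline so the realistic extinction values keep
  reflectance in (0, 1].
* **Artery/vein hint.** Per-ROI absorbance at 630 vs 568 nm against the
  image median as background proxy; a ratio above 1 leans venous
  (HbR-rich). Advisory only; manual labels always win.

## CVR metrics (cvr)

Traces are smoothed with a centred 30 s moving average on the actual
timestamps (irregular sampling allowed) before the minimum and crossing
searches; the integral and closed-form tests can disable smoothing.

* **Peak** = minimum of the smoothed trace after injection.
* **RT**: the study's "return to the range of baseline" is
  operationalized as the first time after the nadir at which the smoothed
  trace exceeds baseline-mean − k·baseline-sd (k = 1) and stays above for
  60 s. k and the dwell are configuration because the underlying tolerance
  band is a judgment call; this is the main free parameter of the whole
  CVR stage. A trace that never leaves the band reports RT = 0 with a
  "no response" note; one that never returns reports the record length
  with `recovered = False`.
* **IR** integrates the smoothed trace trapezoidally over
  [t_inject, t_inject + RT], in %·min (often reported as a.u.; the unit
  is declared here because the trace is % and the axis minutes). Window
  ends are closed by linear interpolation so IR does not depend on sample
  phase.
* **Statistics.** Pooled two-tailed t (zero pooled variance with equal
  means gives p = 1, with unequal means is an error). The 2×2 sex × group
  ANOVA uses Type-II sums of squares — identical to Type I/III when
  balanced and robust to the mildly unbalanced cells of real cohorts —
  with the four pairwise sex/group contrasts Bonferroni-corrected (×4,
  capped at 1).

## Doppler velocimetry (doppler)

Phase differences are the angles of conjugate products of adjacent
A-scans, complex-averaged over a 4-pair window (Kasai-style) before the
angle is taken; output phases are wrapped to (−π, π]. Values are flagged
when they sit at the wrap boundary but are **not** unwrapped by default —
unwrapping is opt-in because silent unwrapping fabricates velocity where
the data are ambiguous. θ = 0 globally (vessels roughly parallel to the
cortical surface, beam normal to it), with a per-vessel override since
real vessels are oblique. Per-vessel CBFv averages per-ROI means along
the vessel; the ROI statistic (mean vs max) is configurable with mean as
default — a max statistic would be noise-biased upward. A vessel whose
mean speed is below 10⁻³ mm/s reports 0 with an occlusion-like flag.
Line rate 6000 A-lines/s fixes T = 1/6000 ≈ 0.000167 s.

## Morphology (morphology)

Preprocessing rescales to [0, 1] and applies a 3×1 median filter along the
fast-scan axis (orientation configurable) to remove single-line speckle.
Vesselness is the standard multiscale Frangi response taken as the
pixelwise **maximum over per-scale-normalized responses**; normalizing
across scales jointly (as a single multi-sigma call would) suppresses the
interior response of wide vessels, which defeats the purpose of the large
pass. Two passes (scales 1–5 px and 5–25 px) are thresholded separately —
Otsu on the nonzero response by default, fixed threshold available — and
unioned; a single scale family produces strong artifacts when vessel
calibers vary by an order of magnitude. Each pass is additionally gated
by the bright support of the image (Otsu on intensity): the Frangi
response spills roughly one scale width beyond vessel walls, and since
lumen pixels are bright in an angiogram the gate trims that halo without
touching the lumen (disable with `intensity_gate=False`). On noiseless
bars of 5–80 px this pipeline reaches IoU ≥ 0.99 against ground truth.

Diameters: thinning skeleton + exact Euclidean distance transform;
φ = 2·EDT − 1 pixels at each centerline pixel, exact for odd-width bars
(a rasterized tube centred on a pixel row is always odd). Analysis is 2D
(maximum-intensity projections); vessel-order labels (1st = primary
branch, 2nd = its bifurcation) are supplied by the user from wide-field
images — automatic branch ordering is out of scope. Per-vessel diameter
averages sequential ROIs along the vessel.

## Density (density)

Skeletons come from the small-scale vesselness pass, thresholded and
thinned. Breakage repair dilates with a 3×3 disk and **re-thins**: a
plain closing's erosion cuts the one-pixel bridge straight back, whereas
thinning keeps connectivity while restoring unit width; gaps up to 2 px
bridge, structures farther apart than twice the radius stay separate.
The fill factor uses an integral image for exact integer counts; for the
even default window w = 60 the patch at (i, j) covers rows/columns
[i − 30, i + 29]. Borders are zero-padded (off-image area has no vessels)
and the σ = 3 Gaussian then suppresses the resulting edge artifacts,
which is that filter's stated purpose. The 0.00–0.15 scale is display
clipping only; statistics always use unclipped FF. Density ROIs are
validated against the diameter map: any centerline pixel wider than
50 μm inside an ROI rejects it, since the measure targets capillaries.

## Synthetic data (synth)

The generators define the study conditions; their defaults are the group
values the package is designed to reproduce.

* **DWI phantom.** Three disjoint rectangular ROIs per compartment
  (artery/vein/tissue) on a 3×3 grid; 10 min baseline + 30 min
  post-injection; the transient is a gamma-variate dip with exponential
  recovery (fast drop, slow return, three interpretable parameters). The
  frame interval is a free parameter (1 s per two-wavelength pair by
  default; only relative timing matters to the metrics, and the exposure
  duration of the real instrument does not constrain it). Compartments
  carry static HbO₂/HbR baselines so arteries and veins differ in
  baseline 630/568 contrast, and a per-compartment oxygen fraction splits
  ΔHbT into ΔHbO₂/ΔHbR. Noise is multiplicative Gaussian on reflectance.
* **OCT phantom.** Tubes are polyline centerlines with plug or parabolic
  profiles (velocity given at the centerline, so parabolic lumen mean is
  half); phase encodes 4πnTv cos θ/λ₀, additive wrapped-Gaussian noise is
  applied **before** the final wrap so downstream wrap handling is
  exercised; encoding beyond |Δφ| = π warns and records the wrap.
  Capillary networks grow as short smoothed random walks rasterized one
  voxel wide and re-thinned as they grow, so the returned ground truth is
  a thinning-stable skeleton (a raw walk trace carries staircase pixels
  any thinning pass would remove, which would bias the density truth
  high); growth stops within 10% of the target fill fraction.
* **Cohorts.** Per-animal true metrics are drawn from N(mean, sd) with
  the configured group tables (CVR peak/IR/RT per ROI class at
  n = 8 WT / 12 AD; CBFv and diameter per artery order at n = 6 + 6;
  density max/mean at n = 9 + 6; sexes split evenly). The configured
  spreads are used directly as per-animal standard deviations. CVR traces
  are piecewise-linear transients constructed so the extraction pipeline
  reads back the drawn truth: linear descent, a 1-min nadir plateau (so
  the smoothed minimum still equals the true peak), a sustained-
  depression level solved in closed form so the area over [0, RT] equals
  the drawn IR, and a linear ramp crossing the expected baseline band
  exactly at the drawn RT with a small overshoot. Per-ROI measurement
  noise (0.5% sd) is added on top; per-artery and per-ROI density values
  are centred around the animal draw so animal-level means are exact.
  Draws are clamped to the shape's feasible region (peak ≤ −0.5%,
  RT ≥ 2 min, IR within the geometrically attainable band); at the
  default parameters clamping is rare.
* **What the generators do not emulate:** speckle statistics and
  interferometric noise of real OCT, photon-transport effects and
  pathlength dispersion in DWI, motion, anesthesia physiology, or
  correlated within-animal structure beyond the centred ROI jitter.
  Passing tests therefore demonstrate correctness of the estimators and
  the power of the group comparisons under the configured effect sizes —
  not robustness to every artifact of real imaging.

All generators are deterministic given (spec, seed); cohort substreams
are spawned from one root seed.

## Pipeline and reproducibility

`RunConfig` (pydantic, unknown keys rejected) carries every stage default;
`run_pipeline` is deterministic given config + seed and writes summary
CSVs plus a provenance record (config hash, package versions). Reports
annotate p-values as *p<0.05, **p<0.01, ***p<0.001, NS otherwise.

Problem sizes used by the shipped tests and acceptance script — 24–256 px
phantom images, 200-seed Monte-Carlo loops, one full cohort per run —
were chosen so the whole suite completes in well under a minute while
keeping every estimate's sampling error far below the tolerances tested.

## Known limitations

* The phase-intensity variant of Doppler reconstruction is not
  implemented (no published formula to implement); only phase
  subtraction is.
* Diameter and density analysis is 2D-projection based; slab-wise 3D
  analysis is a stub behind configuration.
* Recovery-time values depend on the band parameter k and dwell; the
  defaults are reasonable but not canonical.
* The ±-as-sd cohort reading makes per-animal spreads equal to the
  configured dispersion parameters; with dispersions entered as standard
  errors the same tables can be reproduced by multiplying by √n first.
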