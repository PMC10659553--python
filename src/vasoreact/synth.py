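"""Synthetic phantoms and cohorts with known ground truth.

Every input the quantification pipeline consumes can be generated here:

* dual-wavelength reflectance stacks built from the forward Beer–Lambert
  model, with artery/vein/tissue compartments and a vasoconstrictive
  transient (gamma-variate dip, exponential recovery);
* OCT phantoms: tubes with known diameter and flow velocity encoded as
  Doppler phase (plug or parabolic profiles), plus capillary networks of
  known skeleton density grown as smoothed random walks;
* WT/AD cohorts whose per-animal CVR traces, vessel measurements and
  density readings are drawn from configurable group distributions, with
  the exact ground-truth table returned alongside.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .doppler import DopplerParams, _wrap
from .spectral import ExtinctionSet, HemoSeries, RoiSet, SpectralStack

__all__ = [
    "TransientSpec",
    "CompartmentSpec",
    "DwiPhantomSpec",
    "DwiPhantom",
    "default_dwi_phantom_spec",
    "gen_dwi_stack",
    "TubeSpec",
    "CapillarySpec",
    "OctPhantomSpec",
    "OctPhantom",
    "gen_oct_phantom",
    "MetricSpec",
    "CohortSpec",
    "CohortData",
    "default_cohort_spec",
    "gen_cohort",
    "build_cvr_trace",
]

GROUPS = ("WT", "AD")
ROI_CLASSES = ("vein", "artery", "tissue")
ORDERS = ("1st", "2nd")


# --------------------------------------------------------------------------
# DWI reflectance phantom
# --------------------------------------------------------------------------

class TransientSpec(BaseModel):
    """Vasoconstrictive transient: gamma-variate dip, exponential recovery.

    amplitude_pct      : dip depth as % of baseline HbT; <= 0 (constriction).
    time_to_nadir_min  : minutes from injection to the deepest point.
    recovery_tau_min   : exponential recovery time constant, minutes.
    rise_alpha         : sharpness of the gamma-variate rise.
    """

    amplitude_pct: float = Field(le=0.0)
    time_to_nadir_min: float = Field(gt=0.0)
    recovery_tau_min: float = Field(gt=0.0)
    rise_alpha: float = Field(default=3.0, gt=0.0)

    def evaluate(self, t_min: np.ndarray) -> np.ndarray:
        """Dip shape in % units at minutes-after-injection ``t_min``."""
        t = np.asarray(t_min, dtype=float)
        tp, a = self.time_to_nadir_min, self.rise_alpha
        g = np.zeros_like(t)
        rise = (t > 0) & (t <= tp)
        g[rise] = (t[rise] / tp) ** a * np.exp(a * (1.0 - t[rise] / tp))
        fall = t > tp
        g[fall] = np.exp(-(t[fall] - tp) / self.recovery_tau_min)
        return self.amplitude_pct * g


@dataclass
class CompartmentSpec:
    """One tissue compartment: its ROI masks, baseline composition and
    transient.  oxy_fraction splits ΔHbT into ΔHbO2/ΔHbR (arteries are
    HbO2-rich, veins HbR-rich)."""

    masks: list[np.ndarray]
    transient: TransientSpec
    oxy_fraction: float = 0.6
    baseline_hbo2: float = 0.0  # static concentrations, inversion units
    baseline_hbr: float = 0.0


@dataclass
class DwiPhantomSpec:
    """Forward-model phantom for the dual-wavelength imaging channel."""

    shape: tuple[int, int]
    compartments: dict[str, CompartmentSpec]
    frame_interval_s: float = 1.0
    baseline_min: float = 10.0
    post_min: float = 30.0
    noise_sd: float = 0.0
    baseline_hbt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0 or self.baseline_min <= 0 or self.post_min <= 0:
            raise ValueError("frame interval and durations must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        occupancy = np.zeros(self.shape, dtype=int)
        for name, comp in self.compartments.items():
            for m in comp.masks:
                m = np.asarray(m, dtype=bool)
                if m.shape != tuple(self.shape):
                    raise ValueError(f"mask shape mismatch in compartment {name!r}")
                occupancy += m
        if (occupancy > 1).any():
            raise ValueError("compartment ROI masks must be pairwise disjoint")

    def timestamps_s(self) -> np.ndarray:
        total = (self.baseline_min + self.post_min) * 60.0
        return np.arange(0.0, total + 1e-9, self.frame_interval_s)

    @property
    def t_inject_s(self) -> float:
        return self.baseline_min * 60.0


@dataclass
class DwiPhantom:
    stack: SpectralStack
    rois: RoiSet
    truth: HemoSeries
    truth_dhbo2: np.ndarray  # (T, Y, X), inversion units
    truth_dhbr: np.ndarray
    t_inject_s: float


def default_dwi_phantom_spec(shape: tuple[int, int] = (48, 48),
                             frame_interval_s: float = 2.0,
                             noise_sd: float = 0.0, seed: int = 0,
                             amplitudes: dict[str, float] | None = None,
                             baseline_hbt: float = 1e-4,
                             ) -> DwiPhantomSpec:
    """A compact phantom: 3 disjoint rectangular ROIs per compartment laid
    out on a 3×3 grid, with dip depths near the wild-type group values.

    Concentrations are molar (baseline HbT 100 μM) so the phantom pairs
    with the built-in hemoglobin extinction table at 1-cm pathlength.
    """
    amplitudes = amplitudes or {"vein": -16.97, "artery": -16.37, "tissue": -9.56}
    ny, nx = shape
    gy, gx = ny // 3, nx // 3
    comps: dict[str, CompartmentSpec] = {}
    layout = {"vein": 0, "artery": 1, "tissue": 2}
    oxy = {"vein": 0.35, "artery": 0.9, "tissue": 0.6}
    base = {"vein": (0.15, 0.55), "artery": (0.6, 0.08), "tissue": (0.18, 0.12)}
    my, mx = max(1, gy // 8), max(1, gx // 8)
    for cls, row in layout.items():
        masks = []
        for col in range(3):
            m = np.zeros(shape, dtype=bool)
            m[row * gy + my:(row + 1) * gy - my,
              col * gx + mx:(col + 1) * gx - mx] = True
            masks.append(m)
        comps[cls] = CompartmentSpec(
            masks=masks,
            transient=TransientSpec(amplitude_pct=amplitudes[cls],
                                    time_to_nadir_min=3.0,
                                    recovery_tau_min=4.0),
            oxy_fraction=oxy[cls],
            baseline_hbo2=base[cls][0] * baseline_hbt,
            baseline_hbr=base[cls][1] * baseline_hbt)
    return DwiPhantomSpec(shape=shape, compartments=comps,
                          frame_interval_s=frame_interval_s,
                          noise_sd=noise_sd, baseline_hbt=baseline_hbt,
                          seed=seed)


def gen_dwi_stack(spec: DwiPhantomSpec, extinction: ExtinctionSet) -> DwiPhantom:
    """Forward Beer–Lambert rendering of the phantom.

    R_λ(t) = R_λ(0) · exp(−[ε_HbO2^λ·ΔHbO2(t) + ε_HbR^λ·ΔHbR(t)]·L_λ)
    per pixel, with multiplicative Gaussian noise; the exact ΔHbO2/ΔHbR
    fields used are returned as ground truth.
    """
    eps = extinction.matrix
    if np.linalg.det(eps) == 0:
        raise ValueError("extinction matrix is singular")
    t = spec.timestamps_s()
    t_min = (t - spec.t_inject_s) / 60.0
    ny, nx = spec.shape
    nt = t.size
    dhbo2 = np.zeros((nt, ny, nx))
    dhbr = np.zeros((nt, ny, nx))
    r0 = np.ones((2, ny, nx))
    labels = np.zeros((ny, nx), dtype=int)
    classes: dict[int, str] = {}
    truth_o: dict[int, np.ndarray] = {}
    truth_r: dict[int, np.ndarray] = {}
    paths = np.array([extinction.path_l1, extinction.path_l2])
    lab = 0
    for cls, comp in spec.compartments.items():
        dip = comp.transient.evaluate(t_min) / 100.0 * spec.baseline_hbt
        c_o = comp.oxy_fraction * dip
        c_r = (1.0 - comp.oxy_fraction) * dip
        # static baseline composition shapes R_λ(0) (vein vs artery contrast)
        att0 = eps @ np.array([comp.baseline_hbo2, comp.baseline_hbr]) * paths
        for m in comp.masks:
            m = np.asarray(m, dtype=bool)
            dhbo2[:, m] += c_o[:, None]
            dhbr[:, m] += c_r[:, None]
            r0[0][m] = np.exp(-att0[0])
            r0[1][m] = np.exp(-att0[1])
            lab += 1
            labels[m] = lab
            classes[lab] = cls
            truth_o[lab] = c_o.copy()
            truth_r[lab] = c_r.copy()
    att = np.empty((2, nt, ny, nx))
    att[0] = (eps[0, 0] * dhbo2 + eps[0, 1] * dhbr) * paths[0]
    att[1] = (eps[1, 0] * dhbo2 + eps[1, 1] * dhbr) * paths[1]
    channels = r0[:, None] * np.exp(-att)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        channels = channels * (1.0 + spec.noise_sd * rng.standard_normal(channels.shape))
        channels = np.clip(channels, 1e-9, None)
    stack = SpectralStack(channels=channels, timestamps_s=t,
                          baseline_window_s=(0.0, spec.t_inject_s))
    rois = RoiSet(labels=labels, classes=classes)
    truth = HemoSeries(time_s=t, dhbo2=truth_o, dhbr=truth_r,
                       classes=classes, baseline_hbt=spec.baseline_hbt)
    return DwiPhantom(stack=stack, rois=rois, truth=truth,
                      truth_dhbo2=dhbo2, truth_dhbr=dhbr,
                      t_inject_s=spec.t_inject_s)


# --------------------------------------------------------------------------
# OCT phantom (Doppler tubes + capillary network)
# --------------------------------------------------------------------------

class TubeSpec(BaseModel):
    """One flow tube: straight or polyline centerline in voxel coordinates
    (z, y, x), with the velocity given at the centerline (so a parabolic
    profile has cross-section mean v/2)."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    points: np.ndarray  # (k, 3) polyline vertices, voxel coords
    diameter_um: float = Field(gt=0.0)
    velocity_mm_s: float = Field(ge=0.0)
    profile: Literal["plug", "parabolic"] = "plug"
    order: Literal["1st", "2nd"] = "1st"

    @model_validator(mode="after")
    def _check_points(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3 or self.points.shape[0] < 2:
            raise ValueError("tube centerline needs >= 2 (z, y, x) points")
        return self


class CapillarySpec(BaseModel):
    """Capillary network grown as smoothed random walks, 1 voxel wide."""

    target_fill: float = Field(gt=0.0, lt=0.2)  # skeleton px / image px
    tortuosity: float = Field(default=0.25, ge=0.0)  # sd of heading change (rad/step)
    max_walks: int = 4000


class OctPhantomSpec(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    shape: tuple[int, int, int]  # (z, y, x)
    pitch_um: float = 3.0
    tubes: list[TubeSpec] = Field(default_factory=list)
    capillary: CapillarySpec | None = None
    phase_noise_sd: float = Field(default=0.0, ge=0.0)
    speckle_sd: float = Field(default=0.0, ge=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if not self.tubes and self.capillary is None:
            raise ValueError("empty tube list and no capillary network: "
                             "nothing to generate")
        return self


@dataclass
class OctPhantom:
    angiogram: np.ndarray  # (z, y, x) intensity
    dphi: np.ndarray  # (z, y, x) wrapped phase difference, rad
    tube_labels: np.ndarray  # int, 0 background, 1..n tubes
    capillary_skeleton: np.ndarray  # bool (y, x) ground-truth skeleton (2D plane)
    velocity_truth: np.ndarray  # (z, y, x) encoded axial velocity, mm/s
    capillary_fill: float
    wrap_occurred: bool


def _tube_distance(shape: tuple[int, int, int], points: np.ndarray) -> np.ndarray:
    """Distance (voxels) from every voxel to a polyline centerline."""
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in shape),
                             indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1)
    d = np.full(shape, np.inf)
    for a, b in zip(points[:-1], points[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            dist = np.linalg.norm(p - a, axis=-1)
        else:
            tpar = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            dist = np.linalg.norm(p - (a + tpar[..., None] * ab), axis=-1)
        np.minimum(d, dist, out=d)
    return d


def _grow_capillaries(shape_yx: tuple[int, int], cap: CapillarySpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Rasterized smoothed random walks until the skeleton fill fraction is
    within 10% of target.

    The raster is re-thinned as it grows so the returned network is a
    thinning-stable skeleton (a raw walk trace carries staircase pixels
    that any thinning pass would remove, which would bias the density
    ground truth high).
    """
    from skimage.morphology import skeletonize

    ny, nx = shape_yx
    raster = np.zeros(shape_yx, dtype=bool)
    target_px = cap.target_fill * ny * nx
    # short walks keep the per-walk increment well under the 10% band
    walk_len = max(24, min(int(0.04 * target_px), 2 * max(ny, nx)))
    skel = raster
    for i in range(cap.max_walks):
        skel = skeletonize(raster)
        if skel.sum() >= target_px:
            break
        y, x = rng.uniform(0, ny), rng.uniform(0, nx)
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(walk_len):
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < ny and 0 <= ix < nx:
                raster[iy, ix] = True
            theta += cap.tortuosity * rng.standard_normal()
            y += np.sin(theta)
            x += np.cos(theta)
            if not (-2 < y < ny + 2 and -2 < x < nx + 2):
                break
    else:
        skel = skeletonize(raster)
    return skel


def gen_oct_phantom(spec: OctPhantomSpec,
                    params: DopplerParams | None = None) -> OctPhantom:
    """Render tubes and capillaries; encode velocity as Doppler phase.

    Inside a tube, Δφ = 4π·n·T·v(voxel)·cosθ / λ0, wrapped to (−π, π].
    A maximum encoded |Δφ| beyond π triggers a Nyquist warning and sets
    the wrap flag.  Phase noise is additive wrapped Gaussian, applied
    before the final wrap so downstream wrap handling gets exercised.
    """
    params = params or DopplerParams()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    velocity = np.zeros(shape)
    labels = np.zeros(shape, dtype=int)
    angio = np.zeros(shape)
    for i, tube in enumerate(spec.tubes, start=1):
        pts = tube.points
        if (pts < -0.5).any() or (pts > np.array(shape) - 0.5).any():
            raise ValueError(f"tube {i} centerline leaves the volume")
        radius_vox = tube.diameter_um / (2.0 * spec.pitch_um)
        d = _tube_distance(shape, pts)
        inside = d <= radius_vox
        if tube.profile == "plug":
            v = np.where(inside, tube.velocity_mm_s, 0.0)
        else:  # parabolic: v_max at the centerline, 0 at the wall
            v = np.where(inside,
                         tube.velocity_mm_s * (1.0 - (d / radius_vox) ** 2),
                         0.0)
        velocity = np.where(inside, v, velocity)
        labels[inside] = i
        angio[inside] = 1.0
    cap_skel = np.zeros(shape[1:], dtype=bool)
    if spec.capillary is not None:
        cap_skel = _grow_capillaries(shape[1:], spec.capillary, rng)
        mid = shape[0] // 2
        angio[mid][cap_skel] = np.maximum(angio[mid][cap_skel], 1.0)
    phase_scale = (4.0 * np.pi * params.n * params.t_s
                   * np.cos(params.theta_rad) / params.lambda0_mm)
    dphi_enc = phase_scale * velocity
    wrap_occurred = bool(np.max(np.abs(dphi_enc), initial=0.0) > np.pi + 1e-12)
    if wrap_occurred:
        warnings.warn("encoded |dphi| exceeds pi: velocities beyond the "
                      "Nyquist limit will wrap", stacklevel=2)
    if spec.phase_noise_sd > 0:
        dphi_enc = dphi_enc + spec.phase_noise_sd * rng.standard_normal(shape)
    dphi = _wrap(dphi_enc)
    if spec.speckle_sd > 0:
        angio = np.clip(angio * (1.0 + spec.speckle_sd * rng.standard_normal(shape))
                        + 0.05 * spec.speckle_sd * rng.standard_normal(shape),
                        0.0, None)
    fill = float(cap_skel.mean()) if spec.capillary is not None else 0.0
    if spec.capillary is not None and fill > 0:
        if abs(fill - spec.capillary.target_fill) > 0.1 * spec.capillary.target_fill:
            warnings.warn(f"capillary fill {fill:.4f} off target "
                          f"{spec.capillary.target_fill:.4f} by more than 10%",
                          stacklevel=2)
    return OctPhantom(angiogram=angio, dphi=dphi, tube_labels=labels,
                      capillary_skeleton=cap_skel, velocity_truth=velocity,
                      capillary_fill=fill, wrap_occurred=wrap_occurred)


# --------------------------------------------------------------------------
# Synthetic cohorts
# --------------------------------------------------------------------------

class MetricSpec(BaseModel):
    mean: float
    sd: float = Field(ge=0.0)


def _ms(mean: float, sd: float) -> MetricSpec:
    return MetricSpec(mean=mean, sd=sd)


def _default_cvr() -> dict:
    return {
        "WT": {
            "vein": {"peak": _ms(-16.97, 1.22), "ir": _ms(-142.49, 22.29),
                     "rt": _ms(16.40, 1.60)},
            "artery": {"peak": _ms(-16.37, 1.04), "ir": _ms(-147.97, 26.09),
                       "rt": _ms(14.96, 1.38)},
            "tissue": {"peak": _ms(-9.56, 1.00), "ir": _ms(-96.37, 20.59),
                       "rt": _ms(15.93, 1.51)},
        },
        "AD": {
            "vein": {"peak": _ms(-16.09, 1.61), "ir": _ms(-91.92, 13.40),
                     "rt": _ms(11.41, 1.44)},
            "artery": {"peak": _ms(-13.21, 1.13), "ir": _ms(-57.17, 7.41),
                       "rt": _ms(7.61, 1.03)},
            "tissue": {"peak": _ms(-7.45, 0.47), "ir": _ms(-31.48, 4.21),
                       "rt": _ms(7.46, 0.91)},
        },
    }


def _default_vessels() -> dict:
    return {
        "WT": {"1st": {"cbfv": _ms(0.787, 0.014), "diameter": _ms(79.28, 2.54)},
               "2nd": {"cbfv": _ms(0.746, 0.025), "diameter": _ms(72.20, 2.94)}},
        "AD": {"1st": {"cbfv": _ms(0.624, 0.075), "diameter": _ms(78.61, 3.09)},
               "2nd": {"cbfv": _ms(0.537, 0.043), "diameter": _ms(63.77, 3.12)}},
    }


def _default_density() -> dict:
    return {
        "WT": {"ff_max": _ms(0.1045, 0.0034), "ff_mean": _ms(0.0801, 0.0034)},
        "AD": {"ff_max": _ms(0.0839, 0.0049), "ff_mean": _ms(0.0600, 0.0054)},
    }


class CohortSpec(BaseModel):
    """Group distributions for synthetic WT/AD cohorts.

    Defaults are the published group values of the study this package
    reproduces: CVR cohort n = 8 WT / 12 AD (half per sex), vessel cohort
    n = 6 per group, density cohort n = 9 WT / 6 AD.  Per-animal values
    are drawn from N(mean, sd) with the tabulated spreads.
    """

    n_cvr: dict[str, int] = Field(default_factory=lambda: {"WT": 8, "AD": 12})
    n_vessel: dict[str, int] = Field(default_factory=lambda: {"WT": 6, "AD": 6})
    n_density: dict[str, int] = Field(default_factory=lambda: {"WT": 9, "AD": 6})
    cvr: dict[str, dict[str, dict[str, MetricSpec]]] = Field(default_factory=_default_cvr)
    vessels: dict[str, dict[str, dict[str, MetricSpec]]] = Field(default_factory=_default_vessels)
    density: dict[str, dict[str, MetricSpec]] = Field(default_factory=_default_density)
    n_arteries_per_order: int = Field(default=8, ge=1)
    n_density_rois: int = Field(default=3, ge=1)
    n_cvr_rois: int = Field(default=3, ge=1)
    trace_noise_sd_pct: float = Field(default=0.5, ge=0.0)
    frame_interval_s: float = Field(default=2.0, gt=0.0)
    baseline_min: float = Field(default=10.0, gt=0.0)
    post_min: float = Field(default=30.0, gt=0.0)
    recovery_k: float = Field(default=1.0, gt=0.0)
    parts: tuple[str, ...] = ("cvr", "vessels", "density")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for d in (self.n_cvr, self.n_vessel, self.n_density):
            for g, n in d.items():
                if n < 1:
                    raise ValueError(f"cohort size for {g} must be >= 1")
        return self


@dataclass
class CohortData:
    """Synthetic cohort: raw per-animal signals plus the ground truth."""

    spec: CohortSpec
    time_s: np.ndarray
    t_inject_s: float
    baseline_window_s: tuple[float, float]
    # animal_id -> roi_class -> (n_rois, T) noisy ΔHbT% traces
    traces: dict[str, dict[str, np.ndarray]] = dfield(default_factory=dict)
    animals: "pd.DataFrame" = None  # type: ignore[assignment]
    vessels: "pd.DataFrame" = None  # type: ignore[assignment]
    density: "pd.DataFrame" = None  # type: ignore[assignment]
    truth: "pd.DataFrame" = None  # type: ignore[assignment]


def build_cvr_trace(time_s: np.ndarray, t_inject_s: float, peak_pct: float,
                    rt_min: float, ir: float, band_pct: float,
                    nadir_min: float = 2.5, nadir_plateau_min: float = 1.0,
                    settle_min: float = 1.0, ramp_min: float = 1.0) -> np.ndarray:
    """Deterministic piecewise-linear transient realizing target metrics.

    The trace descends to the peak, holds a nadir plateau (so a smoothed
    minimum still reads the true peak), settles to a sustained-depression
    level solved so the area over [0, RT] equals the target IR, then ramps
    linearly through the baseline band exactly at RT, overshoots slightly
    and returns to baseline.  ``band_pct`` is the expected detector band
    depth (k × baseline noise sd of the analyzed trace).
    """
    A = -float(peak_pct)
    if A < 0:
        raise ValueError("peak must be <= 0 (vasoconstriction)")
    T = float(rt_min)
    ir_abs = -float(ir)
    c = max(float(band_pct), 0.0)
    t_n = min(nadir_min, 0.35 * T) if T > 0 else nadir_min
    p = min(nadir_plateau_min, 0.8 * t_n)
    t_f = settle_min
    d = ramp_min
    lo = t_n + p / 2.0 + t_f
    if T < lo + d:  # compress the early phases for very fast recoveries
        scale = T / (lo + d) * 0.95
        t_n, p, t_f, d = t_n * scale, p * scale, t_f * scale, d * scale
        lo = t_n + p / 2.0 + t_f
    t1 = t_n - p / 2.0
    k0 = A * (t1 / 2.0 + p + t_f / 2.0)
    k1 = t_f / 2.0 + (T - d - lo) + d / 2.0
    b = (ir_abs - k0 - c * d / 2.0) / k1 if k1 > 0 else A
    b = float(np.clip(b, max(2.0 * c, 0.03 * A, 1e-6), A))
    m = (b - c) / d  # ramp slope, %/min
    overshoot = min(1.0, 0.3 * b)
    t_over = T + (c + overshoot) / m
    t_end_over = t_over + 2.0
    t_back = t_end_over + 2.0
    tm = (np.asarray(time_s, dtype=float) - t_inject_s) / 60.0
    y = np.zeros_like(tm)
    seg = (tm > 0) & (tm <= t1)
    y[seg] = -A * tm[seg] / t1
    seg = (tm > t1) & (tm <= t1 + p)
    y[seg] = -A
    seg = (tm > t1 + p) & (tm <= lo)
    y[seg] = -A + (A - b) * (tm[seg] - t1 - p) / t_f
    seg = (tm > lo) & (tm <= T - d)
    y[seg] = -b
    seg = (tm > T - d) & (tm <= t_over)
    y[seg] = -b + m * (tm[seg] - (T - d))
    seg = (tm > t_over) & (tm <= t_end_over)
    y[seg] = overshoot
    seg = (tm > t_end_over) & (tm <= t_back)
    y[seg] = overshoot * (1.0 - (tm[seg] - t_end_over) / 2.0)
    return y


def default_cohort_spec(**overrides) -> CohortSpec:
    return CohortSpec(**overrides)


def gen_cohort(spec: CohortSpec) -> CohortData:
    """Draw a full synthetic cohort.

    Per-animal true metrics are drawn from the group normal distributions;
    CVR traces realizing those metrics (plus measurement noise) are built
    for each animal, vessel measurements are tabulated per artery, and
    density ROI readings per animal.  The exact drawn truths are returned
    in a long-format table (animal_id, group, sex, roi_class, metric,
    value).
    """
    import pandas as pd

    root = np.random.SeedSequence(spec.seed)
    ss_cvr, ss_vessel, ss_density = root.spawn(3)
    t = np.arange(0.0, (spec.baseline_min + spec.post_min) * 60.0 + 1e-9,
                  spec.frame_interval_s)
    t_inject = spec.baseline_min * 60.0
    data = CohortData(spec=spec, time_s=t, t_inject_s=t_inject,
                      baseline_window_s=(0.0, t_inject))
    truth_rows, animal_rows = [], []

    if "cvr" in spec.parts:
        rng = np.random.default_rng(ss_cvr)
        band = spec.recovery_k * spec.trace_noise_sd_pct / np.sqrt(spec.n_cvr_rois)
        min_rt = 2.0
        for group in GROUPS:
            n = spec.n_cvr[group]
            for i in range(n):
                aid = f"{group}-cvr-{i:02d}"
                sex = "M" if i < n // 2 else "F"
                animal_rows.append({"animal_id": aid, "group": group,
                                    "sex": sex, "cohort": "cvr"})
                data.traces[aid] = {}
                for cls in spec.cvr[group]:
                    ms = spec.cvr[group][cls]
                    peak = min(rng.normal(ms["peak"].mean, ms["peak"].sd), -0.5)
                    rt = max(rng.normal(ms["rt"].mean, ms["rt"].sd), min_rt)
                    ir = min(rng.normal(ms["ir"].mean, ms["ir"].sd), -1.0)
                    base = build_cvr_trace(t, t_inject, peak, rt, ir, band)
                    noise = spec.trace_noise_sd_pct * rng.standard_normal(
                        (spec.n_cvr_rois, t.size))
                    data.traces[aid][cls] = base[None, :] + noise
                    for metric, val in (("peak", peak), ("ir", ir), ("rt", rt)):
                        truth_rows.append({"animal_id": aid, "group": group,
                                           "sex": sex, "roi_class": cls,
                                           "metric": metric, "value": val})

    vessel_rows = []
    if "vessels" in spec.parts:
        rng = np.random.default_rng(ss_vessel)
        for group in GROUPS:
            n = spec.n_vessel[group]
            for i in range(n):
                aid = f"{group}-oct-{i:02d}"
                sex = "M" if i < n // 2 else "F"
                animal_rows.append({"animal_id": aid, "group": group,
                                    "sex": sex, "cohort": "vessel"})
                for order in ORDERS:
                    ms = spec.vessels[group][order]
                    v_true = max(rng.normal(ms["cbfv"].mean, ms["cbfv"].sd), 0.0)
                    d_true = max(rng.normal(ms["diameter"].mean,
                                            ms["diameter"].sd), 5.0)
                    k = spec.n_arteries_per_order
                    # per-artery spread, centred so the animal mean is exact
                    dv = 0.05 * v_true * rng.standard_normal(k)
                    dd = 2.0 * rng.standard_normal(k)
                    dv -= dv.mean()
                    dd -= dd.mean()
                    for j in range(k):
                        vessel_rows.append({"animal_id": aid, "group": group,
                                            "sex": sex, "order": order,
                                            "vessel_id": f"{aid}-{order}-{j}",
                                            "cbfv_mm_s": v_true + dv[j],
                                            "phi_um": d_true + dd[j]})
                    for metric, val in (("cbfv", v_true), ("diameter", d_true)):
                        truth_rows.append({"animal_id": aid, "group": group,
                                           "sex": sex, "roi_class": order,
                                           "metric": metric, "value": val})

    density_rows = []
    if "density" in spec.parts:
        rng = np.random.default_rng(ss_density)
        for group in GROUPS:
            n = spec.n_density[group]
            for i in range(n):
                aid = f"{group}-dens-{i:02d}"
                sex = "M" if i < n // 2 else "F"
                animal_rows.append({"animal_id": aid, "group": group,
                                    "sex": sex, "cohort": "density"})
                for metric in ("ff_max", "ff_mean"):
                    ms = spec.density[group][metric]
                    val = max(rng.normal(ms.mean, ms.sd), 0.0)
                    k = spec.n_density_rois
                    dr = 0.05 * val * rng.standard_normal(k)
                    dr -= dr.mean()
                    for j in range(k):
                        density_rows.append({"animal_id": aid, "group": group,
                                             "sex": sex, "roi_id": j,
                                             "metric": metric,
                                             "value": val + dr[j]})
                    truth_rows.append({"animal_id": aid, "group": group,
                                       "sex": sex, "roi_class": "capillary",
                                       "metric": metric, "value": val})

    data.animals = pd.DataFrame(animal_rows)
    data.vessels = pd.DataFrame(vessel_rows)
    data.density = pd.DataFrame(density_rows)
    data.truth = pd.DataFrame(truth_rows)
    return data
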