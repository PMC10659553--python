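"""Phase-resolved Doppler OCT velocimetry.

Axial blood-flow velocity is encoded in the phase shift between consecutive
A-scans (phase-subtraction method, PSM).  For a scatterer moving at velocity
``v`` along the beam, two A-scans separated by ``T`` seconds accumulate a
phase difference

    dphi = 4 * pi * n * T * v * cos(theta) / lambda0

so the inverse map is ``v = lambda0 * dphi / (4 * pi * n * T * cos(theta))``.
With the default system constants (lambda0 = 0.00131 mm, n = 1.38,
T = 0.000167 s, theta = 0) a phase shift of pi corresponds to ~1.421 mm/s,
the unambiguous velocity limit before phase wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DopplerParams",
    "SystemOptics",
    "VelocityMap",
    "phase_difference",
    "phase_to_velocity",
    "vessel_cbfv",
    "coherence_length",
    "axial_resolution",
    "transverse_resolution",
]


@dataclass(frozen=True)
class DopplerParams:
    """Constants of the velocity equation.

    lambda0_mm : central wavelength of the source, in mm.
    n          : refractive index of the medium.
    t_s        : time interval between two adjacent A-scans, in seconds
                 (reciprocal of the A-line rate; 1/6000 ≈ 0.000167 s).
    theta_rad  : Doppler angle between flow and beam; assumed 0 by default.
    """

    lambda0_mm: float = 0.00131
    n: float = 1.38
    t_s: float = 0.000167
    theta_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda0_mm <= 0 or self.n <= 0 or self.t_s <= 0:
            raise ValueError("lambda0, n and T must all be positive")

    @property
    def v_max_mm_s(self) -> float:
        """Largest unambiguous |velocity| (|dphi| = pi)."""
        c = abs(np.cos(self.theta_rad))
        if c == 0:
            raise ValueError("cos(theta) = 0: axial velocity unresolvable")
        return self.lambda0_mm / (4.0 * self.n * self.t_s * c)


@dataclass(frozen=True)
class SystemOptics:
    """Source/objective parameters of the OCT engine."""

    center_nm: float = 1310.0
    bandwidth_fwhm_nm: float = 220.0
    numerical_aperture: float = 0.25
    tissue_index: float = 1.38

    def __post_init__(self) -> None:
        if min(self.center_nm, self.bandwidth_fwhm_nm,
               self.numerical_aperture, self.tissue_index) <= 0:
            raise ValueError("all optics parameters must be positive")


def coherence_length(optics: SystemOptics) -> float:
    """Source coherence length L_c = 2 ln2 λ² / (π Δλ_FWHM), in μm (in air)."""
    lc_nm = (2.0 * np.log(2.0) * optics.center_nm ** 2
             / (np.pi * optics.bandwidth_fwhm_nm))
    return lc_nm / 1000.0


def axial_resolution(optics: SystemOptics) -> float:
    """Axial resolution in tissue (μm): coherence length over tissue index."""
    return coherence_length(optics) / optics.tissue_index


def transverse_resolution(optics: SystemOptics) -> float:
    """Diffraction-limited transverse resolution 0.61 λ / NA, in μm."""
    return 0.61 * optics.center_nm / optics.numerical_aperture / 1000.0


@dataclass
class VelocityMap:
    """Voxelwise axial velocity (mm/s) with wrap bookkeeping."""

    v_mm_s: np.ndarray
    wrapped: np.ndarray  # bool, heuristic flag: |dphi| at the wrap boundary
    params: DopplerParams = field(default_factory=DopplerParams)


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap phases to the principal interval (-pi, pi]."""
    out = np.angle(np.exp(1j * np.asarray(phi, dtype=float)))
    # np.angle returns [-pi, pi); map -pi to +pi for the half-open convention
    out = np.where(out == -np.pi, np.pi, out)
    return out


def phase_difference(ascans: np.ndarray, axis: int = 0,
                     pair_window: int = 4) -> np.ndarray:
    """Phase difference between adjacent complex A-scans (PSM).

    Parameters
    ----------
    ascans : complex ndarray
        A-scan stack; consecutive A-scans lie along ``axis``.
    axis : int
        Axis indexing consecutive A-scans.
    pair_window : int
        Number of adjacent conjugate products averaged (complex average,
        Kasai-style) before taking the angle; suppresses phase noise.

    Returns
    -------
    ndarray of phase differences wrapped to (-pi, pi]; one shorter along
    ``axis`` than the input.
    """
    a = np.asarray(ascans)
    if a.shape[axis] < 2:
        raise ValueError("need at least 2 adjacent A-scans along the pair axis")
    a = np.moveaxis(a, axis, 0)
    prod = a[1:] * np.conj(a[:-1])
    w = max(1, int(pair_window))
    if w > 1 and prod.shape[0] > 1:
        from scipy.ndimage import uniform_filter1d

        w = min(w, prod.shape[0])
        # centred complex (Kasai) average of conjugate products along the axis
        prod = (uniform_filter1d(prod.real, w, axis=0, mode="nearest")
                + 1j * uniform_filter1d(prod.imag, w, axis=0, mode="nearest"))
    dphi = np.angle(prod)
    dphi = np.where(dphi == -np.pi, np.pi, dphi)
    return np.moveaxis(dphi, 0, axis)


def phase_to_velocity(dphi: np.ndarray,
                      params: DopplerParams | None = None,
                      wrap_guard: float = 0.999) -> VelocityMap:
    """Convert a phase-difference volume to axial velocity (mm/s).

    v = lambda0 * dphi / (4 pi n T cos(theta)); linear in dphi, exactly
    zero at zero phase.  Voxels whose |dphi| sits at the wrap boundary
    (>= wrap_guard * pi) are flagged; phases are never unwrapped here.
    """
    params = params or DopplerParams()
    c = np.cos(params.theta_rad)
    if abs(c) < 1e-9:
        raise ValueError("cos(theta) = 0: cannot convert phase to velocity")
    dphi = np.asarray(dphi, dtype=float)
    v = params.lambda0_mm * dphi / (4.0 * np.pi * params.n * params.t_s * c)
    wrapped = np.abs(dphi) >= wrap_guard * np.pi
    return VelocityMap(v_mm_s=v, wrapped=wrapped, params=params)


def vessel_cbfv(vmap: VelocityMap, rois: list[np.ndarray],
                stat: str = "mean",
                occlusion_tol: float = 1e-3) -> tuple[float, bool]:
    """Mean blood-flow velocity along one vessel.

    ``rois`` is a chain of boolean masks placed sequentially along the
    vessel; each ROI contributes one statistic (mean by default, or max)
    and the per-ROI values are averaged.  A vessel whose averaged speed is
    below ``occlusion_tol`` mm/s is reported as 0 with an occlusion-like
    flag (visible lumen, no detected flow).
    """
    if not rois:
        raise ValueError("at least one ROI is required per vessel")
    vals = []
    for m in rois:
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError("empty vessel ROI")
        sel = vmap.v_mm_s[m]
        vals.append(float(np.max(np.abs(sel))) if stat == "max" else float(sel.mean()))
    v = float(np.mean(vals))
    occluded = abs(v) < occlusion_tol
    return (0.0 if occluded else v), occluded
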