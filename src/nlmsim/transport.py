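"""Closed-form nonlinear magnetophoresis transport law.

A bead on a micromagnet array driven by a rotating field moves with the
travelling flux-density maxima at one lattice pitch per field rotation
("phase-locked", v = f·d) up to a critical frequency f_c.  Above f_c the
hydrodynamic drag exceeds the peak magnetic restoring force and the bead
periodically slips back one pitch; the time-averaged velocity falls as

    v(f) = [f - sqrt(f² - f_c²)] · d        (f > f_c)

and tends to zero at high drive frequency.  The critical frequency scales as

    f_c = κ · g(β) / (2π),     g(β) = (2πβ)² · exp(-2πβ),   β = r/d,

where κ = χ μ0 σ0(H_ext) / (18 η) aggregates the bead susceptibility χ, the
field-distribution parameter σ0 (experimentally determined for a given array
and drive) and the medium viscosity η.  σ0 is never used on its own here: κ
is identifiable from a single measured f_c via ``calibrate_coupling``.

All user-facing frequencies are cyclic (hertz); κ carries units of rad/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TransportParams",
    "FrequencyCharacteristics",
    "shape_factor",
    "critical_frequency",
    "closed_form_velocity",
    "immobilization_frequency",
    "omega_ratio",
    "calibrate_coupling",
    "estimate_critical_frequency",
    "fit_critical_frequency",
]


@dataclass(frozen=True)
class TransportParams:
    """Physical parameters of the transport law.

    ``beta`` is derived from bead radius and pitch (β = r/d) and must lie in
    (0, 0.5): a bead wider than the pitch cannot resolve the lattice.
    ``coupling_rad_s`` (κ) is the calibratable aggregate χ·μ0·σ0/(18η); leave
    it ``None`` until calibrated against a measured critical frequency.
    """

    bead_radius_m: float = 1.4e-6
    pitch_m: float = 8.0e-6
    susceptibility: float = 0.7
    viscosity_pa_s: float = 1.0e-3
    coupling_rad_s: float | None = None

    def __post_init__(self):
        if self.bead_radius_m <= 0 or self.pitch_m <= 0:
            raise ValueError("radius and pitch must be positive")
        beta = self.bead_radius_m / self.pitch_m
        if not 0.0 < beta < 0.5:
            raise ValueError(f"beta = r/d = {beta:.3g} outside (0, 0.5)")
        if self.viscosity_pa_s <= 0:
            raise ValueError("viscosity must be positive")
        if self.coupling_rad_s is not None and self.coupling_rad_s < 0:
            raise ValueError("coupling must be >= 0")

    @property
    def beta(self) -> float:
        return self.bead_radius_m / self.pitch_m

    def with_coupling(self, coupling_rad_s: float) -> "TransportParams":
        return replace(self, coupling_rad_s=coupling_rad_s)


@dataclass(frozen=True)
class FrequencyCharacteristics:
    """Critical and immobilization frequencies and the sharpness ratio Ω."""

    f_c_hz: float
    f_i_hz: float

    def __post_init__(self):
        if not 0.0 < self.f_c_hz <= self.f_i_hz:
            raise ValueError(
                f"inconsistent characteristics: need 0 < f_c <= f_i, got "
                f"f_c={self.f_c_hz}, f_i={self.f_i_hz}"
            )

    @property
    def omega(self) -> float:
        """Sharpness of the mobile-to-immobile transition, Ω = f_c / f_i."""
        return self.f_c_hz / self.f_i_hz


def shape_factor(beta: float | np.ndarray) -> float | np.ndarray:
    """Geometric factor g(β) = (2πβ)² e^(−2πβ) of the critical frequency.

    Vanishes as β → 0, peaks at β = 1/π with g = 4e⁻² ≈ 0.5413, and decays
    exponentially for large β.
    """
    beta = np.asarray(beta, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta must be positive")
    g = (2.0 * np.pi * beta) ** 2 * np.exp(-2.0 * np.pi * beta)
    return float(g) if g.ndim == 0 else g


def critical_frequency(params: TransportParams) -> float:
    """Critical frequency f_c = κ·g(β)/(2π) in hertz."""
    if params.coupling_rad_s is None:
        raise ValueError(
            "coupling κ is not set: supply coupling_rad_s or calibrate it "
            "from a measured critical frequency with calibrate_coupling()"
        )
    return params.coupling_rad_s * shape_factor(params.beta) / (2.0 * math.pi)


def calibrate_coupling(measured_f_c_hz: float, beta: float) -> float:
    """Invert the critical-frequency law for κ given a measured f_c.

    Round-trips exactly: ``critical_frequency`` with the returned κ
    reproduces ``measured_f_c_hz``.
    """
    if measured_f_c_hz <= 0:
        raise ValueError("measured critical frequency must be positive")
    return 2.0 * math.pi * measured_f_c_hz / shape_factor(beta)


def closed_form_velocity(
    f_hz: float | np.ndarray, f_c_hz: float, pitch_m: float
) -> float | np.ndarray:
    """Mean transport velocity (m/s) of the two-regime law.

    Phase-locked v = f·d for f ≤ f_c; phase-slipping
    v = [f − sqrt(f² − f_c²)]·d above; continuous at f = f_c.
    """
    f = np.asarray(f_hz, dtype=float)
    if np.any(f < 0) or f_c_hz < 0 or pitch_m <= 0:
        raise ValueError("frequencies must be >= 0 and pitch > 0")
    locked = f * pitch_m
    with np.errstate(invalid="ignore"):
        slipping = (f - np.sqrt(np.maximum(f * f - f_c_hz * f_c_hz, 0.0))) * pitch_m
    v = np.where(f <= f_c_hz, locked, slipping)
    return float(v) if v.ndim == 0 else v


def immobilization_frequency(
    frequencies_hz: np.ndarray,
    mean_velocities: np.ndarray,
    fraction: float = 0.1,
) -> tuple[float, bool]:
    """Frequency at which mean velocity falls below ``fraction`` of its max.

    Operates on a sampled velocity-vs-frequency profile; the crossing is
    linearly interpolated between samples.  Returns ``(f_i, crossed)``:
    if the profile never falls below the threshold within the sweep,
    ``crossed`` is False and the sweep maximum is returned as a lower bound.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    v = np.asarray(mean_velocities, dtype=float)
    if f.ndim != 1 or f.shape != v.shape or f.size < 2:
        raise ValueError("need matching 1-D frequency and velocity arrays")
    if not np.all(np.diff(f) > 0):
        raise ValueError("frequencies must be strictly increasing")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    vmax = float(np.max(v))
    i_max = int(np.argmax(v))
    if fraction == 1.0:
        return float(f[i_max]), True
    thresh = fraction * vmax
    for i in range(i_max, f.size - 1):
        if v[i] >= thresh and v[i + 1] < thresh:
            # linear interpolation of the crossing
            t = (v[i] - thresh) / (v[i] - v[i + 1])
            return float(f[i] + t * (f[i + 1] - f[i])), True
    if v[i_max] < thresh:  # degenerate: already below at the max (flat zero)
        return float(f[i_max]), True
    return float(f[-1]), False


def estimate_critical_frequency(
    frequencies_hz: np.ndarray,
    mean_velocities: np.ndarray,
    pitch_m: float,
    divergence_fraction: float = 0.95,
) -> tuple[float, bool]:
    """Critical frequency from a sampled profile: onset of divergence from f·d.

    The phase-locked prediction is v = f·d; f_c is taken as the first
    frequency at which the mean velocity drops below
    ``divergence_fraction × f·d``, linearly interpolated in the ratio
    v/(f·d).  Returns ``(f_c, crossed)``; if the profile never diverges the
    sweep maximum is returned with ``crossed=False``.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    v = np.asarray(mean_velocities, dtype=float)
    if not 0.0 < divergence_fraction < 1.0:
        raise ValueError("divergence_fraction must be in (0, 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(f > 0, v / (f * pitch_m), 1.0)
    below = ratio < divergence_fraction
    if not np.any(below):
        return float(f[-1]), False
    i = int(np.argmax(below))
    if i == 0:
        return float(f[0]), True
    t = (ratio[i - 1] - divergence_fraction) / (ratio[i - 1] - ratio[i])
    return float(f[i - 1] + t * (f[i] - f[i - 1])), True


def fit_critical_frequency(
    frequencies_hz: np.ndarray,
    mean_velocities: np.ndarray,
    pitch_m: float,
    f_c_guess_hz: float | None = None,
) -> float:
    """Least-squares fit of the two-regime velocity law to a noisy profile.

    Robust alternative to the threshold estimators for measured or noisy
    profiles: minimizes the residual between the sampled velocities and
    ``closed_form_velocity(f; f_c)`` over f_c.  The threshold rules remain
    the operational definitions; this fit is the recommended estimator when
    sampling noise would trip a threshold early.
    """
    from scipy.optimize import minimize_scalar

    f = np.asarray(frequencies_hz, dtype=float)
    v = np.asarray(mean_velocities, dtype=float)
    if f_c_guess_hz is None:
        f_c_guess_hz = f[int(np.argmax(v))]

    def loss(fc):
        return float(np.sum((closed_form_velocity(f, fc, pitch_m) - v) ** 2))

    res = minimize_scalar(
        loss, bounds=(f[0] / 2.0, 2.0 * f[-1]), method="bounded",
        options={"xatol": 1e-4 * f_c_guess_hz},
    )
    return float(res.x)


def omega_ratio(f_c_hz: float, f_i_hz: float) -> float:
    """Sharpness parameter Ω = f_c / f_i of the mobile-to-immobile transition."""
    return FrequencyCharacteristics(f_c_hz=f_c_hz, f_i_hz=f_i_hz).omega
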