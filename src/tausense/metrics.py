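"""Sensor figures of merit for the lifetime nanosensor.

From a converged Hill fit and blank statistics this module derives the
standard analytical-chemistry characterization of the sensor:

* apparent dissociation constant K_app (the fitted EC50),
* affinity constant K_aff = 1/K_app,
* sensitivity at low concentration, |τ₂_max − τ₂₀| / K_app (ns·M⁻¹) —
  defined at the fitted parameters rather than as the Hill-curve derivative
  at x = 0, which vanishes for n > 1,
* limit of detection LOD = 3·σ_blank / sensitivity (the 3σ convention),
* linear dynamic range: the concentrations at 10% and 90% of the response
  transition, x_f = EC50·(f/(1−f))^(1/n).

The blank standard deviation is always an explicit input (from ≥2 replicate
blank τ₂ measurements or a supplied override), never a hidden constant.

Also included: the fluorophore-incorporation utilities used to characterize
the nanoparticle synthesis (intensity calibration line and incorporation
percentage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .isotherms import HillParams, IsothermFit

__all__ = [
    "SensorMetrics",
    "CalibrationLine",
    "affinity_constant",
    "sensitivity_low_conc",
    "limit_of_detection",
    "linear_dynamic_range",
    "fluorophore_conc_from_intensity",
    "fit_calibration_line",
    "incorporation_percent",
    "assemble_metrics",
]


@dataclass(frozen=True)
class SensorMetrics:
    """Figure-of-merit bundle for a lifetime nanosensor.

    Units: molar for K_app/LOD/LDR bounds, M⁻¹ for K_aff, ns·M⁻¹ for
    sensitivity (reported in pM / per-pM terms at the presentation layer).
    """

    k_app: float
    k_aff: float
    sensitivity: float
    lod: float
    ldr_low: float
    ldr_high: float
    chi2_red_decay: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("k_app", "k_aff", "sensitivity", "lod"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.ldr_low < self.ldr_high:
            raise ValueError("linear dynamic range bounds must be ordered")

    def as_dict(self) -> dict:
        return {
            "K_app_pM": self.k_app * 1e12,
            "K_aff_per_M": self.k_aff,
            "sensitivity_ns_per_M": self.sensitivity,
            "LOD_pM": self.lod * 1e12,
            "LDR_low_pM": self.ldr_low * 1e12,
            "LDR_high_pM": self.ldr_high * 1e12,
            "chi2_red_decay": self.chi2_red_decay,
        }


@dataclass(frozen=True)
class CalibrationLine:
    """Linear intensity calibration y = slope·[fluorophore, nM] + intercept."""

    slope: float  # rfu per nM
    intercept: float  # rfu

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")

    def predict(self, conc_nM):
        return self.slope * np.asarray(conc_nM, dtype=float) + self.intercept


def affinity_constant(k_app: float) -> float:
    """Affinity constant K_aff = 1/K_app (M⁻¹)."""
    if k_app <= 0:
        raise ValueError("K_app must be positive")
    return 1.0 / k_app


def sensitivity_low_conc(tau2_0: float, tau2_max: float, k_app: float) -> float:
    """Low-concentration sensitivity |τ₂_max − τ₂₀| / K_app (ns·M⁻¹)."""
    if tau2_0 <= 0 or tau2_max <= 0 or k_app <= 0:
        raise ValueError("lifetimes and K_app must be positive")
    span = abs(tau2_max - tau2_0)
    if span == 0:
        raise ValueError("zero response span: sensor is unresponsive")
    return span / k_app


def limit_of_detection(sigma_blank: float, sensitivity: float) -> float:
    """3σ limit of detection: 3·σ_blank / sensitivity (molar)."""
    if sigma_blank < 0:
        raise ValueError("blank standard deviation must be nonnegative")
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    return 3.0 * sigma_blank / sensitivity


def linear_dynamic_range(
    p: HillParams | IsothermFit, lo_frac: float = 0.10, hi_frac: float = 0.90
) -> tuple[float, float]:
    """Concentrations spanning the 10–90% response transition (molar).

    Closed form x_f = EC50·(f/(1−f))^(1/n); the endpoints bracket EC50 and
    their geometric mean equals EC50 exactly.
    """
    if isinstance(p, IsothermFit):
        if not p.converged:
            raise ValueError("refusing a non-converged isotherm fit")
        p = p.params
    if not isinstance(p, HillParams):
        raise TypeError("linear dynamic range is defined for a Hill fit")
    if not 0 < lo_frac < hi_frac < 1:
        raise ValueError("fractions must satisfy 0 < lo < hi < 1")

    def x_at(f: float) -> float:
        return p.ec50 * (f / (1.0 - f)) ** (1.0 / p.n)

    return x_at(lo_frac), x_at(hi_frac)


def fluorophore_conc_from_intensity(cal: CalibrationLine, y: float) -> float:
    """Invert the calibration line: fluorophore concentration (nM) from
    emission intensity (rfu)."""
    return (y - cal.intercept) / cal.slope


def fit_calibration_line(conc_nM, intensity_rfu) -> CalibrationLine:
    """Ordinary least-squares line through calibration standards."""
    slope, intercept = np.polyfit(
        np.asarray(conc_nM, float), np.asarray(intensity_rfu, float), 1
    )
    return CalibrationLine(slope=float(slope), intercept=float(intercept))


def incorporation_percent(added: float, incorporated: float) -> float:
    """Fluorophore incorporation: 100 · incorporated / added (both per mg).

    incorporated > added is physically suspect and warns, but the value is
    still returned.
    """
    if added <= 0:
        raise ValueError("added amount must be positive")
    if incorporated < 0:
        raise ValueError("incorporated amount must be nonnegative")
    if incorporated > added:
        warnings.warn(
            "incorporated exceeds added: physically suspect input", stacklevel=2
        )
    return 100.0 * incorporated / added


def assemble_metrics(
    hill_fit: IsothermFit,
    blank_sd: float | None = None,
    blank_tau2: np.ndarray | None = None,
    decay_chi2: float = float("nan"),
) -> SensorMetrics:
    """Compose the figure-of-merit bundle from a converged Hill fit.

    The blank standard deviation comes either from ``blank_tau2`` (≥2
    replicate blank lifetimes) or from an explicit ``blank_sd`` override;
    a single-replicate blank without an override is refused so that the LOD
    can never rest on one measurement.
    """
    if hill_fit.model != "hill":
        raise ValueError("metrics are defined for a Hill (lifetime) fit")
    if not hill_fit.converged or hill_fit.params is None:
        raise ValueError("refusing a non-converged isotherm fit")
    if blank_sd is None:
        if blank_tau2 is None or len(np.atleast_1d(blank_tau2)) < 2:
            raise ValueError(
                "blank sd unavailable: need ≥2 replicate blank measurements "
                "or an explicit blank_sd override"
            )
        blank_sd = float(np.std(np.atleast_1d(blank_tau2), ddof=1))
    p = hill_fit.params
    k_app = p.ec50
    sens = sensitivity_low_conc(p.tau2_0, p.tau2_max, k_app)
    lod = limit_of_detection(blank_sd, sens)
    lo, hi = linear_dynamic_range(p)
    return SensorMetrics(
        k_app=k_app,
        k_aff=affinity_constant(k_app),
        sensitivity=sens,
        lod=lod,
        ldr_low=lo,
        ldr_high=hi,
        chi2_red_decay=decay_chi2,
    )
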