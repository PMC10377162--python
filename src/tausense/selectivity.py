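"""Comparative workflows: selectivity panels and spiked-matrix assays.

A selectivity panel challenges the nanosensor with the template protein and
a set of competitor proteins at comparable concentrations; each condition's
decays are fit by reconvolution (biexponential, fast component fixed from
the blank) and the per-condition mean τ₂ is compared with the blank.

Calls use a 3σ convention on the pooled replicate scatter: a τ₂ *drop*
larger than ``threshold_sd × pooled sd`` is a binder; an absolute change
below it is a non-binder; anything else — notably a significant *increase*,
the signature of non-specific adsorption — is indeterminate.

The spiked-matrix (wine) assay follows the same logic with the unspiked
matrix sample as the reference condition. Per the underlying measurement
protocol, that matrix blank also serves as the deconvolution prompt for the
spiked samples (a matrix-matched prompt); an instrument prompt can be
supplied instead via ``instrument_prompt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DecayHistogram
from .reconvolution import DecayFitResult, fit_biexponential

__all__ = [
    "PanelRow",
    "PanelResult",
    "percent_tau2_change",
    "run_panel",
    "run_matrix_assay",
]

BLANK_LABEL = "blank"


def percent_tau2_change(tau2_blank: float, tau2_sample: float) -> float:
    """Raw percentage change 100·(τ₂_blank − τ₂_sample)/τ₂_blank.

    Positive for a drop (binding signature), negative for an increment.
    """
    if tau2_blank <= 0:
        raise ValueError("blank lifetime must be positive")
    return 100.0 * (tau2_blank - tau2_sample) / tau2_blank


@dataclass(frozen=True)
class PanelRow:
    label: str
    concentration: float  # molar; 0 for the blank
    tau2: float  # ns, mean over surviving replicates
    tau2_stderr: float  # ns, sem over replicates (nan if < 2)
    delta_pct: float  # % change vs blank (0 for the blank row)
    call: str  # binder | non-binder | indeterminate
    n_replicates: int = 0


@dataclass
class PanelResult:
    """Per-condition τ₂ summary with binary binding calls."""

    rows: list[PanelRow]
    pooled_sd: float = float("nan")
    threshold_sd: float = 3.0
    prompt_label: str = ""
    notes: str = ""
    fits: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        blanks = [r for r in self.rows if r.label == BLANK_LABEL]
        if len(blanks) != 1:
            raise ValueError("panel must contain exactly one blank row")

    @property
    def blank(self) -> PanelRow:
        return next(r for r in self.rows if r.label == BLANK_LABEL)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "concentration_M": r.concentration,
                    "tau2_ns": r.tau2,
                    "tau2_stderr_ns": r.tau2_stderr,
                    "delta_pct": r.delta_pct,
                    "call": r.call,
                    "n_replicates": r.n_replicates,
                }
                for r in self.rows
            ]
        )


def _fit_condition(
    decays: list[DecayHistogram],
    irf: DecayHistogram,
    fixed_tau1: float | None,
    fit_kwargs: dict,
) -> tuple[np.ndarray, list[DecayFitResult]]:
    fits = [
        fit_biexponential(d, irf, fixed_tau1=fixed_tau1, **fit_kwargs) for d in decays
    ]
    tau2 = np.array([f.params.tau2 for f in fits if f.converged])
    return tau2, fits


def _call(delta: float, noise: float, threshold_sd: float) -> str:
    """Classify a τ₂ change (ns, positive = drop) against the noise scale."""
    limit = threshold_sd * noise
    if delta > limit:
        return "binder"
    if abs(delta) <= limit:
        return "non-binder"
    return "indeterminate"  # significant increase: non-specific interaction


def run_panel(
    blank_decays: list[DecayHistogram],
    sample_decays: dict[str, list[DecayHistogram]],
    irf: DecayHistogram,
    concentrations: dict[str, float] | None = None,
    threshold_sd: float = 3.0,
    fixed_tau1: float | None = None,
    fit_kwargs: dict | None = None,
) -> PanelResult:
    """Fit a selectivity panel and call each condition.

    The blank condition is fit first with τ₁ free (unless ``fixed_tau1`` is
    given); its mean fitted τ₁ then clamps the fast component for every
    condition, the fixed-τ₁ convention of titration analysis. Conditions
    whose replicates all fail to converge, or with <2 surviving replicate
    fits, are called indeterminate.
    """
    if len(blank_decays) < 2:
        raise ValueError("need ≥2 replicate blank decays")
    fit_kwargs = dict(fit_kwargs or {})
    concentrations = dict(concentrations or {})

    if fixed_tau1 is None:
        free_fits = [fit_biexponential(d, irf, **fit_kwargs) for d in blank_decays]
        tau1s = [f.params.tau1 for f in free_fits if f.converged]
        if not tau1s:
            return _indeterminate_panel(
                blank_decays,
                sample_decays,
                irf,
                threshold_sd,
                "no blank decay fit converged; cannot derive the fixed τ1",
            )
        fixed_tau1 = float(np.mean(tau1s))

    all_fits: dict[str, list[DecayFitResult]] = {}
    tau2_blank, fits = _fit_condition(blank_decays, irf, fixed_tau1, fit_kwargs)
    all_fits[BLANK_LABEL] = fits
    if len(tau2_blank) < 2:
        return _indeterminate_panel(
            blank_decays,
            sample_decays,
            irf,
            threshold_sd,
            "fewer than 2 converged blank fits; no reference lifetime",
        )
    blank_mean = float(tau2_blank.mean())

    condition_tau2 = {BLANK_LABEL: tau2_blank}
    for label, decays in sample_decays.items():
        if label == BLANK_LABEL:
            raise ValueError("sample label 'blank' is reserved")
        if len(decays) < 2:
            raise ValueError(f"condition {label!r}: need ≥2 replicate decays")
        tau2, fits = _fit_condition(decays, irf, fixed_tau1, fit_kwargs)
        condition_tau2[label] = tau2
        all_fits[label] = fits

    # pooled within-condition replicate sd over conditions with ≥2 survivors
    sq, dof = 0.0, 0
    for tau2 in condition_tau2.values():
        if len(tau2) >= 2:
            sq += float(((tau2 - tau2.mean()) ** 2).sum())
            dof += len(tau2) - 1
    pooled_sd = float(np.sqrt(sq / dof)) if dof > 0 else float("nan")

    rows = [
        PanelRow(
            label=BLANK_LABEL,
            concentration=0.0,
            tau2=blank_mean,
            tau2_stderr=float(tau2_blank.std(ddof=1) / np.sqrt(len(tau2_blank))),
            delta_pct=0.0,
            call="non-binder",
            n_replicates=len(tau2_blank),
        )
    ]
    for label, tau2 in condition_tau2.items():
        if label == BLANK_LABEL:
            continue
        if len(tau2) < 2:
            rows.append(
                PanelRow(
                    label=label,
                    concentration=concentrations.get(label, float("nan")),
                    tau2=float("nan"),
                    tau2_stderr=float("nan"),
                    delta_pct=float("nan"),
                    call="indeterminate",
                    n_replicates=len(tau2),
                )
            )
            continue
        mean = float(tau2.mean())
        rows.append(
            PanelRow(
                label=label,
                concentration=concentrations.get(label, float("nan")),
                tau2=mean,
                tau2_stderr=float(tau2.std(ddof=1) / np.sqrt(len(tau2))),
                delta_pct=percent_tau2_change(blank_mean, mean),
                call=_call(blank_mean - mean, pooled_sd, threshold_sd),
                n_replicates=len(tau2),
            )
        )
    return PanelResult(
        rows=rows,
        pooled_sd=pooled_sd,
        threshold_sd=threshold_sd,
        prompt_label=irf.label or irf.role,
    )


def _indeterminate_panel(
    blank_decays, sample_decays, irf, threshold_sd, reason: str
) -> PanelResult:
    """Degraded panel when the reference condition cannot be fit: every
    condition is indeterminate, with the reason recorded in ``notes``."""
    rows = [
        PanelRow(
            label=BLANK_LABEL,
            concentration=0.0,
            tau2=float("nan"),
            tau2_stderr=float("nan"),
            delta_pct=0.0,
            call="indeterminate",
            n_replicates=0,
        )
    ]
    for label in sample_decays:
        rows.append(
            PanelRow(
                label=label,
                concentration=float("nan"),
                tau2=float("nan"),
                tau2_stderr=float("nan"),
                delta_pct=float("nan"),
                call="indeterminate",
                n_replicates=0,
            )
        )
    return PanelResult(
        rows=rows,
        threshold_sd=threshold_sd,
        prompt_label=irf.label or irf.role,
        notes=reason,
    )


def build_matrix_prompt(matrix_blank_decays: list[DecayHistogram]) -> DecayHistogram:
    """Matrix-matched prompt: summed counts of the unspiked-matrix decays."""
    ref = matrix_blank_decays[0]
    counts = np.sum([np.asarray(d.counts) for d in matrix_blank_decays], axis=0)
    return DecayHistogram(
        times=ref.times,
        counts=counts.astype(np.int64),
        channel_width=ref.channel_width,
        role="prompt",
        label="matrix blank (unspiked) used as prompt",
    )


def run_matrix_assay(
    matrix_blank_decays: list[DecayHistogram],
    matrix_spiked_decays: dict[str, list[DecayHistogram]],
    instrument_prompt: DecayHistogram | None = None,
    threshold_sd: float = 3.0,
    fixed_tau1: float | None = None,
    fit_kwargs: dict | None = None,
) -> PanelResult:
    """Spiked-matrix assay with the unspiked matrix sample as reference.

    By default the deconvolution prompt is built from the matrix blank
    itself (matrix-matched prompt, mirroring the measurement protocol);
    pass ``instrument_prompt`` to use a true instrument response instead.
    The result records which histogram served as prompt.
    """
    if not matrix_blank_decays:
        raise ValueError("matrix blank decays are required")
    prompt = instrument_prompt or build_matrix_prompt(matrix_blank_decays)
    return run_panel(
        blank_decays=matrix_blank_decays,
        sample_decays=matrix_spiked_decays,
        irf=prompt,
        threshold_sd=threshold_sd,
        fixed_tau1=fixed_tau1,
        fit_kwargs=fit_kwargs,
    )
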