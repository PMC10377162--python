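"""Binding-isotherm models and fits for nanosensor titrations.

Two response models are supported:

* **Langmuir** (hyperbolic, for emission-intensity titrations):
  ``y(x) = START + (END − START) · x / (k + x)`` where ``k`` is the
  half-saturation concentration (EC50, the apparent dissociation constant
  K_app).
* **Hill with baseline** (for lifetime titrations):
  ``τ₂(x) = τ₂₀ + (τ₂_max − τ₂₀) · xⁿ / (EC50ⁿ + xⁿ)``.

The bare Hill form ``τ₂_max·xⁿ/(K + xⁿ)`` predicts a zero response at zero
analyte, inconsistent with a finite blank lifetime; the baseline form above
is the implemented model (the bare form is available as
:func:`predict_hill_bare` for reference). With n ≠ 1 the mass-action K in
the bare form carries units of Mⁿ; the fit is therefore parameterized by
EC50 in molar units (EC50ⁿ = K) so that the half-saturation concentration is
the directly fitted quantity.

Fits run on log₁₀-concentration internally for conditioning and use inverse
replicate-variance weights when every point has ≥2 replicates.
Non-convergence (e.g. flat, uninformative titrations) is a reported state
(``converged=False``) rather than an exception.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .io import MIN_CONCENTRATIONS_FOR_FIT, TitrationSeries

__all__ = [
    "LangmuirParams",
    "HillParams",
    "IsothermFit",
    "predict_langmuir",
    "predict_hill",
    "predict_hill_bare",
    "fit_langmuir",
    "fit_hill",
    "normalized_response",
]


@dataclass(frozen=True)
class LangmuirParams:
    """Langmuir isotherm: start/end plateaus (rfu) and EC50 ``k`` (molar)."""

    start: float
    end: float
    k: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("half-saturation k must be positive")

    def predict(self, x):
        return predict_langmuir(self, x)


@dataclass(frozen=True)
class HillParams:
    """Baseline-Hill isotherm for the binding-site lifetime τ₂.

    ``tau2_0``: zero-analyte lifetime (ns); ``tau2_max``: saturation
    lifetime (ns); ``ec50``: half-saturation concentration (molar);
    ``n``: Hill coefficient. A decreasing response simply has
    ``tau2_max < tau2_0``.
    """

    tau2_0: float
    tau2_max: float
    ec50: float
    n: float = 1.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")

    @property
    def span(self) -> float:
        return self.tau2_max - self.tau2_0

    def predict(self, x):
        return predict_hill(self, x)


def predict_langmuir(p: LangmuirParams, x):
    """Evaluate ``START + (END−START)·x/(k+x)`` at concentration(s) x (M)."""
    x = np.asarray(x, dtype=float)
    out = p.start + (p.end - p.start) * x / (p.k + x)
    return out if out.ndim else float(out)


def predict_hill(p: HillParams, x):
    """Evaluate the baseline-Hill model τ₂(x) at concentration(s) x (M)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / p.ec50) ** p.n, 0.0)
    out = p.tau2_0 + (p.tau2_max - p.tau2_0) * ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def predict_hill_bare(p: HillParams, x):
    """The zero-baseline Hill variant τ₂_max·xⁿ/(EC50ⁿ + xⁿ), for reference."""
    x = np.asarray(x, dtype=float)
    ratio = np.where(x > 0, (x / p.ec50) ** p.n, 0.0)
    out = p.tau2_max * ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


@dataclass
class IsothermFit:
    """Result of a Langmuir or Hill fit.

    ``converged=False`` marks an uninformative fit (flat data or failed
    error estimation); downstream metrics assembly refuses such fits.
    """

    model: str
    params: LangmuirParams | HillParams | None
    stderr: dict = field(default_factory=dict)
    r2_adj: float = float("nan")
    converged: bool = False
    message: str = ""
    n_points: int = 0

    def predict(self, x):
        if self.params is None:
            raise ValueError("fit has no parameters")
        return self.params.predict(x)


def _prepare(series: TitrationSeries, kind: str):
    if series.response_kind != kind:
        raise ValueError(
            f"expected a {kind} titration, got {series.response_kind}"
        )
    if series.n_points < MIN_CONCENTRATIONS_FOR_FIT:
        raise ValueError(
            f"isotherm fitting requires ≥{MIN_CONCENTRATIONS_FOR_FIT} distinct "
            f"concentrations, got {series.n_points}"
        )
    x = series.concentrations
    y = series.means
    sd = series.dispersions
    n_rep = np.array([len(r) for r in series.responses])
    # inverse-variance weights on the group means, with the per-point
    # variances moderated to the pooled replicate variance: raw 3-replicate
    # variance estimates are too noisy to weight by directly and wreck the
    # stderr calibration. Noiseless synthetic data → unweighted.
    if np.all(n_rep > 1) and np.all(np.isfinite(sd)) and np.all(sd > 0):
        pooled = np.sqrt(np.mean(sd**2))
        weights = np.sqrt(n_rep) / pooled
    else:
        weights = np.ones_like(y)
    return x, y, sd, weights


def _multistart(residual, pars_list) -> lmfit.minimizer.MinimizerResult:
    """Run Levenberg–Marquardt from several deterministic starting points
    and keep the best result (lowest SSR; error bars preferred).

    Guards against the occasional false ftol stop of a single start on
    plateau-shaped objectives.
    """
    best = None
    for pars in pars_list:
        try:
            res = lmfit.minimize(
                residual, pars, method="leastsq", xtol=1e-12, ftol=1e-12
            )
        except Exception:
            continue
        key = (float(res.chisqr), not res.errorbars)
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise RuntimeError("all isotherm fit starts failed")
    return best[1]


def _pooled_sd(sd: np.ndarray, y: np.ndarray) -> float:
    finite = sd[np.isfinite(sd)]
    if len(finite) and np.any(finite > 0):
        return float(np.sqrt(np.mean(finite**2)))
    return 0.0


def _r2_adjusted(y, yhat, weights, n_params) -> float:
    resid = (y - yhat) * weights
    tot = (y - np.average(y, weights=weights**2)) * weights
    ss_res = float(resid @ resid)
    ss_tot = float(tot @ tot)
    n = len(y)
    if ss_tot == 0 or n - n_params - 1 <= 0:
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def fit_langmuir(series: TitrationSeries) -> IsothermFit:
    """Weighted least-squares fit of the Langmuir model to an intensity
    titration.

    Returns ``converged=False`` for flat data (response span below twice the
    pooled replicate noise) or when the optimizer cannot estimate parameter
    uncertainties — mirroring titrations where the sensor does not respond.
    """
    x, y, sd, weights = _prepare(series, "intensity")
    pooled = _pooled_sd(sd, y)
    span = abs(y[0] - y[-1])
    if pooled > 0 and span < 2 * pooled:
        return IsothermFit(
            model="langmuir",
            params=None,
            converged=False,
            message="flat titration: response span below 2× pooled noise",
            n_points=len(x),
        )

    logx = np.log10(x)

    def make_pars(logk0: float) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        pars.add("start", value=float(y[0]))
        pars.add("end", value=float(y[-1]))
        pars.add(
            "log10_k",
            value=logk0,
            min=float(logx.min() - 3),
            max=float(logx.max() + 3),
        )
        return pars

    def residual(p):
        model = LangmuirParams(
            start=p["start"].value, end=p["end"].value, k=10.0 ** p["log10_k"].value
        )
        return (y - model.predict(x)) * weights

    starts = np.quantile(logx, [0.5, 0.25, 0.75])
    res = _multistart(residual, [make_pars(float(s)) for s in starts])
    k = 10.0 ** res.params["log10_k"].value
    params = LangmuirParams(
        start=res.params["start"].value, end=res.params["end"].value, k=k
    )
    stderr = _extract_stderr(res, {"log10_k": ("k", k)})
    converged = bool(res.success) and res.errorbars and np.isfinite(
        stderr.get("k", np.nan)
    )
    return IsothermFit(
        model="langmuir",
        params=params,
        stderr=stderr,
        r2_adj=_r2_adjusted(y, params.predict(x), weights, 3),
        converged=converged,
        message=res.message if not converged else "",
        n_points=len(x),
    )


def fit_hill(series: TitrationSeries, n_bounds=(0.2, 6.0)) -> IsothermFit:
    """Weighted least-squares fit of the baseline-Hill model to a τ₂
    titration.

    The Hill coefficient is bounded to ``n_bounds`` (default [0.2, 6]);
    decreasing responses (``tau2_max < tau2_0``) are handled naturally.
    Non-monotone data beyond noise produce a warning, not a failure.
    """
    x, y, sd, weights = _prepare(series, "lifetime_tau2")
    pooled = _pooled_sd(sd, y)
    span = abs(y[0] - y[-1])
    if pooled > 0 and span < 2 * pooled:
        return IsothermFit(
            model="hill",
            params=None,
            converged=False,
            message="flat titration: response span below 2× pooled noise",
            n_points=len(x),
        )
    if pooled > 0:
        drops = np.diff(y)
        direction = np.sign(y[-1] - y[0])
        if np.any(direction * drops < -3 * pooled):
            warnings.warn("titration is non-monotone beyond noise", stacklevel=2)

    logx = np.log10(x)

    def make_pars(log_ec0: float, n0: float) -> lmfit.Parameters:
        pars = lmfit.Parameters()
        pars.add("tau2_0", value=float(y[0]))
        pars.add("tau2_max", value=float(y[-1]))
        pars.add(
            "log10_ec50",
            value=log_ec0,
            min=float(logx.min() - 3),
            max=float(logx.max() + 3),
        )
        pars.add("n", value=n0, min=n_bounds[0], max=n_bounds[1])
        return pars

    def residual(p):
        model = HillParams(
            tau2_0=p["tau2_0"].value,
            tau2_max=p["tau2_max"].value,
            ec50=10.0 ** p["log10_ec50"].value,
            n=p["n"].value,
        )
        return (y - model.predict(x)) * weights

    starts = [
        (float(s), n0)
        for s in np.quantile(logx, [0.5, 0.25, 0.75])
        for n0 in (1.0, 2.0)
    ]
    res = _multistart(residual, [make_pars(s, n0) for s, n0 in starts])
    ec50 = 10.0 ** res.params["log10_ec50"].value
    params = HillParams(
        tau2_0=res.params["tau2_0"].value,
        tau2_max=res.params["tau2_max"].value,
        ec50=ec50,
        n=res.params["n"].value,
    )
    stderr = _extract_stderr(res, {"log10_ec50": ("ec50", ec50)})
    converged = bool(res.success) and res.errorbars and np.isfinite(
        stderr.get("ec50", np.nan)
    )
    return IsothermFit(
        model="hill",
        params=params,
        stderr=stderr,
        r2_adj=_r2_adjusted(y, params.predict(x), weights, 4),
        converged=converged,
        message=res.message if not converged else "",
        n_points=len(x),
    )


def _extract_stderr(res, log_map: dict) -> dict:
    """Pull stderr for each varying parameter, delta-transforming the
    log₁₀-space concentration parameter back to linear units."""
    out: dict[str, float] = {}
    for name, par in res.params.items():
        se = par.stderr if par.stderr is not None else np.nan
        if name in log_map:
            lin_name, lin_value = log_map[name]
            out[lin_name] = float(se * lin_value * np.log(10.0))
        else:
            out[name] = float(se)
    return out


def normalized_response(p: HillParams, tau2_obs: float) -> float:
    """Observed lifetime change as a percentage of the full response span.

    ``(τ₂₀ − τ₂_obs)/(τ₂₀ − τ₂_max) × 100``; 0% at the blank lifetime,
    100% at saturation. Values outside [0, 100] are possible with noise.
    """
    span = p.tau2_0 - p.tau2_max
    if span == 0:
        raise ValueError("degenerate span: tau2_0 == tau2_max")
    return 100.0 * (p.tau2_0 - tau2_obs) / span
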