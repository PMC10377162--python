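"""End-to-end orchestration: simulate → fit decays → titration → isotherm →
metrics, under a single validated config with one seed.

Per-stage child seeds are derived deterministically from the config seed so
stages never share RNG state; identical config + seed reproduce every
numeric output byte for byte. A machine-readable run manifest records
inputs, seed, package versions, per-stage status and a SHA-256 hash of each
output file. A stage failure halts the run, preserving partial outputs and
recording the failed stage in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    DecayHistogram,
    TitrationSeries,
    parse_concentration,
    read_decay,
    write_decay,
    write_titration,
)
from .isotherms import HillParams, IsothermFit, fit_hill, fit_langmuir
from .metrics import assemble_metrics
from .reconvolution import fit_biexponential
from .synthetic import (
    DecayModelParams,
    InstrumentConfig,
    default_concentration_grid,
    make_irf,
    simulate_decay,
    simulate_decay_titration,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "RunReport"]

log = logging.getLogger("tausense.pipeline")

_INSTRUMENT_KEYS = {
    "n_channels",
    "channel_width",
    "peak_target",
    "irf_fwhm",
    "irf_center",
}
_GENERATION_KEYS = {
    "tau2_0",
    "tau2_max",
    "ec50",
    "n",
    "tau1",
    "background",
    "replicates",
    "concentrations",
    "n_concentrations",
    "conc_low",
    "conc_high",
    "n_blanks",
}
_FITTING_KEYS = {"fix_tau1", "objective"}
_ISOTHERM_KEYS = {"model"}
_METRICS_KEYS = {"blank_sd"}
_INPUT_KEYS = {"decay_dir", "prompt", "titration"}


@dataclass
class PipelineConfig:
    """Validated, fully defaulted pipeline configuration."""

    seed: int = 0
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    # generation truth (synthetic mode)
    hill: HillParams = field(
        default_factory=lambda: HillParams(
            tau2_0=4.183, tau2_max=3.983, ec50=18e-12, n=1.89
        )
    )
    tau1: float = 1.0
    background: float = 10.0
    replicates: int = 3
    concentrations: np.ndarray = field(
        default_factory=lambda: default_concentration_grid()
    )
    n_blanks: int = 3
    # real-data inputs (exclusive with generation truth)
    input_paths: dict | None = None
    # fitting / isotherm / metrics options
    fix_tau1: bool = True
    objective: str = "neyman"
    isotherm_model: str = "hill"
    blank_sd_override: float | None = None
    output_dir: Path = Path("tausense_run")

    @property
    def synthetic(self) -> bool:
        return self.input_paths is None


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file or a mapping.

    Unknown keys are rejected; a config giving both synthetic generation
    truth and real-data input paths is contradictory and refused. A minimal
    config (just a seed, or empty) yields full defaults at the reference
    instrument settings.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text()) or {}
    else:
        raw = dict(source)
    _reject_unknown(
        raw,
        {"seed", "instrument", "generation", "inputs", "fitting", "isotherm",
         "metrics", "output_dir"},
        "config",
    )
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", 0))

    inst = dict(raw.get("instrument") or {})
    _reject_unknown(inst, _INSTRUMENT_KEYS, "instrument")
    cfg.instrument = InstrumentConfig(seed=cfg.seed, **inst)

    gen = dict(raw.get("generation") or {})
    _reject_unknown(gen, _GENERATION_KEYS, "generation")
    inputs = raw.get("inputs")
    if inputs is not None and gen:
        raise ValueError(
            "contradictory config: both generation truth and input paths given"
        )
    if inputs is not None:
        inputs = dict(inputs)
        _reject_unknown(inputs, _INPUT_KEYS, "inputs")
        if "prompt" not in inputs:
            raise ValueError("inputs require a 'prompt' path")
        cfg.input_paths = inputs
    else:
        cfg.hill = HillParams(
            tau2_0=float(gen.get("tau2_0", cfg.hill.tau2_0)),
            tau2_max=float(gen.get("tau2_max", cfg.hill.tau2_max)),
            ec50=parse_concentration(gen.get("ec50", cfg.hill.ec50)),
            n=float(gen.get("n", cfg.hill.n)),
        )
        cfg.tau1 = float(gen.get("tau1", cfg.tau1))
        cfg.background = float(gen.get("background", cfg.background))
        cfg.replicates = int(gen.get("replicates", cfg.replicates))
        cfg.n_blanks = int(gen.get("n_blanks", cfg.n_blanks))
        if "concentrations" in gen:
            cfg.concentrations = np.array(
                sorted(parse_concentration(c) for c in gen["concentrations"])
            )
        else:
            cfg.concentrations = default_concentration_grid(
                parse_concentration(gen.get("conc_low", 100e-15)),
                parse_concentration(gen.get("conc_high", 150e-9)),
                int(gen.get("n_concentrations", 10)),
            )

    fit = dict(raw.get("fitting") or {})
    _reject_unknown(fit, _FITTING_KEYS, "fitting")
    cfg.fix_tau1 = bool(fit.get("fix_tau1", True))
    cfg.objective = str(fit.get("objective", "neyman"))

    iso = dict(raw.get("isotherm") or {})
    _reject_unknown(iso, _ISOTHERM_KEYS, "isotherm")
    cfg.isotherm_model = str(iso.get("model", "hill"))
    if cfg.isotherm_model not in ("hill", "langmuir"):
        raise ValueError(f"unknown isotherm model {cfg.isotherm_model!r}")

    met = dict(raw.get("metrics") or {})
    _reject_unknown(met, _METRICS_KEYS, "metrics")
    if met.get("blank_sd") is not None:
        cfg.blank_sd_override = float(met["blank_sd"])

    cfg.output_dir = Path(raw.get("output_dir", "tausense_run"))
    return cfg


@dataclass
class RunReport:
    """Outcome of a pipeline run: per-stage status and headline results."""

    config: PipelineConfig
    stages: dict = field(default_factory=dict)
    isotherm: IsothermFit | None = None
    metrics: dict | None = None
    manifest_path: Path | None = None
    failed_stage: str | None = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis under one config.

    Stages: simulate (or load) decays → reconvolution fits (τ₁ fixed from
    the blank) → τ₂ titration table → Hill fit → sensor metrics → report.
    A non-converged isotherm is reported, metrics are omitted, and the run
    still completes.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "synthetic": config.synthetic,
        "stages": {},
        "outputs": {},
    }
    report.manifest_path = out / "manifest.json"

    def finish_stage(name: str, status: str, **extra) -> None:
        manifest["stages"][name] = {"status": status, **extra}
        report.stages[name] = status
        log.info("stage %s: %s %s", name, status, extra or "")

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    def write_manifest() -> None:
        report.manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        t0 = time.perf_counter()
        if config.synthetic:
            irf = make_irf(config.instrument)
            blank_params = DecayModelParams(
                kind="bi",
                a=config.background,
                b1=1.0,
                tau1=config.tau1,
                b2=1.0,
                tau2=config.hill.tau2_0,
            )
            ss = np.random.SeedSequence(config.seed).spawn(config.n_blanks + 1)
            blanks = [
                simulate_decay(
                    blank_params,
                    irf,
                    config.instrument,
                    rng=np.random.default_rng(s),
                    label=f"blank rep {i}",
                )
                for i, s in enumerate(ss[:-1])
            ]
            rep_cfgs = [
                dataclasses.replace(
                    config.instrument, seed=int(np.random.default_rng(ss[-1]).integers(2**31 - 1)) + r
                )
                for r in range(config.replicates)
            ]
            titration_decays: list[tuple[float, int, DecayHistogram]] = []
            for r, rep_cfg in enumerate(rep_cfgs):
                for conc, hist in simulate_decay_titration(
                    config.hill,
                    config.concentrations,
                    blank_params,
                    irf,
                    rep_cfg,
                ):
                    titration_decays.append((conc, r, hist))
            decay_dir = out / "decays"
            decay_dir.mkdir(exist_ok=True)
            write_decay(irf, decay_dir / "prompt.txt")
            record(decay_dir / "prompt.txt")
            for i, b in enumerate(blanks):
                p = decay_dir / f"blank_rep{i}.txt"
                write_decay(b, p)
                record(p)
            for conc, r, hist in titration_decays:
                p = decay_dir / f"decay_{conc:.4e}M_rep{r}.txt"
                write_decay(hist, p)
                record(p)
        else:
            irf = read_decay(config.input_paths["prompt"])
            blanks, titration_decays = _load_real_decays(config)
        finish_stage("simulate" if config.synthetic else "load",
                     "ok", seconds=round(time.perf_counter() - t0, 3))
    except Exception as exc:
        finish_stage("simulate", "failed", error=str(exc))
        report.failed_stage = "simulate"
        write_manifest()
        return report

    try:
        t0 = time.perf_counter()
        blank_fits = [fit_biexponential(b, irf, objective=config.objective)
                      for b in blanks]
        blank_fits = [f for f in blank_fits if f.converged]
        if not blank_fits:
            raise RuntimeError("no blank decay fit converged")
        fixed_tau1 = (
            float(np.mean([f.params.tau1 for f in blank_fits]))
            if config.fix_tau1
            else None
        )
        blank_tau2 = np.array([f.params.tau2 for f in blank_fits])
        rows = []
        for conc, r, hist in titration_decays:
            f = fit_biexponential(
                hist, irf, fixed_tau1=fixed_tau1, objective=config.objective
            )
            rows.append(
                {
                    "concentration_M": conc,
                    "replicate": r,
                    "tau1_ns": f.params.tau1,
                    "tau2_ns": f.params.tau2,
                    "tau2_stderr_ns": f.stderr.get("tau2", np.nan),
                    "chi2_red": f.chi2_red,
                    "converged": f.converged,
                }
            )
        fits_df = pd.DataFrame(rows)
        fits_path = out / "decay_fits.tsv"
        fits_df.to_csv(fits_path, sep="\t", index=False, float_format="%.10g")
        record(fits_path)
        mean_chi2 = float(fits_df.loc[fits_df.converged, "chi2_red"].mean())
        finish_stage("fit_decays", "ok",
                     n_converged=int(fits_df.converged.sum()),
                     n_total=len(fits_df), mean_chi2_red=round(mean_chi2, 4),
                     fixed_tau1_ns=fixed_tau1,
                     seconds=round(time.perf_counter() - t0, 3))
    except Exception as exc:
        finish_stage("fit_decays", "failed", error=str(exc))
        report.failed_stage = "fit_decays"
        write_manifest()
        return report

    try:
        ok = fits_df[fits_df.converged]
        groups = ok.groupby("concentration_M")["tau2_ns"]
        concentrations = np.array(sorted(groups.groups))
        series = TitrationSeries(
            concentrations=concentrations,
            responses=[groups.get_group(c).to_numpy() for c in concentrations],
            response_kind="lifetime_tau2",
            label="tau2 vs analyte concentration",
        )
        tit_path = out / "titration.tsv"
        write_titration(series, tit_path)
        record(tit_path)
        finish_stage("build_titration", "ok", n_points=series.n_points)
    except Exception as exc:
        finish_stage("build_titration", "failed", error=str(exc))
        report.failed_stage = "build_titration"
        write_manifest()
        return report

    try:
        fit = fit_hill(series) if config.isotherm_model == "hill" else fit_langmuir(series)
        report.isotherm = fit
        iso = {
            "model": fit.model,
            "converged": fit.converged,
            "r2_adj": fit.r2_adj,
            "message": fit.message,
            "params": dataclasses.asdict(fit.params) if fit.params else None,
            "stderr": fit.stderr,
        }
        iso_path = out / "isotherm.json"
        iso_path.write_text(json.dumps(iso, indent=2, default=float))
        record(iso_path)
        finish_stage("fit_isotherm", "ok", converged=fit.converged)
    except Exception as exc:
        finish_stage("fit_isotherm", "failed", error=str(exc))
        report.failed_stage = "fit_isotherm"
        write_manifest()
        return report

    if fit.converged and config.isotherm_model == "hill":
        try:
            m = assemble_metrics(
                fit,
                blank_sd=config.blank_sd_override,
                blank_tau2=blank_tau2,
                decay_chi2=mean_chi2,
            )
            report.metrics = m.as_dict()
            met_path = out / "metrics.json"
            met_path.write_text(json.dumps(report.metrics, indent=2))
            record(met_path)
            finish_stage("metrics", "ok")
        except Exception as exc:
            finish_stage("metrics", "failed", error=str(exc))
            report.failed_stage = "metrics"
            write_manifest()
            return report
    else:
        finish_stage("metrics", "skipped",
                     reason="isotherm fit did not converge"
                     if not fit.converged else "langmuir model")

    write_manifest()
    return report


def _load_real_decays(config: PipelineConfig):
    """Load measured decays for the real-data path.

    Blank decays are files whose label starts with 'blank'; titration files
    carry their concentration in the label (molar, or with a unit suffix).
    """
    decay_dir = Path(config.input_paths["decay_dir"])
    blanks, titration = [], []
    for path in sorted(decay_dir.glob("*.txt")):
        hist = read_decay(path)
        if hist.role == "prompt":
            continue
        label = hist.label.strip()
        if label.lower().startswith("blank"):
            blanks.append(hist)
        else:
            conc = parse_concentration(label.split()[-2] + " " + label.split()[-1]
                                       if len(label.split()) >= 2 else label)
            titration.append((conc, 0, hist))
    if not blanks:
        raise ValueError("no blank decays found (labels starting with 'blank')")
    # assign replicate indices per concentration in load order
    counts: dict[float, int] = {}
    out = []
    for conc, _, hist in sorted(titration, key=lambda t: t[0]):
        r = counts.get(conc, 0)
        counts[conc] = r + 1
        out.append((conc, r, hist))
    return blanks, out
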