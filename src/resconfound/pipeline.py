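"""End-to-end pipeline: simulate -> derive -> analyze -> report.

A :class:`RunConfig` captures every stage parameter plus the master seed;
:func:`run_pipeline` executes the stages in order, writes the intermediate
CSVs and a JSON report, and attaches per-stage provenance (rows in/out) and
the adjudication verdict.  Reports are deterministic given the config
(timestamps excluded)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import analysis, measurement, synthetic

__all__ = ["RunConfig", "StageError", "run_pipeline", "analyze_derived"]

log = logging.getLogger("resconfound")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input snapshot path."""

    def __init__(self, stage: str, message: str, snapshot: str | None = None):
        self.stage = stage
        self.snapshot = snapshot
        detail = f" (input snapshot: {snapshot})" if snapshot else ""
        super().__init__(f"stage {stage!r} failed: {message}{detail}")


@dataclass
class RunConfig:
    """Parameters for a full simulate/derive/analyze run."""

    outdir: str = "resconfound_run"
    seed: int = 0
    n: int = 8984
    scenario: str = "residual_confounding"
    rho_true: list | None = None
    rel: list = field(default_factory=lambda: [0.9, 0.9, 0.9])
    direct_effect: float = 0.0
    loadings: list | None = None
    degree_probs: list | None = None
    zero_fraction: float = 0.0
    missing: dict | None = None
    keep_truth: bool = False
    bootstrap: int = 2000
    ci: str = "bootstrap"  # bootstrap | normal
    missing_policy: str = "listwise"
    income_policy: str = "available_year"
    factor_method: str = "principal_axis"
    residual_scatters: bool = False
    verbosity: str = "INFO"

    def latent_spec(self) -> synthetic.LatentSpec:
        kwargs = dict(
            n=self.n,
            rel=tuple(self.rel),
            scenario=self.scenario,
            direct_effect=self.direct_effect,
            seed=self.seed,
        )
        if self.rho_true is not None:
            kwargs["rho_true"] = tuple(map(tuple, self.rho_true))
        return synthetic.LatentSpec(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analyze_derived(
    derived: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    missing_policy: str = "listwise",
) -> dict:
    """Run the full triad analysis on a derived-variables table -> report dict."""
    triad = analysis.correlation_triad(derived, policy=missing_policy)
    effects = analysis.adjusted_effects_all(derived, B=B, seed=seed)
    diff = analysis.difference_score_regression(derived, B=B, seed=seed)
    verdict = analysis.adjudicate(effects, diff)
    return {
        "n_analysis": effects.n_analysis,
        "correlations": {
            "seb_ca": triad.r_sc,
            "seb_edu": triad.r_sd,
            "ca_edu": triad.r_cd,
            "n": triad.n,
        },
        "adjusted_effects": effects.to_records(),
        "ci_method": effects.ci_method,
        "difference_score": asdict(diff),
        "verdict": verdict.verdict,
        "evidence": verdict.evidence,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> derive -> analyze; write CSVs + report JSON.

    Returns the report document.  Every stochastic stage is seeded from
    ``config.seed``; rerunning an identical config reproduces the report
    exactly apart from the timestamp field.
    """
    logging.basicConfig(level=config.verbosity)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = []
    raw_path = outdir / "raw.csv"
    derived_path = outdir / "derived.csv"

    try:
        spec = config.latent_spec()
        battery = synthetic.BatterySpec(
            k=len(config.loadings) if config.loadings else 12,
            loadings=tuple(config.loadings or ()),
            seed=config.seed + 1,
        )
        income = synthetic.IncomeSpec(zero_fraction=config.zero_fraction, seed=config.seed + 2)
        probs = (
            config.degree_probs
            if config.degree_probs is not None
            else synthetic.DEFAULT_DEGREE_PROBS
        )
        raw = synthetic.generate_dataset(
            spec,
            battery=battery,
            income=income,
            degree_probs=probs,
            missing=config.missing,
            keep_truth=config.keep_truth,
        )
        raw.to_csv(raw_path, index=False)
        provenance.append({"stage": "simulate", "n_in": config.n, "n_out": len(raw)})
        log.info("simulate: wrote %d rows to %s", len(raw), raw_path)
    except (ValueError, KeyError) as err:
        raise StageError("simulate", str(err)) from err

    try:
        mcfg = measurement.MeasurementConfig(
            factor_method=config.factor_method,
            income_policy=config.income_policy,
        )
        truth_cols = [c for c in raw.columns if c.endswith("_true") or c.endswith("_obs")]
        derived = measurement.derive_variables(raw.drop(columns=truth_cols), config=mcfg)
        derived.to_csv(derived_path, index=False)
        n_complete = len(analysis.complete_cases(derived))
        provenance.append({"stage": "derive", "n_in": len(raw), "n_out": n_complete})
        log.info("derive: %d rows in, %d complete cases", len(raw), n_complete)
    except (ValueError, KeyError) as err:
        raise StageError("derive", str(err), snapshot=str(raw_path)) from err

    try:
        B = config.bootstrap if config.ci == "bootstrap" else 0
        report_body = analyze_derived(
            derived, B=B, seed=config.seed, missing_policy=config.missing_policy
        )
        if config.residual_scatters:
            for pair, adj in ((("ca", "edu"), "seb"), (("seb", "edu"), "ca"), (("seb", "ca"), "edu")):
                scat = analysis.residual_scatter(derived, pair, adj)
                scat.to_csv(outdir / f"residuals_{pair[0]}_{pair[1]}_adj_{adj}.csv", index=False)
        provenance.append(
            {"stage": "analyze", "n_in": len(derived), "n_out": report_body["n_analysis"]}
        )
    except (ValueError, KeyError) as err:
        raise StageError("analyze", str(err), snapshot=str(derived_path)) from err

    report = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "provenance": provenance,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **report_body,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    log.info("verdict: %s (n=%d)", report["verdict"], report["n_analysis"])
    return report
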