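"""Orchestration: simulate -> summary stats -> linear MR -> nonlinear MR -> MVreg.

A single validated configuration (YAML or dict) drives every arm; identical
configuration and seed give byte-identical report tables. Each arm can be
run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import mr as mrmod
from . import nonlinear as nl
from . import observational as obs
from . import sumstats as ss
from .simulate import (
    EffectShapeSpec,
    OutcomeSpec,
    categorize_exposure,
    simulate_cohort,
)

__all__ = ["RunConfig", "RunReport", "ConfigError", "StageError", "run_pipeline", "render_report"]

log = logging.getLogger("sleepmr")

ARMS = ("sumstats", "linear", "nonlinear", "observational")


class ConfigError(ValueError):
    """Invalid run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed."""


@dataclass
class RunConfig:
    seed: int
    n: int = 100_000
    panel_size: int = 78
    target_r2: float = 0.0069
    noise_sd: float = 1.1
    baseline_hours: float = 7.2
    confounder_effect_hours: float = 0.3
    strata: int = 5
    ivw_effects_model: str = "multiplicative-random"
    n_boot: int = 1000
    arms: tuple = ARMS
    outcomes: dict = field(default_factory=dict)  # name -> spec dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("seed is mandatory")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if self.n < 1000:
            raise ConfigError("n must be at least 1000")
        if not 0 < self.target_r2 < 1:
            raise ConfigError("target_r2 must be in (0, 1)")
        if self.strata < 2:
            raise ConfigError("strata must be >= 2")
        if self.ivw_effects_model not in {"fixed", "multiplicative-random"}:
            raise ConfigError("ivw_effects_model must be fixed or multiplicative-random")
        bad = [a for a in self.arms if a not in ARMS]
        if bad:
            raise ConfigError(f"unknown arms: {bad}")
        names = list(self.outcomes)
        if len(names) != len(set(names)):
            raise ConfigError("outcome names must be unique")
        if not self.outcomes:
            raise ConfigError("at least one outcome is required")
        for name, spec in self.outcomes.items():
            if spec.get("family") not in {"binary", "continuous"}:
                raise ConfigError(f"outcome {name!r}: family must be binary or continuous")
            shp = spec.get("shape", {})
            if shp.get("type", "null") not in {"null", "linear", "quadratic", "piecewise"}:
                raise ConfigError(f"outcome {name!r}: unknown shape")
            if spec["family"] == "binary":
                p = spec.get("prevalence")
                if p is None or not 0 < p < 1:
                    raise ConfigError(f"outcome {name!r}: prevalence must be in (0, 1)")

    def outcome_specs(self) -> dict[str, OutcomeSpec]:
        specs = {}
        for name, spec in self.outcomes.items():
            shp = spec.get("shape", {"type": "null"})
            shape = EffectShapeSpec(
                shp.get("type", "null"),
                shp.get("params", {}),
                shp.get("reference_hours", 8.0),
            )
            specs[name] = OutcomeSpec(
                family=spec["family"],
                shape=shape,
                prevalence=spec.get("prevalence"),
                confounder_effect=spec.get("confounder_effect", 0.3),
                mean=spec.get("mean", 3500.0),
                sd=spec.get("sd", 450.0),
            )
        return specs

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    provenance: dict
    linear: dict = field(default_factory=dict)        # outcome -> list of estimate dicts
    nonlinear: dict = field(default_factory=dict)     # outcome -> {strata, tests, pattern}
    observational: dict = field(default_factory=dict) # outcome -> {categories, midpoint, lrt}
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "linear": self.linear,
            "nonlinear": self.nonlinear,
            "observational": self.observational,
            "warnings": self.warnings,
        }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the requested analysis arms on one simulated cohort."""
    config.validate()
    report = RunReport(
        provenance={
            "config": config.to_dict(),
            "config_sha256": config.digest(),
            "seed": config.seed,
            "package_version": __version__,
        }
    )
    try:
        log.info("simulating cohort n=%d seed=%d", config.n, config.seed)
        from .simulate import make_panel

        panel = make_panel(k=config.panel_size, seed=config.seed)
        cohort = simulate_cohort(
            n=config.n,
            panel=panel,
            outcomes=config.outcome_specs(),
            confounder_effect=config.confounder_effect_hours,
            noise_sd=config.noise_sd,
            baseline=config.baseline_hours,
            target_r2=config.target_r2,
            seed=config.seed,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"simulate: {exc}") from exc

    hours, n_excluded = ss.exposure_qc(cohort.data["exposure_reported"].to_numpy())
    report.provenance["qc_excluded"] = n_excluded
    inc = ss.orientation_from_panel(cohort.panel)
    grs = ss.build_grs(cohort.genotypes, inc)
    fam = {n: ("logistic" if s["family"] == "binary" else "linear")
           for n, s in config.outcomes.items()}

    split = None
    if "sumstats" in config.arms or "linear" in config.arms:
        try:
            traits = {
                name: (cohort.data[name].to_numpy(), fam[name])
                for name in config.outcomes
            }
            split = ss.split_crossover(
                cohort.genotypes, hours, traits, panel=cohort.panel, seed=config.seed + 1
            )
        except Exception as exc:
            raise StageError(f"sumstats: {exc}") from exc

    if "linear" in config.arms:
        for name in config.outcomes:
            try:
                rows = []
                crossed = []
                for exp_half, out_half in (("A", "B"), ("B", "A")):
                    hset = ss.harmonize(split[exp_half]["exposure"], split[out_half][name])
                    est = mrmod.ivw(hset, config.ivw_effects_model)
                    crossed.append(est)
                    rows.append({"direction": f"{exp_half}->{out_half}", **est.to_dict()})
                    rows.append({"direction": f"{exp_half}->{out_half}", **mrmod.mr_egger(hset).to_dict()})
                    rows.append(
                        {"direction": f"{exp_half}->{out_half}",
                         **mrmod.weighted_median(hset, config.n_boot, config.seed + 2).to_dict()}
                    )
                meta = mrmod.meta_fixed(
                    [e.beta for e in crossed], [e.se for e in crossed]
                )
                rows.append(
                    {
                        "direction": "meta",
                        "method": "ivw_meta_fixed",
                        "beta": meta.beta,
                        "se": meta.se,
                        "ci_low": meta.beta - 1.959963984540054 * meta.se,
                        "ci_high": meta.beta + 1.959963984540054 * meta.se,
                        "pval": meta.pval,
                        "k": crossed[0].k,
                        "q": meta.q_between,
                        "q_pval": meta.q_between_pval,
                    }
                )
                hset_ab = ss.harmonize(split["A"]["exposure"], split["B"][name])
                for sid, est in mrmod.leave_one_out(hset_ab, config.ivw_effects_model):
                    rows.append({"direction": "A->B", "omitted": sid, **est.to_dict()})
                report.linear[name] = rows
            except Exception as exc:
                raise StageError(f"linear MR[{name}]: {exc}") from exc

    if "nonlinear" in config.arms:
        try:
            residual, _ = nl.residual_exposure(hours, grs)
            assignment = nl.stratify(residual, k=config.strata)
        except Exception as exc:
            raise StageError(f"nonlinear MR: {exc}") from exc
        for name in config.outcomes:
            try:
                estimates = nl.stratum_wald(
                    grs, hours, cohort.data["exposure_reported"].to_numpy(),
                    assignment, cohort.data[name].to_numpy(),
                    family=fam[name], residual=residual,
                )
                q, df, qp = nl.heterogeneity_across_strata(estimates)
                slope, se_s, p_s = nl.nonlinearity_metareg(estimates)
                const = nl.iv_constancy(estimates)
                linear_est = None
                if name in report.linear:
                    meta_row = next(r for r in report.linear[name] if r.get("method") == "ivw_meta_fixed")
                    linear_est = mrmod.MrEstimate(
                        "ivw_meta_fixed", meta_row["beta"], meta_row["se"],
                        meta_row["ci_low"], meta_row["ci_high"], meta_row["pval"], meta_row["k"],
                    )
                pattern = nl.classify_pattern(estimates, linear_est)
                report.nonlinear[name] = {
                    "strata": [e.to_dict() for e in estimates],
                    "q_across": q, "q_df": df, "q_pval": qp,
                    "metareg_slope": slope, "metareg_se": se_s, "metareg_pval": p_s,
                    "iv_constancy": const,
                    "pattern": pattern,
                }
            except ValueError as exc:
                report.warnings.append(f"nonlinear MR[{name}]: {exc}")
                report.nonlinear[name] = {"error": str(exc)}
            except Exception as exc:
                raise StageError(f"nonlinear MR[{name}]: {exc}") from exc

    if "observational" in config.arms:
        category = categorize_exposure(ss.exposure_qc(cohort.data["exposure_reported"].to_numpy())[0])
        conf = cohort.data["confounder"].to_numpy()
        for name in config.outcomes:
            try:
                catfit = obs.fit_categorical_model(
                    cohort.data[name].to_numpy(), category, conf, fam[name]
                )
                midfit = obs.fit_midpoint_model(
                    cohort.data[name].to_numpy(), category, conf, fam[name]
                )
                stat, df, p = obs.lrt_nonlinearity(catfit, midfit)
                report.observational[name] = {
                    "categories": catfit.effects,
                    "midpoint": {
                        "beta": midfit.beta, "se": midfit.se,
                        "ci_low": midfit.ci_low, "ci_high": midfit.ci_high, "pval": midfit.pval,
                    },
                    "lrt": {"statistic": stat, "df": df, "pval": p},
                    "n": catfit.n,
                }
            except ValueError as exc:
                report.warnings.append(f"observational[{name}]: {exc}")
                report.observational[name] = {"error": str(exc)}
            except Exception as exc:
                raise StageError(f"observational[{name}]: {exc}") from exc

    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _format_or(beta: float, lo: float, hi: float) -> str:
    return f"{np.exp(beta):.2f} ({np.exp(lo):.2f}, {np.exp(hi):.2f})"


def render_report(report: RunReport, outdir: str, formats: tuple = ("tsv", "json", "markdown")) -> list[str]:
    """Write report tables; returns the paths written.

    ``json`` mirrors the full report; ``tsv`` holds one row per outcome and
    method; ``markdown`` presents ORs with 95% CIs for binary outcomes.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    written = []
    d = report.to_dict()
    if "json" in formats:
        path = os.path.join(outdir, "report.json")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True, default=float)
        written.append(path)
    rows = []
    for outcome, entries in report.linear.items():
        for r in entries:
            rows.append({"outcome": outcome, "arm": "linear", **{k: r.get(k) for k in
                        ("direction", "method", "omitted", "beta", "se", "ci_low", "ci_high",
                         "pval", "k", "q", "q_pval")}})
    for outcome, res in report.nonlinear.items():
        for srow in res.get("strata", []):
            rows.append({"outcome": outcome, "arm": "nonlinear", "method": f"stratum_{srow['stratum']}",
                         "beta": srow["beta_iv"], "se": srow["se_iv"],
                         "ci_low": srow["ci_low"], "ci_high": srow["ci_high"], "pval": srow["pval"]})
    if "tsv" in formats and rows:
        path = os.path.join(outdir, "report.tsv")
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)
    if "markdown" in formats:
        path = os.path.join(outdir, "report.md")
        lines = ["# sleepmr run report", "",
                 f"seed: {report.provenance['seed']}  config: {report.provenance['config_sha256']}", ""]
        for outcome, entries in report.linear.items():
            lines += [f"## {outcome} — linear MR", "",
                      "| method | direction | OR or beta (95% CI) | p |", "|---|---|---|---|"]
            for r in entries:
                if "omitted" in r and r.get("omitted"):
                    continue
                lines.append(
                    f"| {r['method']} | {r['direction']} | "
                    f"{_format_or(r['beta'], r['ci_low'], r['ci_high'])} | {r['pval']:.3g} |"
                )
            lines.append("")
        for outcome, res in report.nonlinear.items():
            if "pattern" in res:
                lines += [f"## {outcome} — nonlinear MR", "",
                          f"pattern: **{res['pattern']}**; "
                          f"Q = {res['q_across']:.2f} (p = {res['q_pval']:.3g}); "
                          f"meta-regression slope = {res['metareg_slope']:.4f} "
                          f"(p = {res['metareg_pval']:.3g})", ""]
        lines.append("No multiple-testing adjustment applied; conventional 0.05 thresholds.")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        written.append(path)
    return written
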