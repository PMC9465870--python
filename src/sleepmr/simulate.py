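"""Synthetic pregnancy-cohort generator.

Produces individual-level cohorts with the statistical structure the MR
analysis assumes: an independent biallelic instrument panel (default 78
SNPs jointly explaining ~0.69% of exposure variance), integer-reported
sleep hours, a shared confounder of exposure and outcomes, rare binary
outcomes with configurable exposure-risk shapes (null / linear / quadratic /
piecewise), continuous birthweight, optionally fetal genotypes transmitted
from mothers, and questionnaire-style sleep-duration categories. Every
cohort carries its generating parameters so recovery tests have known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "EffectShapeSpec",
    "OutcomeSpec",
    "SimulatedCohort",
    "make_panel",
    "validate_panel",
    "simulate_genotypes",
    "simulate_fetal_genotypes",
    "simulate_exposure",
    "simulate_outcomes",
    "categorize_exposure",
    "impose_missingness",
    "simulate_cohort",
    "write_cohort",
    "CATEGORY_LABELS",
]

PANEL_COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta_exposure"]

#: Questionnaire reporting categories (the two shortest source categories are
#: merged into "<=5" because of small numbers).
CATEGORY_LABELS = ["<=5", "6-7", "8-9", ">=10"]

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# instrument panel
# ---------------------------------------------------------------------------

def make_panel(
    k: int = 78,
    eaf_range: tuple[float, float] = (0.05, 0.95),
    beta_magnitude: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Instrument panel of ``k`` independent biallelic SNPs.

    Per-SNP true effects on sleep duration have equal magnitude and random
    sign (only the aggregate variance explained is identified from the
    source data); :func:`simulate_exposure` rescales them to the target R^2.
    """
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(*eaf_range, size=k)
    beta = beta_magnitude * rng.choice([-1.0, 1.0], size=k)
    ea_idx = rng.integers(0, 4, size=k)
    shift = rng.integers(1, 4, size=k)  # any base different from the effect allele
    oa_idx = (ea_idx + shift) % 4
    panel = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:04d}" for i in range(k)],
            "effect_allele": _BASES[ea_idx],
            "other_allele": _BASES[oa_idx],
            "eaf": eaf,
            "beta_exposure": beta,
        }
    )
    validate_panel(panel)
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel missing columns: {missing}")
    if len(panel) == 0:
        raise ValueError("panel is empty")
    eaf = panel["eaf"].to_numpy(dtype=float)
    if not np.all(np.isfinite(eaf)) or np.any(eaf <= 0.0) or np.any(eaf >= 1.0):
        raise ValueError("eaf must be finite and strictly inside (0, 1)")
    if panel["snp_id"].duplicated().any():
        raise ValueError("snp_ids must be unique")
    same = panel["effect_allele"].to_numpy() == panel["other_allele"].to_numpy()
    if same.any():
        raise ValueError("effect and other allele must differ")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    panel: pd.DataFrame, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Hardy-Weinberg dosages: each entry is the sum of two Bernoulli(eaf) draws."""
    validate_panel(panel)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eaf = panel["eaf"].to_numpy(dtype=float)
    return rng.binomial(2, eaf, size=(n, len(panel))).astype(np.int8)


def simulate_fetal_genotypes(
    maternal: np.ndarray, panel: pd.DataFrame, seed: int | np.random.Generator
) -> np.ndarray:
    """Fetal dosage = one allele transmitted from the mother + one population allele.

    The maternal transmission is Bernoulli(maternal_dosage / 2); the paternal
    allele is drawn from the population at the panel frequency, which gives
    the expected mother-child dosage correlation of 0.5.
    """
    validate_panel(panel)
    maternal = np.asarray(maternal)
    if maternal.ndim != 2 or maternal.shape[1] != len(panel):
        raise ValueError("maternal genotype matrix does not match the panel")
    if not np.isin(maternal, (0, 1, 2)).all():
        raise ValueError("maternal dosages must be in {0, 1, 2}")
    rng = np.random.default_rng(seed)
    transmitted = rng.binomial(1, maternal / 2.0)
    paternal = rng.binomial(1, panel["eaf"].to_numpy(dtype=float), size=maternal.shape)
    return (transmitted + paternal).astype(np.int8)


# ---------------------------------------------------------------------------
# exposure
# ---------------------------------------------------------------------------

@dataclass
class ExposureResult:
    exposure_true: np.ndarray
    exposure_reported: np.ndarray
    betas_used: np.ndarray          # per-SNP effects after R^2 rescaling
    grs_variance_explained: float   # realized sample R^2 of exposure_true on the score


def simulate_exposure(
    genotypes: np.ndarray,
    panel: pd.DataFrame,
    confounder: np.ndarray | None = None,
    confounder_effect: float = 0.0,
    noise_sd: float = 1.1,
    baseline: float = 7.2,
    target_r2: float | None = 0.0069,
    seed: int | np.random.Generator = 0,
) -> ExposureResult:
    """Sleep-duration exposure: additive genetic + confounder + Gaussian noise.

    When ``target_r2`` is given the per-SNP effects are rescaled so the
    genetic component explains that fraction of total exposure variance
    (default 0.69%, the variance the 78-SNP panel explains in the source
    GWAS). Reported hours are the true hours rounded to the nearest integer
    and clipped to [1, 23]; implausible values are *retained* here and only
    removed by the QC step, mirroring the study's pipeline.
    """
    validate_panel(panel)
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if target_r2 is not None and target_r2 >= 1:
        raise ValueError("target_r2 must be < 1")
    rng = np.random.default_rng(seed)
    G = np.asarray(genotypes, dtype=float)
    n = G.shape[0]
    betas = panel["beta_exposure"].to_numpy(dtype=float).copy()
    if confounder is None:
        confounder = np.zeros(n)
    confounder = np.asarray(confounder, dtype=float)

    if target_r2 is not None and target_r2 > 0:
        # population variance of the genetic component under HWE
        eaf = panel["eaf"].to_numpy(dtype=float)
        var_g = float(np.sum(betas**2 * 2 * eaf * (1 - eaf)))
        if var_g <= 0:
            raise ValueError("cannot rescale a panel with no genetic effect")
        var_rest = confounder_effect**2 * (float(np.var(confounder)) if confounder.size else 0.0)
        var_rest += noise_sd**2
        scale = np.sqrt(target_r2 * var_rest / ((1.0 - target_r2) * var_g))
        betas *= scale

    genetic = G @ betas
    exposure_true = baseline + genetic + confounder_effect * confounder + rng.normal(0.0, noise_sd, n)
    reported = np.clip(np.rint(exposure_true), 1, 23)

    var_gen = float(np.var(genetic))
    r2 = var_gen / float(np.var(exposure_true)) if var_gen > 0 else 0.0
    return ExposureResult(exposure_true, reported, betas, r2)


# ---------------------------------------------------------------------------
# outcome shapes
# ---------------------------------------------------------------------------

@dataclass
class EffectShapeSpec:
    """Exposure-outcome link shape on the log-odds (binary) or mean scale.

    ``f(reference_hours) == 0`` for every shape, so effects are risk shifts
    relative to the reference exposure.

    shapes and parameters:
      * ``null`` -- no parameters
      * ``linear`` -- ``slope`` per hour
      * ``quadratic`` -- ``curvature`` b, f(x) = b (x - ref)^2 (U-shape for b>0)
      * ``piecewise`` -- ``breakpoints`` (strictly increasing) and ``slopes``
        (one per segment), continuous, anchored to 0 at the reference
    """

    shape: str
    params: Mapping[str, object] = field(default_factory=dict)
    reference_hours: float = 8.0

    def __post_init__(self) -> None:
        if self.shape not in {"null", "linear", "quadratic", "piecewise"}:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "linear" and "slope" not in self.params:
            raise ValueError("linear shape needs a 'slope' parameter")
        if self.shape == "quadratic":
            b = self.params.get("curvature")
            if b is None or not np.isfinite(b):
                raise ValueError("quadratic shape needs finite 'curvature'")
        if self.shape == "piecewise":
            bp = np.asarray(self.params.get("breakpoints", ()), dtype=float)
            sl = np.asarray(self.params.get("slopes", ()), dtype=float)
            if bp.size + 1 != sl.size:
                raise ValueError("piecewise needs len(slopes) == len(breakpoints) + 1")
            if bp.size and np.any(np.diff(bp) <= 0):
                raise ValueError("breakpoints must be strictly increasing")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ref = self.reference_hours
        if self.shape == "null":
            return np.zeros_like(x)
        if self.shape == "linear":
            return float(self.params["slope"]) * (x - ref)
        if self.shape == "quadratic":
            return float(self.params["curvature"]) * (x - ref) ** 2
        # piecewise-linear: integrate the segment slopes from ref to x
        bp = np.asarray(self.params.get("breakpoints", ()), dtype=float)
        sl = np.asarray(self.params["slopes"], dtype=float)
        knots = np.concatenate([[-1e9], bp, [1e9]])

        def antideriv(v: np.ndarray) -> np.ndarray:
            out = np.zeros_like(v)
            for i in range(sl.size):
                lo, hi = knots[i], knots[i + 1]
                seg = np.clip(v, lo, hi) - np.clip(ref, lo, hi)
                out += sl[i] * seg
            return out

        return antideriv(x)


@dataclass
class OutcomeSpec:
    """One outcome's generative model."""

    family: str  # "binary" or "continuous"
    shape: EffectShapeSpec
    prevalence: float | None = None       # binary only, marginal target
    confounder_effect: float = 0.3        # log-odds (binary) or units (continuous) per confounder SD
    mean: float = 3500.0                  # continuous only (grams)
    sd: float = 450.0                     # continuous residual SD

    def __post_init__(self) -> None:
        if self.family not in {"binary", "continuous"}:
            raise ValueError(f"unknown outcome family {self.family!r}")
        if self.family == "binary":
            if self.prevalence is None or not 0.0 < self.prevalence < 1.0:
                raise ValueError("binary outcomes need prevalence in (0, 1)")


def _solve_intercept(offset: np.ndarray, prevalence: float, tol: float = 1e-4) -> float:
    """Bisection for the logistic intercept hitting a marginal prevalence."""
    lo, hi = -40.0, 20.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        p = float(np.mean(special.expit(mid + offset)))
        if abs(p - prevalence) < tol * max(prevalence, 1e-12):
            return mid
        if p < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_outcomes(
    exposure_true: np.ndarray,
    confounder: np.ndarray,
    specs: Mapping[str, OutcomeSpec],
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw all outcomes given the true exposure and the shared confounder."""
    rng = np.random.default_rng(seed)
    x = np.asarray(exposure_true, dtype=float)
    u = np.asarray(confounder, dtype=float)
    cols = {}
    for name, spec in specs.items():
        lin = spec.shape.evaluate(x) + spec.confounder_effect * u
        if spec.family == "binary":
            alpha = _solve_intercept(lin, spec.prevalence)
            p = special.expit(alpha + lin)
            cols[name] = rng.binomial(1, p).astype(float)
        else:
            cols[name] = spec.mean + lin + rng.normal(0.0, spec.sd, x.shape[0])
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# reporting categories / missingness
# ---------------------------------------------------------------------------

def categorize_exposure(reported: np.ndarray | pd.Series) -> pd.Series:
    """Map integer reported hours to the four reporting categories.

    <=5 / 6-7 / 8-9 / >=10 hours per day; missing propagates as missing.
    """
    values = pd.Series(np.asarray(reported, dtype=float))
    finite = values.dropna()
    if len(finite) and not np.allclose(finite, np.rint(finite)):
        raise ValueError("reported hours must be integers where present")
    bins = [-np.inf, 5.5, 7.5, 9.5, np.inf]
    cat = pd.cut(values, bins=bins, labels=CATEGORY_LABELS)
    return cat.astype(object).where(values.notna(), other=np.nan)


def impose_missingness(
    data: pd.DataFrame,
    rates: Mapping[str, float],
    mechanism: str = "MCAR",
    driver: str | np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Blank out entries of the named columns at the requested rates.

    MCAR deletes uniformly at random. MAR deletes with probability logistic
    in a fully observed driving covariate (slope 1 per driver SD, intercept
    solved so the marginal rate matches).
    """
    if mechanism not in {"MCAR", "MAR"}:
        raise ValueError("mechanism must be MCAR or MAR")
    for col, r in rates.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"rate for {col!r} must be in [0, 1)")
        if col not in data.columns:
            raise ValueError(f"unknown column {col!r}")
    rng = np.random.default_rng(seed)
    out = data.copy()
    n = len(data)
    if mechanism == "MAR":
        if driver is None:
            raise ValueError("MAR mechanism needs a driving covariate")
        z = out[driver].to_numpy(dtype=float) if isinstance(driver, str) else np.asarray(driver, dtype=float)
        if np.isnan(z).any():
            raise ValueError("MAR driver must be fully observed")
        z = (z - z.mean()) / (z.std() or 1.0)
    for col, r in rates.items():
        if r == 0.0:
            continue
        if mechanism == "MCAR":
            mask = rng.random(n) < r
        else:
            alpha = _solve_intercept(z, r, tol=1e-6)
            mask = rng.random(n) < special.expit(alpha + z)
        out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# whole-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Individual-level cohort with known generating parameters."""

    panel: pd.DataFrame
    genotypes: np.ndarray
    data: pd.DataFrame                      # exposure, confounder, covariates, outcomes
    truth: dict
    fetal_genotypes: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.data)


def simulate_cohort(
    n: int = 100_000,
    panel: pd.DataFrame | None = None,
    outcomes: Mapping[str, OutcomeSpec] | None = None,
    confounder_effect: float = 0.3,
    noise_sd: float = 1.1,
    baseline: float = 7.2,
    target_r2: float | None = 0.0069,
    with_fetal: bool = False,
    seed: int = 0,
) -> SimulatedCohort:
    """End-to-end cohort draw with default study-like settings.

    Defaults: 78-SNP panel explaining 0.69% of exposure variance, mean
    reported duration ~7.2 h/day with SD ~1.1 h, a standard-Gaussian
    composite confounder shifting exposure by ``confounder_effect`` hours
    per SD, and a maternal-age covariate with no true effect.
    """
    ss = np.random.SeedSequence(seed)
    r_panel, r_geno, r_conf, r_exp, r_out, r_fetal, r_age = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]
    if panel is None:
        panel = make_panel(seed=r_panel)
    genotypes = simulate_genotypes(panel, n, r_geno)
    confounder = r_conf.normal(0.0, 1.0, n)
    exp = simulate_exposure(
        genotypes,
        panel,
        confounder=confounder,
        confounder_effect=confounder_effect,
        noise_sd=noise_sd,
        baseline=baseline,
        target_r2=target_r2,
        seed=r_exp,
    )
    if outcomes is None:
        outcomes = {
            "low_birthweight": OutcomeSpec(
                family="binary",
                shape=EffectShapeSpec("quadratic", {"curvature": 0.05}, reference_hours=8.0),
                prevalence=0.05,
            ),
            "birthweight": OutcomeSpec(
                family="continuous",
                shape=EffectShapeSpec("null"),
                confounder_effect=30.0,
            ),
        }
    ycols = simulate_outcomes(exp.exposure_true, confounder, outcomes, r_out)
    data = pd.DataFrame(
        {
            "exposure_true": exp.exposure_true,
            "exposure_reported": exp.exposure_reported,
            "confounder": confounder,
            "age": r_age.normal(30.0, 4.0, n),
        }
    )
    data = pd.concat([data, ycols], axis=1)
    fetal = simulate_fetal_genotypes(genotypes, panel, r_fetal) if with_fetal else None
    truth = {
        "seed": seed,
        "n": n,
        "target_r2": target_r2,
        "realized_r2_true_exposure": exp.grs_variance_explained,
        "betas_used": exp.betas_used.tolist(),
        "confounder_effect_exposure": confounder_effect,
        "noise_sd": noise_sd,
        "baseline_hours": baseline,
        "outcomes": {
            name: {
                "family": s.family,
                "shape": s.shape.shape,
                "params": dict(s.shape.params),
                "reference_hours": s.shape.reference_hours,
                "prevalence": s.prevalence,
                "confounder_effect": s.confounder_effect,
            }
            for name, s in outcomes.items()
        },
    }
    return SimulatedCohort(panel, genotypes, data, truth, fetal)


def write_cohort(cohort: SimulatedCohort, prefix: str, include_genotypes: bool = True) -> None:
    """Write the cohort as CSV (missing = empty field) + JSON truth sidecar."""
    tab = cohort.data.copy()
    if include_genotypes:
        geno = pd.DataFrame(
            cohort.genotypes, columns=[f"g_{s}" for s in cohort.panel["snp_id"]]
        )
        tab = pd.concat([tab.reset_index(drop=True), geno], axis=1)
    tab.to_csv(f"{prefix}.csv", index=False)
    cohort.panel.to_csv(f"{prefix}.panel.tsv", sep="\t", index=False)
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=2, sort_keys=True)
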