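"""Residual-stratification nonlinear MR.

Stratifying directly on the exposure would condition on a collider (the
exposure is downstream of both the instrument and the confounders), biasing
within-stratum IV estimates. Instead the sample is stratified on "residual"
exposure — observed duration minus the mean-centred genetic contribution of
the risk score — which is independent of the instrument by construction.
Within each stratum a Wald-ratio estimate (GRS as single instrument) gives
the local effect per 1 h/day; differences across strata are tested with
Cochran's Q and with meta-regression of the stratum estimates on the
stratum mean of observed duration, and the profile of stratum estimates is
classified into a qualitative pattern (U-shaped, reverse-J, linear, null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._batchreg import batched_linear, batched_logistic
from .mr import MrEstimate

__all__ = [
    "StratumEstimate",
    "NonlinearityResult",
    "residual_exposure",
    "stratify",
    "stratum_wald",
    "heterogeneity_across_strata",
    "nonlinearity_metareg",
    "iv_constancy",
    "classify_pattern",
    "DEFAULT_PATTERN_RULES",
    "plot_forest",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class StratumEstimate:
    stratum: int
    boundaries: tuple[float, float]    # residual-hours interval covered
    n: int
    mean_exposure: float               # mean observed (reported) hours
    grs_beta: float                    # within-stratum GRS->exposure slope (h/allele)
    grs_se: float
    beta_iv: float                     # causal effect per 1 h/day
    se_iv: float
    ci_low: float
    ci_high: float
    pval: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class NonlinearityResult:
    q_across: float
    q_df: int
    q_pval: float
    metareg_slope: float
    metareg_se: float
    metareg_pval: float
    iv_constancy: dict
    pattern: str

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# residualization and stratification
# ---------------------------------------------------------------------------

def residual_exposure(
    exposure: np.ndarray,
    grs: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Residual duration: observed hours minus the mean-centred genetic contribution.

    Fits exposure ~ GRS (+ covariates) on complete rows; the genetic
    contribution g_i = grs_i * beta is centred before subtraction, so the
    residual keeps the observed mean. Missing exposures yield missing
    residuals.
    """
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(grs, dtype=float)
    if np.var(z[~np.isnan(z)]) == 0:
        raise ValueError("genetic risk score has zero variance")
    keep = ~(np.isnan(x) | np.isnan(z))
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= ~np.isnan(C).any(axis=1)
        C = C[keep]
    res = batched_linear(z[keep, None], x[keep], C)
    beta = float(res["beta"][0])
    g = z * beta
    residual = np.where(keep, x - (g - np.nanmean(g[keep])), np.nan)
    return residual, beta


def stratify(
    residual: np.ndarray,
    k: int | None = None,
    boundaries: np.ndarray | None = None,
) -> np.ndarray:
    """Stratum assignment (0..k-1; -1 for missing residuals).

    Quantile scheme: stable rank-and-cut into k near-equal groups (ties are
    broken by original order, so group sizes differ by at most the tie
    count at the cut points). Fixed scheme: half-open intervals [lo, hi)
    defined by strictly increasing interior boundaries.
    """
    r = np.asarray(residual, dtype=float)
    present = ~np.isnan(r)
    assignment = np.full(r.shape[0], -1, dtype=int)
    if boundaries is not None:
        b = np.asarray(boundaries, dtype=float)
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("fixed boundaries must be strictly increasing")
        assignment[present] = np.digitize(r[present], b, right=False)
        return assignment
    if k is None:
        raise ValueError("either k or boundaries must be given")
    values = r[present]
    if values.size < k * 20:
        raise ValueError(f"quantile stratification into {k} needs at least {k * 20} values")
    if np.ptp(values) == 0:
        raise ValueError("residuals are degenerate (all identical)")
    order = np.argsort(values, kind="stable")
    cuts = (np.arange(1, k) * values.size) // k
    groups = np.empty(values.size, dtype=int)
    groups[order] = np.searchsorted(cuts, np.arange(values.size), side="right")
    assignment[present] = groups
    return assignment


# ---------------------------------------------------------------------------
# per-stratum Wald estimation
# ---------------------------------------------------------------------------

def stratum_wald(
    grs: np.ndarray,
    exposure: np.ndarray,
    reported_hours: np.ndarray,
    assignment: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "linear",
    residual: np.ndarray | None = None,
) -> list[StratumEstimate]:
    """Wald-ratio IV estimate within each residual stratum.

    Per stratum: GRS->exposure slope from a linear fit, GRS->outcome slope
    from a logistic (binary) or linear (continuous) fit, causal effect =
    outcome slope / exposure slope with first-order delta SE. The stratum's
    mean exposure is the mean *observed reported* hours (the quantity the
    stratum estimates are regressed on downstream). Strata with no cases
    yield a missing estimate and a warning, not an error.
    """
    z = np.asarray(grs, dtype=float)
    x = np.asarray(exposure, dtype=float)
    rep = np.asarray(reported_hours, dtype=float)
    a = np.asarray(assignment)
    y = np.asarray(outcome, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    res_vals = np.asarray(residual, dtype=float) if residual is not None else None
    out: list[StratumEstimate] = []
    strata = sorted(int(s) for s in np.unique(a) if s >= 0)
    for s in strata:
        m = a == s
        keep = m & ~(np.isnan(z) | np.isnan(x) | np.isnan(y))
        if C is not None:
            keep &= ~np.isnan(C).any(axis=1)
        Cs = None if C is None else C[keep]
        zs, xs, ys = z[keep], x[keep], y[keep]
        if res_vals is not None:
            inb = res_vals[m & ~np.isnan(res_vals)]
            bounds = (float(inb.min()), float(inb.max())) if inb.size else (np.nan, np.nan)
        else:
            bounds = (np.nan, np.nan)
        mean_exp = float(np.nanmean(rep[m])) if np.any(~np.isnan(rep[m])) else np.nan
        gfit = batched_linear(zs[:, None], xs, Cs)
        g_beta, g_se = float(gfit["beta"][0]), float(gfit["se"][0])
        try:
            if family in {"logistic", "binary"}:
                ofit = batched_logistic(zs[:, None], ys, Cs)
            else:
                ofit = batched_linear(zs[:, None], ys, Cs)
            o_beta, o_se = float(ofit["beta"][0]), float(ofit["se"][0])
        except ValueError as exc:
            warnings.warn(f"stratum {s}: {exc}; estimate set missing", stacklevel=2)
            out.append(
                StratumEstimate(s, bounds, int(keep.sum()), mean_exp, g_beta, g_se,
                                np.nan, np.nan, np.nan, np.nan, np.nan)
            )
            continue
        beta_iv = o_beta / g_beta
        se_iv = o_se / abs(g_beta)
        zstat = beta_iv / se_iv if se_iv > 0 else np.nan
        out.append(
            StratumEstimate(
                s, bounds, int(keep.sum()), mean_exp, g_beta, g_se,
                float(beta_iv), float(se_iv),
                float(beta_iv - _Z95 * se_iv), float(beta_iv + _Z95 * se_iv),
                float(2 * stats.norm.sf(abs(zstat))) if np.isfinite(zstat) else np.nan,
            )
        )
    return out


def _usable(estimates: list[StratumEstimate], attr_beta: str, attr_se: str):
    b = np.array([getattr(e, attr_beta) for e in estimates], dtype=float)
    s = np.array([getattr(e, attr_se) for e in estimates], dtype=float)
    x = np.array([e.mean_exposure for e in estimates], dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    return b[ok], s[ok], x[ok]


def heterogeneity_across_strata(estimates: list[StratumEstimate]) -> tuple[float, int, float]:
    """Cochran's Q of the stratum IV estimates against their pooled value."""
    b, s, _ = _usable(estimates, "beta_iv", "se_iv")
    if b.size < 2:
        raise ValueError("need at least 2 strata with finite estimates")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    return q, df, float(stats.chi2.sf(q, df))


def _metareg(b: np.ndarray, s: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    if b.size < 3:
        raise ValueError("meta-regression needs at least 3 strata")
    if np.ptp(x) == 0:
        raise ValueError("no variation in stratum mean exposure")
    w = 1.0 / s**2
    sw = w.sum()
    xbar = np.sum(w * x) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * b) / sxx)
    se = float(np.sqrt(1.0 / sxx))
    z = slope / se
    return slope, se, float(2 * stats.norm.sf(abs(z)))


def nonlinearity_metareg(estimates: list[StratumEstimate]) -> tuple[float, float, float]:
    """WLS of stratum IV estimates on stratum mean duration (weights 1/se^2).

    A non-zero slope is evidence against a constant (linear or null) effect
    per hour; under a quadratic dose-response with curvature b the slope
    approaches 2b (the derivative of the quadratic is linear in duration).
    """
    b, s, x = _usable(estimates, "beta_iv", "se_iv")
    return _metareg(b, s, x)


def iv_constancy(estimates: list[StratumEstimate]) -> dict:
    """Constancy of the GRS-duration association across strata.

    The residual-stratification design assumes the instrument-exposure
    association is the same in every stratum; this applies the same Q and
    meta-regression machinery to the per-stratum GRS slopes.
    """
    b, s, x = _usable(estimates, "grs_beta", "grs_se")
    if b.size < 2:
        raise ValueError("need at least 2 strata with finite GRS slopes")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = b.size - 1
    result = {"q": q, "q_df": df, "q_pval": float(stats.chi2.sf(q, df))}
    if b.size >= 3 and np.ptp(x) > 0:
        slope, se, p = _metareg(b, s, x)
        result.update({"metareg_slope": slope, "metareg_se": se, "metareg_pval": p})
    else:
        result.update({"metareg_slope": np.nan, "metareg_se": np.nan, "metareg_pval": np.nan})
    return result


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

#: Rule table for qualitative effect patterns, applied in order; the first
#: matching rule wins. Keys: sign required of the lowest / highest stratum
#: ("-", "0", "+", or "any"), of all middle strata ("0" = none significant,
#: "any"), and of the overall linear two-sample estimate. Signs are CI-based:
#: "+" means the 95% CI lies entirely above the null, "-" entirely below,
#: "0" means the CI spans the null. Effects are per +1 h/day, so a negative
#: lowest-stratum effect means more sleep is protective there (short
#: duration harmful) and a positive highest-stratum effect means long
#: duration harmful.
DEFAULT_PATTERN_RULES: list[dict] = [
    {"label": "U-shaped (short and long harmful)", "lowest": "-", "highest": "+", "middle": "any", "linear": "any"},
    {"label": "reverse-J (short harmful)", "lowest": "-", "highest": "0", "middle": "0", "linear": "any"},
    {"label": "J (long harmful)", "lowest": "0", "highest": "+", "middle": "0", "linear": "any"},
    {"label": "linear-positive", "lowest": "+", "highest": "+", "middle": "any", "linear": "any"},
    {"label": "linear-negative", "lowest": "-", "highest": "-", "middle": "any", "linear": "any"},
    {"label": "linear-positive", "lowest": "0", "highest": "0", "middle": "0", "linear": "+"},
    {"label": "linear-negative", "lowest": "0", "highest": "0", "middle": "0", "linear": "-"},
    {"label": "null", "lowest": "0", "highest": "0", "middle": "0", "linear": "0"},
]


def _ci_sign(lo: float, hi: float) -> str:
    if not (np.isfinite(lo) and np.isfinite(hi)):
        return "missing"
    if lo > 0:
        return "+"
    if hi < 0:
        return "-"
    return "0"


def classify_pattern(
    estimates: list[StratumEstimate],
    linear_estimate: MrEstimate | None = None,
    rules: list[dict] | None = None,
) -> str:
    """Qualitative label for the profile of stratum estimates.

    Combines CI-based signs of the lowest stratum, highest stratum, middle
    strata and the overall linear MR estimate through the (configurable)
    rule table; anything unmatched, or any missing stratum estimate, is
    "inconclusive".
    """
    rules = DEFAULT_PATTERN_RULES if rules is None else rules
    if len(estimates) < 2:
        return "inconclusive"
    signs = [_ci_sign(e.ci_low, e.ci_high) for e in sorted(estimates, key=lambda e: e.stratum)]
    if "missing" in signs:
        return "inconclusive"
    lowest, highest = signs[0], signs[-1]
    middle = signs[1:-1]
    if linear_estimate is None:
        lin = "0"
    else:
        lin = _ci_sign(linear_estimate.ci_low, linear_estimate.ci_high)

    def match(required: str, actual: str) -> bool:
        return required == "any" or required == actual

    def match_mid(required: str) -> bool:
        if required == "any":
            return True
        return all(s == required for s in middle)

    for rule in rules:
        if (
            match(rule["lowest"], lowest)
            and match(rule["highest"], highest)
            and match_mid(rule["middle"])
            and match(rule["linear"], lin)
        ):
            return rule["label"]
    return "inconclusive"


def plot_forest(estimates: list[StratumEstimate], path: str, title: str = "") -> None:
    """Forest-style plot of stratum IV estimates against stratum mean duration."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    x = [e.mean_exposure for e in estimates]
    y = [e.beta_iv for e in estimates]
    lo = [e.beta_iv - e.ci_low for e in estimates]
    hi = [e.ci_high - e.beta_iv for e in estimates]
    ax.errorbar(x, y, yerr=[lo, hi], fmt="o", capsize=3)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("stratum mean sleep duration (h/day)")
    ax.set_ylabel("effect per 1 h/day")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
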