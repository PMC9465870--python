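"""Linear two-sample MR estimators on harmonized summary statistics.

Implements the Wald ratio, inverse-variance-weighted (IVW) estimation in
its zero-intercept weighted-regression form (with fixed or multiplicative
random effects), MR-Egger with its pleiotropy intercept, the weighted
median with a parametric bootstrap SE, leave-one-out sensitivity analysis,
and fixed-effects inverse-variance meta-analysis with Cochran's Q.

All causal effects are per 1 h/day of sleep duration, on the log-odds
scale for binary outcomes and in grams for birthweight.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

__all__ = [
    "MrEstimate",
    "MetaResult",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "leave_one_out",
    "meta_fixed",
    "snp_subset",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MetaResult:
    beta: float
    se: float
    pval: float
    weights: np.ndarray      # normalized, sum to 1
    q_between: float
    q_between_pval: float


def _finish(method: str, beta: float, se: float, k: int, **kw) -> MrEstimate:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=float(2 * stats.norm.sf(abs(z))),
        k=k,
        **kw,
    )


def wald_ratio(
    beta_zx: float,
    se_zx: float,
    beta_zy: float,
    se_zy: float,
    second_order: bool = False,
) -> MrEstimate:
    """Single-instrument ratio estimate beta_zy / beta_zx.

    Default SE is the first-order delta approximation se_zy / |beta_zx|;
    ``second_order`` adds the instrument-association uncertainty term.
    """
    if beta_zx == 0:
        raise ZeroDivisionError("instrument-exposure association is zero")
    beta = beta_zy / beta_zx
    if second_order:
        se = np.sqrt(se_zy**2 / beta_zx**2 + beta_zy**2 * se_zx**2 / beta_zx**4)
    else:
        se = se_zy / abs(beta_zx)
    return _finish("wald_ratio", beta, se, k=1)


def _arrays(hset: HarmonizedInstrumentSet):
    t = hset.table
    return (
        t["beta_exposure"].to_numpy(float),
        t["se_exposure"].to_numpy(float),
        t["beta_outcome"].to_numpy(float),
        t["se_outcome"].to_numpy(float),
    )


def ivw(hset: HarmonizedInstrumentSet, effects_model: str = "multiplicative-random") -> MrEstimate:
    """Zero-intercept weighted regression of outcome on exposure associations.

    Weights are 1/se_zy^2; the slope equals the inverse-variance-weighted
    mean of per-SNP Wald ratios with weights beta_zx^2/se_zy^2. Under the
    multiplicative random-effects model (default) the SE is inflated by
    sqrt(max(1, Q/(k-1))).
    """
    if effects_model not in {"fixed", "multiplicative-random"}:
        raise ValueError("effects_model must be 'fixed' or 'multiplicative-random'")
    bx, _, by, sy = _arrays(hset)
    k = len(bx)
    if k == 0:
        raise ValueError("no SNPs in harmonized set")
    if np.any(sy <= 0):
        raise ValueError("all outcome SEs must be positive")
    w = bx**2 / sy**2
    if w.sum() == 0:
        raise ValueError("all instrument-exposure associations are zero")
    ratios = np.divide(by, bx, out=np.zeros_like(by), where=bx != 0)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    q_pval = float(stats.chi2.sf(q, k - 1)) if k >= 2 else None
    if effects_model == "multiplicative-random" and k >= 2:
        se *= np.sqrt(max(1.0, q / (k - 1)))
    return _finish("ivw_" + effects_model, beta, se, k, q=q, q_pval=q_pval)


def mr_egger(hset: HarmonizedInstrumentSet) -> MrEstimate:
    """Weighted regression with a free intercept (average directional pleiotropy).

    Exposure associations are oriented non-negative before fitting (the
    intercept is only interpretable under that convention), which makes the
    result invariant to the recorded allele orientation. SEs are inflated by
    sqrt(max(1, Q_egger/(k-2))).
    """
    bx, _, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    if np.ptp(bx) == 0:
        raise ValueError("no variation in instrument-exposure associations after orientation")
    w = 1.0 / sy**2
    sw = w.sum()
    xbar = np.sum(w * bx) / sw
    ybar = np.sum(w * by) / sw
    sxx = np.sum(w * (bx - xbar) ** 2)
    slope = float(np.sum(w * (bx - xbar) * (by - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (k - 2))
    se_slope = float(np.sqrt(scale / sxx))
    se_int = float(np.sqrt(scale * (1.0 / sw + xbar**2 / sxx)))
    zi = intercept / se_int
    return _finish(
        "mr_egger",
        slope,
        se_slope,
        k,
        q=q,
        q_pval=float(stats.chi2.sf(q, k - 2)),
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_pval=float(2 * stats.norm.sf(abs(zi))),
    )


def _weighted_median_point(ratios: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratios, kind="stable")
    r, w = ratios[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, r))


def weighted_median(
    hset: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> MrEstimate:
    """Weighted median of per-SNP Wald ratios.

    Consistent when SNPs carrying at least half the weight are valid
    instruments. Weights are beta_zx^2/se_zy^2; the point estimate linearly
    interpolates the ordered ratios at cumulative weight 0.5 (midpoint
    convention). SE is the SD over ``n_boot`` parametric resamples of the
    per-SNP associations from their normal sampling distributions.
    """
    bx, sx, by, sy = _arrays(hset)
    k = len(bx)
    if k < 3:
        raise ValueError("weighted median needs at least 3 SNPs")
    w = bx**2 / sy**2
    beta = _weighted_median_point(by / bx, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0, 1e-300, bxs)
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _finish("weighted_median", beta, se, k)


def leave_one_out(
    hset: HarmonizedInstrumentSet, effects_model: str = "multiplicative-random"
) -> list[tuple[str, MrEstimate]]:
    """IVW re-estimated k times, each omitting one SNP (labelled by the omission)."""
    if hset.k < 2:
        raise ValueError("leave-one-out needs at least 2 SNPs")
    out = []
    for sid in hset.table["snp_id"]:
        sub = HarmonizedInstrumentSet(
            hset.table[hset.table["snp_id"] != sid].reset_index(drop=True)
        )
        out.append((sid, ivw(sub, effects_model)))
    return out


def meta_fixed(betas: np.ndarray, ses: np.ndarray) -> MetaResult:
    """Fixed-effects inverse-variance meta-analysis with between-study Q."""
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("no estimates to pool")
    if np.any(s <= 0):
        raise ValueError("all SEs must be positive")
    w = 1.0 / s**2
    pooled = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    q_p = float(stats.chi2.sf(q, b.size - 1)) if b.size >= 2 else 1.0
    z = pooled / se
    return MetaResult(
        beta=pooled,
        se=se,
        pval=float(2 * stats.norm.sf(abs(z))),
        weights=w / w.sum(),
        q_between=q,
        q_between_pval=q_p,
    )


def snp_subset(
    hset: HarmonizedInstrumentSet,
    subset: str,
    membership: dict[str, list[str]],
) -> HarmonizedInstrumentSet:
    """Restrict to a named instrument subset (e.g. replicated SNP lists).

    ``membership`` maps subset labels to SNP-id lists (such lists live in
    configuration, not code).
    """
    if subset not in membership:
        raise ValueError(f"unknown subset label {subset!r}")
    return hset.subset(membership[subset], label=subset)
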