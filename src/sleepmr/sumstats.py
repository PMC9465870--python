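"""Per-SNP summary statistics from individual-level data.

Covers exposure QC, the unweighted genetic risk score with its instrument
strength diagnostics, covariate-adjusted per-SNP association scans, the
split cross-over design for within-cohort two-sample MR, allele
harmonization of exposure and outcome associations, and the fetal-genotype
adjustment comparison.

Summary-statistic tables are pandas DataFrames with the column convention
``snp_id effect_allele other_allele eaf beta se pval n`` (written/read as
tab-delimited text).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._batchreg import batched_linear, batched_logistic

__all__ = [
    "SUMSTAT_COLUMNS",
    "GrsResult",
    "HarmonizedInstrumentSet",
    "exposure_qc",
    "build_grs",
    "grs_with_strength",
    "estimate_snp_trait",
    "adjust_for_fetal",
    "split_half_indices",
    "split_crossover",
    "harmonize",
    "f_statistic",
    "read_sumstats",
    "write_sumstats",
    "write_exclusion_log",
]

SUMSTAT_COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]

_PALINDROMIC = {frozenset("AT"), frozenset("CG")}


# ---------------------------------------------------------------------------
# exposure QC
# ---------------------------------------------------------------------------

def exposure_qc(reported: np.ndarray | pd.Series) -> tuple[np.ndarray, int]:
    """Set implausible reported durations to missing.

    Values shorter than 2 h or longer than 12 h are treated like missing
    responses (2 and 12 themselves are retained). Returns the cleaned
    vector and the number of newly excluded values.
    """
    x = np.asarray(reported, dtype=float).copy()
    present = ~np.isnan(x)
    if present.any() and not np.allclose(x[present], np.rint(x[present])):
        raise ValueError("reported hours must be integer-valued where present")
    bad = present & ((x < 2) | (x > 12))
    x[bad] = np.nan
    return x, int(bad.sum())


# ---------------------------------------------------------------------------
# genetic risk score
# ---------------------------------------------------------------------------

@dataclass
class GrsResult:
    score: np.ndarray
    f_statistic: float
    r_squared: float


def build_grs(genotypes: np.ndarray, increases_duration: np.ndarray) -> np.ndarray:
    """Unweighted count of duration-increasing alleles.

    ``increases_duration`` flags, per SNP, whether the stored effect allele
    increases sleep duration; dosages of duration-decreasing effect alleles
    contribute ``2 - dosage``.
    """
    G = np.asarray(genotypes, dtype=float)
    inc = np.asarray(increases_duration)
    if inc.shape[0] != G.shape[1]:
        raise ValueError("orientation vector does not match the genotype panel")
    if inc.dtype != bool:
        if np.isnan(np.asarray(inc, dtype=float)).any():
            raise ValueError("unknown orientation for at least one SNP")
        inc = np.asarray(inc, dtype=float) > 0
    oriented = np.where(inc, G, 2.0 - G)
    return oriented.sum(axis=1)


def orientation_from_panel(panel: pd.DataFrame) -> np.ndarray:
    """Duration-increasing flag per SNP from the sign of the exposure effect."""
    beta = panel["beta_exposure"].to_numpy(dtype=float)
    if np.any(beta == 0) or np.any(~np.isfinite(beta)):
        raise ValueError("cannot orient SNPs with zero or non-finite exposure effect")
    return beta > 0


def grs_with_strength(
    genotypes: np.ndarray,
    increases_duration: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
) -> GrsResult:
    score = build_grs(genotypes, increases_duration)
    f, r2 = f_statistic(score, exposure, covariates)
    return GrsResult(score, f, r2)


def f_statistic(
    instrument: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial F (and R^2) of a single instrument in the exposure regression.

    With no covariates this is the squared t of the slope and satisfies
    F = R^2 (n - 2) / (1 - R^2).
    """
    z = np.asarray(instrument, dtype=float)
    x = np.asarray(exposure, dtype=float)
    keep = ~(np.isnan(z) | np.isnan(x))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        keep &= ~np.isnan(C).any(axis=1)
        C = C[keep]
    z, x = z[keep], x[keep]
    if np.var(z) == 0:
        raise ValueError("instrument has zero variance")
    if covariates is None:
        full = sm.OLS(x, sm.add_constant(z)).fit()
        reduced = sm.OLS(x, np.ones_like(x)).fit()
    else:
        full = sm.OLS(x, sm.add_constant(np.column_stack([z, C]))).fit()
        reduced = sm.OLS(x, sm.add_constant(C)).fit()
    df_resid = full.df_resid
    rss1, rss0 = full.ssr, reduced.ssr
    f = (rss0 - rss1) / (rss1 / df_resid)
    partial_r2 = (rss0 - rss1) / rss0
    return float(f), float(partial_r2)


# ---------------------------------------------------------------------------
# per-SNP association scans
# ---------------------------------------------------------------------------

def _complete_rows(*arrays: np.ndarray | None) -> np.ndarray:
    n = next(a.shape[0] for a in arrays if a is not None)
    keep = np.ones(n, dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        keep &= ~(np.isnan(a).any(axis=1) if a.ndim == 2 else np.isnan(a))
    return keep


def estimate_snp_trait(
    genotypes: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "linear",
    panel: pd.DataFrame | None = None,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """One regression of the trait on dosage (+ covariates) per SNP.

    Complete records only. Logistic fits that fail to converge (separation)
    are returned with missing ``se`` rather than raising. Binary traits with
    zero cases (or zero controls) raise, naming the trait.
    """
    if family not in {"linear", "logistic"}:
        raise ValueError("family must be 'linear' or 'logistic'")
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    keep = _complete_rows(G, y, C)
    G, y = G[keep], y[keep]
    if C is not None:
        C = C[keep]
    if family == "logistic":
        cases = np.nansum(y)
        if cases == 0 or cases == len(y):
            raise ValueError(f"outcome {trait_name!r} has zero cases or zero controls")
        res = batched_logistic(G, y, C)
    else:
        res = batched_linear(G, y, C)
    eaf = G.mean(axis=0) / 2.0
    out = pd.DataFrame(
        {
            "snp_id": panel["snp_id"].to_numpy() if panel is not None else [f"snp{j}" for j in range(G.shape[1])],
            "effect_allele": panel["effect_allele"].to_numpy() if panel is not None else "A",
            "other_allele": panel["other_allele"].to_numpy() if panel is not None else "G",
            "eaf": eaf,
            "beta": res["beta"],
            "se": res["se"],
            "pval": res["pval"],
            "n": res["n"],
        }
    )
    return out


def adjust_for_fetal(
    genotypes: np.ndarray,
    fetal_genotypes: np.ndarray | None,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    family: str = "linear",
    panel: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maternal SNP-outcome associations without and with fetal-dosage adjustment.

    The adjusted model adds the same SNP's fetal dosage as a covariate,
    separating the maternal path from transmission to the fetus. Returns
    (unadjusted, adjusted) association tables.
    """
    if fetal_genotypes is None:
        raise ValueError("fetal genotype matrix is required")
    G = np.asarray(genotypes, dtype=float)
    Gf = np.asarray(fetal_genotypes, dtype=float)
    if Gf.shape != G.shape:
        raise ValueError("maternal and fetal genotype matrices must align")
    unadj = estimate_snp_trait(G, outcome, covariates, family, panel)
    # per-SNP fetal covariate differs across SNPs, so scan SNP by SNP
    y = np.asarray(outcome, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    betas, ses, pvals = [], [], []
    fit = batched_linear if family == "linear" else batched_logistic
    for j in range(G.shape[1]):
        cov_j = Gf[:, j : j + 1] if C is None else np.column_stack([Gf[:, j], C])
        keep = _complete_rows(G[:, j : j + 1], y, cov_j)
        res = fit(G[keep, j : j + 1], y[keep], cov_j[keep])
        betas.append(res["beta"][0])
        ses.append(res["se"][0])
        pvals.append(res["pval"][0])
    adj = unadj.copy()
    adj["beta"], adj["se"], adj["pval"] = betas, ses, pvals
    return unadj, adj


# ---------------------------------------------------------------------------
# split cross-over design
# ---------------------------------------------------------------------------

def split_half_indices(n: int, seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint random halves; with odd n the extra row goes to half B."""
    if n < 200:
        raise ValueError("split cross-over needs n >= 200")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def split_crossover(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    outcomes: dict[str, tuple[np.ndarray, str]],
    covariates: np.ndarray | None = None,
    panel: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Per-SNP summary statistics in two disjoint random halves.

    ``outcomes`` maps name -> (values, family). Returns
    ``{"A": {"exposure": df, <outcome>: df, ...}, "B": {...}}``. The
    downstream contract is crossed MR — exposure associations from one half
    with outcome associations from the other — with the two crossed
    estimates combined by fixed-effects inverse-variance meta-analysis.
    """
    G = np.asarray(genotypes, dtype=float)
    idx_a, idx_b = split_half_indices(G.shape[0], seed)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for label, idx in (("A", idx_a), ("B", idx_b)):
        C = None if covariates is None else np.asarray(covariates, dtype=float)[idx]
        tabs = {
            "exposure": estimate_snp_trait(G[idx], np.asarray(exposure, float)[idx], C, "linear", panel, "exposure")
        }
        for name, (y, family) in outcomes.items():
            fam = "logistic" if family in {"binary", "logistic"} else "linear"
            tabs[name] = estimate_snp_trait(G[idx], np.asarray(y, float)[idx], C, fam, panel, name)
        out[label] = tabs
    return out


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedInstrumentSet:
    """Exposure and outcome associations on a shared effect-allele orientation."""

    table: pd.DataFrame  # snp_id ea oa eaf_exposure beta_exposure se_exposure eaf_outcome beta_outcome se_outcome
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.table)

    def subset(self, snp_ids, label: str = "subset") -> "HarmonizedInstrumentSet":
        """Filtered copy keeping only the listed SNPs; exclusions logged."""
        wanted = set(snp_ids)
        keep = self.table["snp_id"].isin(wanted)
        if not keep.any():
            raise ValueError(f"subset {label!r} shares no SNPs with the harmonized set")
        excl = dict(self.exclusions)
        for sid in self.table.loc[~keep, "snp_id"]:
            excl[sid] = f"not in {label}"
        return HarmonizedInstrumentSet(self.table.loc[keep].reset_index(drop=True), excl)


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset((ea, oa)) in _PALINDROMIC


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_policy: str = "maf",
    maf_threshold: float = 0.42,
) -> HarmonizedInstrumentSet:
    """Align outcome associations to the exposure's effect alleles.

    When the outcome's effect allele equals the exposure's other allele the
    outcome beta sign is flipped and its frequency complemented. SNPs with
    incompatible allele sets are excluded with a reason, not fatal.
    Palindromic (A/T, C/G) SNPs are ambiguous on unknown strands; the
    default policy drops them when the minor-allele frequency exceeds
    ``maf_threshold`` (0.42), ``keep`` keeps all, ``drop`` drops all.
    """
    if palindrome_policy not in {"maf", "keep", "drop"}:
        raise ValueError("palindrome_policy must be one of maf/keep/drop")
    exclusions: dict[str, str] = {}
    out_by_id = outcome.set_index("snp_id")
    rows = []
    for rec in exposure.itertuples(index=False):
        sid = rec.snp_id
        if sid not in out_by_id.index:
            exclusions[sid] = "absent from outcome associations"
            continue
        o = out_by_id.loc[sid]
        ea, oa = rec.effect_allele, rec.other_allele
        beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        if (o["effect_allele"], o["other_allele"]) == (ea, oa):
            pass
        elif (o["effect_allele"], o["other_allele"]) == (oa, ea):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
        else:
            exclusions[sid] = (
                f"incompatible alleles ({o['effect_allele']}/{o['other_allele']} vs {ea}/{oa})"
            )
            continue
        if _is_palindromic(ea, oa):
            maf = min(rec.eaf, 1.0 - rec.eaf)
            if palindrome_policy == "drop" or (palindrome_policy == "maf" and maf > maf_threshold):
                exclusions[sid] = f"palindromic (MAF {maf:.3f})"
                continue
        rows.append(
            {
                "snp_id": sid,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf_exposure": rec.eaf,
                "beta_exposure": rec.beta,
                "se_exposure": rec.se,
                "eaf_outcome": eaf_out,
                "beta_outcome": beta_out,
                "se_outcome": float(o["se"]),
            }
        )
    for sid in out_by_id.index.difference(exposure["snp_id"]):
        exclusions[sid] = "absent from exposure associations"
    if not rows:
        raise ValueError("harmonization left no usable SNPs")
    table = pd.DataFrame(rows)
    if table["snp_id"].duplicated().any():
        raise ValueError("duplicate snp_ids in harmonized set")
    return HarmonizedInstrumentSet(table, exclusions)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_sumstats(df: pd.DataFrame, path: str) -> None:
    df.loc[:, SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistic file missing columns: {missing}")
    return df


def write_exclusion_log(exclusions: dict[str, str], path: str) -> None:
    pd.DataFrame(
        {"snp_id": list(exclusions), "reason": list(exclusions.values())}
    ).to_csv(path, sep="\t", index=False)
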