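"""Summary statistics: QC, GRS, association scans, split design, harmonization."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import sleepmr as smr
from sleepmr.sumstats import write_sumstats, read_sumstats, write_exclusion_log


class TestExposureQc:
    def test_worked_vector(self):
        cleaned, excluded = smr.exposure_qc(np.array([1.0, 2, 7, 12, 13]))
        assert excluded == 2
        assert np.isnan(cleaned[0]) and np.isnan(cleaned[4])
        assert list(cleaned[1:4]) == [2, 7, 12]

    def test_in_range_unchanged(self):
        x = np.arange(2.0, 13.0)
        cleaned, excluded = smr.exposure_qc(x)
        assert excluded == 0
        assert np.array_equal(cleaned, x)

    def test_all_out_of_range(self):
        cleaned, excluded = smr.exposure_qc(np.array([0.0, 1, 13, 23]))
        assert excluded == 4
        assert np.isnan(cleaned).all()

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            smr.exposure_qc(np.array([7.3]))

    def test_missing_propagates_uncounted(self):
        cleaned, excluded = smr.exposure_qc(np.array([np.nan, 7.0]))
        assert excluded == 0
        assert np.isnan(cleaned[0]) and cleaned[1] == 7


class TestGrs:
    def test_zero_dosage_zero_score(self):
        G = np.zeros((4, 3))
        assert np.array_equal(smr.build_grs(G, np.array([True, True, True])), np.zeros(4))

    def test_decreasing_allele_flips(self):
        G = np.array([[2.0]])
        assert smr.build_grs(G, np.array([False]))[0] == 0.0
        assert smr.build_grs(G, np.array([True]))[0] == 2.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(10, 5)).astype(float)
        inc = rng.random(5) > 0.5
        score = smr.build_grs(G, inc)
        for i in range(10):
            expected = sum(
                G[i, k] if inc[k] else 2 - G[i, k] for k in range(5)
            )
            assert score[i] == expected

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(50, 4)).astype(float)
        inc = np.array([True, False, True, False])
        # recording the other allele as effect allele flips dosage and orientation
        assert np.allclose(smr.build_grs(G, inc), smr.build_grs(2 - G, ~inc))

    def test_unknown_orientation_raises(self):
        with pytest.raises(ValueError):
            smr.build_grs(np.zeros((2, 2)), np.array([1.0, np.nan]))


class TestFStatistic:
    def test_equals_t_squared_without_covariates(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=500)
        x = 0.3 * z + rng.normal(size=500)
        f, r2 = smr.f_statistic(z, x)
        fit = sm.OLS(x, sm.add_constant(z)).fit()
        assert f == pytest.approx(fit.tvalues[1] ** 2, rel=1e-10)
        assert f == pytest.approx(r2 * (500 - 2) / (1 - r2), rel=1e-10)

    def test_partial_f_with_covariates(self):
        rng = np.random.default_rng(3)
        n = 2000
        c = rng.normal(size=n)
        z = rng.normal(size=n) + 0.5 * c
        x = 0.2 * z + 0.8 * c + rng.normal(size=n)
        f, r2 = smr.f_statistic(z, x, covariates=c)
        full = sm.OLS(x, sm.add_constant(np.column_stack([z, c]))).fit()
        assert f == pytest.approx(full.tvalues[1] ** 2, rel=1e-8)

    def test_zero_variance_instrument(self):
        with pytest.raises(ValueError):
            smr.f_statistic(np.ones(100), np.random.default_rng(0).normal(size=100))


class TestEstimateSnpTrait:
    def test_exact_linear_relation(self, small_panel):
        G = smr.simulate_genotypes(small_panel, 300, 1).astype(float)
        trait = 3.0 * G[:, 0]
        res = smr.estimate_snp_trait(G[:, :1], trait, family="linear")
        assert res["beta"][0] == pytest.approx(3.0, abs=1e-12)
        assert res["se"][0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_linear_with_covariates(self, small_panel):
        rng = np.random.default_rng(4)
        n = 3000
        G = smr.simulate_genotypes(small_panel, n, 5).astype(float)
        C = rng.normal(size=(n, 2))
        y = 0.1 * G[:, 2] + 0.5 * C[:, 0] + rng.normal(size=n)
        res = smr.estimate_snp_trait(G, y, covariates=C, family="linear", panel=small_panel)
        for j in range(G.shape[1]):
            fit = sm.OLS(y, sm.add_constant(np.column_stack([G[:, j], C]))).fit()
            assert res["beta"][j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["se"][j] == pytest.approx(fit.bse[1], abs=1e-10)
            assert res["pval"][j] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_matches_statsmodels_logistic(self, small_panel):
        rng = np.random.default_rng(6)
        n = 4000
        G = smr.simulate_genotypes(small_panel, n, 7).astype(float)
        eta = -2.0 + 0.2 * G[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        res = smr.estimate_snp_trait(G, y, family="logistic", panel=small_panel)
        for j in range(G.shape[1]):
            fit = sm.Logit(y, sm.add_constant(G[:, j])).fit(disp=0)
            assert res["beta"][j] == pytest.approx(fit.params[1], abs=1e-7)
            assert res["se"][j] == pytest.approx(fit.bse[1], abs=1e-7)

    def test_null_calibration(self, panel):
        """Permuted traits reject at ~ the nominal 5% rate across SNPs x reps."""
        rng = np.random.default_rng(8)
        n = 2000
        G = smr.simulate_genotypes(panel, n, 9).astype(float)
        hits, total = 0, 0
        for _ in range(20):
            y = rng.normal(size=n)
            res = smr.estimate_snp_trait(G, y, family="linear")
            hits += (res["pval"] < 0.05).sum()
            total += len(res)
        rate = hits / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)

    def test_zero_cases_raises_with_name(self, small_panel):
        G = smr.simulate_genotypes(small_panel, 100, 1).astype(float)
        with pytest.raises(ValueError, match="stillbirth"):
            smr.estimate_snp_trait(G, np.zeros(100), family="logistic", trait_name="stillbirth")

    def test_complete_records_only(self, small_panel):
        G = smr.simulate_genotypes(small_panel, 500, 2).astype(float)
        y = np.random.default_rng(3).normal(size=500)
        y[:50] = np.nan
        res = smr.estimate_snp_trait(G, y, family="linear")
        assert res["n"].iloc[0] == 450


class TestFetalAdjustment:
    def _family(self, seed, n=30_000):
        panel = smr.make_panel(k=6, seed=seed)
        G = smr.simulate_genotypes(panel, n, seed + 1)
        F = smr.simulate_fetal_genotypes(G, panel, seed + 2)
        return panel, G.astype(float), F.astype(float)

    def test_maternal_only_outcome_unchanged_by_adjustment(self):
        panel, G, F = self._family(10)
        rng = np.random.default_rng(12)
        y = G @ np.full(6, 0.2) + rng.normal(size=len(G))
        unadj, adj = smr.adjust_for_fetal(G, F, y, family="linear", panel=panel)
        assert np.allclose(unadj["beta"], adj["beta"], atol=4 * unadj["se"].max())

    def test_fetal_only_outcome(self):
        panel, G, F = self._family(20)
        rng = np.random.default_rng(22)
        y = F @ np.full(6, 0.3) + rng.normal(size=len(G))
        unadj, adj = smr.adjust_for_fetal(G, F, y, family="linear", panel=panel)
        # transmission correlation makes the unadjusted maternal effect ~ half the fetal one
        assert np.allclose(unadj["beta"], 0.15, atol=4 * unadj["se"].max())
        assert np.allclose(adj["beta"], 0.0, atol=4 * adj["se"].max())

    def test_missing_fetal_matrix(self, small_panel):
        G = smr.simulate_genotypes(small_panel, 100, 1).astype(float)
        with pytest.raises(ValueError):
            smr.adjust_for_fetal(G, None, np.zeros(100))


class TestSplitCrossover:
    def test_partition(self):
        a, b = smr.split_half_indices(1000, 0)
        assert len(a) == 500 and len(b) == 500
        assert len(np.intersect1d(a, b)) == 0
        assert np.array_equal(np.sort(np.concatenate([a, b])), np.arange(1000))

    def test_odd_n_extra_row_in_b(self):
        a, b = smr.split_half_indices(1001, 0)
        assert len(a) == 500 and len(b) == 501

    def test_deterministic(self):
        a1, b1 = smr.split_half_indices(500, 9)
        a2, b2 = smr.split_half_indices(500, 9)
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            smr.split_half_indices(199, 0)

    def test_half_sample_se_scaling(self, small_panel):
        rng = np.random.default_rng(30)
        n = 20_000
        G = smr.simulate_genotypes(small_panel, n, 31).astype(float)
        x = 0.05 * G.sum(axis=1) + rng.normal(size=n)
        full = smr.estimate_snp_trait(G, x, family="linear", panel=small_panel)
        halves = smr.split_crossover(G, x, {}, panel=small_panel, seed=32)
        ratio = np.concatenate(
            [halves[h]["exposure"]["se"] / full["se"] for h in ("A", "B")]
        )
        assert abs(ratio.mean() - np.sqrt(2)) < 0.05

    def test_cross_half_independence(self, small_panel):
        """Association errors in the two halves are uncorrelated across replicates."""
        rng = np.random.default_rng(33)
        n = 2000
        G = smr.simulate_genotypes(small_panel, n, 34).astype(float)
        errs_a, errs_b = [], []
        for rep in range(40):
            x = rng.normal(size=n)
            halves = smr.split_crossover(G, x, {}, panel=small_panel, seed=35 + rep)
            errs_a.append(halves["A"]["exposure"]["beta"].to_numpy())
            errs_b.append(halves["B"]["exposure"]["beta"].to_numpy())
        A, B = np.array(errs_a), np.array(errs_b)
        r = [np.corrcoef(A[:, j], B[:, j])[0, 1] for j in range(A.shape[1])]
        assert abs(np.mean(r)) < 3 / np.sqrt(40 * A.shape[1])


class TestHarmonize:
    def _assoc(self, snp, ea, oa, eaf, beta, se=0.1):
        return {"snp_id": snp, "effect_allele": ea, "other_allele": oa,
                "eaf": eaf, "beta": beta, "se": se, "pval": 0.5, "n": 100}

    def test_swapped_alleles_flip_sign(self):
        exp = pd.DataFrame([self._assoc("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([self._assoc("rs1", "G", "A", 0.7, 0.3)])
        h = smr.harmonize(exp, out)
        assert h.table["beta_outcome"][0] == pytest.approx(-0.3)
        assert h.table["eaf_outcome"][0] == pytest.approx(0.3)

    def test_identical_orientation_unchanged(self):
        exp = pd.DataFrame([self._assoc("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([self._assoc("rs1", "A", "G", 0.3, 0.3)])
        h = smr.harmonize(exp, out)
        assert h.table["beta_outcome"][0] == pytest.approx(0.3)

    def test_ambiguous_palindrome_dropped(self):
        exp = pd.DataFrame([self._assoc("rs1", "A", "T", 0.5, 0.1),
                            self._assoc("rs2", "C", "G", 0.1, 0.1),
                            self._assoc("rs3", "A", "G", 0.5, 0.1)])
        out = pd.DataFrame([self._assoc("rs1", "A", "T", 0.5, 0.2),
                            self._assoc("rs2", "C", "G", 0.1, 0.2),
                            self._assoc("rs3", "A", "G", 0.5, 0.2)])
        h = smr.harmonize(exp, out)
        assert "rs1" in h.exclusions and "palindromic" in h.exclusions["rs1"]
        assert set(h.table["snp_id"]) == {"rs2", "rs3"}
        assert smr.harmonize(exp, out, palindrome_policy="keep").k == 3
        assert smr.harmonize(exp, out, palindrome_policy="drop").k == 1

    def test_incompatible_alleles_excluded_not_fatal(self):
        exp = pd.DataFrame([self._assoc("rs1", "A", "G", 0.3, 0.1),
                            self._assoc("rs2", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([self._assoc("rs1", "A", "C", 0.3, 0.2),
                            self._assoc("rs2", "A", "G", 0.3, 0.2)])
        h = smr.harmonize(exp, out)
        assert "incompatible" in h.exclusions["rs1"]
        assert h.k == 1

    def test_missing_overlap_logged_and_empty_raises(self):
        exp = pd.DataFrame([self._assoc("rs1", "A", "G", 0.3, 0.1)])
        out = pd.DataFrame([self._assoc("rs2", "A", "G", 0.3, 0.2)])
        with pytest.raises(ValueError):
            smr.harmonize(exp, out)

    def test_involution_leaves_ivw_unchanged(self, panel):
        rng = np.random.default_rng(40)
        k = len(panel)
        exp = pd.DataFrame({
            "snp_id": panel["snp_id"], "effect_allele": panel["effect_allele"],
            "other_allele": panel["other_allele"], "eaf": panel["eaf"],
            "beta": rng.normal(0.02, 0.01, k), "se": np.full(k, 0.004),
            "pval": 0.5, "n": 1000,
        })
        out = exp.copy()
        out["beta"] = 0.5 * exp["beta"] + rng.normal(0, 0.01, k)
        out["se"] = 0.01
        flipped = out.copy()
        flipped["effect_allele"], flipped["other_allele"] = out["other_allele"], out["effect_allele"]
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1 - out["eaf"]
        est1 = smr.ivw(smr.harmonize(exp, out, palindrome_policy="keep"))
        est2 = smr.ivw(smr.harmonize(exp, flipped, palindrome_policy="keep"))
        assert est1.beta == pytest.approx(est2.beta, abs=1e-12)
        assert est1.se == pytest.approx(est2.se, abs=1e-12)


class TestIo:
    def test_sumstats_round_trip(self, tmp_path, small_panel):
        G = smr.simulate_genotypes(small_panel, 500, 1).astype(float)
        y = np.random.default_rng(0).normal(size=500)
        df = smr.estimate_snp_trait(G, y, family="linear", panel=small_panel)
        path = str(tmp_path / "sumstats.tsv")
        write_sumstats(df, path)
        back = read_sumstats(path)
        assert np.allclose(back["beta"], df["beta"])

    def test_exclusion_log(self, tmp_path):
        path = str(tmp_path / "excl.tsv")
        write_exclusion_log({"rs1": "palindromic (MAF 0.500)"}, path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["snp_id", "reason"]
        assert back["snp_id"][0] == "rs1"
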