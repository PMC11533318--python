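"""Variant filtering, GRM, mixed-model Wald tests and effect classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from toxgwas import SimulationConfig, simulate_genotypes
from toxgwas.association import (
    ANALYSES,
    bonferroni_threshold,
    classify_infection,
    classify_sex_effects,
    compute_grm,
    derive_phenotypes,
    filter_variants,
    lmm_wald,
    screen_covariates,
)
from toxgwas.containers import GenotypeMatrix


def _matrix(calls, line_ids=None):
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(m)],
            "chrom": "2L",
            "pos": (np.arange(m) + 1) * 100,
            "ref": "A",
            "alt": "T",
            "vtype": "SNP",
        }
    )
    return GenotypeMatrix(calls, line_ids or [f"l{i}" for i in range(n)], variants)


class TestFilter:
    def test_missing_rate_boundary(self):
        calls = np.zeros((10, 1))
        calls[:5, 0] = 2.0
        calls[:2, 0] = np.nan  # missing rate 0.2 > 0.1
        gm = _matrix(calls)
        assert filter_variants(gm).n_variants == 0

    def test_maf_boundary_inclusive(self):
        calls = np.zeros((200, 1))
        calls[:3, 0] = 2.0  # MAF = 3/200 = 0.015 exactly
        gm = _matrix(calls)
        assert filter_variants(gm).n_variants == 1

    def test_monomorphic_removed(self):
        gm = _matrix(np.full((20, 1), 2.0))
        with pytest.warns(UserWarning):
            assert filter_variants(gm).n_variants == 0

    def test_matches_brute_force_and_idempotent(self, small_genotypes):
        filt = filter_variants(small_genotypes)
        # independent recount
        expected = 0
        for k in range(small_genotypes.n_variants):
            col = small_genotypes.calls[:, k]
            obs = col[~np.isnan(col)]
            miss = np.isnan(col).mean()
            f = obs.mean() / 2 if obs.size else np.nan
            maf = min(f, 1 - f)
            if miss <= 0.1 and maf >= 0.015 and maf > 0:
                expected += 1
        assert filt.n_variants == expected
        again = filter_variants(filt)
        np.testing.assert_array_equal(again.calls, filt.calls)


class TestInfection:
    @pytest.mark.parametrize("count,status", [(7001, 1), (7000, 0), (0, 0)])
    def test_strict_threshold(self, count, status):
        assert classify_infection([count])[0] == status

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_infection([-1])


class TestDerivePhenotypes:
    def test_average_and_difference(self):
        pooled = pd.DataFrame(
            {
                "line_id": ["a", "a", "b", "b"],
                "sex": ["F", "M", "F", "M"],
                "p": [0.8, 0.2, 0.5, 0.5],
            }
        )
        phen = derive_phenotypes(pooled)
        assert phen.loc["a", "average"] == pytest.approx(0.5)
        assert phen.loc["a", "difference"] == pytest.approx(0.6)
        assert phen.loc["b", "difference"] == pytest.approx(0.0)

    def test_line_missing_one_sex_dropped_from_contrasts(self):
        pooled = pd.DataFrame(
            {"line_id": ["a", "a", "b"], "sex": ["F", "M", "F"], "p": [0.8, 0.2, 0.5]}
        )
        phen = derive_phenotypes(pooled)
        assert np.isnan(phen.loc["b", "average"])
        assert np.isnan(phen.loc["b", "difference"])
        assert phen.loc["b", "female"] == 0.5


class TestCovariateScreen:
    def test_perfect_predictor_included(self):
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=50), index=[f"l{i}" for i in range(50)])
        cov = pd.DataFrame({"self": y})
        out = screen_covariates(y, cov)
        assert out.loc[0, "included"]
        assert out.loc[0, "p_value"] < 1e-10

    def test_constant_covariate_excluded(self):
        rng = np.random.default_rng(1)
        idx = [f"l{i}" for i in range(30)]
        y = pd.Series(rng.normal(size=30), index=idx)
        cov = pd.DataFrame({"const": np.ones(30)}, index=idx)
        with pytest.warns(UserWarning):
            out = screen_covariates(y, cov)
        assert not out.loc[0, "included"]

    def test_null_inclusion_rate_matches_alpha(self):
        """An independent covariate enters at frequency ~ alpha = 0.1."""
        rng = np.random.default_rng(2)
        idx = [f"l{i}" for i in range(200)]
        included = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = pd.Series(rng.normal(size=200), index=idx)
            cov = pd.DataFrame({"c": rng.integers(0, 2, 200)}, index=idx)
            included += int(screen_covariates(y, cov).loc[0, "included"])
        assert 0.07 < included / n_rep < 0.13


class TestGRM:
    def test_two_line_hand_computation(self):
        gm = _matrix([[0.0], [2.0]])
        np.testing.assert_allclose(compute_grm(gm), [[1.0, -1.0], [-1.0, 1.0]])

    def test_identical_lines_zero_matrix(self):
        gm = _matrix(np.full((4, 3), 2.0))
        np.testing.assert_allclose(compute_grm(gm), np.zeros((4, 4)))

    @pytest.mark.parametrize("seed", range(10))
    def test_positive_semidefinite(self, seed):
        cfg = SimulationConfig(n_lines=30, n_variants=100, seed=seed)
        grm = compute_grm(simulate_genotypes(cfg))
        assert np.linalg.eigvalsh(grm).min() >= -1e-10


class TestLmmWald:
    def test_ols_equivalence_under_identity_grm(self):
        rng = np.random.default_rng(0)
        n, m = 80, 40
        calls = (rng.random((n, m)) < 0.3).astype(float) * 2
        gm = _matrix(calls)
        y = pd.Series(rng.normal(size=n), index=gm.line_ids)
        res = lmm_wald(y, gm, None, np.eye(n)).set_index("variant_id")
        for k in rng.choice(m, 10, replace=False):
            X = np.column_stack([np.ones(n), calls[:, k]])
            beta = np.linalg.lstsq(X, y.to_numpy(), rcond=None)[0]
            resid = y.to_numpy() - X @ beta
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            p = stats.chi2.sf((beta[1] / se) ** 2, 1)
            row = res.loc[f"v{k}"]
            assert row["beta"] == pytest.approx(beta[1], abs=1e-8)
            assert row["wald_p"] == pytest.approx(p, abs=1e-8)

    def test_constant_phenotype(self):
        rng = np.random.default_rng(1)
        calls = (rng.random((20, 5)) < 0.4).astype(float) * 2
        gm = _matrix(calls)
        y = pd.Series(0.5, index=gm.line_ids)
        res = lmm_wald(y, gm, None, np.eye(20))
        assert (res["beta"] == 0).all()
        assert (res["wald_p"] == 1).all()

    def test_sign_convention_flips_with_allele_coding(self):
        rng = np.random.default_rng(2)
        n = 60
        calls = (rng.random((n, 8)) < 0.4).astype(float) * 2
        gm = _matrix(calls)
        flipped = _matrix(2.0 - calls)
        y = pd.Series(rng.normal(size=n) + 0.3 * calls[:, 0], index=gm.line_ids)
        grm = np.eye(n)
        a = lmm_wald(y, gm, None, grm).set_index("variant_id")
        b = lmm_wald(y, flipped, None, grm).set_index("variant_id")
        np.testing.assert_allclose(a["beta"], -b["beta"], atol=1e-10)
        np.testing.assert_allclose(a["wald_p"], b["wald_p"], atol=1e-10)

    def test_missing_genotypes_use_case_deletion(self):
        rng = np.random.default_rng(3)
        n = 50
        calls = (rng.random((n, 2)) < 0.4).astype(float) * 2
        calls[:5, 0] = np.nan
        gm = _matrix(calls)
        y = pd.Series(rng.normal(size=n), index=gm.line_ids)
        res = lmm_wald(y, gm, None, np.eye(n)).set_index("variant_id")
        assert res.loc["v0", "n_lines_used"] == 45
        # oracle: plain OLS on the 45 observed lines
        obs = ~np.isnan(calls[:, 0])
        X = np.column_stack([np.ones(obs.sum()), calls[obs, 0]])
        beta = np.linalg.lstsq(X, y.to_numpy()[obs], rcond=None)[0]
        assert res.loc["v0", "beta"] == pytest.approx(beta[1], abs=1e-8)

    def test_lmm_deflates_inflation_from_relatedness(self):
        """With block relatedness and a polygenic phenotype, the GRM model's
        genomic inflation factor must not exceed naive OLS's."""
        rng = np.random.default_rng(4)
        n_groups, per, m = 10, 20, 1000
        n = n_groups * per
        group = (rng.random((n_groups, m)) < rng.uniform(0.1, 0.5, m)).astype(float) * 2
        calls = np.repeat(group, per, axis=0)
        flip = rng.random((n, m)) < 0.05
        calls[flip] = 2 - calls[flip]
        gm = _matrix(calls)
        y = pd.Series(
            calls @ rng.normal(0, 0.05, m) + rng.normal(0, 1.0, n),
            index=gm.line_ids,
        )
        grm = compute_grm(gm)

        def lam(p):
            return np.median(stats.chi2.isf(p, 1)) / stats.chi2.median(1)

        lam_lmm = lam(lmm_wald(y, gm, None, grm)["wald_p"])
        lam_ols = lam(lmm_wald(y, gm, None, np.eye(n))["wald_p"])
        assert lam_lmm <= lam_ols + 0.05
        assert lam_ols > 2.0  # the design does induce inflation


class TestThresholds:
    def test_bonferroni_reproduces_printed_value(self):
        thr = bonferroni_threshold(0.05, 2_514_186)
        assert float(f"{thr:.3g}") == pytest.approx(1.99e-8)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5000, 1e-5)])
    def test_simple_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


def _results(vid, pf, pm, pa, pd_, bf, bm, ba=None, bd=None):
    rows = []
    for analysis, p, b in [
        ("female", pf, bf),
        ("male", pm, bm),
        ("average", pa, ba if ba is not None else (bf + bm) / 2),
        ("difference", pd_, bd if bd is not None else bf - bm),
    ]:
        rows.append((vid, analysis, b, 0.1, p, 0.2, 100))
    return pd.DataFrame(
        rows,
        columns=["variant_id", "analysis", "beta", "se_beta", "wald_p", "maf", "n_lines_used"],
    )


class TestEffectClassification:
    def test_female_specific(self):
        res = _results("v1", 1e-7, 0.4, 0.2, 0.3, bf=0.5, bm=0.4)
        out = classify_sex_effects(res)
        assert out.iloc[0]["effect_class"] == "sex_specific_F"

    def test_sex_antagonistic(self):
        res = _results("v1", 0.2, 0.3, 0.5, 1e-6, bf=0.5, bm=-0.4)
        out = classify_sex_effects(res)
        assert "sex_antagonistic" in out.iloc[0]["effect_class"]

    def test_concordant_single_sex_plus_average(self):
        res = _results("v1", 1e-6, 0.2, 5e-6, 0.4, bf=0.5, bm=0.3)
        labels = classify_sex_effects(res).iloc[0]["effect_class"].split(";")
        assert "concordant_sex_specific" in labels
        assert "sex_specific_F" in labels

    def test_nonsignificant_unclassified(self):
        res = _results("v1", 0.5, 0.5, 0.5, 0.5, bf=0.1, bm=0.1)
        assert classify_sex_effects(res).iloc[0]["effect_class"] == "unclassified"

    def test_missing_analysis_rejected(self):
        res = _results("v1", 0.5, 0.5, 0.5, 0.5, bf=0.1, bm=0.1)
        res = res[res["analysis"] != "male"]
        with pytest.raises(ValueError, match="male"):
            classify_sex_effects(res)
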