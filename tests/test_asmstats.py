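"""Statistical battery: rank tests, screens, regressions, matching, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import statsmodels.api as sm

from hapmeth.asmstats import (
    bh_fdr,
    cognition_glm,
    covariate_screen,
    kruskal_p,
    logistic_per_site,
    mann_whitney_p,
    matched_pair_analysis,
    pooled_t_from_summary,
    rank_tests,
)

from oracles import best_matching, bh_direct, kruskal_h, logistic_ml_fit, ols_normal_equations


def _records(site_groups):
    rows = []
    for site, groups in site_groups.items():
        i = 0
        for hap, values in groups.items():
            for v in values:
                rows.append((f"s{i}", hap, site, v))
                i += 1
    return pd.DataFrame(rows, columns=["subject_id", "haplotype", "site_id", "M"])


class TestRankTests:
    def test_closed_form_h(self):
        groups = [(1, 2, 3), (4, 5, 6), (7, 8, 9)]
        h, p = kruskal_p([np.array(g, float) for g in groups])
        assert h == pytest.approx(7.2)
        assert h == pytest.approx(kruskal_h(groups))

    def test_degenerate_all_equal(self):
        h, p = kruskal_p([np.ones(3), np.ones(3), np.ones(3)])
        assert h == 0.0 and p == 1.0

    def test_two_group_kw_equals_mann_whitney(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(0.3, 1, size=50)
        _, p_kw = kruskal_p([x, y])
        p_mw = mann_whitney_p(x, y)
        assert p_kw == pytest.approx(p_mw, abs=1e-6)

    def test_per_site_table(self):
        rng = np.random.default_rng(1)
        rec = _records(
            {
                "siteA": {
                    "h1": rng.normal(0.3, 0.05, 20),
                    "h2": rng.normal(0.7, 0.05, 20),
                    "h3": rng.normal(0.3, 0.05, 20),
                },
                "siteB": {"h1": [0.5], "h2": rng.normal(0.5, 0.1, 10)},
            }
        )
        df = rank_tests(rec, risk_haplotype="h2").set_index("site_id")
        assert df.loc["siteA", "kw_p"] < 1e-6
        assert df.loc["siteA", "posthoc_p"] < 1e-6
        assert df.loc["siteA", "mean_h2"] == pytest.approx(0.7, abs=0.05)
        assert df.loc["siteB", "skipped"] == "small_group"
        assert np.isnan(df.loc["siteB", "kw_p"])


class TestCovariateScreen:
    def _subjects(self, n, rng, constant_age=False):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["case"] * (n // 2) + ["control"] * (n - n // 2),
                "age": 30.0 if constant_age else rng.uniform(18, 45, n),
                "sex": ["F", "M"] * (n // 2),
                "cognitive_T": rng.normal(45, 8, n),
                "smoking": ["yes", "no"] * (n // 2),
            }
        )

    def test_null_age_correlation_small(self):
        rng = np.random.default_rng(3)
        n = 400
        subj = self._subjects(n, rng)
        mat = pd.DataFrame({"s1": rng.uniform(0.2, 0.8, n)},
                           index=subj["subject_id"])
        out = covariate_screen(mat, subj).iloc[0]
        assert abs(out["age_rho"]) < 2 / np.sqrt(n)

    def test_identical_sexes_p_one(self):
        rng = np.random.default_rng(4)
        subj = self._subjects(20, rng)
        mat = pd.DataFrame({"s1": np.full(20, 0.5)}, index=subj["subject_id"])
        assert covariate_screen(mat, subj).iloc[0]["sex_p"] == 1.0

    def test_constant_age_skipped(self):
        rng = np.random.default_rng(5)
        subj = self._subjects(20, rng, constant_age=True)
        mat = pd.DataFrame({"s1": rng.uniform(0, 1, 20)}, index=subj["subject_id"])
        out = covariate_screen(mat, subj).iloc[0]
        assert np.isnan(out["age_p"]) and out["skipped"] == "constant_age_or_M"

    def test_unknown_smoking_dropped_from_smoking_test_only(self):
        rng = np.random.default_rng(6)
        subj = self._subjects(30, rng)
        subj.loc[:20, "smoking"] = "unknown"
        m = rng.uniform(0, 1, 30)
        mat = pd.DataFrame({"s1": m}, index=subj["subject_id"])
        out = covariate_screen(mat, subj).iloc[0]
        known = subj["smoking"] != "unknown"
        expected = mann_whitney_p(
            m[known & (subj["smoking"] == "yes")],
            m[known & (subj["smoking"] == "no")],
        )
        assert out["smoking_p"] == pytest.approx(expected)
        assert not np.isnan(out["sex_p"])


class TestLogistic:
    def _fixture(self, n=40, seed=7, effect=0.0):
        rng = np.random.default_rng(seed)
        m = rng.uniform(0.1, 0.9, n)
        age = rng.uniform(18, 45, n)
        sex = rng.integers(0, 2, n)
        logit = -0.5 + effect * m
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        subj = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": np.where(y == 1, "case", "control"),
                "age": age,
                "sex": np.where(sex == 1, "M", "F"),
                "cognitive_T": rng.normal(45, 8, n),
                "smoking": "no",
                "hap1": "h1",
                "hap2": rng.choice(["h1", "h2"], n),
            }
        )
        mat = pd.DataFrame({"siteX": m}, index=subj["subject_id"])
        return subj, mat

    def test_matches_independent_ml_oracle(self):
        subj, mat = self._fixture(effect=1.5)
        out = logistic_per_site(mat, subj, ["siteX"], ["h1", "h2"]).iloc[0]
        # rebuild the same design and fit by raw Newton iteration
        X = np.column_stack(
            [
                np.ones(len(subj)),
                mat["siteX"].to_numpy(),
                subj["age"].to_numpy(float),
                (subj["sex"] == "M").to_numpy(float),
                ((subj["hap1"] == "h2") | False).astype(float)
                + (subj["hap2"] == "h2").astype(float),
            ]
        )
        y = (subj["group"] == "case").to_numpy(float)
        beta = logistic_ml_fit(X, y)
        assert out["logistic_beta"] == pytest.approx(beta[1], abs=1e-6)

    def test_intercept_only_balanced(self):
        n = 40
        y = np.array([0, 1] * (n // 2), float)
        fit = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)

    def test_separation_flagged(self):
        subj, mat = self._fixture(n=30)
        subj["group"] = np.where(mat["siteX"].to_numpy() > 0.5, "case", "control")
        out = logistic_per_site(mat, subj, ["siteX"], ["h1", "h2"]).iloc[0]
        assert np.isnan(out["logistic_p"])
        assert out["flag"] != ""


class TestMatchedPairs:
    def _subjects(self, genotypes):
        rows = []
        for sid, (group, g) in genotypes.items():
            rows.append(
                {
                    "subject_id": sid, "group": group, "age": 30.0, "sex": "F",
                    "cognitive_T": 45.0, "smoking": "no",
                    "hap1": g[0], "hap2": g[1],
                }
            )
        return pd.DataFrame(rows)

    def test_single_pair_formed_regardless_of_coverage(self):
        subj = self._subjects(
            {"c1": ("case", ("a", "b")), "k1": ("control", ("a", "b"))}
        )
        mat = pd.DataFrame({"s": [0.5, 0.5]}, index=["c1", "k1"])
        pairs, _ = matched_pair_analysis(
            subj, {"c1": 10, "k1": 99}, mat, np.random.default_rng(0)
        )
        assert len(pairs) == 1 and pairs[0].control_id == "k1"

    def test_genotype_mismatch_leaves_case_unmatched(self):
        subj = self._subjects(
            {"c1": ("case", ("a", "a")), "k1": ("control", ("a", "b"))}
        )
        mat = pd.DataFrame({"s": [0.5, 0.5]}, index=["c1", "k1"])
        pairs, _ = matched_pair_analysis(
            subj, {}, mat, np.random.default_rng(0)
        )
        assert pairs == []

    def test_matches_exhaustive_oracle_on_toy(self):
        """6 cases x 6 controls with unique nearest-coverage partners: the
        greedy pairing achieves the brute-force optimum."""
        geno = ("a", "b")
        cases = {f"c{i}": (geno, 10.0 * i) for i in range(6)}
        controls = {f"k{i}": (geno, 10.0 * i + 1.0) for i in range(6)}
        subj = self._subjects(
            {**{c: ("case", geno) for c in cases},
             **{k: ("control", geno) for k in controls}}
        )
        coverage = {**{c: cov for c, (_, cov) in cases.items()},
                    **{k: cov for k, (_, cov) in controls.items()}}
        mat = pd.DataFrame({"s": 0.5}, index=list(cases) + list(controls))
        pairs, _ = matched_pair_analysis(subj, coverage, mat,
                                         np.random.default_rng(1))
        total = sum(p.coverage_difference for p in pairs)
        n_opt, cost_opt = best_matching(cases, controls)
        assert len(pairs) == n_opt == 6
        assert total == pytest.approx(cost_opt)

    def test_controls_used_at_most_once(self):
        subj = self._subjects(
            {
                "c1": ("case", ("a", "b")), "c2": ("case", ("a", "b")),
                "k1": ("control", ("a", "b")),
            }
        )
        mat = pd.DataFrame({"s": [0.4, 0.6, 0.5]}, index=["c1", "c2", "k1"])
        pairs, _ = matched_pair_analysis(subj, {}, mat, np.random.default_rng(2))
        assert len(pairs) == 1


class TestCognitionGlm:
    def _subjects(self, n, rng, diag_effect=-10.97, risk_effect=0.0):
        risk = rng.integers(0, 3, n)
        group = np.array(["case", "control"])[rng.integers(0, 2, n)]
        t = (
            49.63
            + diag_effect * (group == "case")
            + risk_effect * risk
            + rng.normal(0, 5.5, n)
        )
        hap1 = np.where(risk >= 1, "risk", "other")
        hap2 = np.where(risk == 2, "risk", "other")
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": group,
                "age": rng.uniform(18, 45, n),
                "sex": np.where(rng.integers(0, 2, n) == 1, "M", "F"),
                "cognitive_T": t,
                "smoking": "no",
                "hap1": hap1,
                "hap2": hap2,
            }
        )

    def test_null_dosage_p_uniform(self):
        """With no genotype effect the dosage p-values are U(0,1)."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(500):
            subj = self._subjects(60, rng)
            mat = pd.DataFrame(index=subj["subject_id"])
            out = cognition_glm(mat, subj, "genotype", "risk_dosage", "risk")
            ps.append(out["p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_diagnosis_effect_recovered(self):
        rng = np.random.default_rng(12)
        subj = self._subjects(2000, rng)
        mat = pd.DataFrame(index=subj["subject_id"])
        out = cognition_glm(mat, subj, "genotype", "risk_dosage", "risk")
        assert out["coef_diagnosis"] == pytest.approx(-10.97, abs=0.6)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        subj = self._subjects(80, rng, risk_effect=1.5)
        mat = pd.DataFrame(index=subj["subject_id"])
        out = cognition_glm(mat, subj, "genotype", "risk_dosage", "risk")
        dosage = (subj["hap1"] == "risk").astype(float) + (
            subj["hap2"] == "risk"
        ).astype(float)
        X = np.column_stack(
            [
                np.ones(len(subj)),
                subj["age"].to_numpy(float),
                (subj["sex"] == "M").to_numpy(float),
                (subj["group"] == "case").to_numpy(float),
                dosage.to_numpy(),
            ]
        )
        beta = ols_normal_equations(X, subj["cognitive_T"].to_numpy(float))
        assert out["beta"] == pytest.approx(beta[4], abs=1e-8)

    def test_full_genotype_coding_runs(self):
        rng = np.random.default_rng(14)
        subj = self._subjects(80, rng, risk_effect=2.0)
        mat = pd.DataFrame(index=subj["subject_id"])
        out = cognition_glm(mat, subj, "genotype", "full_genotype")
        assert 0 < out["p"] <= 1


class TestBhFdr:
    def test_direct_formula_example(self):
        q, flags = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])
        assert flags.all()

    def test_single_p(self):
        q, _ = bh_fdr([0.04])
        assert q[0] == pytest.approx(0.04)

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_direct_formula_and_monotone(self, ps):
        q, _ = bh_fdr(ps)
        assert np.allclose(q, bh_direct(ps), atol=1e-12)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty(self):
        q, flags = bh_fdr([])
        assert len(q) == 0 and len(flags) == 0


class TestPooledT:
    def test_reported_cognitive_contrast(self):
        t, p = pooled_t_from_summary(38.66, 6.53, 77, 49.63, 5.04, 70)
        assert abs(t) == pytest.approx(11.31, abs=0.02)
        assert p < 1e-6

    def test_equal_means_zero(self):
        t, _ = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0

    def test_agrees_with_raw_data_t(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 25)
        t_raw, p_raw = stats.ttest_ind(x, y, equal_var=True)
        t_sum, p_sum = pooled_t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)
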