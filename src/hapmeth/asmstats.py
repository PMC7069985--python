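"""Per-site ASM statistics: rank tests, covariate screens, regressions, FDR.

The battery mirrors a haplotype-resolved methylation study: Kruskal-Wallis
across haplotypes with Mann-Whitney post-hocs (risk haplotype vs the pooled
others), sex / age / smoking covariate screens, per-site logistic regression
of diagnosis on M adjusted for sex, age and haplotype dosage, a matched-pairs
Wilcoxon analysis controlling haplotype and coverage, general linear models
of the cognitive T-score, and Benjamini-Hochberg FDR at 0.05 per test family.
All tests are two-sided; rank tests use the tie-corrected normal/chi-square
approximations without continuity correction, so a two-group Kruskal-Wallis
agrees with the two-sided Mann-Whitney asymptotically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value, tie-corrected normal approximation.

    Degenerate inputs (all values identical across both groups) give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def kruskal_p(groups: Sequence[np.ndarray]) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p; all-equal data -> (0, 1)."""
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def rank_tests(
    records: pd.DataFrame,
    risk_haplotype: str,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Kruskal-Wallis ASM test and risk-vs-others Mann-Whitney post-hoc per site.

    ``records`` is the long (subject, haplotype, site, M) table; one
    observation per (subject, haplotype). Sites with any haplotype group
    below ``min_per_group`` observations are reported as skipped.
    """
    rows = []
    for site_id, sub in records.groupby("site_id", sort=True):
        groups = {h: g["M"].to_numpy() for h, g in sub.groupby("haplotype")}
        row: Dict[str, object] = {"site_id": site_id}
        for h, v in groups.items():
            row[f"n_{h}"] = len(v)
            row[f"mean_{h}"] = float(np.mean(v))
            row[f"sd_{h}"] = float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
        if len(groups) < 2 or any(len(v) < min_per_group for v in groups.values()):
            row.update(kw_p=np.nan, kw_h=np.nan, posthoc_p=np.nan, skipped="small_group")
            rows.append(row)
            continue
        h_stat, kw_p = kruskal_p(list(groups.values()))
        row.update(kw_h=h_stat, kw_p=kw_p, skipped="")
        if risk_haplotype in groups and len(groups) > 1:
            others = np.concatenate(
                [v for h, v in groups.items() if h != risk_haplotype]
            )
            row["posthoc_p"] = mann_whitney_p(groups[risk_haplotype], others)
        else:
            row["posthoc_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def covariate_screen(matrix: pd.DataFrame, subjects: pd.DataFrame) -> pd.DataFrame:
    """Sex and smoking Mann-Whitney screens and Spearman age correlation per site.

    Subjects with unknown smoking status are dropped from the smoking test
    only. Screens with a degenerate covariate are skipped with a reason.
    """
    subj = subjects.set_index("subject_id").loc[matrix.index]
    rows = []
    for site_id in matrix.columns:
        m = matrix[site_id]
        ok = m.notna()
        row: Dict[str, object] = {"site_id": site_id, "skipped": ""}
        v = m[ok].to_numpy()
        sex = subj.loc[ok, "sex"].to_numpy()
        if len(set(sex)) == 2 and min((sex == "F").sum(), (sex == "M").sum()) >= 2:
            row["sex_p"] = mann_whitney_p(v[sex == "F"], v[sex == "M"])
        else:
            row["sex_p"] = np.nan
        age = subj.loc[ok, "age"].to_numpy(dtype=float)
        if len(v) >= 3 and np.ptp(age) > 0 and np.ptp(v) > 0:
            rho, p = stats.spearmanr(age, v)
            row["age_rho"], row["age_p"] = float(rho), float(p)
        else:
            row["age_rho"], row["age_p"] = np.nan, np.nan
            row["skipped"] = "constant_age_or_M"
        smoking = subj.loc[ok, "smoking"]
        known = smoking != "unknown"
        vy = v[known & (smoking == "yes").to_numpy()]
        vn = v[known & (smoking == "no").to_numpy()]
        row["smoking_p"] = (
            mann_whitney_p(vy, vn) if len(vy) >= 2 and len(vn) >= 2 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _haplotype_dosage(
    subjects: pd.DataFrame, haplotype_names: Sequence[str]
) -> pd.DataFrame:
    """Per-subject counts of each non-reference haplotype (first name = reference)."""
    out = {}
    for h in haplotype_names[1:]:
        out[f"dosage_{h}"] = subjects.apply(
            lambda r: (r["hap1"] == h) + (r["hap2"] == h), axis=1
        )
    return pd.DataFrame(out, index=subjects.index)


def logistic_per_site(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    analysis_set: Sequence[str],
    haplotype_names: Sequence[str],
) -> pd.DataFrame:
    """Per-site logistic regression: diagnosis ~ M + age + sex + haplotype dosage.

    Fit by iteratively reweighted least squares (maximum likelihood); the
    reported p is the Wald test of the M coefficient. Separation or
    non-convergence flags the site as untestable instead of emitting a p.
    """
    subj = subjects.set_index("subject_id").loc[matrix.index]
    dosage = _haplotype_dosage(subj, list(haplotype_names))
    rows = []
    for site_id in analysis_set:
        if site_id not in matrix.columns:
            continue
        m = matrix[site_id]
        ok = m.notna()
        row: Dict[str, object] = {"site_id": site_id, "logistic_p": np.nan, "flag": ""}
        if ok.sum() < 10:
            row["flag"] = "too_few_subjects"
            rows.append(row)
            continue
        X = pd.DataFrame(
            {
                "M": m[ok].astype(float),
                "age": subj.loc[ok, "age"].astype(float),
                "sex_M": (subj.loc[ok, "sex"] == "M").astype(float),
            }
        )
        for c in dosage.columns:
            X[c] = dosage.loc[ok, c].astype(float)
        X = sm.add_constant(X, has_constant="add")
        y = (subj.loc[ok, "group"] == "case").astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not fit.mle_retvals.get("converged", False):
                row["flag"] = "not_converged"
            else:
                row["logistic_p"] = float(fit.pvalues["M"])
                row["logistic_beta"] = float(fit.params["M"])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            row["flag"] = "separation"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MatchedPair:
    case_id: str
    control_id: str
    genotype: Tuple[str, str]
    coverage_difference: float


def matched_pair_analysis(
    subjects: pd.DataFrame,
    coverage: Dict[str, float],
    matrix: pd.DataFrame,
    rng: np.random.Generator,
) -> Tuple[List[MatchedPair], pd.DataFrame]:
    """Greedy genotype- and coverage-matched case-control pairing + Wilcoxon.

    Cases are processed in a seeded random order; each is matched to the
    unused control with the identical (unordered) genotype minimizing the
    absolute coverage difference, ties breaking to the smallest control id.
    Per site, a two-sided Wilcoxon signed-rank test compares paired M values.
    """
    subj = subjects.set_index("subject_id")
    cases = [s for s in subj.index if subj.loc[s, "group"] == "case"]
    controls = [s for s in subj.index if subj.loc[s, "group"] == "control"]
    geno = {
        s: tuple(sorted((subj.loc[s, "hap1"], subj.loc[s, "hap2"])))
        for s in subj.index
    }
    order = [cases[i] for i in rng.permutation(len(cases))]
    unused = set(controls)
    pairs: List[MatchedPair] = []
    for case in order:
        candidates = [c for c in unused if geno[c] == geno[case]]
        if not candidates:
            continue
        candidates.sort(
            key=lambda c: (abs(coverage.get(c, 0.0) - coverage.get(case, 0.0)), c)
        )
        chosen = candidates[0]
        unused.discard(chosen)
        pairs.append(
            MatchedPair(
                case,
                chosen,
                geno[case],
                abs(coverage.get(chosen, 0.0) - coverage.get(case, 0.0)),
            )
        )
    rows = []
    for site_id in matrix.columns:
        a, b = [], []
        for p in pairs:
            if p.case_id in matrix.index and p.control_id in matrix.index:
                x, y = matrix.at[p.case_id, site_id], matrix.at[p.control_id, site_id]
                if not (np.isnan(x) or np.isnan(y)):
                    a.append(x)
                    b.append(y)
        row = {"site_id": site_id, "n_pairs": len(a), "wilcoxon_matched_p": np.nan}
        if len(a) >= 2:
            d = np.asarray(a) - np.asarray(b)
            if np.all(d == 0):
                row["wilcoxon_matched_p"] = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = stats.wilcoxon(a, b, alternative="two-sided")
                row["wilcoxon_matched_p"] = float(res.pvalue)
        rows.append(row)
    return pairs, pd.DataFrame(rows)


def cognition_glm(
    matrix: pd.DataFrame,
    subjects: pd.DataFrame,
    predictor: str = "genotype",
    coding: str = "risk_dosage",
    risk_haplotype: Optional[str] = None,
    site_id: Optional[str] = None,
) -> Dict[str, float]:
    """General linear model of the cognitive T-score.

    cognitive_T ~ predictor + age + sex + diagnosis, ordinary least squares.
    ``predictor`` is "genotype" (coding "full_genotype": all diplotypes as a
    factor, F test; coding "risk_dosage": 0/1/2 risk alleles, Wald t test) or
    "site_M" (the allele-averaged M of one site).
    """
    subj = subjects.set_index("subject_id")
    if predictor == "site_M":
        if site_id is None:
            raise ValueError("site_M predictor needs a site_id")
        subj = subj.loc[matrix.index]
        pred = matrix[site_id]
    elif predictor == "genotype":
        pred = None
    else:
        raise ValueError(f"unknown predictor {predictor!r}")

    base = pd.DataFrame(
        {
            "age": subj["age"].astype(float),
            "sex_M": (subj["sex"] == "M").astype(float),
            "diagnosis": (subj["group"] == "case").astype(float),
        },
        index=subj.index,
    )
    y = subj["cognitive_T"].astype(float)

    if predictor == "site_M":
        X = base.copy()
        X["predictor"] = pred.astype(float)
        ok = X.notna().all(axis=1)
        X, y = sm.add_constant(X[ok], has_constant="add"), y[ok]
        fit = sm.OLS(y, X).fit()
        return {
            "p": float(fit.pvalues["predictor"]),
            "beta": float(fit.params["predictor"]),
            "coef_diagnosis": float(fit.params["diagnosis"]),
        }

    if coding == "risk_dosage":
        if risk_haplotype is None:
            raise ValueError("risk_dosage coding needs the risk haplotype")
        X = base.copy()
        X["predictor"] = (
            (subj["hap1"] == risk_haplotype).astype(int)
            + (subj["hap2"] == risk_haplotype).astype(int)
        ).astype(float)
        X, yv = sm.add_constant(X, has_constant="add"), y
        fit = sm.OLS(yv, X).fit()
        return {
            "p": float(fit.pvalues["predictor"]),
            "beta": float(fit.params["predictor"]),
            "coef_diagnosis": float(fit.params["diagnosis"]),
        }
    if coding == "full_genotype":
        geno = subj.apply(lambda r: "/".join(sorted((r["hap1"], r["hap2"]))), axis=1)
        dummies = pd.get_dummies(geno, prefix="g", drop_first=True).astype(float)
        X = pd.concat([base, dummies], axis=1)
        X = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            return {"p": np.nan, "flag": "rank_deficient"}  # type: ignore[return-value]
        fit = sm.OLS(y, X).fit()
        if dummies.shape[1] == 0:
            return {"p": np.nan, "coef_diagnosis": float(fit.params["diagnosis"])}
        ftest = fit.f_test([f"{c} = 0" for c in dummies.columns])
        return {
            "p": float(ftest.pvalue),
            "coef_diagnosis": float(fit.params["diagnosis"]),
        }
    raise ValueError(f"unknown coding {coding!r}")


def bh_fdr(pvalues: Sequence[float], alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    NaN p-values propagate as NaN q and a False flag; q is monotone
    non-decreasing in p within the family.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return q, flags
    rej, qv, _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    q[ok] = qv
    flags[ok] = qv <= alpha
    return q, flags


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, float]:
    """Pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=True
    )
    return float(res.statistic), float(res.pvalue)
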