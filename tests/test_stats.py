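"""Mixed-model inference, LSD contrasts, rank statistics and study analysis."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mucoquant.stats import (
    ModelSpec,
    SchemaError,
    SingularDesignError,
    dichotomize_nancy,
    fit_lmm,
    icc,
    kruskal_wallis,
    pairwise_contrasts,
    run_study_analysis,
    spearman_corr,
    validate_cohort,
)
from mucoquant.synthetic import (
    CohortDesign,
    GroupSpec,
    default_cohort_design,
    generate_cohort_counts,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def midranks(v):
    v = np.asarray(v, float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j < len(v) and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = (i + j - 1) / 2 + 1
        i = j
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of mid-ranks."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def kruskal_oracle(groups):
    """Tie-corrected Kruskal-Wallis H from the textbook rank-sum formula."""
    all_v = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(all_v)
    ranks = midranks(all_v)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_v, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


# ---------------------------------------------------------------------------
# Nancy dichotomy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("grade,expected", [
    (0, "inactive"), (1, "inactive"), (2, "active"), (3, "active"), (4, "active")])
def test_nancy_dichotomy(grade, expected):
    assert dichotomize_nancy(grade) == expected


def test_nancy_out_of_range_raises():
    with pytest.raises(ValueError):
        dichotomize_nancy(5)


# ---------------------------------------------------------------------------
# Mixed model
# ---------------------------------------------------------------------------

def _two_group_frame(values_a, values_b):
    rows = []
    for i, v in enumerate(values_a):
        rows.append({"subject_id": f"a{i}", "grp": "A", "y": v})
    for i, v in enumerate(values_b):
        rows.append({"subject_id": f"b{i}", "grp": "B", "y": v})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_identical_groups_give_unit_fold_change(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        df = _two_group_frame(vals, vals)
        res = fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp",),
                                    log_transform=False))
        row = pairwise_contrasts(res, "grp").iloc[0]
        assert row.fc == pytest.approx(1.0, abs=1e-9)
        assert row.ci_low < 1.0 < row.ci_high
        assert row.p > 0.99

    def test_reduces_to_ols_without_subject_variance(self):
        """One observation per subject: fixed effects match the closed-form
        least-squares solution to 1e-8."""
        rng = np.random.default_rng(0)
        df = _two_group_frame(rng.normal(0, 1, 30), rng.normal(0.7, 1, 30))
        res = fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp",),
                                    log_transform=False))
        x = np.column_stack([np.ones(60), (df.grp == "B").to_numpy(float)])
        beta_ols = np.linalg.lstsq(x, df.y.to_numpy(), rcond=None)[0]
        assert np.abs(res.params.to_numpy() - beta_ols).max() < 1e-8
        assert res.sigma2_subject == pytest.approx(0.0, abs=1e-8)

    def test_lsd_equals_pooled_t_test_oracle(self):
        """Three balanced groups, no subject variance: LSD p-values equal
        the classical pooled-MSE t-test (df = N - k) to 1e-6."""
        rng = np.random.default_rng(1)
        rows = []
        means = {"A": 0.0, "B": 0.4, "C": 1.0}
        for g, mu in means.items():
            for i in range(12):
                rows.append({"subject_id": f"{g}{i}", "grp": g,
                             "y": rng.normal(mu, 1.0)})
        df = pd.DataFrame(rows)
        res = fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp",),
                                    log_transform=False))
        table = pairwise_contrasts(res, "grp").set_index("contrast")
        # pooled-variance oracle
        resid = df.y - df.groupby("grp").y.transform("mean")
        mse = (resid**2).sum() / (len(df) - 3)
        for a, b in itertools.combinations("ABC", 2):
            ya = df[df.grp == a].y
            yb = df[df.grp == b].y
            se = np.sqrt(mse * (1 / len(ya) + 1 / len(yb)))
            t = (ya.mean() - yb.mean()) / se
            p = 2 * sps.t.sf(abs(t), len(df) - 3)
            assert table.loc[f"{a} vs {b}", "p"] == pytest.approx(p, abs=1e-6)

    def test_recovers_planted_fold_change_and_covers(self):
        """Planted FC 2.0 (sigma_b 0.3, sigma_e 0.4, 50 subjects/group)
        estimated within the generative band; CI covers the truth in most
        of a small replicate set."""
        fcs, cover = [], 0
        for r in range(30):
            d = CohortDesign(
                groups=[GroupSpec("A", 50, "HC", False),
                        GroupSpec("B", 50, "UC", False)],
                baselines={("CD3", "epithelium"): 150.0},
                fold_changes={"A": {}, "B": {("CD3", "epithelium"): 2.0}},
                sigma_subject=0.3, sigma_resid=0.4, proximal_fold_change=1.0,
                steroid_prob={"HC": 0, "inactive": 0, "active": 0},
                denominator_sd=0.0, seed=500 + r)
            df = generate_cohort_counts(d)
            df["log_measure"] = np.log(
                100 * (df["count"] + 0.5) / df["epithelial_cells"])
            res = fit_lmm(df, ModelSpec(
                response="log_measure", fixed_factors=("group", "location"),
                log_transform=False))
            row = pairwise_contrasts(res, "group", pairs=[("B", "A")]).iloc[0]
            fcs.append(row.fc)
            cover += row.ci_low <= 2.0 <= row.ci_high
        assert 1.7 <= np.mean(fcs) <= 2.35
        assert cover >= 24  # ~95% nominal on 30 replicates

    def test_variance_components_and_icc(self):
        d = CohortDesign(
            groups=[GroupSpec("A", 200, "HC", False)],
            baselines={("CD3", "epithelium"): 2000.0},
            fold_changes={"A": {}},
            sigma_subject=0.5, sigma_resid=0.5, proximal_fold_change=1.0,
            steroid_prob={"HC": 0, "inactive": 0, "active": 0},
            denominator_sd=0.0, seed=77)
        df = generate_cohort_counts(d)
        df["log_measure"] = np.log(df["count"].astype(float))
        res = fit_lmm(df, ModelSpec(response="log_measure", log_transform=False))
        assert 0.4 <= icc(res) <= 0.6
        assert res.sigma2_subject == pytest.approx(0.25, rel=0.3)
        assert res.sigma2_resid == pytest.approx(0.25, rel=0.3)

    def test_matches_independent_reml_implementation(self):
        """Profiled-REML estimates agree with an independently implemented
        random-intercept REML fit (statsmodels MixedLM) on fixed effects,
        standard errors and both variance components."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        rows = []
        for g, mu in (("A", 0.0), ("B", 0.6), ("C", 1.1)):
            for i in range(20):
                b = rng.normal(0, 0.5)
                for _ in range(3):
                    rows.append({"subject_id": f"{g}{i}", "grp": g,
                                 "y": mu + b + rng.normal(0, 0.4)})
        df = pd.DataFrame(rows)
        res = fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp",),
                                    log_transform=False))
        ref = smf.mixedlm("y ~ grp", df, groups=df["subject_id"]).fit(reml=True)
        assert np.allclose(res.params.to_numpy(), ref.fe_params.values, atol=1e-5)
        assert np.allclose(np.sqrt(np.diag(res.cov_params)),
                           ref.bse_fe.values, atol=1e-5)
        assert res.sigma2_subject == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                                   rel=1e-4)
        assert res.sigma2_resid == pytest.approx(float(ref.scale), rel=1e-4)

    def test_singular_design_names_aliased_column(self):
        df = _two_group_frame([1, 2, 3], [4, 5, 6])
        df["dup"] = df["grp"]
        with pytest.raises(SingularDesignError, match="dup"):
            fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp", "dup"),
                                  log_transform=False))

    def test_contrast_of_level_with_itself(self):
        df = _two_group_frame([1.0, 2.0, 4.0], [2.0, 3.0, 5.0])
        res = fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp",),
                                    log_transform=False))
        row = pairwise_contrasts(res, "grp", pairs=[("A", "A")]).iloc[0]
        assert row.fc == 1.0
        assert row.p == 1.0

    def test_back_transform_consistency(self):
        df = _two_group_frame([1.0, 2.0, 4.0], [3.0, 5.0, 9.0])
        res = fit_lmm(df, ModelSpec(response="y", fixed_factors=("grp",),
                                    log_transform=False))
        row = pairwise_contrasts(res, "grp", pairs=[("B", "A")]).iloc[0]
        assert row.fc == pytest.approx(np.exp(row.log_fc), rel=1e-15)
        assert row.ci_low < row.fc < row.ci_high


# ---------------------------------------------------------------------------
# Rank statistics vs brute-force oracles
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_corr(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert spearman_corr(x, x[::-1])[0] == pytest.approx(-1.0)

    def test_tied_case_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho, _ = spearman_corr(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_exhaustive_permutations_match_oracle(self):
        """All permutations up to n = 5 plus tied grids up to n = 8."""
        for n in (3, 4, 5):
            base = np.arange(n, dtype=float)
            for perm in itertools.permutations(range(n)):
                rho, _ = spearman_corr(base, np.array(perm, float))
                assert rho == pytest.approx(
                    spearman_oracle(base, np.array(perm, float)), abs=1e-12)
        y8 = np.arange(8, dtype=float)
        for x in itertools.product((0.0, 1.0, 2.0), repeat=8):
            if len(set(x)) == 1:
                continue  # rho undefined for a constant margin
            rho, _ = spearman_corr(np.array(x), y8)
            assert rho == pytest.approx(spearman_oracle(np.array(x), y8), abs=1e-12)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2], [3, 4])


class TestKruskalWallis:
    def test_identical_constant_groups_give_zero(self):
        assert kruskal_wallis([[2, 2, 2], [2, 2], [2, 2, 2, 2]]) == (0.0, 1.0)

    def test_two_group_example_matches_formula(self):
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(kruskal_oracle([[1, 2, 3], [4, 5, 6]]), abs=1e-12)

    def test_exhaustive_small_cases_match_oracle(self):
        """All 2-group splits of tied sequences up to n = 8 match the
        tie-corrected rank-sum formula to 1e-12."""
        for vals in itertools.product((0.0, 1.0, 2.0), repeat=6):
            g1, g2 = list(vals[:3]), list(vals[3:])
            if len(set(vals)) == 1:
                continue
            h, p = kruskal_wallis([g1, g2])
            assert h == pytest.approx(kruskal_oracle([g1, g2]), abs=1e-12)
            assert p == pytest.approx(float(sps.chi2.sf(h, 1)), abs=1e-12)
        vals8 = [1.0, 1.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0]
        for k in (2, 4, 6):
            h, _ = kruskal_wallis([vals8[:k], vals8[k:]])
            assert h == pytest.approx(kruskal_oracle([vals8[:k], vals8[k:]]),
                                      abs=1e-12)

    def test_single_group_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


# ---------------------------------------------------------------------------
# Whole-study analysis
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_results():
    design = default_cohort_design(seed=3)
    design.groups = [GroupSpec(g.name, 15, g.diagnosis, g.active)
                     for g in design.groups]
    cohort = generate_cohort_counts(design)
    return cohort, run_study_analysis(cohort)


class TestStudyAnalysis:

    def test_contrast_table_schema(self, small_results):
        _, res = small_results
        needed = {"stain", "compartment", "measure", "contrast",
                  "fc", "ci_low", "ci_high", "p"}
        assert needed.issubset(res.contrasts.columns)
        # one row per (stain, compartment, pair): 5 groups -> 10 pairs
        per_unit = res.contrasts.groupby(["stain", "compartment"]).size()
        assert (per_unit == 10).all()
        assert set(res.contrasts.stain) == {"CD3", "TCRdelta", "gd_cd3_ratio"}

    def test_fold_changes_positive_and_bracketed(self, small_results):
        _, res = small_results
        c = res.contrasts
        assert (c.fc > 0).all()
        assert ((c.ci_low <= c.fc) & (c.fc <= c.ci_high)).all()
        assert c.p.between(0, 1).all()

    def test_variance_components_and_icc_in_range(self, small_results):
        _, res = small_results
        vc = res.variance_components
        assert (vc.sigma2_subject >= 0).all()
        assert (vc.sigma2_resid > 0).all()
        assert vc.icc.between(0, 1).all()

    def test_covariate_and_interaction_tables(self, small_results):
        _, res = small_results
        assert {"oral_steroids", "age", "gender",
                "duration_months"}.issubset(set(res.covariate_effects.covariate))
        assert (res.interactions.p.dropna().between(0, 1)).all()

    def test_spearman_and_kruskal_tables(self, small_results):
        _, res = small_results
        assert res.spearman.rho.abs().max() <= 1.0
        assert (res.kruskal.H >= 0).all()

    def test_results_roundtrip_to_disk(self, small_results, tmp_path):
        _, res = small_results
        res.write(tmp_path)
        assert (tmp_path / "contrasts.csv").exists()
        assert (tmp_path / "report.txt").read_text().startswith(
            "Compartmental T-cell study analysis")
        back = pd.read_csv(tmp_path / "contrasts.csv")
        assert len(back) == len(res.contrasts)

    def test_schema_violations_reported_with_rows(self):
        design = default_cohort_design(seed=4)
        cohort = generate_cohort_counts(design)
        cohort.loc[3, "nancy_grade"] = 9
        with pytest.raises(SchemaError, match="3"):
            validate_cohort(cohort)
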