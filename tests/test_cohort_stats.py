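import numpy as np
import pandas as pd
import pytest
import scipy.stats as sp_stats
from hypothesis import given, settings
from hypothesis import strategies as st

from tspoquant.cohort_stats import (
    clinical_correlations,
    levene_test,
    overall_percent_difference,
    percent_difference,
    region_summary,
    significance_level,
    stratified_t_tests,
    two_way_ancova,
)
from tspoquant.errors import NumericalError, ValidationError
from tspoquant.synthetic_data import (
    REFERENCE_CELL_MEANS,
    REFERENCE_CELL_SDS,
    REFERENCE_N_PER_CELL,
    REFERENCE_ROIS,
    CohortDesign,
    simulate_cohort,
)
from tspoquant.tac_io import CohortTable

# ---------------------------------------------------------------------------
# independent oracles


def ancova_oracle(df, covariate="injected_amount"):
    """Type-III F tests via brute-force effects-coded regression: each
    effect's F compares the full model against the model with that
    single column deleted."""
    d = np.where(df["disease"] == "HC", 1.0, -1.0)
    g = np.where(df["genotype"] == "HAB", 1.0, -1.0)
    y = df["vt"].to_numpy(float)
    cols = [np.ones(len(df))]
    names = []
    if covariate:
        cols.append(df[covariate].to_numpy(float))
        names.append(covariate)
    cols += [d, g, d * g]
    names += ["disease", "genotype", "disease:genotype"]
    X = np.column_stack(cols)

    def rss(Xm):
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        r = y - Xm @ beta
        return float(r @ r)

    full = rss(X)
    df_resid = len(df) - X.shape[1]
    out = {}
    for i, name in enumerate(names, start=1):
        F = (rss(np.delete(X, i, axis=1)) - full) / (full / df_resid)
        out[name] = F
    return out, df_resid


def pooled_t_oracle(x, y):
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def _mini_cohort(rng, n=8, rois=("frontal",), geno_shift=0.0):
    rows = []
    for roi in rois:
        i = 0
        for dis in ("HC", "PD"):
            for gen in ("MAB", "HAB"):
                for _ in range(n):
                    rows.append(
                        {
                            "subject_id": f"s{i}",
                            "disease": dis,
                            "genotype": gen,
                            "roi": roi,
                            "vt": 10.0
                            + (geno_shift if gen == "HAB" else 0.0)
                            + rng.normal(0, 1.5),
                            "injected_amount": rng.normal(4.9, 0.25),
                        }
                    )
                    i += 1
    return CohortTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------


class TestPercentDifference:
    def test_published_style_cells(self):
        assert round(percent_difference(13.9, 19.4), 1) == 33.0
        assert round(percent_difference(8.0, 13.5), 1) == 51.2

    def test_equal_means_give_zero(self):
        assert percent_difference(7.3, 7.3) == 0.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            percent_difference(0.0, 5.0)

    @given(st.floats(0.1, 100.0), st.floats(0.1, 100.0), st.floats(0.1, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_scale_invariant(self, a, b, c):
        assert percent_difference(a, b) == pytest.approx(-percent_difference(b, a))
        assert percent_difference(c * a, c * b) == pytest.approx(
            percent_difference(a, b), rel=1e-9
        )


class TestAncova:
    def test_matches_regression_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            table = _mini_cohort(rng, n=rng.integers(3, 15))
            res = two_way_ancova(table, "frontal")
            orc, df_resid = ancova_oracle(table.df)
            for eff in ("disease", "genotype", "disease:genotype"):
                assert res[eff].statistic == pytest.approx(orc[eff], abs=1e-8)
                assert res[eff].df == (1, df_resid)

    def test_duplicated_groups_give_zero_f(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 1, 6)
        rows = []
        i = 0
        for dis in ("HC", "PD"):
            for gen in ("MAB", "HAB"):
                for v in base:
                    rows.append(
                        {
                            "subject_id": f"s{i}",
                            "disease": dis,
                            "genotype": gen,
                            "roi": "frontal",
                            "vt": v,
                        }
                    )
                    i += 1
        res = two_way_ancova(CohortTable(pd.DataFrame(rows)), "frontal", covariate=None)
        for eff in ("disease", "genotype", "disease:genotype"):
            assert res[eff].statistic == pytest.approx(0.0, abs=1e-6)

    def test_empty_cell_named_in_error(self):
        rng = np.random.default_rng(1)
        table = _mini_cohort(rng, n=4)
        df = table.df[
            ~((table.df.disease == "PD") & (table.df.genotype == "HAB"))
        ].reset_index(drop=True)
        with pytest.raises(ValidationError, match=r"\(PD, HAB\)"):
            two_way_ancova(CohortTable(df), "frontal")

    def test_genotype_effect_detected_disease_null_calibrated(self):
        """With a strong genotype shift and no disease effect, genotype
        is significant every time and disease rejects at ~alpha."""
        rng = np.random.default_rng(9)
        geno_p, dis_p = [], []
        for _ in range(60):
            table = _mini_cohort(rng, n=13, geno_shift=1.5 * 1.5)
            res = two_way_ancova(table, "frontal")
            geno_p.append(res["genotype"].p)
            dis_p.append(res["disease"].p)
        assert np.mean(np.asarray(geno_p) < 0.05) > 0.95
        assert np.mean(np.asarray(dis_p) < 0.05) < 0.2
        # null p-values look uniform
        ks = sp_stats.kstest(dis_p, "uniform")
        assert ks.pvalue > 0.01


class TestLevene:
    def test_matches_anova_on_absolute_deviations(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, s, n) for s, n in ((1, 12), (2, 9), (1.5, 15))]
        res = levene_test(*groups)
        devs = [np.abs(g - g.mean()) for g in groups]
        F, p = sp_stats.f_oneway(*devs)
        assert res.statistic == pytest.approx(F, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_zero_spread_everywhere_is_degenerate(self):
        with pytest.raises(NumericalError):
            levene_test([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_equal_variance_calibration(self):
        rng = np.random.default_rng(5)
        n_keep = sum(
            levene_test(rng.normal(0, 1, 15), rng.normal(5, 1, 15)).p > 0.05
            for _ in range(100)
        )
        assert n_keep >= 90

    def test_gates_significance_level(self):
        assert significance_level(0.016) == 0.01
        assert significance_level(0.2) == 0.05


class TestStratifiedT:
    def test_identical_groups(self):
        rows = []
        for i, gen in enumerate(["MAB"] * 3 + ["HAB"] * 3):
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "disease": "HC",
                    "genotype": gen,
                    "roi": "frontal",
                    "vt": [8.0, 9.0, 10.0][i % 3],
                }
            )
        res = stratified_t_tests(CohortTable(pd.DataFrame(rows)), "HC")
        assert res["frontal"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["frontal"].p == pytest.approx(1.0)

    def test_matches_textbook_formula_on_3_plus_3(self):
        mab = [8.1, 9.3, 8.8]
        hab = [12.0, 13.4, 12.6]
        rows = [
            {
                "subject_id": f"s{i}",
                "disease": "PD",
                "genotype": gen,
                "roi": "putamen",
                "vt": v,
            }
            for i, (gen, v) in enumerate(zip(["MAB"] * 3 + ["HAB"] * 3, mab + hab))
        ]
        res = stratified_t_tests(CohortTable(pd.DataFrame(rows)), "PD")
        assert res["putamen"].statistic == pytest.approx(
            pooled_t_oracle(hab, mab), abs=1e-10
        )
        assert res["putamen"].df == (4,)

    def test_singleton_group_rejected(self):
        rows = [
            {"subject_id": "a", "disease": "HC", "genotype": "MAB", "roi": "r", "vt": 8.0},
            {"subject_id": "b", "disease": "HC", "genotype": "MAB", "roi": "r", "vt": 9.0},
            {"subject_id": "c", "disease": "HC", "genotype": "HAB", "roi": "r", "vt": 12.0},
        ]
        with pytest.raises(ValidationError):
            stratified_t_tests(CohortTable(pd.DataFrame(rows)), "HC")

    def test_published_effect_sizes_detected_in_pd_stratum(self):
        """At the published PD cell means/SDs and n = 14/16, the genotype
        contrast reaches significance in every region for most seeds."""
        hits = 0
        n_seeds = 12
        for seed in range(n_seeds):
            table, _ = simulate_cohort(
                CohortDesign(
                    roi_means=dict(REFERENCE_CELL_MEANS),
                    roi_sds=dict(REFERENCE_CELL_SDS),
                    seed=seed,
                )
            )
            res = stratified_t_tests(table, "PD")
            hits += all(r.p < 0.05 for r in res.values())
        assert hits > n_seeds / 2


class TestCorrelations:
    def _pd_table(self, rng, measure_vals, vt_vals):
        rows = []
        for i, (m, v) in enumerate(zip(measure_vals, vt_vals)):
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "disease": "PD",
                    "genotype": "HAB",
                    "roi": "frontal",
                    "vt": v,
                    "ledd": m,
                }
            )
        return CohortTable(pd.DataFrame(rows))

    def test_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = np.linspace(5, 15, 8)
        res = clinical_correlations(self._pd_table(rng, x, x), measures=("ledd",))
        assert res[0].statistic == pytest.approx(1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(300, 100, 10), rng.uniform(5, 20, 10)
        res = clinical_correlations(self._pd_table(rng, x, y), measures=("ledd",))
        r_def = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res[0].statistic == pytest.approx(r_def, abs=1e-12)

    def test_null_measure_uncorrelated(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(40):
            res = clinical_correlations(
                self._pd_table(rng, rng.normal(300, 100, 14), rng.uniform(5, 20, 14)),
                measures=("ledd",),
            )
            ps.append(res[0].p)
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_zero_variance_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(NumericalError):
            clinical_correlations(
                self._pd_table(rng, np.full(5, 300.0), np.arange(5) + 5.0),
                measures=("ledd",),
            )


class TestRegionSummary:
    def _table_with_cell_means(self):
        """Deterministic cohort whose cell means equal the reference
        values exactly (two subjects per cell, symmetric about the mean)."""
        rows = []
        i = 0
        for roi in REFERENCE_ROIS:
            for (dis, gen), n in REFERENCE_N_PER_CELL.items():
                mean = REFERENCE_CELL_MEANS[(roi, dis, gen)]
                for delta in (-0.5, 0.5):
                    rows.append(
                        {
                            "subject_id": f"s{i}",
                            "disease": dis,
                            "genotype": gen,
                            "roi": roi,
                            "vt": mean + delta,
                            "injected_amount": 4.9 + 0.01 * (i % 7),
                        }
                    )
                    i += 1
        return CohortTable(pd.DataFrame(rows))

    def test_cell_means_and_percent_differences(self):
        table = self._table_with_cell_means()
        summaries = region_summary(table, with_anova=False)
        assert len(summaries) == len(REFERENCE_ROIS)
        for s in summaries:
            for (dis, gen), m in s.cell_means.items():
                assert m == pytest.approx(REFERENCE_CELL_MEANS[(s.roi, dis, gen)])
            expect_hc = percent_difference(
                REFERENCE_CELL_MEANS[(s.roi, "HC", "MAB")],
                REFERENCE_CELL_MEANS[(s.roi, "HC", "HAB")],
            )
            assert s.pct_diff_hc == pytest.approx(expect_hc)

    def test_overall_percent_differences_match_reported_values(self):
        summaries = region_summary(self._table_with_cell_means(), with_anova=False)
        assert round(overall_percent_difference(summaries, "HC"), 1) == 32.6
        assert round(overall_percent_difference(summaries, "PD"), 1) == 43.1

    def test_single_roi_table(self):
        table = self._table_with_cell_means()
        sub = CohortTable(table.df[table.df.roi == "frontal"].reset_index(drop=True))
        assert len(region_summary(sub, with_anova=False)) == 1

    def test_permutation_invariance(self):
        table = self._table_with_cell_means()
        shuffled = CohortTable(
            table.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        a = region_summary(table, with_anova=False)
        b = region_summary(shuffled, with_anova=False)
        b = {s.roi: s for s in b}
        for s in a:
            assert s.pct_diff_hc == pytest.approx(b[s.roi].pct_diff_hc)
            assert s.cell_means == pytest.approx(b[s.roi].cell_means)
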