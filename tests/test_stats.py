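"""Repeated-measures statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from restband.stats import (
    RepeatedMeasuresAnova,
    pairwise_tests,
    rm_anova,
    run_statistics,
    within_subject_ci,
)

from conftest import make_table


def brute_force_rm_anova(y: np.ndarray) -> tuple[float, int, int]:
    """Definitional sums over every cell: independent of the implementation."""
    n, j = y.shape
    grand = sum(y[i][k] for i in range(n) for k in range(j)) / (n * j)
    ss_total = sum((y[i][k] - grand) ** 2 for i in range(n) for k in range(j))
    ss_subj = sum(j * (sum(y[i]) / j - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (sum(y[i][k] for i in range(n)) / n - grand) ** 2 for k in range(j))
    ss_err = ss_total - ss_subj - ss_cond
    df1, df2 = j - 1, (j - 1) * (n - 1)
    return (ss_cond / df1) / (ss_err / df2), df1, df2


class TestRmAnova:
    def test_toy_table_matches_brute_force(self):
        y = np.array([[1, 2, 3], [2, 3, 4], [1, 1, 1], [0, 2, 4]], dtype=float)
        res = rm_anova(make_table(y), "beta", "Fz")
        f_ref, df1, df2 = brute_force_rm_anova(y)
        assert res.F == pytest.approx(f_ref, rel=1e-12)
        assert (res.df1, res.df2) == (df1, df2)

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            y = rng.uniform(0.1, 3.0, size=(5, 3))
            res = rm_anova(make_table(y), "beta", "Fz")
            f_ref, _, _ = brute_force_rm_anova(y)
            assert res.F == pytest.approx(f_ref, rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        y = rng.uniform(0.2, 2.0, size=(12, 4))
        res = rm_anova(make_table(y), "beta", "Fz")
        d = make_table(y).data
        aov = pg.rm_anova(
            data=d, dv="power_uv2", within="condition", subject="subject_id", detailed=True
        )
        assert res.F == pytest.approx(aov.loc[0, "F"], rel=1e-9)
        assert res.p == pytest.approx(aov.loc[0, "p_unc"], rel=1e-9)
        sph = pg.sphericity(data=d, dv="power_uv2", within="condition", subject="subject_id")
        assert res.sphericity_W == pytest.approx(sph.W, rel=1e-9)
        assert res.sphericity_p == pytest.approx(sph.pval, rel=1e-9)
        eps = pg.epsilon(
            data=d, dv="power_uv2", within="condition", subject="subject_id", correction="gg"
        )
        assert res.gg_epsilon == pytest.approx(eps, rel=1e-9)

    def test_two_conditions_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            y = rng.normal(1.0, 0.4, size=(8, 2))
            res = rm_anova(make_table(np.abs(y)), "beta", "Fz")
            t, _ = sps.ttest_rel(np.abs(y)[:, 0], np.abs(y)[:, 1])
            assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_no_condition_effect_gives_zero_f(self):
        y = np.array([[1.0, 1.0, 1.0], [2.5, 2.5, 2.5], [0.3, 0.3, 0.3]])
        res = rm_anova(make_table(y), "beta", "Fz")
        assert res.F == pytest.approx(0.0, abs=1e-20)

    def test_zero_error_variance_reports_infinite_f(self):
        # additive subject and condition effects, no residual
        y = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]])
        with pytest.warns(UserWarning, match="zero error variance"):
            res = rm_anova(make_table(y), "beta", "Fz")
        assert np.isinf(res.F)
        assert res.p == 0.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 complete subjects"):
            rm_anova(make_table(np.ones((2, 3))), "beta", "Fz")

    def test_listwise_deletion_of_incomplete_subjects(self):
        tab = make_table(np.arange(12.0).reshape(4, 3) + 1.0)
        data = tab.data[~((tab.data.subject_id == "s03") & (tab.data.condition == "c2"))]
        m = RepeatedMeasuresAnova(data)
        assert len(m.wide) == 3

    def test_partial_eta_squared_definition(self):
        y = np.array([[1, 2, 3], [2, 3, 4], [1, 1, 1], [0, 2, 4]], dtype=float)
        res = rm_anova(make_table(y), "beta", "Fz")
        assert res.partial_eta_sq == pytest.approx(
            res.ss_conditions / (res.ss_conditions + res.ss_error)
        )


class TestPairwise:
    def test_holm_step_down_arithmetic(self):
        # raw (0.01, 0.03, 0.04) with m=3 -> (0.03, 0.06, 0.06)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.03, 0.04], method="holm")[1]
        assert np.allclose(adj, [0.03, 0.06, 0.06])
        bonf = multipletests([0.01, 0.03, 0.04], method="bonferroni")[1]
        assert np.allclose(bonf, [0.03, 0.09, 0.12])

    def test_holm_never_exceeds_bonferroni(self):
        rng = np.random.default_rng(21)
        y = rng.uniform(0.2, 1.5, size=(10, 4))
        tab = make_table(y)
        holm = pairwise_tests(tab, "beta", "Fz", method="holm")
        bonf = pairwise_tests(tab, "beta", "Fz", method="bonferroni")
        assert (holm["p_adjusted"] <= bonf["p_adjusted"] + 1e-15).all()
        assert (holm["p_adjusted"] >= holm["p_raw"] - 1e-15).all()

    def test_pooled_error_term_t_and_df(self):
        y = np.array([[1, 2, 3], [2, 3, 4], [1, 1, 2], [0, 2, 4], [1, 3, 3]], dtype=float)
        res = rm_anova(make_table(y), "beta", "Fz")
        pw = res.pairwise(error_term="anova_pooled")
        n = 5
        for _, row in pw.iterrows():
            t_ref = (row["mean_a"] - row["mean_b"]) / np.sqrt(2 * res.ms_error / n)
            assert row["t"] == pytest.approx(t_ref, rel=1e-12)
            assert row["df"] == res.df2

    def test_per_pair_matches_scipy_paired_t(self):
        rng = np.random.default_rng(22)
        y = rng.uniform(0.2, 2.0, size=(9, 3))
        pw = pairwise_tests(make_table(y), "beta", "Fz", error_term="per_pair")
        conds = sorted(set(pw["condition_a"]) | set(pw["condition_b"]))
        cols = {c: y[:, i] for i, c in enumerate(conds)}
        for _, row in pw.iterrows():
            t_ref, p_ref = sps.ttest_rel(cols[row["condition_a"]], cols[row["condition_b"]])
            assert row["t"] == pytest.approx(t_ref, rel=1e-10)
            assert row["p_raw"] == pytest.approx(p_ref, rel=1e-10)
            assert row["df"] == 8

    def test_identical_conditions_give_t_zero_p_one(self):
        y = np.ones((5, 3))
        y[:, 2] = [1, 2, 3, 4, 5]
        pw = pairwise_tests(make_table(y), "beta", "Fz", error_term="per_pair")
        row = pw[(pw.condition_a == "c0") & (pw.condition_b == "c1")].iloc[0]
        assert row["t"] == 0.0
        assert row["p_raw"] == 1.0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            pairwise_tests(make_table(np.ones((4, 3)) + np.eye(4, 3)), "beta", "Fz", method="fdr")


class TestWithinSubjectCI:
    def test_perfect_within_subject_consistency_gives_zero_width(self):
        # S1 (1, 2), S2 (3, 4): identical condition differences -> width 0
        y = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        ci = within_subject_ci(make_table(y), "beta", "Fz")
        assert np.allclose(ci["ci_high"] - ci["ci_low"], 0.0, atol=1e-12)

    def test_no_subject_offsets_equals_morey_scaled_ordinary_ci(self):
        rng = np.random.default_rng(31)
        n, j = 8, 3
        y = rng.normal(0, 1, (n, j))
        y -= y.mean(axis=1, keepdims=True)  # remove subject offsets
        y += 5.0
        ci = within_subject_ci(make_table(y), "beta", "Fz")
        tcrit = sps.t.ppf(0.975, n - 1)
        morey = np.sqrt(j / (j - 1))
        for k in range(j):
            half_ref = tcrit * sps.sem(y[:, k]) * morey
            row = ci[ci.condition == f"c{k}"].iloc[0]
            assert (row["ci_high"] - row["ci_low"]) / 2 == pytest.approx(half_ref, rel=1e-10)

    def test_single_condition_reduces_to_one_sample_t_interval(self):
        y = np.array([[1.0], [2.0], [4.0], [5.0], [3.0]])
        tab = make_table(y)
        ci = within_subject_ci(tab, "beta", "Fz")
        lo, hi = sps.t.interval(0.95, 4, loc=y.mean(), scale=sps.sem(y[:, 0]))
        row = ci.iloc[0]
        assert row["ci_low"] == pytest.approx(lo, rel=1e-10)
        assert row["ci_high"] == pytest.approx(hi, rel=1e-10)

    def test_subject_offset_invariance(self):
        rng = np.random.default_rng(33)
        y = rng.uniform(0.5, 2.0, (7, 3))
        base = within_subject_ci(make_table(y), "beta", "Fz")
        offsets = rng.uniform(1.0, 5.0, (7, 1))  # keep powers positive
        shifted = within_subject_ci(make_table(y + offsets), "beta", "Fz")
        assert np.allclose(
            base["ci_high"] - base["ci_low"],
            shifted["ci_high"] - shifted["ci_low"],
            atol=1e-10,
        )

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            within_subject_ci(make_table(np.ones((4, 3)) + np.eye(4, 3)), "beta", "Fz", level=1.5)


class TestRunStatistics:
    def _full_table(self, seed=44):
        rng = np.random.default_rng(seed)
        frames = []
        for ch in ("Fz", "Cz", "Pz"):
            for band in ("theta", "alpha", "beta"):
                frames.append(make_table(rng.uniform(0.2, 2.0, (6, 3)), band, ch).data)
        from restband.spectral import BandPowerTable

        return BandPowerTable(pd.concat(frames, ignore_index=True))

    def test_default_grid_yields_nine_analyses(self):
        report = run_statistics(self._full_table())
        assert len(report["analyses"]) == 9
        entry = report["analyses"][0]
        assert {"band", "channel", "F", "df1", "df2", "p", "pairwise"} <= set(entry)
        for pw in entry["pairwise"]:
            assert {"p_raw", "p_holm", "p_bonferroni"} <= set(pw)

    def test_report_is_deterministic(self):
        from restband.stats import report_to_json

        tab = self._full_table()
        assert report_to_json(run_statistics(tab)) == report_to_json(run_statistics(tab))
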