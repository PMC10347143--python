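"""RM-ANOVA decomposition, sphericity handling, post hocs, effect sizes."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from copkit import (
    bonferroni_pairwise, build_condition_table, cohens_d_paired,
    eta_p_sq_from_f, rm_anova3, rm_anova_within, run_full_analysis,
)
from copkit.stats import FACTORS, LEVELS, AnalysisError, PARAMETER_COLUMNS


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def random_table(rng, n=6):
    """Random subjects x 12 condition table with subject heterogeneity."""
    cols = pd.MultiIndex.from_tuples(
        list(itertools.product(LEVELS["direction"], LEVELS["ramp_rate"],
                               LEVELS["displacement"])),
        names=list(FACTORS))
    data = rng.normal(0, 1, (n, 12)) + rng.normal(0, 1, (n, 1))
    return pd.DataFrame(data, columns=cols,
                        index=[f"S{i}" for i in range(n)])


def results_frame_from_cells(values):
    """Trial-results rows from {(subject, dir, rate, disp): [v, ...]}."""
    rows = []
    for (subj, d, r, x), vals in values.items():
        for rep, v in enumerate(vals, start=1):
            rows.append({
                "subject": subj, "repetition": rep, "direction": d,
                "displacement_mm": x, "ramp_rate_mm_s": r, "pp_time_s": 30.0,
                **{c: v for c in PARAMETER_COLUMNS.values()},
                "flags": "",
            })
    return pd.DataFrame(rows)


def brute_force_rm_anova(Y):
    """Inclusion-exclusion sum-of-squares oracle (explicit loops).

    Marginal means over every subset of {subject, factors}; effect
    estimates by inclusion-exclusion; SS by direct summation.
    """
    n = Y.shape[0]
    levels = Y.shape[1:]
    k = len(levels)

    def marginal(fixed):  # fixed: {axis_index: level}; axis 0 = subject
        sel = Y
        for ax in sorted(range(k + 1), reverse=True):
            if ax in fixed:
                sel = np.take(sel, fixed[ax], axis=ax)
            else:
                sel = sel.mean(axis=ax)
        return float(sel)

    out = {}
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(1, k + 1), r):
            # effect estimate at each level combination
            ss_eff = 0.0
            for lv in itertools.product(*(range(levels[a - 1]) for a in combo)):
                est = 0.0
                for sub_r in range(r + 1):
                    for sub in itertools.combinations(range(r), sub_r):
                        fixed = {combo[i]: lv[i] for i in sub}
                        est += (-1) ** (r - sub_r) * marginal(fixed)
                ss_eff += est ** 2
            mult = np.prod([levels[a - 1] for a in range(1, k + 1)
                            if a not in combo])
            ss_eff *= n * mult
            # subject-by-effect interaction (error term)
            ss_err = 0.0
            for s in range(n):
                for lv in itertools.product(*(range(levels[a - 1]) for a in combo)):
                    dev = 0.0
                    for sub_r in range(r + 1):
                        for sub in itertools.combinations(range(r), sub_r):
                            fixed = {combo[i]: lv[i] for i in sub}
                            dev += (-1) ** (r - sub_r) * (
                                marginal({0: s, **fixed}) - marginal(fixed))
                    ss_err += dev ** 2
            ss_err *= mult
            name = ":".join(FACTORS[a - 1] for a in combo)
            df1 = int(np.prod([levels[a - 1] - 1 for a in combo]))
            df2 = (n - 1) * df1
            F = (ss_eff / df1) / (ss_err / df2)
            out[name] = (ss_eff, ss_err, F)
    return out


# ---------------------------------------------------------------------------
# Partial eta squared
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("F,df1,df2,expected", [
    (8.123, 1, 19, 0.299),
    (112.365, 1, 19, 0.855),
    (47.657, 1, 19, 0.715),
    (182.187, 1, 19, 0.906),
    (40.022, 2, 38, 0.678),
    (0.0, 1, 19, 0.0),
])
def test_eta_p_sq_from_f(F, df1, df2, expected):
    assert round(eta_p_sq_from_f(F, df1, df2), 3) == expected


# ---------------------------------------------------------------------------
# RM-ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            table = random_table(rng)
            Y = table.to_numpy().reshape(6, 2, 2, 3)
            mine = rm_anova3(table).effects
            oracle = brute_force_rm_anova(Y)
            assert set(mine) == set(oracle)
            for name, (ss_eff, ss_err, F) in oracle.items():
                e = mine[name]
                assert e.ss_effect == pytest.approx(ss_eff, rel=1e-10)
                assert e.ss_error == pytest.approx(ss_err, rel=1e-10)
                assert e.F == pytest.approx(F, rel=1e-10)

    def test_matches_statsmodels(self, rng):
        table = random_table(rng, n=8)
        mine = rm_anova3(table).effects
        rows = []
        for subj, row in table.iterrows():
            for cell, v in row.items():
                rows.append(dict(subject=subj, direction=cell[0],
                                 ramp_rate=cell[1], displacement=cell[2], y=v))
        from statsmodels.stats.anova import AnovaRM
        sm = AnovaRM(pd.DataFrame(rows), "y", "subject",
                     within=list(FACTORS)).fit().anova_table
        for name, e in mine.items():
            assert e.F == pytest.approx(sm.loc[name, "F Value"], rel=1e-8)
            assert e.p == pytest.approx(sm.loc[name, "Pr > F"], abs=1e-10)

    def test_null_data_gives_zero_ss(self):
        table = random_table(np.random.default_rng(0))
        table.iloc[:, :] = 4.2
        res = rm_anova3(table)
        for e in res.effects.values():
            assert e.ss_effect == pytest.approx(0.0, abs=1e-20)
            assert e.eta_p_sq == 0.0
            assert math.isnan(e.F)
            assert "degenerate_zero_ss" in e.flags

    def test_eta_consistent_with_f_identity(self, rng):
        table = random_table(rng)
        for e in rm_anova3(table).effects.values():
            assert e.eta_p_sq == pytest.approx(
                eta_p_sq_from_f(e.F, e.df1, e.df2), rel=1e-12)

    def test_ss_additivity(self, rng):
        """Effects + error terms tile the within-subject sum of squares."""
        table = random_table(rng)
        Y = table.to_numpy().reshape(6, 2, 2, 3)
        total_within = float(
            ((Y - Y.mean(axis=(1, 2, 3), keepdims=True)) ** 2).sum())
        parts = sum(e.ss_effect + e.ss_error
                    for e in rm_anova3(table).effects.values())
        assert parts == pytest.approx(total_within, rel=1e-10)

    def test_two_level_single_factor_equals_paired_t(self, rng):
        """RM-ANOVA of one 2-level factor: F = t^2 (hand-rolled t-test)."""
        Y = rng.normal(0, 1, (10, 2))
        e = rm_anova_within(Y, ["cond"])["cond"]
        diff = Y[:, 0] - Y[:, 1]
        t = diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff)))
        assert e.F == pytest.approx(t * t, rel=1e-10)
        assert e.p == pytest.approx(
            2 * sps.t.sf(abs(t), len(diff) - 1), rel=1e-10)

    def test_gg_changes_p_not_f(self, rng):
        # strong heteroscedasticity across displacement violates sphericity
        n = 12
        base = rng.normal(0, 1, (n, 1, 1, 1))
        Y = base + rng.normal(0, 1, (n, 2, 2, 3)) * np.array([0.2, 1.0, 3.0])
        res = rm_anova_within(Y, FACTORS)
        e = res["displacement"]
        assert e.mauchly_p < 0.05 and e.gg_applied
        assert 0.5 <= e.gg_epsilon < 1.0
        assert e.p_gg > e.p  # df deflation weakens the evidence
        assert e.df1_gg == pytest.approx(e.gg_epsilon * e.df1)
        # 2-level effects are exempt from sphericity machinery
        assert res["direction"].mauchly_w is None
        assert not res["direction"].gg_applied

    def test_gg_epsilon_bounds(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            Y = r.normal(0, 1, (8, 2, 2, 3))
            for e in rm_anova_within(Y, FACTORS).values():
                if e.gg_epsilon is not None:
                    assert 1 / (e.df1) <= e.gg_epsilon <= 1.0


# ---------------------------------------------------------------------------
# Condition table
# ---------------------------------------------------------------------------

class TestConditionTable:
    def _full(self, n=4, reps=(4.0, 6.0)):
        vals = {}
        for s in range(n):
            for d in LEVELS["direction"]:
                for r in LEVELS["ramp_rate"]:
                    for x in LEVELS["displacement"]:
                        vals[(f"S{s}", d, r, x)] = list(reps)
        return vals

    def test_shape_and_rep_average(self):
        frame = results_frame_from_cells(self._full())
        table = build_condition_table(frame, "fp")
        assert table.shape == (4, 12)
        assert (table.to_numpy() == 5.0).all()  # mean of (4, 6)

    def test_incomplete_subject_dropped(self, caplog):
        vals = self._full()
        del vals[("S0", "FW", 100.0, 25.0)]
        frame = results_frame_from_cells(vals)
        import logging
        with caplog.at_level(logging.WARNING, logger="copkit.stats"):
            table = build_condition_table(frame, "fp")
        assert table.shape == (3, 12)
        assert "S0" in caplog.text

    def test_too_few_complete_subjects(self):
        frame = results_frame_from_cells(self._full(n=1))
        with pytest.raises(AnalysisError):
            build_condition_table(frame, "fp")

    def test_catch_trials_excluded(self):
        frame = results_frame_from_cells(self._full())
        null_row = frame.iloc[[0]].assign(direction="NONE",
                                          displacement_mm=np.nan,
                                          ramp_rate_mm_s=np.nan, fp_mm=np.nan)
        table = build_condition_table(pd.concat([frame, null_row]), "fp")
        assert table.shape == (4, 12)


# ---------------------------------------------------------------------------
# Post hocs and Cohen's d
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_displacement_family_has_three_comparisons(self, rng):
        table = random_table(rng)
        res = bonferroni_pairwise(table, "displacement")
        assert [r.comparison for r in res] == [
            "25.0 vs 50.0", "25.0 vs 100.0", "50.0 vs 100.0"]
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_identical_levels_give_p_one(self):
        # subject offsets only, no level differences
        table = random_table(np.random.default_rng(1))
        offsets = np.random.default_rng(2).normal(0, 1, (6, 1))
        table.iloc[:, :] = np.repeat(offsets, 12, axis=1)
        res = bonferroni_pairwise(table, "ramp_rate")
        assert res[0].p_bonferroni == 1.0

    def test_bonferroni_clipped_at_one(self, rng):
        table = random_table(rng)
        res = bonferroni_pairwise(table, "displacement")
        assert all(r.p_bonferroni <= 1.0 for r in res)

    def test_sign_consistency_and_ci_contains_d(self, rng):
        table = random_table(rng)
        for factor in FACTORS:
            for r in bonferroni_pairwise(table, factor):
                assert math.copysign(1, r.cohens_d) == math.copysign(1, r.mean_diff)
                lo, hi = r.ci_d_95
                assert lo <= r.cohens_d <= hi
                lo_m, hi_m = r.ci_diff_95
                assert lo_m <= r.mean_diff <= hi_m


class TestCohensD:
    def test_hand_computed_example(self):
        d, _ = cohens_d_paired(np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.0, 1.0]))
        assert d == pytest.approx(2.0)

    def test_identity_gives_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d, _ = cohens_d_paired(x, x.copy())
        assert d == 0.0

    def test_constant_shift_is_infinite_flag(self):
        x = np.array([1.0, 2.0, 3.0])
        d, ci = cohens_d_paired(x + 2.0, x)
        assert math.isinf(d) and d > 0
        assert all(math.isnan(c) for c in ci)

    def test_ci_inverts_noncentral_t(self, rng):
        x = rng.normal(1.0, 1.0, 15)
        y = rng.normal(0.0, 1.0, 15)
        d, (lo, hi) = cohens_d_paired(x, y)
        n = 15
        t_obs = d * math.sqrt(n)
        assert sps.nct.cdf(t_obs, n - 1, lo * math.sqrt(n)) == pytest.approx(0.975, abs=1e-6)
        assert sps.nct.cdf(t_obs, n - 1, hi * math.sqrt(n)) == pytest.approx(0.025, abs=1e-6)

    def test_ci_coverage_against_r_effectsize_convention(self):
        """Spot value: d CI for a known vector, cross-checked numerically."""
        x = np.array([10.0, 12.0, 9.0, 11.0, 13.0, 8.0, 10.5, 12.5])
        y = np.array([9.0, 10.0, 9.5, 9.0, 11.0, 8.5, 9.0, 11.0])
        d, (lo, hi) = cohens_d_paired(x, y)
        assert lo < d < hi
        assert hi - lo < 4.0  # n=8 paired CI is wide but finite


def test_run_full_analysis_schema(rng):
    vals = {}
    for s in range(6):
        for d in LEVELS["direction"]:
            for r in LEVELS["ramp_rate"]:
                for x in LEVELS["displacement"]:
                    vals[(f"S{s}", d, r, x)] = list(rng.normal(10, 2, 2))
    frame = results_frame_from_cells(vals)
    report = run_full_analysis(frame)
    assert set(report) == set(PARAMETER_COLUMNS)
    for blocks in report.values():
        assert len(blocks["anova"].effects) == 7
        assert sum(len(v) for v in blocks["pairwise"].values()) == 1 + 1 + 3
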