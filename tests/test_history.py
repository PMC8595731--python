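import numpy as np
import pandas as pd
import pytest

import pursuithist as ph
from pursuithist import history as hist
from conftest import simulate_timing_table
from oracles import vif_by_regression


def small_table(reversals, velocity=16.0, observer="s01", block=0,
                included=None):
    n = len(reversals)
    return pd.DataFrame({
        "observer": observer, "condition": "unpredictable", "block": block,
        "trial": np.arange(n), "leftward_velocity": velocity,
        "eye_reversal": np.asarray(reversals, float),
        "included": True if included is None else included,
    })


class TestRankClassify:
    def test_cell_of_30_gives_6_and_6(self):
        rng = np.random.default_rng(0)
        tab = small_table(rng.normal(0, 30, 30))
        lab = hist.rank_classify(tab)
        assert (lab == "UPPER").sum() == 6
        assert (lab == "LOWER").sum() == 6
        assert (lab == "middle").sum() == 18

    def test_earliest_and_latest_labelled(self):
        vals = np.arange(10.0)  # distinct, ascending
        tab = small_table(vals)
        lab = hist.rank_classify(tab)
        assert list(lab[:2]) == ["UPPER", "UPPER"]
        assert list(lab[-2:]) == ["LOWER", "LOWER"]

    def test_ties_stable_and_balanced(self):
        tab = small_table(np.zeros(10))
        lab = hist.rank_classify(tab)
        assert (lab == "UPPER").sum() == (lab == "LOWER").sum() == 2
        # stable tie-break: earliest trials get UPPER
        assert list(lab[:2]) == ["UPPER", "UPPER"]

    def test_small_cell_skipped(self, caplog):
        tab = small_table([1.0, 2.0, 3.0])
        lab = hist.rank_classify(tab)
        assert lab.isna().all()

    def test_upper_timings_before_lower(self):
        rng = np.random.default_rng(5)
        tab = small_table(rng.normal(0, 30, 49))
        lab = hist.rank_classify(tab)
        up = tab.loc[lab == "UPPER", "eye_reversal"]
        lo = tab.loc[lab == "LOWER", "eye_reversal"]
        assert up.max() <= lo.min()


class TestNodeSort:
    def test_behavior_history_sign(self):
        # positive lag-1 behavior weight: UPPER-preceded trials are earlier
        m = ph.SimModel(beta0=20.0, subject_intercept_sd=0.0,
                        beta_stim=(), beta_behav=(0.5,), noise_sd=10.0)
        tab = simulate_timing_table(3, n_obs=6, model=m)
        means = hist.node_sort(tab, lag=1, by="behavior")
        assert (means["group_a_mean"] < means["group_b_mean"]).all()

    def test_stimulus_grouping_levels(self):
        tab = simulate_timing_table(4, n_obs=3)
        means = hist.node_sort(tab, lag=2, by="stimulus")
        assert len(means) == 3
        # each block of 49 holds 7 trials per velocity; at most that many
        # predecessors per level and lag
        assert (means["n_a"] <= 5 * 7).all()
        assert (means["n_b"] <= 5 * 7).all()

    def test_lag_never_crosses_blocks(self):
        # two 2-trial blocks: only the second trial of each block can have a
        # lag-1 predecessor
        tab = pd.concat([
            small_table([0.0, 10.0], velocity=4.0, block=0),
            small_table([0.0, 10.0], velocity=28.0, block=1),
        ]).reset_index(drop=True)
        tab.loc[tab.block == 0, "leftward_velocity"] = [4.0, 28.0]
        tab.loc[tab.block == 1, "leftward_velocity"] = [28.0, 4.0]
        means = hist.node_sort(tab, lag=1, by="stimulus")
        # each block contributes exactly one classifiable trial
        assert means.loc["s01", "n_a"] + means.loc["s01", "n_b"] == 2

    def test_null_no_group_difference(self):
        m = ph.SimModel(beta0=20.0, subject_intercept_sd=0.0,
                        beta_stim=(), beta_behav=(), noise_sd=30.0)
        tab = simulate_timing_table(9, n_obs=12, model=m)
        means = hist.node_sort(tab, lag=1, by="stimulus")
        tt = hist.paired_t(means["group_a_mean"], means["group_b_mean"])
        assert abs(tt["t"]) < 3.0  # no systematic effect


class TestPairedT:
    def test_hand_computed_five_pairs(self):
        # diffs = (2, 4, 6, 3, 5): mean 4, sd sqrt(2.5)
        a = np.array([12.0, 15.0, 18.0, 11.0, 16.0])
        b = a - np.array([2.0, 4.0, 6.0, 3.0, 5.0])
        out = hist.paired_t(a, b)
        sd = np.sqrt(2.5)
        t_exp = 4.0 / (sd / np.sqrt(5))
        assert out["t"] == pytest.approx(t_exp)
        assert out["df"] == 4
        from scipy import stats
        assert out["p"] == pytest.approx(2 * stats.t.sf(t_exp, 4))
        assert out["cohens_d"] == pytest.approx(4.0 / sd)

    def test_zero_variance_edge(self):
        out = hist.paired_t([1.0, 1.0, 1.0, 1.0], [0.0, 0.0, 0.0, 0.0])
        assert out["p"] == 0.0 and np.isinf(out["t"])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hist.paired_t([1.0, 2.0], [0.0, 1.0])


class TestHistoryDesign:
    def test_one_lag_loses_one_row_per_block(self):
        tab = simulate_timing_table(2, n_obs=1)
        d = hist.build_history_design(tab, ks=1, kb=0)
        assert len(d) == 5 * 48

    def test_first_five_trials_predictors_only(self):
        tab = simulate_timing_table(2, n_obs=1)
        d = hist.build_history_design(tab, ks=5, kb=5)
        assert len(d) == 5 * 44
        assert d["trial"].min() == 5  # trials 0..4 only feed lag columns
        # lag columns of the first response rows reference trials 0..4
        first = d[d.trial == 5].iloc[0]
        blk = tab[(tab.observer == first["observer"])
                  & (tab.block == first["block"])]
        for k in range(1, 6):
            assert first[f"behav_lag{k}"] == pytest.approx(
                blk.iloc[5 - k]["eye_reversal"])

    def test_no_predictor_crosses_block_boundary(self):
        tab = simulate_timing_table(2, n_obs=1)
        d = hist.build_history_design(tab, ks=2, kb=2)
        assert d["trial"].min() == 2

    def test_excluded_lag_drops_row(self):
        tab = simulate_timing_table(2, n_obs=1)
        tab.loc[(tab.block == 0) & (tab.trial == 10), "included"] = False
        d = hist.build_history_design(tab, ks=0, kb=1)
        # trial 10 (excluded response) and trial 11 (excluded lag) both gone
        blk0 = d[d.block == 0]
        assert 10 not in blk0["trial"].values
        assert 11 not in blk0["trial"].values
        assert 12 in blk0["trial"].values

    def test_requires_some_history(self):
        tab = simulate_timing_table(2, n_obs=1)
        with pytest.raises(ValueError):
            hist.build_history_design(tab, ks=0, kb=0)


class TestFitLme:
    def test_noiseless_data_recovered_exactly(self):
        m = ph.SimModel(beta0=25.0, subject_intercept_sd=0.0,
                        beta_stim=(-0.4, -0.2), beta_behav=(0.1,),
                        noise_sd=0.0)
        tab = simulate_timing_table(6, n_obs=3, model=m)
        d = hist.build_history_design(tab, ks=2, kb=1)
        res = hist.fit_lme(d)
        assert res.estimates["stim_lag1"] == pytest.approx(-0.4, abs=1e-6)
        assert res.estimates["stim_lag2"] == pytest.approx(-0.2, abs=1e-6)
        assert res.estimates["behav_lag1"] == pytest.approx(0.1, abs=1e-6)
        assert res.estimates["const"] == pytest.approx(25.0, abs=1e-4)

    def test_zero_intercept_variance_matches_ols(self):
        import statsmodels.api as sm
        m = ph.SimModel(beta0=25.0, subject_intercept_sd=0.0,
                        beta_stim=(-0.4,), beta_behav=(), noise_sd=20.0)
        tab = simulate_timing_table(8, n_obs=4, model=m)
        d = hist.build_history_design(tab, ks=1, kb=0)
        res = hist.fit_lme(d)
        X = sm.add_constant(d[["stim_lag1"]])
        ols = sm.OLS(d["eye_reversal"], X).fit()
        assert res.random_intercept_var < 5.0
        assert res.estimates["stim_lag1"] == pytest.approx(
            ols.params["stim_lag1"], abs=0.01)

    def test_aic_counts_all_parameters(self):
        tab = simulate_timing_table(2, n_obs=3)
        d = hist.build_history_design(tab, ks=1, kb=0)
        res = hist.fit_lme(d)
        assert res.aic == pytest.approx(2 * (2 + 2) - 2 * res.llf)

    def test_aic_ordering_invariant_to_response_shift(self):
        tab = simulate_timing_table(5, n_obs=4)
        r1, _ = hist.model_grid_and_select(tab)
        tab2 = tab.assign(eye_reversal=tab.eye_reversal + 500.0)
        r2, _ = hist.model_grid_and_select(tab2)
        o1 = np.argsort([r.aic for r in r1])
        o2 = np.argsort([r.aic for r in r2])
        assert np.array_equal(o1, o2)


class TestModelGrid:
    def test_grid_structure(self):
        grid = hist.model_grid()
        assert [mid for mid, _ in grid] == list(range(1, 16))
        assert grid[4][1] == [f"stim_lag{k}" for k in range(1, 6)]
        assert grid[9][1] == [f"behav_lag{k}" for k in range(1, 6)]
        assert len(grid[14][1]) == 10

    def test_common_row_set_across_models(self):
        tab = simulate_timing_table(3, n_obs=4)
        results, _ = hist.model_grid_and_select(tab)
        assert len(results) == 15
        assert len({r.n_obs for r in results}) == 1

    def test_stimulus_only_truth_selects_stimulus_model(self):
        wins = 0
        m = ph.SimModel(beta0=25.0, subject_intercept_sd=5.0,
                        beta_stim=(-0.5, -0.8), beta_behav=(),
                        noise_sd=20.0)
        for s in range(10):
            tab = simulate_timing_table(100 + s, n_obs=12, model=m)
            _, sel = hist.model_grid_and_select(tab)
            if sel <= 5 or sel > 10:
                # stimulus-containing model (pure or both)
                wins += 1
        assert wins >= 9


class TestVif:
    def test_orthogonal_predictors_unity(self):
        n = 400
        d = pd.DataFrame({"stim_lag1": np.resize([1.0, -1.0], n),
                          "stim_lag2": np.resize([1.0, 1.0, -1.0, -1.0], n)})
        v = hist.compute_vif(d)
        assert np.allclose(v, 1.0, atol=1e-12)

    def test_exact_collinearity_infinite(self):
        x = np.random.default_rng(0).normal(size=100)
        d = pd.DataFrame({"stim_lag1": x, "stim_lag2": x,
                          "stim_lag3": np.random.default_rng(1).normal(size=100)})
        v = hist.compute_vif(d)
        assert np.isinf(v["stim_lag1"]) and np.isinf(v["stim_lag2"])

    def test_correlated_pair_closed_form(self):
        # two predictors with correlation r: VIF = 1/(1-r^2)
        rng = np.random.default_rng(2)
        x = rng.normal(size=200_000)
        y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=200_000)
        v = hist.compute_vif(pd.DataFrame({"stim_lag1": x, "stim_lag2": y}))
        assert v["stim_lag1"] == pytest.approx(1 / (1 - 0.25), abs=0.01)

    def test_matches_brute_force_regression(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            X = rng.normal(size=(80, 4)) @ rng.normal(size=(4, 4))
            d = pd.DataFrame(X, columns=[f"stim_lag{k}" for k in range(1, 5)])
            v = hist.compute_vif(d)
            assert np.allclose(v.to_numpy(), vif_by_regression(X),
                               rtol=1e-9, atol=1e-9)

    def test_cohort_scale_design_low_collinearity(self):
        tab = simulate_timing_table(6, n_obs=12)
        d = hist.build_history_design(tab, 5, 5)
        v = hist.compute_vif(d)
        assert (v < 1.5).all()


class TestWithinSubjectCorrelation:
    def test_perfect_within_subject_relation(self):
        rng = np.random.default_rng(0)
        xs, ys, ss = [], [], []
        for s, off in enumerate([0.0, 100.0, -50.0]):
            x = rng.normal(size=20)
            xs.append(x); ys.append(2 * x + off); ss.append(np.full(20, s))
        r, p = hist.within_subject_correlation(
            np.concatenate(xs), np.concatenate(ys), np.concatenate(ss))
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_simpsons_paradox_across_subjects(self):
        # strong between-subject confound, zero within-subject relation
        rng = np.random.default_rng(1)
        xs, ys, ss = [], [], []
        for s in range(6):
            x = rng.normal(size=50) + 10 * s
            y = rng.normal(size=50) + 10 * s
            xs.append(x); ys.append(y); ss.append(np.full(50, s))
        x, y, sub = (np.concatenate(v) for v in (xs, ys, ss))
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.9   # naive pooled corr
        r, p = hist.within_subject_correlation(x, y, sub)
        assert abs(r) < 0.15

    def test_equals_centered_data_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=120)
        y = 0.3 * x + rng.normal(size=120)
        sub = np.repeat(np.arange(6), 20)
        r, _ = hist.within_subject_correlation(x, y, sub)
        xc = x - pd.Series(x).groupby(sub).transform("mean").to_numpy()
        yc = y - pd.Series(y).groupby(sub).transform("mean").to_numpy()
        assert r == pytest.approx(np.corrcoef(xc, yc)[0, 1], abs=1e-10)
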