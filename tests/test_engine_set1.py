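"""Set-1 engine: experiment pipeline, one-sample tests, grid bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from cuesim.models import ConflictSpec
from cuesim.engine_set1 import (
    ExperimentConfig,
    Set1Grid,
    grid_counts,
    one_sample_t,
    one_sample_wilcoxon,
    oracle_significance_rate,
    run_experiment,
    run_grid,
    run_observer,
    true_observer_functions,
)
from cuesim.psychometrics import RejectionThresholds


def cfg_with(**kw):
    base = dict(ratio=1.0, n_observers=4, reps_per_level=10)
    base.update(kw)
    return ExperimentConfig(**base)


class TestTrueObserverFunctions:
    def test_equal_cues_no_conflict(self):
        a, b, c = true_observer_functions(cfg_with())
        assert (a.mu, a.sigma) == (55.0, 4.86)
        assert (b.mu, b.sigma) == (55.0, 4.86)
        assert c.mu == pytest.approx(55.0)
        assert c.sigma == pytest.approx(4.86 / math.sqrt(2), rel=1e-6)

    def test_symmetric_conflict_cancels_at_equal_reliability(self):
        a, b, c = true_observer_functions(cfg_with(conflict=ConflictSpec(6.0)))
        assert (a.mu, b.mu) == (58.0, 52.0)
        assert c.mu == pytest.approx(55.0)

    def test_unbalanced_reliability_pulls_percept_toward_better_cue(self):
        _, _, c = true_observer_functions(cfg_with(ratio=2.0, conflict=ConflictSpec(3.0)))
        assert c.mu == pytest.approx(0.8 * 56.5 + 0.2 * 53.5)  # = 55.9

    def test_ms_observer_tracks_lower_sigma_cue(self):
        a, _, c = true_observer_functions(cfg_with(ratio=2.0, observer_model="MS"))
        assert (c.mu, c.sigma) == (a.mu, a.sigma)


class TestOneSampleTests:
    def test_no_deviation_no_significance(self):
        res = one_sample_t([2.0, 2.0, 2.0, 2.0], 2.0)
        assert (res.t, res.p, res.significant) == (0.0, 1.0, False)

    def test_closed_form_t_statistic(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.t == pytest.approx(2 * math.sqrt(3), rel=1e-12)
        assert res.p == pytest.approx(0.0742, abs=2e-4)
        assert not res.significant

    def test_mean_equal_to_point(self):
        res = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_conventions(self):
        off = one_sample_t([3.0, 3.0, 3.0], 2.0)
        assert off.significant and off.p == 0.0

    def test_wilcoxon_agrees_on_clear_cases(self):
        clear = one_sample_wilcoxon(list(np.arange(10.0, 20.0)), 0.0)
        assert clear.significant
        null = one_sample_wilcoxon([2.0, 2.0, 2.0], 2.0)
        assert not null.significant

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            one_sample_t([1.0], 0.0)


class TestEnumeration:
    def test_full_published_grid(self):
        n_exp, n_obs = grid_counts()
        assert n_exp == 874_800
        assert n_obs == 14_871_600

    def test_observer_sum_per_cellset(self):
        assert sum(range(4, 31)) == 459

    def test_scaled_grid_counts(self):
        g = Set1Grid(ratios=(1.0, 2.0), observer_counts=(4, 10), regimes=(10,),
                     deltas=(0.0,), repetitions=3)
        assert grid_counts(g) == (2 * 2 * 3, 2 * 3 * (4 + 10))


class TestObserverAndExperiment:
    def test_fitted_parameters_track_truth_at_high_trials(self):
        cfg = cfg_with(reps_per_level=55, n_observers=2)
        recs = [run_observer(cfg, 7, (i,)) for i in range(60)]
        sig_a = np.array([r.fit_a.sigma for r in recs if not r.excluded])
        sig_c = np.array([r.fit_c.sigma for r in recs if not r.excluded])
        # within 3 standard errors, allowing the small-sample ML shrinkage
        assert sig_a.mean() == pytest.approx(4.86, abs=max(3 * sig_a.std() / len(sig_a) ** 0.5, 0.07))
        assert sig_c.mean() == pytest.approx(4.86 / math.sqrt(2), abs=max(3 * sig_c.std() / len(sig_c) ** 0.5, 0.06))

    def test_ms_prediction_selects_reliable_cue_at_high_ratio(self):
        cfg = cfg_with(ratio=4.0, n_observers=2)
        recs = [run_observer(cfg, 13, (i,)) for i in range(100) ]
        kept = [r for r in recs if not r.excluded]
        frac_a = np.mean([r.pred_ms.sigma == r.fit_a.sigma for r in kept])
        assert frac_a >= 0.95

    def test_rejected_observer_is_excluded(self):
        # impossible threshold rejects every function
        cfg = cfg_with(thresholds=RejectionThresholds(flat_sigma_span_factor=1e-9))
        rec = run_observer(cfg, 3, (0,))
        assert rec.excluded and rec.pred_ms is None

    def test_experiment_with_too_few_retained_observers_is_invalid(self):
        cfg = cfg_with(thresholds=RejectionThresholds(flat_sigma_span_factor=1e-9))
        outcome = run_experiment(cfg, 3)
        assert not outcome.valid and outcome.tests == {}

    def test_experiment_status_conservation(self):
        cfg = cfg_with(n_observers=5)
        outcome = run_experiment(cfg, 11)
        assert sum(outcome.status_counts.values()) == 3 * cfg.n_observers


@pytest.fixture(scope="module")
def small_grid_summary():
    grid = Set1Grid(ratios=(1.0, 4.0), observer_counts=(10,), regimes=(10, 55),
                    deltas=(0.0,), repetitions=12)
    return run_grid(grid, seed=21)


class TestGrid:
    def test_identical_seed_reproduces_results_byte_for_byte(self, small_grid_summary):
        grid = Set1Grid(ratios=(1.0, 4.0), observer_counts=(10,), regimes=(10, 55),
                        deltas=(0.0,), repetitions=12)
        again = run_grid(grid, seed=21)
        assert (
            again.summary_table().to_csv(index=False)
            == small_grid_summary.summary_table().to_csv(index=False)
        )
        pd.testing.assert_frame_equal(again.experiments, small_grid_summary.experiments)

    def test_sigma_discrimination_trends(self, small_grid_summary):
        # distinguishing MVUE from MS by sigma gets easier with more data
        # and harder as reliabilities unbalance
        tbl = small_grid_summary.summary_table()
        sel = tbl[(tbl.measure == "sigma") & (tbl.comparison == "MS")].set_index(
            ["ratio", "reps_per_level"]
        )["pct_significant"]
        assert sel[(1.0, 55)] >= sel[(1.0, 10)]
        assert sel[(1.0, 55)] > sel[(4.0, 55)]

    def test_pcs_sigma_gap_dominates_ms_gap_at_equal_reliability(self, small_grid_summary):
        tbl = small_grid_summary.summary_table()
        at_ratio1 = tbl[(tbl.ratio == 1.0) & (tbl.measure == "sigma") & (tbl.reps_per_level == 55)]
        pcs = at_ratio1[at_ratio1.comparison == "PCS"]["pct_significant"].iloc[0]
        ms = at_ratio1[at_ratio1.comparison == "MS"]["pct_significant"].iloc[0]
        assert pcs >= ms

    def test_percentages_and_conservation(self, small_grid_summary):
        tbl = small_grid_summary.summary_table()
        assert ((tbl.pct_significant >= 0) & (tbl.pct_significant <= 100)).all()
        s = small_grid_summary
        assert s.functions_simulated == sum(s.status_counts.values())
        assert s.observers_simulated == 2 * 1 * 2 * 12 * 10

    def test_pse_vs_pcs_stays_at_false_positive_level_under_conflict(self):
        # PCS and MVUE make identical PSE predictions at matched switching
        # probabilities, so conflict must not create PSE significance vs PCS
        grid = Set1Grid(ratios=(1.75,), observer_counts=(10,), regimes=(40,),
                        deltas=(6.0,), repetitions=25)
        s = run_grid(grid, seed=29)
        tbl = s.summary_table().set_index(["comparison", "measure"])
        pcs_rate = tbl.loc[("PCS", "pse"), "pct_significant"]
        ms_rate = tbl.loc[("MS", "pse"), "pct_significant"]
        assert ms_rate > pcs_rate
        assert pcs_rate <= 40.0


def test_oracle_calibration_matches_nominal_alpha():
    rate = oracle_significance_rate(10, 600, seed=2)
    assert rate == pytest.approx(5.0, abs=2.0)
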