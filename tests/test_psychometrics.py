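"""Constant-stimuli designs, response simulation, and ML psychometric fitting."""

import io

import numpy as np
import pytest
from scipy.special import ndtr

from cuesim.psychometrics import (
    STATUS_FLAT,
    STATUS_OK,
    STATUS_STEP,
    CumulativeGaussianPsychometric,
    PFParams,
    ResponseSet,
    fit_pf,
    handle_rejection,
    make_design,
    simulate_responses,
)
from cuesim.seeding import child_rng


class TestDesign:
    def test_default_nine_levels_over_20mm(self):
        d = make_design(55.0, 10)
        np.testing.assert_allclose(
            d.levels, [45, 47.5, 50, 52.5, 55, 57.5, 60, 62.5, 65]
        )
        assert d.n_trials == 90

    @pytest.mark.parametrize("reps,total", [(10, 90), (25, 225), (40, 360), (55, 495)])
    def test_trial_counts_per_regime(self, reps, total):
        assert make_design(55.0, reps).n_trials == total

    def test_small_custom_design(self):
        d = make_design(0.0, 10, span=2.0, n_levels=3)
        np.testing.assert_allclose(d.levels, [-1.0, 0.0, 1.0])

    def test_rejects_degenerate_designs(self):
        with pytest.raises(ValueError):
            make_design(55.0, 10, n_levels=1)
        with pytest.raises(ValueError):
            make_design(55.0, 0)


class TestSimulateResponses:
    def test_same_seed_reproduces_counts(self):
        pf, d = PFParams(55.0, 4.86), make_design(55.0, 25)
        r1 = simulate_responses(pf, d, 42)
        r2 = simulate_responses(pf, d, 42)
        np.testing.assert_array_equal(r1.n_larger, r2.n_larger)

    def test_proportions_match_the_generating_function(self):
        # at the PSE half the responses are "larger"; one sigma above, ~84%
        pf = PFParams(55.0, 4.86)
        d = make_design(55.0, 100_000, span=2 * 4.86, n_levels=3)
        r = simulate_responses(pf, d, 3)
        props = r.n_larger / r.n_total
        for p_obs, p_true in zip(props, [ndtr(-1.0), 0.5, ndtr(1.0)]):
            assert p_obs == pytest.approx(p_true, abs=3 * np.sqrt(p_true * (1 - p_true) / 1e5))


def _grid_search_oracle(resp, mu_grid, sigma_grid):
    """Brute-force likelihood maximization on a lattice."""
    x, k, n = resp.levels, resp.n_larger, resp.n_total
    mus = mu_grid[:, None, None]
    sigmas = sigma_grid[None, :, None]
    p = np.clip(ndtr((x[None, None, :] - mus) / sigmas), 1e-12, 1 - 1e-12)
    ll = (k * np.log(p) + (n - k) * np.log1p(-p)).sum(axis=2)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return mu_grid[i], sigma_grid[j], ll[i, j]


class TestFit:
    def test_recovers_parameters_from_expected_counts(self):
        # counts set to their binomial expectations at a huge trial count
        pf, d = PFParams(55.0, 4.86), make_design(55.0, 10_000)
        expected = np.round(d.reps_per_level * pf.prob_larger(d.levels)).astype(int)
        resp = ResponseSet(d.levels, expected, np.full(d.n_levels, d.reps_per_level))
        res = fit_pf(resp)
        assert res.ok
        assert res.mu == pytest.approx(55.0, rel=0.01)
        assert res.sigma == pytest.approx(4.86, rel=0.01)

    def test_matches_grid_search_oracle(self):
        mu_grid = np.linspace(45.0, 65.0, 801)
        sigma_grid = np.exp(np.linspace(np.log(0.5), np.log(40.0), 801))
        rng = np.random.default_rng(17)
        for i in range(20):
            pf = PFParams(rng.uniform(50, 60), rng.uniform(2, 12))
            resp = simulate_responses(pf, make_design(55.0, 25), child_rng(23, i))
            res = fit_pf(resp)
            assert res.ok
            mu_o, sigma_o, ll_o = _grid_search_oracle(resp, mu_grid, sigma_grid)
            assert res.loglik >= ll_o - 1e-6
            assert abs(res.mu - mu_o) <= mu_grid[1] - mu_grid[0]
            assert abs(np.log(res.sigma) - np.log(sigma_o)) <= np.log(
                sigma_grid[1] / sigma_grid[0]
            )

    def test_chance_performance_is_rejected_flat(self):
        d = make_design(55.0, 10)
        resp = ResponseSet(d.levels, np.full(9, 5), np.full(9, 10))
        assert fit_pf(resp).status == STATUS_FLAT

    def test_step_function_is_rejected(self):
        d = make_design(55.0, 10)
        counts = np.where(d.levels < 55.0, 0, 10)
        resp = ResponseSet(d.levels, counts, np.full(9, 10))
        assert fit_pf(resp).status == STATUS_STEP

    def test_fit_likelihood_dominates_truth(self):
        pf, d = PFParams(55.0, 4.86), make_design(55.0, 10)
        for i in range(50):
            resp = simulate_responses(pf, d, child_rng(31, i))
            model = CumulativeGaussianPsychometric(resp)
            res = model.fit()
            if res.ok:
                assert res.loglik >= model.loglike(pf.mu, pf.sigma) - 1e-8

    def test_estimator_bias_shrinks_with_trials(self):
        pf = PFParams(55.0, 4.86)
        biases = {}
        for reps in (10, 1000):
            d = make_design(55.0, reps)
            fits = [fit_pf(simulate_responses(pf, d, child_rng(37, reps, i))) for i in range(200)]
            mus = [f.mu for f in fits if f.ok]
            sigmas = [f.sigma for f in fits if f.ok]
            biases[reps] = (abs(np.mean(mus) - pf.mu), abs(np.mean(sigmas) - pf.sigma))
        assert biases[1000][0] < biases[10][0]
        assert biases[1000][1] < biases[10][1]

    def test_rejection_rate_declines_with_trials(self):
        # a function much shallower than the sampling span rejects often
        # with little data and rarely with much
        pf = PFParams(55.0, 30.0)
        rates = []
        for reps in (5, 10, 25):
            d = make_design(55.0, reps)
            n_rej = sum(
                not fit_pf(simulate_responses(pf, d, child_rng(41, reps, i))).ok
                for i in range(300)
            )
            rates.append(n_rej / 300)
        assert rates[0] > rates[-1]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_standard_errors_are_finite_for_healthy_fits(self):
        resp = simulate_responses(PFParams(55.0, 4.86), make_design(55.0, 55), 5)
        res = fit_pf(resp)
        assert res.ok
        assert 0 < res.bse_mu < 2.0
        assert 0 < res.bse_sigma < 3.0
        assert "sigma" in res.summary()


class TestRejectionHandling:
    def test_ok_fit_passes_through(self):
        resp = simulate_responses(PFParams(55.0, 4.86), make_design(55.0, 25), 1)
        res = fit_pf(resp)
        assert handle_rejection(res, "drop") is res
        assert handle_rejection(res, "resimulate") is res

    def test_drop_marks_excluded(self):
        d = make_design(55.0, 10)
        flat = fit_pf(ResponseSet(d.levels, np.full(9, 5), np.full(9, 10)))
        dropped = handle_rejection(flat, "drop")
        assert dropped.excluded and dropped.status == STATUS_FLAT

    def test_resimulate_recovers_within_bounded_retries(self):
        d = make_design(55.0, 10)
        flat = fit_pf(ResponseSet(d.levels, np.full(9, 5), np.full(9, 10)))
        counter = {"n": 0}

        def simulate():
            counter["n"] += 1
            return fit_pf(simulate_responses(PFParams(55.0, 4.86), d, child_rng(43, counter["n"])))

        res = handle_rejection(flat, "resimulate", simulate=simulate, max_retries=10)
        assert res.status == STATUS_OK and counter["n"] <= 10

    def test_retry_bound_is_enforced(self):
        d = make_design(55.0, 10)
        flat = fit_pf(ResponseSet(d.levels, np.full(9, 5), np.full(9, 10)))
        with pytest.raises(RuntimeError):
            handle_rejection(flat, "resimulate", simulate=lambda: flat, max_retries=3)


class TestResponseCSV:
    def test_round_trip(self):
        resp = simulate_responses(PFParams(55.0, 4.86), make_design(55.0, 10), 9)
        buf = io.StringIO()
        resp.to_csv(buf)
        buf.seek(0)
        back = ResponseSet.from_csv(buf)
        np.testing.assert_allclose(back.levels, resp.levels)
        np.testing.assert_array_equal(back.n_larger, resp.n_larger)

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError, match="missing columns"):
            ResponseSet.from_csv(io.StringIO("a,b\n1,2\n"))

    def test_count_invariants(self):
        with pytest.raises(ValueError):
            ResponseSet(np.array([1.0, 2.0]), np.array([5, 3]), np.array([4, 3]))
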