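"""EM fitter: E-step posteriors, closed-form updates, convergence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from blinkmix import (
    BlinkDataset,
    DegenerateDataError,
    DegenerateModelError,
    EMConfig,
    MixtureParams,
    Responsibilities,
    e_step,
    fit_em,
    log_likelihood,
    m_step_lambda,
    negbinom_log_pmf,
    update_weights,
)


class TestEStep:
    def test_zero_weight_component_gets_zero_posterior(self):
        data = BlinkDataset(np.array([2, 5, 9]))
        params = MixtureParams(h=2, weights=np.array([1.0, 0.0]), lam=3.0)
        r = e_step(data, params).r
        np.testing.assert_allclose(r, np.tile([1.0, 0.0], (3, 1)))

    def test_single_blink_must_be_monomer(self):
        data = BlinkDataset(np.array([1, 1]))
        params = MixtureParams(h=3, weights=np.array([0.2, 0.3, 0.5]), lam=4.0)
        r = e_step(data, params).r
        np.testing.assert_allclose(r, np.tile([1.0, 0.0, 0.0], (2, 1)))

    def test_hand_evaluated_posterior(self):
        # r_2 for B=3 under an equal-weight M/D mixture at lam=2
        data = BlinkDataset(np.array([3]))
        params = MixtureParams(h=2, weights=np.array([0.5, 0.5]), lam=2.0)
        p31 = np.exp(negbinom_log_pmf(3, 1, 2.0))
        p32 = np.exp(negbinom_log_pmf(3, 2, 2.0))
        r = e_step(data, params).r
        assert r[0, 1] == pytest.approx(p32 / (p31 + p32), rel=1e-12)

    def test_rows_sum_to_one_and_support_zeroed(self, trimer_dataset):
        params = MixtureParams(h=3, weights=np.array([0.3, 0.3, 0.4]), lam=3.6)
        r = e_step(trimer_dataset.data, params).r
        np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-12)
        counts = trimer_dataset.data.counts
        for k in range(1, 4):
            assert np.all(r[counts < k, k - 1] == 0.0)

    def test_degenerate_model_names_record(self):
        data = BlinkDataset(np.array([5, 1]))
        params = MixtureParams(h=2, weights=np.array([0.0, 1.0]), lam=3.0)
        with pytest.raises(DegenerateModelError, match=r"\[1\]"):
            e_step(data, params)


class TestUpdateWeights:
    def test_hard_assignments(self):
        r = np.array([[1.0, 0.0], [1.0, 0.0]])
        np.testing.assert_allclose(update_weights(r), [1.0, 0.0])
        r = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(update_weights(r), [0.5, 0.5])

    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 20), st.integers(1, 4)),
            elements=st.floats(1e-3, 1.0),
        )
    )
    def test_matches_naive_loop_and_sums_to_one(self, raw):
        r = raw / raw.sum(axis=1, keepdims=True)
        got = update_weights(Responsibilities(r))
        naive = [sum(r[i, k] for i in range(r.shape[0])) / r.shape[0]
                 for k in range(r.shape[1])]
        np.testing.assert_allclose(got, naive, rtol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            update_weights(np.empty((0, 2)))


class TestMStepLambda:
    def test_monomer_closed_form(self):
        # pure-monomer responsibilities: lam = 1/ln(sum B / (sum B - N))
        data = BlinkDataset(np.array([2, 4, 6]))
        r = Responsibilities(np.ones((3, 1)))
        assert m_step_lambda(data, r) == pytest.approx(1 / np.log(12 / 9), rel=1e-12)

    def test_all_ones_is_degenerate(self):
        data = BlinkDataset(np.array([1, 1, 1]))
        r = Responsibilities(np.ones((3, 1)))
        with pytest.raises(DegenerateDataError):
            m_step_lambda(data, r)

    def test_clamped_with_warning(self):
        data = BlinkDataset(np.array([2, 4, 6]))
        r = Responsibilities(np.ones((3, 1)))
        with pytest.warns(RuntimeWarning, match="clamped"):
            assert m_step_lambda(data, r, lam_bounds=(1e-3, 2.0)) == 2.0

    @pytest.mark.parametrize("seed", range(10))
    def test_maximizes_expected_complete_data_loglik(self, seed):
        """The closed form agrees with a 1-D numerical maximizer of
        Q(lam) = sum_ik r_ik log p(B_i | k, lam)."""
        from scipy.optimize import minimize_scalar

        rng = np.random.default_rng(seed)
        n, h = 40, 3
        counts = rng.integers(h, 60, size=n)
        raw = rng.random((n, h))
        # zero out unsupported components before normalizing
        for k in range(1, h + 1):
            raw[counts < k, k - 1] = 0.0
        r = raw / raw.sum(axis=1, keepdims=True)
        data = BlinkDataset(counts)

        def neg_q(lam):
            logp = np.stack(
                [negbinom_log_pmf(counts, np.full(n, k), lam) for k in range(1, h + 1)],
                axis=1,
            )
            return -np.sum(np.where(r > 0, r * logp, 0.0))

        res = minimize_scalar(neg_q, bounds=(0.05, 100), method="bounded",
                              options={"xatol": 1e-10})
        got = m_step_lambda(data, Responsibilities(r))
        assert got == pytest.approx(res.x, rel=1e-6)


class TestFitEM:
    def test_monomer_recovery(self):
        # lam recovered within 10% on a pure monomer simulation, and the
        # fit agrees with the closed-form truncated-geometric MLE
        from blinkmix import SimulationConfig, simulate_dataset

        hits = 0
        for seed in range(20):
            sim = simulate_dataset(
                SimulationConfig(true_weights=(1.0,), lam=4.0,
                                 n_complexes=1000, seed=seed)
            )
            fit = fit_em(sim.data, 1, config=EMConfig(seed=seed, n_restarts=1))
            total = sim.data.counts.sum()
            closed = 1 / np.log(total / (total - sim.data.size))
            assert fit.params.lam == pytest.approx(closed, rel=1e-6)
            if abs(fit.params.lam - 4.0) / 4.0 < 0.10:
                hits += 1
        assert hits >= 19

    def test_loglik_trace_non_decreasing(self, trimer_dataset):
        fit = fit_em(trimer_dataset.data, 3, config=EMConfig(seed=0, n_restarts=2))
        trace = fit.loglik_trace
        slack = 1e-10 * np.abs(trace[:-1])
        assert np.all(np.diff(trace) >= -slack)
        assert fit.converged
        assert np.isfinite(fit.loglik)

    def test_init_at_truth_converges(self, trimer_dataset):
        truth = MixtureParams(h=3, weights=np.array([0.4, 0.4, 0.2]), lam=3.6)
        fit = fit_em(trimer_dataset.data, 3,
                     config=EMConfig(seed=1, n_restarts=0), init=truth)
        assert fit.converged
        d = np.diff(fit.loglik_trace)
        assert np.all(d >= -1e-10 * np.abs(fit.loglik_trace[:-1]))

    def test_final_loglik_consistent_with_model(self, trimer_dataset):
        fit = fit_em(trimer_dataset.data, 3, config=EMConfig(seed=3, n_restarts=1))
        assert fit.loglik == pytest.approx(
            log_likelihood(trimer_dataset.data, fit.params), rel=1e-9
        )

    def test_permutation_invariance(self, trimer_dataset, rng):
        counts = trimer_dataset.data.counts
        shuffled = counts[rng.permutation(counts.size)]
        cfg = EMConfig(seed=7, n_restarts=2)
        a = fit_em(BlinkDataset(counts), 3, config=cfg)
        b = fit_em(BlinkDataset(shuffled), 3, config=cfg)
        np.testing.assert_allclose(a.params.weights, b.params.weights, atol=1e-12)
        assert a.params.lam == pytest.approx(b.params.lam, rel=1e-12)

    def test_trimer_fraction_recovered_on_average(self):
        """Mean fitted trimer fraction over replicates is close to the
        true 0.2 at lam=4 (accuracy degrades only for tiny fractions)."""
        from blinkmix import SimulationConfig, run_benchmark

        res = run_benchmark(
            SimulationConfig(true_weights=(0.4, 0.4, 0.2), lam=4.0,
                             n_complexes=1000, n_replicates=25, seed=12),
            3,
            em=EMConfig(n_restarts=1),
            apply_correction=False,
        )
        mean_pi3 = res.summary.set_index("parameter").loc["pi3_apparent", "mean"]
        assert mean_pi3 == pytest.approx(0.2, abs=0.05)

    def test_warns_when_h_exceeds_max_count(self):
        data = BlinkDataset(np.array([1, 2, 2, 1, 2]))
        with pytest.warns(RuntimeWarning, match="below h"):
            fit_em(data, 3, config=EMConfig(seed=0, n_restarts=0, max_iter=50))

    def test_nonconvergence_is_flagged_not_raised(self, trimer_dataset):
        fit = fit_em(trimer_dataset.data, 3,
                     config=EMConfig(seed=0, n_restarts=0, max_iter=3))
        assert not fit.converged
        assert fit.n_iter == 3
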