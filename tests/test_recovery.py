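"""Percept recovery: window statistics, inverse problem, OMP, combination."""

import numpy as np
import pytest

import rivalnet as rn
from rivalnet.mean_field import expected_voltage_map
from rivalnet.recovery import (
    DCTBasis,
    IdentityBasis,
    WindowStatistics,
    assemble_inverse_problem,
    combine_percepts,
    compute_window_statistics,
    dominance_metric,
    relative_error,
    sparse_reconstruct,
)


class TestWindowStatistics:
    def test_window_tiling_and_weights(self, rivalry_run):
        _, res = rivalry_run
        stats = compute_window_statistics(res, 0.6)
        assert len(stats) == int(np.floor(res.duration / 0.6))
        for st in stats:
            if st.weights_defined:
                assert st.weights.sum() == pytest.approx(1.0)
                assert np.all(st.weights >= 0)

    def test_dominance_window_weight_is_extreme(self, rivalry_run):
        # a window wholly inside one dominance period gives the dominant
        # pool nearly all the weight
        from rivalnet.analysis import dominant_pool_series, extract_dominance_durations
        _, res = rivalry_run
        labels = dominant_pool_series(res)
        rec = extract_dominance_durations(labels, exclude_transient=True)
        stats = compute_window_statistics(res, 0.6)
        found = False
        for start, end, pool in rec.segments:
            for st in stats:
                if st.t_start >= start + 0.1 and st.t_end <= end - 0.1:
                    assert st.weights[pool] > 0.9
                    found = True
        assert found

    def test_rate_counting(self, rivalry_run):
        _, res = rivalry_run
        stats = compute_window_statistics(res, 0.5)
        total_from_windows = sum(st.rates.sum() * 0.5 for st in stats)
        assert total_from_windows == pytest.approx(len(res.spike_times), rel=1e-12)

    def test_window_must_fit(self, rivalry_run):
        _, res = rivalry_run
        with pytest.raises(ValueError):
            compute_window_statistics(res, res.duration * 2)
        with pytest.raises(ValueError):
            compute_window_statistics(res, 0.03)   # not a stat-bin multiple


class TestInverseProblem:
    def test_exact_forward_stats_give_zero_residual(self, network, gratings, params):
        # fabricate statistics from a known stimulus via the exact linear
        # map; the true image must solve the assembled system to round-off
        n_total = params.q * params.N
        rng = np.random.default_rng(4)
        rates = rng.uniform(0, 30, n_total)
        thbar = np.tile(params.theta_base(), params.q) + rng.uniform(0, 0.3, n_total)
        vbar = expected_voltage_map(network, rates, thbar, gratings)
        st = WindowStatistics(
            index=1, t_start=0.6, t_end=1.2, rates=rates,
            mean_voltage=vbar, mean_threshold=thbar,
            pool_exc_rates=np.array([10.0, 10.0]),
            weights=np.array([0.5, 0.5]), weights_defined=True,
        )
        for pool in range(params.q):
            A, rhs = assemble_inverse_problem(network, st, pool)
            assert A.shape == (params.N_E, gratings.n)
            resid = A @ gratings.images[pool].vector - rhs
            assert np.max(np.abs(resid)) < 1e-8 * np.max(np.abs(rhs))

    def test_silent_pool_rhs_vanishes(self, network, gratings, params):
        # a fully silent pool (reset voltage, base threshold, zero rates)
        # contributes no excitatory-row right-hand side: the cross-pool
        # terms target inhibitory neurons only
        n_total = params.q * params.N
        st = WindowStatistics(
            index=0, t_start=0, t_end=0.6, rates=np.zeros(n_total),
            mean_voltage=np.full(n_total, params.V_Re),
            mean_threshold=np.tile(params.theta_base(), params.q),
            pool_exc_rates=np.zeros(2), weights=np.full(2, np.nan),
            weights_defined=False,
        )
        _, rhs = assemble_inverse_problem(network, st, 0)
        assert np.allclose(rhs, 0.0)


class TestOMP:
    def test_exact_sparse_recovery(self):
        # standard guarantee regime: 10-sparse signal, 200 Gaussian rows
        rng = np.random.default_rng(12)
        m, n, k = 200, 1000, 10
        A = rng.standard_normal((m, n)) / np.sqrt(m)
        support = rng.choice(n, k, replace=False)
        x = np.zeros(n)
        x[support] = rng.uniform(1, 3, k) * rng.choice([-1, 1], k)
        rhs = A @ x
        recon, diag = sparse_reconstruct(
            A, rhs, IdentityBasis(), max_atoms=k, residual_tol=1e-10,
        )
        assert set(diag["atoms"]) == set(support.tolist())
        # nonneg clipping applies to images; compare pre-clip via atoms
        coeffs = np.zeros(n)
        coeffs[diag["atoms"]] = np.linalg.lstsq(A[:, diag["atoms"]], rhs, rcond=None)[0]
        assert np.max(np.abs(coeffs - x)) < 1e-6

    def test_residual_monotone(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((50, 200))
        rhs = rng.standard_normal(50)
        _, diag = sparse_reconstruct(A, rhs, IdentityBasis(), max_atoms=20,
                                     residual_tol=0.0)
        r = diag["residual_norms"]
        assert all(r[i + 1] <= r[i] + 1e-12 for i in range(len(r) - 1))

    def test_zero_rhs_zero_reconstruction(self):
        A = np.eye(10)
        recon, diag = sparse_reconstruct(A, np.zeros(10), IdentityBasis())
        assert np.array_equal(recon, np.zeros(10))
        assert diag["atoms"] == []

    def test_matches_sklearn_omp(self):
        # independent implementation cross-check on a dense problem
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(8)
        m, n, k = 80, 300, 6
        A = rng.standard_normal((m, n))
        A /= np.linalg.norm(A, axis=0)
        x = np.zeros(n)
        x[rng.choice(n, k, replace=False)] = rng.standard_normal(k)
        rhs = A @ x
        ours, diag = sparse_reconstruct(A, rhs, IdentityBasis(), max_atoms=k,
                                        residual_tol=1e-12)
        ref = sklearn.OrthogonalMatchingPursuit(n_nonzero_coefs=k, fit_intercept=False)
        ref.fit(A, rhs)
        assert set(diag["atoms"]) == set(np.flatnonzero(ref.coef_).tolist())

    def test_dct_basis_roundtrip(self):
        rng = np.random.default_rng(5)
        basis = DCTBasis((8, 8))
        sig = rng.random(64)
        assert np.allclose(basis.synthesize(basis.analyze(sig)), sig)

    def test_nonfinite_rhs_rejected(self):
        with pytest.raises(ValueError):
            sparse_reconstruct(np.eye(4), np.array([1.0, np.nan, 0, 0]),
                               IdentityBasis())


class TestCombination:
    def test_weighted_combination_exact(self):
        r = np.array([[1.0, 0.0, 2.0], [0.0, 1.0, 2.0]])
        w = np.array([0.40271, 0.59729])
        out = combine_percepts(r, w)
        assert np.allclose(out, w[0] * r[0] + w[1] * r[1])

    def test_degenerate_weight(self):
        r = np.array([[1.0, 2.0], [5.0, 6.0]])
        assert np.array_equal(combine_percepts(r, np.array([0.0, 1.0])), r[1])

    def test_identical_reconstructions_invariant(self):
        r = np.array([[3.0, 1.0], [3.0, 1.0]])
        out = combine_percepts(r, np.array([0.21, 0.79]))
        assert np.allclose(out, r[0])

    def test_invalid_weights(self):
        r = np.zeros((2, 4))
        with pytest.raises(ValueError):
            combine_percepts(r, np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            combine_percepts(r, np.array([-0.5, 1.5]))


class TestErrorAndMetric:
    def test_relative_error_values(self):
        truth = np.array([3.0, 4.0])
        assert relative_error(truth, truth) == 0.0
        assert relative_error(truth, np.zeros(2)) == 1.0
        assert relative_error(truth, 2 * truth) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            relative_error(np.zeros(2), truth)

    def test_dominance_metric_values(self):
        assert dominance_metric(np.array([5.0, 5.0]))[0] == 0.0
        assert dominance_metric(np.array([7.0, 0.0]))[0] == 1.0
        r = np.array([[3.0, 1.0], [1.0, 3.0]])
        M = dominance_metric(r)
        assert M[0] == pytest.approx(-M[1])
        assert np.all(np.abs(M) <= 1.0)
        assert np.isnan(dominance_metric(np.array([0.0, 0.0]))[0])
        with pytest.raises(ValueError):
            dominance_metric(np.array([1.0, 2.0, 3.0]))


def test_end_to_end_reconstruction(rivalry_run, gratings):
    """Full pipeline on the shared run: dominant windows reconstruct well."""
    realization, res = rivalry_run
    recons = rn.reconstruct_windows(
        realization, res, gratings, window=0.6, max_atoms=60,
        window_indices={2, 3, 4},
    )
    assert len(recons) == 3
    for rc in recons:
        assert rc.weights.sum() == pytest.approx(1.0)
        assert np.all(rc.percept >= 0)
        exact = combine_percepts(rc.pool_reconstructions, rc.weights)
        assert np.allclose(exact, rc.percept)
    clear = [rc for rc in recons if rc.weights.max() > 0.9]
    assert clear, "no unambiguous window among those reconstructed"
    for rc in clear:
        assert rc.percept_error < 0.5
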