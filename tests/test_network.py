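"""Connectivity sampling: statistics, sign structure, scalings, normalization."""

import numpy as np
import pytest

import rivalnet as rn
from rivalnet.network import (
    build_feedforward_bernoulli,
    build_feedforward_localized,
    build_long_range,
    build_recurrent,
    perturb_feedforward_gaussian,
)


class TestParameters:
    def test_defaults_satisfy_invariants(self, params):
        assert params.R_EE > 0 and params.R_IE > 0
        assert params.R_EI < 0 and params.R_II < 0
        assert params.lambda_phys == pytest.approx(0.3125)
        assert params.N == 2000

    @pytest.mark.parametrize("kw", [
        dict(R_EI=2.0), dict(K=0), dict(K=5000), dict(q=0),
        dict(phi=-1.0), dict(theta_E=-0.5), dict(rho=1.5), dict(sigma_rf=0.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            rn.ModelParameters(**kw)


class TestRecurrent:
    def test_mean_in_degree(self, network, params):
        # each row receives ~K connections from each source population
        R = network.recurrent[0]
        nonzero = (R.toarray() != 0)
        from_E = nonzero[:, : params.N_E].sum(axis=1)
        from_I = nonzero[:, params.N_E :].sum(axis=1)
        for counts in (from_E, from_I):
            se = np.sqrt(params.K * (1 - params.K / params.N_E) / params.N)
            assert abs(counts.mean() - params.K) < 3 * se

    def test_dense_when_K_equals_N(self):
        p = rn.ModelParameters(N_E=6, N_I=6, K=6)
        R = build_recurrent(p, np.random.default_rng(0))[0]
        arr = R.toarray()
        off_diag = ~np.eye(12, dtype=bool)
        assert np.all(arr[off_diag] != 0)
        assert arr[0, 1] == pytest.approx(p.R_EE / np.sqrt(6))
        assert arr[0, 7] == pytest.approx(p.R_EI / np.sqrt(6))

    def test_zero_diagonal_and_sign_pattern(self, network, params):
        for R in network.recurrent:
            arr = R.toarray()
            assert np.all(np.diag(arr) == 0)
            assert np.all(arr[:, : params.N_E] >= 0)
            assert np.all(arr[:, params.N_E :] <= 0)

    def test_SI_scaling_equivariance(self, params):
        base = build_recurrent(params, np.random.default_rng(42))[0].toarray()
        scaled = build_recurrent(
            params.with_(S_I=0.6), np.random.default_rng(42)
        )[0].toarray()
        ncols = params.N_E
        assert np.array_equal(scaled[:, :ncols], base[:, :ncols])
        assert np.array_equal(scaled[:, ncols:], 0.6 * base[:, ncols:])

    def test_SE_scaling_equivariance(self, params):
        base = build_recurrent(params, np.random.default_rng(43))[0].toarray()
        scaled = build_recurrent(
            params.with_(S_E=1.4), np.random.default_rng(43)
        )[0].toarray()
        ncols = params.N_E
        assert np.allclose(scaled[:, :ncols], 1.4 * base[:, :ncols])
        assert np.array_equal(scaled[:, ncols:], base[:, ncols:])


class TestLongRange:
    def test_block_structure(self, network, params):
        for (src, tgt), C in network.long_range.items():
            arr = C.toarray()
            assert np.all(arr[: params.N_E] == 0)          # no E targets
            assert np.all(arr[:, params.N_E :] == 0)        # no I sources
            assert np.all(arr[params.N_E :, : params.N_E] >= 0)

    def test_expected_in_degree(self, network, params):
        C = network.long_range[(0, 1)].toarray()
        counts = (C[params.N_E :, : params.N_E] != 0).sum(axis=1)
        se = np.sqrt(params.K * (1 - params.K / params.N_E) / params.N_I)
        assert abs(counts.mean() - params.K) < 3 * se

    def test_SC_scales_one_ordered_pair(self, params):
        base = build_long_range(params, np.random.default_rng(7))
        scaled = build_long_range(
            params.with_(S_C={(0, 1): 1.5}), np.random.default_rng(7)
        )
        assert np.allclose(
            scaled[(0, 1)].toarray(), 1.5 * base[(0, 1)].toarray()
        )
        assert np.array_equal(scaled[(1, 0)].toarray(), base[(1, 0)].toarray())

    def test_single_pool_has_no_long_range(self, small_gratings):
        p = rn.ModelParameters(q=1)
        assert build_long_range(p, np.random.default_rng(0)) == {}


class TestFeedforwardLocalized:
    def test_center_sampling_probability(self, network, params, gratings):
        # fraction of neurons sampling their own center pixel ~= rho
        # (checked indirectly: nnz per row matches the analytic expectation)
        F = network.feedforward[0]
        nnz = np.diff(F.indptr)
        # expected samples per neuron: the Gaussian profile summed over the
        # grid ~= 2*pi*sigma^2*rho
        expected = 2 * np.pi * params.sigma_rf**2 * params.rho
        assert abs(nnz.mean() - expected) / expected < 0.1

    def test_sampling_probability_profile(self, params, gratings):
        # Monte-Carlo over neurons: empirical sampling frequency at the
        # receptive-field center is rho, and at grid distance 1 it is
        # rho * exp(-1 / (2 sigma^2)) ~= 0.8154
        p = params
        centers = []
        F = build_feedforward_localized(
            p, gratings, np.random.default_rng(11), centers_out=centers
        )
        rows_px, cols_px = gratings.shape
        hits0, n0 = 0, 0
        hits1, n1 = 0, 0
        for x in range(p.q):
            mask = F[x] != 0
            cr, cc = centers[x]
            for i in range(p.N):
                r0, c0 = cr[i], cc[i]
                j0 = (r0 - 1) * cols_px + (c0 - 1)
                hits0 += bool(mask[i, j0]); n0 += 1
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    r, c = r0 + dr, c0 + dc
                    if 1 <= r <= rows_px and 1 <= c <= cols_px:
                        hits1 += bool(mask[i, (r - 1) * cols_px + (c - 1)])
                        n1 += 1
        p0, p1 = hits0 / n0, hits1 / n1
        d1 = p.rho * np.exp(-1.0 / (2 * p.sigma_rf**2))
        assert abs(p0 - p.rho) < 3 * np.sqrt(p.rho * (1 - p.rho) / n0)
        assert abs(p1 - d1) < 3 * np.sqrt(d1 * (1 - d1) / n1)
        assert d1 == pytest.approx(0.8154, abs=5e-4)

    def test_drive_normalization(self, network, params, gratings):
        drive = network.feedforward_drive(gratings)
        target_E = params.g_L * params.sqrtK * params.f_E * params.m0
        target_I = params.g_L * params.sqrtK * params.f_I * params.m0
        for x in range(params.q):
            sl_E = slice(x * params.N, x * params.N + params.N_E)
            sl_I = slice(x * params.N + params.N_E, (x + 1) * params.N)
            assert drive[sl_E].mean() == pytest.approx(target_E, rel=1e-12)
            assert drive[sl_I].mean() == pytest.approx(target_I, rel=1e-12)
            assert np.all(drive >= 0)


class TestFeedforwardBernoulli:
    def test_full_density_is_homogeneous(self, small_params, small_gratings):
        F = build_feedforward_bernoulli(
            small_params, 1.0, small_gratings, np.random.default_rng(0)
        )
        drive = F[0] @ small_gratings.images[0].vector
        assert np.ptp(drive[: small_params.N_E]) < 1e-9 * drive.mean()

    def test_halving_prob_doubles_weight(self, small_params, small_gratings):
        rng1 = np.random.default_rng(5)
        rng2 = np.random.default_rng(5)
        F_half = build_feedforward_bernoulli(small_params, 0.5, small_gratings, rng1)
        F_quarter = build_feedforward_bernoulli(small_params, 0.25, small_gratings, rng2)
        w_half = F_half[0].data.max()
        w_quarter = F_quarter[0].data.max()
        assert w_quarter / w_half == pytest.approx(2.0, rel=0.05)

    def test_drive_std_decreases_with_density(self, small_params, small_gratings):
        stds = []
        for prob in (0.02, 0.2, 1.0):
            F = build_feedforward_bernoulli(
                small_params, prob, small_gratings, np.random.default_rng(9)
            )
            drive = F[0] @ small_gratings.images[0].vector
            stds.append(drive[: small_params.N_E].std())
        assert stds[0] > stds[1] > stds[2]

    def test_mean_drive_invariant_in_density(self, small_params, small_gratings):
        means = []
        for prob in (0.05, 0.5, 1.0):
            F = build_feedforward_bernoulli(
                small_params, prob, small_gratings, np.random.default_rng(3)
            )
            means.append((F[0] @ small_gratings.images[0].vector)[: small_params.N_E].mean())
        assert np.allclose(means, means[0], rtol=1e-12)

    def test_invalid_probability(self, small_params, small_gratings):
        with pytest.raises(ValueError):
            build_feedforward_bernoulli(
                small_params, 0.0, small_gratings, np.random.default_rng(0)
            )


class TestGaussianPerturbation:
    def test_zero_std_identity(self):
        drive = np.linspace(1, 5, 100)
        out, clipped = perturb_feedforward_gaussian(drive, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, drive)
        assert clipped == 0

    def test_sample_std(self):
        drive = np.full(2000, 100.0)
        out, _ = perturb_feedforward_gaussian(drive, 5.0, np.random.default_rng(1))
        se = 5.0 / np.sqrt(2 * (2000 - 1))
        assert abs(out.std() - 5.0) < 3 * se
        assert out.mean() == pytest.approx(100.0, abs=3 * 5.0 / np.sqrt(2000))

    def test_seeded_determinism_and_clipping(self):
        drive = np.full(500, 1.0)
        a, ca = perturb_feedforward_gaussian(drive, 2.0, np.random.default_rng(7))
        b, cb = perturb_feedforward_gaussian(drive, 2.0, np.random.default_rng(7))
        assert np.array_equal(a, b) and ca == cb
        assert ca > 0              # std >> mean, so clipping must occur
        assert np.all(a >= 0)


def test_coupling_matrix_block_layout(network, params):
    W = network.coupling_matrix()
    assert W.shape == (params.q * params.N, params.q * params.N)
    arr = W.toarray()
    # cross-pool blocks: only I rows x E columns nonzero
    blk = arr[params.N : 2 * params.N, : params.N]
    assert np.all(blk[: params.N_E] == 0)
    assert np.all(blk[:, params.N_E :] == 0)
    assert np.all(np.diag(arr) == 0)
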