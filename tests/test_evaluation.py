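"""Evaluation metrics: accuracy bookkeeping, transfer entropy against a
quadrature oracle, KL optimality, analytic moments, information capacity."""

import numpy as np
import pytest

import dualhebb as dh
from dualhebb.evaluation import (
    KLEvaluator,
    analytic_accuracy,
    analytic_moments,
    assign_selectivity,
    bootstrap_accuracy,
    estimate_accuracy,
    hillclimb_connectivity,
    info_capacity,
    info_gain_profile,
    kl_gap,
    model_error,
    simulate_membrane_moments,
    te_gradient_alignment,
    transfer_entropy,
)
from dualhebb.families import GaussianFamily
from dualhebb.generative import truncated_normal_moments
from dualhebb.network import Network


class TestSelectivityAndAccuracy:
    def test_diagonal_activity_recovers_groups(self):
        s = np.array([0, 1, 2, 0, 1, 2])
        rY = np.eye(3)[s]  # neuron mu fires only for state mu
        np.testing.assert_array_equal(assign_selectivity(s, rY, 3), [0, 1, 2])

    def test_uniform_activity_ties_break_low(self):
        s = np.array([0, 1, 0, 1])
        rY = np.ones((4, 3))
        np.testing.assert_array_equal(assign_selectivity(s, rY, 2), [0, 0, 0])

    def test_empty_window_raises(self):
        with pytest.raises(ValueError):
            assign_selectivity(np.array([], dtype=int), np.zeros((0, 2)), 2)

    def test_perfect_decoder_scores_one(self):
        s = np.tile([0, 1, 2], 20)
        rY = np.eye(3)[s]
        assert estimate_accuracy(s, rY, np.array([0, 1, 2]), 3) == 1.0

    def test_state_without_neurons_counts_as_failure(self):
        s = np.array([0, 1, 0, 1])
        rY = np.ones((4, 2))
        acc = estimate_accuracy(s, rY, np.array([0, 0]), 2)
        # steps of the unrepresented state fail; state-0 steps win vacuously
        assert acc == 0.5

    def test_ties_fail_strict_comparison(self):
        s = np.zeros(4, dtype=int)
        rY = np.ones((4, 2))
        assert estimate_accuracy(s, rY, np.array([0, 1]), 2) == 0.0

    def test_bootstrap_splits_windows(self):
        s = np.tile([0, 1], 200)
        rY = np.eye(2)[s]
        assert bootstrap_accuracy(s, rY, 2, T_o=100) == 1.0
        with pytest.raises(ValueError):
            bootstrap_accuracy(s[:50], rY[:50], 2, T_o=100)


class TestTransferEntropy:
    def test_bounded_by_log_p(self, small_gaussian_model):
        m = small_gaussian_model
        net = dh.build_random_coding(m, rho_o=0.3, N=8, seed=1)
        te = transfer_entropy(m, net, n_samples=500, seed=2)
        assert 0.0 <= te <= np.log(m.p) + 1e-9

    def test_disconnected_network_transfers_nothing(self, small_gaussian_model):
        m = small_gaussian_model
        net = Network(C=np.zeros((8, m.M)), W=np.zeros((8, m.M)),
                      selectivity=dh.selectivity_map(m.p, 8), p=m.p)
        assert transfer_entropy(m, net, n_samples=200, seed=3) == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_dense_limit_saturates(self):
        m = dh.make_gaussian_model(p=4, M=30, seed=5, sigma_X=0.02)
        net = dh.dense_network(m, N=4)
        te = transfer_entropy(m, net, n_samples=400, seed=6)
        assert te == pytest.approx(np.log(4), abs=1e-3)

    def test_matches_quadrature_oracle_on_tiny_instance(self):
        """p=2, M=2 dense decoding checked against grid integration."""
        theta = np.array([[1.0, 0.2], [0.2, 1.0]])
        m = dh.ExternalModel(theta=theta, family=GaussianFamily(sigma=1.0))
        net = dh.dense_network(m, N=2)

        # oracle: TE = ln 2 - E_r[H(posterior)] by 2-D grid quadrature
        grid = np.linspace(-5.5, 6.5, 241)
        dx = grid[1] - grid[0]
        R1, R2 = np.meshgrid(grid, grid, indexing="ij")
        def loglik(mu):
            return -0.5 * ((R1 - theta[mu, 0]) ** 2 + (R2 - theta[mu, 1]) ** 2)
        L0, L1 = loglik(0), loglik(1)
        mx = np.maximum(L0, L1)
        p0 = np.exp(L0 - mx)
        p1 = np.exp(L1 - mx)
        Z = p0 + p1
        p0, p1 = p0 / Z, p1 / Z
        dens = 0.5 * (np.exp(L0) + np.exp(L1)) / (2 * np.pi)
        H = -(np.where(p0 > 0, p0 * np.log(p0), 0) + np.where(p1 > 0, p1 * np.log(p1), 0))
        expected = np.log(2) - np.sum(dens * H) * dx * dx

        reps = [transfer_entropy(m, net, n_samples=4000, seed=s) for s in range(5)]
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert np.mean(reps) == pytest.approx(expected, abs=max(3 * se, 5e-3))

    def test_removing_connections_cannot_add_information(self, small_gaussian_model):
        m = small_gaussian_model
        dense = dh.dense_network(m, N=8)
        tes = []
        for s in range(6):
            sub = dh.build_random_coding(m, rho_o=0.3, N=8, seed=40 + s)
            tes.append(transfer_entropy(m, sub, n_samples=400, seed=50 + s))
        te_dense = transfer_entropy(m, dense, n_samples=400, seed=60)
        assert te_dense >= np.mean(tes)


class TestModelError:
    def test_exact_readout_gives_zero(self, small_gaussian_model):
        m = small_gaussian_model
        net = dh.dense_network(m, N=8)
        assert model_error(m, net, "combined") == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_global_weight_scale(self, small_gaussian_model):
        m = small_gaussian_model
        net = dh.build_dual_coding(m, gamma=0.3, N=8, seed=7)
        d1 = model_error(m, net, "combined")
        net.W *= 7.3
        assert model_error(m, net, "combined") == pytest.approx(d1, rel=1e-9)

    @pytest.mark.parametrize("mode", ["combined", "connectivity_only", "weight_only"])
    def test_modes_nonnegative(self, mode, small_gaussian_model):
        m = small_gaussian_model
        net = dh.build_random_coding(m, rho_o=0.3, N=8, seed=8)
        assert model_error(m, net, mode) >= 0

    def test_structured_connectivity_beats_random(self, default_gaussian_model):
        """Connectivity-coded wiring reads out the model better than random
        wiring of equal density."""
        m = default_gaussian_model
        diffs = []
        for s in range(5):
            net_c = dh.build_connectivity_coding(m, gamma=0.1, N=50, seed=70 + s)
            net_r = dh.build_random_coding(m, rho_o=float(net_c.C.mean()), N=50, seed=80 + s)
            diffs.append(
                model_error(m, net_r, "connectivity_only")
                - model_error(m, net_c, "connectivity_only")
            )
        assert np.mean(diffs) > 0

    def test_empty_group_raises(self, small_gaussian_model):
        m = small_gaussian_model
        net = dh.build_random_coding(m, rho_o=0.3, N=8, seed=9)
        bad_sel = np.zeros(8, dtype=int)  # nobody represents states 1..3
        with pytest.raises(ValueError):
            model_error(m, net, "combined", selectivity=bad_sel)


class TestKLGap:
    def test_dense_structure_has_zero_gap(self, small_gaussian_model):
        m = small_gaussian_model
        C = np.ones((8, m.M))
        assert kl_gap(m, C, dh.selectivity_map(m.p, 8)) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_and_positive_for_sparse(self, small_gaussian_model, rng):
        m = small_gaussian_model
        C = (rng.random((8, m.M)) < 0.2).astype(float)
        gap = kl_gap(m, C, dh.selectivity_map(m.p, 8))
        assert gap > 0

    def test_closed_form_tracks_monte_carlo_ordering(self):
        """The noise integral inside the softmax overestimates the divergence
        (roughly a constant factor at unit noise) but preserves the ordering
        of structures, which is what hill-climbing and the information gain
        rely on."""
        m = dh.make_gaussian_model(p=4, M=40, seed=1)
        sel = dh.selectivity_map(4, 12)
        rng = np.random.default_rng(2)
        cfs, mcs = [], []
        for k in range(10):
            C = (rng.random((12, 40)) < (0.15 + 0.05 * (k % 4))).astype(float)
            cfs.append(kl_gap(m, C, sel, mode="closed_form"))
            mcs.append(kl_gap(m, C, sel, mode="monte_carlo", n_samples=1500, seed=100 + k))
        from scipy.stats import pearsonr

        assert pearsonr(cfs, mcs).statistic > 0.6
        assert np.all(np.asarray(cfs) > 0) and np.all(np.asarray(mcs) > 0)


class TestInfoGain:
    def test_uninformative_input_gains_nothing(self):
        theta = np.abs(np.random.default_rng(1).normal(1, 0.5, (3, 12)))
        theta[:, 0] = 1e-6  # silent input
        m = dh.ExternalModel(theta=theta, family=GaussianFamily())
        gains = info_gain_profile(m, neuron=0, N=6, n_structures=20, rho=0.2, seed=2)
        assert abs(gains[0]) < 1e-6

    def test_gain_correlates_with_weight_in_homogeneous_model(self):
        m = dh.make_gaussian_model(p=4, M=30, seed=14)
        gains = info_gain_profile(m, neuron=0, N=40, n_structures=40, rho=0.1, seed=15)
        w = m.q[0]  # neuron 0 is selective for state 0
        from scipy.stats import spearmanr

        rho_s = spearmanr(w, gains).statistic
        assert rho_s > 0.4

    def test_constant_inputs_gain_little_despite_large_weights(self):
        m = dh.make_structured_binary_model(p=4, M=40, seed=16)
        n_const = m.meta["n_const"]
        gains = info_gain_profile(m, neuron=0, N=40, n_structures=40, rho=0.1, seed=17)
        w = m.q[0]
        assert w[:n_const].min() >= w[n_const:].max()  # largest weights...
        assert np.mean(np.abs(gains[:n_const])) < np.mean(np.abs(gains[n_const:]))


class TestHillclimb:
    def test_full_density_returns_dense(self, small_gaussian_model):
        m = small_gaussian_model
        C = hillclimb_connectivity(m, N=8, density=1.0, restarts=1, seed=18)
        assert np.all(C == 1)

    def test_beats_random_structures(self):
        m = dh.make_gaussian_model(p=3, M=20, seed=19)
        sel = dh.selectivity_map(3, 6)
        ev = KLEvaluator(m, sel)
        C_opt = hillclimb_connectivity(m, N=6, density=0.25, restarts=2, seed=20,
                                       max_proposals=800, patience=150)
        rng = np.random.default_rng(21)
        randoms = [ev.divergence((rng.random((6, 20)) < 0.25).astype(float)) for _ in range(20)]
        assert ev.divergence(C_opt) < np.mean(randoms)

    def test_preserves_connection_count(self):
        m = dh.make_gaussian_model(p=3, M=20, seed=22)
        C = hillclimb_connectivity(m, N=6, density=0.3, restarts=1, seed=23,
                                   max_proposals=300, patience=100)
        assert C.sum() == round(0.3 * 6 * 20)


class TestAnalyticTheory:
    def test_degenerate_tuning_has_no_signal(self):
        mo = analytic_moments(1.0, 0.0, 1.0, 1.0, 200, "weight", 0.3)
        assert mo.sigma_theta == 0 and mo.mean_sel == 0

    def test_mu_sigma_normalization_identity(self):
        mo = analytic_moments(1.2876, 0.7935, 1.0, 1.0, 200, "weight", 0.3)
        assert mo.mu_theta**2 + mo.sigma_theta**2 == pytest.approx(1.0, abs=1e-6)

    def test_equal_marginals_give_chance_tail(self):
        mo = analytic_moments(1.0, 1.0, 1.0, 1.0, 200, "weight", 0.3)
        mo.mean_sel = mo.mean_nonsel = 5.0
        mo.var_sel = mo.var_nonsel = 4.0
        mo.cov = 1.0
        eps, acc, _ = analytic_accuracy(mo, 10)
        assert eps == pytest.approx(0.5)
        assert acc == pytest.approx(0.5**9)

    def test_large_gap_limit_is_perfect(self):
        mo = analytic_moments(1.0, 1.0, 1.0, 1.0, 200, "weight", 0.3)
        mo.mean_sel = 1e9
        _, acc, _ = analytic_accuracy(mo, 10)
        assert acc == pytest.approx(1.0)

    def test_connectivity_cv_below_weight_cv_when_sparse(self):
        mu, sd = truncated_normal_moments(1.0, 1.0)
        for rho in [0.05, 0.1, 0.2]:
            cv_w = analytic_accuracy(analytic_moments(mu, sd, 1, 1, 200, "weight", rho), 10)[2]
            cv_c = analytic_accuracy(
                analytic_moments(mu, sd, 1, 1, 200, "connectivity", rho), 10
            )[2]
            assert cv_c < cv_w

    def test_accuracy_crossing_over_density(self):
        """Connectivity coding wins when sparse; the advantage fades when dense."""
        mu, sd = truncated_normal_moments(1.0, 1.0)
        rhos = [0.05, 0.1, 0.4, 0.8, 0.95]
        acc = {
            s: [analytic_accuracy(analytic_moments(mu, sd, 1, 1, 200, s, r), 10)[1] for r in rhos]
            for s in ("weight", "connectivity")
        }
        gaps = np.array(acc["connectivity"]) - np.array(acc["weight"])
        assert gaps[0] > 0 and gaps[1] > 0  # sparse regime: connectivity wins
        assert gaps[-1] < gaps[-2] < gaps[-3]  # advantage fades toward dense
        assert gaps[-1] < 0.1

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            analytic_moments(1.0, 1.0, 1.0, 1.0, 200, "weight", 0.0)

    def test_moments_match_small_monte_carlo(self):
        """Smoke-scale version of the moment validation (full scale in
        acceptance): means and trial covariance from the actual generator."""
        r = simulate_membrane_moments("weight", rho=0.3, n_models=20, n_trials=500, seed=24)
        mo = r["moments"]
        for key, target in [("mean_sel", mo.mean_sel), ("mean_nonsel", 0.0),
                            ("cov_trial", mo.cov_trial)]:
            value, se = r[key]
            assert abs(value - target) < 4 * se


class TestInfoCapacity:
    def test_half_density_break_even_is_two_bits(self):
        cap = info_capacity(200, 100, 0.5)
        assert cap.break_even_b == pytest.approx(4.0, rel=1e-12)
        assert cap.break_even_bits == pytest.approx(2.0, rel=1e-12)

    def test_sparse_cortical_operating_point(self):
        cap = info_capacity(200, 100, 0.06)
        assert cap.break_even_bits == pytest.approx(5.458, abs=2e-3)

    def test_exact_log_binomial_approaches_stirling(self):
        rel_err = []
        for scale in [10, 100, 1000]:
            cap = info_capacity(scale, scale, 0.2)
            rel_err.append(abs(cap.I_C - cap.I_C_stirling) / cap.I_C_stirling)
        assert rel_err[0] > rel_err[1] > rel_err[2]
        assert rel_err[2] < 1e-3

    def test_break_even_consistency(self):
        # at b = b* the two capacities coincide (Stirling scale)
        cap = info_capacity(500, 500, 0.13)
        cap_at_bstar = info_capacity(500, 500, 0.13, b=cap.break_even_b)
        assert cap_at_bstar.I_w == pytest.approx(cap.I_C_stirling, rel=1e-12)

    def test_boundary_flagged(self):
        cap = info_capacity(10, 10, 0.0)
        assert cap.boundary and cap.I_C == 0.0


class TestCapacityProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, max_examples=60)
    @given(st.floats(min_value=0.01, max_value=0.98))
    def test_exact_capacity_bracketed_and_break_even_decreasing(self, rho):
        cap = info_capacity(60, 40, rho)
        # exact log-binomial is below the Stirling entropy bound and positive
        assert 0 < cap.I_C <= cap.I_C_stirling + 1e-9
        denser = info_capacity(60, 40, min(rho + 0.01, 0.99))
        assert denser.break_even_bits < cap.break_even_bits


class TestGradientAlignment:
    def test_bounded_reproducible_and_near_orthogonal(self, default_gaussian_model):
        """The raw update directions of the wiring rule and the
        transfer-entropy gradient are nearly orthogonal on a selective
        network: the (1 + log r_Y) prefactor is negative for every
        non-winning neuron, cancelling the shared Hebbian structure."""
        m = default_gaussian_model
        net = dh.build_dual_coding(m, gamma=0.1, N=50, seed=25)
        cos = te_gradient_alignment(m, net, n_samples=100, seed=26, w_o=1.0 / 0.1)
        again = te_gradient_alignment(m, net, n_samples=100, seed=26, w_o=1.0 / 0.1)
        assert cos == again
        assert -1.0 <= cos <= 1.0
        assert abs(cos) < 0.25
        cm = te_gradient_alignment(
            m, net, n_samples=100, seed=26, w_o=1.0 / 0.1, aggregate="mean_update"
        )
        assert -1.0 <= cm <= 1.0
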