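"""First- and second-level sequence GLM against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdlm.core import EmpiricalTransitions, StateSpace, build_lag_pairs
from tdlm.glm import (
    FirstLevelDesign,
    SingularDesignError,
    add_oscillation_controls,
    build_templates,
    empirical_transitions,
    sequenceness,
    sequenceness_curve,
    simple_pairwise_transitions,
)
from tdlm.simulate import line_transition_matrix


def one_hot_cycle(n_states=3, n_samples=30):
    X = np.zeros((n_samples, n_states))
    X[np.arange(n_samples), np.arange(n_samples) % n_states] = 1.0
    return StateSpace(X, 0.01)


class TestFirstLevel:
    def test_deterministic_cycle_recovers_exact_transitions(self):
        sp = one_hot_cycle()
        beta = empirical_transitions(sp, 1, FirstLevelDesign(intercept=False)).betas[0]
        expect = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
        np.testing.assert_allclose(beta, expect, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((200, 4))
        sp = StateSpace(X, 0.01)
        beta = empirical_transitions(sp, 2).betas[0]
        A = np.hstack([X[:-2], np.ones((198, 1))])
        oracle = np.linalg.solve(A.T @ A, A.T @ X[2:])[:4]
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_constant_state_column_raises_named_singularity(self, rng):
        X = rng.standard_normal((100, 3))
        X[:, 1] = 0.7
        sp = StateSpace(X, 0.01, state_labels=["a", "b", "c"])
        with pytest.raises(SingularDesignError, match="b"):
            empirical_transitions(sp, 1)

    def test_pseudo_inverse_escape_hatch(self, rng):
        X = rng.standard_normal((100, 3))
        X[:, 1] = 0.7
        sp = StateSpace(X, 0.01)
        beta = empirical_transitions(
            sp, 1, FirstLevelDesign(allow_pseudo_inverse=True)
        ).betas[0]
        assert np.all(np.isfinite(beta))

    def test_demeaning_columns_leaves_beta_unchanged_with_intercept(self, rng):
        X = rng.standard_normal((300, 4)) + rng.uniform(-2, 2, size=4)
        b1 = empirical_transitions(StateSpace(X, 0.01), 3).betas[0]
        b2 = empirical_transitions(StateSpace(X - X.mean(0), 0.01), 3).betas[0]
        np.testing.assert_allclose(b1, b2, atol=1e-9)


class TestPairwiseNegativeControl:
    def test_correlated_autocorrelated_null_is_spurious_only_pairwise(self):
        """Shared autocorrelated signal inflates pairwise lag coefficients;
        the multiple regression absorbs it via the co-regressors."""
        from scipy import signal as sps

        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 600
            common = sps.lfilter([1], [1, -0.95], rng.standard_normal(n))
            X = np.stack(
                [
                    0.8 * common
                    + sps.lfilter([1], [1, -0.9], rng.standard_normal(n))
                    for _ in range(4)
                ],
                axis=1,
            )
            sp = StateSpace(X, 0.01)
            pair = simple_pairwise_transitions(sp, 3)
            multi = empirical_transitions(sp, 3).betas[0]
            off = ~np.eye(4, dtype=bool)
            ratios.append(np.abs(pair[off]).mean() / np.abs(multi[off]).mean())
        assert np.mean(ratios) > 3.0

    def test_white_noise_states_give_null_coefficients(self, rng):
        X = rng.standard_normal((2000, 3))
        sp = StateSpace(X, 0.01)
        pair = simple_pairwise_transitions(sp, 1)
        se = 1.0 / np.sqrt(2000)
        assert np.all(np.abs(pair) < 4 * se)

    def test_single_state_returns_autoregression(self, rng):
        x = rng.standard_normal(500)
        x = np.convolve(x, [1, 0.5], "full")[:500]
        sp = StateSpace(x[:, None], 0.01)
        coef = simple_pairwise_transitions(sp, 1)
        A = np.column_stack([x[:-1], np.ones(499)])
        oracle = np.linalg.lstsq(A, x[1:], rcond=None)[0][0]
        np.testing.assert_allclose(coef[0, 0], oracle, atol=1e-10)


class TestTemplates:
    def test_line_templates(self):
        t = build_templates(line_transition_matrix(4))
        assert [x.name for x in t] == ["forward", "backward", "auto", "const"]
        np.testing.assert_array_equal(t[1].matrix, t[0].matrix.T)
        np.testing.assert_array_equal(t[2].matrix, np.eye(4))
        np.testing.assert_array_equal(t[3].matrix, np.ones((4, 4)))

    def test_symmetric_forward_equals_backward(self):
        T = np.array([[0, 1], [1, 0]], dtype=float)
        t = build_templates(T)
        np.testing.assert_array_equal(t[0].matrix, t[1].matrix)

    def test_one_state_degenerate(self):
        t = build_templates(np.zeros((1, 1)))
        np.testing.assert_array_equal(t[2].matrix, [[1.0]])
        np.testing.assert_array_equal(t[3].matrix, [[1.0]])


class TestSecondLevel:
    def test_beta_in_template_span_recovers_unit_weight(self):
        T_F = line_transition_matrix(4)
        res = sequenceness(EmpiricalTransitions(betas=T_F[None], lags=[1]), T_F)
        assert res.z_forward[0] == pytest.approx(1.0, abs=1e-12)
        assert res.z_backward[0] == pytest.approx(0.0, abs=1e-12)
        assert res.z_auto[0] == pytest.approx(0.0, abs=1e-12)
        assert res.z_const[0] == pytest.approx(0.0, abs=1e-12)

    def test_symmetrised_beta_loads_both_directions(self):
        T_F = line_transition_matrix(4)
        beta = T_F + T_F.T
        res = sequenceness(EmpiricalTransitions(betas=beta[None], lags=[1]), T_F)
        assert res.z_forward[0] == pytest.approx(1.0, abs=1e-12)
        assert res.z_backward[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_vectorized_least_squares_oracle(self, rng):
        T_F = line_transition_matrix(5)
        beta = rng.standard_normal((5, 5))
        res = sequenceness(EmpiricalTransitions(betas=beta[None], lags=[1]), T_F)
        D = np.column_stack([t.matrix.ravel() for t in build_templates(T_F)])
        z = np.linalg.lstsq(D, beta.ravel(), rcond=None)[0]
        np.testing.assert_allclose(
            [res.z_forward[0], res.z_backward[0], res.z_auto[0], res.z_const[0]],
            z,
            atol=1e-10,
        )

    def test_symmetric_template_set_raises_rank_error(self, rng):
        T = np.array([[0, 1], [1, 0]], dtype=float)
        beta = rng.standard_normal((2, 2))
        with pytest.raises(SingularDesignError, match="duplicate"):
            sequenceness(EmpiricalTransitions(betas=beta[None], lags=[1]), T)

    def test_drop_diagonal_matches_include_diagonal_for_offdiag_templates(self, rng):
        T_F = line_transition_matrix(5)
        beta = rng.standard_normal((5, 5))
        emp = EmpiricalTransitions(betas=beta[None], lags=[1])
        a = sequenceness(emp, T_F, include_diagonal=True)
        b = sequenceness(emp, T_F, include_diagonal=False)
        assert a.z_forward[0] == pytest.approx(b.z_forward[0], abs=1e-10)
        assert a.z_backward[0] == pytest.approx(b.z_backward[0], abs=1e-10)
        assert np.isnan(b.z_auto[0])  # unsupported off-diagonal

    def test_oracle_equivalence_many_random_instances(self, rng):
        """First and second level match independent solvers to 1e-10."""
        for _ in range(100):
            n = int(rng.integers(3, 7))
            T_samp = int(rng.integers(50, 120))
            lag = int(rng.integers(1, 4))
            X = rng.standard_normal((T_samp, n))
            sp = StateSpace(X, 0.01)
            beta = empirical_transitions(sp, lag).betas[0]
            A = np.hstack([X[:-lag], np.ones((T_samp - lag, 1))])
            oracle = (np.linalg.pinv(A) @ X[lag:])[:n]
            np.testing.assert_allclose(beta, oracle, atol=1e-10)
            T_F = line_transition_matrix(n)
            res = sequenceness(
                EmpiricalTransitions(betas=beta[None], lags=[lag]), T_F
            )
            D = np.column_stack(
                [t.matrix.ravel() for t in build_templates(T_F)]
            )
            z = np.linalg.pinv(D) @ beta.ravel()
            np.testing.assert_allclose(res.z_forward[0], z[0], atol=1e-10)
            np.testing.assert_allclose(res.z_backward[0], z[1], atol=1e-10)


class TestCurveAndProperties:
    def test_state_relabelling_equivariance(self, rng):
        X = rng.standard_normal((300, 5))
        T_F = line_transition_matrix(5)
        perm = rng.permutation(5)
        res1 = sequenceness_curve(StateSpace(X, 0.01), T_F, [1, 2, 3])
        res2 = sequenceness_curve(
            StateSpace(X[:, perm], 0.01), T_F[np.ix_(perm, perm)], [1, 2, 3]
        )
        np.testing.assert_allclose(res1.z_forward, res2.z_forward, atol=1e-10)
        np.testing.assert_allclose(res1.z_backward, res2.z_backward, atol=1e-10)

    def test_time_reversal_swaps_regression_roles(self, rng):
        """beta on reversed samples equals the role-swapped OLS on the
        matched pair set (explicit pair bookkeeping oracle)."""
        X = rng.standard_normal((120, 3))
        lag = 2
        rev = empirical_transitions(StateSpace(X[::-1], 0.01), lag).betas[0]
        pairs = build_lag_pairs(StateSpace(X, 0.01), lag)
        # reversed-time regression: predictor X[t+lag], outcome X[t]
        A = np.hstack([X[pairs.target_rows], np.ones((len(pairs), 1))])
        oracle = (np.linalg.pinv(A) @ X[pairs.source_rows])[:3]
        np.testing.assert_allclose(rev, oracle, atol=1e-10)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 10.0))
    def test_homogeneity_z_linear_in_beta_and_beta_scale_invariant(self, scale):
        """Z is linear in beta; rescaling the whole state space leaves the
        regression coefficients (hence Z) unchanged, since predictors and
        outcome scale together."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((150, 4))
        T_F = line_transition_matrix(4)
        beta = empirical_transitions(StateSpace(X, 0.01), 1).betas[0]
        beta_scaled = empirical_transitions(StateSpace(X * scale, 0.01), 1).betas[0]
        np.testing.assert_allclose(beta_scaled, beta, atol=1e-9)
        z1 = sequenceness(EmpiricalTransitions(betas=beta[None], lags=[1]), T_F)
        z2 = sequenceness(
            EmpiricalTransitions(betas=scale * beta[None], lags=[1]), T_F
        )
        assert z2.z_forward[0] == pytest.approx(
            scale * z1.z_forward[0], rel=1e-9, abs=1e-12
        )


class TestOscillationControls:
    def test_duplicate_tau_rejected(self):
        with pytest.raises(SingularDesignError, match="duplicate"):
            add_oscillation_controls(
                add_oscillation_controls(FirstLevelDesign(), 10), 10
            )

    def test_tau_equal_to_lag_raises_in_single_fit(self, rng):
        sp = StateSpace(rng.standard_normal((100, 3)), 0.01)
        design = add_oscillation_controls(FirstLevelDesign(), 5)
        with pytest.raises(ValueError, match="equals the outcome lag"):
            empirical_transitions(sp, 5, design)

    def test_white_noise_controls_barely_move_z(self, rng):
        """Independent white-noise control columns shift Z by < 2 SE."""
        X = rng.standard_normal((800, 4))
        T_F = line_transition_matrix(4)
        plain = sequenceness_curve(StateSpace(X, 0.01), T_F, [3])
        ctl = sequenceness_curve(
            StateSpace(X, 0.01), T_F, [3], add_oscillation_controls(FirstLevelDesign(), 10)
        )
        se = np.sqrt(plain.variance[0, 0])
        assert abs(ctl.z_forward[0] - plain.z_forward[0]) < 2 * se

    def test_tau_out_of_range_raises(self, rng):
        sp = StateSpace(rng.standard_normal((50, 3)), 0.01)
        design = add_oscillation_controls(FirstLevelDesign(), 200)
        with pytest.raises(ValueError, match="out of range"):
            empirical_transitions(sp, 2, design)


def test_monotonic_sequenceness_in_injection_count():
    """Mean Z_F at the true lag is non-decreasing over injection levels
    (Page-style trend over 3 levels x 10 seeds)."""
    from tdlm.pipeline import simulate_decoded_subject
    from tdlm.simulate import SimulationConfig

    levels = [0, 60, 200]
    means = []
    for n_inj in levels:
        vals = []
        for seed in range(10):
            sim = SimulationConfig(
                n_injected_sequences=n_inj, duration=1500, n_sensors=32,
                n_task_obs_per_state=25,
            )
            space, _, _ = simulate_decoded_subject(sim, seed)
            res = sequenceness_curve(
                space, sim.resolved_transitions(), [4]
            )
            vals.append(res.z_forward[0])
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
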