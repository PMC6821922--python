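"""Resource budget model dynamics: single map, coupled ensemble, reduced limit."""

import numpy as np
import pytest

from mastsync import ModelParams, reduced_map, simulate, step_coupled, step_uncoupled


def scalar_coupled_oracle(S, params, sigma, delta):
    """Straight-line per-tree transcription of the coupled update rule.

    Kept deliberately unvectorised and independent of the library code
    path; agreement is asserted to near machine precision.
    """
    N = params.N
    S_next, C_f, C_a, C_S, Y = [], [], [], [], []
    cf = []
    for i in range(N):
        P_S = params.P_0 * (1 + params.e_C * sigma) * (1 + params.e_I * delta[i])
        acc = S[i] + P_S
        cf.append(acc - params.L_T if acc > params.L_T else 0.0)
    for i in range(N):
        P_S = params.P_0 * (1 + params.e_C * sigma) * (1 + params.e_I * delta[i])
        acc = S[i] + P_S
        others = sum(cf[j] for j in range(N) if j != i)
        y = (others / ((N - 1) * params.P_0)) ** params.beta if params.beta else 1.0
        ca = params.R_C * cf[i] * y
        C_f.append(cf[i])
        C_a.append(ca)
        C_S.append(cf[i] * y)
        Y.append(y)
        S_next.append(acc if acc <= params.L_T else acc - cf[i] - ca)
    return map(np.array, (S_next, C_f, C_a, C_S, Y))


class TestStepUncoupled:
    def test_sub_threshold_accumulates(self):
        S_next, C_f = step_uncoupled(50.0, ModelParams())
        assert (S_next, C_f) == (60.0, 0.0)

    def test_flowering_branch(self):
        S_next, C_f = step_uncoupled(95.0, ModelParams(R_C=1.0))
        assert C_f == 5.0
        assert S_next == 95.0  # L_T - R_C * C_f = 100 - 5

    def test_fixed_point_closed_form(self):
        # S* = L_T - R_C P_0 / (1 + R_C), from S* = L_T - R_C (S* + P_0 - L_T)
        p = ModelParams(R_C=0.5)
        S_star = p.L_T - p.R_C * p.P_0 / (1 + p.R_C)
        assert S_star == pytest.approx(96.6667, abs=1e-4)
        S_next, _ = step_uncoupled(S_star, p)
        assert S_next == pytest.approx(S_star, abs=1e-12)

    def test_negative_reserve_allowed_after_heavy_year(self):
        S_next, _ = step_uncoupled(120.0, ModelParams(R_C=4.0))
        assert S_next < 0


class TestReducedMap:
    def test_sub_threshold_branch_independent_of_parameters(self):
        for R_C, beta in [(0.5, 0.0), (2.0, 6.0), (3.7, 1.0)]:
            assert reduced_map(50.0, R_C, beta) == 60.0

    def test_beta_zero_equals_uncoupled(self):
        p = ModelParams(R_C=1.7, beta=0.0)
        S = np.linspace(-10, 120, 301)
        expected, _ = step_uncoupled(S, p)
        assert np.allclose(reduced_map(S, 1.7, 0.0), expected, atol=0)

    @pytest.mark.parametrize(
        "beta,right", [(0.0, "minus_rc"), (6.0, "zero")], ids=["beta0", "beta6"]
    )
    def test_border_one_sided_derivatives(self, beta, right):
        # kink at S = L_T - P_0: left slope 1 always; right slope -R_C
        # for beta=0 and 0 for beta>0
        # the accumulation branch is exactly linear, so a finite step
        # on the left gives the one-sided derivative without rounding;
        # on the right a small step suffices (the beta>0 branch opens
        # with a zero derivative of order h^beta)
        R_C, border = 1.3, 90.0
        left = reduced_map(border, R_C, beta) - reduced_map(border - 1.0, R_C, beta)
        h = 1e-3
        rd = (reduced_map(border + h, R_C, beta) - reduced_map(border, R_C, beta)) / h
        assert left == pytest.approx(1.0, abs=1e-12)
        expected = -R_C if right == "minus_rc" else 0.0
        assert rd == pytest.approx(expected, abs=1e-9)

    def test_synchronised_three_cycle_value(self):
        # L_T - R_C C_f^(beta+1) / P_0^beta at the top of the 3-cycle
        out = reduced_map(99.9438, 1.6171, 6.0)
        assert out == pytest.approx(84.4545, abs=1e-3)


class TestStepCoupled:
    def test_symmetric_population_follows_reduced_map(self):
        p = ModelParams(R_C=1.8, beta=6.0, N=12)
        for S in (50.0, 95.0, 99.5):
            S_next, *_ = step_coupled(np.full(12, S), p, 0.0, np.zeros(12))
            assert np.allclose(S_next, reduced_map(S, 1.8, 6.0), atol=1e-12)

    def test_lone_flowering_tree_sets_no_seed(self):
        p = ModelParams(R_C=2.0, beta=6.0, N=5)
        S = np.array([95.0, 50.0, 60.0, 70.0, 80.0])
        _, C_f, C_a, C_S, Y = step_coupled(S, p, 0.0, np.zeros(5))
        assert C_f[0] > 0 and np.all(C_f[1:] == 0)
        assert Y[0] == 0 and C_a[0] == 0 and C_S[0] == 0

    def test_synchronised_step_matches_printed_cycle(self):
        p = ModelParams(R_C=1.6171, beta=6.0, N=8)
        S_next, *_ = step_coupled(np.full(8, 99.9438), p, 0.0, np.zeros(8))
        assert np.allclose(S_next, 84.4545, atol=1e-3)

    def test_resource_accounting_identity(self, rng):
        # above threshold: S(t+1) = S(t) + P_S - C_f - C_a exactly
        p = ModelParams(R_C=2.0, beta=6.0, e_I=0.2, e_C=0.1, N=40)
        S = rng.uniform(0, 110, 40)
        sigma = rng.standard_normal()
        delta = rng.standard_normal(40)
        S_next, C_f, C_a, _, _ = step_coupled(S, p, sigma, delta)
        P_S = p.P_0 * (1 + p.e_C * sigma) * (1 + p.e_I * delta)
        above = S + P_S > p.L_T
        assert np.array_equal(S_next[above], (S + P_S - C_f - C_a)[above])
        assert np.array_equal(S_next[~above], (S + P_S)[~above])

    def test_scalar_oracle_equivalence(self, rng):
        p = ModelParams(R_C=1.9, beta=6.0, e_I=0.2, e_C=0.2, N=17)
        for _ in range(1000):
            S = rng.uniform(-20, 130, p.N)
            sigma = rng.standard_normal()
            delta = rng.standard_normal(p.N)
            got = step_coupled(S, p, sigma, delta)
            for g, e in zip(got, scalar_coupled_oracle(S, p, sigma, delta)):
                np.testing.assert_allclose(g, e, rtol=0, atol=1e-12)

    def test_rejects_wrong_shapes(self):
        p = ModelParams(N=4)
        with pytest.raises(ValueError):
            step_coupled(np.zeros(3), p, 0.0, np.zeros(3))
        with pytest.raises(ValueError):
            step_coupled(np.zeros(4), p, 0.0, np.zeros(3))


class TestSimulate:
    def test_deterministic_given_seed(self):
        p = ModelParams(R_C=2.0, beta=6.0, e_I=0.2, N=20, seed=7, T_record=10)
        a, b = simulate(p), simulate(p)
        for name in ("S", "C_f", "C_a", "C_S", "Y"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_noise_free_period3_synchrony(self, noise_free_sync_trajectory):
        traj = noise_free_sync_trajectory
        # all trees identical (full synchronisation) ...
        assert np.allclose(traj.S, traj.S[0], atol=1e-8)
        # ... on a period-3 orbit
        assert np.allclose(traj.S[:, 3:], traj.S[:, :-3], atol=1e-8)

    def test_common_noise_preserves_exact_synchrony(self):
        p = ModelParams(R_C=2.0, beta=6.0, e_I=0.0, e_C=0.2, N=15, seed=3)
        traj = simulate(p)
        assert np.array_equal(traj.S, np.tile(traj.S[:1], (15, 1)))
        assert np.array_equal(traj.C_S, np.tile(traj.C_S[:1], (15, 1)))

    def test_beta_zero_equals_independent_uncoupled_runs(self):
        p = ModelParams(R_C=1.5, beta=0.0, e_I=0.0, e_C=0.0, N=6, seed=11,
                        T_transient=0, T_record=40)
        traj = simulate(p)
        rng = np.random.default_rng(11)
        S = rng.uniform(0, p.L_T, p.N)
        for t in range(40):
            np.testing.assert_allclose(traj.S[:, t], S, atol=1e-12)
            S, _ = step_uncoupled(S, p)

    def test_shapes_and_flux_consistency(self, fig8_like_trajectory):
        traj = fig8_like_trajectory
        assert traj.S.shape == (106, 15)
        np.testing.assert_allclose(traj.C_a, traj.params.R_C * traj.C_f * traj.Y)
        np.testing.assert_allclose(traj.C_S, traj.C_f * traj.Y)
        assert np.all(traj.C_f >= 0) and np.all(traj.C_S >= 0)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(P_0=0.0),
            dict(L_T=-1.0),
            dict(R_C=-0.1),
            dict(beta=-1.0),
            dict(e_I=-0.5),
            dict(N=0),
            dict(N=1, beta=2.0),
            dict(T_record=0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_roundtrip_and_defaults(self):
        p = ModelParams()
        assert (p.P_0, p.L_T) == (10.0, 100.0)
        assert ModelParams.from_dict(p.to_dict()) == p
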