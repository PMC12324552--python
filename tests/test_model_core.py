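"""Transition, turn-decision and emission probability computations."""

import numpy as np
import pytest
from scipy.integrate import quad

from stapaw import model as M
from stapaw.preprocessing import Track


@pytest.fixture()
def basis():
    return M.RaisedCosineBasis(n_basis=4, n_lags=14)


def _emission(basis, **kw):
    defaults = dict(
        M=0.8, m=0.05,
        K_C=M.Kernel.zeros(basis), K_h=M.Kernel.zeros(basis),
        alpha=0.1, kappa_turn=2.0, kappa_wv=20.0,
        K_dcp=M.Kernel.zeros(basis),
        gamma_turn=(2.0, 0.5), gamma_run=(5.0, 0.2),
    )
    defaults.update(kw)
    return M.EmissionParams(**defaults)


def _params(basis, emissions, baselines, kernels=None):
    Z = len(emissions)
    return M.StaPAWParams(
        n_states=Z, emissions=emissions,
        transitions=M.TransitionParams(Z, np.asarray(baselines, float),
                                       kernels or {}),
    )


class TestBasisAndKernel:
    def test_realized_weights_are_basis_times_coeffs(self, basis):
        c = np.array([1.0, -2.0, 0.5, 0.0])
        k = M.Kernel(c, basis)
        assert np.allclose(k.weights, basis.matrix @ c)

    def test_projection_recovers_smooth_target(self, basis):
        target = basis.matrix @ np.array([0.3, -1.0, 2.0, 0.1])
        k = M.Kernel.from_weights(target, basis)
        assert np.allclose(k.weights, target, atol=1e-10)

    def test_zero_sum_projection_sums_to_zero(self, basis):
        prof = np.zeros(14)
        prof[:2], prof[2:4] = 0.5, -0.5
        k = M.Kernel.from_weights(prof, basis, zero_sum=True)
        assert abs(k.weights.sum()) < 1e-9

    def test_featurize_matches_manual_lagged_sum(self, basis, rng):
        s = rng.standard_normal(30)
        F = M.featurize(s, basis)
        B = basis.matrix
        t = 20
        manual = np.array([
            sum(B[l, k] * s[t - 1 - l] for l in range(14))
            for k in range(4)
        ])
        assert np.allclose(F[t], manual)
        assert np.allclose(F[0], 0.0)  # no history before the first step


class TestTransitionMatrix:
    def test_zero_kernels_zero_baselines_give_uniform_rows(self, basis):
        p = _params(basis, [_emission(basis)] * 2, [0.0, 0.0])
        P = M.transition_matrix(p, np.zeros(14))
        assert np.allclose(P, 0.5)

    def test_unit_logit_softmax_value(self, basis):
        # drive the 0->1 logit to exactly 1: P = e/(e+1) ~ 0.7311
        kern = M.Kernel.from_weights(np.ones(14) / 14, basis)
        hist = np.full(14, 1.0 / (kern.weights.sum()))
        p = _params(basis, [_emission(basis)] * 2, [0.0, 0.0],
                    {(0, 1): kern, (1, 0): M.Kernel.zeros(basis)})
        P = M.transition_matrix(p, hist)
        assert P[0, 1] == pytest.approx(np.e / (np.e + 1), abs=1e-6)

    def test_large_baseline_pins_self_transition(self, basis):
        p = _params(basis, [_emission(basis)] * 2, [30.0, 0.0])
        P = M.transition_matrix(p, np.zeros(14))
        assert P[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_rows_are_stochastic_for_random_inputs(self, basis, rng):
        kernels = {(i, j): M.Kernel(rng.standard_normal(4), basis)
                   for i in range(3) for j in range(3) if i != j}
        p = _params(basis, [_emission(basis)] * 3, rng.standard_normal(3),
                    kernels)
        feats = M.featurize_track(_sensory_track(rng, 50), p)
        P = M.transition_matrices(p, feats)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(P >= 0)


def _sensory_track(rng, T):
    return Track("t", 5 / 14, rng.vonmises(0, 4, T), rng.gamma(2, 0.1, T),
                 rng.uniform(-1, 1, (T, 2)), rng.uniform(-np.pi, np.pi, T),
                 C=rng.uniform(0, 50, T), dC_perp=rng.normal(0, 0.3, T))


class TestTurnProbability:
    def test_zero_drive_gives_logistic_midpoint(self, basis):
        em = _emission(basis, m=0.05, M=0.8)
        p = M.turn_probability(em, np.zeros(14), np.zeros(14))
        assert p == pytest.approx(0.05 + (0.8 - 0.05) / 2)

    def test_degenerate_range_is_constant(self, basis, rng):
        em = _emission(basis, m=0.1, M=0.1,
                       K_C=M.Kernel(rng.standard_normal(4), basis))
        for _ in range(5):
            p = M.turn_probability(em, rng.uniform(0, 50, 20), rng.uniform(0, 3, 20))
            assert p == pytest.approx(0.1)

    def test_limits_are_m_and_M(self, basis):
        kern = M.Kernel.from_weights(np.ones(14), basis)
        em = _emission(basis, K_C=kern)
        assert M.turn_probability(em, np.full(14, 1e4), np.zeros(14)) == pytest.approx(em.m)
        assert M.turn_probability(em, np.full(14, -1e4), np.zeros(14)) == pytest.approx(em.M)

    def test_bounded_for_arbitrary_inputs(self, basis, rng):
        em = _emission(basis, K_C=M.Kernel(10 * rng.standard_normal(4), basis),
                       K_h=M.Kernel(10 * rng.standard_normal(4), basis))
        for _ in range(20):
            p = M.turn_probability(em, rng.normal(0, 100, 14), rng.uniform(0, 3, 14))
            assert em.m <= p <= em.M

    def test_m_above_M_rejected(self, basis):
        with pytest.raises(ValueError):
            _emission(basis, m=0.9, M=0.3)


class TestHeadingDensity:
    def test_pure_uniform_mixture(self, basis):
        em = _emission(basis, alpha=1.0)
        for x in (-3.0, 0.0, 2.5):
            assert M.heading_density(em, x, 1) == pytest.approx(1 / (2 * np.pi))

    def test_weathervane_mode_at_zero_without_steering(self, basis):
        em = _emission(basis)
        d0 = M.heading_density(em, 0.0, 0, np.zeros(14))
        for x in (0.5, -1.0, 3.0):
            assert d0 > M.heading_density(em, x, 0, np.zeros(14))

    @pytest.mark.parametrize("q", [0, 1])
    def test_densities_integrate_to_one(self, basis, q):
        em = _emission(basis, alpha=0.3, kappa_turn=1.7, kappa_wv=9.0)
        total, _ = quad(lambda x: M.heading_density(em, x, q, np.zeros(14)),
                        -np.pi, np.pi, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_invalid_kappa_rejected(self, basis):
        with pytest.raises(ValueError):
            _emission(basis, kappa_wv=-1.0)


class TestSpeedDensity:
    def test_shape_one_is_exponential(self, basis):
        em = _emission(basis, gamma_turn=(1.0, 0.3))
        x = 0.25
        assert M.speed_density(em, x, 1) == pytest.approx(np.exp(-x / 0.3) / 0.3)

    def test_closed_form_value(self, basis):
        # Gamma(2, 0.5) at x=1: x e^{-2} / b^2 Gamma(2) = 4 e^{-2}
        em = _emission(basis, gamma_run=(2.0, 0.5))
        assert M.speed_density(em, 1.0, 0) == pytest.approx(4 * np.exp(-2))

    def test_sample_mean_matches_shape_times_scale(self, basis, rng):
        a, b = 3.0, 0.4
        x = rng.gamma(a, b, 100_000)
        assert x.mean() == pytest.approx(a * b, rel=0.02)


class TestEmissionLoglik:
    def test_identical_states_give_equal_columns(self, basis, rng):
        em = _emission(basis)
        p = _params(basis, [em, em], [1.0, -1.0])
        ll = M.emission_loglik(p, _sensory_track(rng, 40))
        assert np.allclose(ll[:, 0], ll[:, 1])

    def test_single_step_matches_hand_computed_mixture(self, basis):
        em = _emission(basis)
        p = _params(basis, [em], [0.0])
        tr = Track("one", 5 / 14, np.array([0.3]), np.array([0.2]),
                   np.zeros((1, 2)), np.zeros(1),
                   C=np.array([25.0]), dC_perp=np.array([0.0]))
        ll = M.emission_loglik(p, tr)
        pq = em.mid_turn_probability  # zero-padded history -> midpoint
        expected = np.log(
            pq * M.heading_density(em, 0.3, 1) * M.speed_density(em, 0.2, 1)
            + (1 - pq) * M.heading_density(em, 0.3, 0, np.zeros(14))
            * M.speed_density(em, 0.2, 0))
        assert ll[0, 0] == pytest.approx(expected, abs=1e-10)


class TestPosteriorTurnProbability:
    def test_reversal_with_sharp_turn_mode_is_attributed_to_turning(self, basis, rng):
        em = _emission(basis, kappa_turn=20.0, kappa_wv=20.0)
        p = _params(basis, [em], [0.0])
        tr = _sensory_track(rng, 10)
        tr.dtheta[:] = np.pi
        post = M.posterior_turn_probability(p, tr, np.ones((10, 1)))
        assert np.all(post > 0.99)

    def test_zero_heading_change_with_impossible_turn_mode(self, basis, rng):
        em = _emission(basis, alpha=0.0, kappa_turn=500.0)
        p = _params(basis, [em], [0.0])
        tr = _sensory_track(rng, 10)
        tr.dtheta[:] = 0.0
        post = M.posterior_turn_probability(p, tr, np.ones((10, 1)))
        assert np.all(post < 1e-6)

    def test_complementarity(self, basis, rng):
        em = _emission(basis)
        p = _params(basis, [em, _emission(basis, M=0.5)], [0.0, 0.0])
        tr = _sensory_track(rng, 30)
        gamma = rng.dirichlet([1, 1], size=30)
        comp = M.emission_components(p, tr)
        llm = M._logsumexp2(comp)
        r1 = np.sum(gamma * np.exp(comp[:, :, 1] - llm), axis=1)
        r0 = np.sum(gamma * np.exp(comp[:, :, 0] - llm), axis=1)
        assert np.allclose(r1 + r0, 1.0, atol=1e-10)


class TestSerialization:
    def test_round_trip_is_bit_stable(self, basis, rng, tmp_path):
        kernels = {(0, 1): M.Kernel(rng.standard_normal(4), basis),
                   (1, 0): M.Kernel(rng.standard_normal(4), basis)}
        p = _params(basis, [_emission(basis), _emission(basis, M=0.5)],
                    [1.2, -0.3], kernels)
        path = tmp_path / "params.json"
        M.save_params(p, path)
        q = M.load_params(path)
        assert q.n_states == p.n_states
        for pe, qe in zip(p.emissions, q.emissions):
            assert np.array_equal(pe.K_C.weights, qe.K_C.weights)
            assert pe.M == qe.M and pe.gamma_run == qe.gamma_run
        for key in kernels:
            assert np.array_equal(p.transitions.kernels[key].weights,
                                  q.transitions.kernels[key].weights)


class TestCanonicalize:
    def test_orders_states_by_turn_probability(self, basis):
        hi = _emission(basis, m=0.3, M=0.9)
        lo = _emission(basis, m=0.01, M=0.2)
        p = _params(basis, [hi, lo], [1.0, 2.0],
                    {(0, 1): M.Kernel(np.ones(4), basis),
                     (1, 0): M.Kernel(-np.ones(4), basis)})
        c, order = M.canonicalize(p)
        assert c.emissions[0].M == lo.M and c.emissions[1].M == hi.M
        assert np.allclose(c.transitions.baselines, [2.0, 1.0])
        # the kernel that pointed hi->lo is now T->S = (1, 0)
        assert np.allclose(c.transitions.kernels[(1, 0)].coeffs, 1.0)
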