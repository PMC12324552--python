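"""Turn detection, interval statistics, bearing analyses, chemotaxis index."""

import numpy as np
import pytest

from stapaw import stats
from stapaw.environment import LinearEnvironment
from stapaw.preprocessing import Track


def _track_from_dtheta(dtheta_deg, dt=5 / 14):
    d = np.radians(np.asarray(dtheta_deg, float))
    n = len(d)
    heading = np.cumsum(d)
    pos = np.concatenate([[[0, 0]], np.cumsum(
        0.01 * np.stack([np.cos(heading), np.sin(heading)], 1), axis=0)[:-1]])
    return Track("t", dt, d, np.full(n, 0.01), pos, heading)


class TestDetectTurns:
    def test_onset_rule_merges_consecutive_suprathreshold_steps(self):
        tr = _track_from_dtheta([10, 60, 55, 20, -80])
        ev = stats.detect_turns(tr)
        assert list(ev.indices) == [1, 4]

    def test_subthreshold_series_has_no_events(self):
        tr = _track_from_dtheta([10, -30, 45, -49, 0])
        assert len(stats.detect_turns(tr)) == 0

    def test_default_threshold_is_50_degrees(self):
        tr = _track_from_dtheta([49.9, 0, 50.1])
        ev = stats.detect_turns(tr)
        assert ev.threshold_deg == 50.0
        assert list(ev.indices) == [2]


class TestInterTurnIntervals:
    def test_interval_arithmetic(self):
        ev = stats.TurnEvents(np.array([1, 4]))
        iti = stats.inter_turn_intervals(ev, 5 / 14)
        assert iti == pytest.approx([3 * 5 / 14])

    def test_single_event_tracks_contribute_nothing(self):
        evs = [stats.TurnEvents(np.array([3])), stats.TurnEvents(np.array([2, 9]))]
        iti = stats.inter_turn_intervals(evs, 1.0)
        assert len(iti) == 1

    def test_poisson_turns_give_exponential_intervals(self, rng):
        # memoryless-turn oracle: geometric inter-event steps
        from scipy.stats import kstest
        p = 0.08
        gaps = rng.geometric(p, 4000)
        iti = gaps * 0.1
        fit = stats.fit_exponentials(iti, "single")
        assert fit.rates[0] == pytest.approx(p / 0.1, rel=0.15)


class TestFitExponentials:
    def test_single_rate_recovered_and_double_degenerates(self, rng):
        x = rng.exponential(1.0, 10_000)
        single = stats.fit_exponentials(x, "single")
        assert single.rates[0] == pytest.approx(1.0, rel=0.1)
        double = stats.fit_exponentials(x, "double")
        similar_rates = double.rates[0] / double.rates[1] < 3
        tiny_weight = min(double.weights) < 0.1
        assert similar_rates or tiny_weight

    def test_two_timescale_mixture_recovered(self, rng):
        n = 10_000
        x = np.where(rng.random(n) < 0.5,
                     rng.exponential(1.0, n), rng.exponential(10.0, n))
        double = stats.fit_exponentials(x, "double")
        single = stats.fit_exponentials(x, "single")
        assert double.r2 > single.r2
        assert double.rates[0] == pytest.approx(1.0, rel=0.2)
        assert double.rates[1] == pytest.approx(0.1, rel=0.2)

    def test_crossing_time_matches_closed_form(self, rng):
        # w1 l1 e^{-l1 t} = w2 l2 e^{-l2 t} at t = log(l1/l2)/(l1-l2) for w=1/2
        l1, l2 = 1.0, 0.1
        n = 20_000
        x = np.where(rng.random(n) < 0.5,
                     rng.exponential(1 / l1, n), rng.exponential(1 / l2, n))
        fit = stats.fit_exponentials(x, "double")
        expected = np.log(l1 / l2) / (l1 - l2)
        assert fit.t_c == pytest.approx(expected, rel=0.15)

    def test_requires_enough_samples(self):
        with pytest.raises(ValueError):
            stats.fit_exponentials(np.ones(10), "single")


class TestSpeedAutocorrelation:
    def _tracks_from_dr(self, dr):
        n = len(dr)
        return [Track("v", 5 / 14, np.zeros(n), dr, np.zeros((n, 2)), np.zeros(n))]

    def test_lag_zero_is_one_and_white_noise_decorrelates(self, rng):
        dr = rng.gamma(4, 0.01, 4000)
        lags, acf, fits = stats.speed_autocorrelation(self._tracks_from_dr(dr), 20)
        assert acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf[1:]) < 0.08)

    def test_ar1_decay_rate(self, rng):
        rho = 0.8
        n = 20_000
        x = np.empty(n)
        x[0] = 0
        eps = rng.normal(0, 1, n)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        dr = x - x.min() + 0.01
        dt = 5 / 14
        lags, acf, fits = stats.speed_autocorrelation(self._tracks_from_dr(dr), 25)
        expected_rate = -np.log(rho) / dt
        assert fits["single"].rates[0] == pytest.approx(expected_rate, rel=0.15)


class TestClassicalPirouettes:
    def test_turns_closer_than_tc_merge_into_one_bout(self):
        dt = 1.0
        ev = stats.TurnEvents(np.array([0, 3]))
        mask = stats.identify_pirouettes_classical(ev, t_c=6.8, dt=dt, n_steps=12)
        assert mask[:4].all() and not mask[4:].any()

    def test_distant_turns_stay_separate_bouts(self):
        ev = stats.TurnEvents(np.array([0, 10]))
        mask = stats.identify_pirouettes_classical(ev, t_c=6.8, dt=1.0, n_steps=12)
        assert mask[0] and mask[10]
        assert not mask[1:10].any()

    def test_no_turns_empty_mask(self):
        mask = stats.identify_pirouettes_classical(
            stats.TurnEvents(np.array([], int)), 6.8, 1.0, 10)
        assert not mask.any()


class TestBearings:
    def _tracks_with_headings(self, headings, state):
        n = len(headings)
        tr = Track("b", 5 / 14, np.zeros(n), np.full(n, 0.01),
                   np.zeros((n, 2)), np.asarray(headings, float))
        return [tr], [np.asarray(state, int)]

    def test_uniform_exit_headings_give_half_aligned(self, rng):
        n = 4000
        headings = rng.uniform(-np.pi, np.pi, n)
        state = np.tile([1, 0], n // 2)  # exit at every odd step
        tracks, states = self._tracks_with_headings(headings, state)
        bs = stats.bearing_at_transitions(tracks, states, LinearEnvironment(),
                                          mode="exit")
        assert bs.aligned_fraction == pytest.approx(0.5, abs=0.03)

    def test_all_upgradient_exits_fully_aligned(self):
        headings = np.zeros(10)  # +x = upgradient
        state = np.array([1, 0] * 5)
        tracks, states = self._tracks_with_headings(headings, state)
        bs = stats.bearing_at_transitions(tracks, states, LinearEnvironment(),
                                          mode="exit")
        assert bs.aligned_fraction == 1.0

    def test_resampled_fractions_are_reproducible(self, rng):
        headings = rng.uniform(-np.pi, np.pi, 400)
        state = np.tile([1, 0], 200)
        tracks, states = self._tracks_with_headings(headings, state)
        a = stats.bearing_at_transitions(tracks, states, LinearEnvironment(),
                                         seed=3)
        b = stats.bearing_at_transitions(tracks, states, LinearEnvironment(),
                                         seed=3)
        assert np.array_equal(a.resampled_fractions, b.resampled_fractions)
        assert len(a.resampled_fractions) == 50

    def test_no_events_raises(self):
        tracks, states = self._tracks_with_headings(np.zeros(5), np.zeros(5))
        with pytest.raises(ValueError):
            stats.bearing_at_transitions(tracks, states, LinearEnvironment())


class TestShuffledControl:
    def test_identical_turn_angles_make_shuffle_a_noop(self):
        d = [0, 90, 0, 0, 90, 0]
        tr = _track_from_dtheta(d)
        ev = [stats.detect_turns(tr)]
        b = stats.shuffled_exit_control([tr], ev, LinearEnvironment(), seed=0)
        grads = LinearEnvironment().gradient(tr.position[ev[0].indices])
        from stapaw.preprocessing import bearing_deg
        orig = bearing_deg(tr.heading[ev[0].indices], grads)
        assert np.allclose(np.sort(b), np.sort(orig), atol=1e-9)

    def test_seeded_shuffle_reproducible(self, small_sim, linear_env):
        ev = [stats.detect_turns(tr) for tr in small_sim.tracks]
        a = stats.shuffled_exit_control(small_sim.tracks, ev, linear_env, seed=5)
        b = stats.shuffled_exit_control(small_sim.tracks, ev, linear_env, seed=5)
        assert np.array_equal(a, b)


class TestChemotaxisIndex:
    def test_all_at_source(self):
        finals = np.zeros((5, 2))
        assert stats.chemotaxis_index(finals, (0, 0), 1.0) == 1.0

    def test_none_within_radius(self):
        finals = np.full((5, 2), 3.0)
        assert stats.chemotaxis_index(finals, (0, 0), 1.0) == 0.0

    def test_uniform_disk_matches_area_ratio(self, rng):
        # uniform in a disk of radius R, target R/2: expect 1/4
        R = 2.0
        r = R * np.sqrt(rng.random(20_000))
        ang = rng.uniform(0, 2 * np.pi, 20_000)
        finals = np.stack([r * np.cos(ang), r * np.sin(ang)], 1)
        ci = stats.chemotaxis_index(finals, (0, 0), R / 2)
        assert ci == pytest.approx(0.25, abs=0.01)


class TestClassicalHeuristicVsLatentState:
    def test_pirouette_bouts_are_enriched_for_the_turn_state(
            self, paperlike_params, linear_env):
        # the threshold-and-merge heuristic should broadly recover the
        # turn-enriched state without access to the latent dynamics
        from stapaw import simulate
        res = simulate.simulate(
            paperlike_params, linear_env,
            simulate.SimConfig(n_tracks=10, n_steps=1500, seed=21))
        inter = mask_tot = t_tot = union = n = 0
        for tr, z in zip(res.tracks, res.z):
            ev = stats.detect_turns(tr)
            mask = stats.identify_pirouettes_classical(ev, 6.8, tr.dt, len(tr))
            t = z == 1
            inter += (mask & t).sum()
            mask_tot += mask.sum()
            t_tot += t.sum()
            union += (mask | t).sum()
            n += len(tr)
        precision = inter / mask_tot
        base_rate = t_tot / n
        assert precision > 1.4 * base_rate
        assert inter / t_tot > 0.5  # bouts recover most turn-state time
        assert inter / union > 0.35
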