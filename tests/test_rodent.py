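"""Rate maps, place-cell selection, candidate events, posterior decoding."""

import numpy as np
import pytest
from scipy.special import logsumexp

from tdlm.core import build_lag_pairs
from tdlm.rodent import (
    EventConfig,
    RateMap,
    RateMapConfig,
    classify_place_cells,
    compute_rate_maps,
    concatenate_events,
    decode_posterior,
    detect_candidate_events,
    radon_score,
    weighted_correlation,
)


def uniform_run(n_cells=3, track=100.0, dt=0.02, speed=10.0, seed=0):
    """Constant-speed sweep across the track, both directions."""
    t = np.arange(0.0, 2 * track / speed, dt)
    half = t.size // 2
    x = np.concatenate([speed * t[:half], track - speed * (t[:half])])[: t.size]
    x = np.clip(x, 0, track)
    sp = np.full(t.size, speed)
    return t, x, sp


class TestRateMaps:
    def test_no_spikes_all_zero(self):
        t, x, sp = uniform_run()
        maps = compute_rate_maps(
            np.empty(0, int), np.empty(0), t, x, sp, 2, 100.0
        )
        for m in maps["outbound"]:
            valid = np.isfinite(m.rates)
            assert np.all(m.rates[valid] == 0)

    def test_smoothing_conserves_spike_mass(self):
        """Uniform dwell, all spikes in one central bin: sum(rate * smoothed
        dwell) returns the spike count because the same kernel hits the
        numerator and denominator."""
        t, x, sp = uniform_run()
        n_spikes = 7
        # spikes at track centre during the outbound half
        spike_t = np.full(n_spikes, t[len(t) // 4])
        maps = compute_rate_maps(
            np.zeros(n_spikes, int), spike_t, t, x, sp, 1, 100.0,
            RateMapConfig(bin_width=2.0, smoothing_sigma=5.0),
        )
        m = maps["outbound"][0]
        # reconstruct smoothed dwell from rate conservation
        from scipy.ndimage import gaussian_filter1d

        dwell = np.histogram(x[: len(x) // 2], bins=m.n_bins, range=(0, 100))[0] * 0.02
        dwell_s = gaussian_filter1d(dwell.astype(float), 5.0, mode="constant")
        total = np.nansum(m.rates * dwell_s)
        assert total == pytest.approx(n_spikes, abs=1e-6)

    def test_slow_samples_contribute_nothing(self):
        t, x, _ = uniform_run()
        slow = np.full(t.size, 1.0)  # below the 3 cm/s filter
        with pytest.raises(ValueError, match="zero dwell"):
            compute_rate_maps(np.zeros(3, int), t[:3], t, x, slow, 1, 100.0)

    def test_spikes_during_slow_running_excluded(self):
        t, x, sp = uniform_run()
        sp[: t.size // 8] = 1.0  # slow at the start of the outbound run
        spike_t = t[: t.size // 8][:5]  # spikes only while slow
        maps = compute_rate_maps(np.zeros(5, int), spike_t, t, x, sp, 1, 100.0)
        m = maps["outbound"][0]
        assert np.nansum(m.rates) == pytest.approx(0.0)

    def test_masked_zone_bins_are_nan(self):
        t, x, sp = uniform_run()
        maps = compute_rate_maps(
            np.empty(0, int), np.empty(0), t, x, sp, 1, 100.0,
            RateMapConfig(masked_zones=[(0.0, 10.0)]),
        )
        m = maps["outbound"][0]
        assert np.all(np.isnan(m.rates[:3]))  # 0-6 cm well inside the mask


class TestPlaceCells:
    def make_map(self, peak, width_cm, bin_width=2.0, n_bins=50):
        rates = np.zeros(n_bins)
        centre = n_bins // 2
        half_bins = int(width_cm / bin_width / 2)
        rates[centre - half_bins : centre + half_bins + 1] = peak
        rates[centre] = peak  # flat-top field of the requested width
        return RateMap(rates=rates, bin_width=bin_width, direction="outbound")

    def test_low_peak_excluded(self):
        m = self.make_map(peak=0.5, width_cm=30)
        assert not classify_place_cells([m])[0]

    def test_narrow_field_excluded(self):
        m = self.make_map(peak=2.0, width_cm=10)
        assert m.field_width < 20
        assert not classify_place_cells([m])[0]

    def test_wide_strong_field_included(self):
        m = self.make_map(peak=2.0, width_cm=30)
        assert m.field_width >= 20
        assert classify_place_cells([m])[0]


class TestCandidateEvents:
    def bg_spikes(self, rng, rate_hz, n_cells, t0, t1):
        n = rng.poisson(rate_hz * (t1 - t0) * n_cells)
        return rng.integers(0, n_cells, n), rng.uniform(t0, t1, n)

    def test_constant_rate_rarely_false_alarms(self):
        """Poisson background with the 3 SD + duration + participation
        filters: under one false event per 10 minutes on average (a chance
        3 SD excursion of the smoothed trace rarely lasts 40 ms)."""
        counts = []
        for seed in range(4):
            rng = np.random.default_rng(seed)
            cells, times = self.bg_spikes(rng, 2.0, 30, 0.0, 600.0)
            events = detect_candidate_events(cells, np.sort(times), 30, 0.0, 600.0)
            counts.append(len(events))
        assert np.mean(counts) <= 1.0

    def test_short_burst_rejected_by_duration_rule(self):
        rng = np.random.default_rng(6)
        cells, times = self.bg_spikes(rng, 1.0, 20, 0.0, 60.0)
        # strong 30 ms burst with every cell active
        bc = np.repeat(np.arange(20), 8)
        bt = np.sort(rng.uniform(30.0, 30.030, bc.size))
        allc = np.concatenate([cells, bc])
        allt = np.concatenate([times, bt])
        order = np.argsort(allt)
        cfg = EventConfig(mua_sigma=0.002)  # tight smoothing keeps the span short
        events = detect_candidate_events(allc[order], allt[order], 20, 0.0, 60.0, cfg)
        assert all(not (29.9 < e.start < 30.2) for e in events)

    def test_low_participation_burst_rejected(self):
        rng = np.random.default_rng(7)
        cells, times = self.bg_spikes(rng, 0.5, 40, 0.0, 60.0)
        # 60 ms burst from only 4 of 40 cells (10% < 15%)
        bc = np.repeat(np.arange(4), 40)
        bt = np.sort(rng.uniform(30.0, 30.060, bc.size))
        allc = np.concatenate([cells, bc])
        allt = np.concatenate([times, bt])
        order = np.argsort(allt)
        events = detect_candidate_events(allc[order], allt[order], 40, 0.0, 60.0)
        assert all(e.participation >= 0.15 for e in events)
        assert all(not (29.9 < e.start < 30.2) for e in events)

    def test_good_burst_detected(self):
        rng = np.random.default_rng(8)
        cells, times = self.bg_spikes(rng, 0.5, 20, 0.0, 60.0)
        bc = np.tile(np.arange(20), 10)
        bt = np.sort(rng.uniform(30.0, 30.080, bc.size))
        allt = np.concatenate([times, bt])
        order = np.argsort(allt)
        events = detect_candidate_events(
            np.concatenate([cells, bc])[order], allt[order], 20, 0.0, 60.0
        )
        assert any(29.8 < e.start < 30.1 for e in events)

    def test_empty_input_empty_list(self):
        assert detect_candidate_events(np.empty(0, int), np.empty(0), 10, 0, 10) == []


def flat_maps(n_cells, n_bins, rate=5.0):
    return [
        RateMap(rates=np.full(n_bins, rate), bin_width=2.0, direction="outbound", cell=c)
        for c in range(n_cells)
    ]


class TestDecodePosterior:
    def test_flat_map_gives_uniform_posterior(self):
        maps = flat_maps(1, 8)
        post = decode_posterior(
            np.zeros(3, int), np.array([0.001, 0.005, 0.009]), maps, 0.0, 0.02
        )
        np.testing.assert_allclose(post.values, 1.0 / 8, atol=1e-12)

    def test_selective_cell_pins_the_argmax(self):
        maps = flat_maps(3, 10, rate=1.0)
        rates = np.full(10, 0.01)
        rates[6] = 30.0
        maps[0] = RateMap(rates=rates, bin_width=2.0, direction="outbound", cell=0)
        post = decode_posterior(
            np.array([0]), np.array([0.005]), maps, 0.0, 0.01
        )
        assert post.values[0].argmax() == 6

    def test_matches_log_likelihood_enumeration(self, rng):
        """3 cells, 5 bins, a few spikes: hand-coded Poisson posterior."""
        rates = rng.uniform(0.5, 20.0, size=(3, 5))
        maps = [
            RateMap(rates=rates[c], bin_width=2.0, direction="outbound", cell=c)
            for c in range(3)
        ]
        cells = np.array([0, 2])
        times = np.array([0.002, 0.007])
        tau = 0.01
        post = decode_posterior(cells, times, maps, 0.0, tau, decode_bin=tau)
        counts = np.array([1.0, 0.0, 1.0])
        ll = np.zeros(5)
        for k in range(5):
            ll[k] = np.sum(counts * np.log(rates[:, k])) - tau * rates[:, k].sum()
        expect = np.exp(ll - logsumexp(ll))
        np.testing.assert_allclose(post.values[0], expect, atol=1e-10)

    def test_scale_invariance_of_decoding_shape(self, rng):
        """Multiplying all maps by a constant changes the exposure term but
        not which bin wins for a matched spike pattern."""
        rates = rng.uniform(1.0, 10.0, size=(4, 6))
        mk = lambda R: [
            RateMap(rates=R[c], bin_width=2.0, direction="outbound", cell=c)
            for c in range(4)
        ]
        cells = np.array([1, 1, 3])
        times = np.array([0.001, 0.004, 0.008])
        p1 = decode_posterior(cells, times, mk(rates), 0.0, 0.01)
        p2 = decode_posterior(cells, times, mk(rates * 3.0), 0.0, 0.01)
        assert p1.values[0].argmax() == p2.values[0].argmax()

    def test_rows_sum_to_one(self, rng):
        maps = flat_maps(5, 12, rate=rng.uniform(1, 5))
        post = decode_posterior(
            rng.integers(0, 5, 20), np.sort(rng.uniform(0, 0.1, 20)), maps, 0.0, 0.1
        )
        np.testing.assert_allclose(post.values.sum(axis=1), 1.0, atol=1e-9)

    def test_all_masked_maps_rejected(self):
        maps = [RateMap(rates=np.full(5, np.nan), bin_width=2.0, direction="outbound")]
        with pytest.raises(ValueError, match="missing|valid"):
            decode_posterior(np.zeros(1, int), np.zeros(1), maps, 0.0, 0.01)


class TestConcatenation:
    def test_lagged_pairs_respect_event_boundaries(self, rng):
        maps = flat_maps(2, 4)
        posts = [
            decode_posterior(
                np.zeros(2, int), np.array([0.01, 0.03]), maps, 0.0, 0.05
            )
            for _ in range(2)
        ]
        cat = concatenate_events(posts)
        assert cat.n_samples == 10
        pairs = build_lag_pairs(cat, 2)
        assert len(pairs) == 6  # 2 events x (5 - 2)

    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            concatenate_events([])


class TestLineSearchBaselines:
    def test_radon_finds_perfect_diagonal(self):
        n = 8
        P = np.full((n, n), 0.01)
        P[np.arange(n), np.arange(n)] = 1.0
        P /= P.sum(axis=1, keepdims=True)
        (slope, icpt), score, p = radon_score(P, n_perm=50, seed=0)
        assert slope == pytest.approx(1.0, abs=0.2)
        assert icpt == pytest.approx(0.0, abs=1.0)
        assert score == pytest.approx(P[0, 0], rel=0.05)
        assert p < 0.05

    def test_uniform_posterior_flat_scores(self):
        P = np.full((6, 10), 0.1)
        _, score, _ = radon_score(P, n_perm=10, seed=0)
        assert score == pytest.approx(0.1, abs=1e-9)

    def test_weighted_correlation_limits(self):
        n = 10
        P = np.zeros((n, n))
        P[np.arange(n), np.arange(n)] = 1.0
        assert weighted_correlation(P) == pytest.approx(1.0)
        assert weighted_correlation(P[::-1]) == pytest.approx(-1.0)
        assert weighted_correlation(np.full((5, 7), 1.0)) == pytest.approx(0.0)

    def test_method_concordance_across_noise_levels(self, rng):
        """Radon score, |weighted correlation| and per-event forward
        sequenceness rank noise levels identically."""
        from tdlm.core import StateSpace
        from tdlm.glm import FirstLevelDesign, empirical_transitions, sequenceness
        from tdlm.simulate import line_transition_matrix

        def noisy_ramp(noise):
            # position advances one bin every 3 decode bins (30 x 10):
            # enough rows for the GLM, still a clean single-event line
            n, hold = 10, 3
            P = np.full((hold * n, n), noise)
            P[np.arange(hold * n), np.arange(hold * n) // hold] += 1.0
            P += rng.uniform(0, noise, P.shape)
            P /= P.sum(axis=1, keepdims=True)
            return P

        noises = [0.02, 0.3, 2.0]
        radon, wcorr, tdlm_z = [], [], []
        for nz in noises:
            P = noisy_ramp(nz)
            radon.append(radon_score(P, n_perm=10, seed=1)[1])
            wcorr.append(abs(weighted_correlation(P)))
            sp = StateSpace(P, 0.01, mode="posterior")
            emp = empirical_transitions(sp, 3, FirstLevelDesign(intercept=False))
            tdlm_z.append(
                sequenceness(emp, line_transition_matrix(10)).z_forward[0]
            )
        assert radon == sorted(radon, reverse=True)
        assert wcorr == sorted(wcorr, reverse=True)
        assert tdlm_z == sorted(tdlm_z, reverse=True)
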