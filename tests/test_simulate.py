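"""Simulator correctness: Gillespie paths, bleach times, trace rendering."""

import numpy as np
import pytest
from scipy import stats

from fretbind.scheme import KineticScheme, Photophysics, SimConfig
from fretbind.simulate import (
    gillespie_path,
    render_trace,
    sample_bleach_times,
    simulate_dataset,
)
from fretbind.scenarios import load_scenario


def scheme_from_rates(names, fret, rates):
    return KineticScheme(tuple(names), np.asarray(fret, float),
                         np.asarray(rates, float))


class TestGillespiePath:
    def test_absorbing_bound_state(self, rng):
        """With no exit from B the path is U then B, spanning the trace."""
        s = scheme_from_rates(["U", "B"], [0, 0.7], [[0, 1.0], [0, 0]])
        path = gillespie_path(s, 1000.0, rng)
        assert [name for name, _ in path] == ["U", "B"]
        assert path[0] == ("U", 0.0)

    def test_all_zero_exit_is_single_epoch(self, rng):
        s = scheme_from_rates(["U", "B"], [0, 0.7], [[0, 0], [0, 0]])
        path = gillespie_path(s, 10.0, rng)
        assert path == [("U", 0.0)]

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="rates"):
            scheme_from_rates(["U", "B"], [0, 0.7], [[0, -1.0], [0.5, 0]])

    def test_mean_bound_dwell(self, two_state_scheme):
        """k_on = k_off = 0.5 /s: B dwells average 2 s (3 SE).

        Dwells cut by the end of the window are kept with censored
        accounting (total time / completed count); discarding them would
        length-bias the mean low by ~ mean^2 / window.
        """
        rng = np.random.default_rng(7)
        total_time = 0.0
        n_completed = 0
        n_dwells = 0
        for _ in range(2000):
            path = gillespie_path(two_state_scheme, 50.0, rng)
            times = [t for _, t in path] + [50.0]
            for (name, t0), t1 in zip(path, times[1:]):
                if name == "B":
                    total_time += t1 - t0
                    n_dwells += 1
                    n_completed += t1 < 50.0
        assert n_dwells > 10000
        mean = total_time / n_completed
        se = mean / np.sqrt(n_completed)  # exponential: sd == mean
        assert abs(mean - 2.0) < 3 * se

    @pytest.mark.parametrize("state", ["U", "B_low", "B_high"])
    def test_holding_times_exponential(self, state):
        """Holding times in each state of a 3-state cycle are exponential
        with the state's total exit rate (KS test at alpha = 0.01)."""
        s = scheme_from_rates(
            ["U", "B_low", "B_high"], [0, 0.5, 0.8],
            [[0, 0.6, 0.0], [0.4, 0, 0.9], [0.4, 0.7, 0]],
        )
        rng = np.random.default_rng(11)
        holds = []
        while len(holds) < 10000:
            path = gillespie_path(s, 200.0, rng)
            times = [t for _, t in path] + [200.0]
            for (name, t0), t1 in zip(path, times[1:]):
                if name == state and t1 < 200.0:
                    holds.append(t1 - t0)
        total_exit = s.exit_rate(s.index(state))
        p = stats.kstest(holds, stats.expon(scale=1.0 / total_exit).cdf).pvalue
        assert p > 0.01

    def test_equilibrium_bound_fraction(self, two_state_scheme):
        """Long-run fraction bound approaches k_on/(k_on+k_off) = 0.5."""
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(200):
            path = gillespie_path(two_state_scheme, 500.0, rng)
            times = [t for _, t in path] + [500.0]
            bound = sum(t1 - t0 for (name, t0), t1 in zip(path, times[1:])
                        if name == "B")
            fracs.append(bound / 500.0)
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.5) < 3 * se


class TestBleachTimes:
    def test_zero_rates_never_bleach(self, rng):
        ph = Photophysics(donor_bleach_rate=0.0, acceptor_bleach_rate=0.0)
        assert sample_bleach_times(ph, rng) == (np.inf, np.inf)

    def test_mean_bleach_time(self):
        ph = Photophysics(donor_bleach_rate=0.01, acceptor_bleach_rate=0.0)
        rng = np.random.default_rng(5)
        draws = np.array([sample_bleach_times(ph, rng)[0] for _ in range(10000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - 100.0) < 3 * se

    def test_faster_dye_bleaches_first_usually(self):
        ph = Photophysics(donor_bleach_rate=0.01, acceptor_bleach_rate=1.0)
        rng = np.random.default_rng(6)
        first = sum(a < d for d, a in
                    (sample_bleach_times(ph, rng) for _ in range(500)))
        assert first > 400


class TestRenderTrace:
    def make(self, path, scheme, ph, max_duration, bleach=(np.inf, np.inf)):
        rng = np.random.default_rng(0)
        return render_trace(path, bleach, ph, 0.08, rng, scheme, max_duration)

    def test_single_state_frame_inverts_fret(self, noiseless_photophysics):
        s = scheme_from_rates(["U", "B"], [0, 0.8], [[0, 0], [0, 0]])
        tr = self.make([("B", 0.0)], s, noiseless_photophysics, 0.08)
        assert tr.donor[0] == pytest.approx(200.0)
        assert tr.acceptor[0] == pytest.approx(800.0)

    def test_frame_split_between_states_time_weighted(self, noiseless_photophysics):
        s = scheme_from_rates(["U", "B"], [0, 0.8], [[0, 0], [0, 0]])
        tr = self.make([("U", 0.0), ("B", 0.04)], s, noiseless_photophysics, 0.08)
        assert tr.donor[0] == pytest.approx(600.0)
        assert tr.acceptor[0] == pytest.approx(400.0)

    def test_after_donor_bleach_both_channels_background(self):
        ph = Photophysics(total_intensity=1000, background=50,
                          read_noise_sd=0.0, shot_noise_scale=0.0)
        s = scheme_from_rates(["U", "B"], [0, 0.8], [[0, 0], [0, 0]])
        tr = self.make([("B", 0.0)], s, ph, 0.8, bleach=(0.4, np.inf))
        np.testing.assert_allclose(tr.donor[5:], 50.0)
        np.testing.assert_allclose(tr.acceptor[5:], 50.0)

    def test_after_acceptor_bleach_donor_only(self):
        ph = Photophysics(total_intensity=1000, background=50,
                          read_noise_sd=0.0, shot_noise_scale=0.0)
        s = scheme_from_rates(["U", "B"], [0, 0.8], [[0, 0], [0, 0]])
        tr = self.make([("B", 0.0)], s, ph, 0.8, bleach=(np.inf, 0.4))
        np.testing.assert_allclose(tr.acceptor[5:], 50.0)
        np.testing.assert_allclose(tr.donor[5:], 1050.0)

    def test_bad_frame_interval_rejected(self, two_state_scheme,
                                         noiseless_photophysics):
        with pytest.raises(ValueError):
            render_trace([("U", 0.0)], (np.inf, np.inf), noiseless_photophysics,
                         0.0, np.random.default_rng(0), two_state_scheme, 1.0)


class TestSimulateDataset:
    def test_bit_identical_reruns(self, two_state_scheme):
        cfg = SimConfig(scheme=two_state_scheme, n_molecules=5,
                        max_duration=10.0, rng_seed=42)
        t1, g1 = simulate_dataset(cfg)
        t2, g2 = simulate_dataset(cfg)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.donor, b.donor)
            np.testing.assert_array_equal(a.acceptor, b.acceptor)
        assert [g.path for g in g1] == [g.path for g in g2]

    def test_per_molecule_substreams_stable_under_n(self, two_state_scheme):
        """Growing the ensemble never reshuffles earlier molecules."""
        small = SimConfig(scheme=two_state_scheme, n_molecules=3,
                          max_duration=10.0, rng_seed=9)
        large = SimConfig(scheme=two_state_scheme, n_molecules=6,
                          max_duration=10.0, rng_seed=9)
        ts, _ = simulate_dataset(small)
        tl, _ = simulate_dataset(large)
        for a, b in zip(ts, tl):
            np.testing.assert_array_equal(a.donor, b.donor)

    def test_zero_molecules_rejected(self, two_state_scheme):
        with pytest.raises(ValueError):
            SimConfig(scheme=two_state_scheme, n_molecules=0)

    def test_traces_end_at_bleach_or_max_duration(self):
        cfg = load_scenario("unmodified_binary", n_molecules=20, rng_seed=2)
        traces, truths = simulate_dataset(cfg)
        n_frames = int(cfg.max_duration / cfg.frame_interval)
        for tr, gt in zip(traces, truths):
            assert len(tr) == n_frames
            bleach_f = int(min(gt.donor_bleach, cfg.max_duration)
                           / cfg.frame_interval)
            post = tr.donor[min(bleach_f + 1, n_frames):]
            if post.size:  # both channels at background after donor bleach
                assert np.all(np.abs(post - cfg.photophysics.background) < 200)


class TestSchemeValidation:
    def test_exactly_one_unbound_state(self):
        with pytest.raises(ValueError, match="unbound"):
            scheme_from_rates(["U", "U"], [0, 0], [[0, 1], [1, 0]])

    def test_unbound_fret_must_be_zero(self):
        with pytest.raises(ValueError):
            scheme_from_rates(["U", "B"], [0.3, 0.7], [[0, 1], [1, 0]])

    def test_fret_bounds(self):
        with pytest.raises(ValueError):
            scheme_from_rates(["U", "B"], [0, 1.4], [[0, 1], [1, 0]])
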