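"""Stochastic-mechanism simulator: dwell laws, determinism, rendering,
gating-series construction."""

import numpy as np
import pytest
from scipy import stats

import ionflux as fx
from ionflux.errors import ConfigError


def two_state(k12=1.0, k21=1.0):
    return fx.MechanismConfig(
        species=("Na_a",),
        states={
            "u": fx.LigationState.from_dict({"Na_a": "vestibule"}),
            "b": fx.LigationState.from_dict({"Na_a": "Na1pp"}),
        },
        rates={("u", "b"): k12, ("b", "u"): k21},
        initial="u",
    )


class TestSimulate:
    def test_no_transitions_truncates_with_warning(self):
        cfg = fx.MechanismConfig(
            species=("Na_a",),
            states={"u": fx.LigationState.from_dict({"Na_a": "vestibule"})},
            rates={},
            initial="u",
        )
        with pytest.warns(UserWarning, match="absorbing"):
            tl = fx.simulate_mechanism(cfg, 100.0, seed=0)
        assert tl.events == [(0.0, "u")]
        assert tl.total_duration == 100.0

    def test_exponential_mean_dwell(self):
        # symmetric 1 μs⁻¹ chain over 10^4 μs: mean dwell 1.0 μs within 3 SE
        tl = fx.simulate_mechanism(two_state(1.0, 1.0), 1.0e7, seed=2)
        dwells = np.array([d for _, d, done in tl.dwells() if done]) / 1e3
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert dwells.size > 5000
        assert abs(dwells.mean() - 1.0) <= 3 * se

    def test_bound_dwell_matches_reciprocal_unbinding_rate(self):
        # default-rate cycle: mean Na1''-bound dwell = 1/k_u = 1/2.3 μs
        tl = fx.simulate_mechanism(fx.binding_cycle_config(), 5.0e6, seed=3)
        bound = np.array([d for s, d, done in tl.dwells()
                          if done and s == "bound"]) / 1e3
        se = bound.std(ddof=1) / np.sqrt(bound.size)
        assert abs(bound.mean() - 1 / 2.3) <= 3 * se

    def test_determinism(self):
        a = fx.simulate_mechanism(two_state(), 1e5, seed=9)
        b = fx.simulate_mechanism(two_state(), 1e5, seed=9)
        assert a.events == b.events

    def test_dwell_law_kolmogorov_smirnov(self):
        # dwells in each state are exponential with that state's exit rate
        tl = fx.simulate_mechanism(two_state(2.0, 5.0), 6.0e6, seed=4)
        for state, rate in [("u", 2.0), ("b", 5.0)]:
            d = np.array([dur for s, dur, done in tl.dwells()
                          if done and s == state]) / 1e3
            assert d.size >= 5000
            p = stats.kstest(d, "expon", args=(0, 1 / rate)).pvalue
            assert p > 0.01

    def test_stationary_occupancy(self):
        kb, ku = 55.0, 2.3
        tl = fx.simulate_mechanism(two_state(kb, ku), 3.0e6, seed=5)
        t_in_b = sum(d for s, d, _ in tl.dwells() if s == "b")
        frac = t_in_b / tl.total_duration
        n_cycles = tl.n_transitions / 2
        p = kb / (kb + ku)
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n_cycles)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            two_state(-1.0, 1.0)


class TestEmbed:
    def test_site_jitter_bound(self, geometry):
        cfg = two_state(0.0, 0.0)
        cfg = fx.MechanismConfig(species=cfg.species, states=cfg.states,
                                 rates={}, initial="b")
        with pytest.warns(UserWarning, match="absorbing"):
            tl = fx.simulate_mechanism(cfg, 1000.0, seed=1)
        traj = fx.embed_timeline(tl, geometry, seed=1)
        d = np.linalg.norm(traj.frames[:, 0, :] - geometry.centers["Na1pp"], axis=1)
        assert d.max() <= 1.5  # 5 sigma of 0.3 Å jitter

    def test_hop_switches_nearest_center_within_one_frame(self, geometry):
        states = {
            "pp": fx.LigationState.from_dict({"Na_a": "Na1pp"}),
            "one": fx.LigationState.from_dict({"Na_a": "Na1"}),
        }
        tl = fx.StateTimeline(events=[(0.0, "pp"), (100.0, "one")], states=states,
                              total_duration=250.0)
        traj = fx.embed_timeline(tl, geometry, frame_interval=1.25, seed=2)
        centers = np.stack([geometry.centers["Na1pp"], geometry.centers["Na1"]])
        nearest = np.linalg.norm(
            traj.frames[:, 0, None, :] - centers[None], axis=2).argmin(axis=1)
        switch = np.flatnonzero(np.diff(nearest))[0] + 1
        assert abs(switch * 1.25 - 100.0) <= 1.25

    def test_undersampling_warning(self, geometry):
        states = {
            "u": fx.LigationState.from_dict({"Na_a": "vestibule"}),
            "b": fx.LigationState.from_dict({"Na_a": "Na1pp"}),
        }
        tl = fx.StateTimeline(events=[(0.0, "u"), (10.0, "b"), (10.5, "u")],
                              states=states, total_duration=50.0)
        with pytest.warns(UserWarning, match="invisible"):
            fx.embed_timeline(tl, geometry, frame_interval=1.25, seed=0)

    def test_determinism(self, geometry):
        tl = fx.simulate_mechanism(two_state(5.0, 5.0), 5e4, seed=3)
        a = fx.embed_timeline(tl, geometry, seed=7)
        b = fx.embed_timeline(tl, geometry, seed=7)
        assert np.array_equal(a.frames, b.frames)

    def test_vestibule_walk_stays_in_axis(self, geometry):
        cfg = fx.MechanismConfig(
            species=("Na_a",),
            states={"u": fx.LigationState.from_dict({"Na_a": "vestibule"})},
            rates={}, initial="u")
        with pytest.warns(UserWarning, match="absorbing"):
            tl = fx.simulate_mechanism(cfg, 5e3, seed=4)
        traj = fx.embed_timeline(tl, geometry, seed=4)
        z = traj.frames[:, 0, 2]
        lo, hi = geometry.vestibule_axis
        assert z.min() >= lo and z.max() <= hi


def _manual_release_timeline():
    """One full loading + release pass with hand-placed event times."""
    cfg = fx.full_mechanism_config()
    events = [
        (0.0, "apo"), (50.0, "a_na1pp"), (100.0, "a_na1"), (150.0, "b_vest"),
        (200.0, "b_na1pp"), (250.0, "b_na2"), (300.0, "s_vest"),
        (350.0, "loaded"), (700.0, "s_released"), (750.0, "s_gone"),
    ]
    return fx.StateTimeline(events=events, states=dict(cfg.states),
                            total_duration=900.0)


class TestGatingSeries:
    def test_flat_baselines_without_events(self):
        cfg = fx.full_mechanism_config()
        tl = fx.StateTimeline(events=[(0.0, "loaded")], states=dict(cfg.states),
                              total_duration=500.0)
        g = fx.generate_gating_series(tl, seed=0)
        assert (g.opening_tm1b < 50).all() and (g.opening_tm6a < 50).all()
        assert np.abs(g.saltbridge - 4.2).max() < 1.0
        assert all(fx.chi1_class(a) == "occluded" for a in g.chi1)
        assert 15 <= np.median(g.water) <= 20

    def test_water_rises_before_opening(self):
        tl = _manual_release_timeline()
        g = fx.generate_gating_series(tl, seed=1)
        _, lags = fx.hydration_opening_curve(
            g.water, g.opening_tm1b, g.opening_tm6a, g.frame_interval)
        assert len(lags) >= 1
        assert (lags > 0).all()
        # water moves from the 15-20 band into the 30-35 band
        assert np.median(g.water[:20]) <= 20
        assert np.median(g.water[np.flatnonzero(g.opening_tm1b > 60)]) >= 30

    def test_release_cascade_ordering(self):
        tl = _manual_release_timeline()
        g = fx.generate_gating_series(tl, seed=2)
        t = g.times
        release = 700.0
        window = (t > 500) & (t <= release)
        joint = np.minimum(g.opening_tm1b, g.opening_tm6a)
        t_open = t[window][np.argmax(joint[window] >= 60)]
        t_sb = t[window][np.argmax(g.saltbridge[window] >= 7.65)]
        chi_open = np.array([fx.chi1_class(a) == "open" for a in g.chi1[window]])
        t_chi = t[window][np.argmax(chi_open)]
        assert t_open < t_sb < t_chi < release

    def test_negative_lag_rejected(self):
        with pytest.raises(ConfigError):
            fx.GatingCoupling(water_lead=-1.0)
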