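"""First-passage times, reciprocal-MFPT rates, ligation bookkeeping, CTMC
estimation, z-traces and event ordering."""

import numpy as np
import pytest

import ionflux as fx
from ionflux.errors import ConfigError, EmptyInputError, InconsistencyError
from conftest import label_series


class TestFirstPassage:
    def test_single_passage_arithmetic(self):
        s = label_series(["vestibule"] * 10 + ["Na1pp"] * 5)
        times, censored = fx.first_passage_times(s, "vestibule", "Na1pp")
        assert censored == 0
        assert times.tolist() == [pytest.approx(0.0125)]

    def test_censored_passage_counted_not_averaged(self):
        s = label_series(["vestibule"] * 10 + ["Na1pp"] * 10 + ["vestibule"] * 10)
        times, censored = fx.first_passage_times(s, "vestibule", "Na1pp")
        assert len(times) == 1
        assert censored == 1

    def test_no_completed_passages_is_not_an_error(self):
        s = label_series(["vestibule"] * 20)
        times, censored = fx.first_passage_times(s, "vestibule", "Na1pp")
        assert len(times) == 0 and censored == 1

    def test_timeline_route_uses_exact_event_times(self):
        cfg = fx.binding_cycle_config()
        tl = fx.simulate_mechanism(cfg, 1e5, seed=2)
        times, _ = fx.first_passage_times(tl, "vestibule", "Na1pp")
        dwells = np.array([d for s, d, done in tl.dwells()
                           if done and s == "unbound"]) / 1e3
        assert times == pytest.approx(dwells)

    def test_set_valued_target(self):
        s = label_series(["Na1pp"] * 100 + ["bulk"] * 5)
        times, _ = fx.first_passage_times(s, "Na1pp", {"vestibule", "bulk"})
        assert times.tolist() == [pytest.approx(0.125)]


class TestRateFromMfpt:
    def test_reciprocal_of_measured_binding_mfpt(self):
        est = fx.rate_from_mfpt(np.full(100, 0.018))
        assert est.rate == pytest.approx(1 / 0.018)
        assert est.rate * est.mfpt_mean == pytest.approx(1.0, abs=1e-12)

    def test_unbinding_scale_display(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(0.43, size=20000)
        est = fx.rate_from_mfpt(t)
        assert est.rate == pytest.approx(2.3, rel=0.05)
        assert est.display() == "2.3"

    def test_single_time(self):
        est = fx.rate_from_mfpt([2.0])
        assert est.rate == 0.5
        assert est.mfpt_sd == 0.0
        assert est.n == 1

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            fx.rate_from_mfpt([])


class TestEpisodeDwells:
    def test_successor_filter(self):
        eps = [
            fx.Episode("a", "Na1", 0.0, 100.0),
            fx.Episode("a", "Na1p", 100.0, 150.0),
            fx.Episode("a", "Na1", 150.0, 400.0),
            fx.Episode("a", "Na2", 400.0, 500.0),
        ]
        d = fx.episode_dwells(eps, "Na1", next_site="Na1p")
        assert d.tolist() == [pytest.approx(0.1)]

    def test_particles_chained_independently(self):
        eps = [
            fx.Episode("a", "Na1", 0.0, 100.0),
            fx.Episode("b", "Na2", 50.0, 90.0),  # interleaved other particle
            fx.Episode("a", "Na1p", 100.0, 150.0),
        ]
        d = fx.episode_dwells(eps, "Na1", next_site="Na1p")
        assert d.tolist() == [pytest.approx(0.1)]


class TestLigationTransitions:
    def test_hop_chain_counts(self):
        s = label_series(["Na1pp"] * 80 + ["Na1"] * 80 + ["Na1p"] * 80)
        records = fx.ligation_transitions([s], min_dwell=50.0)
        assert len(records) == 2
        assert records[0].from_state == frozenset({("Na1pp", "Na_x")})
        assert records[0].to_state == frozenset({("Na1", "Na_x")})

    def test_stationary_particle_contributes_nothing(self):
        mobile = label_series(["Na1pp"] * 100 + ["Na1"] * 100, particle="m")
        still = label_series(["Na2"] * 200, particle="s")
        records = fx.ligation_transitions([mobile, still], min_dwell=50.0)
        assert len(records) == 1
        assert all(("Na2", "s") in r.from_state and ("Na2", "s") in r.to_state
                   for r in records)

    def test_subthreshold_blip_never_enters_the_record(self):
        # a 12.5-ns Na1'' blip is dropped, not bridged: the filtered state
        # passes through unbound, and Na1'' itself appears in no record
        s = label_series(["Na1"] * 100 + ["Na1pp"] * 10 + ["Na1"] * 100)
        records = fx.ligation_transitions([s], min_dwell=50.0)
        assert len(records) == 2
        touched = {site for r in records for site, _ in (r.from_state | r.to_state)}
        assert "Na1pp" not in touched

    def test_site_conflict_detected(self):
        a = label_series(["Na1"] * 100, particle="a")
        b = label_series(["Na1"] * 100, particle="b")
        with pytest.raises(InconsistencyError, match="Na1"):
            fx.ligation_transitions([a, b], min_dwell=50.0)

    def test_ground_truth_count_recovered(self, binding_run):
        chain, geometry = binding_run
        analysis = fx.analyze_chain(chain.trajectory, geometry, min_dwell=50.0)
        truth = fx.LabelSeries(
            particle="Na_a",
            labels=chain.timeline.particle_locations("Na_a", 1.25),
            frame_interval=1.25)
        measured = fx.ligation_transitions(analysis.series, min_dwell=50.0)
        expected = fx.ligation_transitions([truth], min_dwell=50.0)
        assert len(measured) == len(expected)


class TestCtmcRates:
    def test_single_jump_definition(self):
        s = label_series(["i"] * 1600 + ["j"] * 400)
        k = fx.estimate_ctmc_rates(s)
        assert k.loc["i", "j"] == pytest.approx(0.5)  # one jump / 2 μs
        assert k.loc["j", "i"] == 0.0

    def test_unvisited_state_flagged_undefined(self):
        s = label_series(["i"] * 100 + ["j"] * 100)
        k = fx.estimate_ctmc_rates(s, states=["i", "j", "ghost"])
        assert np.isnan(k.loc["ghost"]).all()
        assert not np.isnan(k.loc["i", "j"])

    def test_consistency_error_shrinks_with_run_length(self):
        cfg = fx.binding_cycle_config()
        errs = []
        for dur in (5e3, 5e4, 5e5):
            tl = fx.simulate_mechanism(cfg, dur, seed=30)
            k = fx.estimate_ctmc_rates(tl, particle="Na_a")
            errs.append(abs(k.loc["vestibule", "Na1pp"] - 55.0) / 55.0)
        assert errs[-1] < 0.10
        assert errs[-1] < errs[0]


class TestZTrace:
    def test_fixed_at_origin_is_s1(self):
        trace = fx.substrate_z_trace(np.zeros(50), 1.25)
        assert (trace.regions == "S1").all()

    def test_release_path_hits_regions_in_order(self):
        z = np.concatenate([np.zeros(20), np.full(20, 5.0), np.full(20, 20.0)])
        trace = fx.substrate_z_trace(z, 1.25)
        seq = [trace.regions[0], trace.regions[20], trace.regions[40]]
        assert seq == ["S1", "vestibule", "EC"]

    def test_boundaries_half_open(self):
        bands = fx.ZBands(s1_halfwidth=2.0, s2_lo=8.0, s2_hi=12.0)
        trace = fx.substrate_z_trace(np.array([2.0, 8.0, 12.0]), 1.25, bands=bands)
        assert list(trace.regions) == ["vestibule", "S2_band", "EC"]

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ConfigError):
            fx.ZBands(s1_halfwidth=9.0, s2_lo=8.0, s2_hi=12.0)


class TestEventOrder:
    def test_release_ordering_verdict(self):
        leu = [fx.Episode("sub", "S1", 0.0, 800.0)]
        na2 = [fx.Episode("Na_b", "Na2", 0.0, 900.0)]
        verdicts, aggregate, unpaired = fx.event_order_test(
            leu, na2, "a_release_before_b_release")
        assert verdicts == [(pytest.approx(0.1), True)]
        assert aggregate == 1.0 and unpaired == 0

    def test_reversed_order_fails(self):
        leu = [fx.Episode("sub", "S1", 0.0, 900.0)]
        na2 = [fx.Episode("Na_b", "Na2", 0.0, 800.0)]
        _, aggregate, _ = fx.event_order_test(leu, na2,
                                              "a_release_before_b_release")
        assert aggregate == 0.0

    def test_bind_relation_uses_start_times(self):
        a = [fx.Episode("a", "Na1", 100.0, 500.0)]
        b = [fx.Episode("b", "Na1p", 200.0, 400.0)]
        verdicts, aggregate, _ = fx.event_order_test(a, b, "a_bind_before_b_bind")
        assert aggregate == 1.0
        assert verdicts[0][0] == pytest.approx(0.1)

    def test_no_matchable_events(self):
        _, aggregate, unpaired = fx.event_order_test([], [], "a_release_before_b_release")
        assert np.isnan(aggregate) and unpaired == 0
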