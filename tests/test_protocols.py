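"""Spike detection, conduction velocity, reliability and sweeps."""
import numpy as np
import pytest

from tjunction import protocols as proto
from tjunction.fixtures import make_preset, list_presets, make_synthetic_trace


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        tr = make_synthetic_trace([])
        st = proto.detect_spikes(tr.t_ms, tr.v_mV[:, 0])
        assert len(st) == 0

    def test_counts_and_times(self):
        tr = make_synthetic_trace([10.0, 20.0, 35.0])
        st = proto.detect_spikes(tr.t_ms, tr.v_mV[:, 0])
        assert len(st) == 3
        assert np.abs(st.times_ms - [10.0, 20.0, 35.0]).max() < 0.5
        assert st.amplitudes_mV == pytest.approx([75.0] * 3, abs=0.5)

    def test_double_peak_separation(self):
        tr = make_synthetic_trace([30.0, 33.0], width_ms=1.0)
        st = proto.detect_spikes(tr.t_ms, tr.v_mV[:, 0], refractory_ms=2.0)
        assert len(st) == 2

    def test_refractory_merges_close_peaks(self):
        tr = make_synthetic_trace([30.0, 31.0], width_ms=0.6)
        st = proto.detect_spikes(tr.t_ms, tr.v_mV[:, 0], refractory_ms=2.0)
        assert len(st) == 1


class TestConductionVelocity:
    def test_peripheral_cv(self, orthodromic_trace, active_model):
        cv = proto.conduction_velocity(
            orthodromic_trace, ("peripheral", 3500.0), ("peripheral", 1500.0),
            active_model.graph,
        )
        assert 0.4 < cv < 0.65

    def test_central_cv_sqrt_diameter_scaling(self, orthodromic_trace, active_model):
        cv_p = proto.conduction_velocity(
            orthodromic_trace, ("peripheral", 3500.0), ("peripheral", 1500.0),
            active_model.graph,
        )
        cv_c = proto.conduction_velocity(
            orthodromic_trace, ("central", 1500.0), ("central", 3500.0),
            active_model.graph,
        )
        assert cv_p / cv_c == pytest.approx(np.sqrt(2.0), rel=0.15)

    def test_missing_spike_raises(self, active_model):
        from tjunction.solver import SimulationConfig, run_simulation

        cfg = SimulationConfig(dt_ms=0.05, duration_ms=5.0,
                               record_sites=(("peripheral", 3500.0),
                                             ("peripheral", 1500.0)))
        tr = run_simulation(proto.make_model(), [], cfg)
        with pytest.raises(ValueError):
            proto.conduction_velocity(tr, ("peripheral", 3500.0),
                                      ("peripheral", 1500.0), active_model.graph)


class TestAmplitudeProfile:
    def test_profile_shape(self):
        prof = proto.amplitude_profile(proto.make_model(), spacing_um=20.0,
                                       early_window_ms=1.5).table
        # trough near the junction on the approach side, recovery beyond
        approach = prof[(prof.distance_um >= -60) & (prof.distance_um <= 0)]
        assert approach.amplitude_mV.min() < prof.amplitude_mV.iloc[0]
        assert prof.amplitude_mV.iloc[-1] > 50.0  # active propagation at 40 mS/cm2

    def test_somatic_gna_does_not_change_profile(self):
        p20 = proto.amplitude_profile(proto.make_model(gna_somatic=20.0),
                                      spacing_um=50.0, early_window_ms=1.5).table
        p40 = proto.amplitude_profile(proto.make_model(gna_somatic=40.0),
                                      spacing_um=50.0, early_window_ms=1.5).table
        assert np.abs(p20.amplitude_mV - p40.amplitude_mV).max() < 2.0


class TestReliability:
    def test_low_frequency_full_reliability(self, active_model):
        r = proto.propagation_reliability(proto.make_model(), 20.0, n_stimuli=6)
        assert r.reliability_pct == 100.0
        assert r.n_scored == 5  # first stimulus excluded from the score

    def test_rejects_bad_inputs(self, active_model):
        with pytest.raises(ValueError):
            proto.propagation_reliability(active_model, 10.0, n_stimuli=0)
        with pytest.raises(ValueError):
            proto.propagation_reliability(active_model, 0.0, n_stimuli=5)

    def test_monotone_nonincreasing_in_frequency(self):
        """Reliability never rises with stimulus frequency."""
        model = lambda: proto.make_model(stem_length_um=75.0, gkcnq=0.4)
        rels = [
            proto.propagation_reliability(model(), f, n_stimuli=8).reliability_pct
            for f in (20.0, 60.0, 120.0)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(rels, rels[1:]))

    def test_propagation_latency_exceeds_distance_over_cvmax(self, active_model):
        """Central-site spikes trail their stimulus by at least d/CV_max."""
        tr = proto._train_trace(proto.make_model(), 20.0, 3, (proto.DETECT_SITE,))
        spikes = proto.detect_spikes(tr.t_ms, tr.site_v(proto.DETECT_SITE))
        stim_times = 5.0 + np.arange(3) * 50.0
        d_mm = 9.6  # 4.6 mm peripheral + 5 mm central
        cv_max = 2.0
        for ts, tspk in zip(stim_times, spikes.times_ms):
            assert tspk - ts > d_mm / cv_max


class TestFollowingFrequency:
    def test_returns_saturated_flag_when_everything_conducts(self):
        ff, sat = proto.following_frequency(
            proto.make_model, f_min=10.0, f_max=30.0, n_stimuli=5,
            coarse_step=10.0,
        )
        assert ff == 30.0 and sat is True

    def test_dc_hyperpolarization_blocks_conduction(self):
        """A steady somatic hyperpolarization gates the junction."""
        from tjunction.solver import SimulationConfig, StimulusProtocol, run_simulation

        m = proto.make_model()
        cfg = SimulationConfig(dt_ms=0.025, duration_ms=400.0,
                               record_sites=(proto.DETECT_SITE,), sample_ms=0.05)
        stims = [
            StimulusProtocol(site=proto.STIM_SITE, frequency_hz=10.0, count=3,
                             onset_ms=60.0),
            StimulusProtocol(site=("soma", 0.0), amplitude_nA=-0.15,
                             width_ms=400.0, onset_ms=0.0),
        ]
        tr = run_simulation(m, stims, cfg)
        spikes = proto.detect_spikes(tr.t_ms, tr.site_v(proto.DETECT_SITE))
        assert len(spikes) == 0


class TestEctopicClassification:
    def _two_site_traces(self, events):
        """events: list of (t_at_distal, t_at_proximal)."""
        td = [e[0] for e in events if e[0] is not None]
        tp = [e[1] for e in events if e[1] is not None]
        dist = make_synthetic_trace(td)
        prox = make_synthetic_trace(tp)
        return dist, prox

    def test_orthodromic_pattern(self):
        # distal first (5.1 mm), proximal (2.6 mm) 4.6 ms later: CV ~0.54
        dist, prox = self._two_site_traces([(10.0, 14.6), (40.0, 44.6)])
        res = proto.detect_ectopic_spikes(
            dist.t_ms, prox.v_mV[:, 0], dist.v_mV[:, 0], 2600.0, 5100.0,
            [9.0, 39.0],
        )
        assert len(res["orthodromic_ms"]) == 2
        assert len(res["antidromic_ms"]) == 0

    def test_antidromic_pattern(self):
        dist, prox = self._two_site_traces([(14.6, 10.0)])
        res = proto.detect_ectopic_spikes(
            dist.t_ms, prox.v_mV[:, 0], dist.v_mV[:, 0], 2600.0, 5100.0, [5.0]
        )
        assert len(res["antidromic_ms"]) == 1
        assert len(res["orthodromic_ms"]) == 0

    def test_collision_reported(self):
        # distal spike with no proximal partner
        dist = make_synthetic_trace([10.0, 40.0])
        prox = make_synthetic_trace([14.6])
        res = proto.detect_ectopic_spikes(
            dist.t_ms, prox.v_mV[:, 0], dist.v_mV[:, 0], 2600.0, 5100.0,
            [9.0, 39.0],
        )
        assert len(res["collisions_ms"]) == 1

    def test_subthreshold_no_events(self):
        m = proto.make_model()
        tr = proto._train_trace(m, 20.0, 3,
                                (("peripheral", 2600.0), ("peripheral", 5100.0)),
                                amplitude_nA=0.001)
        res = proto.detect_ectopic_spikes(
            tr.t_ms, tr.site_v(("peripheral", 2600.0)),
            tr.site_v(("peripheral", 5100.0)), 2600.0, 5100.0,
            5.0 + np.arange(3) * 50.0,
        )
        assert len(res["orthodromic_ms"]) == 0
        assert len(res["antidromic_ms"]) == 0


class TestSweep:
    def test_following_frequency_sweep_table(self):
        res = proto.sweep(
            lambda **kw: proto.make_model(**kw),
            {"gkdr": [40.0]},
            outcome="following_frequency",
            outcome_kwargs={"f_min": 10.0, "f_max": 20.0, "n_stimuli": 4},
        )
        assert "following_frequency_hz" in res.table.columns
        assert len(res.table) == 1

    def test_failed_point_recorded_not_dropped(self):
        res = proto.sweep(
            lambda **kw: proto.make_model(**kw),
            {"gna_axonal": [0.0]},   # no spikes at all
            outcome="amplitude",
        )
        assert len(res.table) == 1
        assert "error" in res.table.columns


class TestPresets:
    def test_known_presets(self):
        assert "fig5_kcnq" in list_presets()
        pre = make_preset("fig5_kcnq")
        assert pre.geometry_overrides["stem_length_um"] == 75.0
        assert 0.2 in pre.sweep_grids["gkcnq"] and 0.8 in pre.sweep_grids["gkcnq"]

    def test_sk_axonal_grid_includes_7p5(self):
        pre = make_preset("fig7_sk_axonal")
        assert 7.5 in pre.sweep_grids["gsk"]
        assert pre.densities["sk_location"] == "axonal"

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            make_preset("fig9_does_not_exist")

    def test_round_trip_serialization(self):
        import yaml

        pre = make_preset("fig7_sk_soma")
        restored = yaml.safe_load(yaml.safe_dump(pre.to_dict()))
        assert restored == pre.to_dict()


class TestPumpExperiment:
    def test_single_spike_barely_shifts_equilibria(self):
        """One spike in the thin central axon moves E_Na/E_K by little."""
        m = proto.make_model(ion_dynamics=True, pump=True, i_pump_max=1e-4)
        tr = proto._train_trace(m, 0.0, 1, (("central", 20.0),), dt_ms=0.025)
        assert abs(tr.ena_mV[-1, 0] - 55.0) < 5.0
        assert abs(tr.ek_mV[-1, 0] + 90.0) < 5.0
        # but they did move (the mechanism is live)
        assert abs(tr.ena_mV[-1, 0] - 55.0) > 1e-4

    def test_mechanisms_off_equals_base_model(self):
        base = proto.make_model()
        off = proto.make_model(ion_dynamics=False, pump=False)
        tr1 = proto._train_trace(base, 0.0, 1, (("junction", 0.0),))
        tr2 = proto._train_trace(off, 0.0, 1, (("junction", 0.0),))
        np.testing.assert_array_equal(tr1.v_mV, tr2.v_mV)

    def test_surface_to_volume_scaling(self):
        """Same current density in 0.4 vs 0.8 um axons: concentration rate
        ratio equals the 2x surface-to-volume ratio."""
        g = proto.make_model().graph
        from tjunction.geometry import CD, PD

        sov_thin = 4.0 / (g.diam_um[g.branch == CD][0] * 1e-4)
        sov_thick = 4.0 / (g.diam_um[g.branch == PD][0] * 1e-4)
        assert sov_thin / sov_thick == pytest.approx(2.0, rel=1e-12)

    def test_high_pump_hyperpolarizes_during_train(self):
        res = proto.pump_ion_experiment(n_stimuli=10)
        vj_low = res["low"]["trace"].site_v(("junction", 0.0))
        vj_high = res["high"]["trace"].site_v(("junction", 0.0))
        t = res["low"]["trace"].t_ms
        # baseline drift measured between the last two spikes
        window = (t > 95.0) & (t < 99.0)
        assert vj_high[window].min() < vj_low[window].min() - 0.5
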