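"""Integrator correctness: oracles, conservation, convergence, stability."""
import numpy as np
import pytest
from scipy.optimize import curve_fit

from tjunction import (
    SimulationConfig,
    StimulusProtocol,
    build_membrane,
    run_simulation,
    steady_state_init,
)
from tjunction.fixtures import (
    make_toy_models,
    single_compartment_graph,
    two_compartment_graph,
    uniform_cable_graph,
)
from tjunction import protocols as proto


class TestToyOracles:
    def test_single_compartment_rc(self):
        """Isolated passive compartment: analytic RC charging, tau = 10 ms."""
        toys = make_toy_models()
        g = toys["single"]["graph"]
        m = build_membrane(g, passive_only=True)
        cfg = SimulationConfig(dt_ms=0.005, duration_ms=60.0,
                               record_sites=(("soma", 0.0),), sample_ms=0.05)
        stim = StimulusProtocol(site=("soma", 0.0), amplitude_nA=0.02,
                                width_ms=100.0, onset_ms=0.0)
        tr = run_simulation(m, [stim], cfg)
        area = g.area_cm2[g.resolve_site("soma", 0.0)]
        ref = -60.0 + toys["single"]["reference"](tr.t_ms, 0.02, area)
        assert np.abs(tr.site_v(("soma", 0.0)) - ref).max() < 0.05
        assert toys["single"]["tau_ms"] == pytest.approx(10.0)

    def test_two_compartment_vs_scipy(self):
        """Coupled pair matches an independently coded ODE solve to <0.1 mV."""
        toys = make_toy_models()
        g = toys["two"]["graph"]
        m = build_membrane(g, passive_only=True)
        cfg = SimulationConfig(dt_ms=0.005, duration_ms=50.0,
                               record_sites=(("soma", 0.0), ("stem", 0.0)),
                               sample_ms=0.05)
        stim = StimulusProtocol(site=("soma", 0.0), amplitude_nA=0.05,
                                width_ms=200.0, onset_ms=0.0)
        tr = run_simulation(m, [stim], cfg)
        ref = toys["two"]["reference"](g, 0.05, tr.t_ms)
        got = np.column_stack([tr.site_v(("soma", 0.0)), tr.site_v(("stem", 0.0))])
        assert np.abs(got - ref).max() < 0.1

    def test_uniform_cable_interior_matches_infinite_cable(self):
        """Early response in the cable interior matches the infinite-cable
        closed form before boundary reflections arrive."""
        from scipy.special import erfc

        g = uniform_cable_graph(length_um=4000.0, diameter_um=0.8, nseg=400)
        m = build_membrane(g, passive_only=True)
        inj = ("stem", 2000.0)   # mid-cable
        rec = ("stem", 2600.0)   # 600 um away
        cfg = SimulationConfig(dt_ms=0.005, duration_ms=12.0,
                               record_sites=(rec,), sample_ms=0.05)
        i0 = 0.01
        stim = StimulusProtocol(site=inj, amplitude_nA=i0, width_ms=100.0,
                                onset_ms=0.0)
        tr = run_simulation(m, [stim], cfg)
        # analytic: V(x,t) for current step onto an infinite cable
        rm, ra, cm = 1e4, 100.0, 1.0
        d = 0.8e-4
        lam = np.sqrt(rm * d / (4.0 * ra))            # cm
        tau = rm * cm * 1e-3                          # ms
        r_inf = (2 / np.pi) * np.sqrt(rm * ra) / d**1.5 * 1e-6  # MOhm semi-inf
        x = abs(g.arc_um[g.resolve_site(*rec)] - g.arc_um[g.resolve_site(*inj)]) * 1e-4 / lam
        t = tr.t_ms[1:] / tau
        analytic = (i0 * r_inf / 4.0) * (
            np.exp(-x) * erfc(x / (2 * np.sqrt(t)) - np.sqrt(t))
            - np.exp(x) * erfc(x / (2 * np.sqrt(t)) + np.sqrt(t))
        )
        got = tr.site_v((rec))[1:] + 60.0
        steady = analytic[-1]
        assert np.abs(got - analytic).max() < 0.02 * steady

    def test_symmetric_y_junction(self):
        """Equal daughter diameters: identical spikes in both branches."""
        m = proto.make_model(geometry_overrides={"central_diameter_um": 0.8})
        cfg = SimulationConfig(
            dt_ms=0.025, duration_ms=30.0,
            record_sites=(("peripheral", 300.0), ("central", 300.0)),
            sample_ms=0.05,
        )
        stim = StimulusProtocol(site=("stem", 75.0), amplitude_nA=0.3)
        tr = run_simulation(m, [stim], cfg)
        assert np.abs(
            tr.site_v(("peripheral", 300.0)) - tr.site_v(("central", 300.0))
        ).max() < 1e-6


class TestTreeSolve:
    def test_matches_dense_linear_solve(self):
        """One implicit step of the Hines solver equals a dense solve."""
        g = two_compartment_graph()
        m = build_membrane(g, passive_only=True)
        cfg = SimulationConfig(dt_ms=0.01, duration_ms=5.0,
                               record_sites=(("soma", 0.0), ("stem", 0.0)),
                               sample_ms=0.01)
        stim = StimulusProtocol(site=("stem", 0.0), amplitude_nA=0.1,
                                width_ms=10.0, onset_ms=0.0)
        tr = run_simulation(m, [stim], cfg)
        # dense reference: backward Euler on the same matrices
        n = g.n
        dt = 0.01
        gl = m.gleak * g.area_cm2 * 1e3
        A = np.zeros((n, n))
        for i in range(1, n):
            p = g.parent[i]
            A[i, p] -= g.gax_uS[i]
            A[p, i] -= g.gax_uS[i]
            A[i, i] += g.gax_uS[i]
            A[p, p] += g.gax_uS[i]
        A += np.diag(gl + g.c_nF / dt)
        comp = g.resolve_site("stem", 0.0)
        v = np.full(n, -60.0)
        traj = [v.copy()]
        for _ in range(500):
            b = g.c_nF / dt * v + gl * (-60.0)
            b[comp] += 0.1
            v = np.linalg.solve(A, b)
            traj.append(v.copy())
        traj = np.array(traj)
        got = np.column_stack([tr.site_v(("soma", 0.0)), tr.site_v(("stem", 0.0))])
        ref = traj[:, [g.resolve_site("soma", 0.0), comp]]
        assert np.abs(got - ref).max() < 1e-9


class TestConservationAndStability:
    def test_charge_conservation_passive(self):
        """Injected charge = capacitive + leak charge to <0.5%."""
        g = uniform_cable_graph(length_um=500.0, diameter_um=1.0, nseg=25)
        m = build_membrane(g, passive_only=True)
        sites = tuple(("stem", x) for x in np.linspace(10, 490, 25))
        cfg = SimulationConfig(dt_ms=0.005, duration_ms=40.0,
                               record_sites=sites, sample_ms=0.01)
        stim = StimulusProtocol(site=("stem", 250.0), amplitude_nA=0.05,
                                width_ms=10.0, onset_ms=1.0)
        tr = run_simulation(m, [stim], cfg)
        comps = tr.site_index
        c = g.c_nF[comps]
        gl = m.gleak[comps] * g.area_cm2[comps] * 1e3
        dv = tr.v_mV - (-60.0)
        q_cap = (c * dv[-1]).sum()                         # nA*ms
        q_leak = np.trapezoid(gl * dv, tr.t_ms, axis=0).sum()
        q_in = 0.05 * 10.0
        assert (q_cap + q_leak) == pytest.approx(q_in, rel=5e-3)

    def test_resting_stability_1s(self, active_model):
        cfg = SimulationConfig(dt_ms=0.025, duration_ms=1000.0,
                               record_sites=(("soma", 0.0), ("junction", 0.0),
                                             ("central", 5000.0)),
                               sample_ms=1.0)
        tr = run_simulation(proto.make_model(), [], cfg)
        assert np.abs(tr.v_mV + 60.0).max() < 0.5

    def test_steady_state_init_quiescent(self):
        m = proto.make_model(gca=0.05, gsk=1.0)
        state = steady_state_init(m)
        cfg = SimulationConfig(dt_ms=0.025, duration_ms=100.0,
                               record_sites=(("soma", 0.0),), sample_ms=0.5)
        tr = run_simulation(m, [], cfg, state=state)
        assert np.abs(tr.site_v(("soma", 0.0)) + 60.0).max() < 0.1

    def test_dt_convergence_active(self):
        """Halving dt changes the junction spike by <1% of its amplitude."""
        m = proto.make_model()

        def run(dt):
            cfg = SimulationConfig(dt_ms=dt, duration_ms=30.0,
                                   record_sites=(("junction", 0.0),),
                                   sample_ms=0.1)
            stim = StimulusProtocol(site=("peripheral", 4600.0))
            return run_simulation(proto.make_model(), [stim], cfg).site_v(("junction", 0.0))

        v1, v2 = run(0.025), run(0.0125)
        amp = v2.max() + 60.0
        assert abs(v1.max() - v2.max()) / amp < 0.01

    def test_nonfinite_detection(self):
        g = single_compartment_graph()
        m = build_membrane(g, passive_only=True)
        cfg = SimulationConfig(dt_ms=0.01, duration_ms=5.0,
                               record_sites=(("soma", 0.0),))
        with pytest.raises((FloatingPointError, ValueError)):
            stim = StimulusProtocol(site=("soma", 0.0), amplitude_nA=np.inf)
            run_simulation(m, [stim], cfg)


class TestPassiveBenchmarks:
    def test_input_resistance_consistent_with_linear_analysis(
        self, passive_step_trace, default_graph
    ):
        from tjunction.linear_analysis import input_impedance

        tr, stim = passive_step_trace
        v = tr.site_v(("soma", 0.0))
        t = tr.t_ms
        v_ss = v[(t > 430) & (t < 450)].mean()
        rn_solver = (v_ss + 60.0) / stim.amplitude_nA
        rn_linear = input_impedance(default_graph, ("soma", 0.0), 0.0)
        assert rn_solver == pytest.approx(rn_linear, rel=0.01)

    def test_slowest_time_constant(self, passive_step_trace):
        """Late-phase decay fits a single exponential of ~8 ms."""
        tr, stim = passive_step_trace
        v = tr.site_v(("soma", 0.0))
        t = tr.t_ms
        off = stim.onset_ms + stim.width_ms
        dv = np.abs(v + 60.0)
        d0 = dv[np.argmin(np.abs(t - off))]
        mask = (t > off + 0.2) & (dv < 0.95 * d0) & (dv > 0.01 * d0)
        popt, _ = curve_fit(lambda x, a, tau: a * np.exp(-x / tau),
                            t[mask] - off, dv[mask], p0=[d0, 8.0])
        assert 7.0 < popt[1] < 9.0
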