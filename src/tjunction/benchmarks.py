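"""Benchmark quantities of the exemplar model, computed from scratch.

Each function builds the relevant model, runs the protocol and measures one
headline quantity (input resistance, time constant, conduction velocities,
spike amplitude, junction impedance, geometric-ratio crossing, critical NaV
density, following frequencies, SK failure threshold).  They are used by the
reproduction script and by the acceptance test suite.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .geometry import build_geometry, discretize, geometric_ratio
from .membrane import build_membrane
from .solver import SimulationConfig, StimulusProtocol, run_simulation
from . import protocols as proto
from . import linear_analysis as lin

__all__ = [
    "passive_step_benchmarks",
    "single_spike_benchmarks",
    "junction_impedance_250",
    "gr_unity_crossing",
    "critical_gna",
    "base_following_frequency",
    "kcnq_following_frequency",
    "sk_failure_threshold",
    "sk_following_frequency",
]


def passive_step_benchmarks():
    """R_N (MOhm) and slowest time constant tau0 (ms) at the soma.

    A small hyperpolarizing current step is injected at the soma of the
    passive model; R_N is the steady-state deflection over current, tau0 a
    single-exponential fit of the off-decay between 95% and 1% of the
    initial deflection.
    """
    graph = discretize(build_geometry())
    model = build_membrane(graph, passive_only=True)
    stim = StimulusProtocol(site=("soma", 0.0), amplitude_nA=-0.01,
                            width_ms=400.0, onset_ms=50.0)
    cfg = SimulationConfig(dt_ms=0.025, duration_ms=700.0,
                           record_sites=(("soma", 0.0),), sample_ms=0.1)
    tr = run_simulation(model, [stim], cfg)
    v, t = tr.site_v(("soma", 0.0)), tr.t_ms
    v_ss = v[(t > 430) & (t < 450)].mean()
    rn = (v_ss + 60.0) / stim.amplitude_nA
    off = stim.onset_ms + stim.width_ms
    dv = np.abs(v + 60.0)
    d0 = dv[np.argmin(np.abs(t - off))]
    mask = (t > off + 0.2) & (dv < 0.95 * d0) & (dv > 0.01 * d0)
    popt, _ = curve_fit(lambda x, a, tau: a * np.exp(-x / tau),
                        t[mask] - off, dv[mask], p0=[d0, 8.0])
    return {"rn_MOhm": float(rn), "tau0_ms": float(popt[1]), "n": graph.n}


def single_spike_benchmarks():
    """Peripheral/central CV (m/s) and somatic AP amplitude (mV).

    One orthodromic spike (0.2 nA, 1 ms at 4.6 mm peripheral); CVs measured
    between distal sites 2 mm apart on each branch, amplitude as the somatic
    peak minus the -60 mV rest.
    """
    model = proto.make_model()
    sites = (("soma", 0.0), ("peripheral", 3500.0), ("peripheral", 1500.0),
             ("central", 1500.0), ("central", 3500.0))
    cfg = SimulationConfig(dt_ms=0.01, duration_ms=60.0, record_sites=sites,
                           sample_ms=0.025)
    tr = run_simulation(model, [StimulusProtocol(site=proto.STIM_SITE)], cfg)
    cv_p = proto.conduction_velocity(tr, ("peripheral", 3500.0),
                                     ("peripheral", 1500.0), model.graph)
    cv_c = proto.conduction_velocity(tr, ("central", 1500.0),
                                     ("central", 3500.0), model.graph)
    amp = float(tr.site_v(("soma", 0.0)).max() + 60.0)
    return {"cv_peripheral_m_s": cv_p, "cv_central_m_s": cv_c,
            "somatic_amplitude_mV": amp, "n": model.graph.n}


def junction_impedance_250():
    """|Z_N| at the T-junction at 250 Hz (MOhm), default geometry."""
    graph = discretize(build_geometry())
    return {"z_MOhm": lin.input_impedance(graph, ("junction", 0.0), 250.0),
            "n": graph.n}


def gr_unity_crossing(step: float = 0.01):
    """Smallest stem diameter with orthodromic GR > 1 (grid scan)."""
    diams = np.round(np.arange(0.1, 2.0 + 1e-9, step), 10)
    gr = geometric_ratio(0.8, (diams, np.full_like(diams, 0.4)))
    return {"diameter_um": float(diams[gr > 1.0][0]), "n": len(diams)}


def critical_gna(grid=None):
    """Smallest axonal NaV density whose single orthodromic spike actively
    crosses the junction (somatic density at half the axonal value)."""
    grid = np.arange(2.5, 60.0 + 1e-9, 2.5) if grid is None else np.asarray(grid)
    cfg = SimulationConfig(dt_ms=0.025, duration_ms=70.0,
                           record_sites=(proto.DETECT_SITE,), sample_ms=0.05)
    for gna in grid:
        model = proto.make_model(gna_axonal=float(gna))
        tr = run_simulation(model, [StimulusProtocol(site=proto.STIM_SITE)], cfg)
        if tr.site_v(proto.DETECT_SITE).max() > proto.DEFAULT_THRESHOLD_MV:
            return {"gna_mS_cm2": float(gna), "n": len(grid)}
    # nothing on the grid propagates: report the cap as a lower bound
    return {"gna_mS_cm2": float(grid[-1]), "n": len(grid)}


def base_following_frequency(f_max: float = 200.0):
    """Following frequency of the NaV+KDR model (75 um stem)."""
    ff, sat = proto.following_frequency(
        lambda: proto.make_model(stem_length_um=75.0), f_min=10.0, f_max=f_max,
    )
    return {"ff_hz": float(ff), "saturated": sat, "n": 20}


def kcnq_following_frequency(gkcnq: float, f_max: float = 200.0):
    """Following frequency with KCNQ at the given density (75 um stem)."""
    ff, sat = proto.following_frequency(
        lambda: proto.make_model(stem_length_um=75.0, gkcnq=gkcnq),
        f_min=10.0, f_max=f_max,
    )
    return {"ff_hz": float(ff), "saturated": sat, "gkcnq": gkcnq, "n": 20}


def sk_failure_threshold(grid=None, frequency_hz: float = 10.0):
    """Smallest somatic SK density producing propagation failure at 10 Hz.

    Somatic CaV (at the calibrated default density) and calcium dynamics
    accompany the SK conductance; 20-pulse trains; failure = any scored
    stimulus whose spike does not reach the distal central axon.  If no
    density on the grid produces failure, the scan cap is returned as a
    lower bound.
    """
    from .membrane import GCA_SOMATIC_DEFAULT

    grid = np.round(np.arange(0.25, 3.0 + 1e-9, 0.25), 10) if grid is None \
        else np.asarray(grid)
    for gsk in grid:
        model = proto.make_model(gca=GCA_SOMATIC_DEFAULT, gsk=float(gsk),
                                 sk_location="soma")
        r = proto.propagation_reliability(model, frequency_hz)
        if r.reliability_pct < 100.0:
            return {"gsk_mS_cm2": float(gsk), "n": len(grid)}
    # no failure anywhere on the grid: report the scan cap (a lower bound)
    return {"gsk_mS_cm2": float(grid[-1]), "n": len(grid)}


def sk_following_frequency(gna_axonal: float = 40.0, gsk: float = 1.0,
                           f_max: float = 40.0):
    """Following frequency of the somatic-SK model at the given NaV density."""
    from .membrane import GCA_SOMATIC_DEFAULT

    ff, sat = proto.following_frequency(
        lambda: proto.make_model(gna_axonal=gna_axonal,
                                 gca=GCA_SOMATIC_DEFAULT, gsk=gsk,
                                 sk_location="soma"),
        f_min=2.0, f_max=f_max, coarse_step=4.0,
    )
    return {"ff_hz": float(ff), "saturated": sat, "n": 20}
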