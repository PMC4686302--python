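"""Experiment layer: spike detection, conduction velocity, amplitude
profiles, propagation reliability, following frequency, ectopic-spike
classification, parameter sweeps, and the pump/ion-accumulation experiment.

The canonical protocol drives the model with 0.2 nA, 1 ms current pulses
injected in the peripheral axon 4.6 mm from the T-junction and scores
propagation by spike arrival in the central axon 5 mm beyond the junction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CompartmentGraph, build_geometry, discretize
from .membrane import MembraneModel, KineticsParams, build_membrane
from .solver import SimulationConfig, StimulusProtocol, Trace, run_simulation

__all__ = [
    "SpikeTrain",
    "PropagationResult",
    "SweepResult",
    "detect_spikes",
    "conduction_velocity",
    "amplitude_profile",
    "propagation_reliability",
    "following_frequency",
    "detect_ectopic_spikes",
    "sweep",
    "pump_ion_experiment",
    "STIM_SITE",
    "DETECT_SITE",
    "PROTOCOL_DT_MS",
]

STIM_SITE = ("peripheral", 4600.0)   # 4.6 mm from the T-junction
DETECT_SITE = ("central", 5000.0)    # 5 mm into the central axon
PROTOCOL_DT_MS = 0.025               # time step for protocol sweeps
DEFAULT_THRESHOLD_MV = -10.0
DEFAULT_REFRACTORY_MS = 2.0
V_REST = -60.0


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spikes at one site."""

    site: tuple
    times_ms: np.ndarray
    amplitudes_mV: np.ndarray  # peak minus rest

    def __len__(self) -> int:
        return len(self.times_ms)


@dataclass(frozen=True)
class PropagationResult:
    frequency_hz: float
    n_stimuli: int
    n_scored: int
    n_propagated: int

    @property
    def reliability_pct(self) -> float:
        return 100.0 * self.n_propagated / self.n_scored


@dataclass
class SweepResult:
    """Tidy sweep outcome: one row per grid point."""

    parameter: str
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_spikes(
    t_ms: np.ndarray,
    v_mV: np.ndarray,
    threshold_mV: float = DEFAULT_THRESHOLD_MV,
    refractory_ms: float = DEFAULT_REFRACTORY_MS,
    v_rest_mV: float = V_REST,
    site: tuple = ("", 0.0),
) -> SpikeTrain:
    """Upward threshold crossings, at most one spike per refractory window.

    Spike time is the linearly interpolated crossing; amplitude is the local
    peak within the refractory window minus the resting potential.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mV, dtype=float)
    idx = np.where((v[1:] > threshold_mV) & (v[:-1] <= threshold_mV))[0]
    times, amps = [], []
    for i in idx:
        tc = t[i] + (t[i + 1] - t[i]) * (threshold_mV - v[i]) / (v[i + 1] - v[i])
        if times and tc - times[-1] < refractory_ms:
            continue
        j_end = np.searchsorted(t, tc + refractory_ms)
        peak = v[i:max(j_end, i + 2)].max()
        times.append(tc)
        amps.append(peak - v_rest_mV)
    return SpikeTrain(site, np.array(times), np.array(amps))


def conduction_velocity(
    trace: Trace,
    site_a: tuple,
    site_b: tuple,
    graph: CompartmentGraph,
    threshold_mV: float = DEFAULT_THRESHOLD_MV,
) -> float:
    """CV (m/s) of the first spike between two sites on one branch.

    Uses the actual arc distance between the resolved compartments and the
    interpolated threshold-crossing latency.
    """
    ta = detect_spikes(trace.t_ms, trace.site_v(site_a), threshold_mV, site=site_a)
    tb = detect_spikes(trace.t_ms, trace.site_v(site_b), threshold_mV, site=site_b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("spike missing at one of the CV measurement sites")
    d_um = abs(
        graph.arc_um[graph.resolve_site(*site_a)]
        - graph.arc_um[graph.resolve_site(*site_b)]
    )
    dt = abs(tb.times_ms[0] - ta.times_ms[0])
    if dt <= 0:
        raise ValueError("zero spike latency between CV sites")
    return (d_um * 1e-3) / dt  # mm/ms == m/s


# ---------------------------------------------------------------------------
# Model factory for the standard experiments
# ---------------------------------------------------------------------------

def make_model(
    *,
    stem_length_um: float = 150.0,
    geometry_overrides: dict | None = None,
    params: KineticsParams | None = None,
    gna_axonal: float = 40.0,
    gna_somatic: float | None = None,
    gkdr: float = 40.0,
    gkcnq: float = 0.0,
    gca: float = 0.0,
    gsk: float = 0.0,
    sk_location: str = "soma",
    ion_dynamics: bool = False,
    pump: bool = False,
    i_pump_max: float = 0.0,
) -> MembraneModel:
    """Build the exemplar model with the given mechanism configuration."""
    cfg = dict(geometry_overrides or {})
    cfg.setdefault("stem_length_um", stem_length_um)
    graph = discretize(build_geometry(cfg))
    return build_membrane(
        graph,
        params,
        gna_axonal=gna_axonal,
        gna_somatic=gna_somatic,
        gkdr=gkdr,
        gkcnq=gkcnq,
        gca=gca,
        gsk=gsk,
        sk_location=sk_location,
        ion_dynamics=ion_dynamics,
        pump=pump,
        i_pump_max=i_pump_max,
    )


def _train_trace(
    model: MembraneModel,
    frequency_hz: float,
    n_stimuli: int,
    record_sites,
    stim_site=STIM_SITE,
    amplitude_nA: float = 0.2,
    width_ms: float = 1.0,
    onset_ms: float = 5.0,
    dt_ms: float = PROTOCOL_DT_MS,
    tail_ms: float = 40.0,
) -> Trace:
    isi = 1000.0 / frequency_hz if frequency_hz > 0 else 0.0
    duration = onset_ms + isi * (n_stimuli - 1) + width_ms + tail_ms
    cfg = SimulationConfig(
        dt_ms=dt_ms, duration_ms=duration, record_sites=tuple(record_sites),
        sample_ms=0.05,
    )
    stim = StimulusProtocol(
        site=stim_site, amplitude_nA=amplitude_nA, width_ms=width_ms,
        frequency_hz=frequency_hz, count=n_stimuli, onset_ms=onset_ms,
    )
    return run_simulation(model, [stim], cfg)


# ---------------------------------------------------------------------------
# Reliability and following frequency
# ---------------------------------------------------------------------------

def propagation_reliability(
    model: MembraneModel,
    frequency_hz: float,
    n_stimuli: int = 20,
    score_from: int = 2,
    detect_site=DETECT_SITE,
    stim_site=STIM_SITE,
    dt_ms: float = PROTOCOL_DT_MS,
) -> PropagationResult:
    """Fraction of stimuli whose spike reaches the distal central axon.

    Each detected central-axon spike is matched (greedily, in time order) to
    the earliest unmatched stimulus whose expected arrival window contains
    it; the window is centered on the latency of the first conducted spike
    and extends one inter-stimulus interval.  Stimuli before ``score_from``
    are excluded from the score (the first spike of a train always
    propagates).
    """
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    if frequency_hz <= 0:
        raise ValueError("train frequency must be > 0")
    trace = _train_trace(model, frequency_hz, n_stimuli, (detect_site,),
                         stim_site=stim_site, dt_ms=dt_ms)
    spikes = detect_spikes(trace.t_ms, trace.site_v(detect_site), site=detect_site)
    isi = 1000.0 / frequency_hz
    stim_times = 5.0 + np.arange(n_stimuli) * isi
    matched = np.full(n_stimuli, False)
    if len(spikes) > 0:
        lat0 = spikes.times_ms[0] - stim_times[0]
        used = np.full(len(spikes), False)
        for k, ts in enumerate(stim_times):
            lo = ts + 0.5 * lat0
            hi = ts + lat0 + isi
            for j, tspk in enumerate(spikes.times_ms):
                if not used[j] and lo <= tspk < hi:
                    used[j] = True
                    matched[k] = True
                    break
    scored = matched[score_from - 1:]
    return PropagationResult(
        frequency_hz=frequency_hz,
        n_stimuli=n_stimuli,
        n_scored=len(scored),
        n_propagated=int(scored.sum()),
    )


def following_frequency(
    model_factory,
    f_min: float = 5.0,
    f_max: float = 200.0,
    n_stimuli: int = 20,
    coarse_step: float = 10.0,
    resolution: float = 1.0,
    dt_ms: float = PROTOCOL_DT_MS,
) -> tuple:
    """Highest frequency with 100% propagation, found by coarse scan plus
    bisection to ``resolution`` (Hz).

    ``model_factory()`` must return a fresh model (each evaluation is an
    independent deterministic run).  Returns (frequency, saturated) where
    ``saturated`` is True if 100% reliability persists at ``f_max``.
    """
    def ok(f):
        r = propagation_reliability(model_factory(), f, n_stimuli, dt_ms=dt_ms)
        return r.reliability_pct >= 100.0

    if not ok(f_min):
        return f_min, False
    if ok(f_max):
        return f_max, True
    lo = f_min
    hi = None
    f = f_min + coarse_step
    while f <= f_max + 1e-9:
        if ok(f):
            lo = f
        else:
            hi = f
            break
        f += coarse_step
    if hi is None:
        return f_max, True
    while hi - lo > resolution:
        mid = round((lo + hi) / 2.0)
        if mid in (lo, hi):
            break
        if ok(mid):
            lo = mid
        else:
            hi = mid
    return lo, False


# ---------------------------------------------------------------------------
# Amplitude profile (single orthodromic spike)
# ---------------------------------------------------------------------------

def amplitude_profile(
    model: MembraneModel,
    window_um: float = 100.0,
    spacing_um: float = 10.0,
    early_window_ms: float = 3.0,
    dt_ms: float = 0.01,
) -> SweepResult:
    """Early-mode spike amplitude vs signed distance from the T-junction.

    A single orthodromic spike is evoked; at each site the early mode is the
    maximum depolarization within ``early_window_ms`` of the expected
    orthodromic arrival (anchored on the threshold crossing at the -100 um
    peripheral reference site), separating it from the later somatic
    reflection.
    """
    g = model.graph
    dists = np.arange(-window_um, window_um + 1e-9, spacing_um)
    sites = []
    for d in dists:
        if d < 0:
            sites.append(("peripheral", -d))
        elif d == 0:
            sites.append(("junction", 0.0))
        else:
            sites.append(("central", d))
    # reference sites well before the junction give the orthodromic arrival
    # time and speed, so each site's window tracks the propagating wavefront
    # and excludes the later somatic reflection
    ref_far = ("peripheral", 600.0)
    ref_near = ("peripheral", 200.0)
    trace = _train_trace(model, 0.0, 1, tuple(sites) + (ref_far, ref_near),
                         dt_ms=dt_ms, tail_ms=50.0)
    s_far = detect_spikes(trace.t_ms, trace.site_v(ref_far), site=ref_far)
    s_near = detect_spikes(trace.t_ms, trace.site_v(ref_near), site=ref_near)
    if len(s_far) == 0 or len(s_near) == 0:
        raise ValueError("no orthodromic spike at the peripheral reference sites")
    cv_um_ms = 400.0 / (s_near.times_ms[0] - s_far.times_ms[0])
    t_at = lambda d: s_near.times_ms[0] + (d + 200.0) / cv_um_ms
    rows = []
    for d, site in zip(dists, sites):
        v = trace.site_v(site)
        lo = t_at(min(d, 0.0)) - 0.5          # central sites: window from the
        hi = t_at(max(d, 0.0)) + early_window_ms  # junction arrival onwards
        mask = (trace.t_ms >= lo) & (trace.t_ms <= hi)
        rows.append({"distance_um": d, "amplitude_mV": v[mask].max() - V_REST})
    return SweepResult(
        "distance_um",
        pd.DataFrame(rows),
        meta={"early_window_ms": early_window_ms},
    )


# ---------------------------------------------------------------------------
# Ectopic (antidromic) spike classification
# ---------------------------------------------------------------------------

def detect_ectopic_spikes(
    t_ms: np.ndarray,
    v_proximal: np.ndarray,
    v_distal: np.ndarray,
    proximal_distance_um: float,
    distal_distance_um: float,
    stimulus_times_ms,
    max_cv_m_s: float = 2.0,
    min_cv_m_s: float = 0.1,
) -> dict:
    """Classify events at two peripheral sites as orthodromic or antidromic.

    The two traces are recorded at distances ``proximal_distance_um`` (closer
    to the junction) and ``distal_distance_um`` from the T-junction on the
    peripheral axon.  Spikes are paired greedily across sites within the lag
    bounds implied by ``min_cv``/``max_cv``; a pair arriving first at the
    junction-proximal site is antidromic.  Unpaired spikes at the distal site
    are reported as collisions (the orthodromic spike vanished between the
    sites).
    """
    s_prox = detect_spikes(t_ms, v_proximal)
    s_dist = detect_spikes(t_ms, v_distal)
    gap_um = abs(distal_distance_um - proximal_distance_um)
    max_lag = gap_um * 1e-3 / min_cv_m_s   # ms
    min_lag = gap_um * 1e-3 / max_cv_m_s
    used = np.full(len(s_prox), False)
    ortho, anti = [], []
    for td in s_dist.times_ms:
        best = None
        for j, tp in enumerate(s_prox.times_ms):
            if used[j]:
                continue
            lag = tp - td
            if min_lag <= abs(lag) <= max_lag:
                if best is None or abs(lag) < abs(s_prox.times_ms[best] - td):
                    best = j
        if best is not None:
            used[best] = True
            tp = s_prox.times_ms[best]
            (ortho if tp > td else anti).append(min(tp, td))
    collisions = [
        float(td)
        for td, matched in zip(
            s_dist.times_ms,
            [any(min_lag <= abs(tp - td) <= max_lag for tp in s_prox.times_ms)
             for td in s_dist.times_ms],
        )
        if not matched
    ]
    stim = np.asarray(stimulus_times_ms, dtype=float)
    # antidromic events also include proximal spikes preceding their stimulus
    anti_times = sorted(set(np.round(anti, 6)))
    return {
        "orthodromic_ms": np.array(sorted(ortho)),
        "antidromic_ms": np.array(anti_times),
        "collisions_ms": np.array(collisions),
        "n_stimuli": len(stim),
    }


# ---------------------------------------------------------------------------
# Generic sweep
# ---------------------------------------------------------------------------

def sweep(
    model_factory,
    grid: dict,
    outcome: str = "following_frequency",
    outcome_kwargs: dict | None = None,
) -> SweepResult:
    """Run an outcome over the cartesian product of ``grid``.

    ``model_factory(**point)`` builds the model for one grid point.
    ``outcome`` is 'following_frequency', 'reliability' or 'amplitude'.
    Failed simulations are recorded as NaN with the diagnostic message, not
    silently dropped.
    """
    from itertools import product

    kw = dict(outcome_kwargs or {})
    names = list(grid)
    rows = []
    for values in product(*(np.atleast_1d(grid[k]) for k in names)):
        point = dict(zip(names, [float(v) for v in values]))
        row = dict(point)
        try:
            if outcome == "following_frequency":
                ff, sat = following_frequency(lambda: model_factory(**point), **kw)
                row["following_frequency_hz"] = ff
                row["saturated"] = sat
            elif outcome == "reliability":
                r = propagation_reliability(model_factory(**point), **kw)
                row["reliability_pct"] = r.reliability_pct
            elif outcome == "amplitude":
                prof = amplitude_profile(model_factory(**point), **kw)
                row["junction_amplitude_mV"] = float(
                    prof.table.loc[prof.table.distance_um == 0.0, "amplitude_mV"].iloc[0]
                )
            else:
                raise ValueError(f"unknown outcome {outcome!r}")
        except (ValueError, FloatingPointError) as err:
            row["error"] = str(err)
        rows.append(row)
    return SweepResult(",".join(names), pd.DataFrame(rows), meta={"outcome": outcome})


# ---------------------------------------------------------------------------
# Pump / ion-accumulation experiment
# ---------------------------------------------------------------------------

def pump_ion_experiment(
    i_pump_max_low: float = 1e-4,
    i_pump_max_high: float = 0.1,
    frequency_hz: float = 100.0,
    n_stimuli: int = 20,
    gsk: float = 0.0,
    params: KineticsParams | None = None,
) -> dict:
    """100-Hz spike train with ion accumulation and a low vs high pump.

    Returns per-condition traces at the junction and 20 um into the central
    axon (V, [Ca], E_Na, E_K) plus the propagation result.  The high pump
    density is the low density scaled 1000-fold by default.
    """
    out = {}
    for label, ipm in (("low", i_pump_max_low), ("high", i_pump_max_high)):
        model = make_model(
            params=params,
            ion_dynamics=True,
            pump=True,
            i_pump_max=ipm,
            gca=0.05 if gsk else 0.0,
            gsk=gsk,
        )
        trace = _train_trace(
            model, frequency_hz, n_stimuli,
            (("junction", 0.0), ("central", 20.0), DETECT_SITE),
        )
        rel = propagation_reliability(model, frequency_hz, n_stimuli)
        out[label] = {"trace": trace, "propagation": rel, "i_pump_max": ipm}
    return out
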