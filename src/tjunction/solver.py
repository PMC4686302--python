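"""Time-domain integration of the branched cable with active membrane.

`run_simulation` advances the coupled voltage/gating/ion system with an
unconditionally stable implicit (backward-Euler) scheme on the Hines-ordered
tree, Rush-Larsen exponential gating updates, and explicit ion updates.  The
default time step is 10 us; long protocol sweeps use 25 us (grid-convergence
tests verify <1% sensitivity to halving dt).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kernel
from .geometry import CompartmentGraph, JUNCTION
from .membrane import (
    MembraneModel,
    nav_rates,
    kdr_rates,
    kcnq_rates,
    cav_rates,
    sk_rates,
    resting_gates,
    solve_eleak,
    pump_current,
)

__all__ = ["StimulusProtocol", "SimulationConfig", "Trace", "SimulationState",
           "steady_state_init", "run_simulation"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Train of rectangular current pulses injected at one site.

    ``site`` is (branch, arc-distance um) as accepted by
    CompartmentGraph.resolve_site.  frequency_hz = 0 with count = 1 gives a
    single pulse at ``onset_ms``.
    """

    site: tuple
    amplitude_nA: float = 0.2
    width_ms: float = 1.0
    frequency_hz: float = 0.0
    count: int = 1
    onset_ms: float = 5.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude_nA):
            raise ValueError("amplitude must be finite")
        if self.frequency_hz < 0:
            raise ValueError("frequency must be >= 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.count > 1 and self.frequency_hz <= 0:
            raise ValueError("pulse trains need frequency > 0")

    @property
    def interval_ms(self) -> float:
        return 1000.0 / self.frequency_hz if self.frequency_hz > 0 else 0.0

    def pulse_times(self) -> np.ndarray:
        return self.onset_ms + np.arange(self.count) * self.interval_ms


@dataclass(frozen=True)
class SimulationConfig:
    dt_ms: float = 0.01
    duration_ms: float = 100.0
    record_sites: tuple = (("soma", 0.0),)
    sample_ms: float = 0.025     # recording resolution (rounded to dt multiple)

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt must be > 0")
        if self.duration_ms < self.dt_ms:
            raise ValueError("duration must be >= dt")


@dataclass
class SimulationState:
    """Full dynamical state of every compartment."""

    v: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    l: np.ndarray
    mq: np.ndarray
    mca: np.ndarray
    q: np.ndarray
    ca: np.ndarray
    nai: np.ndarray
    nao: np.ndarray
    ki: np.ndarray
    ko: np.ndarray
    ena: np.ndarray
    ek: np.ndarray


@dataclass
class Trace:
    """Recorded time series at the requested sites."""

    t_ms: np.ndarray
    sites: tuple                  # site labels as passed in
    site_index: np.ndarray        # compartment indices
    v_mV: np.ndarray              # (ntime, nsites)
    ca_mM: np.ndarray
    ena_mV: np.ndarray
    ek_mV: np.ndarray
    v_rest_mV: float = -60.0

    def site_v(self, site) -> np.ndarray:
        return self.v_mV[:, self.sites.index(tuple(site))]

    def to_dataframe(self):
        """Long/tidy format: time_ms, site, variable, value."""
        import pandas as pd

        frames = []
        for j, site in enumerate(self.sites):
            label = f"{site[0]}@{site[1]:g}um"
            for var, arr in (
                ("v_mV", self.v_mV),
                ("ca_mM", self.ca_mM),
                ("ena_mV", self.ena_mV),
                ("ek_mV", self.ek_mV),
            ):
                frames.append(
                    pd.DataFrame(
                        {
                            "time_ms": self.t_ms,
                            "site": label,
                            "variable": var,
                            "value": arr[:, j],
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def steady_state_init(model: MembraneModel, v_rest: float = -60.0) -> SimulationState:
    """Resting state: gates at x_inf(v_rest), Ca at rest, ion pools at baseline.

    With the leak reversal calibrated, the initialized state carries zero net
    membrane current in every compartment.
    """
    if model.eleak is None:
        solve_eleak(model, v_rest)
    g = model.graph
    p = model.params
    gates = resting_gates(model, v_rest)
    full = lambda x: np.full(g.n, float(x))
    return SimulationState(
        v=full(v_rest),
        m=full(gates["m"]),
        h=full(gates["h"]),
        n=full(gates["n"]),
        l=full(gates["l"]),
        mq=full(gates["mq"]),
        mca=full(gates["mca"]),
        q=full(gates["q"]),
        ca=full(p.ca_rest_mM),
        nai=full(p.nai_mM),
        nao=full(p.nao_mM),
        ki=full(p.ki_mM),
        ko=full(p.ko_mM),
        ena=full(p.ena_mV),
        ek=full(p.ek_mV),
    )


def _rate_tables(model: MembraneModel, dt: float):
    """Tabulate x_inf(V) and exp(-dt/tau(V)) for every gate."""
    p = model.params
    v = np.arange(-150.0, 100.0 + 1e-9, 0.025)
    a_m, b_m, a_h, b_h = nav_rates(v, p.v_ref, p.dv_h, p.s_h)
    minf, mtau = a_m / (a_m + b_m), 1.0 / (a_m + b_m)
    hinf, htau = a_h / (a_h + b_h), 1.0 / (a_h + b_h)
    ninf, ntau, linf, ltau = kdr_rates(v, p.a0_n, p.a0_l)
    mqinf, mqtau = kcnq_rates(v)
    a_c, b_c = cav_rates(v)
    mcainf, mcatau = a_c / (a_c + b_c), 1.0 / (a_c + b_c)

    lgrid = np.arange(-9.0, 0.0 + 1e-9, 0.01)
    a_q, b_q = sk_rates(10.0**lgrid, p.sk_divisor)
    qinf, qtau = a_q / (a_q + b_q), 1.0 / (a_q + b_q)

    e = lambda tau: np.exp(-dt / np.maximum(tau, 1e-9))
    return dict(
        v0=v[0], inv_dv=1.0 / 0.025,
        minf=minf, mexp=e(mtau), hinf=hinf, hexp=e(htau),
        ninf=ninf, nexp=e(ntau), linf=linf, lexp=e(ltau),
        mqinf=mqinf, mqexp=e(mqtau), mcainf=mcainf, mcaexp=e(mcatau),
        l0=lgrid[0], inv_dl=1.0 / 0.01, qinf=qinf, qexp=e(qtau),
    )


def _expand_stimuli(graph: CompartmentGraph, stimuli) -> tuple:
    comps, amps, t0s, t1s = [], [], [], []
    for stim in stimuli:
        c = graph.resolve_site(*stim.site)
        for t in stim.pulse_times():
            comps.append(c)
            amps.append(stim.amplitude_nA)
            t0s.append(t)
            t1s.append(t + stim.width_ms)
    return (
        np.array(comps, dtype=np.int64),
        np.array(amps, dtype=float),
        np.array(t0s, dtype=float),
        np.array(t1s, dtype=float),
    )


def run_simulation(
    model: MembraneModel,
    stimuli,
    config: SimulationConfig,
    state: SimulationState | None = None,
) -> Trace:
    """Integrate the model and return traces at the requested sites.

    If ``state`` is given the run continues from it (mutating it); otherwise
    the model starts from the calibrated resting state.
    """
    g = model.graph
    p = model.params
    if state is None:
        state = steady_state_init(model)
    dt = config.dt_ms
    nsteps = int(round(config.duration_ms / dt))
    stride = max(1, int(round(config.sample_ms / dt)))
    nrec = nsteps // stride + 1

    tabs = _rate_tables(model, dt)

    area = g.area_cm2
    to_uS = area * 1e3  # density mS/cm^2 -> absolute uS
    gna_abs = model.gna * to_uS
    gkdr_abs = model.gkdr * to_uS
    gkcnq_abs = model.gkcnq * to_uS
    gca_abs = model.gca * to_uS
    gsk_abs = model.gsk * to_uS
    gleak_abs = model.gleak * to_uS

    idx = lambda dens: np.where(dens * area > 0)[0].astype(np.int64)
    na_idx = idx(model.gna)
    kdr_idx = idx(model.gkdr)
    kcnq_idx = idx(model.gkcnq)
    ca_idx = idx(model.gca)
    sk_idx = idx(model.gsk)

    cdt = g.c_nF / dt  # nF/ms = uS
    gax_tot = g.gax_total_uS

    # surface-to-volume ratios for ion pools (1/cm)
    sov_i = np.zeros(g.n)
    sov_o = np.zeros(g.n)
    mask = g.area_cm2 > 0
    sov_i[mask] = 4.0 / (g.diam_um[mask] * 1e-4)
    sov_o[mask] = 1.0 / (model.shell_thickness_um * 1e-4)

    # baseline ionic fluxes (subtracted so the calibrated rest is a fixed
    # point of the concentration dynamics: accumulation tracks deviations
    # from rest, with no lateral diffusion and no buffering)
    jna0 = np.zeros(g.n)
    jk0 = np.zeros(g.n)
    if model.ion_dynamics:
        gates = resting_gates(model)
        vr = -60.0
        jna0 = model.gna * gates["m"] ** 3 * gates["h"] * (vr - p.ena_mV) * 1e-3
        jk0 = (
            model.gkdr * gates["n"] ** 3 * gates["l"]
            + model.gkcnq * gates["mq"]
            + model.gsk * gates["q"] ** 2
        ) * (vr - p.ek_mV) * 1e-3
        if model.pump:
            i_na, i_k = pump_current(p.nai_mM, model.i_pump_max, p.km_pump_mM)
            jna0 = jna0 + i_na
            jk0 = jk0 + i_k

    ipmax = np.full(g.n, float(model.i_pump_max))
    ipmax[~mask] = 0.0

    stim_comp, stim_amp, stim_t0, stim_t1 = _expand_stimuli(g, stimuli)

    rec_idx = np.array(
        [g.resolve_site(*site) for site in config.record_sites], dtype=np.int64
    )
    out_v = np.empty((nrec, rec_idx.size))
    out_ca = np.empty_like(out_v)
    out_ena = np.empty_like(out_v)
    out_ek = np.empty_like(out_v)

    kernel.integrate(
        nsteps, dt, 0.0,
        state.v, state.m, state.h, state.n, state.l, state.mq, state.mca,
        state.q, state.ca, state.nai, state.nao, state.ki, state.ko,
        state.ena, state.ek,
        g.parent, g.gax_uS, gax_tot, cdt, gleak_abs, model.eleak,
        gna_abs, gkdr_abs, gkcnq_abs, gca_abs, gsk_abs,
        na_idx, kdr_idx, kcnq_idx, ca_idx, sk_idx,
        area,
        tabs["v0"], tabs["inv_dv"],
        tabs["minf"], tabs["mexp"], tabs["hinf"], tabs["hexp"],
        tabs["ninf"], tabs["nexp"], tabs["linf"], tabs["lexp"],
        tabs["mqinf"], tabs["mqexp"], tabs["mcainf"], tabs["mcaexp"],
        tabs["l0"], tabs["inv_dl"], tabs["qinf"], tabs["qexp"],
        p.ca_rest_mM,
        model.ion_dynamics, model.pump, ipmax, p.km_pump_mM,
        sov_i, sov_o, jna0, jk0,
        stim_comp, stim_amp, stim_t0, stim_t1,
        rec_idx, stride, out_v, out_ca, out_ena, out_ek,
    )

    if not np.all(np.isfinite(out_v)):
        raise FloatingPointError(
            "non-finite membrane potential encountered; "
            f"dt={dt} ms, max|V|={np.nanmax(np.abs(out_v)):.3g} mV"
        )

    t = np.arange(nrec) * (stride * dt)
    return Trace(
        t_ms=t,
        sites=tuple(tuple(s) for s in config.record_sites),
        site_index=rec_idx,
        v_mV=out_v,
        ca_mM=out_ca,
        ena_mV=out_ena,
        ek_mV=out_ek,
    )
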