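"""Experiment presets, toy oracle morphologies and synthetic traces.

Everything needed to exercise the package is generated here: no external
data.  Presets pin down the full configuration of each standard experiment
(geometry overrides, mechanism densities, stimulus protocol, sweep grids);
toy models carry independent analytic or brute-force reference solutions so
the solver can be validated against something it does not share code with.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import (
    SectionSpec,
    NeuronGeometry,
    PassiveParams,
    CompartmentGraph,
    build_geometry,
    discretize,
)
from .solver import Trace

__all__ = [
    "ExperimentPreset",
    "make_preset",
    "list_presets",
    "make_toy_models",
    "make_synthetic_trace",
    "single_compartment_graph",
    "two_compartment_graph",
    "uniform_cable_graph",
]


@dataclass(frozen=True)
class ExperimentPreset:
    """Complete, reproducible configuration of one standard experiment."""

    name: str
    note: str
    geometry_overrides: dict = field(default_factory=dict)
    densities: dict = field(default_factory=dict)    # build_membrane kwargs
    protocol: dict = field(default_factory=dict)     # stimulus description
    sweep_grids: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


_STANDARD_PROTOCOL = {
    "stim_site": ["peripheral", 4600.0],
    "amplitude_nA": 0.2,
    "width_ms": 1.0,
    "n_stimuli": 20,
    "detect_site": ["central", 5000.0],
}

_PRESETS = {
    "fig1_gr": ExperimentPreset(
        name="fig1_gr",
        note="3/2-power geometric ratios at the T-junction versus stem "
             "diameter, for spikes originating from each of the three "
             "branches; central axon 0.4 um (variant: 0.8 um).",
        sweep_grids={
            "stem_diameters_um": [round(float(x), 2) for x in np.arange(0.1, 2.01, 0.01)],
            "central_diameters_um": [0.4, 0.8],
        },
    ),
    "fig2_impedance": ExperimentPreset(
        name="fig2_impedance",
        note="Input impedance at 250 Hz (spike half-width ~2 ms): spatial "
             "profile +-100 um around the junction, and junction impedance "
             "vs stem length x diameter and soma diameter x stem diameter.",
        sweep_grids={
            "frequency_hz": 250.0,
            "stem_lengths_um": [25, 50, 75, 100, 150, 200, 300, 400],
            "stem_diameters_um": [0.8, 1.0, 1.2, 1.4, 1.6, 2.0],
            "soma_diameters_um": [10, 15, 20, 25, 30, 40, 50],
            "central_diameters_um": [0.4, 0.8],
        },
    ),
    "fig3_amplitude": ExperimentPreset(
        name="fig3_amplitude",
        note="Early-mode spike amplitude profile +-100 um around the "
             "junction for axonal NaV densities around the critical value; "
             "single orthodromic stimulus.",
        densities={"gkdr": 40.0},
        protocol={**_STANDARD_PROTOCOL, "n_stimuli": 1},
        sweep_grids={"gna_axonal": [30.0, 35.0, 40.0]},
    ),
    "fig4_transfer": ExperimentPreset(
        name="fig4_transfer",
        note="DC soma-to-junction voltage transfer ratio vs stem length, "
             "stem diameter and soma diameter (passive model).",
        sweep_grids={
            "stem_lengths_um": [25, 50, 75, 100, 150, 200, 300],
            "stem_diameters_um": [0.8, 1.0, 1.2, 1.4, 1.6],
            "soma_diameters_um": [10, 25, 50],
        },
    ),
    "fig5_kcnq": ExperimentPreset(
        name="fig5_kcnq",
        note="KCNQ density vs following frequency; 75 um stem; KCNQ in "
             "soma, stem and proximal axons; 20-pulse trains.",
        geometry_overrides={"stem_length_um": 75.0},
        densities={"gkcnq": 0.4},
        protocol=_STANDARD_PROTOCOL,
        sweep_grids={"gkcnq": [0.0, 0.2, 0.4, 0.8, 1.6]},
    ),
    "fig5_ectopic": ExperimentPreset(
        name="fig5_ectopic",
        note="Ectopic antidromic spikes during a 40 Hz train with KCNQ at "
             "0.4 mS/cm^2; recordings at 2.6 and 5.1 mm in the peripheral "
             "axon.",
        geometry_overrides={"stem_length_um": 75.0},
        densities={"gkcnq": 0.4},
        protocol={**_STANDARD_PROTOCOL, "frequency_hz": 40.0,
                  "record_sites": [["peripheral", 2600.0], ["peripheral", 5100.0]]},
    ),
    "fig6_gna_kcnq": ExperimentPreset(
        name="fig6_gna_kcnq",
        note="Following frequency vs somatic NaV density x KCNQ density "
             "(75 um stem); doubling somatic NaV counters the M-current.",
        geometry_overrides={"stem_length_um": 75.0},
        protocol=_STANDARD_PROTOCOL,
        sweep_grids={"gna_somatic": [20.0, 40.0], "gkcnq": [0.2, 0.4, 0.8]},
    ),
    "fig6_stem_length": ExperimentPreset(
        name="fig6_stem_length",
        note="Following frequency and junction spike amplitude vs stem "
             "length; somatic influence fades for electrotonically long "
             "stems.",
        protocol=_STANDARD_PROTOCOL,
        sweep_grids={"stem_length_um": [25, 50, 75, 100, 150, 200, 300],
                     "gna_somatic": [20.0, 40.0]},
    ),
    "fig7_sk_soma": ExperimentPreset(
        name="fig7_sk_soma",
        note="Somatic SK (with CaV and Ca dynamics) vs propagation "
             "reliability at 10 Hz and following frequency; SK density grid "
             "in 0.25 mS/cm^2 steps.",
        densities={"gca": 30.0, "gsk": 1.0, "sk_location": "soma"},
        protocol={**_STANDARD_PROTOCOL, "frequency_hz": 10.0},
        sweep_grids={"gsk": [round(float(x), 2) for x in np.arange(0.25, 2.01, 0.25)],
                     "gna_axonal": [40.0, 60.0]},
    ),
    "fig7_sk_axonal": ExperimentPreset(
        name="fig7_sk_axonal",
        note="SK + CaV placed in the proximal axons instead of the soma; "
             "the density required for failure at 10 Hz is several-fold "
             "higher (grid includes 7.5 mS/cm^2).",
        densities={"gca": 30.0, "gsk": 7.5, "sk_location": "axonal"},
        protocol={**_STANDARD_PROTOCOL, "frequency_hz": 10.0},
        sweep_grids={"gsk": [1.0, 2.5, 5.0, 7.5, 10.0]},
    ),
    "fig8_pump": ExperimentPreset(
        name="fig8_pump",
        note="Ion accumulation with an electrogenic Na/K pump: 100 Hz x 20 "
             "spikes with low vs 1000x pump density, alone and combined "
             "with SK at 0.2 mS/cm^2.",
        densities={"ion_dynamics": True, "pump": True},
        protocol={**_STANDARD_PROTOCOL, "frequency_hz": 100.0},
        sweep_grids={"i_pump_max": [1e-4, 0.1], "gsk": [0.0, 0.2]},
    ),
}


def list_presets() -> list:
    return sorted(_PRESETS)


def make_preset(name: str) -> ExperimentPreset:
    """Look up a standard experiment preset by name."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        ) from None


# ---------------------------------------------------------------------------
# Toy morphologies with independent reference solutions
# ---------------------------------------------------------------------------

def _chain_graph(lengths_um, diams_um, nsegs, passive=None) -> CompartmentGraph:
    """Discretize an unbranched chain of cylinders as a degenerate 'neuron'.

    Reuses the standard section machinery by mapping the chain onto the
    soma+stem sections and shrinking every other section to negligible size.
    """
    passive = passive or PassiveParams()
    eps = {"length_um": 1e-3, "diameter_um": 1e-3, "nseg": 1}
    secs = {
        "soma": SectionSpec("soma", lengths_um[0], diams_um[0], nsegs[0]),
        "stem": SectionSpec("stem", *(
            (lengths_um[1], diams_um[1], nsegs[1]) if len(lengths_um) > 1
            else (1e-3, diams_um[0], 1)
        )),
        "peripheral_proximal": SectionSpec("peripheral_proximal", **eps),
        "peripheral_distal": SectionSpec("peripheral_distal", **eps),
        "central_proximal": SectionSpec("central_proximal", **eps),
        "central_distal": SectionSpec("central_distal", **eps),
    }
    return discretize(NeuronGeometry(secs), passive)


def single_compartment_graph(diameter_um: float = 25.0, length_um: float = 25.0,
                             passive: PassiveParams | None = None) -> CompartmentGraph:
    """One isolated compartment (plus vestigial micro-sections)."""
    return _chain_graph([length_um], [diameter_um], [1], passive)


def two_compartment_graph(passive: PassiveParams | None = None) -> CompartmentGraph:
    """Two coupled compartments for the scalar-ODE oracle."""
    return _chain_graph([25.0, 50.0], [25.0, 2.0], [1, 1], passive)


def uniform_cable_graph(length_um: float = 2000.0, diameter_um: float = 0.8,
                        nseg: int = 200, passive: PassiveParams | None = None) -> CompartmentGraph:
    """Uniform unbranched cable (vestigial soma stub at one end)."""
    return _chain_graph([1e-3, length_um], [diameter_um, diameter_um], [1, nseg],
                        passive)


def make_toy_models() -> dict:
    """Toy fixtures, each with an independent reference attached.

    Keys: 'single' (RC step response, tau = Rm*Cm = 10 ms), 'two' (coupled
    two-ODE system integrated by scipy), 'cable' (semi-infinite cable
    closed form), 'symmetric_y' (full neuron with equal daughter diameters:
    responses in the two branches must be identical).
    """
    passive = PassiveParams()

    def rc_step_response(t_ms, i_nA, area_cm2):
        g_uS = (1e3 / passive.rm_ohm_cm2) * area_cm2 * 1e3
        tau = passive.rm_ohm_cm2 * passive.cm_uF_cm2 * 1e-3  # ms
        return i_nA / g_uS * (1.0 - np.exp(-np.asarray(t_ms) / tau))

    def two_compartment_ode(graph, i_nA, t_ms):
        """Reference: scipy integration of the two-ODE passive system."""
        from scipy.integrate import solve_ivp

        sel = np.where(graph.area_cm2 > 1e-9)[0]
        assert len(sel) == 2
        c = graph.c_nF[sel]
        gl = graph.gleak_mS_cm2 * graph.area_cm2[sel] * 1e3
        # coupling between the two real compartments (through vestigial
        # micro-sections whose axial resistance is negligible)
        g12 = 1.0 / sum(
            1.0 / graph.gax_uS[i]
            for i in range(sel[0] + 1, sel[1] + 1)
            if graph.gax_uS[i] > 0
        )

        def rhs(t, v):
            i_ext = np.array([i_nA, 0.0])
            ax = g12 * np.array([v[1] - v[0], v[0] - v[1]])
            return (i_ext - gl * (v - (-60.0)) + ax) / c

        sol = solve_ivp(rhs, (0.0, t_ms[-1]), [-60.0, -60.0], t_eval=t_ms,
                        rtol=1e-10, atol=1e-10, method="LSODA")
        return sol.y.T

    def semi_infinite_dc_impedance(diameter_um):
        d_cm = diameter_um * 1e-4
        return (2.0 / math.pi) * math.sqrt(
            passive.rm_ohm_cm2 * passive.ra_ohm_cm
        ) / d_cm**1.5 * 1e-6  # MOhm

    return {
        "single": {
            "graph": single_compartment_graph(),
            "reference": rc_step_response,
            "tau_ms": passive.rm_ohm_cm2 * passive.cm_uF_cm2 * 1e-3,
        },
        "two": {
            "graph": two_compartment_graph(),
            "reference": two_compartment_ode,
        },
        "cable": {
            "graph": uniform_cable_graph(),
            "reference": semi_infinite_dc_impedance,
        },
        "symmetric_y": {
            "geometry": build_geometry({"central_diameter_um": 0.8}),
        },
    }


def make_synthetic_trace(
    spike_times_ms,
    duration_ms: float = 100.0,
    dt_ms: float = 0.05,
    amplitude_mV: float = 75.0,
    width_ms: float = 1.0,
    v_rest_mV: float = -60.0,
    site=("synthetic", 0.0),
) -> Trace:
    """Constructed trace with triangular spikes at known times.

    Used to unit-test the detectors; peak value is v_rest + amplitude at
    exactly the requested times.
    """
    times = np.sort(np.asarray(spike_times_ms, dtype=float))
    t = np.arange(0.0, duration_ms + 1e-9, dt_ms)
    v = np.full_like(t, v_rest_mV)
    for ts in times:
        tri = amplitude_mV * np.clip(1.0 - np.abs(t - ts) / (width_ms / 2.0), 0.0, None)
        v = np.maximum(v, v_rest_mV + tri)
    z = np.zeros((len(t), 1))
    return Trace(
        t_ms=t,
        sites=(tuple(site),),
        site_index=np.array([0]),
        v_mV=v[:, None],
        ca_mM=z + 5e-5,
        ena_mV=z + 55.0,
        ek_mV=z - 90.0,
        v_rest_mV=v_rest_mV,
    )
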