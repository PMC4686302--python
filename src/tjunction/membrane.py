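"""Ionic membrane mechanisms for the sensory-neuron model.

Mechanisms: fast voltage-gated Na+ (NaV, m^3 h), delayed-rectifier K+
(KDR, n^3 l with slow inactivation), slowly activating KCNQ/Kv7 M-current
(single gate), high-threshold L-type Ca2+ current (m^2), SK-type
Ca2+-activated K+ current (q^2) with first-order intracellular Ca2+
dynamics, an ohmic leak whose reversal is solved per compartment to pin the
resting potential at -60 mV, and optional Na+/K+ concentration dynamics with
an electrogenic 3:2 Na+-K+ pump.

Units throughout: mV, ms, mM, mS/cm^2, mA/cm^2.  Temperature is fixed at
308 K (35 C); the KDR exponential slopes are F/RT at that temperature and no
additional Q10 scaling is applied anywhere.

The NaV rate constants are written in a rest-relative voltage convention
(V' = V - V_REF); V_REF, the KDR rate scales A0_N/A0_L and the somatic CaV
density GCA_SOMATIC_DEFAULT are the model's one-time calibration constants
(see docs/methods.md) and are exposed in every run's provenance dump.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import (
    CompartmentGraph,
    SOMA,
    STEM,
    JUNCTION,
    PP,
    PD,
    CP,
    CD,
)

__all__ = [
    "KineticsParams",
    "MembraneModel",
    "nav_rates",
    "kdr_rates",
    "kcnq_rates",
    "cav_rates",
    "eca_nernst",
    "sk_rates",
    "ca_dynamics_step",
    "pump_current",
    "solve_eleak",
    "build_membrane",
    "resting_gates",
    "resting_current_density",
]

# physical constants
R_GAS = 8.314          # J/(mol K)
FARADAY = 96_485.0     # C/mol
T_KELVIN = 308.0
RT_F_MV = 1e3 * R_GAS * T_KELVIN / FARADAY        # ~26.54 mV
ECA_COEF_MV = 3.08e5 * R_GAS / (2.0 * FARADAY)    # ~13.27 mV per ln unit

# KDR exponential slopes: z-factor * F/RT with F/RT = 9.648e4/2562.35 per volt
_F_RT_PER_MV = 9.648e4 / 2562.35 * 1e-3
SLOPE_N = 5e-3 * 9.648e4 / 2562.35   # 0.1883 / mV
SLOPE_L = 2e-3 * 9.648e4 / 2562.35   # 0.0753 / mV

# one-time calibration constants (frozen; see docs/methods.md)
V_REF_DEFAULT = -57.8      # mV, NaV activation voltage reference
DV_H_DEFAULT = 0.0         # mV, extra shift of the NaV inactivation frame
S_H_DEFAULT = 3.0          # NaV inactivation rate scale (tau_h multiplier)
A0_N_DEFAULT = 0.5         # 1/ms, KDR activation rate scale
A0_L_DEFAULT = 0.02        # 1/ms, KDR inactivation rate scale
GCA_SOMATIC_DEFAULT = 30.0  # mS/cm^2, L-type Ca density accompanying SK


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-7
    denom = np.expm1(np.clip(x / y, -500, 500))
    denom = np.where(small, 1.0, denom)  # placeholder where the limit applies
    return np.where(small, y * (1.0 - x / (2.0 * y)), x / denom)


@dataclass(frozen=True)
class KineticsParams:
    """Kinetic constants shared by all compartments."""

    v_ref: float = V_REF_DEFAULT
    dv_h: float = DV_H_DEFAULT
    s_h: float = S_H_DEFAULT
    a0_n: float = A0_N_DEFAULT
    a0_l: float = A0_L_DEFAULT
    sk_divisor: float = -4.0        # printed value; cited source family uses -4.5
    ca_rest_mM: float = 5e-5        # 50 nM
    ena_mV: float = 55.0
    ek_mV: float = -90.0
    erest_mV: float = -60.0
    km_pump_mM: float = 10.0        # pump half-saturation in [Na]_i
    # initial ion pools (satisfy E_Na=+55, E_K=-90 at 308 K)
    nai_mM: float = 14.0
    nao_mM: float = 111.0
    ki_mM: float = 140.0
    ko_mM: float = 4.7


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

def nav_rates(v, v_ref: float = V_REF_DEFAULT, dv_h: float = DV_H_DEFAULT,
              s_h: float = S_H_DEFAULT):
    """NaV rate constants (alpha_m, beta_m, alpha_h, beta_h) in 1/ms.

    Traub-family forms evaluated at a rest-relative potential; activation
    uses V' = V - v_ref and inactivation V'' = V - (v_ref + dv_h), placing
    the inactivation curve ``dv_h`` millivolts below activation as in
    DRG NaV1.7/NaV1.8 channels.  The activation rates carry the
    (exp(x)-1) denominator with removable singularities handled
    analytically.
    """
    vp = np.asarray(v, dtype=float) - v_ref
    vh = np.asarray(v, dtype=float) - (v_ref + dv_h)
    a_m = 0.55 * _vtrap(7.1 - vp, 4.0)
    b_m = 0.48 * _vtrap(vp - 46.1, 5.0)
    a_h = 0.22 * np.exp(np.clip((23.0 - vh) / 18.0, -500, 500)) / s_h
    b_h = 6.92 / (1.0 + np.exp(np.clip((46.0 - vh) / 5.0, -500, 500))) / s_h
    return a_m, b_m, a_h, b_h


def kdr_rates(v, a0_n: float = A0_N_DEFAULT, a0_l: float = A0_L_DEFAULT):
    """KDR gating: returns (n_inf, tau_n, l_inf, tau_l).

    Borg-Graham parameterization for activation: n_inf = 1/(1 + alpha(V)),
    tau_n = beta(V)/(a0_n*(1 + alpha(V))), with exponential slopes
    0.1883/mV about V1/2 = -32 mV.  Slow inactivation l has the printed
    steady state (V1/2 = -61 mV, slope 0.0753/mV) and a voltage-independent
    time constant tau_l = 1/(2*a0_l).
    """
    v = np.asarray(v, dtype=float)
    a_n = np.exp(np.clip(-SLOPE_N * (v + 32.0), -500, 500))
    b_n = np.exp(np.clip(-SLOPE_L * (v + 32.0), -500, 500))
    a_l = np.exp(np.clip(SLOPE_L * (v + 61.0), -500, 500))
    b_l = np.exp(np.clip(-SLOPE_L * (v + 32.0), -500, 500))
    n_inf = 1.0 / (1.0 + a_n)
    tau_n = b_n / (a0_n * (1.0 + a_n))
    l_inf = 1.0 / (1.0 + a_l)
    # slow inactivation: single calibrated timescale (the value the printed
    # rate pair takes at the half-voltage); the literal voltage dependence
    # collapses at spike potentials and is not used
    tau_l = np.full_like(np.asarray(v, dtype=float), 1.0 / (2.0 * a0_l))
    return n_inf, tau_n, l_inf, tau_l


def kcnq_rates(v):
    """KCNQ (M-current) two-state gate: returns (m_inf, tau_m [ms]).

    Logistic activation with V1/2 = -35 mV, slope 10 mV; bell-shaped time
    constant peaking at V1/2 (the /3.54 factor is the printed temperature
    adjustment).
    """
    v = np.asarray(v, dtype=float)
    x = np.clip((v + 35.0) / 20.0, -250, 250)
    m_inf = 1.0 / (1.0 + np.exp(np.clip(-(v + 35.0) / 10.0, -500, 500)))
    tau = (1000.0 / (3.3 * (np.exp(x) + np.exp(-x)))) / 3.54
    return m_inf, tau


def cav_rates(v):
    """High-threshold Ca channel activation rates (alpha_m, beta_m), 1/ms.

    The gate enters the current squared (m^2); the removable singularity of
    alpha at V = 81.5 mV takes its limit value 156.9/ms.
    """
    v = np.asarray(v, dtype=float)
    a = 15.69 * _vtrap(81.5 - v, 10.0)
    b = 0.29 * np.exp(np.clip(-v / 10.86, -500, 500))
    return a, b


def eca_nernst(ca_i_mM, ca_o_mM: float = 2.0):
    """Ca2+ Nernst potential (mV) at 308 K with 2 mM extracellular Ca2+."""
    ca = np.asarray(ca_i_mM, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("[Ca]_i must be > 0")
    out = ECA_COEF_MV * np.log(ca_o_mM / ca)
    return float(out) if out.ndim == 0 else out


def sk_rates(ca_i_mM, divisor: float = -4.0):
    """SK gate rate constants (alpha_q = opening, beta_q = closing), 1/ms.

    Both rates are exponentials of 12*log10([Ca]_i in mM); the opening rate
    grows and the closing rate shrinks with [Ca]_i, so q_inf = a/(a+b)
    increases with calcium (half-activation ~1.3 uM with the default
    divisor).  The gate enters the current squared (q^2).
    """
    ca = np.asarray(ca_i_mM, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("[Ca]_i must be > 0")
    logc = 12.0 * np.log10(ca)
    a_q = 0.006 * np.exp(np.clip((logc + 60.4) / 35.0, -500, 500))
    b_q = 0.00246 * np.exp(np.clip((logc + 28.48) / divisor, -500, 500))
    return a_q, b_q


def ca_dynamics_step(ca_i_mM, i_ca_mA_cm2, dt_ms, ca_rest_mM: float = 5e-5):
    """Explicit-Euler update of intracellular Ca2+.

    d[Ca]/dt = -0.026 * I_Ca - ([Ca] - [Ca]_rest)/20, with I_Ca in mA/cm^2
    (inward currents negative, raising [Ca]).  The pool is floored at a tiny
    positive value.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    ca = np.asarray(ca_i_mM, dtype=float)
    dca = -0.026 * np.asarray(i_ca_mA_cm2, dtype=float) - (ca - ca_rest_mM) / 20.0
    out = np.maximum(ca + dt_ms * dca, 1e-12)
    return float(out) if out.ndim == 0 else out


def pump_current(nai_mM, i_pump_max_mA_cm2, km_mM: float = 10.0):
    """Electrogenic Na+/K+ pump: returns (I_pump_Na, I_pump_K) in mA/cm^2.

    The net (outward, hyperpolarizing) pump current is
    I = I_max * [Na]_i/([Na]_i + Km); with 3 Na+ out : 2 K+ in per net
    charge, the ionic components are I_Na = +3I (efflux) and I_K = -2I
    (influx).
    """
    nai = np.asarray(nai_mM, dtype=float)
    if np.any(nai < 0):
        raise ValueError("[Na]_i must be >= 0")
    inet = np.asarray(i_pump_max_mA_cm2, dtype=float) * nai / (nai + km_mM)
    i_na, i_k = 3.0 * inet, -2.0 * inet
    if np.ndim(inet) == 0:
        return float(i_na), float(i_k)
    return i_na, i_k


# ---------------------------------------------------------------------------
# Assembled per-compartment membrane model
# ---------------------------------------------------------------------------

@dataclass
class MembraneModel:
    """Per-compartment mechanism densities plus shared kinetics parameters."""

    graph: CompartmentGraph
    params: KineticsParams = field(default_factory=KineticsParams)
    gna: np.ndarray = None      # mS/cm^2 per compartment
    gkdr: np.ndarray = None
    gkcnq: np.ndarray = None
    gca: np.ndarray = None
    gsk: np.ndarray = None
    gleak: np.ndarray = None
    eleak: np.ndarray = None    # solved by solve_eleak
    ion_dynamics: bool = False
    pump: bool = False
    i_pump_max: float = 0.0     # mA/cm^2 (uniform)
    shell_thickness_um: float = 0.1

    def __post_init__(self) -> None:
        n = self.graph.n
        zeros = lambda: np.zeros(n)
        if self.gna is None:
            self.gna = zeros()
        if self.gkdr is None:
            self.gkdr = zeros()
        if self.gkcnq is None:
            self.gkcnq = zeros()
        if self.gca is None:
            self.gca = zeros()
        if self.gsk is None:
            self.gsk = zeros()
        if self.gleak is None:
            self.gleak = np.full(n, self.graph.gleak_mS_cm2)
            self.gleak[self.graph.branch == JUNCTION] = 0.0
        for name in ("gna", "gkdr", "gkcnq", "gca", "gsk", "gleak"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative density in {name}")

    def provenance(self) -> dict:
        """Machine-readable channel-parameter dump for run logs."""
        dens = {}
        for name in ("gna", "gkdr", "gkcnq", "gca", "gsk"):
            arr = getattr(self, name)
            per_branch = {}
            for code in np.unique(self.graph.branch):
                vals = np.unique(np.round(arr[self.graph.branch == code], 9))
                per_branch[int(code)] = vals.tolist()
            dens[name] = per_branch
        return {
            "params": asdict(self.params),
            "densities_mS_cm2_by_branch": dens,
            "ion_dynamics": self.ion_dynamics,
            "pump": self.pump,
            "i_pump_max_mA_cm2": self.i_pump_max,
        }


def resting_gates(model: MembraneModel, v: float = -60.0):
    """Steady-state gating values at voltage v (dict of arrays, scalar Ca)."""
    p = model.params
    a_m, b_m, a_h, b_h = nav_rates(v, p.v_ref, p.dv_h, p.s_h)
    n_inf, _, l_inf, _ = kdr_rates(v, p.a0_n, p.a0_l)
    mq_inf, _ = kcnq_rates(v)
    a_c, b_c = cav_rates(v)
    a_q, b_q = sk_rates(p.ca_rest_mM, p.sk_divisor)
    return {
        "m": float(a_m / (a_m + b_m)),
        "h": float(a_h / (a_h + b_h)),
        "n": float(n_inf),
        "l": float(l_inf),
        "mq": float(mq_inf),
        "mca": float(a_c / (a_c + b_c)),
        "q": float(a_q / (a_q + b_q)),
    }


def resting_current_density(model: MembraneModel, v: float = -60.0) -> np.ndarray:
    """Total non-leak resting membrane current density (uA/cm^2) at v."""
    p = model.params
    g = resting_gates(model, v)
    eca = eca_nernst(p.ca_rest_mM)
    i = (
        model.gna * g["m"] ** 3 * g["h"] * (v - p.ena_mV)
        + model.gkdr * g["n"] ** 3 * g["l"] * (v - p.ek_mV)
        + model.gkcnq * g["mq"] * (v - p.ek_mV)
        + model.gca * g["mca"] ** 2 * (v - eca)
        + model.gsk * g["q"] ** 2 * (v - p.ek_mV)
    )
    if model.pump:
        i_na, i_k = pump_current(p.nai_mM, model.i_pump_max, p.km_pump_mM)
        i = i + (i_na + i_k) * 1e3  # mA/cm^2 -> uA/cm^2
    return i


def solve_eleak(model: MembraneModel, v_rest: float = -60.0) -> np.ndarray:
    """Solve the leak reversal so net membrane current vanishes at rest.

    Per compartment: g_leak*(V_rest - E_leak) + I_active(V_rest) = 0, hence
    E_leak = V_rest + I_active/g_leak.  Sets ``model.eleak`` and returns it.
    """
    i_rest = resting_current_density(model, v_rest)  # uA/cm^2
    eleak = np.full(model.graph.n, v_rest)
    mask = model.gleak > 0
    eleak[mask] = v_rest + i_rest[mask] / model.gleak[mask]
    if np.any(~np.isfinite(eleak)) or np.any(np.abs(eleak) > 2000):
        raise ValueError("E_leak calibration infeasible for this configuration")
    model.eleak = eleak
    return eleak


def build_membrane(
    graph: CompartmentGraph,
    params: KineticsParams | None = None,
    *,
    passive_only: bool = False,
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
    """Assemble the standard model's density map.

    NaV and KDR are expressed everywhere (densities in mS/cm^2), with the
    somatic NaV density defaulting to half the axonal value.  KCNQ, when
    present, occupies the soma, stem and the 100-um proximal peripheral and
    central segments.  The CaV + SK pair (with Ca2+ dynamics) is placed
    either on the soma (``sk_location='soma'``) or on the proximal axonal
    segments (``'axonal'``).  The leak reversal is calibrated on return.
    """
    params = params or KineticsParams()
    model = MembraneModel(graph, params)
    br = graph.branch
    if not passive_only:
        if gna_somatic is None:
            gna_somatic = gna_axonal / 2.0
        model.gna[:] = gna_axonal
        model.gna[br == SOMA] = gna_somatic
        model.gkdr[:] = gkdr
        if gkcnq:
            kcnq_mask = np.isin(br, (SOMA, STEM, PP, CP))
            model.gkcnq[kcnq_mask] = gkcnq
        if gca or gsk:
            if sk_location == "soma":
                sk_mask = br == SOMA
            elif sk_location == "axonal":
                sk_mask = np.isin(br, (PP, CP))
            else:
                raise ValueError("sk_location must be 'soma' or 'axonal'")
            model.gca[sk_mask] = gca
            model.gsk[sk_mask] = gsk
        model.gna[br == JUNCTION] = 0.0
        model.gkdr[br == JUNCTION] = 0.0
        model.gkcnq[br == JUNCTION] = 0.0
    model.ion_dynamics = ion_dynamics
    model.pump = pump
    model.i_pump_max = i_pump_max
    solve_eleak(model)
    return model
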