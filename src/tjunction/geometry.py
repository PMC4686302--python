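"""Morphology of a pseudo-unipolar sensory neuron and its compartmentalization.

The cell is a cylindrical soma joined by a stem axon to the T-junction, where
the peripheral axon (toward the receptive field) and the central axon (toward
the spinal cord) meet.  Each axonal section is a cylinder subdivided into
equal-length compartments; the T-junction itself is represented by a
zero-area node shared by the three meeting sections, so that "the junction"
is a well-defined recording location at arc distance 0.

Signed arc distances are measured along the axon from the junction node:
negative on the peripheral side, positive on the central side.  The stem and
soma carry positive distances along their own branch and are distinguished
by their branch label.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SectionSpec",
    "NeuronGeometry",
    "PassiveParams",
    "CompartmentGraph",
    "geometric_ratio",
    "gr_sweep",
    "build_geometry",
    "discretize",
    "DEFAULT_SECTIONS",
]

# branch codes used in CompartmentGraph.branch
SOMA, STEM, JUNCTION, PP, PD, CP, CD = 0, 1, 2, 3, 4, 5, 6
BRANCH_NAMES = {
    SOMA: "soma",
    STEM: "stem",
    JUNCTION: "junction",
    PP: "peripheral_proximal",
    PD: "peripheral_distal",
    CP: "central_proximal",
    CD: "central_distal",
}
PERIPHERAL = (PP, PD)
CENTRAL = (CP, CD)


@dataclass(frozen=True)
class SectionSpec:
    """One unbranched cylindrical section of the morphology."""

    name: str
    length_um: float
    diameter_um: float
    nseg: int = 100

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError(f"section {self.name!r}: length must be > 0")
        if self.diameter_um <= 0:
            raise ValueError(f"section {self.name!r}: diameter must be > 0")
        if self.nseg < 1:
            raise ValueError(f"section {self.name!r}: nseg must be >= 1")

    @property
    def area_cm2(self) -> float:
        """Lateral cylinder area (no end caps), in cm^2."""
        return math.pi * self.diameter_um * self.length_um * 1e-8


DEFAULT_SECTIONS = {
    "soma": SectionSpec("soma", 25.0, 25.0, 100),
    "stem": SectionSpec("stem", 150.0, 1.4, 100),
    "peripheral_proximal": SectionSpec("peripheral_proximal", 100.0, 0.8, 100),
    "peripheral_distal": SectionSpec("peripheral_distal", 5000.0, 0.8, 100),
    "central_proximal": SectionSpec("central_proximal", 100.0, 0.4, 100),
    "central_distal": SectionSpec("central_distal", 5000.0, 0.4, 100),
}

# fixed pseudo-unipolar topology: soma—stem—junction—{peripheral, central}
TOPOLOGY = (
    ("soma", "stem"),
    ("stem", "junction"),
    ("junction", "peripheral_proximal"),
    ("peripheral_proximal", "peripheral_distal"),
    ("junction", "central_proximal"),
    ("central_proximal", "central_distal"),
)


@dataclass(frozen=True)
class NeuronGeometry:
    """Collection of sections plus the (fixed) pseudo-unipolar topology."""

    sections: dict
    topology: tuple = TOPOLOGY

    def __post_init__(self) -> None:
        missing = set(DEFAULT_SECTIONS) - set(self.sections)
        if missing:
            raise ValueError(f"geometry is missing sections: {sorted(missing)}")

    def section(self, name: str) -> SectionSpec:
        return self.sections[name]

    def with_overrides(self, **overrides) -> "NeuronGeometry":
        """Return a copy with per-section field overrides.

        Keys are ``<section>_<field>``, e.g. ``stem_length_um=75`` or
        ``central_diameter_um=0.8`` (applied to both central sections).
        """
        secs = dict(self.sections)

        def _patch(name, **kw):
            secs[name] = replace(secs[name], **kw)

        for key, value in overrides.items():
            matched = False
            for sec in list(secs):
                for fld in ("length_um", "diameter_um", "nseg"):
                    if key == f"{sec}_{fld}":
                        _patch(sec, **{fld: value})
                        matched = True
            # branch-wide shorthands
            if key == "central_diameter_um":
                _patch("central_proximal", diameter_um=value)
                _patch("central_distal", diameter_um=value)
                matched = True
            elif key == "peripheral_diameter_um":
                _patch("peripheral_proximal", diameter_um=value)
                _patch("peripheral_distal", diameter_um=value)
                matched = True
            elif key == "soma_diameter_um":
                _patch("soma", diameter_um=value, length_um=value)
                matched = True
            elif key == "nseg_scale":
                for sec in list(secs):
                    _patch(sec, nseg=int(round(secs[sec].nseg * value)))
                matched = True
            if not matched:
                raise KeyError(f"unknown geometry override: {key!r}")
        return NeuronGeometry(secs, self.topology)


def build_geometry(config: dict | None = None) -> NeuronGeometry:
    """Build the exemplar morphology, optionally overriding dimensions.

    Defaults: soma 25x25 um cylinder; stem 1.4 um x 150 um; peripheral axon
    0.8 um (100 um proximal + 5 mm distal); central axon 0.4 um (100 um
    proximal + 5 mm distal); 100 compartments per axonal section.
    """
    geom = NeuronGeometry(dict(DEFAULT_SECTIONS))
    if config:
        geom = geom.with_overrides(**config)
    return geom


# ---------------------------------------------------------------------------
# Geometric (3/2-power) ratio
# ---------------------------------------------------------------------------

def geometric_ratio(parent_diameter, daughter_diameters) -> float:
    """3/2-power diameter ratio at a branch point.

    GR = (d1^3/2 + d2^3/2) / d_parent^3/2.  GR > 1 indicates an impedance
    mismatch that attenuates spikes crossing from parent into daughters.
    """
    d1, d2 = daughter_diameters
    parent = np.asarray(parent_diameter, dtype=float)
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(parent <= 0) or np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("all diameters must be > 0")
    gr = (d1**1.5 + d2**1.5) / parent**1.5
    return float(gr) if gr.ndim == 0 else gr


_DIRECTIONS = ("stem-origin", "peripheral-origin", "central-origin")


def gr_sweep(
    stem_diameters,
    direction: str,
    peripheral_diameter: float = 0.8,
    central_diameter: float = 0.4,
):
    """GR at the T-junction as the stem diameter is swept.

    ``direction`` names the branch the spike originates from (the parent):
    ``stem-origin`` (somatically generated), ``peripheral-origin``
    (orthodromic) or ``central-origin`` (antidromic).

    Returns a pandas DataFrame with columns stem_diameter_um, direction, GR.
    """
    import pandas as pd

    if direction not in _DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; expected one of {_DIRECTIONS}")
    stem = np.asarray(stem_diameters, dtype=float)
    if direction == "stem-origin":
        gr = geometric_ratio(stem, (np.full_like(stem, peripheral_diameter),
                                    np.full_like(stem, central_diameter)))
    elif direction == "peripheral-origin":
        gr = geometric_ratio(np.full_like(stem, peripheral_diameter),
                             (stem, np.full_like(stem, central_diameter)))
    else:  # central-origin
        gr = geometric_ratio(np.full_like(stem, central_diameter),
                             (stem, np.full_like(stem, peripheral_diameter)))
    return pd.DataFrame(
        {"stem_diameter_um": stem, "direction": direction, "GR": np.atleast_1d(gr)}
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PassiveParams:
    """Uniform passive cable parameters."""

    ra_ohm_cm: float = 100.0      # axial resistivity
    cm_uF_cm2: float = 1.0        # specific capacitance
    rm_ohm_cm2: float = 10_000.0  # specific membrane resistivity


@dataclass
class CompartmentGraph:
    """Discretized tree: one row of each array per compartment.

    Compartments are ordered so that ``parent[i] < i`` (Hines ordering) with
    the soma's first compartment as the root.  ``gax_uS[i]`` is the axial
    conductance coupling compartment i to its parent (symmetric by
    construction); the junction node has zero area and capacitance.
    """

    n: int
    parent: np.ndarray        # int64, parent[0] == -1
    branch: np.ndarray        # int8 branch codes
    arc_um: np.ndarray        # signed arc distance of compartment center
    seg_len_um: np.ndarray
    diam_um: np.ndarray
    area_cm2: np.ndarray
    c_nF: np.ndarray
    gax_uS: np.ndarray        # coupling to parent (0 for root)
    half_r_MOhm: np.ndarray   # half-segment axial resistance of each compartment
    gleak_mS_cm2: float
    passive: PassiveParams = field(default_factory=PassiveParams)
    geometry: NeuronGeometry | None = None

    # -- derived topology ---------------------------------------------------
    def children(self):
        kids = [[] for _ in range(self.n)]
        for i in range(1, self.n):
            kids[self.parent[i]].append(i)
        return kids

    @property
    def gax_total_uS(self) -> np.ndarray:
        tot = self.gax_uS.copy()
        np.add.at(tot, self.parent[1:], self.gax_uS[1:])
        return tot

    @property
    def junction_index(self) -> int:
        return int(np.where(self.branch == JUNCTION)[0][0])

    def resolve_site(self, branch: str, distance_um: float = 0.0) -> int:
        """Index of the compartment on ``branch`` closest to ``distance_um``
        (unsigned arc distance from the T-junction)."""
        codes = {
            "soma": (SOMA,),
            "stem": (STEM,),
            "junction": (JUNCTION,),
            "peripheral": PERIPHERAL,
            "central": CENTRAL,
            "peripheral_proximal": (PP,),
            "peripheral_distal": (PD,),
            "central_proximal": (CP,),
            "central_distal": (CD,),
        }
        if branch not in codes:
            raise KeyError(f"unknown branch {branch!r}")
        mask = np.isin(self.branch, codes[branch])
        idx = np.where(mask)[0]
        if idx.size == 0:
            raise KeyError(f"no compartments on branch {branch!r}")
        return int(idx[np.argmin(np.abs(np.abs(self.arc_um[idx]) - distance_um))])


def _half_r_MOhm(ra: float, length_um: float, diam_um: float) -> float:
    """Axial resistance of half a compartment, in MOhm."""
    # Ra (Ohm cm) * (L/2 cm) / (pi d^2/4 cm^2) -> Ohm; 1e-6 -> MOhm
    l_cm = length_um * 1e-4 / 2.0
    a_cm2 = math.pi * (diam_um * 1e-4) ** 2 / 4.0
    return ra * l_cm / a_cm2 * 1e-6


def discretize(geometry: NeuronGeometry, passive: PassiveParams | None = None) -> CompartmentGraph:
    """Compartmentalize the morphology into a Hines-ordered tree.

    Per-compartment membrane area is the lateral cylinder area
    pi*d*(L/nseg) (no end caps).  Adjacent compartments are coupled by the
    series sum of their half-segment axial resistances; the three sections
    meeting at the T-junction connect through an explicit zero-area node.
    """
    passive = passive or PassiveParams()
    secs = geometry.sections

    rows = []  # (branch, arc, seg_len, diam, parent_row_or_callable)

    def add_section(name, code, parent_idx, arc_of, reverse=False):
        """Append a section's compartments chained from parent_idx.

        arc_of(k) gives the signed arc distance of compartment k's center,
        k counted from the end attached to ``parent_idx``.
        """
        sec = secs[name]
        dl = sec.length_um / sec.nseg
        first = len(rows)
        for k in range(sec.nseg):
            p = parent_idx if k == 0 else first + k - 1
            rows.append([code, arc_of(k, dl, sec), dl, sec.diameter_um, p])
        return first, len(rows) - 1

    # soma (root): arc distance = stem length + distance of center from stem end
    stem_len = secs["stem"].length_um
    s0, s_last = add_section(
        "soma", SOMA, -1,
        lambda k, dl, sec: stem_len + sec.length_um - (k + 0.5) * dl,
    )
    # stem: attached to soma at its far-from-junction end
    t0, t_last = add_section(
        "stem", STEM, s_last,
        lambda k, dl, sec: sec.length_um - (k + 0.5) * dl,
    )
    # junction node: zero length/area
    j = len(rows)
    rows.append([JUNCTION, 0.0, 0.0, secs["stem"].diameter_um, t_last])
    # peripheral: negative arc
    pp0, pp_last = add_section(
        "peripheral_proximal", PP, j, lambda k, dl, sec: -(k + 0.5) * dl
    )
    pd0, pd_last = add_section(
        "peripheral_distal", PD, pp_last,
        lambda k, dl, sec: -(secs["peripheral_proximal"].length_um + (k + 0.5) * dl),
    )
    # central: positive arc
    cp0, cp_last = add_section(
        "central_proximal", CP, j, lambda k, dl, sec: (k + 0.5) * dl
    )
    cd0, cd_last = add_section(
        "central_distal", CD, cp_last,
        lambda k, dl, sec: secs["central_proximal"].length_um + (k + 0.5) * dl,
    )

    n = len(rows)
    branch = np.array([r[0] for r in rows], dtype=np.int8)
    arc = np.array([r[1] for r in rows], dtype=float)
    seg_len = np.array([r[2] for r in rows], dtype=float)
    diam = np.array([r[3] for r in rows], dtype=float)
    parent = np.array([r[4] for r in rows], dtype=np.int64)

    area = np.pi * diam * seg_len * 1e-8  # cm^2
    area[branch == JUNCTION] = 0.0
    c_nF = area * passive.cm_uF_cm2 * 1e3  # uF/cm2 * cm2 = uF; *1e3 -> nF

    half_r = np.array(
        [
            _half_r_MOhm(passive.ra_ohm_cm, seg_len[i], diam[i]) if seg_len[i] > 0 else 0.0
            for i in range(n)
        ]
    )
    gax = np.zeros(n)
    for i in range(1, n):
        r = half_r[i] + half_r[parent[i]]
        if r <= 0:
            raise ValueError("zero axial resistance between distinct compartments")
        gax[i] = 1.0 / r  # 1/MOhm = uS

    if not np.all(parent[1:] < np.arange(1, n)):
        raise AssertionError("compartment ordering violates parent[i] < i")

    return CompartmentGraph(
        n=n,
        parent=parent,
        branch=branch,
        arc_um=arc,
        seg_len_um=seg_len,
        diam_um=diam,
        area_cm2=area,
        c_nF=c_nF,
        gax_uS=gax,
        half_r_MOhm=half_r,
        gleak_mS_cm2=1e3 / passive.rm_ohm_cm2,  # mS/cm2
        passive=passive,
        geometry=geometry,
    )
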