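"""Morphology, compartmentalization and channel layout of a layer-5 pyramidal cell.

The model is a simplified compartmental representation of a cortical layer-5
pyramidal neuron: a cylindrical soma giving rise to one apical dendrite, two
basal dendrites, and an axon whose initial segment (AIS) carries graded
densities of two sodium-channel subtypes.  Na_V1.2 occupies soma, dendrites
and the proximal/middle AIS; Na_V1.6 occupies the distal AIS and the nodes of
Ranvier, with steady-state activation and inactivation left-shifted by 6 mV
and 3 mV relative to Na_V1.2.

Geometry is discretized into isopotential cylindrical compartments of at most
1 um length.  Membrane area uses the lateral cylinder surface only (ends
excluded), the standard compartmental-modelling convention.

Units used throughout the package:

==============  ===========
quantity        unit
==============  ===========
length          um
voltage         mV
time            ms
capacitance     nF
conductance     uS
current         nA
conc.           mmol/l (mM)
density         pS/um^2
Rm              Ohm cm^2
Ri              Ohm cm
Cm              uF/cm^2
==============  ===========
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "SectionSpec",
    "CompartmentGraph",
    "TauSpec",
    "GateSpec",
    "GatingModel",
    "ChannelLayout",
    "default_gating_models",
    "build_default_morphology",
    "segmentize",
    "assign_channel_densities",
    "steady_state_gate",
    "gate_time_constant",
    "apply_nav12_shift",
    "nernst",
]

#: region labels in the order used for integer region codes
REGIONS = (
    "soma",
    "apical",
    "basal",
    "ais_proximal",
    "ais_middle",
    "ais_distal",
    "internode",
    "node",
)
REGION_CODE = {name: i for i, name in enumerate(REGIONS)}

FARADAY = 96485.33212  # C / mol
GAS_CONSTANT = 8.314462618  # J / (mol K)


def nernst(c_out: float, c_in: float, z: int = 1, temperature_c: float = 18.0) -> float:
    """Nernst equilibrium potential in mV."""
    if c_out <= 0 or c_in <= 0:
        raise ValueError("concentrations must be positive")
    t_kelvin = temperature_c + 273.15
    return 1e3 * GAS_CONSTANT * t_kelvin / (z * FARADAY) * math.log(c_out / c_in)


# ---------------------------------------------------------------------------
# sections and morphology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SectionSpec:
    """An unbranched cylindrical neurite section before discretization."""

    name: str
    length: float  # um
    diameter: float  # um
    region: str
    parent: str | None = None
    cm: float = 1.0  # uF/cm^2
    rm: float = 25000.0  # Ohm cm^2
    ri: float = 150.0  # Ohm cm

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"section {self.name!r}: length and diameter must be positive"
            )
        if self.region not in REGION_CODE:
            raise ValueError(f"section {self.name!r}: unknown region {self.region!r}")
        if self.cm <= 0 or self.rm <= 0 or self.ri <= 0:
            raise ValueError(f"section {self.name!r}: Cm, Rm, Ri must be positive")


#: morphological defaults; lengths/diameters in um.  The axon continues past
#: the first 50 um myelinated segment as alternating 1 um nodes of Ranvier and
#: 2 um internodes; with such short internodes the distal axon is electrically
#: compact, so enough node/internode pairs are needed for the axon end to be
#: electrotonically remote from the initiation zone.  The cut axon end is
#: represented by a passive terminal bleb (standard for slice recordings).
DEFAULT_MORPHOLOGY: dict = {
    "soma": {"length": 35.0, "diameter": 23.0},
    "apical": {"length": 350.0, "diameter": 3.5},
    "basal": {"length": 200.0, "diameter": 1.2, "count": 2},
    "ais": {"length": 45.0, "diameter": 1.2, "fractions": (1 / 3, 1 / 3, 1 / 3)},
    "myelin0": {"length": 50.0, "diameter": 1.2},
    "node": {"length": 1.0, "diameter": 1.2},
    "internode": {"length": 2.0, "diameter": 1.2},
    "n_node_pairs": 150,
    "terminal_bleb": {"length": 5.0, "diameter": 5.0},
}

DEFAULT_PASSIVE = {"rm": 25000.0, "cm": 1.0, "cm_internode": 0.5, "ri": 150.0}


def build_default_morphology(
    overrides: Mapping | None = None,
    *,
    passive: Mapping | None = None,
    force_ais_length: bool = False,
) -> list[SectionSpec]:
    """Build the default section list of the layer-5 cell.

    Soma (35 x 23 um) carries one apical dendrite (350 x 3.5), two basal
    dendrites (200 x 1.2) and the axon: a 45 um AIS (three parts:
    proximal/middle/distal), a 50 um myelinated segment, then alternating
    1 um nodes of Ranvier and 2 um myelinated internodes.

    Parameters
    ----------
    overrides
        Nested mapping merged over the built-in morphology defaults.
    passive
        Mapping with ``rm``, ``cm``, ``cm_internode``, ``ri``.
    force_ais_length
        Allow an AIS length outside the anatomically plausible 40-50 um.
    """
    morph = copy.deepcopy(DEFAULT_MORPHOLOGY)
    if overrides:
        for key, val in overrides.items():
            if isinstance(val, Mapping) and isinstance(morph.get(key), dict):
                morph[key].update(val)
            else:
                morph[key] = val
    pas = dict(DEFAULT_PASSIVE)
    if passive:
        pas.update(passive)

    ais_len = float(morph["ais"]["length"])
    if not force_ais_length and not (40.0 <= ais_len <= 50.0):
        raise ValueError(
            f"AIS length {ais_len} um outside [40, 50] um; "
            "pass force_ais_length=True to override"
        )
    fractions = tuple(morph["ais"].get("fractions", (1 / 3, 1 / 3, 1 / 3)))
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("AIS partition fractions must be 3 positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("AIS partition fractions must sum to 1")

    common = {"cm": pas["cm"], "rm": pas["rm"], "ri": pas["ri"]}

    def sec(name, cfg, region, parent, **kw):
        params = dict(common)
        params.update(kw)
        return SectionSpec(
            name=name,
            length=float(cfg["length"]),
            diameter=float(cfg["diameter"]),
            region=region,
            parent=parent,
            **params,
        )

    sections = [sec("soma", morph["soma"], "soma", None)]
    sections.append(sec("apical", morph["apical"], "apical", "soma"))
    n_basal = int(morph["basal"].get("count", 2))
    for i in range(n_basal):
        sections.append(sec(f"basal{i}", morph["basal"], "basal", "soma"))

    d_ais = float(morph["ais"]["diameter"])
    parent = "soma"
    for part, frac in zip(("proximal", "middle", "distal"), fractions):
        name = f"ais_{part}"
        sections.append(
            sec(name, {"length": ais_len * frac, "diameter": d_ais}, name, parent)
        )
        parent = name
    sections.append(
        sec("myelin0", morph["myelin0"], "internode", parent, cm=pas["cm_internode"])
    )
    parent = "myelin0"
    for i in range(int(morph["n_node_pairs"])):
        node_name = f"node{i}"
        sections.append(sec(node_name, morph["node"], "node", parent))
        inter_name = f"internode{i}"
        sections.append(
            sec(inter_name, morph["internode"], "internode", node_name,
                cm=pas["cm_internode"])
        )
        parent = inter_name
    bleb = morph.get("terminal_bleb")
    if bleb:
        sections.append(sec("bleb", bleb, "internode", parent))
    return sections


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

AXONAL_REGIONS = frozenset(
    {"ais_proximal", "ais_middle", "ais_distal", "internode", "node"}
)
DENDRITIC_REGIONS = frozenset({"apical", "basal"})


@dataclass
class CompartmentGraph:
    """Discretized morphology: a tree of isopotential cylindrical compartments.

    Arrays are indexed by compartment id; ``parent[i] < i`` for every i > 0
    (topological order rooted at the first soma compartment), which the
    tree-structured linear solver relies on.
    """

    length: np.ndarray  # um
    diameter: np.ndarray  # um
    area: np.ndarray  # um^2, lateral surface pi*d*l
    volume: np.ndarray  # um^3
    region: np.ndarray  # int codes into REGIONS
    section: list[str]  # section name per compartment
    position: np.ndarray  # center position along its own section, um
    distance: np.ndarray  # path distance from the soma edge, um (0 inside soma)
    parent: np.ndarray  # int, -1 for root
    g_axial: np.ndarray  # uS, coupling to parent (0 for root)
    cm: np.ndarray  # uF/cm^2 per compartment
    rm: np.ndarray  # Ohm cm^2
    capacitance: np.ndarray = field(init=False)  # nF

    def __post_init__(self) -> None:
        # 1 uF/cm^2 over 1 um^2 equals 1e-5 nF
        self.capacitance = self.cm * self.area * 1e-5

    @property
    def n(self) -> int:
        return len(self.length)

    def region_mask(self, *names: str) -> np.ndarray:
        codes = [REGION_CODE[name] for name in names]
        return np.isin(self.region, codes)

    def axonal_mask(self) -> np.ndarray:
        return self.region_mask(*AXONAL_REGIONS)

    def locate(self, region: str, offset: float = 0.0) -> int:
        """Compartment id in `region` closest to `offset` um from the soma edge
        (for the soma itself: closest to the soma center)."""
        mask = self.region_mask(region)
        if not mask.any():
            raise KeyError(f"no compartments in region {region!r}")
        idx = np.where(mask)[0]
        return int(idx[np.argmin(np.abs(self.distance[idx] - offset))])

    def to_table(self):
        """Plain-text-friendly table of the discretization (one row/compartment)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "section": self.section,
                "region": [REGIONS[c] for c in self.region],
                "parent": self.parent,
                "position_um": self.position,
                "distance_um": self.distance,
                "length_um": self.length,
                "diameter_um": self.diameter,
                "area_um2": self.area,
            }
        )


def _axial_half_resistance(ri: float, half_len: float, diam: float) -> float:
    """Axial resistance of half a compartment, in MOhm (1/uS)."""
    # g [uS] for full cylinder = 100 * pi * d^2 / (4 * Ri * l); see unit notes
    return 4.0 * ri * half_len / (100.0 * math.pi * diam * diam)


def segmentize(sections: Sequence[SectionSpec], max_len: float = 1.0) -> CompartmentGraph:
    """Discretize sections into compartments of at most `max_len` um.

    Each section is split into ``ceil(L / max_len)`` equal compartments, so
    per-section compartment lengths sum exactly to the section length.  Axial
    conductance between adjacent compartments is the series combination of the
    two half-cylinder resistances g = 1 / (r_half_i + r_half_j) with
    r_half = 4 Ri (l/2) / (100 pi d^2) MOhm.
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    by_name = {s.name: s for s in sections}
    roots = [s for s in sections if s.parent is None]
    if len(roots) != 1:
        raise ValueError(f"expected exactly one root section, found {len(roots)}")
    for s in sections:
        if s.parent is not None and s.parent not in by_name:
            raise ValueError(f"section {s.name!r} has unknown parent {s.parent!r}")

    # order sections parent-first (DFS from root)
    children: dict[str, list[SectionSpec]] = {s.name: [] for s in sections}
    for s in sections:
        if s.parent is not None:
            children[s.parent].append(s)
    ordered: list[SectionSpec] = []
    stack = [roots[0]]
    while stack:
        s = stack.pop()
        ordered.append(s)
        stack.extend(reversed(children[s.name]))
    if len(ordered) != len(sections):
        raise ValueError("sections do not form a connected tree")

    length, diam, region, sec_names, position, cm, rm = [], [], [], [], [], [], []
    parent_idx: list[int] = []
    g_axial: list[float] = []
    distance: list[float] = []
    # last compartment id and exit distance of each section
    sec_tail: dict[str, int] = {}
    sec_exit_dist: dict[str, float] = {}
    root_name = roots[0].name

    for s in ordered:
        nseg = max(1, math.ceil(s.length / max_len - 1e-12))
        seg_len = s.length / nseg
        if s.parent is None:
            prev = -1
            dist0 = 0.0
            prev_halfres = 0.0
        else:
            prev = sec_tail[s.parent]
            dist0 = sec_exit_dist[s.parent]
            p = by_name[s.parent]
            prev_halfres = _axial_half_resistance(
                p.ri, (p.length / max(1, math.ceil(p.length / max_len - 1e-12))) / 2,
                p.diameter,
            )
        for k in range(nseg):
            idx = len(length)
            length.append(seg_len)
            diam.append(s.diameter)
            region.append(REGION_CODE[s.region])
            sec_names.append(s.name)
            position.append((k + 0.5) * seg_len)
            cm.append(s.cm)
            rm.append(s.rm)
            parent_idx.append(prev)
            if prev < 0:
                g_axial.append(0.0)
            else:
                rhalf = _axial_half_resistance(s.ri, seg_len / 2, s.diameter)
                g_axial.append(1.0 / (prev_halfres + rhalf))
            # distance from the soma edge: 0 within the root (soma) section
            if s.name == root_name:
                distance.append(0.0)
            else:
                distance.append(dist0 + (k + 0.5) * seg_len)
            prev = idx
            prev_halfres = _axial_half_resistance(s.ri, seg_len / 2, s.diameter)
        sec_tail[s.name] = prev
        sec_exit_dist[s.name] = 0.0 if s.name == root_name else dist0 + s.length

    length_a = np.asarray(length)
    diam_a = np.asarray(diam)
    return CompartmentGraph(
        length=length_a,
        diameter=diam_a,
        area=math.pi * diam_a * length_a,
        volume=math.pi * diam_a**2 / 4.0 * length_a,
        region=np.asarray(region, dtype=np.int64),
        section=sec_names,
        position=np.asarray(position),
        distance=np.asarray(distance),
        parent=np.asarray(parent_idx, dtype=np.int64),
        g_axial=np.asarray(g_axial),
        cm=np.asarray(cm),
        rm=np.asarray(rm),
    )


# ---------------------------------------------------------------------------
# gating models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TauSpec:
    """Bell-shaped voltage dependence of a gating time constant (ms).

    tau(V) = base + amp / (exp((V - vmid)/width) + exp(-(V - vmid)/width))
    """

    base: float
    amp: float
    vmid: float
    width: float

    def __call__(self, v: float | np.ndarray):
        u = (np.asarray(v, dtype=float) - self.vmid) / self.width
        return self.base + self.amp / (np.exp(u) + np.exp(-u))


@dataclass(frozen=True)
class GateSpec:
    """Boltzmann steady state: x_inf(V) = 1 / (1 + exp(-(V - vhalf)/k)).

    ``k`` is positive for activation gates and negative for inactivation gates
    (which makes x_inf decreasing in V).
    """

    vhalf: float
    k: float
    tau: TauSpec

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("Boltzmann slope k must be nonzero")

    def inf(self, v: float | np.ndarray):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - self.vhalf) / self.k))


@dataclass(frozen=True)
class GatingModel:
    """Hodgkin-Huxley-style channel kinetics for one species.

    Open fraction = activation^act_exponent * (p_persist + (1 - p_persist) * inact)
    where ``inact`` is 1 for species without an inactivation gate.  p_persist
    is a non-inactivating fraction (default 0) available for sensitivity
    analyses of persistent current.
    """

    species: str
    activation: GateSpec
    act_exponent: int = 3
    inactivation: GateSpec | None = None
    reversal: float | None = None  # mV; None = ion-derived (Na)
    p_persist: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_persist <= 1.0):
            raise ValueError("p_persist must lie in [0, 1]")
        if self.activation.k <= 0:
            raise ValueError("activation slope must be positive")
        if self.inactivation is not None and self.inactivation.k >= 0:
            raise ValueError("inactivation slope must be negative")


def steady_state_gate(model: GatingModel, gate: str, v):
    """Steady-state open probability of `gate` ('activation'/'inactivation') at V."""
    if gate == "activation":
        return model.activation.inf(v)
    if gate == "inactivation":
        if model.inactivation is None:
            raise KeyError(f"species {model.species!r} has no inactivation gate")
        return model.inactivation.inf(v)
    raise KeyError(f"unknown gate {gate!r}")


def gate_time_constant(model: GatingModel, gate: str, v):
    """Voltage-dependent time constant (ms) of `gate` at V."""
    if gate == "activation":
        return model.activation.tau(v)
    if gate == "inactivation":
        if model.inactivation is None:
            raise KeyError(f"species {model.species!r} has no inactivation gate")
        return model.inactivation.tau(v)
    raise KeyError(f"unknown gate {gate!r}")


#: default kinetic parameters.  Absolute Na kinetics and the Kv/Kv1 models are
#: reconstructions (defined directly at the 18 degC nominal temperature); the
#: relative Na_V1.6 vs Na_V1.2 gating shifts (-6 mV activation, -3 mV
#: inactivation) are the constrained quantities.
DEFAULT_GATING: dict = {
    "nav12": {
        "act": {"vhalf": -30.0, "k": 7.0},
        "inact": {"vhalf": -62.0, "k": -7.0},
        "tau_act": {"base": 0.06, "amp": 0.80, "vmid": -45.0, "width": 12.0},
        "tau_inact": {"base": 0.50, "amp": 10.0, "vmid": -55.0, "width": 14.0},
        "exponent": 3,
        "p_persist": 0.0,
    },
    "nav16_shift": {"act": -6.0, "inact": -3.0},
    "kv": {
        "act": {"vhalf": -20.0, "k": 10.0},
        "tau_act": {"base": 0.50, "amp": 4.0, "vmid": -30.0, "width": 20.0},
        "exponent": 4,
        "reversal": -85.0,
    },
    "kv1": {
        "act": {"vhalf": -50.0, "k": 8.0},
        "tau_act": {"base": 0.15, "amp": 0.8, "vmid": -50.0, "width": 20.0},
        "exponent": 1,
        "reversal": -85.0,
    },
}


def _gate_from_cfg(gcfg: Mapping, tcfg: Mapping) -> GateSpec:
    return GateSpec(
        vhalf=float(gcfg["vhalf"]), k=float(gcfg["k"]), tau=TauSpec(**tcfg)
    )


def default_gating_models(config: Mapping | None = None) -> dict[str, GatingModel]:
    """Construct the gating models for nav12, nav16, kv, kv1.

    Na_V1.6 is derived from Na_V1.2 by applying the configured activation and
    inactivation shifts (default -6 / -3 mV).
    """
    cfg = copy.deepcopy(DEFAULT_GATING)
    if config:
        for key, val in config.items():
            if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
                for k2, v2 in val.items():
                    if isinstance(v2, Mapping) and isinstance(cfg[key].get(k2), dict):
                        cfg[key][k2].update(v2)
                    else:
                        cfg[key][k2] = v2
            else:
                cfg[key] = val

    n12 = cfg["nav12"]
    nav12 = GatingModel(
        species="nav12",
        activation=_gate_from_cfg(n12["act"], n12["tau_act"]),
        act_exponent=int(n12["exponent"]),
        inactivation=_gate_from_cfg(n12["inact"], n12["tau_inact"]),
        reversal=None,
        p_persist=float(n12.get("p_persist", 0.0)),
    )
    sh = cfg["nav16_shift"]
    nav16 = GatingModel(
        species="nav16",
        activation=replace(nav12.activation, vhalf=nav12.activation.vhalf + sh["act"]),
        act_exponent=nav12.act_exponent,
        inactivation=replace(
            nav12.inactivation, vhalf=nav12.inactivation.vhalf + sh["inact"]
        ),
        reversal=None,
        p_persist=nav12.p_persist,
    )
    kv_cfg = cfg["kv"]
    kv = GatingModel(
        species="kv",
        activation=_gate_from_cfg(kv_cfg["act"], kv_cfg["tau_act"]),
        act_exponent=int(kv_cfg["exponent"]),
        inactivation=None,
        reversal=float(kv_cfg["reversal"]),
    )
    kv1_cfg = cfg["kv1"]
    kv1 = GatingModel(
        species="kv1",
        activation=_gate_from_cfg(kv1_cfg["act"], kv1_cfg["tau_act"]),
        act_exponent=int(kv1_cfg["exponent"]),
        inactivation=None,
        reversal=float(kv1_cfg["reversal"]),
    )
    return {"nav12": nav12, "nav16": nav16, "kv": kv, "kv1": kv1}


def apply_nav12_shift(
    gating: Mapping[str, GatingModel],
    dv: float,
    genotype: str = "WT",
    *,
    inact_dv: float = 0.0,
    species: str = "nav12",
) -> dict[str, GatingModel]:
    """Shift the Na_V1.2 activation midpoint by `dv` mV (negative = leftward).

    This is the model's representation of (de)SUMOylation of Na_V1.2: SUMO1
    shifts activation leftward, SENP1 rightward.  Na_V1.6 carries no SUMO
    site and is never shifted.  For the Lys38Gln (K38Q) genotype, which lacks
    the SUMO-conjugation site, the shift is a structural no-op: the returned
    gating is identical to the input.

    An optional inactivation shift `inact_dv` (default 0) is provided because
    only the half-activation voltage is constrained by the modelled effect.
    """
    if species != "nav12":
        raise ValueError(
            "voltage shifts act on Na_V1.2 only; Na_V1.6 is not SUMOylatable"
        )
    if abs(dv) > 30.0 or abs(inact_dv) > 30.0:
        raise ValueError("|shift| > 30 mV is outside the sane modulation range")
    if genotype not in ("WT", "K38Q", "Lys38Gln"):
        raise ValueError(f"unknown genotype {genotype!r}")
    out = dict(gating)
    if genotype != "WT":
        return out
    base = gating["nav12"]
    shifted = GatingModel(
        species=base.species,
        activation=replace(base.activation, vhalf=base.activation.vhalf + dv),
        act_exponent=base.act_exponent,
        inactivation=None
        if base.inactivation is None
        else replace(base.inactivation, vhalf=base.inactivation.vhalf + inact_dv),
        reversal=base.reversal,
        p_persist=base.p_persist,
    )
    out["nav12"] = shifted
    return out


# ---------------------------------------------------------------------------
# channel densities
# ---------------------------------------------------------------------------

#: conductance densities in pS/um^2.  Scalars apply uniformly to a region;
#: 2-tuples are linear ramps (proximal -> distal end of the region).  Na
#: densities follow the published immunohistochemistry-motivated layout;
#: Kv/Kv1 densities are reconstruction defaults.
DEFAULT_DENSITIES: dict = {
    "nav12": {
        "soma": 200.0,
        "apical": 200.0,
        "basal": 40.0,
        "ais_proximal": (200.0, 800.0),
        "ais_middle": 800.0,
    },
    "nav16": {"ais_distal": (800.0, 0.0), "node": 1200.0},
    "kv": {
        "soma": 60.0,
        "apical": 10.0,
        "basal": 10.0,
        "ais_proximal": 150.0,
        "ais_middle": 150.0,
        "ais_distal": 150.0,
        "node": 1500.0,
    },
    "kv1": {
        "soma": 120.0,
        "apical": 30.0,
        "basal": 30.0,
        "ais_proximal": 60.0,
        "ais_middle": 60.0,
        "ais_distal": 30.0,
        "node": 800.0,
        "internode": 300.0,
    },
}


@dataclass
class ChannelLayout:
    """Per-compartment conductance densities (pS/um^2) for each species,
    plus the leak density derived from Rm, and gating models."""

    densities: dict[str, np.ndarray]
    leak_density: np.ndarray  # pS/um^2, = 1e4 / Rm
    gating: dict[str, GatingModel]

    def conductance(self, species: str, area: np.ndarray) -> np.ndarray:
        """Maximal conductance per compartment in uS (density * area)."""
        dens = self.leak_density if species == "leak" else self.densities[species]
        return dens * area * 1e-6


def assign_channel_densities(
    graph: CompartmentGraph,
    density_config: Mapping | None = None,
    gating: Mapping[str, GatingModel] | None = None,
) -> ChannelLayout:
    """Assign conductance densities to every compartment.

    Na_V1.2: 200 pS/um^2 in soma and apical dendrite, 40 in basal dendrites,
    a 200->800 linear ramp along the proximal AIS and constant 800 in the
    middle AIS.  Na_V1.6: an 800->0 ramp along the distal AIS and 1200 in
    nodes of Ranvier.  Internodes carry no Na channels.  Ramps are evaluated
    at compartment centers, so the profile is continuous (800 at the
    proximal/middle and middle/distal junctions).
    """
    cfg = copy.deepcopy(DEFAULT_DENSITIES)
    if density_config:
        for sp, regions in density_config.items():
            if sp not in cfg:
                cfg[sp] = {}
            cfg[sp].update(regions)

    # per-section extent for ramp evaluation
    sec_len: dict[str, float] = {}
    for name, ln in zip(graph.section, graph.length):
        sec_len[name] = sec_len.get(name, 0.0) + float(ln)

    densities: dict[str, np.ndarray] = {}
    for sp, regions in cfg.items():
        arr = np.zeros(graph.n)
        for region_name, value in regions.items():
            mask = graph.region_mask(region_name)
            if not mask.any():
                continue
            if isinstance(value, (tuple, list)):
                d0, d1 = float(value[0]), float(value[1])
                if d0 < 0 or d1 < 0:
                    raise ValueError(f"negative density for {sp}/{region_name}")
                for i in np.where(mask)[0]:
                    frac = graph.position[i] / sec_len[graph.section[i]]
                    arr[i] = d0 + (d1 - d0) * frac
            else:
                value = float(value)
                if value < 0:
                    raise ValueError(f"negative density for {sp}/{region_name}")
                arr[mask] = value
        densities[sp] = arr

    leak = 1e4 / graph.rm  # 1/(Ohm cm^2) -> pS/um^2
    models = dict(gating) if gating is not None else default_gating_models()
    return ChannelLayout(densities=densities, leak_density=leak, gating=models)
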