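"""Passive circulation: Windkessel compartments, pulmonary-vein branches and
the topology builder for the three anatomies.

The closed loop is, in flow order::

    LV -> aortic valve -> SYS-AR -> SYS-C -> SYS-VEN -> VC -> RA
       -> tricuspid -> RV -> pulmonary valve -> PUL-AR
       -> (4 parallel vein paths: precapillary OX||SH -> capillary node
           -> R_vein,L_vein -> destination)
       -> VEN-PUL-POOL -> LA -> mitral -> LV

Each of the four pulmonary veins drains one quarter of the capillary bed
(by default) and terminates either at the pulmonary venous pool upstream
of the left atrium (normal), directly at the right atrium (RA-variant
anomalous vein), or at the caval node upstream of the caval resistance
(VC-variant anomalous vein).  The caval compartment — a single lumped
element for superior plus inferior vena cava — is present in every
anatomy; the variants differ only in where anomalous veins terminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

from .heart import ConfigurationError, ElastanceParams, ValveParams

__all__ = [
    "WOOD_UNIT",
    "RLCCompartment",
    "PulmonaryVeinBranch",
    "AnatomyConfig",
    "ModelParameters",
    "CircuitModel",
    "default_parameters",
    "build_model",
    "set_pvr",
    "scale_anomalous_postcap",
    "validate_model",
    "edge_list",
]

#: 1 Wood unit = 1 mmHg*min/L = 0.06 mmHg*s/mL
WOOD_UNIT = 0.06

CHAMBER_NAMES = ("LA", "LV", "RA", "RV")
VALVE_NAMES = ("MV", "AV", "TV", "PV")
COMPARTMENT_NAMES = (
    "SYS-AR",
    "SYS-C",
    "SYS-VEN",
    "VC",
    "PUL-AR",
    "PUL-C-OX",
    "PUL-C-SH",
    "VEN-PUL-POOL",
)

Variant = Literal["baseline", "RA", "VC"]
Destination = Literal["LA", "RA", "VC"]


@dataclass(frozen=True)
class RLCCompartment:
    """One Windkessel building block: series resistance and inertance feeding
    a compliant node (any of R, L, C may be zero except where noted)."""

    name: str
    r: float = 0.0
    l: float = 0.0
    c: float = 0.0

    def __post_init__(self) -> None:
        if self.r < 0.0 or self.l < 0.0 or self.c < 0.0:
            raise ConfigurationError(f"{self.name}: R, L, C must all be >= 0")


@dataclass(frozen=True)
class PulmonaryVeinBranch:
    """One of the four pulmonary veins: postcapillary R-L branch plus the
    share of the capillary bed it drains and its downstream terminal."""

    index: int
    r_vein: float
    l_vein: float
    destination: Destination = "LA"
    capillary_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3, 4):
            raise ConfigurationError(f"vein index must be 1..4, got {self.index}")
        if self.r_vein < 0.0 or self.l_vein < 0.0:
            raise ConfigurationError("vein R and L must be >= 0")
        if not (0.0 < self.capillary_fraction <= 1.0):
            raise ConfigurationError("capillary_fraction must lie in (0, 1]")
        if self.destination not in ("LA", "RA", "VC"):
            raise ConfigurationError(f"unknown destination {self.destination!r}")


@dataclass(frozen=True)
class AnatomyConfig:
    """Declarative description of one anatomy.

    ``variant`` selects where anomalous veins terminate ("RA": right
    atrium; "VC": caval node upstream of the caval resistance); baseline
    has no anomalous veins.  ``pvr_wood_units`` sets the total
    precapillary pulmonary resistance; ``anomalous_postcap_scale``
    multiplies the postcapillary (vein) resistance of anomalous branches.
    """

    variant: Variant = "baseline"
    anomalous_veins: frozenset[int] = frozenset()
    pvr_wood_units: float = 1.0
    anomalous_postcap_scale: float = 1.0

    def __post_init__(self) -> None:
        veins = frozenset(self.anomalous_veins)
        object.__setattr__(self, "anomalous_veins", veins)
        if self.variant not in ("baseline", "RA", "VC"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.variant == "baseline" and veins:
            raise ConfigurationError("baseline anatomy cannot have anomalous veins")
        if self.variant != "baseline" and not veins:
            raise ConfigurationError(f"{self.variant} variant requires >= 1 anomalous vein")
        if not veins <= {1, 2, 3, 4}:
            raise ConfigurationError("anomalous_veins must be a subset of {1,2,3,4}")
        if self.pvr_wood_units <= 0.0:
            raise ConfigurationError("pvr_wood_units must be > 0")
        if self.anomalous_postcap_scale < 1.0:
            raise ConfigurationError("anomalous_postcap_scale must be >= 1")


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the closed loop (units mmHg, mL, s).

    ``sh_fraction`` is the share of each vein's precapillary conductance
    carried by the non-oxygenated (shunt) capillary path.
    ``volume_offset`` is extra stressed blood volume (mL) added to the
    systemic venous node at initialisation; it is the main calibration
    handle for filling pressures.
    """

    chambers: dict[str, ElastanceParams]
    valves: dict[str, ValveParams]
    compartments: dict[str, RLCCompartment]
    vein_r: float = 0.18
    vein_l: float = 5e-4
    capillary_fractions: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    sh_fraction: float = 0.03
    volume_offset: float = 0.0
    valve_smoothing_eps: float = 1e-3

    def __post_init__(self) -> None:
        missing = set(CHAMBER_NAMES) - set(self.chambers)
        if missing:
            raise ConfigurationError(f"missing chambers: {sorted(missing)}")
        missing = set(VALVE_NAMES) - set(self.valves)
        if missing:
            raise ConfigurationError(f"missing valves: {sorted(missing)}")
        missing = set(COMPARTMENT_NAMES) - set(self.compartments)
        if missing:
            raise ConfigurationError(f"missing compartments: {sorted(missing)}")
        if not (0.0 < self.sh_fraction < 1.0):
            raise ConfigurationError("sh_fraction must lie in (0, 1)")
        if abs(sum(self.capillary_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("capillary fractions must sum to 1")

    def replace(self, **changes) -> "ModelParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class CircuitModel:
    """An assembled anatomy: parameters plus the four routed vein branches
    and the ordered state layout used by the integrator."""

    anatomy: AnatomyConfig
    params: ModelParameters
    veins: tuple[PulmonaryVeinBranch, ...]
    state_layout: tuple[tuple[str, str], ...]  # (name, kind)

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.state_layout)

    @property
    def chambers(self) -> dict[str, ElastanceParams]:
        return self.params.chambers

    @property
    def valves(self) -> dict[str, ValveParams]:
        return self.params.valves

    @property
    def compartments(self) -> dict[str, RLCCompartment]:
        return self.params.compartments

    @property
    def c_venpul(self) -> float:
        return self.params.compartments["VEN-PUL-POOL"].c

    @property
    def precap_resistance(self) -> float:
        """Total precapillary pulmonary resistance (mmHg*s/mL)."""
        return self.anatomy.pvr_wood_units * WOOD_UNIT

    def vein_precap_conductances(self, index: int) -> tuple[float, float]:
        """(oxygenated, shunt) precapillary conductances feeding vein ``index``."""
        frac = self.veins[index - 1].capillary_fraction
        g_total = frac / self.precap_resistance
        sh = self.params.sh_fraction
        return (1.0 - sh) * g_total, sh * g_total


# ---------------------------------------------------------------------------
# Default parameter set
# ---------------------------------------------------------------------------

# Calibrated to clinical-normal anchors at baseline anatomy and 1 WU:
# cardiac output ~5 L/min, mean aortic pressure ~90 mmHg, mean pulmonary
# artery pressure ~16 mmHg, mean right atrial pressure ~8 mmHg.
_PERIOD = 0.8  # 75 bpm

_DEFAULT_CHAMBERS = {
    # atria activate ~0.1*period before the ventricles (AV delay)
    "LA": ElastanceParams(
        e_max=0.25, e_min=0.15, v_rest=4.0,
        t_onset=0.85, t_contract=0.10, t_relax=0.10, period=_PERIOD,
    ),
    "RA": ElastanceParams(
        e_max=0.30, e_min=0.20, v_rest=4.0,
        t_onset=0.85, t_contract=0.10, t_relax=0.10, period=_PERIOD,
    ),
    "LV": ElastanceParams(
        e_max=2.75, e_min=0.080, v_rest=5.0,
        t_onset=0.0, t_contract=0.25, t_relax=0.1875, period=_PERIOD,
    ),
    # a relatively stiff RV diastole (e_min) reproduces the high-normal
    # right atrial filling pressure and makes the left-to-right shunt
    # self-limiting as the right heart volume-loads
    "RV": ElastanceParams(
        e_max=0.50, e_min=0.095, v_rest=10.0,
        t_onset=0.0, t_contract=0.25, t_relax=0.1875, period=_PERIOD,
    ),
}

# closed resistances are set well above the r_closed/r_open >= 1e3 diode
# floor because the atrioventricular valves face reverse gradients ~50x
# larger than their forward ones; this keeps the regurgitant leak < 1% of
# forward flow
_DEFAULT_VALVES = {
    "MV": ValveParams(r_open=0.003, r_closed=150.0),
    "AV": ValveParams(r_open=0.005, r_closed=250.0),
    "TV": ValveParams(r_open=0.003, r_closed=150.0),
    "PV": ValveParams(r_open=0.003, r_closed=150.0),
}

_DEFAULT_COMPARTMENTS = {
    "SYS-AR": RLCCompartment("SYS-AR", r=0.73, l=5e-4, c=1.4),
    "SYS-C": RLCCompartment("SYS-C", r=0.12, l=0.0, c=0.0),
    "SYS-VEN": RLCCompartment("SYS-VEN", r=0.06, l=0.0, c=70.0),
    "VC": RLCCompartment("VC", r=0.04, l=5e-4, c=40.0),
    "PUL-AR": RLCCompartment("PUL-AR", r=0.0, l=0.0, c=4.5),
    # precapillary resistance is set by AnatomyConfig.pvr_wood_units; the
    # r stored here is the 1-WU reference through the oxygenated path
    "PUL-C-OX": RLCCompartment("PUL-C-OX", r=WOOD_UNIT / 0.97, l=0.0, c=10.0),
    "PUL-C-SH": RLCCompartment("PUL-C-SH", r=WOOD_UNIT / 0.03, l=0.0, c=0.0),
    "VEN-PUL-POOL": RLCCompartment("VEN-PUL-POOL", r=0.006, l=0.0, c=12.0),
}


def default_parameters() -> ModelParameters:
    """Baseline-calibrated adult parameter set."""
    return ModelParameters(
        chambers=dict(_DEFAULT_CHAMBERS),
        valves=dict(_DEFAULT_VALVES),
        compartments=dict(_DEFAULT_COMPARTMENTS),
        volume_offset=800.0,
    )


# ---------------------------------------------------------------------------
# Topology builder
# ---------------------------------------------------------------------------

def _state_layout(model_veins: Sequence[PulmonaryVeinBranch]) -> tuple[tuple[str, str], ...]:
    layout: list[tuple[str, str]] = [
        ("V_LA", "chamber-volume"),
        ("V_LV", "chamber-volume"),
        ("V_RA", "chamber-volume"),
        ("V_RV", "chamber-volume"),
        ("p_sys_ar", "node-pressure"),
        ("p_sys_ven", "node-pressure"),
        ("p_vc", "node-pressure"),
        ("p_pul_ar", "node-pressure"),
    ]
    layout += [(f"p_cap_{v.index}", "node-pressure") for v in model_veins]
    layout.append(("p_ven_pool", "node-pressure"))
    layout.append(("q_sys_ar", "branch-flow"))
    layout.append(("q_vc", "branch-flow"))
    layout += [(f"q_vein_{v.index}", "branch-flow") for v in model_veins]
    return tuple(layout)


def build_model(anatomy: AnatomyConfig, params: ModelParameters | None = None) -> CircuitModel:
    """Assemble the circuit for one anatomy.

    Normal veins drain through the common pulmonary venous pool into the
    LA.  In the RA variant each anomalous vein terminates at the right
    atrium; in the VC variant at the caval node upstream of the caval
    resistance.
    """
    if params is None:
        params = default_parameters()
    dest: Destination = "LA"
    if anatomy.variant in ("RA", "VC"):
        dest = anatomy.variant  # type: ignore[assignment]
    veins = []
    for i, frac in zip((1, 2, 3, 4), params.capillary_fractions):
        anomalous = i in anatomy.anomalous_veins
        veins.append(
            PulmonaryVeinBranch(
                index=i,
                r_vein=params.vein_r
                * (anatomy.anomalous_postcap_scale if anomalous else 1.0),
                l_vein=params.vein_l,
                destination=dest if anomalous else "LA",
                capillary_fraction=frac,
            )
        )
    veins = tuple(veins)
    return CircuitModel(
        anatomy=anatomy, params=params, veins=veins, state_layout=_state_layout(veins)
    )


def set_pvr(model: CircuitModel, wood_units: float) -> CircuitModel:
    """Return a copy with the total precapillary pulmonary resistance set to
    ``wood_units`` WU (1 WU = 0.06 mmHg*s/mL), scaled uniformly across the
    four parallel per-vein precapillary paths (oxygenated and shunt alike)."""
    if wood_units <= 0.0:
        raise ConfigurationError("PVR target must be > 0 WU")
    return build_model(replace(model.anatomy, pvr_wood_units=wood_units), model.params)


def scale_anomalous_postcap(model: CircuitModel, factor: float) -> CircuitModel:
    """Return a copy with the postcapillary resistance of every anomalous
    vein multiplied by ``factor`` (relative to the unscaled template)."""
    if factor < 1.0:
        raise ConfigurationError("postcapillary scale factor must be >= 1")
    if not model.anatomy.anomalous_veins:
        raise ConfigurationError("model has no anomalous limb to scale")
    return build_model(
        replace(model.anatomy, anomalous_postcap_scale=factor), model.params
    )


# ---------------------------------------------------------------------------
# Edge list and validation
# ---------------------------------------------------------------------------

def edge_list(model: CircuitModel) -> pd.DataFrame:
    """Dump the circuit as an element table (element, kind, from, to, R, L, C).

    Capacitive nodes appear as ``node`` rows grounded at ``REF``;
    series elements as ``branch``/``valve`` rows between their nodes.
    """
    rows: list[dict] = []
    comp = model.compartments

    def node(name: str, c: float) -> None:
        rows.append(
            dict(element=name, kind="node", from_node=name, to_node="REF", r=0.0, l=0.0, c=c)
        )

    def branch(name: str, u: str, v: str, r: float, l: float = 0.0, kind: str = "branch") -> None:
        rows.append(dict(element=name, kind=kind, from_node=u, to_node=v, r=r, l=l, c=0.0))

    for ch in CHAMBER_NAMES:
        rows.append(
            dict(element=ch, kind="chamber", from_node=ch, to_node="REF", r=0.0, l=0.0, c=0.0)
        )
    branch("MV", "LA", "LV", model.valves["MV"].r_open, kind="valve")
    branch("AV", "LV", "sys_ar", model.valves["AV"].r_open, kind="valve")
    branch("TV", "RA", "RV", model.valves["TV"].r_open, kind="valve")
    branch("PV", "RV", "pul_ar", model.valves["PV"].r_open, kind="valve")
    node("sys_ar", comp["SYS-AR"].c)
    branch(
        "SYS-AR+SYS-C", "sys_ar", "sys_ven", comp["SYS-AR"].r + comp["SYS-C"].r, comp["SYS-AR"].l
    )
    node("sys_ven", comp["SYS-VEN"].c)
    branch("SYS-VEN", "sys_ven", "vc", comp["SYS-VEN"].r)
    node("vc", comp["VC"].c)
    branch("VC", "vc", "RA", comp["VC"].r, comp["VC"].l)
    node("pul_ar", comp["PUL-AR"].c)
    dest_node = {"LA": "ven_pool", "RA": "RA", "VC": "vc"}
    for v in model.veins:
        g_ox, g_sh = model.vein_precap_conductances(v.index)
        node(f"cap_{v.index}", comp["PUL-C-OX"].c * v.capillary_fraction)
        branch(f"PUL-C-OX_{v.index}", "pul_ar", f"cap_{v.index}", 1.0 / g_ox)
        branch(f"PUL-C-SH_{v.index}", "pul_ar", f"cap_{v.index}", 1.0 / g_sh)
        branch(f"VEIN_{v.index}", f"cap_{v.index}", dest_node[v.destination], v.r_vein, v.l_vein)
    node("ven_pool", model.c_venpul)
    branch("VEN-PUL-POOL", "ven_pool", "LA", comp["VEN-PUL-POOL"].r)
    return pd.DataFrame(rows)


def validate_model(model: CircuitModel) -> list[str]:
    """Check structural invariants; returns a list of violations (empty if OK)."""
    violations: list[str] = []
    fractions = sum(v.capillary_fraction for v in model.veins)
    if abs(fractions - 1.0) > 1e-9:
        violations.append(
            f"capillary fractions of the 4 veins must sum to 1, got {fractions:.6g}"
        )
    for v in model.veins:
        anomalous = v.index in model.anatomy.anomalous_veins
        expected = (
            model.anatomy.variant if anomalous and model.anatomy.variant != "baseline" else "LA"
        )
        if v.destination != expected:
            violations.append(
                f"vein {v.index} destination {v.destination!r}, expected {expected!r}"
            )
    for name in COMPARTMENT_NAMES:
        if name not in model.compartments:
            violations.append(f"missing compartment {name}")
    # graph connectivity: every node reachable in the undirected element graph
    edges = edge_list(model)
    g = nx.Graph()
    for _, row in edges.iterrows():
        if row["kind"] != "node":
            g.add_edge(row["from_node"], row["to_node"])
    g.add_nodes_from(
        row["from_node"] for _, row in edges.iterrows() if row["kind"] == "node"
    )
    if g.number_of_nodes() and not nx.is_connected(g):
        parts = sorted(len(c) for c in nx.connected_components(g))
        violations.append(f"circuit graph is not a single closed loop (components {parts})")
    # state layout bijection
    names = [n for n, _ in model.state_layout]
    if len(names) != len(set(names)):
        violations.append("state_layout contains duplicate names")
    return violations
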