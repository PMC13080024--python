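"""Hardware-graph compilation: map synthesis pathways onto module graphs.

A hardware inventory is a typed graph of laboratory modules (reagent
flasks, pumps, valves, a reactor, a stirrer/heater/cooler, separator,
sensors, chromatography, waste and product vessels) connected by
matter, energy, or information channels.  *Chempiling* assigns every
primitive of a compiled pathway to a capable module together with a
matter route from the pathway's reactor, or reports the first
unschedulable primitive — never a silent partial schedule.

Capability reading of the module roles:

====================== =======================================
module kind             role
====================== =======================================
reagent_flask           AM source
pump / valve            AM routing (every AM route must pass
                        through at least one of them)
reactor                 the mapped tape cell
stirrer_heater_cooler   AE and SE
separator               SM executor
chromatography          SM executor
waste / product_vessel  SM sinks
sensors                 information only (scheduling-neutral;
                        their use lives in :mod:`cstm.dec`)
====================== =======================================

Routing is by shortest matter-edge path with lexicographic node-id
tie-breaks, so schedules are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx

from .core import CSTMError, Primitive
from .unit_ops import SynthesisPathway, UnitOpRegistry, compile_pathway

MODULE_KINDS = (
    "reagent_flask",
    "pump",
    "valve",
    "reactor",
    "stirrer_heater_cooler",
    "separator",
    "conductivity_sensor",
    "photon_sensor",
    "chromatography",
    "waste",
    "product_vessel",
)

SENSOR_KINDS = ("conductivity_sensor", "photon_sensor")

#: primitive kinds each module kind can execute
KIND_CAPABILITIES: dict[str, frozenset[str]] = {
    "reagent_flask": frozenset({"AM"}),
    "pump": frozenset({"AM"}),
    "valve": frozenset({"AM"}),
    "reactor": frozenset(),
    "stirrer_heater_cooler": frozenset({"AE", "SE"}),
    "separator": frozenset({"SM"}),
    "chromatography": frozenset({"SM"}),
    "conductivity_sensor": frozenset(),
    "photon_sensor": frozenset(),
    "waste": frozenset(),
    "product_vessel": frozenset(),
}

#: module kinds that terminate an SM route
SINK_KINDS = ("waste", "product_vessel")

CHANNELS = ("matter", "energy", "information")


class GraphSchemaError(CSTMError):
    """Malformed hardware-graph file."""


@dataclass(frozen=True)
class HardwareModule:
    id: str
    kind: str
    capabilities: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        if self.kind not in MODULE_KINDS:
            raise GraphSchemaError(f"unknown module kind {self.kind!r} for node {self.id!r}")
        if not self.capabilities:
            object.__setattr__(self, "capabilities", KIND_CAPABILITIES[self.kind])


@dataclass
class HardwareGraph:
    """Typed module nodes plus channelled edges."""

    nodes: dict[str, HardwareModule] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def add_module(self, node_id: str, kind: str) -> None:
        if node_id in self.nodes:
            raise GraphSchemaError(f"duplicate node id {node_id!r}")
        self.nodes[node_id] = HardwareModule(node_id, kind)

    def connect(self, u: str, v: str, channel: str = "matter") -> None:
        if channel not in CHANNELS:
            raise GraphSchemaError(f"unknown channel {channel!r}")
        for n in (u, v):
            if n not in self.nodes:
                raise GraphSchemaError(f"edge references unknown node {n!r}")
        self.edges.append((u, v, channel))

    def of_kind(self, *kinds: str) -> list[str]:
        return sorted(n for n, m in self.nodes.items() if m.kind in kinds)

    def channel_graph(self, channel: str) -> nx.Graph:
        """Undirected view of one channel (matter can be pumped either way)."""
        g = nx.Graph()
        g.add_nodes_from(n for n, m in self.nodes.items()
                         if any(c == channel for _, _, c in self._incident(n)))
        g.add_edges_from((u, v) for u, v, c in self.edges if c == channel)
        return g

    def _incident(self, node: str) -> list[tuple[str, str, str]]:
        return [(u, v, c) for u, v, c in self.edges if node in (u, v)]

    # -- serialization -----------------------------------------------------

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n, m in self.nodes.items():
            g.add_node(n, kind=m.kind)
        for u, v, c in self.edges:
            g.add_edge(u, v, channel=c)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "HardwareGraph":
        hw = cls()
        for n, data in sorted(g.nodes(data=True)):
            if "kind" not in data:
                raise GraphSchemaError(f"node {n!r} lacks a 'kind' attribute")
            hw.add_module(str(n), data["kind"])
        if g.is_multigraph():
            edge_iter = [(u, v, d) for u, v, _, d in g.edges(keys=True, data=True)]
        else:
            edge_iter = list(g.edges(data=True))
        for u, v, data in edge_iter:
            hw.connect(str(u), str(v), data.get("channel", "matter"))
        return hw

    def to_node_link(self) -> dict[str, Any]:
        return {
            "nodes": [{"id": n, "kind": m.kind} for n, m in sorted(self.nodes.items())],
            "edges": [{"from": u, "to": v, "channel": c} for u, v, c in self.edges],
        }

    @classmethod
    def from_node_link(cls, doc: Mapping[str, Any]) -> "HardwareGraph":
        hw = cls()
        for node in doc.get("nodes", ()):
            hw.add_module(node["id"], node["kind"])
        for edge in doc.get("edges", ()):
            hw.connect(edge["from"], edge["to"], edge.get("channel", "matter"))
        return hw


def export_graph(g: HardwareGraph, path: str) -> None:
    """Write GraphML (``.graphml``) or the JSON node-link dialect (``.json``)."""
    if path.endswith(".graphml"):
        nx.write_graphml(g.to_networkx(), path)
    else:
        with open(path, "w") as fh:
            json.dump(g.to_node_link(), fh, indent=2)


def import_graph(path: str) -> HardwareGraph:
    """Read a hardware graph; unknown kinds or duplicate ids are schema errors."""
    if path.endswith(".graphml"):
        return HardwareGraph.from_networkx(nx.read_graphml(path))
    with open(path) as fh:
        doc = json.load(fh)
    return HardwareGraph.from_node_link(doc)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class GraphDiagnostics:
    findings: list[tuple[str, str]] = field(default_factory=list)  # (level, message)

    def add(self, level: str, message: str) -> None:
        self.findings.append((level, message))

    @property
    def status(self) -> str:
        levels = {lvl for lvl, _ in self.findings}
        if "fail" in levels:
            return "fail"
        if "warn" in levels:
            return "warn"
        return "pass"

    def messages(self, level: str) -> list[str]:
        return [m for lvl, m in self.findings if lvl == level]


def validate_graph(g: HardwareGraph) -> GraphDiagnostics:
    """Structural checks: required modules, matter connectivity, orphans.

    All findings are report entries (pass/warn/fail); nothing raises.
    """
    diag = GraphDiagnostics()
    for kind in ("reactor", "waste", "product_vessel"):
        if not g.of_kind(kind):
            diag.add("fail", f"no {kind} module present")
    matter = g.channel_graph("matter")
    if matter.number_of_nodes():
        components = list(nx.connected_components(matter))
        if len(components) > 1:
            diag.add("fail", f"matter subgraph splits into {len(components)} components")
    for reactor in g.of_kind("reactor"):
        if reactor not in matter or matter.degree(reactor) == 0:
            diag.add("fail", f"reactor {reactor!r} has no matter connection")
    for node, module in sorted(g.nodes.items()):
        incident = g._incident(node)
        if module.kind in SENSOR_KINDS:
            if not incident:
                diag.add("warn", f"sensor {node!r} is isolated (no edges on any channel)")
        elif not any(c == "matter" for _, _, c in incident):
            diag.add("warn", f"module {node!r} ({module.kind}) has no matter edge")
    return diag


# ---------------------------------------------------------------------------
# chempiling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScheduleEntry:
    step_index: int
    op_name: str
    primitive: Primitive
    module_id: str
    route: tuple[str, ...]


@dataclass
class Schedule:
    entries: list[ScheduleEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self) -> list[dict[str, Any]]:
        return [
            {
                "step_index": e.step_index,
                "op": e.op_name,
                "primitive": e.primitive.to_dict(),
                "module": e.module_id,
                "route": list(e.route),
            }
            for e in self.entries
        ]


@dataclass
class ChempileResult:
    """Either a complete schedule or a diagnosis of the first gap."""

    feasible: bool
    schedule: Schedule | None = None
    diagnosis: str | None = None


def _shortest_route(matter: nx.Graph, src: str, dst: str) -> tuple[str, ...] | None:
    if src not in matter or dst not in matter:
        return None
    try:
        # lexicographic tie-break: Dijkstra over unit weights visits
        # sorted neighbours deterministically
        return tuple(nx.shortest_path(matter, src, dst))
    except nx.NetworkXNoPath:
        return None


def _am_route(g: HardwareGraph, matter: nx.Graph, reactor: str) -> tuple[str, tuple[str, ...]] | None:
    """Best (flask, route) for an AM: route must cross a pump or valve."""
    best: tuple[int, str, tuple[str, ...]] | None = None
    movers = set(g.of_kind("pump", "valve"))
    for flask in g.of_kind("reagent_flask"):
        direct = _shortest_route(matter, flask, reactor)
        candidates: list[tuple[str, ...]] = []
        if direct is not None and movers.intersection(direct):
            candidates.append(direct)
        else:
            for mover in sorted(movers):
                first = _shortest_route(matter, flask, mover)
                second = _shortest_route(matter, mover, reactor)
                if first is not None and second is not None:
                    candidates.append(first + second[1:])
        for route in candidates:
            key = (len(route), flask, route)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], best[2]


def _nearest_capable(g: HardwareGraph, matter: nx.Graph, reactor: str,
                     kinds: Sequence[str]) -> tuple[str, tuple[str, ...]] | None:
    best: tuple[int, str, tuple[str, ...]] | None = None
    for node in g.of_kind(*kinds):
        route = _shortest_route(matter, reactor, node)
        if route is None:
            continue
        key = (len(route), node, route)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[1], best[2]


def chempile(sigma: SynthesisPathway, inventory: HardwareGraph,
             registry: UnitOpRegistry | None = None) -> ChempileResult:
    """Map a synthesis pathway onto a hardware inventory.

    Every primitive of the compiled pathway is assigned to a capable
    module with a deterministic matter route from the reactor, or the
    first unschedulable primitive is diagnosed (with the missing
    capability named).  Adding modules or edges can only grow the
    candidate sets, so feasibility is monotone in the inventory.
    """
    program = compile_pathway(sigma, registry)
    matter = inventory.channel_graph("matter")
    reactors = inventory.of_kind("reactor")
    reactor = reactors[0] if reactors else None

    schedule = Schedule()
    # (step index, op name) per primitive, recovered from the checkpoint spans
    op_spans: list[tuple[int, str]] = []
    prev = 0
    for i, name, state in program.checkpoints:
        end = int(state[1:])
        op_spans.extend([(i, name)] * (end - prev))
        prev = end

    for prim_index, primitive in enumerate(program.primitives):
        step_index, op_name = op_spans[prim_index]
        if reactor is None:
            return ChempileResult(
                False, None,
                f"primitive {prim_index} ({primitive.kind} in {op_name!r}): "
                f"no reactor module in the inventory",
            )
        if primitive.kind == "AM":
            hit = _am_route(inventory, matter, reactor)
            missing = "reagent_flask with a pump/valve matter route to the reactor"
        elif primitive.kind == "SM":
            hit = _nearest_capable(inventory, matter, reactor,
                                   ("separator", "chromatography"))
            if hit is not None and primitive.port == "waste":
                module, route = hit
                tail = _nearest_capable(inventory, matter, module, ("waste",))
                if tail is not None:
                    hit = (module, route + tail[1][1:])
            missing = "separator/chromatography matter-reachable from the reactor"
        else:  # AE / SE
            hit = _nearest_capable(inventory, matter, reactor, ("stirrer_heater_cooler",))
            missing = "stirrer_heater_cooler matter-reachable from the reactor"
        if hit is None:
            return ChempileResult(
                False, None,
                f"primitive {prim_index} ({primitive.kind} in {op_name!r}): "
                f"no capable module — needs a {missing}",
            )
        module, route = hit
        schedule.entries.append(
            ScheduleEntry(step_index, op_name, primitive, module, route)
        )
    return ChempileResult(True, schedule, None)


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------


def reference_graph() -> HardwareGraph:
    """The shipped general-purpose bench graph.

    Two reagent flasks feed the reactor through pumps and a shared
    valve; the stirrer/heater/cooler sits on the reactor (matter jacket
    loop plus an energy channel); work-up runs through the separator,
    isolation/purification through chromatography into the product
    vessel; both can divert to waste.  Sensors attach on information
    channels only.
    """
    g = HardwareGraph()
    for node, kind in (
        ("flask_a", "reagent_flask"),
        ("flask_b", "reagent_flask"),
        ("pump_1", "pump"),
        ("pump_2", "pump"),
        ("valve_1", "valve"),
        ("reactor_1", "reactor"),
        ("stirrer_1", "stirrer_heater_cooler"),
        ("separator_1", "separator"),
        ("conductivity_1", "conductivity_sensor"),
        ("photon_1", "photon_sensor"),
        ("chromatography_1", "chromatography"),
        ("waste_1", "waste"),
        ("product_1", "product_vessel"),
    ):
        g.add_module(node, kind)
    for u, v in (
        ("flask_a", "pump_1"), ("pump_1", "valve_1"),
        ("flask_b", "pump_2"), ("pump_2", "valve_1"),
        ("valve_1", "reactor_1"),
        ("stirrer_1", "reactor_1"),
        ("reactor_1", "separator_1"),
        ("separator_1", "waste_1"),
        ("separator_1", "chromatography_1"),
        ("chromatography_1", "product_1"),
        ("chromatography_1", "waste_1"),
    ):
        g.connect(u, v, "matter")
    g.connect("stirrer_1", "reactor_1", "energy")
    g.connect("photon_1", "reactor_1", "information")
    g.connect("conductivity_1", "separator_1", "information")
    g.connect("chromatography_1", "photon_1", "information")
    return g
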