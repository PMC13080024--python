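"""Unit-operation macro library and synthesis-pathway compiler.

A unit operation is a named laboratory procedure — liquid–liquid
extraction, drying, crystallization, distillation, hot/cold reaction,
sublimation — expressed as a short sequence of the four machine
primitives.  The canonical seven entries ship in
``data/unit_ops.yaml`` (the "hot reaction; cold reaction" table row is
registered as two operations).  Macros expose *parameter slots* (the
``$name`` fields) that callers must bind explicitly: amounts,
temperatures, and species are program data, never library defaults.

:func:`compile_pathway` lowers an ordered sequence of unit-operation
invocations into a runnable machine program: states ``q0..qn``, one
transition per primitive, and a terminal transition into ``q_out``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping, Sequence

import yaml

from .core import (
    DEFAULT_CONDITION_BANDS,
    DEFAULT_EPSILON,
    AlphabetError,
    CSTMError,
    Machine,
    MachineConfig,
    Primitive,
    ReactionRule,
    Trace,
    TransitionRule,
    WILDCARD,
    mass_ledger,
)


class RegistryError(CSTMError):
    """Unknown unit-operation name."""


class ParameterError(CSTMError):
    """A macro parameter slot was left unbound."""


@dataclass(frozen=True)
class _PrimitiveTemplate:
    kind: str
    fields: tuple[tuple[str, Any], ...]  # field -> literal or "$slot"
    head_move: str = "N"

    def required_slots(self) -> set[str]:
        return {v[1:] for _, v in self.fields if isinstance(v, str) and v.startswith("$")}

    def bind(self, name: str, params: Mapping[str, Any]) -> Primitive:
        bound: dict[str, Any] = {"kind": self.kind}
        for fld, value in self.fields:
            if isinstance(value, str) and value.startswith("$"):
                slot = value[1:]
                if slot not in params:
                    raise ParameterError(
                        f"unit operation {name!r}: parameter slot {slot!r} is unbound"
                    )
                value = params[slot]
            bound[fld] = value
        if "amount" in bound:
            bound["amount"] = float(bound["amount"])
        return Primitive.from_dict(bound)


@dataclass(frozen=True)
class UnitOperation:
    """A named macro: primitive kinds with parameter slots."""

    name: str
    template: tuple[_PrimitiveTemplate, ...]
    notes: str = ""

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(t.kind for t in self.template)

    def slots(self) -> set[str]:
        out: set[str] = set()
        for t in self.template:
            out |= t.required_slots()
        return out

    def expand(self, params: Mapping[str, Any]) -> list[Primitive]:
        return [t.bind(self.name, params) for t in self.template]


#: canonical operation names; user registries may not shadow them
CANONICAL_NAMES = (
    "liquid-liquid extraction",
    "drying",
    "crystallization",
    "distillation",
    "hot reaction",
    "cold reaction",
    "sublimation",
)


class UnitOpRegistry:
    """Name → macro mapping; names are case-insensitive."""

    def __init__(self) -> None:
        self._ops: dict[str, UnitOperation] = {}

    def register(self, op: UnitOperation, *, allow_canonical: bool = False) -> None:
        key = op.name.lower()
        if key in (n.lower() for n in CANONICAL_NAMES) and not allow_canonical:
            raise RegistryError(f"{op.name!r} is a reserved canonical operation name")
        self._ops[key] = op

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._ops

    def get(self, name: str) -> UnitOperation:
        try:
            return self._ops[name.lower()]
        except KeyError:
            known = ", ".join(sorted(self._ops))
            raise RegistryError(f"unknown unit operation {name!r}; known: {known}") from None

    def names(self) -> list[str]:
        return sorted(self._ops)

    def merge_file(self, path: str) -> None:
        """Merge user-defined operations from a YAML registry file."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for name, entry in doc.items():
            self.register(_op_from_entry(name, entry))


def _op_from_entry(name: str, entry: Mapping[str, Any]) -> UnitOperation:
    templates = []
    for prim in entry.get("sequence", ()):
        prim = dict(prim)
        kind = prim.pop("kind")
        head_move = prim.pop("head_move", "N")
        templates.append(
            _PrimitiveTemplate(kind, tuple(sorted(prim.items())), head_move)
        )
    if not templates:
        raise RegistryError(f"unit operation {name!r} has an empty primitive sequence")
    return UnitOperation(name=name, template=tuple(templates), notes=entry.get("notes", ""))


def _load_canonical() -> UnitOpRegistry:
    reg = UnitOpRegistry()
    text = resources.files("cstm").joinpath("data/unit_ops.yaml").read_text()
    for name, entry in yaml.safe_load(text).items():
        reg.register(_op_from_entry(name, entry), allow_canonical=True)
    return reg


_DEFAULT_REGISTRY: UnitOpRegistry | None = None


def default_registry() -> UnitOpRegistry:
    """The shipped registry with the canonical table entries."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = _load_canonical()
    return _DEFAULT_REGISTRY


def expand_unit_op(name: str, params: Mapping[str, Any],
                   registry: UnitOpRegistry | None = None) -> list[Primitive]:
    """Expand a named unit operation into its fully bound primitive list."""
    registry = registry or default_registry()
    return registry.get(name).expand(params)


# ---------------------------------------------------------------------------
# synthesis pathways
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnitOpCall:
    """One pathway step: an operation name plus its slot bindings."""

    name: str
    params: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def make(cls, name: str, params: Mapping[str, Any] | None = None) -> "UnitOpCall":
        return cls(name, tuple(sorted((params or {}).items())))

    @property
    def params_dict(self) -> dict[str, Any]:
        return dict(self.params)


@dataclass
class SynthesisPathway:
    """An ordered unit-operation sequence from initial reagents to a target."""

    target: str
    steps: list[UnitOpCall] = field(default_factory=list)
    initial_reagents: dict[str, float] = field(default_factory=dict)
    reagent_alphabet: set[str] | None = None
    reactions: list[ReactionRule] = field(default_factory=list)
    condition_bands: Sequence[tuple[str, float]] = DEFAULT_CONDITION_BANDS

    def alphabet(self) -> set[str]:
        if self.reagent_alphabet is not None:
            return set(self.reagent_alphabet)
        sigma = set(self.initial_reagents) | {self.target}
        for rule in self.reactions:
            sigma |= {sp for sp, _ in rule.reactants} | {sp for sp, _ in rule.products}
        return sigma


@dataclass
class CompiledProgram:
    """A pathway lowered to a machine configuration.

    ``checkpoints`` marks unit-operation boundaries as
    (op index, op name, state entered after the op), which the
    error-correction loop uses as its validation points.
    ``primitives`` is the flat primitive stream, one per transition.
    """

    config: MachineConfig
    pathway: SynthesisPathway
    primitives: list[Primitive]
    checkpoints: list[tuple[int, str, str]]

    def machine(self) -> Machine:
        return Machine(self.config)


def compile_pathway(sigma: SynthesisPathway,
                    registry: UnitOpRegistry | None = None,
                    max_steps: int | None = None) -> CompiledProgram:
    """Lower a synthesis pathway to a runnable program.

    Emits states ``q0..qn`` (n = total expanded primitives) plus the
    four halting states, one transition per primitive (reading the
    wildcard symbol, since the symbolized cell contents depend on run
    data), and a terminal transition into ``q_out``.
    """
    registry = registry or default_registry()
    sigma_r = sigma.alphabet()

    primitives: list[Primitive] = []
    moves: list[str] = []
    checkpoints: list[tuple[int, str, str]] = []
    for i, call in enumerate(sigma.steps):
        expanded = registry.get(call.name).expand(call.params_dict)
        for prim, tpl in zip(expanded, registry.get(call.name).template):
            if prim.species is not None and prim.species not in sigma_r:
                raise AlphabetError(
                    f"pathway step {call.name!r} references species {prim.species!r} "
                    f"outside the reagent alphabet"
                )
            primitives.append(prim)
            moves.append(tpl.head_move)
        checkpoints.append((i, call.name, f"q{len(primitives)}"))

    states = [f"q{i}" for i in range(len(primitives) + 1)]
    rules = [
        TransitionRule(
            from_state=f"q{i}", read=WILDCARD, to_state=f"q{i + 1}",
            move=moves[i], actions=(primitives[i],),
        )
        for i in range(len(primitives))
    ]
    rules.append(TransitionRule(from_state=states[-1], read=WILDCARD, to_state="q_out"))

    reservoirs = {sp: float(a) for sp, a in sigma.initial_reagents.items()}
    config = MachineConfig(
        states=states,
        q0="q0",
        reagent_alphabet=sigma_r,
        rules=rules,
        reactions=sigma.reactions,
        reservoirs=reservoirs,
        condition_bands=sigma.condition_bands,
        max_steps=max_steps if max_steps is not None else len(rules) + 8,
    )
    return CompiledProgram(config=config, pathway=sigma,
                           primitives=primitives, checkpoints=checkpoints)


# ---------------------------------------------------------------------------
# mass-balance verification
# ---------------------------------------------------------------------------


@dataclass
class MassBalanceReport:
    passed: bool
    deltas: dict[str, float]
    epsilon: float

    def failing_species(self) -> list[str]:
        return sorted(sp for sp, d in self.deltas.items() if abs(d) > self.epsilon)


def verify_mass_balance(trace: Trace, epsilon: float = DEFAULT_EPSILON) -> MassBalanceReport:
    """Audit a trace: pass iff every per-species ledger delta is ≤ epsilon."""
    ledger = mass_ledger(trace)
    deltas = {sp: e.delta for sp, e in ledger.items()}
    return MassBalanceReport(
        passed=all(abs(d) <= epsilon for d in deltas.values()),
        deltas=deltas,
        epsilon=epsilon,
    )


# ---------------------------------------------------------------------------
# pathway files
# ---------------------------------------------------------------------------


def pathway_from_dict(doc: Mapping[str, Any]) -> SynthesisPathway:
    steps = [UnitOpCall.make(s["op"], s.get("params")) for s in doc.get("steps", ())]
    alphabet = doc.get("reagent_alphabet")
    return SynthesisPathway(
        target=doc["target"],
        steps=steps,
        initial_reagents={sp: float(a) for sp, a in (doc.get("initial_reagents") or {}).items()},
        reagent_alphabet=None if alphabet is None else set(alphabet),
        reactions=[ReactionRule.from_dict(r) for r in doc.get("reactions", ())],
        condition_bands=(
            DEFAULT_CONDITION_BANDS if doc.get("condition_bands") is None
            else [(str(l), float(u)) for l, u in doc["condition_bands"]]
        ),
    )


def load_pathway(path: str) -> SynthesisPathway:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise CSTMError(f"{path!r} does not contain a pathway document")
    return pathway_from_dict(doc)
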