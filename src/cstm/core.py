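"""Vessel-tape virtual machine for chemical state-machine simulation.

The machine is a Turing-style abstraction of an automated synthesis
platform: an extendable tape of reaction vessels, a single head, and an
instruction set of exactly four primitives — add matter (AM), subtract
matter (SM), add energy (AE), subtract energy (SE).  Named laboratory
unit operations (extraction, distillation, ...) are macros over these
primitives and live in :mod:`cstm.unit_ops`.

A deterministic transition function reads a *symbolized* view of the
head vessel (dominant species paired with an energy-derived condition
label, or the blank symbol for an empty vessel), executes a primitive
sequence, lets declared stoichiometric reaction rules fire, writes the
re-symbolized cell back to the tape, and moves the head.  Runs halt in
one of four chemical outcomes — ``q_out`` (characterized success),
``q_uout`` (predicted but unoptimized), ``q_nout`` (novel
transformation), ``q_fail`` (unrecoverable) — or exhaust the step
budget (``budget_exceeded``, an artifact-level outcome).

Every step appends a record to a :class:`Trace`.  Per-species totals
over tape + waste + hold − reservoir drawdown are constant across
records: primitives and reactions move or transform matter but never
create or destroy it.  :func:`mass_ledger` audits this invariant.

Amounts are dimensionless mass units; a reaction product inherits the
summed mass of its reactants.  Energy is a per-cell scalar proxy for
temperature/agitation and is deliberately *not* conserved globally.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Mapping, Sequence

import yaml

#: blank tape symbol
BLANK = "b"
#: wildcard read symbol: matches any tape symbol, at lower precedence
#: than an exact match, so the transition table stays deterministic
WILDCARD = "*"

#: amounts below this are pruned to exactly zero after each primitive
DEFAULT_EPSILON = 1e-12

#: (condition label, upper energy edge) pairs, ascending.  A cell with
#: energy e carries the first label whose edge satisfies e <= edge.
DEFAULT_CONDITION_BANDS = (("cold", -0.5), ("ambient", 0.5), ("hot", math.inf))

#: |energy| above which a non-empty vessel counts as "active"
ACTIVE_ENERGY = 0.5

PRIMITIVE_KINDS = ("AM", "SM", "AE", "SE")
CHEMICAL_HALTS = ("q_out", "q_uout", "q_nout", "q_fail")


class CSTMError(Exception):
    """Base class for machine-level errors."""


class ConfigurationError(CSTMError):
    """Malformed machine configuration (ambiguous rules, unbalanced reactions...)."""


class AlphabetError(CSTMError):
    """A species outside the reagent alphabet was referenced."""


class SymbolizationError(CSTMError):
    """Cell contents cannot be mapped to a tape symbol."""


class MachineHaltedError(CSTMError):
    """Attempt to step a machine that has already halted."""


class HaltState(str, Enum):
    q_out = "q_out"
    q_uout = "q_uout"
    q_nout = "q_nout"
    q_fail = "q_fail"
    #: step budget exhausted — an artifact-level outcome distinct from
    #: the four chemical halts
    budget_exceeded = "budget_exceeded"


# ---------------------------------------------------------------------------
# tape and vessels
# ---------------------------------------------------------------------------


@dataclass
class VesselCell:
    """One tape cell: a reaction vessel.

    ``state`` is derived, never stored: a vessel is *empty* iff its
    contents mapping is empty, *active* if it holds matter under
    significant energy input (|energy| > :data:`ACTIVE_ENERGY`), and
    *filled* otherwise.
    """

    id: str
    contents: dict[str, float] = field(default_factory=dict)
    energy: float = 0.0

    @property
    def state(self) -> str:
        if not self.contents:
            return "empty"
        return "active" if abs(self.energy) > ACTIVE_ENERGY else "filled"

    def total_mass(self) -> float:
        return sum(self.contents.values())

    def prune(self, epsilon: float = DEFAULT_EPSILON) -> None:
        for sp in [s for s, a in self.contents.items() if a < epsilon]:
            del self.contents[sp]

    def copy(self) -> "VesselCell":
        return VesselCell(self.id, dict(self.contents), self.energy)


@dataclass(frozen=True)
class Primitive:
    """One machine instruction.

    AM/SM name a species, a positive amount, and a matter port; AE/SE
    carry only a positive energy delta.  Ports: ``reservoir`` (AM
    source), ``waste`` (SM sink, write-only), ``hold`` (off-tape
    buffer/condenser vessel, both directions), ``cell:<id>`` (another
    tape cell).  Requested SM amounts may exceed what is present; the
    actual moved amount is clipped and a warning is recorded — a pump
    cannot withdraw absent material.
    """

    kind: str
    species: str | None = None
    amount: float = 0.0
    port: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise ConfigurationError(f"unknown primitive kind {self.kind!r}")
        if not (self.amount > 0.0 and math.isfinite(self.amount)):
            raise ConfigurationError(
                f"{self.kind} requires a positive finite amount, got {self.amount!r}"
            )
        if self.kind in ("AM", "SM"):
            if not self.species:
                raise ConfigurationError(f"{self.kind} requires a species label")
            port = self.port or ("reservoir" if self.kind == "AM" else "waste")
            object.__setattr__(self, "port", port)
            cellish = port.startswith("cell:")
            if self.kind == "AM" and not (port in ("reservoir", "hold") or cellish):
                raise ConfigurationError(f"AM source must be reservoir/hold/cell:<id>, got {port!r}")
            if self.kind == "SM" and not (port in ("waste", "hold") or cellish):
                raise ConfigurationError(f"SM sink must be waste/hold/cell:<id>, got {port!r}")
        else:
            if self.species is not None or self.port is not None:
                raise ConfigurationError(f"{self.kind} carries no species or port")

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"kind": self.kind, "amount": self.amount}
        if self.species is not None:
            d["species"] = self.species
        if self.port is not None:
            d["port"] = self.port
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Primitive":
        return cls(
            kind=d["kind"],
            species=d.get("species"),
            amount=float(d["amount"]),
            port=d.get("port"),
        )


@dataclass
class PrimitiveOutcome:
    """What actually happened when a primitive executed."""

    kind: str
    species: str | None
    requested: float
    moved: float  # mass moved (AM/SM) or energy delta applied (AE/SE)
    port: str | None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "species": self.species,
            "requested": self.requested,
            "moved": self.moved,
            "port": self.port,
            "warnings": list(self.warnings),
        }


@dataclass
class Tape:
    """Vessel tape plus the off-tape waste and hold vessels.

    The tape is conceptually infinite: fresh empty cells materialize
    lazily when the head moves past either end.  ``waste`` only ever
    receives matter (its totals are monotonically non-decreasing over a
    run); ``hold`` is a recoverable buffer so operations like
    distillation can park a vapor fraction and collect it later.
    ``reservoirs`` maps species to remaining stock (``math.inf`` means
    unbounded); ``drawdown`` records cumulative consumption so the mass
    ledger can close.
    """

    cells: list[VesselCell] = field(default_factory=list)
    head: int = 0
    waste: VesselCell = field(default_factory=lambda: VesselCell("waste"))
    hold: VesselCell = field(default_factory=lambda: VesselCell("hold"))
    reservoirs: dict[str, float] = field(default_factory=dict)
    drawdown: dict[str, float] = field(default_factory=dict)
    #: cumulative per-species mass produced / consumed by reaction firing,
    #: so the per-species ledger closes across transformations
    converted_in: dict[str, float] = field(default_factory=dict)
    converted_out: dict[str, float] = field(default_factory=dict)
    epsilon: float = DEFAULT_EPSILON
    _next_id: int = 0

    @classmethod
    def fresh(cls, reservoirs: Mapping[str, float] | None = None,
              epsilon: float = DEFAULT_EPSILON) -> "Tape":
        tape = cls(reservoirs=dict(reservoirs or {}), epsilon=epsilon)
        tape.cells.append(tape._new_cell())
        return tape

    def _new_cell(self) -> VesselCell:
        cell = VesselCell(f"v{self._next_id}")
        self._next_id += 1
        return cell

    @property
    def current_cell(self) -> VesselCell:
        return self.cells[self.head]

    def cell_by_id(self, cell_id: str) -> VesselCell:
        for cell in self.cells:
            if cell.id == cell_id:
                return cell
        raise CSTMError(f"no tape cell with id {cell_id!r}")

    def move(self, direction: str) -> None:
        if direction in ("N", "None", "stay"):
            return
        if direction in ("R", "Right"):
            self.head += 1
            if self.head == len(self.cells):
                self.cells.append(self._new_cell())
        elif direction in ("L", "Left"):
            if self.head == 0:
                self.cells.insert(0, self._new_cell())
            else:
                self.head -= 1
        else:
            raise ConfigurationError(f"unknown head move {direction!r}")

    def species_totals(self) -> dict[str, dict[str, float]]:
        """Per-species mass split by location plus cumulative flows.

        Buckets: ``tape``, ``waste``, ``hold`` (where the species sits),
        ``drawdown`` (cumulative reservoir consumption), ``reacted_in`` /
        ``reacted_out`` (cumulative mass produced / consumed by reaction
        firing).  The conserved net per species is
        tape + waste + hold + reacted_out − drawdown − reacted_in.
        """
        totals: dict[str, dict[str, float]] = {}

        def bucket(sp: str) -> dict[str, float]:
            return totals.setdefault(sp, {
                "tape": 0.0, "waste": 0.0, "hold": 0.0,
                "drawdown": 0.0, "reacted_in": 0.0, "reacted_out": 0.0,
            })

        for cell in self.cells:
            for sp, amt in cell.contents.items():
                bucket(sp)["tape"] += amt
        for sp, amt in self.waste.contents.items():
            bucket(sp)["waste"] += amt
        for sp, amt in self.hold.contents.items():
            bucket(sp)["hold"] += amt
        for sp, amt in self.drawdown.items():
            bucket(sp)["drawdown"] += amt
        for sp, amt in self.converted_in.items():
            bucket(sp)["reacted_in"] += amt
        for sp, amt in self.converted_out.items():
            bucket(sp)["reacted_out"] += amt
        return totals

    # -- primitive execution -----------------------------------------------

    def apply(self, p: Primitive, *, reagent_alphabet: Iterable[str] | None = None,
              energy_limits: tuple[float, float] = (-math.inf, math.inf)) -> PrimitiveOutcome:
        cell = self.current_cell
        out = PrimitiveOutcome(p.kind, p.species, p.amount, 0.0, p.port)

        if p.kind == "AM":
            if reagent_alphabet is not None and p.species not in reagent_alphabet:
                raise AlphabetError(f"species {p.species!r} is not in the reagent alphabet")
            source = self._matter_port(p.port)
            if source is None:  # reservoir
                available = self.reservoirs.get(p.species, 0.0)
            else:
                available = source.contents.get(p.species, 0.0)
            moved = min(p.amount, available)
            if moved < p.amount:
                out.warnings.append(
                    f"AM clipped: requested {p.amount} of {p.species}, "
                    f"only {available} available at {p.port}"
                )
            if moved > 0.0:
                if source is None:
                    if math.isfinite(self.reservoirs.get(p.species, 0.0)):
                        self.reservoirs[p.species] -= moved
                    self.drawdown[p.species] = self.drawdown.get(p.species, 0.0) + moved
                else:
                    source.contents[p.species] -= moved
                    source.prune(self.epsilon)
                cell.contents[p.species] = cell.contents.get(p.species, 0.0) + moved
            out.moved = moved

        elif p.kind == "SM":
            present = cell.contents.get(p.species, 0.0)
            moved = min(p.amount, present)
            if present == 0.0:
                out.warnings.append(
                    f"SM no-op: {p.species} absent from cell {cell.id}"
                )
            elif moved < p.amount:
                out.warnings.append(
                    f"SM clipped: requested {p.amount} of {p.species}, only {present} present"
                )
            if moved > 0.0:
                cell.contents[p.species] -= moved
                sink = self._matter_port(p.port)
                assert sink is not None  # reservoir sink rejected at construction
                sink.contents[p.species] = sink.contents.get(p.species, 0.0) + moved
            out.moved = moved

        elif p.kind == "AE":
            new = cell.energy + p.amount
            if new > energy_limits[1]:
                out.warnings.append(f"AE clipped at energy ceiling {energy_limits[1]}")
                new = energy_limits[1]
            out.moved = new - cell.energy
            cell.energy = new

        elif p.kind == "SE":
            new = cell.energy - p.amount
            if new < energy_limits[0]:
                out.warnings.append(f"SE clipped at energy floor {energy_limits[0]}")
                new = energy_limits[0]
            out.moved = cell.energy - new
            cell.energy = new

        cell.prune(self.epsilon)
        return out

    def _matter_port(self, port: str | None) -> VesselCell | None:
        """Resolve a matter port; ``None`` stands for the reservoir bank."""
        if port == "reservoir":
            return None
        if port == "waste":
            return self.waste
        if port == "hold":
            return self.hold
        if port is not None and port.startswith("cell:"):
            return self.cell_by_id(port[5:])
        raise ConfigurationError(f"unknown matter port {port!r}")


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionRule:
    """Mass-typed stoichiometric transformation.

    Coefficients are abstract mass units, so conservation requires the
    reactant and product coefficient sums to be equal — validated at
    load time.  The rule fires when every reactant is present at its
    full stoichiometric amount and the cell energy lies inside
    [energy_min, energy_max]; it converts ``yield_fraction`` of the
    limiting stoichiometric extent.
    """

    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    energy_min: float = -math.inf
    energy_max: float = math.inf
    yield_fraction: float = 1.0

    @classmethod
    def make(cls, reactants: Mapping[str, float], products: Mapping[str, float],
             energy_min: float = -math.inf, energy_max: float = math.inf,
             yield_fraction: float = 1.0) -> "ReactionRule":
        rule = cls(
            tuple(sorted(reactants.items())),
            tuple(sorted(products.items())),
            float(energy_min),
            float(energy_max),
            float(yield_fraction),
        )
        rule.validate()
        return rule

    def validate(self) -> None:
        if not self.reactants or not self.products:
            raise ConfigurationError("reaction needs at least one reactant and one product")
        for sp, amt in self.reactants + self.products:
            if amt <= 0.0:
                raise ConfigurationError(f"non-positive stoichiometric amount for {sp!r}")
        r_mass = sum(a for _, a in self.reactants)
        p_mass = sum(a for _, a in self.products)
        if abs(r_mass - p_mass) > 1e-9:
            raise ConfigurationError(
                f"reaction violates mass balance: reactants {r_mass} vs products {p_mass}"
            )
        if not (0.0 < self.yield_fraction <= 1.0):
            raise ConfigurationError("yield_fraction must lie in (0, 1]")

    def to_dict(self) -> dict[str, Any]:
        return {
            "reactants": dict(self.reactants),
            "products": dict(self.products),
            "energy_min": self.energy_min,
            "energy_max": self.energy_max,
            "yield_fraction": self.yield_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ReactionRule":
        return cls.make(
            d["reactants"],
            d["products"],
            _number(d.get("energy_min", -math.inf)),
            _number(d.get("energy_max", math.inf)),
            float(d.get("yield_fraction", 1.0)),
        )


def _fire_reactions(cell: VesselCell, rules: Sequence[ReactionRule],
                    epsilon: float = DEFAULT_EPSILON) -> list[int]:
    """Fire each eligible rule once, in declaration order.

    Returns the indices of the rules that fired.  Declaration order is
    the determinism tie-break: the transition function is single-valued.
    """
    fired: list[int] = []
    for i, rule in enumerate(rules):
        if not cell.contents:
            continue
        if not (rule.energy_min <= cell.energy <= rule.energy_max):
            continue
        if any(cell.contents.get(sp, 0.0) + epsilon < amt for sp, amt in rule.reactants):
            continue
        extent = min(cell.contents[sp] / amt for sp, amt in rule.reactants)
        conv = extent * rule.yield_fraction
        for sp, amt in rule.reactants:
            cell.contents[sp] -= amt * conv
        for sp, amt in rule.products:
            cell.contents[sp] = cell.contents.get(sp, 0.0) + amt * conv
        cell.prune(epsilon)
        fired.append(i)
    return fired


def fire_reactions(cell: VesselCell, rules: Sequence[ReactionRule],
                   epsilon: float = DEFAULT_EPSILON) -> VesselCell:
    """Apply every eligible reaction rule to ``cell`` (mutating it)."""
    _fire_reactions(cell, rules, epsilon)
    return cell


# ---------------------------------------------------------------------------
# machine configuration
# ---------------------------------------------------------------------------

Symbol = Any  # BLANK, WILDCARD, or (species, condition) tuple


def _normalize_symbol(value: Any, *, allow_wildcard: bool = False) -> Symbol:
    if value is None or value == BLANK:
        return BLANK
    if value == WILDCARD:
        if not allow_wildcard:
            raise ConfigurationError("wildcard symbol only allowed in rule reads")
        return WILDCARD
    if isinstance(value, (list, tuple)) and len(value) == 2:
        return (str(value[0]), str(value[1]))
    raise ConfigurationError(f"malformed tape symbol {value!r}")


@dataclass(frozen=True)
class TransitionRule:
    """One entry of the transition function δ.

    ``read`` is an exact tape symbol or the wildcard ``*``; an exact
    match always wins over the wildcard.  ``write`` is the *declared*
    post-symbol: the tape symbol is always re-derived from the actual
    cell contents, and a mismatch with the declaration is recorded as a
    warning rather than an error.  ``actions`` is the primitive
    sequence executed on the head cell before reactions fire.
    """

    from_state: str
    read: Symbol
    to_state: str
    write: Symbol | None = None
    move: str = "N"
    actions: tuple[Primitive, ...] = ()

    def to_dict(self) -> dict[str, Any]:
        return {
            "from": self.from_state,
            "read": list(self.read) if isinstance(self.read, tuple) else self.read,
            "to": self.to_state,
            "write": list(self.write) if isinstance(self.write, tuple) else self.write,
            "move": self.move,
            "actions": [p.to_dict() for p in self.actions],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TransitionRule":
        return cls(
            from_state=d.get("from", d.get("from_state")),
            read=_normalize_symbol(d.get("read"), allow_wildcard=True),
            to_state=d.get("to", d.get("to_state")),
            write=None if d.get("write") is None else _normalize_symbol(d["write"]),
            move={"Left": "L", "Right": "R"}.get(d.get("move", "N"), d.get("move", "N")),
            actions=tuple(Primitive.from_dict(a) for a in d.get("actions", ())),
        )


class MachineConfig:
    """The machine 8-tuple plus an execution budget.

    States Q, initial state q0, reagent alphabet Σ_R, process alphabet
    Σ_P (the condition-band labels), blank b, transition rules δ, and
    the four halting labels (always members of Q).  ``condition_bands``
    is the symbolization contract: an ascending list of
    ``(label, upper energy edge)`` pairs mapping a cell's energy scalar
    to its condition label.
    """

    def __init__(
        self,
        states: Iterable[str],
        q0: str,
        reagent_alphabet: Iterable[str],
        rules: Sequence[TransitionRule],
        reactions: Sequence[ReactionRule] = (),
        reservoirs: Mapping[str, float] | None = None,
        condition_bands: Sequence[tuple[str, float]] = DEFAULT_CONDITION_BANDS,
        max_steps: int = 1000,
        epsilon: float = DEFAULT_EPSILON,
        energy_limits: tuple[float, float] = (-math.inf, math.inf),
    ) -> None:
        self.states = set(states) | set(CHEMICAL_HALTS)
        self.q0 = q0
        self.reagent_alphabet = set(reagent_alphabet)
        self.rules = tuple(rules)
        self.reactions = tuple(reactions)
        self.reservoirs = dict(reservoirs or {})
        self.condition_bands = tuple((str(l), float(u)) for l, u in condition_bands)
        self.max_steps = int(max_steps)
        self.epsilon = float(epsilon)
        self.energy_limits = (float(energy_limits[0]), float(energy_limits[1]))
        self._validate()
        self._table = {(r.from_state, r.read): (r, i) for i, r in enumerate(self.rules)}

    @property
    def process_alphabet(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.condition_bands)

    def _validate(self) -> None:
        if self.q0 not in self.states:
            raise ConfigurationError(f"initial state {self.q0!r} not in Q")
        if not self.condition_bands:
            raise ConfigurationError("at least one condition band is required")
        uppers = [u for _, u in self.condition_bands]
        if uppers != sorted(uppers):
            raise ConfigurationError("condition band edges must be ascending")
        if self.max_steps < 0:
            raise ConfigurationError("max_steps must be non-negative")
        seen: set[tuple[str, Symbol]] = set()
        for rule in self.rules:
            key = (rule.from_state, rule.read)
            if key in seen:
                raise ConfigurationError(f"ambiguous transition rules for {key!r}")
            seen.add(key)
            for st, role in ((rule.from_state, "from"), (rule.to_state, "to")):
                if st not in self.states:
                    raise ConfigurationError(f"rule {role}-state {st!r} not in Q")
            if rule.move not in ("L", "R", "N"):
                raise ConfigurationError(f"unknown head move {rule.move!r}")
            for sym in (rule.read, rule.write):
                if isinstance(sym, tuple):
                    sp, cond = sym
                    if sp not in self.reagent_alphabet:
                        raise ConfigurationError(f"symbol species {sp!r} not in reagent alphabet")
                    if cond not in self.process_alphabet:
                        raise ConfigurationError(f"symbol condition {cond!r} not in process alphabet")
        for rule in self.reactions:
            rule.validate()

    def condition_of(self, energy: float) -> str:
        for label, upper in self.condition_bands:
            if energy <= upper:
                return label
        return self.condition_bands[-1][0]

    def lookup(self, state: str, symbol: Symbol) -> tuple[TransitionRule | None, int | None]:
        hit = self._table.get((state, symbol)) or self._table.get((state, WILDCARD))
        return hit if hit is not None else (None, None)

    def to_dict(self) -> dict[str, Any]:
        return {
            "states": sorted(self.states),
            "initial_state": self.q0,
            "reagents": sorted(self.reagent_alphabet),
            "condition_bands": [[l, u] for l, u in self.condition_bands],
            "reservoirs": {
                sp: ("unbounded" if math.isinf(v) else v) for sp, v in self.reservoirs.items()
            },
            "max_steps": self.max_steps,
            "epsilon": self.epsilon,
            "energy_limits": list(self.energy_limits),
            "reactions": [r.to_dict() for r in self.reactions],
            "rules": [r.to_dict() for r in self.rules],
        }


def _number(v: Any) -> float:
    if isinstance(v, str):
        low = v.strip().lower()
        if low in ("inf", "+inf", ".inf", "infinity", "unbounded"):
            return math.inf
        if low in ("-inf", "-.inf", "-infinity"):
            return -math.inf
    return float(v)


def config_from_dict(doc: Mapping[str, Any]) -> MachineConfig:
    try:
        reservoirs = {sp: _number(v) for sp, v in (doc.get("reservoirs") or {}).items()}
        bands = doc.get("condition_bands")
        return MachineConfig(
            states=doc.get("states", ()),
            q0=doc.get("initial_state", doc.get("q0", "q0")),
            reagent_alphabet=doc.get("reagents", doc.get("reagent_alphabet", ())),
            rules=[TransitionRule.from_dict(r) for r in doc.get("rules", ())],
            reactions=[ReactionRule.from_dict(r) for r in doc.get("reactions", ())],
            reservoirs=reservoirs,
            condition_bands=(
                DEFAULT_CONDITION_BANDS if bands is None
                else [(str(l), _number(u)) for l, u in bands]
            ),
            max_steps=doc.get("max_steps", doc.get("budget", 1000)),
            epsilon=doc.get("epsilon", DEFAULT_EPSILON),
            energy_limits=tuple(
                _number(v) for v in doc.get("energy_limits", (-math.inf, math.inf))
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed machine program: {exc}") from exc


# ---------------------------------------------------------------------------
# symbolization
# ---------------------------------------------------------------------------


def symbolize(cell: VesselCell, config: MachineConfig) -> Symbol:
    """Map vessel contents to a tape symbol.

    Empty cell → blank.  Otherwise the dominant species by amount
    (ties broken lexicographically), paired with the condition label of
    the cell's energy.  Only species in the reagent alphabet are
    considered; a cell holding none of them cannot be symbolized.
    """
    if not cell.contents:
        return BLANK
    candidates = [s for s in cell.contents if s in config.reagent_alphabet]
    if not candidates:
        raise SymbolizationError(
            f"cell {cell.id!r} holds no species from the reagent alphabet; "
            f"alien species: {sorted(cell.contents)}"
        )
    dominant = min(candidates, key=lambda s: (-cell.contents[s], s))
    return (dominant, config.condition_of(cell.energy))


def read_symbol(tape: Tape, config: MachineConfig) -> Symbol:
    """Symbolize the cell under the head."""
    return symbolize(tape.current_cell, config)


def apply_primitive(tape: Tape, p: Primitive) -> Tape:
    """Execute one primitive on the head cell of ``tape`` (mutating it)."""
    tape.apply(p)
    return tape


# ---------------------------------------------------------------------------
# trace
# ---------------------------------------------------------------------------


def _symbol_json(sym: Symbol | None) -> Any:
    return list(sym) if isinstance(sym, tuple) else sym


def _symbol_from_json(v: Any) -> Symbol | None:
    return tuple(v) if isinstance(v, list) else v


@dataclass
class TraceRecord:
    step: int
    state_before: str
    state_after: str
    head_before: int
    head_after: int
    symbol_read: Symbol
    symbol_written: Symbol | None
    rule_index: int | None
    primitives: list[dict[str, Any]]
    reactions_fired: list[int]
    warnings: list[str]
    totals: dict[str, dict[str, float]]

    def to_dict(self) -> dict[str, Any]:
        d = {
            "step": self.step,
            "state_before": self.state_before,
            "state_after": self.state_after,
            "head_before": self.head_before,
            "head_after": self.head_after,
            "symbol_read": _symbol_json(self.symbol_read),
            "symbol_written": _symbol_json(self.symbol_written),
            "rule_index": self.rule_index,
            "primitives": self.primitives,
            "reactions_fired": self.reactions_fired,
            "warnings": self.warnings,
            "totals": self.totals,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "TraceRecord":
        return cls(
            step=d["step"],
            state_before=d["state_before"],
            state_after=d["state_after"],
            head_before=d["head_before"],
            head_after=d["head_after"],
            symbol_read=_symbol_from_json(d["symbol_read"]),
            symbol_written=_symbol_from_json(d["symbol_written"]),
            rule_index=d["rule_index"],
            primitives=list(d["primitives"]),
            reactions_fired=list(d["reactions_fired"]),
            warnings=list(d["warnings"]),
            totals={sp: dict(t) for sp, t in d["totals"].items()},
        )


@dataclass
class Trace:
    """Complete laboratory trace of a run: one record per machine step.

    ``baseline`` snapshots the per-species totals before the first
    step; the conservation invariant is that every record's net total
    (tape + waste + hold − drawdown) equals the baseline net total.
    """

    baseline: dict[str, dict[str, float]] = field(default_factory=dict)
    records: list[TraceRecord] = field(default_factory=list)

    def to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"baseline": self.baseline}) + "\n")
            for rec in self.records:
                fh.write(json.dumps(rec.to_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path: str) -> "Trace":
        with open(path) as fh:
            lines = [json.loads(line) for line in fh if line.strip()]
        if not lines or "baseline" not in lines[0]:
            raise CSTMError(f"{path!r} is not a trace file")
        return cls(
            baseline=lines[0]["baseline"],
            records=[TraceRecord.from_dict(d) for d in lines[1:]],
        )


def _net_totals(totals: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    return {
        sp: (t.get("tape", 0.0) + t.get("waste", 0.0) + t.get("hold", 0.0)
             + t.get("reacted_out", 0.0) - t.get("drawdown", 0.0) - t.get("reacted_in", 0.0))
        for sp, t in totals.items()
    }


@dataclass(frozen=True)
class LedgerEntry:
    initial: float
    final: float
    delta: float


def mass_ledger(trace: Trace) -> dict[str, LedgerEntry]:
    """Per-species (initial, final, delta) over a run.

    Totals are net of reservoir drawdown, so the delta is exactly zero
    (up to the pruning epsilon) for a conservation-respecting run; a
    nonzero delta is reported, never raised.
    """
    if not trace.records:
        raise ValueError("mass_ledger requires a non-empty trace")
    initial = _net_totals(trace.baseline)
    final = _net_totals(trace.records[-1].totals)
    out: dict[str, LedgerEntry] = {}
    for sp in sorted(set(initial) | set(final)):
        a, b = initial.get(sp, 0.0), final.get(sp, 0.0)
        out[sp] = LedgerEntry(a, b, b - a)
    return out


# ---------------------------------------------------------------------------
# the machine
# ---------------------------------------------------------------------------


class Machine:
    """A configured machine instance: config + tape + control state."""

    def __init__(self, config: MachineConfig, tape: Tape | None = None,
                 state: str | None = None) -> None:
        self.config = config
        self.tape = tape if tape is not None else Tape.fresh(
            dict(config.reservoirs), epsilon=config.epsilon
        )
        self.state = state if state is not None else config.q0
        self.halted: HaltState | None = None
        self.trace = Trace(baseline=self.tape.species_totals())

    # -- execution ---------------------------------------------------------

    def read_symbol(self) -> Symbol:
        return symbolize(self.tape.current_cell, self.config)

    def step(self) -> TraceRecord:
        """Execute one transition; may set :attr:`halted`."""
        if self.halted is not None or self.state in CHEMICAL_HALTS:
            raise MachineHaltedError(f"cannot step a machine halted in {self.state!r}")
        state_before = self.state
        head_before = self.tape.head
        step_index = len(self.trace.records)
        symbol = self.read_symbol()
        rule, rule_index = self.config.lookup(state_before, symbol)

        if rule is None:
            # unrecoverable chemical termination: δ has no entry
            self.state = "q_fail"
            self.halted = HaltState.q_fail
            rec = TraceRecord(
                step=step_index, state_before=state_before, state_after="q_fail",
                head_before=head_before, head_after=head_before,
                symbol_read=symbol, symbol_written=None, rule_index=None,
                primitives=[], reactions_fired=[],
                warnings=[f"no transition for state {state_before!r} reading {symbol!r}"],
                totals=self.tape.species_totals(),
            )
            self.trace.records.append(rec)
            return rec

        warnings: list[str] = []
        outcomes: list[dict[str, Any]] = []
        for p in rule.actions:
            out = self.tape.apply(
                p,
                reagent_alphabet=self.config.reagent_alphabet,
                energy_limits=self.config.energy_limits,
            )
            outcomes.append(out.to_dict())
            warnings.extend(out.warnings)
        cell = self.tape.current_cell
        before = dict(cell.contents)
        fired = _fire_reactions(cell, self.config.reactions, self.config.epsilon)
        if fired:
            for sp in set(before) | set(cell.contents):
                diff = cell.contents.get(sp, 0.0) - before.get(sp, 0.0)
                if diff > 0:
                    self.tape.converted_in[sp] = self.tape.converted_in.get(sp, 0.0) + diff
                elif diff < 0:
                    self.tape.converted_out[sp] = self.tape.converted_out.get(sp, 0.0) - diff
        written = symbolize(self.tape.current_cell, self.config)
        if rule.write is not None and rule.write != written:
            warnings.append(
                f"declared write {rule.write!r} differs from symbolized cell {written!r}"
            )
        self.tape.move(rule.move)
        self.state = rule.to_state
        if rule.to_state in CHEMICAL_HALTS:
            self.halted = HaltState(rule.to_state)
        rec = TraceRecord(
            step=step_index, state_before=state_before, state_after=rule.to_state,
            head_before=head_before, head_after=self.tape.head,
            symbol_read=symbol, symbol_written=written, rule_index=rule_index,
            primitives=outcomes, reactions_fired=fired, warnings=warnings,
            totals=self.tape.species_totals(),
        )
        self.trace.records.append(rec)
        return rec

    def run(self, max_steps: int | None = None) -> tuple[HaltState, Trace]:
        """Iterate :meth:`step` until a halt or the step budget."""
        limit = self.config.max_steps if max_steps is None else int(max_steps)
        while self.halted is None and len(self.trace.records) < limit:
            self.step()
        if self.halted is None:
            self.halted = HaltState.budget_exceeded
        return self.halted, self.trace

    # -- snapshot / restore (used by the error-correction loop) -----------

    def snapshot(self) -> dict[str, Any]:
        return {
            "tape": copy.deepcopy(self.tape),
            "state": self.state,
            "halted": self.halted,
            "n_records": len(self.trace.records),
        }

    def restore(self, snap: Mapping[str, Any]) -> None:
        self.tape = copy.deepcopy(snap["tape"])
        self.state = snap["state"]
        self.halted = snap["halted"]
        del self.trace.records[snap["n_records"]:]

    # -- rendering ---------------------------------------------------------

    def render_tape(self) -> str:
        """Plain-text color tape: ``.`` empty, ``o`` filled, ``*`` active."""
        glyphs = {"empty": ".", "filled": "o", "active": "*"}
        parts = []
        for i, cell in enumerate(self.tape.cells):
            g = glyphs[cell.state]
            parts.append(f"[{g}]" if i == self.tape.head else f" {g} ")
        return "".join(parts)


def step(machine: Machine) -> TraceRecord:
    """Functional wrapper: execute one transition of ``machine``."""
    return machine.step()


def run(machine: Machine, max_steps: int | None = None) -> tuple[HaltState, Trace]:
    """Functional wrapper: run ``machine`` to halt or budget."""
    return machine.run(max_steps)


# ---------------------------------------------------------------------------
# program files
# ---------------------------------------------------------------------------


def machine_from_dict(doc: Mapping[str, Any]) -> Machine:
    config = config_from_dict(doc)
    machine = Machine(config)
    for i, spec in enumerate(doc.get("initial_tape", ()) or ()):
        if i == 0:
            cell = machine.tape.cells[0]
        else:
            machine.tape.cells.append(machine.tape._new_cell())
            cell = machine.tape.cells[-1]
        for sp, amt in (spec.get("contents") or {}).items():
            if sp not in config.reagent_alphabet:
                raise AlphabetError(f"initial tape species {sp!r} not in reagent alphabet")
            cell.contents[sp] = float(amt)
        cell.energy = float(spec.get("energy", 0.0))
    machine.trace.baseline = machine.tape.species_totals()
    return machine


def load_program(path: str) -> Machine:
    """Load a YAML/JSON machine program and return a fresh machine."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path!r} does not contain a program document")
    return machine_from_dict(doc)


def save_program(config: MachineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
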