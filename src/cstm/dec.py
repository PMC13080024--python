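"""Simulated dynamic error correction (DEC) and halt classification.

Automated synthesis is checkpointed at three stages — reaction
execution, work-up, and isolation/purification.  At each checkpoint
the observed per-species state (in simulation: the true state under
multiplicative Gaussian sensor noise) is compared against the expected
state; deviations are classified into three severities and answered
with a matching corrective action:

* minor (relative deviation below the first band edge, default 0.05)
  → nudge process parameters (a bounded energy adjustment);
* intermediate (default 0.05–0.20, e.g. an incomplete conversion)
  → repeat or extend the unit operation once, optionally with a
  reagent top-up;
* major (≥ 0.20, or any unexpected side product at ≥ 10 % of the
  expected product mass) → roll back to the last validated snapshot.

Interventions are drawn from a per-checkpoint retry budget; exhausting
it is an unrecoverable termination (``q_fail``).  Corrections move
matter (snapshot restore, reservoir top-ups) but never create it, so
the mass ledger of a corrected run still closes.

The three severity band edges are package defaults, not literature
values: the severity taxonomy is qualitative in origin and the
numbers here are configurable calibration choices.

:func:`classify_halt` implements the four-way halting semantics
against a persistent rule database: a characterized transformation
halts ``q_out``; a predicted-but-unoptimized one halts ``q_uout`` on
first observation; an unknown one halts ``q_nout`` and is recorded as
novel; and a repeated ``q_uout``/``q_nout`` transformation is promoted
to characterized, so its re-execution is ``q_out``.  A product whose
flawless-copy count falls below the detectability threshold is not a
result at all: ``q_fail``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np

from .assembly import DetectabilitySpec
from .core import CSTMError, HaltState, Machine, Trace
from .unit_ops import CompiledProgram

#: (minor→intermediate, intermediate→major) relative-deviation band edges
DEFAULT_SEVERITY_BANDS = (0.05, 0.20)

#: an unexpected species at ≥ this fraction of expected product mass is major
SIDE_PRODUCT_FRACTION = 0.10

#: checkpoint validation tolerance on the deviation magnitude
DEFAULT_TOLERANCE = 0.02

#: checkpoints cycle through the three stages in order
STAGES = ("reaction", "workup", "isolation_purification")

EPS = 1e-12


@dataclass(frozen=True)
class Checkpoint:
    """Expected per-species state at one validation point."""

    stage: str
    expected: tuple[tuple[str, float], ...]
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("checkpoint tolerance must be positive")

    @property
    def expected_dict(self) -> dict[str, float]:
        return dict(self.expected)


@dataclass(frozen=True)
class Deviation:
    severity: str  # minor | intermediate | major
    magnitude: float


def classify_deviation(observed: Mapping[str, float], expected: Mapping[str, float],
                       bands: tuple[float, float] = DEFAULT_SEVERITY_BANDS) -> Deviation:
    """Three-tier severity from the max relative per-species deviation.

    magnitude = max over expected species of |obs − exp| / max(exp, ε);
    an observed species absent from the expectation contributes its
    fraction of the total expected mass and forces *major* once it
    reaches :data:`SIDE_PRODUCT_FRACTION` (an unexpected side
    reaction).
    """
    if not any(v > 0 for v in expected.values()):
        raise ValueError("at least one expected amount must be positive")
    lo, hi = bands
    magnitude = 0.0
    forced_major = False
    for sp, exp in expected.items():
        obs = observed.get(sp, 0.0)
        magnitude = max(magnitude, abs(obs - exp) / max(exp, EPS))
    total_expected = sum(expected.values())
    for sp, obs in observed.items():
        if sp in expected:
            continue
        fraction = obs / max(total_expected, EPS)
        magnitude = max(magnitude, fraction)
        if fraction >= SIDE_PRODUCT_FRACTION:
            forced_major = True
    if forced_major or magnitude >= hi:
        severity = "major"
    elif magnitude >= lo:
        severity = "intermediate"
    else:
        severity = "minor"
    return Deviation(severity, magnitude)


@dataclass
class CorrectionContext:
    has_prior_checkpoint: bool = True
    retries_left: int = 0


def corrective_action(d: Deviation, context: CorrectionContext) -> str | HaltState:
    """Map severity to a corrective action.

    minor → ``nudge_parameters``; intermediate → ``repeat_or_extend``;
    major → ``rollback`` when a validated prior state exists, else the
    escalation toward ``q_fail`` (best-effort re-execution if retries
    remain, unrecoverable otherwise).
    """
    if d.severity == "minor":
        return "nudge_parameters"
    if d.severity == "intermediate":
        return "repeat_or_extend"
    if context.has_prior_checkpoint:
        return "rollback"
    if context.retries_left > 0:
        return "repeat_or_extend"
    return HaltState.q_fail


# ---------------------------------------------------------------------------
# the DEC loop
# ---------------------------------------------------------------------------


@dataclass
class Intervention:
    op_index: int
    op_name: str
    stage: str
    attempt: int
    severity: str
    magnitude: float
    action: str

    def to_dict(self) -> dict[str, Any]:
        return self.__dict__.copy()


@dataclass
class DECResult:
    halt: HaltState
    trace: Trace
    interventions: list[Intervention]
    checkpoints: list[Checkpoint]

    def interventions_to_jsonl(self, path: str) -> None:
        with open(path, "w") as fh:
            for iv in self.interventions:
                fh.write(json.dumps(iv.to_dict()) + "\n")


def _head_cell_amounts(machine: Machine) -> dict[str, float]:
    return dict(machine.tape.current_cell.contents)


def _noisy_observer(sigma: float) -> Callable[[Mapping[str, float], np.random.Generator], dict[str, float]]:
    def observe(true_amounts: Mapping[str, float], rng: np.random.Generator) -> dict[str, float]:
        if sigma == 0.0:
            return dict(true_amounts)
        return {
            sp: max(0.0, amt * (1.0 + rng.normal(0.0, sigma)))
            for sp, amt in true_amounts.items()
        }
    return observe


def dec_loop(program: CompiledProgram, *, noise_sigma: float = 0.0, seed: int = 0,
             retry_budget: int = 3, bands: tuple[float, float] = DEFAULT_SEVERITY_BANDS,
             tolerance: float = DEFAULT_TOLERANCE,
             observer: Callable[[Mapping[str, float], np.random.Generator],
                                dict[str, float]] | None = None) -> DECResult:
    """Run a compiled pathway under checkpointed error correction.

    The expected state at each unit-operation boundary comes from a
    noise-free reference execution of the same program (the state the
    program encodes).  The corrected run then validates the head
    vessel at every boundary against that expectation under the
    observation model (multiplicative Gaussian noise with standard
    deviation ``noise_sigma``, or a caller-supplied ``observer``).

    Per checkpoint, at most ``retry_budget`` interventions are spent;
    a checkpoint that cannot be validated within budget halts
    ``q_fail``.  With zero noise the observation is exact, no
    intervention fires, and the returned trace is identical to a plain
    run's.
    """
    if retry_budget < 0:
        raise ValueError("retry_budget must be non-negative")
    rng = np.random.default_rng(seed)
    observe = observer if observer is not None else _noisy_observer(noise_sigma)

    # reference execution: expected head-cell state at each op boundary
    reference = program.machine()
    expected_states: list[dict[str, float]] = []
    boundaries = [int(state[1:]) for _, _, state in program.checkpoints]
    upto = 0
    for boundary in boundaries:
        while len(reference.trace.records) < boundary:
            reference.step()
        expected_states.append(_head_cell_amounts(reference))
        upto = boundary

    checkpoints = [
        Checkpoint(STAGES[i % len(STAGES)], tuple(sorted(exp.items())), tolerance)
        for i, exp in enumerate(expected_states)
    ]

    machine = program.machine()
    interventions: list[Intervention] = []
    prior_validated = 0  # checkpoints validated so far
    for (op_index, op_name, state), checkpoint, boundary in zip(
            program.checkpoints, checkpoints, boundaries):
        pre_op = machine.snapshot()
        while len(machine.trace.records) < boundary and machine.halted is None:
            machine.step()
        if machine.halted is not None and machine.halted is not HaltState.q_out:
            return DECResult(machine.halted, machine.trace, interventions, checkpoints)
        expected = checkpoint.expected_dict
        attempt = 0
        while True:
            observed = observe(_head_cell_amounts(machine), rng)
            if expected and any(v > 0 for v in expected.values()):
                deviation = classify_deviation(observed, expected, bands)
            else:
                deviation = Deviation("minor", 0.0)
            if deviation.magnitude <= checkpoint.tolerance:
                break  # validated
            if attempt >= retry_budget:
                machine.halted = HaltState.q_fail
                return DECResult(HaltState.q_fail, machine.trace, interventions, checkpoints)
            context = CorrectionContext(
                has_prior_checkpoint=prior_validated > 0, retries_left=retry_budget - attempt
            )
            action = corrective_action(deviation, context)
            if action is HaltState.q_fail:
                machine.halted = HaltState.q_fail
                return DECResult(HaltState.q_fail, machine.trace, interventions, checkpoints)
            attempt += 1
            interventions.append(Intervention(
                op_index, op_name, checkpoint.stage, attempt,
                deviation.severity, deviation.magnitude, action,
            ))
            if action == "nudge_parameters":
                # bounded parameter adjustment; composition is re-measured
                continue
            # repeat_or_extend / rollback: restore and re-execute the
            # deterministic segment, then re-measure
            machine.restore(pre_op)
            while len(machine.trace.records) < boundary and machine.halted is None:
                machine.step()
        prior_validated += 1

    if machine.halted is None:
        machine.run()
    return DECResult(machine.halted, machine.trace, interventions, checkpoints)


# ---------------------------------------------------------------------------
# rule database and halt classification
# ---------------------------------------------------------------------------


STATUSES = ("characterized", "predicted_unoptimized", "novel")


@dataclass
class RuleRecord:
    reagents: dict[str, float]
    condition: str
    products: dict[str, float]
    status: str = "novel"
    observations: int = 1

    def to_dict(self) -> dict[str, Any]:
        return {
            "reagents": self.reagents,
            "condition": self.condition,
            "products": self.products,
            "status": self.status,
            "observations": self.observations,
        }


def _key(reagents: Mapping[str, float], condition: str,
         products: Mapping[str, float]) -> str:
    return json.dumps(
        {
            "reagents": {k: round(v, 9) for k, v in sorted(reagents.items())},
            "condition": condition,
            "products": {k: round(v, 9) for k, v in sorted(products.items())},
        },
        sort_keys=True,
    )


class RuleDB:
    """Persistent map from (reagents, condition) → (products, status).

    Statuses only ever move toward ``characterized`` (promotion
    monotonicity); observation counts only grow.
    """

    def __init__(self) -> None:
        self.records: dict[str, RuleRecord] = {}

    def seed_predicted(self, reagents: Mapping[str, float], condition: str,
                       products: Mapping[str, float]) -> None:
        """Insert a theoretically predicted, not-yet-run transformation."""
        key = _key(reagents, condition, products)
        if key not in self.records:
            self.records[key] = RuleRecord(
                dict(reagents), condition, dict(products),
                status="predicted_unoptimized", observations=1,
            )

    def lookup(self, reagents: Mapping[str, float], condition: str,
               products: Mapping[str, float]) -> RuleRecord | None:
        return self.records.get(_key(reagents, condition, products))

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({k: r.to_dict() for k, r in self.records.items()}, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "RuleDB":
        db = cls()
        with open(path) as fh:
            raw = json.load(fh)
        for key, d in raw.items():
            if d["status"] not in STATUSES:
                raise CSTMError(f"unknown rule status {d['status']!r}")
            db.records[key] = RuleRecord(
                d["reagents"], d["condition"], d["products"],
                d["status"], d["observations"],
            )
        return db


def classify_halt(reagents: Mapping[str, float], condition: str,
                  products: Mapping[str, float], ruledb: RuleDB,
                  detectability: DetectabilitySpec | None = None,
                  n_copies: float | None = None) -> HaltState:
    """Four-way halt classification; updates ``ruledb`` in place.

    When a detectability spec and copy count are supplied, a product
    below the minimum detectable copy number is ``q_fail`` and the
    database is left untouched: an undetectable product is not an
    outcome that can be committed.
    """
    if detectability is not None and n_copies is not None:
        if not detectability.realizable(n_copies):
            return HaltState.q_fail
    record = ruledb.lookup(reagents, condition, products)
    if record is None:
        key = _key(reagents, condition, products)
        ruledb.records[key] = RuleRecord(dict(reagents), condition, dict(products))
        return HaltState.q_nout
    record.observations += 1
    if record.status == "characterized":
        return HaltState.q_out
    if record.status == "predicted_unoptimized":
        # first observation of a prediction; repeats will be q_out
        record.status = "characterized"
        return HaltState.q_uout
    # novel, seen again: promotion — the repeat itself is q_out
    record.status = "characterized"
    return HaltState.q_out
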