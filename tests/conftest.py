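"""Shared fixtures: the worked two-reagent coupling program and friends."""

from __future__ import annotations

import pytest

from cstm import (
    Machine,
    MachineConfig,
    Primitive,
    ReactionRule,
    SynthesisPathway,
    TransitionRule,
    UnitOpCall,
    WILDCARD,
    reference_graph,
)


def make_ab_machine() -> Machine:
    """The worked A + B → C program.

    Five transitions: add A, add B, heat (the coupling rule fires in
    the hot window), park the product in the hold while moving right,
    then collect it into the fresh cell and halt q_out.  Hand trace:

    ====  =====================  =========================
    step  action                 head cell after
    ====  =====================  =========================
    1     AM A 1.0               v0 {A: 1}
    2     AM B 1.0               v0 {A: 1, B: 1}
    3     AE +2.0 (reaction)     v0 {C: 2}, energy 2
    4     SM C → hold, move R    v0 {}, hold {C: 2}
    5     AM C ← hold, halt      v1 {C: 2}
    ====  =====================  =========================
    """
    rules = [
        TransitionRule("q0", WILDCARD, "q1", actions=(Primitive("AM", "A", 1.0, "reservoir"),)),
        TransitionRule("q1", WILDCARD, "q2", actions=(Primitive("AM", "B", 1.0, "reservoir"),)),
        TransitionRule("q2", WILDCARD, "q3", actions=(Primitive("AE", amount=2.0),)),
        TransitionRule("q3", WILDCARD, "q4", move="R",
                       actions=(Primitive("SM", "C", 2.0, "hold"),)),
        TransitionRule("q4", WILDCARD, "q_out",
                       actions=(Primitive("AM", "C", 2.0, "hold"),)),
    ]
    config = MachineConfig(
        states=["q0", "q1", "q2", "q3", "q4"],
        q0="q0",
        reagent_alphabet=["A", "B", "C"],
        rules=rules,
        reactions=[ReactionRule.make({"A": 1, "B": 1}, {"C": 2}, energy_min=0.5)],
        reservoirs={"A": 10.0, "B": 10.0},
        max_steps=50,
    )
    return Machine(config)


@pytest.fixture
def ab_machine() -> Machine:
    return make_ab_machine()


def make_coupling_pathway() -> SynthesisPathway:
    """A two-op pathway (hot coupling, then drying) used across tests."""
    return SynthesisPathway(
        target="C",
        steps=[
            UnitOpCall.make("hot reaction",
                            {"reagent": "B", "amount": 1.0, "source": "reservoir",
                             "heat": 2.0}),
            UnitOpCall.make("drying",
                            {"heat": 1.0, "moisture_species": "W",
                             "moisture_amount": 0.5, "moisture_sink": "waste"}),
        ],
        initial_reagents={"A": 5.0, "B": 5.0, "W": 1.0},
        reagent_alphabet={"A", "B", "C", "W"},
        reactions=[ReactionRule.make({"A": 1, "B": 1}, {"C": 2}, energy_min=0.5)],
    )


@pytest.fixture
def coupling_pathway() -> SynthesisPathway:
    return make_coupling_pathway()


@pytest.fixture
def bench_graph():
    return reference_graph()
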