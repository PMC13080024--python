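"""Seeded generator of random well-formed machine programs.

Used by the conservation property suite: every generated program is
valid by construction (deterministic rule table, mass-balanced
reaction rules, unbounded reservoirs) but otherwise arbitrary, so a
run exercises clipped subtractions, empty-cell no-ops, head motion in
both directions, reactions firing mid-run, and all halting modes.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    Machine,
    MachineConfig,
    Primitive,
    ReactionRule,
    TransitionRule,
    WILDCARD,
)

_SPECIES_POOL = ("A", "B", "C", "D", "E")


def random_reaction(rng: np.random.Generator, species: list[str]) -> ReactionRule:
    """A random stoichiometric rule, mass-balanced by construction."""
    n_reactants = int(rng.integers(1, min(3, len(species)) + 1))
    picks = rng.choice(len(species), size=n_reactants, replace=False)
    reactants = {species[i]: float(rng.integers(1, 3)) for i in picks}
    remaining = [s for s in species if s not in reactants]
    product = remaining[int(rng.integers(len(remaining)))] if remaining else species[0]
    products = {product: sum(reactants.values())}
    window = sorted(rng.uniform(-5.0, 5.0, size=2))
    return ReactionRule.make(
        reactants, products,
        energy_min=window[0] if rng.random() < 0.5 else -math.inf,
        energy_max=window[1] if rng.random() < 0.5 else math.inf,
        yield_fraction=float(rng.uniform(0.25, 1.0)),
    )


def random_primitive(rng: np.random.Generator, species: list[str]) -> Primitive:
    kind = ("AM", "SM", "AE", "SE")[int(rng.integers(4))]
    if kind == "AM":
        port = ("reservoir", "reservoir", "hold")[int(rng.integers(3))]
        return Primitive("AM", species[int(rng.integers(len(species)))],
                         float(rng.uniform(0.1, 2.0)), port)
    if kind == "SM":
        port = ("waste", "hold")[int(rng.integers(2))]
        return Primitive("SM", species[int(rng.integers(len(species)))],
                         float(rng.uniform(0.1, 2.0)), port)
    return Primitive(kind, amount=float(rng.uniform(0.1, 3.0)))


def random_program(rng: np.random.Generator, max_steps: int = 15) -> Machine:
    """A fresh machine with a random well-formed program loaded."""
    species = list(_SPECIES_POOL[: int(rng.integers(2, len(_SPECIES_POOL) + 1))])
    n_states = int(rng.integers(2, 5))
    states = [f"q{i}" for i in range(n_states)]
    reactions = [random_reaction(rng, species) for _ in range(int(rng.integers(0, 3)))]

    rules = []
    for i, state in enumerate(states):
        # bias forward so many programs reach a chemical halt
        roll = rng.random()
        if roll < 0.15:
            to_state = ("q_out", "q_uout", "q_nout")[int(rng.integers(3))]
        elif i + 1 < n_states and roll < 0.85:
            to_state = states[i + 1]
        else:
            to_state = states[int(rng.integers(n_states))]
        actions = tuple(
            random_primitive(rng, species) for _ in range(int(rng.integers(0, 4)))
        )
        move = ("L", "R", "N")[int(rng.integers(3))]
        rules.append(TransitionRule(state, WILDCARD, to_state, move=move, actions=actions))

    config = MachineConfig(
        states=states,
        q0="q0",
        reagent_alphabet=species,
        rules=rules,
        reactions=reactions,
        reservoirs={sp: math.inf for sp in species},
        max_steps=max_steps,
    )
    return Machine(config)
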