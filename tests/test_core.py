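"""Core machine semantics: symbolization, primitives, reactions, runs."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cstm.core import (
    BLANK,
    DEFAULT_EPSILON,
    AlphabetError,
    ConfigurationError,
    HaltState,
    Machine,
    MachineConfig,
    MachineHaltedError,
    Primitive,
    ReactionRule,
    SymbolizationError,
    Tape,
    TransitionRule,
    VesselCell,
    WILDCARD,
    _net_totals,
    fire_reactions,
    machine_from_dict,
    mass_ledger,
    read_symbol,
    symbolize,
)
from cstm.random_programs import random_program

from conftest import make_ab_machine


def _default_config(**kw):
    base = dict(states=["q0"], q0="q0", reagent_alphabet=["A", "B"], rules=[])
    base.update(kw)
    return MachineConfig(**base)


class TestSymbolization:
    def test_empty_cell_is_blank(self):
        config = _default_config()
        assert symbolize(VesselCell("v"), config) == BLANK

    def test_single_species_ambient(self):
        config = _default_config()
        cell = VesselCell("v", {"A": 1.0}, energy=0.0)
        assert symbolize(cell, config) == ("A", "ambient")

    def test_dominant_species_wins(self):
        config = _default_config()
        cell = VesselCell("v", {"A": 1.0, "B": 3.0})
        assert symbolize(cell, config) == ("B", "ambient")

    def test_tie_breaks_lexicographically(self):
        config = _default_config()
        cell = VesselCell("v", {"B": 2.0, "A": 2.0})
        assert symbolize(cell, config)[0] == "A"

    @pytest.mark.parametrize("energy,label", [(-3.0, "cold"), (0.0, "ambient"), (2.0, "hot")])
    def test_condition_bands(self, energy, label):
        config = _default_config()
        cell = VesselCell("v", {"A": 1.0}, energy=energy)
        assert symbolize(cell, config) == ("A", label)

    def test_alien_species_raises(self):
        config = _default_config()
        with pytest.raises(SymbolizationError, match="X"):
            symbolize(VesselCell("v", {"X": 1.0}), config)

    def test_read_symbol_uses_head_cell(self):
        config = _default_config()
        tape = Tape.fresh()
        assert read_symbol(tape, config) == BLANK


class TestPrimitives:
    def test_am_to_empty_cell_fills_it(self):
        tape = Tape.fresh({"A": math.inf})
        tape.apply(Primitive("AM", "A", 2.0, "reservoir"))
        assert tape.current_cell.contents == {"A": 2.0}
        assert tape.current_cell.state == "filled"

    def test_sm_clips_to_available(self):
        tape = Tape.fresh()
        tape.current_cell.contents["A"] = 2.0
        out = tape.apply(Primitive("SM", "A", 5.0, "waste"))
        assert out.moved == 2.0
        assert tape.current_cell.state == "empty"
        assert tape.waste.contents == {"A": 2.0}
        assert out.warnings

    def test_sm_from_empty_is_warned_noop(self):
        tape = Tape.fresh()
        out = tape.apply(Primitive("SM", "A", 1.0, "waste"))
        assert out.moved == 0.0 and out.warnings

    def test_ae_se_are_inverse(self):
        tape = Tape.fresh()
        tape.apply(Primitive("AE", amount=10.0))
        tape.apply(Primitive("SE", amount=10.0))
        assert tape.current_cell.energy == 0.0

    def test_am_outside_alphabet_raises(self):
        tape = Tape.fresh({"X": 1.0})
        with pytest.raises(AlphabetError):
            tape.apply(Primitive("AM", "X", 1.0, "reservoir"), reagent_alphabet={"A"})

    def test_finite_reservoir_drawdown(self):
        tape = Tape.fresh({"A": 3.0})
        tape.apply(Primitive("AM", "A", 2.0, "reservoir"))
        assert tape.reservoirs["A"] == 1.0
        assert tape.drawdown["A"] == 2.0

    def test_hold_round_trip(self):
        tape = Tape.fresh()
        tape.current_cell.contents["A"] = 1.5
        tape.apply(Primitive("SM", "A", 1.5, "hold"))
        tape.apply(Primitive("AM", "A", 1.5, "hold"))
        assert tape.current_cell.contents == {"A": 1.5}
        assert tape.hold.contents == {}

    def test_invalid_primitives_rejected(self):
        with pytest.raises(ConfigurationError):
            Primitive("XX", "A", 1.0)
        with pytest.raises(ConfigurationError):
            Primitive("AM", "A", -1.0)
        with pytest.raises(ConfigurationError):
            Primitive("AM", "A", 1.0, "waste")  # waste is not a source
        with pytest.raises(ConfigurationError):
            Primitive("SM", "A", 1.0, "reservoir")  # reservoir is not a sink

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.1, 5.0), min_size=1, max_size=8), st.data())
    def test_energy_reversibility(self, deltas, data):
        """Any interleaving of AE(+x)/SE(x) pairs returns to baseline."""
        tape = Tape.fresh()
        ops = [("AE", d) for d in deltas] + [("SE", d) for d in deltas]
        order = data.draw(st.permutations(ops))
        for kind, d in order:
            tape.apply(Primitive(kind, amount=d))
        assert tape.current_cell.energy == pytest.approx(0.0, abs=1e-12)


def _oracle_reactions(contents, energy, rules):
    """Independent stoichiometric calculator: pure-dict bookkeeping."""
    state = dict(contents)
    for rule in rules:
        if not state:
            continue
        if not (rule.energy_min <= energy <= rule.energy_max):
            continue
        if any(state.get(sp, 0.0) + 1e-12 < amt for sp, amt in rule.reactants):
            continue
        extent = min(state[sp] / amt for sp, amt in rule.reactants)
        conv = extent * rule.yield_fraction
        consumed = {sp: amt * conv for sp, amt in rule.reactants}
        produced = {sp: amt * conv for sp, amt in rule.products}
        state = {sp: state.get(sp, 0.0) - consumed.get(sp, 0.0) + produced.get(sp, 0.0)
                 for sp in set(state) | set(produced)}
        state = {sp: a for sp, a in state.items() if a >= 1e-12}
    return state


class TestReactions:
    RULE = ReactionRule.make({"A": 1, "B": 1}, {"C": 2})

    def test_full_conversion(self):
        cell = VesselCell("v", {"A": 1.0, "B": 1.0})
        fire_reactions(cell, [self.RULE])
        assert cell.contents == {"C": 2.0}

    def test_missing_reactant_is_noop(self):
        cell = VesselCell("v", {"A": 1.0})
        fire_reactions(cell, [self.RULE])
        assert cell.contents == {"A": 1.0}

    def test_partial_yield(self):
        rule = ReactionRule.make({"A": 1, "B": 1}, {"C": 2}, yield_fraction=0.5)
        cell = VesselCell("v", {"A": 1.0, "B": 1.0})
        fire_reactions(cell, [rule])
        assert cell.contents == pytest.approx({"A": 0.5, "B": 0.5, "C": 1.0})

    def test_energy_window_gates_firing(self):
        rule = ReactionRule.make({"A": 1}, {"B": 1}, energy_min=1.0, energy_max=2.0)
        cell = VesselCell("v", {"A": 1.0}, energy=0.0)
        fire_reactions(cell, [rule])
        assert cell.contents == {"A": 1.0}
        cell.energy = 1.5
        fire_reactions(cell, [rule])
        assert cell.contents == {"B": 1.0}

    def test_unbalanced_rule_rejected_at_load(self):
        with pytest.raises(ConfigurationError, match="mass balance"):
            ReactionRule.make({"A": 1.0}, {"B": 2.0})

    def test_agrees_with_brute_force_oracle(self):
        """Randomized small rule sets match an independent calculator."""
        rng = np.random.default_rng(7)
        species = ["A", "B", "C"]
        for _ in range(200):
            n_rules = int(rng.integers(1, 3))
            rules = []
            for _ in range(n_rules):
                picks = rng.choice(3, size=int(rng.integers(1, 3)), replace=False)
                reactants = {species[i]: float(rng.integers(1, 3)) for i in picks}
                rules.append(ReactionRule.make(
                    reactants, {"P": sum(reactants.values())},
                    yield_fraction=float(rng.uniform(0.25, 1.0)),
                ))
            contents = {sp: float(rng.uniform(0.0, 4.0)) for sp in species
                        if rng.random() < 0.8}
            energy = float(rng.uniform(-2, 2))
            cell = VesselCell("v", dict(contents), energy)
            fire_reactions(cell, rules)
            expected = _oracle_reactions(contents, energy, rules)
            assert set(cell.contents) == set(expected)
            for sp in expected:
                assert cell.contents[sp] == pytest.approx(expected[sp], abs=1e-9)


class TestStepAndRun:
    def test_single_step_hand_trace(self):
        rule = TransitionRule("q0", BLANK, "q1", write=("A", "ambient"), move="R",
                              actions=(Primitive("AM", "A", 1.0, "reservoir"),))
        config = MachineConfig(states=["q0", "q1"], q0="q0", reagent_alphabet=["A"],
                               rules=[rule], reservoirs={"A": math.inf})
        machine = Machine(config)
        rec = machine.step()
        assert machine.state == "q1"
        assert machine.tape.head == 1
        assert machine.tape.cells[0].contents == {"A": 1.0}
        assert rec.symbol_written == ("A", "ambient") and not rec.warnings

    def test_stepping_halted_machine_raises(self, ab_machine):
        ab_machine.run()
        with pytest.raises(MachineHaltedError):
            ab_machine.step()

    def test_empty_delta_fails_on_first_step(self):
        config = MachineConfig(states=["q0"], q0="q0", reagent_alphabet=["A"], rules=[])
        machine = Machine(config)
        halt, trace = machine.run()
        assert halt is HaltState.q_fail
        assert len(trace.records) == 1
        assert trace.records[0].rule_index is None

    def test_worked_coupling_program(self, ab_machine):
        halt, trace = ab_machine.run()
        assert halt is HaltState.q_out
        assert len(trace.records) == 5
        # product collected into the fresh cell right of the start
        assert ab_machine.tape.cells[1].contents == {"C": 2.0}
        assert trace.records[2].reactions_fired == [0]

    def test_rule_into_q_fail_gives_one_record(self):
        rule = TransitionRule("q0", WILDCARD, "q_fail")
        config = MachineConfig(states=["q0"], q0="q0", reagent_alphabet=["A"], rules=[rule])
        halt, trace = Machine(config).run()
        assert halt is HaltState.q_fail and len(trace.records) == 1

    def test_zero_budget_is_budget_exceeded(self, ab_machine):
        halt, trace = ab_machine.run(max_steps=0)
        assert halt is HaltState.budget_exceeded
        assert trace.records == []

    def test_determinism_bit_identical_traces(self):
        t1 = make_ab_machine().run()[1]
        t2 = make_ab_machine().run()[1]
        assert [r.to_dict() for r in t1.records] == [r.to_dict() for r in t2.records]

    def test_halting_totality_on_random_programs(self):
        """Every random program terminates in a halt state within budget + 1."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            machine = random_program(rng)
            halt, trace = machine.run()
            assert halt in set(HaltState)
            assert len(trace.records) <= machine.config.max_steps + 1

    def test_ambiguous_rules_rejected(self):
        rules = [TransitionRule("q0", WILDCARD, "q0"), TransitionRule("q0", WILDCARD, "q_out")]
        with pytest.raises(ConfigurationError, match="ambiguous"):
            MachineConfig(states=["q0"], q0="q0", reagent_alphabet=["A"], rules=rules)

    def test_exact_read_beats_wildcard(self):
        rules = [
            TransitionRule("q0", WILDCARD, "q_fail"),
            TransitionRule("q0", BLANK, "q_out"),
        ]
        config = MachineConfig(states=["q0"], q0="q0", reagent_alphabet=["A"], rules=rules)
        halt, _ = Machine(config).run()
        assert halt is HaltState.q_out


class TestLedger:
    def test_coupling_run_conserves(self, ab_machine):
        _, trace = ab_machine.run()
        assert all(e.delta == pytest.approx(0.0, abs=DEFAULT_EPSILON)
                   for e in mass_ledger(trace).values())

    def test_sm_to_waste_counted(self):
        rule = TransitionRule("q0", WILDCARD, "q_out", actions=(
            Primitive("AM", "A", 2.0, "reservoir"), Primitive("SM", "A", 1.0, "waste")))
        config = MachineConfig(states=["q0"], q0="q0", reagent_alphabet=["A"],
                               rules=[rule], reservoirs={"A": math.inf})
        machine = Machine(config)
        _, trace = machine.run()
        totals = trace.records[-1].totals["A"]
        assert totals["tape"] == 1.0 and totals["waste"] == 1.0
        assert mass_ledger(trace)["A"].delta == pytest.approx(0.0, abs=1e-12)

    def test_corrupted_trace_is_flagged(self, ab_machine):
        _, trace = ab_machine.run()
        trace.records[-1].totals["C"]["tape"] += 0.5  # negative control
        assert abs(mass_ledger(trace)["C"].delta) > 0.1

    def test_conservation_at_every_record(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            machine = random_program(rng)
            _, trace = machine.run()
            base = _net_totals(trace.baseline)
            for rec in trace.records:
                net = _net_totals(rec.totals)
                for sp in set(base) | set(net):
                    assert abs(net.get(sp, 0.0) - base.get(sp, 0.0)) <= 1e-12

    def test_empty_trace_rejected(self, ab_machine):
        with pytest.raises(ValueError):
            mass_ledger(ab_machine.trace)


class TestProgramIO:
    DOC = {
        "states": ["q0", "q1"],
        "initial_state": "q0",
        "reagents": ["A"],
        "reservoirs": {"A": "unbounded"},
        "max_steps": 10,
        "rules": [
            {"from": "q0", "read": "b", "to": "q1", "move": "R",
             "actions": [{"kind": "AM", "species": "A", "amount": 1.0,
                          "port": "reservoir"}]},
            {"from": "q1", "read": "*", "to": "q_out"},
        ],
    }

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "program.yaml"
        path.write_text(yaml.safe_dump(self.DOC))
        from cstm import load_program

        machine = load_program(str(path))
        halt, trace = machine.run()
        assert halt is HaltState.q_out and len(trace.records) == 2

    def test_trace_jsonl_round_trip(self, tmp_path, ab_machine):
        from cstm.core import Trace

        _, trace = ab_machine.run()
        path = tmp_path / "trace.jsonl"
        trace.to_jsonl(str(path))
        loaded = Trace.from_jsonl(str(path))
        assert [r.to_dict() for r in loaded.records] == [r.to_dict() for r in trace.records]

    def test_malformed_program_raises(self):
        with pytest.raises(ConfigurationError):
            machine_from_dict({"states": ["q0"], "q0": "q0", "reagents": ["A"],
                               "rules": [{"from": "q0", "read": "nonsense pair",
                                          "to": "q0"}]})

    def test_render_tape_glyphs(self, ab_machine):
        ab_machine.step()
        assert "[o]" in ab_machine.render_tape() or "[*]" in ab_machine.render_tape()
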