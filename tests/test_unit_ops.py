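"""Macro expansions, pathway compilation, and mass-balance verification."""

from __future__ import annotations

import pytest

from cstm import (
    HaltState,
    SynthesisPathway,
    UnitOpCall,
    compile_pathway,
    default_registry,
    expand_unit_op,
    verify_mass_balance,
)
from cstm.core import AlphabetError
from cstm.unit_ops import ParameterError, RegistryError, UnitOpRegistry, _op_from_entry

from conftest import make_coupling_pathway

#: the canonical primitive sequences, as printed in the reference table
CANONICAL_KINDS = {
    "liquid-liquid extraction": ("AM", "AE", "SM"),
    "drying": ("AE", "SM"),
    "crystallization": ("AE", "SE", "SM"),
    "distillation": ("AE", "SM", "SE", "AM"),
    "hot reaction": ("AM", "AE"),
    "cold reaction": ("AM", "SE"),
    "sublimation": ("SM", "AE", "SE", "AM"),
}

EXAMPLE_PARAMS = {
    "liquid-liquid extraction": {
        "solvent": "S", "solvent_amount": 1.0, "solvent_source": "reservoir",
        "mix_energy": 1.0, "extract_species": "P", "extract_amount": 0.5,
        "extract_sink": "hold",
    },
    "drying": {"heat": 1.0, "moisture_species": "W", "moisture_amount": 0.2,
               "moisture_sink": "waste"},
    "crystallization": {"heat": 1.0, "cool": 2.0, "solid_species": "P",
                        "solid_amount": 0.8, "solid_sink": "hold"},
    "distillation": {"heat": 2.0, "cool": 2.0, "vapor_species": "V",
                     "vapor_amount": 0.5},
    "hot reaction": {"reagent": "A", "amount": 1.0, "source": "reservoir", "heat": 1.0},
    "cold reaction": {"reagent": "A", "amount": 1.0, "source": "reservoir", "cool": 1.0},
    "sublimation": {"atmosphere_species": "air", "atmosphere_amount": 1.0,
                    "heat": 1.0, "cool": 1.0, "collect_species": "P",
                    "collect_amount": 0.5, "collect_source": "hold"},
}


class TestExpansion:
    @pytest.mark.parametrize("name,kinds", sorted(CANONICAL_KINDS.items()))
    def test_canonical_primitive_sequences(self, name, kinds):
        """The seven macro expansions match the printed table exactly."""
        primitives = expand_unit_op(name, EXAMPLE_PARAMS[name])
        assert tuple(p.kind for p in primitives) == kinds

    def test_names_are_case_insensitive(self):
        assert expand_unit_op("DRYING", EXAMPLE_PARAMS["drying"])[0].kind == "AE"

    def test_unknown_name_lists_registry(self):
        with pytest.raises(RegistryError, match="drying"):
            expand_unit_op("frobnicate", {})

    def test_missing_slot_is_parameter_error(self):
        with pytest.raises(ParameterError, match="moisture"):
            expand_unit_op("drying", {"heat": 1.0})

    def test_user_registry_cannot_shadow_canonical(self):
        registry = UnitOpRegistry()
        op = _op_from_entry("drying", {"sequence": [{"kind": "AE", "amount": 1.0}]})
        with pytest.raises(RegistryError, match="reserved"):
            registry.register(op)

    def test_user_defined_operation(self):
        registry = UnitOpRegistry()
        registry.register(_op_from_entry(
            "quench", {"sequence": [
                {"kind": "AM", "species": "$q", "amount": "$amt", "port": "reservoir"},
                {"kind": "SE", "amount": "$cool"},
            ]}))
        prims = registry.get("quench").expand({"q": "Q", "amt": 1.0, "cool": 3.0})
        assert [p.kind for p in prims] == ["AM", "SE"]


class TestCompilePathway:
    def test_single_hot_reaction(self):
        sigma = SynthesisPathway(
            target="P",
            steps=[UnitOpCall.make("hot reaction",
                                   {"reagent": "A", "amount": 1.0,
                                    "source": "reservoir", "heat": 1.0})],
            initial_reagents={"A": 2.0},
        )
        program = compile_pathway(sigma)
        assert [p.kind for p in program.primitives] == ["AM", "AE"]
        # two primitive transitions plus the terminal halt transition
        assert len(program.config.rules) == 3
        assert program.config.rules[-1].to_state == "q_out"

    def test_empty_pathway_halts_immediately(self):
        program = compile_pathway(SynthesisPathway(target="X", initial_reagents={"X": 1.0}))
        halt, trace = program.machine().run()
        assert halt is HaltState.q_out and len(trace.records) == 1

    def test_three_step_primitive_count(self):
        sigma = SynthesisPathway(
            target="P",
            steps=[
                UnitOpCall.make("hot reaction", EXAMPLE_PARAMS["hot reaction"]),
                UnitOpCall.make("crystallization", EXAMPLE_PARAMS["crystallization"]),
                UnitOpCall.make("drying", EXAMPLE_PARAMS["drying"]),
            ],
            reagent_alphabet={"A", "P", "W"},
            initial_reagents={"A": 5.0},
        )
        program = compile_pathway(sigma)
        assert len(program.primitives) == 2 + 3 + 2

    def test_compositionality_of_primitive_streams(self):
        s1 = [UnitOpCall.make("hot reaction", EXAMPLE_PARAMS["hot reaction"])]
        s2 = [UnitOpCall.make("drying", EXAMPLE_PARAMS["drying"])]
        alphabet = {"A", "P", "W"}

        def stream(steps):
            sigma = SynthesisPathway(target="P", steps=list(steps),
                                     reagent_alphabet=alphabet,
                                     initial_reagents={"A": 1.0})
            return [p.to_dict() for p in compile_pathway(sigma).primitives]

        assert stream(s1 + s2) == stream(s1) + stream(s2)

    def test_species_outside_alphabet_rejected(self):
        sigma = SynthesisPathway(
            target="P",
            steps=[UnitOpCall.make("hot reaction",
                                   {"reagent": "Z", "amount": 1.0,
                                    "source": "reservoir", "heat": 1.0})],
            reagent_alphabet={"A", "P"},
            initial_reagents={"A": 1.0},
        )
        with pytest.raises(AlphabetError, match="Z"):
            compile_pathway(sigma)

    def test_compiled_pathway_runs_and_conserves(self):
        program = compile_pathway(make_coupling_pathway())
        machine = program.machine()
        machine.tape.current_cell.contents["A"] = 1.0
        machine.trace.baseline = machine.tape.species_totals()
        halt, trace = machine.run()
        assert halt is HaltState.q_out
        assert machine.tape.current_cell.contents == {"C": 2.0}
        assert verify_mass_balance(trace).passed

    def test_distillation_collects_to_the_right(self):
        sigma = SynthesisPathway(
            target="V",
            steps=[UnitOpCall.make("distillation", EXAMPLE_PARAMS["distillation"])],
            reagent_alphabet={"V", "R"},
            initial_reagents={},
        )
        program = compile_pathway(sigma)
        machine = program.machine()
        machine.tape.current_cell.contents.update({"R": 1.0, "V": 0.5})
        machine.trace.baseline = machine.tape.species_totals()
        halt, _ = machine.run()
        assert halt is HaltState.q_out
        assert machine.tape.cells[0].contents == {"R": 1.0}
        assert machine.tape.cells[1].contents == {"V": 0.5}


class TestMassBalanceReport:
    def test_compiled_run_passes(self):
        program = compile_pathway(make_coupling_pathway())
        _, trace = program.machine().run()
        report = verify_mass_balance(trace)
        assert report.passed and report.failing_species() == []

    def test_corrupted_trace_names_species(self):
        program = compile_pathway(make_coupling_pathway())
        _, trace = program.machine().run()
        trace.records[-1].totals["B"]["tape"] += 1.0
        report = verify_mass_balance(trace)
        assert not report.passed and report.failing_species() == ["B"]

    def test_waste_heavy_run_still_passes(self):
        sigma = SynthesisPathway(
            target="P",
            steps=[UnitOpCall.make("drying", EXAMPLE_PARAMS["drying"])] * 3,
            reagent_alphabet={"P", "W"},
            initial_reagents={"W": 1.0},
        )
        program = compile_pathway(sigma)
        machine = program.machine()
        machine.tape.current_cell.contents["W"] = 0.9
        machine.trace.baseline = machine.tape.species_totals()
        _, trace = machine.run()
        assert verify_mass_balance(trace).passed
        assert trace.records[-1].totals["W"]["waste"] > 0
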