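# Canonical unit-operation macro registry.
#
# Each entry expands a named laboratory unit operation into a primitive
# sequence over the four-instruction set (AM/SM/AE/SE).  Field values
# starting with "$" are parameter slots that must be bound explicitly at
# invocation: the macros carry no default amounts, species, or energy
# deltas, because process parameters are program data, not library data.
# An optional head_move (L/R/N) on a primitive sets the tape move of the
# transition carrying it when a pathway is compiled, letting an
# operation collect material into a neighbouring vessel.
liquid-liquid extraction:
  notes: add solvent, mix, separate a phase
  sequence:
    - {kind: AM, species: $solvent, amount: $solvent_amount, port: $solvent_source}
    - {kind: AE, amount: $mix_energy}
    - {kind: SM, species: $extract_species, amount: $extract_amount, port: $extract_sink}
drying:
  notes: heat, remove the volatile/moisture fraction
  sequence:
    - {kind: AE, amount: $heat}
    - {kind: SM, species: $moisture_species, amount: $moisture_amount, port: $moisture_sink}
crystallization:
  notes: heat, cool, filter off the solid
  sequence:
    - {kind: AE, amount: $heat}
    - {kind: SE, amount: $cool}
    - {kind: SM, species: $solid_species, amount: $solid_amount, port: $solid_sink}
distillation:
  notes: heat, take the vapor to the hold (condenser), cool, collect to the right
  sequence:
    - {kind: AE, amount: $heat}
    - {kind: SM, species: $vapor_species, amount: $vapor_amount, port: hold}
    - {kind: SE, amount: $cool, head_move: R}
    - {kind: AM, species: $vapor_species, amount: $vapor_amount, port: hold}
hot reaction:
  notes: add matter then heat
  sequence:
    - {kind: AM, species: $reagent, amount: $amount, port: $source}
    - {kind: AE, amount: $heat}
cold reaction:
  notes: add matter then cool
  sequence:
    - {kind: AM, species: $reagent, amount: $amount, port: $source}
    - {kind: SE, amount: $cool}
sublimation:
  notes: evacuate the atmosphere species to waste, heat, cool window (move right), collect
  sequence:
    - {kind: SM, species: $atmosphere_species, amount: $atmosphere_amount, port: waste}
    - {kind: AE, amount: $heat}
    - {kind: SE, amount: $cool, head_move: R}
    - {kind: AM, species: $collect_species, amount: $collect_amount, port: $collect_source}
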