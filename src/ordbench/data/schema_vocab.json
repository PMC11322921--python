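{
  "version": "1.0",
  "description": "Vocabulary for the modeled subset of the Open Reaction Database schema: the inputs/conditions/workups/outcomes branches of a Reaction message, restricted to the fields this toolkit generates and scores. Path patterns use '*' for a map key and '[]' for a list index.",
  "fields": [
    {"path": "inputs", "kind": "map-of-message"},
    {"path": "inputs.*.components", "kind": "repeated-message"},
    {"path": "inputs.*.components[].identifiers", "kind": "repeated-message"},
    {"path": "inputs.*.components[].identifiers[].type", "kind": "enum",
     "enum": ["NAME", "SMILES", "INCHI", "CAS_NUMBER"]},
    {"path": "inputs.*.components[].identifiers[].value", "kind": "scalar-string"},
    {"path": "inputs.*.components[].amount", "kind": "message"},
    {"path": "inputs.*.components[].amount.mass", "kind": "message"},
    {"path": "inputs.*.components[].amount.mass.value", "kind": "scalar-number"},
    {"path": "inputs.*.components[].amount.mass.units", "kind": "enum",
     "enum": ["KILOGRAM", "GRAM", "MILLIGRAM", "MICROGRAM"]},
    {"path": "inputs.*.components[].amount.volume", "kind": "message"},
    {"path": "inputs.*.components[].amount.volume.value", "kind": "scalar-number"},
    {"path": "inputs.*.components[].amount.volume.units", "kind": "enum",
     "enum": ["LITER", "MILLILITER", "MICROLITER"]},
    {"path": "inputs.*.components[].amount.moles", "kind": "message"},
    {"path": "inputs.*.components[].amount.moles.value", "kind": "scalar-number"},
    {"path": "inputs.*.components[].amount.moles.units", "kind": "enum",
     "enum": ["MOLE", "MILLIMOLE", "MICROMOLE"]},
    {"path": "inputs.*.components[].reaction_role", "kind": "enum",
     "enum": ["REACTANT", "REAGENT", "SOLVENT", "CATALYST", "PRODUCT", "WORKUP", "INTERNAL_STANDARD"]},
    {"path": "conditions", "kind": "message"},
    {"path": "conditions.temperature", "kind": "message"},
    {"path": "conditions.temperature.setpoint", "kind": "message"},
    {"path": "conditions.temperature.setpoint.value", "kind": "scalar-number"},
    {"path": "conditions.temperature.setpoint.units", "kind": "enum",
     "enum": ["CELSIUS", "KELVIN", "FAHRENHEIT"]},
    {"path": "conditions.temperature.control", "kind": "message"},
    {"path": "conditions.temperature.control.type", "kind": "enum",
     "enum": ["AMBIENT", "OIL_BATH", "ICE_BATH", "DRY_ICE_BATH", "HEATING_MANTLE", "CUSTOM"]},
    {"path": "conditions.stirring", "kind": "message"},
    {"path": "conditions.stirring.type", "kind": "enum",
     "enum": ["STIR_BAR", "OVERHEAD_MIXER", "AGITATION", "NONE", "CUSTOM"]},
    {"path": "workups", "kind": "repeated-message"},
    {"path": "workups[].type", "kind": "enum",
     "enum": ["ADDITION", "TEMPERATURE", "CONCENTRATION", "EXTRACTION", "FILTRATION",
              "WASH", "DRY_IN_VACUUM", "DRY_WITH_MATERIAL", "DISTILLATION",
              "RECRYSTALLIZATION", "CHROMATOGRAPHY", "PH_ADJUST", "STIRRING", "CUSTOM"]},
    {"path": "workups[].details", "kind": "scalar-string"},
    {"path": "workups[].amount", "kind": "message"},
    {"path": "workups[].amount.volume", "kind": "message"},
    {"path": "workups[].amount.volume.value", "kind": "scalar-number"},
    {"path": "workups[].amount.volume.units", "kind": "enum",
     "enum": ["LITER", "MILLILITER", "MICROLITER"]},
    {"path": "workups[].temperature", "kind": "message"},
    {"path": "workups[].temperature.setpoint", "kind": "message"},
    {"path": "workups[].temperature.setpoint.value", "kind": "scalar-number"},
    {"path": "workups[].temperature.setpoint.units", "kind": "enum",
     "enum": ["CELSIUS", "KELVIN", "FAHRENHEIT"]},
    {"path": "outcomes", "kind": "repeated-message"},
    {"path": "outcomes[].products", "kind": "repeated-message"},
    {"path": "outcomes[].products[].identifiers", "kind": "repeated-message"},
    {"path": "outcomes[].products[].identifiers[].type", "kind": "enum",
     "enum": ["NAME", "SMILES", "INCHI", "CAS_NUMBER"]},
    {"path": "outcomes[].products[].identifiers[].value", "kind": "scalar-string"},
    {"path": "outcomes[].products[].measurements", "kind": "repeated-message"},
    {"path": "outcomes[].products[].measurements[].type", "kind": "enum",
     "enum": ["YIELD", "AMOUNT", "PURITY", "IDENTITY"]},
    {"path": "outcomes[].products[].measurements[].percentage", "kind": "message"},
    {"path": "outcomes[].products[].measurements[].percentage.value", "kind": "scalar-number"},
    {"path": "outcomes[].products[].measurements[].amount", "kind": "message"},
    {"path": "outcomes[].products[].measurements[].amount.mass", "kind": "message"},
    {"path": "outcomes[].products[].measurements[].amount.mass.value", "kind": "scalar-number"},
    {"path": "outcomes[].products[].measurements[].amount.mass.units", "kind": "enum",
     "enum": ["KILOGRAM", "GRAM", "MILLIGRAM", "MICROGRAM"]},
    {"path": "outcomes[].products[].texture", "kind": "message"},
    {"path": "outcomes[].products[].texture.type", "kind": "enum",
     "enum": ["CRYSTAL", "POWDER", "OIL", "AMORPHOUS_SOLID", "FOAM", "WAX", "SEMI_SOLID", "SOLID", "LIQUID", "CUSTOM"]},
    {"path": "outcomes[].products[].isolated_color", "kind": "scalar-string"},
    {"path": "outcomes[].products[].reaction_role", "kind": "enum",
     "enum": ["REACTANT", "REAGENT", "SOLVENT", "CATALYST", "PRODUCT", "WORKUP", "INTERNAL_STANDARD"]},
    {"path": "notes", "kind": "message"},
    {"path": "notes.procedure_details", "kind": "scalar-string"}
  ]
}
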