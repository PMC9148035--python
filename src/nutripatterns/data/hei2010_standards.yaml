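# HEI-2010 component scoring standards (density basis, alcohol omitted from
# empty calories). Each component is scored by linear interpolation between
# its zero-score and maximum-score standards, truncated to [0, max_points];
# moderation components have zero_standard > max_standard and are therefore
# reverse-scored by the same interpolation. Max points sum to 100.
#
# Densities are per 1000 kcal except fatty_acid_ratio ((MUFA+PUFA)/SFA,
# unitless) and empty_calories (% of energy).
version: 1
components:
  - {name: total_fruit,            max_points: 5,  max_standard: 0.8, zero_standard: 0.0,  units: cup eq/1000 kcal}
  - {name: whole_fruit,            max_points: 5,  max_standard: 0.4, zero_standard: 0.0,  units: cup eq/1000 kcal}
  - {name: total_vegetables,       max_points: 5,  max_standard: 1.1, zero_standard: 0.0,  units: cup eq/1000 kcal}
  - {name: greens_beans,           max_points: 5,  max_standard: 0.2, zero_standard: 0.0,  units: cup eq/1000 kcal}
  - {name: whole_grains,           max_points: 10, max_standard: 1.5, zero_standard: 0.0,  units: oz eq/1000 kcal}
  - {name: dairy,                  max_points: 10, max_standard: 1.3, zero_standard: 0.0,  units: cup eq/1000 kcal}
  - {name: total_protein,          max_points: 5,  max_standard: 2.5, zero_standard: 0.0,  units: oz eq/1000 kcal}
  - {name: seafood_plant_protein,  max_points: 5,  max_standard: 0.8, zero_standard: 0.0,  units: oz eq/1000 kcal}
  - {name: fatty_acid_ratio,       max_points: 10, max_standard: 2.5, zero_standard: 1.2,  units: (MUFA+PUFA)/SFA}
  - {name: refined_grains,         max_points: 10, max_standard: 1.8, zero_standard: 4.3,  units: oz eq/1000 kcal}
  - {name: sodium,                 max_points: 10, max_standard: 1.1, zero_standard: 2.0,  units: g/1000 kcal}
  - {name: empty_calories,         max_points: 20, max_standard: 19.0, zero_standard: 50.0, units: '% of energy'}
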