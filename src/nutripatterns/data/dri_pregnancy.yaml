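# Dietary Reference Intakes for the adequacy appraisal (pregnancy, 19-50 y),
# from the IOM DRI report series. version 1.
#
# method: probability -> Beaton probability approach, Phi((intake-EAR)/SD);
#         cutpoint    -> proportion of individuals at/above the AI (or the
#                        EAR for calcium, which lacks an SD of requirement).
# Where the reports state only a CV of the requirement, SD = CV x EAR
# (default CV 10%; protein 12%; carbohydrate and niacin 15%; copper 15%).
# decimals: rounding precision applied to usual intakes before cut-point
# comparison, matched to the precision of the reference value.
version: 1
life_stage: pregnancy_19_50
nutrients:
  - {name: protein,      method: probability, ear: 50,   cv: 0.12, units: g/d}
  - {name: carbohydrate, method: probability, ear: 135,  cv: 0.15, units: g/d}
  - {name: thiamin,      method: probability, ear: 1.2,  cv: 0.10, units: mg/d}
  - {name: riboflavin,   method: probability, ear: 1.2,  cv: 0.10, units: mg/d}
  - {name: niacin,       method: probability, ear: 14,   cv: 0.15, units: mg/d}
  - {name: vitamin_b6,   method: probability, ear: 1.6,  cv: 0.10, units: mg/d}
  - {name: folate,       method: probability, ear: 520,  cv: 0.10, units: ug DFE/d}
  - {name: vitamin_b12,  method: probability, ear: 2.2,  cv: 0.10, units: ug/d}
  - {name: vitamin_c,    method: probability, ear: 70,   cv: 0.10, units: mg/d}
  - {name: phosphorus,   method: probability, ear: 580,  cv: 0.10, units: mg/d}
  - {name: magnesium,    method: probability, ear: 290,  cv: 0.10, units: mg/d}
  - {name: zinc,         method: probability, ear: 9.5,  cv: 0.10, units: mg/d}
  - {name: copper,       method: probability, ear: 800,  cv: 0.15, units: ug/d}
  - {name: selenium,     method: probability, ear: 49,   cv: 0.10, units: ug/d}
  - {name: fiber,        method: cutpoint,    ai: 28,    decimals: 0, units: g/d}
  - {name: potassium,    method: cutpoint,    ai: 2.9,   decimals: 1, units: g/d}
  - {name: calcium,      method: cutpoint,    ear: 800,  decimals: 0, units: mg/d}
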