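# Built-in nitrogen-fixation cycle definitions, per N2 reduced.
#
# All numeric fields are parsed as exact rationals ("1.6" -> 8/5,
# "2/15" -> 2/15).  Fields:
#   substrates / products  : stoichiometry per N2 (display bookkeeping)
#   reaction_steps         : enzymatic steps in one turn of the cycle
#   nadh_total             : NADH generated by catabolism
#   nadh_bifurcated        : NADH routed through the bifurcating complex
#                            (one low-potential electron each to nitrogenase)
#   qh2_catabolic          : quinol generated directly (succinate dehydrogenase)
#   extra_electrons_to_oxidase : electrons reaching the oxidase beyond
#                            bifurcated NADH + 2 per QH2; carries the
#                            pathway's full oxidase electron flux where the
#                            quinol column alone does not close the balance
#   h_enzymatic            : cytosolic protons consumed by enzymatic
#                            reactions (ammonia release, decarboxylations)
#   substrate_level_atp    : ATP from enzyme-coupled (substrate-level) synthesis
#   transaminations_per_arginine : transamination events per arginine
#                            (sets the secreted amino-acid count in the
#                            nitrogen budget)
#   non_reconciled         : the shipped parameters do not reproduce the
#                            published summary row under the main accounting
#                            rules; excluded from exact checks

- name: CATCH-N1
  substrates: {succinate: 2, arginine: 2}
  products: {alanine: 2}
  amino_product: alanine
  reaction_steps: 9
  nadh_total: 8
  nadh_bifurcated: 8
  qh2_catabolic: 4
  extra_electrons_to_oxidase: 0
  h_enzymatic: 8
  substrate_level_atp: 2
  transaminations_per_arginine: 2

- name: CATCH-N2
  substrates: {succinate: 2, arginine: 2}
  products: {aspartate: 2}
  amino_product: aspartate
  reaction_steps: 9
  nadh_total: 8
  nadh_bifurcated: 8
  qh2_catabolic: 4
  extra_electrons_to_oxidase: 0
  h_enzymatic: 4
  substrate_level_atp: 2
  transaminations_per_arginine: 2

- name: CATCH-N3
  substrates: {malate: 2, arginine: 2}
  products: {alanine: 2}
  amino_product: alanine
  reaction_steps: 9
  nadh_total: 8
  nadh_bifurcated: 8
  qh2_catabolic: 1
  extra_electrons_to_oxidase: 2
  h_enzymatic: 8
  substrate_level_atp: 2
  transaminations_per_arginine: 2

- name: CATCH-N4
  substrates: {malate: 2, arginine: 2}
  products: {aspartate: 2}
  amino_product: aspartate
  reaction_steps: 9
  nadh_total: 8
  nadh_bifurcated: 8
  qh2_catabolic: 1
  extra_electrons_to_oxidase: 2
  h_enzymatic: 4
  substrate_level_atp: 2
  transaminations_per_arginine: 2

- name: TCA-malate
  substrates: {malate: "1.6"}
  products: {co2: "6.4"}
  reaction_steps: 11
  nadh_total: 8
  nadh_bifurcated: 8
  qh2_catabolic: "1.6"
  extra_electrons_to_oxidase: 0
  h_enzymatic: "5.2"
  substrate_level_atp: "1.6"

- name: TCA-succinate
  substrates: {succinate: "1.6"}
  products: {co2: "6.4"}
  reaction_steps: 11
  nadh_total: 8
  nadh_bifurcated: 8
  qh2_catabolic: "3.2"
  extra_electrons_to_oxidase: "2/15"
  h_enzymatic: "5.2"
  substrate_level_atp: "1.6"
  non_reconciled: true
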