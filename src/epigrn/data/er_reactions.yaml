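# Default reaction table for the per-gene epigenetic-regulation (ER) network.
#
# Species (7):
#   M  -- methylated sites               (Y1)
#   U  -- unmodified sites               (Y2)
#   A  -- acetylated sites               (Y3)
#   HDM  -- free histone demethylase     (Y4)
#   C_HDM -- HDM.M substrate complex     (Y5)
#   HDAC -- free histone deacetylase     (Y6)
#   C_HDAC -- HDAC.A substrate complex   (Y7)
#
# Each channel fires with mass-action propensity c_k * prod(counts of `factors`).
# `factors` lists reactants and catalytic modifiers; `stoich` is the net change.
# Recruitment (positive feedback) enters through the binding/conversion factors:
# A recruits demethylation (ch 4) and acetylation (ch 16); M recruits methylation
# (ch 8) and deacetylation (ch 12).
species: [M, U, A, HDM, C_HDM, HDAC, C_HDAC]
site_species: [M, U, A, C_HDM, C_HDAC]
hdm_species: [HDM, C_HDM]
hdac_species: [HDAC, C_HDAC]
channels:
  - {label: "unrecruited demethylation, binding",    factors: [HDM, M],       stoich: {M: -1, HDM: -1, C_HDM: 1}}
  - {label: "unrecruited demethylation, unbinding",  factors: [C_HDM],        stoich: {M: 1, HDM: 1, C_HDM: -1}}
  - {label: "unrecruited demethylation, catalysis",  factors: [C_HDM],        stoich: {U: 1, HDM: 1, C_HDM: -1}}
  - {label: "A-recruited demethylation, binding",    factors: [HDM, M, A],    stoich: {M: -1, HDM: -1, C_HDM: 1}}
  - {label: "A-recruited demethylation, unbinding",  factors: [C_HDM],        stoich: {M: 1, HDM: 1, C_HDM: -1}}
  - {label: "A-recruited demethylation, catalysis",  factors: [C_HDM],        stoich: {U: 1, HDM: 1, C_HDM: -1}}
  - {label: "unrecruited methylation",               factors: [U],            stoich: {U: -1, M: 1}}
  - {label: "M-recruited methylation",               factors: [U, M],         stoich: {U: -1, M: 1}}
  - {label: "unrecruited deacetylation, binding",    factors: [HDAC, A],      stoich: {A: -1, HDAC: -1, C_HDAC: 1}}
  - {label: "unrecruited deacetylation, unbinding",  factors: [C_HDAC],       stoich: {A: 1, HDAC: 1, C_HDAC: -1}}
  - {label: "unrecruited deacetylation, catalysis",  factors: [C_HDAC],       stoich: {U: 1, HDAC: 1, C_HDAC: -1}}
  - {label: "M-recruited deacetylation, binding",    factors: [HDAC, A, M],   stoich: {A: -1, HDAC: -1, C_HDAC: 1}}
  - {label: "M-recruited deacetylation, unbinding",  factors: [C_HDAC],       stoich: {A: 1, HDAC: 1, C_HDAC: -1}}
  - {label: "M-recruited deacetylation, catalysis",  factors: [C_HDAC],       stoich: {U: 1, HDAC: 1, C_HDAC: -1}}
  - {label: "unrecruited acetylation",               factors: [U],            stoich: {U: -1, A: 1}}
  - {label: "A-recruited acetylation",               factors: [U, A],         stoich: {U: -1, A: 1}}
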