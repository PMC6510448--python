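# SYNTHETIC stand-in reference parameter sets.
#
# These four exemplar ER systems (two differentiation-gene systems DERS1/2,
# two pluripotency-gene systems PERS1/2), the ABC reference system and the
# two-gene GRN rates were constructed for this package from qualitative
# descriptions of the regimes they must realise: all bistable at the default
# scales (Y = 15 sites, Z = 5 enzymes); DERS1 red-cluster-like (fast opening,
# slow closing: larger unrecruited demethylation c1 and acetylation c15,
# smaller unrecruited deacetylation c11 and recruited acetylation c16);
# DERS2 blue-cluster-like (the mirrored biases); PERS1 the most
# opening-resistant, PERS2 intermediate.  They are NOT published values.
#
# c order: [c1..c16] as in er_reactions.yaml.
er_scales:
  n_sites: 15
  e_hdm: 5
  e_hdac: 5
  enzyme_scale: 5
  y0: 0.5

er_systems:
  reference:   # ABC raw-data generator, near-symmetric bistable system
    c: [0.05, 1.0, 0.3, 0.13333, 1.0, 0.3, 0.25, 0.04, 0.05, 1.0, 0.3, 0.13333, 1.0, 0.3, 0.25, 0.04]
  ders1:       # red-cluster-like differentiation ER system
    c: [0.18, 1.0, 0.3, 0.13333, 1.0, 0.3, 0.25, 0.04, 0.05, 1.0, 0.20, 0.13333, 1.0, 0.3, 0.30, 0.035]
  ders2:       # blue-cluster-like differentiation ER system
    c: [0.015, 1.0, 0.3, 0.13333, 1.0, 0.3, 0.25, 0.04, 0.05, 1.0, 0.45, 0.13333, 1.0, 0.3, 0.20, 0.06]
  pers1:       # most opening-resistant pluripotency ER system
    c: [0.008, 1.0, 0.3, 0.13333, 1.0, 0.3, 0.25, 0.04, 0.05, 1.0, 0.36, 0.13333, 1.0, 0.3, 0.21, 0.06]
  pers2:       # readily opening pluripotency ER system
    c: [0.09, 1.0, 0.3, 0.13333, 1.0, 0.3, 0.25, 0.04, 0.05, 1.0, 0.26, 0.13333, 1.0, 0.3, 0.25, 0.038]

grn:
  R: [0.02, 0.02]
  omega1: [4.0, 4.0]
  omega2: [1.0, 1.0]
  beta: [[4.0, 2.0], [2.0, 4.0]]
  delta: [[1.0, 1.0], [1.0, 1.0]]
  S: 100.0
  E: 3
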