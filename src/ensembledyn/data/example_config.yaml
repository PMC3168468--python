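# Seeded two-system comparison on the packaged synthetic fixture: a
# "wildtype" and a "mutant" bead-chain ensemble sharing one long-range
# correlated pair and one persistent salt bridge, with the mutant carrying
# one extra correlated pair (8-35) and one gained bridge (12-33).
systems:
  - label: wildtype
    synthetic: {preset: comparative, role: wildtype}
  - label: mutant
    synthetic: {preset: comparative, role: mutant}
correspondence:
  mutant: identity
seed: 7
outdir: ensembledyn_out
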