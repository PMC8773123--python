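# AcrA (membrane fusion protein) domain blocks for one protomer, chain A.
# The four structural domains each assemble from two discontinuous sequence
# segments (the chain folds back on itself: MP1, BB1, Lip1, HLH hairpin,
# Lip2, BB2, MP2).  Boundaries below are illustrative, rounded to published
# domain assignments of the mature protein; refine them against the
# deposition being analysed.
blocks:
  MP:     [[A, 29, 52], [A, 300, 366]]
  BB:     [[A, 53, 94], [A, 251, 299]]
  lipoyl: [[A, 95, 139], [A, 211, 250]]
  HLH:    [[A, 140, 210]]
order: [MP, BB, lipoyl, HLH]
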