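# TolC periplasmic-helix blocks, author numbering of the E. coli TolC
# protomer: helices H3/H4 span residues 126-206 and H7/H8 span 348-427.
# Chains A/B/C are the three protomers of the trimer; adjust chain ids to
# the deposition being analysed.
blocks:
  H3H4_A: [[A, 126, 206]]
  H7H8_A: [[A, 348, 427]]
  H3H4_B: [[B, 126, 206]]
  H7H8_B: [[B, 348, 427]]
  H3H4_C: [[C, 126, 206]]
  H7H8_C: [[C, 348, 427]]
order: [H3H4_A, H7H8_A, H3H4_B, H7H8_B, H3H4_C, H7H8_C]
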