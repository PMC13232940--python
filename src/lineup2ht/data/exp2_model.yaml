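# Base model for the four-condition experiment (format x number of
# culprit-present lineups): b and dA equated across all four conditions.
conditions: [combined_three, separate_three, combined_one, separate_one]
guess_split_c: 0.16667
equalities:
  b: all
  dA: all
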