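# Base model for the two-format lineup experiment: biased suspect selection
# (b) and culprit-absence detection (dA) equated across formats; detection
# of culprit presence (dP) and guessing (g) free per format.
conditions: [combined, separate]
guess_split_c: 0.16667
equalities:
  b: all
  dA: all
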