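# Default domain map for human KIF5B (heavy chain) used to classify
# crosslink contacts.  Intervals are half-open [start, end) in 1-based
# full-length sequence numbering.  Boundaries are approximate: only the
# fragment limits used for structure prediction are printed exactly
# (1-540, 401-690, 691-820, 821-963); interior domain edges were read off
# the domain diagram and are deliberately configuration, not code.
KIF5B:
  motor: [1, 336]
  cc1: [336, 401]
  cc2: [401, 541]
  cc3a: [541, 691]
  cc3b: [691, 821]
  cc4: [821, 908]
  tail: [908, 964]
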