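# Seven-group biophysical partition of the 20 standard amino acids, used to
# judge conservative (group-preserving) substitutions. Every residue belongs
# to exactly one group. Configurable: supply an alternative file with the
# same shape (group name -> string of one-letter codes).
groups:
  aliphatic: AVLI
  aromatic: FWY
  polar_neutral: STNQ
  acidic: DE
  basic: KRH
  sulfur: CM
  conformational: GP
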