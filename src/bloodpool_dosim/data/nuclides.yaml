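# Physical half-lives of the packaged radionuclides.
# Provenance: NNDC/ENSDF evaluated nuclear structure data.
#   F-18:   109.77 min
#   Tc-99m: 6.0067 h = 360.40 min
nuclides:
  F-18:
    half_life_minutes: 109.77
  Tc-99m:
    half_life_minutes: 360.40
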