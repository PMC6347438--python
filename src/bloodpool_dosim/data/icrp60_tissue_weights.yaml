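# Tissue weighting factors w_T for the effective dose.
# Provenance: ICRP Publication 60 (1991), Table 2. Weights sum to 1
# including the 0.05 remainder. The remainder organ list follows the
# ICRP 60 convention as applied in classical stylized-phantom dosimetry
# software (upper large intestine included).
provenance: "ICRP Publication 60 (1991), Table 2"
weights:
  gonads: 0.20
  colon: 0.12
  lungs: 0.12
  red_marrow: 0.12
  stomach: 0.12
  bladder: 0.05
  breasts: 0.05
  liver: 0.05
  oesophagus: 0.05
  thyroid: 0.05
  skin: 0.01
  bone_surfaces: 0.01
remainder_weight: 0.05
remainder_organs:
  - adrenals
  - brain
  - kidneys
  - muscles
  - pancreas
  - small_intestine
  - spleen
  - thymus
  - upper_large_intestine
  - uterus
# Surrogate target organs used when a phantom table does not report a
# weighted tissue directly (stylized-phantom convention for an adult
# male report): oesophagus dose taken as thymus dose, gonads as testes.
surrogates:
  oesophagus: thymus
  gonads: testes
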