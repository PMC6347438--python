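# Radiation dose limits for research uses of radioactive drugs in adults.
# Provenance: 21 CFR 361.1(b)(3)(i).
#   Whole body, active blood-forming organs, lens of the eye, gonads:
#     3 rem (30 mSv) per single administration, 5 rem (50 mSv) per year.
#   All other organs: 5 rem (50 mSv) single, 15 rem (150 mSv) per year.
# Limits are on absorbed/equivalent organ dose; the ICRP effective dose
# is not a 21 CFR 361.1 quantity.
provenance: "21 CFR 361.1(b)(3)(i)"
single_admin_mSv:
  restricted: 30.0
  other: 50.0
annual_mSv:
  restricted: 50.0
  other: 150.0
restricted_organs:
  - whole_body
  - gonads
  - testes
  - ovaries
  - red_marrow
  - blood_forming_organs
  - lens_of_eye
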