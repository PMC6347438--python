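# Regional distribution of blood volume, reference adult male.
# Provenance: transcribed from ICRP Publication 89 (2002), Table 2.14,
# "Distribution of blood in the vascular system" (percent of total blood
# volume, here expressed as fractions). Transcription is coarse-grained;
# verify against the publication before clinical use. Organs not listed
# are pooled into the synthetic region "rest_of_body" at load time so the
# fractions total exactly 1.
# Blood residing within an organ is assigned to that organ as the SOURCE
# region (the wall for hollow organs) — a blood-pool agent sits in the
# vasculature, not in any lumen.
organ,fraction
fat,0.050
brain,0.012
stomach,0.010
small_intestine,0.038
large_intestine,0.022
heart_contents,0.090
heart_wall,0.010
kidneys,0.020
liver,0.100
bronchial_tissue,0.020
lungs,0.105
muscles,0.140
pancreas,0.006
skeleton,0.070
skin,0.030
spleen,0.014
thyroid,0.0006
aorta_large_arteries,0.060
large_veins,0.180
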