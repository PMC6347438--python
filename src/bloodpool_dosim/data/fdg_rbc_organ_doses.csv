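# Published adult-male organ absorbed-dose coefficients (mGy/MBq) for
# FDG-labeled erythrocyte blood-pool PET imaging, computed with
# OLINDA/EXM 1.1 on the Christy-Eckerman stylized phantom under two
# biodistribution scenarios:
#   full_retention — 100% in-vivo retention, pure physical decay
#   free_fdg_25pct — poor labeling, 25% urinary excretion of free FDG
# heart_wall is the myocardial wall; colon is the average of the upper
# (ULI) and lower (LLI) large intestine rows.
organ,full_retention,free_fdg_25pct
adrenals,2.82E-02,2.42E-02
bladder,9.70E-03,3.98E-02
bone_surfaces,1.81E-02,1.63E-02
brain,7.16E-03,1.49E-02
breasts,9.75E-03,9.51E-03
gallbladder,1.64E-02,1.56E-02
stomach,2.48E-02,2.13E-02
small_intestine,3.46E-02,2.90E-02
colon,3.52E-02,2.97E-02
upper_large_intestine,3.37E-02,2.83E-02
lower_large_intestine,3.67E-02,3.10E-02
heart_wall,7.78E-02,7.51E-02
kidneys,4.07E-02,3.48E-02
liver,3.94E-02,3.48E-02
lungs,6.39E-02,5.29E-02
muscles,8.71E-03,9.03E-03
ovaries,1.21E-02,1.26E-02
pancreas,4.14E-02,3.43E-02
red_marrow,1.77E-02,1.60E-02
skin,5.93E-03,6.40E-03
spleen,4.59E-02,3.72E-02
testes,8.44E-03,9.08E-03
thymus,1.47E-02,1.40E-02
thyroid,1.76E-02,1.57E-02
uterus,1.11E-02,1.28E-02
remaining_organs,1.21E-02,1.21E-02
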