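# Demo pipeline configuration: published organ-dose table, reference
# effective-dose coefficient, planned 185-370 MBq injection range,
# 370 MBq per administration, noiseless synthetic labeling runs at the
# measured 2-hour incorporation fraction for day-old cells.
nuclide: F-18
seed: 1
labeling:
  mode: synthetic
  incorporated_fraction: 0.582
  wash_carryover: [0.03, 0.02, 0.01]
  calibrator_cv: 0.0
  n_replicates: 5
  initial_activity_mbq: 55.5
  planning_initial_mbq: 740.0
  prep_time_min: 65.0
leakage_points:
  - [46.0, 10.5]
  - [76.0, 19.4]
  - [106.0, 23.7]
dose_input:
  mode: organ_table
  organ_doses: packaged
scenarios:
  - {name: full_retention, excreted_fraction: 0.0}
  - {name: free_fdg_25pct, excreted_fraction: 0.25}
activity_per_admin_mbq: 370.0
planned_activity_range_mbq: [185.0, 370.0]
effective_dose_coefficient_mSv_per_MBq: 3.90e-02
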