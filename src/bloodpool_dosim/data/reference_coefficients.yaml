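# Headline effective-dose coefficients used for planning and for the
# agent comparison. The FDG-erythrocyte value is the published
# OLINDA/EXM ICRP-60 estimate for the blood-pool biodistribution; the
# Tc-99m-erythrocyte value is the ICRP biokinetic-model coefficient for
# Tc-99m-labeled red cells.
effective_dose_mSv_per_MBq:
  fdg_labeled_erythrocytes: 3.90e-02
  tc99m_labeled_erythrocytes: 7.0e-03
# SNMMI-guideline administered-activity ranges (MBq).
planned_activity_range_MBq:
  fdg_labeled_erythrocytes: [185.0, 370.0]
  tc99m_labeled_erythrocytes: [555.0, 1110.0]
  intravenous_fdg: [370.0, 740.0]
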