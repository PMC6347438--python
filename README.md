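# bloodpool-dosim

Planning-grade dosimetry and labeling kinetics for radiolabeled-erythrocyte
blood-pool PET imaging.

Human erythrocytes express GLUT1 at very high copy number and will
internalise the glucose analog FDG, so FDG-labeled autologous red cells
are a candidate PET blood-pool agent (cardiac blood-pool imaging, occult
GI bleeding) to replace Tc-99m-labeled erythrocyte scintigraphy. Taking
such an agent toward a first-in-human protocol needs a reproducible
desk-side computation chain, which this package provides for medical
physicists and imaging scientists:

* **Labeling kinetics** — decay-corrected mass balance of
  incubate-and-wash labeling runs (percent incorporation, wash fractions,
  recovery), saturating-uptake and leakage fits, and batch yield
  prediction.
* **Biodistribution** — the well-mixed blood-pool model: each organ's
  fraction of the injected dose equals its fractional blood volume
  (ICRP Publication 89), with full-retention and partial-urinary-excretion
  scenarios (dynamic voiding-bladder model).
* **MIRD dosimetry** — organ absorbed doses
  `D(r_T) = Σ_S ã(r_S)·S(r_T ← r_S)` from any supplied S-value matrix,
  hollow-organ wall electron self-dose correction, ICRP-60 effective dose
  `E = Σ_T w_T·H_T`, and 21 CFR 361.1 single/annual administration limits.
* **Synthetic data** — seeded generators for every input (labeling runs,
  leakage series, blood-volume tables, S-matrices) with known ground
  truth, so the whole chain is testable offline.

S-values are *input*: classical stylized-phantom tables are proprietary,
so real use takes a user-transcribed phantom CSV while tests use the
synthetic generator. See `docs/methods.md` for models, assumptions and
defaults.

## Worked example

```python
import bloodpool_dosim as bpd

f18 = bpd.load_nuclide("F-18")

# Batch planning: 740 MBq added, measured 58.2% incorporation,
# 65 min total preparation time.
print(round(bpd.predict_yield(740, 0.582, 65, f18), 1))   # 285.7  (MBq)

# Leakage at a 1-hour imaging horizon, from three measured means.
leak = bpd.fit_leakage([(46, 10.5), (76, 19.4), (106, 23.7)])
print(round(bpd.predict_leakage_at(leak, 60), 1))         # 14.3   (%)

# Regulatory screening of the packaged published organ-dose table.
doses = bpd.load_reference_organ_doses()["full_retention"].to_dict()
limits = bpd.load_regulatory_limits()
res = bpd.admin_limits(doses, 3.90e-2, 370.0, limits)
print(res.limiting_organ, res.max_annual_admins)          # heart_wall 5

# Planned-range effective dose from the reference coefficient.
print(bpd.total_effective_dose(3.90e-2, 185),
      bpd.total_effective_dose(3.90e-2, 370))             # 7.2 14.4  (mSv)
```

The batch yields ≈285.7 MBq of cell-bound activity; ≈14.3% of it is
expected to have leaked back to plasma by one hour; the heart wall is the
dose-limiting organ under 21 CFR 361.1 (28.8 mSv per 370 MBq
administration against the 150 mSv annual organ limit → 5 administrations
per year); and the planned 185–370 MBq injection spans 7.2–14.4 mSv
effective dose.

The same chain runs end-to-end from a YAML config:

```bash
bloodpool-dosim report --out out/          # packaged demo configuration
bloodpool-dosim simulate --seed 1 --out sim/
bloodpool-dosim label-analyze --run sim/labeling_run_0.csv --report report.yaml
```

`report` writes a bundle (per-scenario dose CSVs, scenario comparison,
YAML + text summary) that is byte-identical across re-runs.

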