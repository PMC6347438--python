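# Methods

This note documents the models behind `bloodpool_dosim`, the assumptions
they make, the defaults they ship with, and what the synthetic-data
generators do and do not emulate.

## Scope and problem

The package covers the desk-side computational chain for a
radiolabeled-erythrocyte blood-pool PET agent: analysing the cell-labeling
experiments (incorporation, washes, leakage), converting the blood-pool
biodistribution into time-integrated activity coefficients, turning those
into organ absorbed doses via the MIRD schema, and screening the result
against ICRP-60 effective dose and 21 CFR 361.1 administration limits.
Image acquisition, reconstruction, VOI analysis and flow cytometry are out
of scope: they belong to scanner and cytometer vendor software.

## Decay arithmetic

All kinetics run on a clock in minutes (from injection, or from tracer
addition for labeling runs); wall-clock parsing is I/O's job. Activities
decay as `2^(-t/T½)`. Packaged half-lives (`data/nuclides.yaml`, NNDC/ENSDF
values): F-18 = 109.77 min, Tc-99m = 360.40 min. Decay correction is the
exact inverse, so correct-after-decay round-trips to machine precision —
a property the test suite checks rather than assumes.

## Labeling-run analysis

A run is one cells measurement, at most one incubation supernatant, and up
to three wash supernatants, each a dose-calibrator reading with a
timestamp. Every reading is decay-corrected to run start before any ratio
is formed, which makes percent incorporation invariant to a common
measurement time and honest when compartments were counted at different
times. The denominator of percent incorporation is the *recovered* sum of
compartments, not the nominal added activity; unrecovered residue is
reported separately (`recovery_fraction`) so losses to tube walls never
masquerade as incorporation. A mass-balance guard rejects runs whose
corrected sum exceeds the nominal initial activity by more than a
configurable tolerance (default 5%, roughly five calibrator CVs).

**Uptake model.** `F(t) = f_inf·(1 − e^(−k t))` — first-order
transporter-mediated (GLUT1) uptake, the simplest saturating form
consistent with 30-minute incubations approaching 2-hour incorporation.
Two points determine the exact interpolant (solved by bracketed root
finding on the incorporation ratio); more points go to bounded nonlinear
least squares. Fitting the 1-h:2-h ratio of 0.99 pins `k = ln(99)/60 ≈
0.0766 min⁻¹`, which *implies* a 30-min:2-h ratio of ≈0.90; measured
values near 0.92 are compatible within their standard errors but the
functional form cannot be pushed harder with three timepoints, so no test
asserts the 0.92.

**Leakage model.** Percent leaked vs minutes of plasma incubation is fit
by ordinary least squares (default), matching the approximately linear
release observed over 46–106 min; a first-order release variant
(`fit_leakage_first_order`) is available for longer horizons where a line
must eventually fail. Predictions are clamped to [0, 100]% and warn more
than 30 min outside the fitted range. On the three measured means
(46 min, 10.5%), (76 min, 19.4%), (106 min, 23.7%) the line is
`0.22 %/min × t + 1.147 %` (R² ≈ 0.96 on the means; replicate-level R²
would differ), giving ≈14.3% at a 1-hour imaging horizon.

**Batch yield.** `initial × incorporated fraction × decay(prep time)`.
Default planning point: 740 MBq, fraction 0.582 (2-h incubation of
day-old cells), 65 min preparation (midpoint of a 60–70 min
incubate-and-wash protocol) → 285.7 MBq.

## Biodistribution

Under the well-mixed assumption the injected labeled cells distribute
uniformly in the blood volume within minutes, so an organ's fraction of
the dose equals its fractional blood content. Fractions come from a
transcription of ICRP Publication 89 Table 2.14 (`data/
icrp89_blood_volumes.csv`); blood in an organ is assigned to that organ as
source — the *wall* for hollow organs, which is what makes the wall
correction below meaningful — and the unassigned remainder becomes
`rest_of_body`, so dose fractions always sum to exactly 1.

Two scenarios:

* **Full retention** (`retained_fraction = 1`): the whole dose decays in
  place; each region's ã is `fraction · T½/ln 2` hours, and Σã equals
  `T½/ln 2` exactly (2.639 h for F-18) — a conservation law the tests
  enforce.
* **Partial urinary excretion** (default 25%, emulating poor labeling):
  the retained 75% decays in the blood pool; the excreted 25% passes
  through a dynamic voiding-bladder model with first-order biologic entry
  (half-time 12 min, free-FDG-like) and voiding every 3.5 h, both
  configurable. Between voids the bladder contents have the closed form
  `B(t) = f·e^(−λ_p t)(e^(−λ_b t_k) − e^(−λ_b t))`; the integral is summed
  interval-by-interval to convergence. Activity decaying "in transit"
  (before reaching the bladder) is credited to neither pool, so
  Σã ≤ T½/ln 2, with equality in the instant-entry, no-voiding limit.
  The tests cross-check this integral against an independent fine-grid
  trapezoid oracle that integrates each inter-void interval separately
  (the contents are discontinuous at voids).

## MIRD dose engine

`D(target) = Σ_sources ã(source)·S(target←source)`. S-values are **input**
— a user-transcribed phantom table or the synthetic generator — because
classical stylized-phantom (Christy–Eckerman/OLINDA) tables are
proprietary. Validation enforces non-negativity and self-dose dominance
(`S(s←s) ≥ S(t←s)`), and the engine is checked against an element-wise
double-loop oracle on random instances.

**Hollow-organ wall correction.** Classical phantoms put hollow-organ
activity in the lumen and credit the wall with half the contents-absorbed
electron dose (surface convention). For a blood-pool agent the activity is
in the wall, so the term `½·ã_contents·Δ_e/m_contents` is replaced by the
wall self-absorbed term `ã_wall·Δ_e/m_wall`. Photon terms are untouched;
in the equal-mass, equal-ã limit the electron term exactly doubles.

**Effective dose.** ICRP-60 weights (`data/icrp60_tissue_weights.yaml`):
gonads 0.20; colon, lungs, red marrow, stomach 0.12; bladder, breasts,
liver, oesophagus, thyroid 0.05; skin, bone surfaces 0.01; remainder 0.05
as the unweighted mean of ten remainder organs (mass-weighted variant via
an argument). Surrogates for an adult-male stylized report: oesophagus ←
thymus, gonads ← testes. Equivalent dose equals absorbed dose numerically
(w_R = 1 for photons and positrons/electrons). Recomputing E from the
packaged published organ-dose table with these textbook conventions gives
≈2.5E−02 mSv/MBq, whereas the published headline coefficient is
3.90E−02 mSv/MBq — the originating software's remainder and surrogate
conventions are not public, so the package reports the recomputed value
*side-by-side* with the reference coefficient and uses the latter for
planning totals. No test asserts the two are equal.

**Regulatory screening (21 CFR 361.1).** Restricted organs (whole body,
gonads, red marrow/blood-forming organs, eye lens) carry 30 mSv single /
50 mSv annual limits; all others 50/150 mSv. Per organ,
per-administration dose = coefficient × activity; an organ over its
single-administration limit allows zero administrations, otherwise
`floor(annual limit / per-admin dose)`; the limiting organ attains the
minimum (ties broken toward the higher dose). The whole-body limit is an
*absorbed* dose limit: it is screened only when a `whole_body` entry is
present in the dose table, and the effective dose — which is not a
361.1 quantity — is reported alongside but never screened. Doses exactly
at a limit are compliant (10⁻⁹ relative tolerance on the floor and the
comparison). All-zero doses return a "no binding constraint" sentinel.
With the packaged coefficients at 370 MBq per administration the heart
wall (7.78E−02 mGy/MBq → 28.8 mSv/admin) is limiting at
`floor(150/28.8) = 5` administrations per year.

## Synthetic data

Generators are pure functions of their seed and define the conditions the
tests run under:

* **Labeling runs** — the activity partition (cells fraction, wash
  carry-overs, supernatant remainder) is fixed truth; readings get
  multiplicative lognormal noise with mean 1 (calibrator error is
  scale-proportional), default CV 1%. Defaults mirror the measured
  operating point: fraction 0.582, carry-overs (3, 2, 1)%, 55.5 MBq
  added, counted 120 min after tracer addition.
* **Leakage series** — linear truth plus the same noise model.
* **S-matrices** — an 8-organ + `rest_of_body` phantom (masses
  0.02–20 kg, so wall-correction and remainder logic are both exercised),
  positron-emitter energies (0.242 MeV electron, 0.990 MeV photon per
  decay; 1 MeV per decay = 0.5767 mGy·kg per MBq·h), 30% photon
  self-absorption with half the escaping energy re-absorbed
  mass-proportionally. Off-diagonal entries are capped at 95% of the
  column's self term so self-dose dominance holds by construction.

What passing tests show: the estimators are unbiased (to 3 SE at 1000
replicates) under unbiased multiplicative noise, and the dose chain is
exact given its inputs. What they do not show: real calibrator
nonlinearity, pipetting losses, inter-donor biological variation in
uptake, or the fidelity of any real phantom's S-values — those enter only
through user-supplied tables.

## Numerical choices and degenerate inputs

* Two-point uptake fits use Brent root finding (xtol 1e−14) on the
  incorporation ratio; ratios at or below `t1/t2` (sub-linear) or at/above
  1 are non-identifiable and raise a fit error, as do coincident times in
  any fit.
* All-zero compartment activities raise an undefined-ratio error rather
  than returning 0/0.
* The bladder series is truncated when a term falls below 1e−16 of the
  running total; instant entry and infinite voiding interval use their
  closed-form limits.
* ã vectors validate `Σã ≤ T½/ln 2 (1 + 1e−9)`; wash fractions normalise
  to 1 within 1e−9 and dose linearity holds to 1e−12 in the tests.

## Problem sizes

The Monte-Carlo bias checks use 1000 replicates; property suites run 100
randomized cases per invariant on 10×10 dose matrices; the full pipeline
demo runs in well under a second. These sizes give standard errors small
enough to detect percent-level estimator bias while keeping the whole
suite near-instant.

## Known limitations

* No true multi-compartment kinetic biodistribution (first-pass
  extraction, organ-specific washout); the well-mixed model is static by
  design.
* The 5-day-old-cell uptake decline is observed, not modelled.
* The ICRP-89 transcription is coarse; users doing real dosimetry should
  verify it and supply a real phantom S-matrix.
* Female/paediatric phantoms and decay chains are out of scope.
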