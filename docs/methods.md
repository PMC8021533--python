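# Methods

## Study design being operationalized

The pipeline describes, without inferential statistics, how blood
coagulability and liver function evolve in patients stably treated with
warfarin who undergo a course of interferon-free hepatitis-C therapy
(direct-acting antivirals, DAAs).  The working hypothesis it is equipped to
display — not test — is that clearing the virus improves hepatic synthesis
of clotting factors and warfarin metabolism, so the same warfarin dose
yields a lower PT-INR during and right after therapy.  The dose-adjusted
summary statistic is the warfarin sensitivity index, WSI = PT-INR / daily
dose (INR per mg/day): it falls when coagulability rises relative to dose,
and clinicians' compensatory dose increases make the raw PT-INR alone an
understated signal.

All calendar arithmetic is day-granular on closed intervals; "12 weeks" is
exactly 84 days throughout.

## Treatment episodes (drug eras)

Two consecutive prescription records of one patient and one drug key merge
into the same episode iff `next.start − prev.end ≤ gap_days` (default 30;
the day-30 gap is inclusive).  Overlapping records merge as a zero gap.  An
episode spans min start to max end of its members.  Consequences worth
noting:

* with `gap_days = 0`, only overlapping or same-day-touching records merge;
  records on adjacent days remain separate episodes even though their day
  coverage is contiguous (their merged coverage is identical either way,
  which is how the day-set oracle in the tests compares them);
* warfarin products are pooled under one class key, because persistence and
  dosing are patient-level; DAA episodes are keyed per regimen, because the
  completion rule is regimen-specific, so switching regimens ends an
  episode.

Episode duration is the inclusive day count `end − start + 1`.

## Eligibility cascade

Steps run in a fixed order and the attrition ledger records survivors after
each; a patient excluded at one step is never evaluated at later ones.

0. **Dual prescribing** — at least one warfarin and one DAA prescription
   each individually intersecting the closed study window (the window
   intersecting reading is this package's resolution of an underdetermined
   inclusion rule).
1. **Concurrent exposure** — the earliest DAA episode wholly contained in a
   single warfarin episode (strict containment, not overlap) defines T1/T2;
   T3 = T2 + 84 days.  One anchor set per patient.
2. **Completion** — episode duration ≥ designated duration − 15-day
   allowance (a 12-week regimen therefore needs ≥ 69 days).
3. **Persistence** — the containing warfarin episode ends on or after T3.
4. **Lab availability** — at each anchor, a PT-INR (exact date, else the
   most recent within the lookback) *and* a positive warfarin daily dose on
   the PT-INR measurement date.  The conjunctive reading is primary; a
   disjunctive variant is available (`require_inr_and_dose=False`).

The lookback is retrospective, `[anchor − 30, anchor]`, with the exact date
preferred and the day-30 record eligible.  A symmetric ±14-day window
(`lab_window="symmetric"`, nearest record, earlier side on ties) is provided
because retrospective-only and symmetric allowances are both defensible
readings of such designs; the retrospective rule is the default.  Same-day
duplicate measurements resolve deterministically to the last record in file
order.

## Outcome extraction and summaries

For each cohort patient × anchor, the PT-INR row carries the daily dose
evaluated **on the measurement date** (which may precede the anchor), summed
over concurrent warfarin products, and the WSI.  The other seven series
(AST, ALT, ALP, γ-GTP, FIB-4, platelets, HCV viral load) are optional:
missing values are recorded as NaN and the patient is retained.

Summaries per series × timepoint over non-missing patients: mean and sample
SD (n−1 denominator; an n = 1 cell reports SD 0 with a degeneracy flag
rather than NaN), and the mean ± SD of the per-patient percentage
`100 × value_t / value_T1` over patients with a T1 value (T1 row: 100% ± 0
by construction).  The pipeline deliberately averages per-patient ratios —
the mean WSI is the mean of PT-INR/dose, not mean PT-INR over mean dose; a
test asserts the two differ on an asymmetric fixture.  The viral load is
summarized on the raw scale (its T2 collapse is naturally read as a
percentage); a log10 companion series is available as an option.

## Synthetic EHR generator

The generator emulates the data structure the analysis assumes, with known
labels.  Each patient draws one archetype: *eligible* (probability 0.6 by
default) or one of four failure modes (0.1 each) that each violate exactly
one cascade criterion — no containment, early DAA termination, warfarin
stop before T3, or a missing PT-INR window at one anchor.  Prescription
streams are cut into ~3–5-week refills separated by benign gaps of up to
min(gap period, 12) days, so episode merging is exercised on every patient
without ever splitting an intended episode; gaps are suppressed on planned
measurement dates so the dose is always computable where the design
requires it.  About half the PT-INR anchor measurements fall on the exact
anchor date and half a few days earlier, covering both lab-selection code
paths by construction.

Latent values per test: a between-patient lognormal level around the T1
target mean (CV 0.1 for chemistry, 0.3 for viral load; PT-INR 0.15, dose
0.25), and T2/T3 values equal to the patient's *own* T1 value times the
configured multiplier times a smaller mean-one lognormal trajectory noise
(CV 0.03–0.10).  Anchoring T2/T3 to the patient's T1 value makes the
per-patient proportion an unbiased lognormal around the multiplier, so the
mean-of-proportion summaries estimate the configured effects directly; it
also reflects the strong within-patient tracking of real laboratory series.
Warfarin dose segments switch halfway between measurement dates, so the
dose read on each measurement date is exactly that timepoint's latent dose.

Default T2/T3 multipliers are calibrated to the reported cohort trends:
PT-INR 0.878/1.0, dose 1.051/1.013 (hence WSI ≈ 0.835 at T2 with a T3
rebound), AST/ALT 0.575 maintained, γ-GTP/FIB-4 0.80 then 0.95, ALP and
platelets flat, viral load 0.05 maintained.  They are defaults describing
the emulated scenario, not assertions about truth.  T1 means (e.g. AST 60
U/L, FIB-4 3.5, viral load 2×10⁶ IU/mL) are chosen as typical for
anticoagulated chronic hepatitis-C patients; the corresponding SDs in the
source material are not printed in text, so the CVs are free parameters.

What the generator does **not** model: warfarin pharmacokinetics or
clinician dose-titration feedback, genotype effects, inter-test
correlation beyond the shared patient level, informative missingness, or
measurement-date clustering across tests.  Passing the label-recovery and
effect-recovery suites therefore demonstrates correctness of the pipeline's
logic under the assumed structure, not robustness to real-world EHR
pathologies such as irregular coding or transcription error.

## Numerical and design choices

* Problem sizes in the validation suites — 1,000 randomized record sets for
  the episode oracle, 5 × 200 patients for label recovery, 500 eligible
  patients for effect recovery — are chosen so sampling error is far below
  the tolerances being checked while the whole suite runs in seconds.
* Effect recovery is judged within 3 empirical standard errors of the
  configured multiplier; the WSI, a ratio whose mean has no closed-form
  target under the noise model, is checked qualitatively (T2 < T1, T3 > T2).
* Ties and degeneracies: same-day labs → last in file order; n = 1 SD → 0
  with a flag; empty cohort → empty summary and a warning, not an error.
* The generator rejects configurations it cannot honour (probabilities not
  summing to 1, regimens shorter than allowance + 28 days, a study window
  too short to place a contained episode with follow-up) instead of
  silently producing unlabeled pathologies.

## Known limitations

The cascade keeps one anchor set per patient (the earliest contained DAA
episode); re-treatment courses are not analyzed separately.  Prescription
periods must carry explicit end dates (no days-supplied inference).  No
per-regimen stratification or inferential statistics are produced — the
design is descriptive, and cohorts of realistic size for this question are
far too small for them anyway.
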