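# Methods notes

This note records the model, the fixed numerical choices, and the design
decisions taken where the method left room, in the package's own words.

## Study frame

The pipeline reproduces a retrospective claims-cohort design for locally
advanced (stage III–IVB) squamous cell carcinoma of the head and neck
(LA SCCHN) in four sites — oral cavity, oropharynx, hypopharynx, larynx.
The observation calendar runs 2015-01-01 to 2022-07-31; index dates (first
confirmed LA diagnosis) are restricted to 2016-01-01 through 2021-06-30 so
that every patient can have 12 months of pre-index history and at least some
post-index follow-up inside the calendar. Follow-up ends at the earliest of
calendar end, loss of coverage (end of enrollment) or in-hospital death.

## Date arithmetic

Claims carry day resolution, so all window tests are whole-day differences
on calendar dates, inclusive (`|Δ| ≤ w`). Six months is fixed at 183 days
and twelve months at 365 days; month arithmetic is never used, because it is
not reproducible across implementations.

## Cohort selection

A diagnosis is *confirmed* by one inpatient HNC code or by two outpatient
claims with a primary HNC code. The index claim must fall inside the accrual
window; the second (confirming) outpatient claim may fall anywhere in the
record, which is the more permissive of the two defensible readings and is a
deliberate choice. The stage III/IVA/IVB claim may precede or follow the
diagnosis within the 60-day staging window: the window is applied two-sided
because the rule's direction is not otherwise determined.

The exclusion cascade is evaluated in a fixed order — confirmed diagnosis,
valid stage, age ≥ 18, prior metastasis code (C78.x/C79.x), prior stage
I/II/IVC claim, other primary cancer in the pre-index year, ≥ 365 days of
pre-index enrollment, chemotherapy-only treatment, clinical-trial flag — and
only the first failing criterion is recorded, so the attrition log reads as
a sequential flow and per-reason counts are well defined. "Other primary
cancer" means any C-coded claim outside the four-site HNC set and outside
C78/C79, strictly before index and within the pre-index year (the narrowest
reading consistent with the criterion).

The chemotherapy-only exclusion (a proxy for non-squamous histology) checks
for systemic therapy inside the 183-day treated window with no surgical
resection, no radiotherapy fraction and no neck dissection over a 12-month
post-index horizon; a neck dissection exempts the patient. All-cause
prescriptions never count as systemic therapy here (see *Drug semantics*).

Trial participation is a boolean column in `patients.csv`; real databases
flag it in database-specific ways that are out of scope. Lymph-node
involvement (N0 vs N1–N3) is reported as `unknown` because staging claims in
this data model carry only the stage group; the field exists so that a
richer staging feed can populate it.

## Elixhauser Comorbidity Index

Thirty comorbidity categories with ICD-10 prefix sets (Quan-style coding)
and van Walraven weights, shipped as `data/eci_weights.csv` (category,
semicolon-separated prefixes, integer weight). The positive weights sum to
+89 and the negative weights to −19, which are therefore the attainable
score extremes. A category is flagged by any matching code strictly before
the index date within the pre-index year; duplicates count once. The index
date itself is excluded so the qualifying cancer diagnosis does not flag the
solid-tumor category for every patient. Codes are matched on dot-stripped
uppercase prefixes.

## Drug semantics

Two kinds of drug claims share one table. Named agents from the controlled
vocabulary (cisplatin, carboplatin, nedaplatin, fluorouracil, docetaxel,
paclitaxel, cetuximab, tegafur/gimeracil/oteracil) are systemic therapy.
Unknown drug names map to agent `other` with a warning rather than an error,
because all-cause prescription counting must not drop rows; an `other` claim
enters regimen construction only when its ATC code begins with `L01`
(antineoplastic), in which case it is a distinct regimen component named
"other". Everything else is utilization only. This is what makes pattern
classification invariant to the prescription stream, a property the tests
assert.

## Treatment sequencing

Radiotherapy fractions merge into a course while inter-fraction gaps stay
≤ 14 days. Systemic administrations group into regimens: the earliest
unassigned administration anchors a block; agents whose first unassigned
administration falls within 8 days of the anchor are its components; the
merged component stream extends the block until a > 60-day lapse. An agent
introduced later opens its own (possibly overlapping) block, which the
line-end logic interprets as an add-on or a switch.

A systemic block and a radiotherapy course starting within 14 days of each
other pair into one concurrent-CRT unit (each block pairs at most once,
nearest start first, ties to the earlier block; widening the window can only
add pairs, never remove them). The *treated* flag requires a first treatment
block of any modality within 183 days of index — any modality, because
surgery-only patients are plainly treated. The LA treatment comprises blocks
starting within 90 days of the first treatment's start; a CRT partner of an
in-window block is kept even when its own start falls just outside, and
blocks are never split at the window edge. Same-day modality ties order
surgery < systemic < radiotherapy; concurrency is consulted first, so the
tiebreak rarely matters.

Line end walks the patient's systemic blocks in start order, because the
switch/discontinuation rules are prescription rules. Per-component last
administration dates let the walk see one component stopping while the rest
continues: a monotherapy switch is a different single agent starting ≥ 8
days after the current start and within 60 days of the current end; a
combination switch removes one component and adds a new one within 60 days,
the new combination persisting ≥ 8 days; a pure addition is an add-on and
neither ends nor advances the line; a > 60-day lapse with no qualifying
successor is a discontinuation; if observation ends within 60 days of the
last administration the line is ongoing. Patients without systemic therapy
fall back to the same lapse rule on their last treatment block.

The sequencing rules apply uniformly to all modalities where a rule does not
mention agents; whether a radiotherapy-only lapse should count as a
prescription gap is genuinely open, and the uniform reading was chosen for
determinism.

## Pattern taxonomy

Sequence elements are surgery (all surgeries in the window collapse to one
element — the taxonomy has no repeat-surgery label), CRT units, radiotherapy
courses and systemic regimens, ordered by start. Surgery-containing
sequences beyond the four named ones fall into `other_resection`. Induction
chemotherapy followed by concurrent CRT classifies as chemotherapy→
radiotherapy, not CRT alone: the 14-day pairing decides which side of the
line a systemic block falls on. A systemic-only sequence is the
chemotherapy + neck-dissection group; without a dissection such patients are
removed upstream by the chemotherapy-only exclusion, and the classifier logs
the sequence if it ever sees one. Longer nonsurgical sequences fold into the
label of their leading strategy, with the sequence logged.

Percentages in report tables are round-half-up at one decimal, so a cell is
always within half a unit of the exact ratio.

## HCRU and costs

Eight categories: physician visits, all-cause admissions, all-cause
prescriptions, laboratory tests, diagnostic imaging, LA-SCCHN surgeries
(resection + neck dissection, a category-level proxy for an unstated
procedure-code list), radiotherapy fractions, rehabilitation/homecare.
Events count in `[index, index + 365)`; an admission overlapping the window
edge counts, with its full cost, if its admission date is inside — claims
are billed at admission granularity, and the convention must be pinned for
the additivity tests to be exact. Count statistics are computed among users
(patients with ≥ 1 event), matching how such tables are conventionally
reported.

Cost per patient-year divides a category's total expenditure by the summed
follow-up duration in years of every patient in the HCRU cohort. The
denominator defaults to full (uncapped) follow-up: published tables of this
kind are internally consistent only when totals divided by cost-per-
patient-year exceed the cohort size, implying multi-year denominators. A
capped-at-one-year alternative is a configuration switch
(`HcruConfig.denominator = "capped_1y"`). The HCRU cohort itself requires a
full 365-day window by default, which also excludes patients dying in
hospital within the first year; `require_full_window=False` relaxes this.

## Synthetic generator

The generator's defaults are the study conditions, not tuning knobs: the
pathway mix uses the published overall pattern proportions (e.g. CRT alone
2655/6741, not treated 1085/6741), the site and stage mixes the published
distributions (oropharynx 28.6%, …; IVA 53.1%, …), regimen menus per context
the published initial-chemotherapy tables (cisplatin 74.7% of CRT backbones;
TPF 55.6% of induction before radiotherapy; residual probability mass folds
into cisplatin), and age/sex the published demographics (mean 67.7 ± 11.8
years, 80.9% male).

Pathway realization is constructive, never rejection-based: every gap is
drawn strictly inside the legal range its label implies (concurrent systemic
starts 0–14 days from the radiotherapy course start; sequential induction
gaps 15–75 days; combination components within 0–4 days of the anchor;
cycles every 21 days; a "not treated" patient's late therapy starts 190+
days after index). This guarantees by design that the classifier recovers
the intended label — the closure property the acceptance suite checks at 500
realizations per label.

Counts for the utilization stream are negative binomial, moment-matched to
the published mean/SD per category and clipped to the published min/max,
with a separate user probability (e.g. admissions 99.8%); this puts the
medians within the published values' neighborhood without targeting them
directly. Per-event costs are log-normal around the published per-user
annual mean divided by the mean count. Follow-up is log-normal around a
652-day median (clipped 60–2427 days and to the calendar), so roughly
three quarters of eligible patients reach the 12-month HCRU window.

Contaminants — deliberately ineligible patients — default to ~20% of the
cohort, split across all seven generable exclusion branches, so the
attrition cascade is exercised end to end; each contaminant trips exactly
one criterion by construction. Comorbidities are independent category draws
from a fixed prevalence menu (baseline mean index ≈ 2); C-coded categories
are absent from the menu because any pre-index malignancy code would
(correctly) exclude the patient.

A single root seed drives per-patient child streams (`[seed, i]`), so
cohorts are byte-stable under changes of `n_patients` and across runs.

**What the generator does not emulate:** comorbidity co-occurrence
structure, seasonal/COVID-era utilization shifts, hospital-level linkage,
fee-schedule unit prices, dose/cycle detail, HPV status and histology.
Passing tests therefore demonstrate the correctness of the derivation rules
on data with the assumed structure, not the clinical fidelity of any
particular synthetic cohort.

## Verification strategy

The episode engine is cross-checked against an independent brute-force
day-scanner (`tests/oracle.py`) that re-derives blocks, CRT pairings and
line ends by literal day-stepping, on 1000 random small timelines, plus
boundary probes at 8/9, 14/15, 60/61, 90/91 and 183/184 days. Report
arithmetic is checked against printed-table cells reproduced from their
printed numerators and denominators. End-to-end recovery of configured
proportions is accepted within three binomial standard errors at the stated
cohort sizes (n = 6741 for the definitive-nonsurgical share; n = 400
patients on the chemotherapy→radiotherapy pathway for the TPF share).
Problem sizes in the test suite (300–2000-patient cohorts for property
tests, 6741 for the full-scale recovery) were chosen so the whole suite runs
in well under a minute per file on one CPU.

## Known limitations

* Second and later treatment lines are not modeled beyond line-end
  detection.
* The 90-day modality window is anchored literally at the first treatment's
  start; genuinely adjuvant blocks starting on day 91+ fall outside the LA
  treatment, which is one reason a small residual `other` group exists in
  real data.
* BMI and lymph-node involvement are carried as fields but not populated by
  the synthetic feed.
* The ICD-10 prefix sets in the comorbidity table are a faithful but
  editable transcription; institutions with local coding quirks should
  adjust the CSV rather than the code.
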