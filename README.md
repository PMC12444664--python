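# hnclaims

Claims-based analysis of treatment patterns, comorbidity burden, healthcare
resource utilization (HCRU) and costs for **locally advanced squamous cell
carcinoma of the head and neck (LA SCCHN)** — TNM stage III–IVB tumors of the
oral cavity, oropharynx, hypopharynx and larynx.

Real analyses of this kind run on proprietary hospital administrative claims
databases that cannot be redistributed. `hnclaims` therefore ships two things
together:

1. **The analysis pipeline** — cohort construction from raw claims tables, a
   rule-based temporal treatment-sequencing engine, a two-level treatment
   pattern taxonomy, Elixhauser comorbidity scoring, and 12-month HCRU/cost
   aggregation.
2. **A seeded synthetic claims generator** that emulates the structure of such
   a database (per-patient dated event streams over a 2015–2022 calendar
   window) and emits a ground-truth table, so every pipeline stage is testable
   end to end without any external data.

Who it is for: pharmacoepidemiologists and health-outcomes researchers who
need a reproducible, fully tested reference implementation of claims-based
treatment-pathway derivation for head and neck cancer.

## The method

**Cohort.** The index date is the first confirmed LA HNC diagnosis in the
accrual window (2016-01-01 to 2021-06-30): ≥1 inpatient HNC ICD-10 code, or
≥2 outpatient claims with a primary HNC code, plus a stage III/IVA/IVB claim
within ±60 days. Patients are then excluded, in a fixed cascade order, if
they are under 18 at index, carry a metastasis code (C78.x/C79.x) or a stage
I/II/IVC claim before index, have another primary cancer in the 12-month
pre-index window, have under 12 months of pre-index enrollment, received
chemotherapy as their only treatment (unless a neck dissection was also
performed), or are flagged as clinical-trial participants.

**Treatment sequencing.** Dated claims are merged into modality-level blocks
and combined with inclusive day-count window rules:

| rule | window |
|---|---|
| patient is *treated* if first treatment follows index within | 183 days |
| LA treatment = blocks starting within ... of the first treatment | 90 days |
| agents join one combination regimen if first administered within | 8 days |
| systemic therapy and radiotherapy are concurrent (CRT) if starts within | 14 days |
| a regimen ends at a lapse in administrations longer than | 60 days |

Switches (monotherapy and combination), add-ons and discontinuations are read
off the resulting block sequence; an add-on never ends or advances the line.

**Patterns.** Each patient's LA treatment maps to a two-level label: primary
resection (surgery alone, surgery→CRT, surgery→RT, chemo→surgery, other),
definitive nonsurgical treatment (CRT alone, RT alone, chemo→RT, RT→chemo),
chemotherapy + neck dissection, or not treated.

**Comorbidity.** The Elixhauser Comorbidity Index is computed from pre-index
ICD-10 codes over 30 categories with van Walraven weights (attainable range
−19 to +89), shipped as an editable table
(`src/hnclaims/data/eci_weights.csv`).

**HCRU and costs.** Eight utilization categories are counted over
`[index, index + 365)` among patients with a full year of follow-up; count
statistics are computed among users, and cost per patient-year divides each
category's total expenditure by the summed follow-up years of the denominator
population.

## Worked example

```python
from hnclaims import (GeneratorConfig, generate_cohort, run_pipeline,
                      tabulate_patterns, regimen_distribution, attrition_log)

cfg = GeneratorConfig(n_patients=2000, seed=42)
bundles, truth = generate_cohort(cfg)          # synthetic claims + ground truth
records, classified = run_pipeline(bundles)    # selection -> episodes -> labels
labels = {pid: lab for pid, (_, lab) in classified.items()}

print(attrition_log(records))
table = tabulate_patterns(labels, records, "overall")
print(table[table["sub"] == ""][["top", "n", "pct"]].to_string(index=False))
```

Output:

```
{'all_patients': 2000, 'confirmed_hnc_diagnosis': 2000, 'valid_la_stage': 2000,
 'age_18_plus': 1958, 'no_prior_metastasis': 1897, 'no_prior_other_stage': 1843,
 'no_other_primary_cancer': 1775, 'sufficient_pre_index': 1688,
 'not_chemo_only': 1642, 'no_clinical_trial': 1590, 'eligible': 1590}
                   top   n  pct
     primary_resection 495 31.1
definitive_nonsurgical 825 51.9
 chemo_neck_dissection   2  0.1
           not_treated 268 16.9
```

2000 generated patients enter; the default ~20% contaminant mix is removed by
the cascade (each step's count is the patients surviving that filter), and the
1590 eligible patients split across the four top-level patterns close to the
generator's configured mix (51.9% definitive nonsurgical here). Regimen
distributions are available per context, e.g. the systemic backbone of
definitive CRT:

```python
print(regimen_distribution(list(classified.values()), "crt_backbone").head(3))
```

```
                  regimen    n   pct
                cisplatin  474  78.0
                cetuximab   61  10.0
 fluorouracil + cisplatin   24   3.9
```

The same stages are scriptable from a shell:

```bash
hnclaims simulate --out claims/ --seed 42 --n 2000
hnclaims select-cohort --claims claims/ --out cohort.csv --attrition attrition.json
hnclaims classify --claims claims/ --cohort cohort.csv --out tables/
hnclaims hcru --claims claims/ --cohort cohort.csv --out tables/
```

## Layout

```
src/hnclaims/
  model.py      claims data model (patients, diagnoses, staging, drugs,
                procedures, admissions)
  io.py         CSV claims tables, TSV report tables, n (%) formatting
  synth.py      seeded synthetic cohort generator + truth table
  cohort.py     index date, exclusion cascade, Elixhauser index, baselines
  episodes.py   treatment blocks, CRT pairing, LA assembly, line end
  patterns.py   two-level taxonomy, pattern tables, regimen distributions
  hcru.py       12-month utilization and cost aggregation
  pipeline.py   end-to-end drivers
  cli.py        `hnclaims` command group
docs/methods.md methodological notes and design decisions
tests/          unit, property and end-to-end acceptance tests
```
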