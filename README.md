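# neosps

Toolkit for the **sepsis prediction score (SPS)** used to anticipate
late-onset sepsis (LOS) in neonatal intensive care. The score targets the
everyday NICU question: a hospitalised neonate deteriorates, a blood
culture is drawn — how likely is that culture to come back positive, and
could the deterioration have been flagged earlier?

The SPS sums eight equally weighted binary indicators, each dichotomised by
a strict threshold:

| indicator | fires when |
|---|---|
| fever | body temperature > 38 °C |
| feeding | feeding volume decrease or residuals > 20% |
| circulation | capillary refill time > 5 s, or hypotension |
| o2_increase | increased oxygen requirement (clinical judgment) |
| respiratory | apnea, or new/changed need for mechanical ventilation |
| glucose | blood glucose change > 50% (hyper- or hypoglycemia) |
| platelets | platelet count < 150,000/mm³ |
| crp | CRP > 1 mg/dL |

The score ranges 0–8; a neonate with score ≥ 3 is predicted septic, and the
bands 0–2 / 3–4 / 5–8 stratify suspicion (low / strong / effectively
certain). Against blood-culture status the usual seven statistics are
computed from the 2×2 table: Se, Sp, PLR = Se/(1−Sp), NLR = (1−Se)/Sp, PPV,
NPV and accuracy, with zero-denominator cases reported as undefined ("-").

The package provides, for researchers evaluating or re-deriving such scores:

- **scoring** — raw observations → indicators → score → cutoff classification;
- **diagnostics** — 2×2 tables from patient-level data *or reconstructed
  from published summary counts*, the seven statistics, exact
  (Clopper–Pearson) binomial intervals;
- **association** — per-indicator two-sided Fisher exact comparisons
  between culture-positive and culture-negative groups (point-probability
  rule, exact over the whole hypergeometric support);
- **stratification** — score distributions, risk bands, cutoff sweeps;
- **simulate** — a synthetic cohort generator with packaged presets
  matching the published derivation (63 BC+ / 57 BC−) and validation
  (94 BC+ / 51 BC−) cohorts, optional latent-correlation dependence, and
  Poisson-binomial analytic oracles;
- **published** — the printed summary tables of both cohorts as data, the
  reconstruction of every published diagnostic cell from them, and a
  discrepancy report for cells the counts cannot reproduce.

## Worked example

Reconstructing the published diagnostic rows from the published score
distributions and septic band counts (`examples/02_reconstruct_published_results.py`):

```
     study timepoint  tp  fp  fn  tn     Se      Sp   PLR  NLR     PPV    NPV Accuracy
derivation       48h  23   2  40  55 36.51%  96.49% 10.40 0.66  92.00% 57.89%   65.00%
derivation       24h  28   3  35  54 44.44%  94.74%  8.44 0.59  90.32% 60.67%   68.33%
derivation        0h  52   8  11  49 82.54%  85.96%  5.88 0.20  86.67% 81.67%   84.17%
validation       48h   6   0  88  51  6.38% 100.00%     - 0.94 100.00% 36.69%   39.31%
validation       24h   8   0  86  51  8.51% 100.00%     - 0.91 100.00% 37.23%   40.69%
validation        0h  72  14  22  37 76.60%  72.55%  2.79 0.32  83.72% 62.71%   75.17%
```

Reading the derivation 0h row: on the day the blood culture was taken,
score ≥ 3 identified 52 of the 63 culture-positive neonates (Se 82.54%)
while only 8 of 57 culture-negative neonates reached the cutoff
(Sp 85.96%); a positive classification multiplied the odds of sepsis by
PLR 5.88. The "-" PLR cells mark perfect specificity — no culture-negative
neonate reached the cutoff, so the likelihood ratio is undefined. The
reconstruction reproduces 40 of the 42 printed cells exactly at their
printed precision; the remaining two (prospective Se, printed 63.8 and
85.1) are decimal-shift typos of the derivable 6.38 and 8.51 and are
flagged, not corrected, together with a scrambled p-value column and one
frequency cell (see the discrepancy report in the same example).

Scoring a single neonate (`examples/01_score_a_neonate.py`):

```
indicators: {'fever': True, 'feeding': False, 'circulation': False, 'o2_increase': False,
             'respiratory': False, 'glucose': False, 'platelets': True, 'crp': True}
score: 3
predicted septic at cutoff 3: True
```

The other examples simulate a full validation-style cohort and run the
pipeline end to end (`03`), and compare the Poisson-binomial closed form
with Monte-Carlo estimates (`04`).

## Command line

A thin CLI wraps the library:

```
neosps simulate --preset validation2017 --seed 1 --out cohort.csv
neosps evaluate --cohort cohort.csv --cutoff 3
neosps associate --cohort cohort.csv --timepoint 0h
neosps sweep --cohort cohort.csv --timepoint 0h
neosps reproduce-tables
```

Cohort CSVs carry one row per neonate-timepoint (`id`, `group` = pos|neg,
`timepoint` = 48h|24h|0h, then either the eight 0/1 indicator columns or
the ten raw observation columns). Threshold and simulation configs are
YAML; see `neosps.io`.

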