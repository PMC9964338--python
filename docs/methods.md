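# Methods

## The score and its evaluation

The sepsis prediction score is the count of eight binary indicators of
clinical/laboratory deterioration in a neonate suspected of late-onset
sepsis, assessed at three timepoints: 48 h prior, 24 h prior, and the day
the blood culture was taken (0 h). Every threshold comparison is strict
(`>` / `<`) — a temperature of exactly 38.0 °C or a platelet count of
exactly 150,000/mm³ does not score. This follows the operational
definitions of the score; the package keeps all six numeric thresholds
configurable (`ThresholdConfig`) but treats the strictness as fixed.

Two definitional ambiguities in the source material were resolved as
follows. First, the narrative summary speaks of "temperature instability"
while the operational definition is fever > 38 °C; the operational
definition is implemented (the threshold is configurable for users who want
a different temperature criterion). Second, the per-variable frequency
tables label the feeding row "> 50%" while the score definition says
"> 20%"; the default is 0.20, matching the score definition, and the
discrepancy is noted here rather than reconciled. The glucose indicator is
the *absolute* relative change from a caller-supplied reference value
(covering both hyper- and hypoglycemia); the package never infers
baselines. Oxygen-requirement increase and respiratory deterioration have
no numeric definition and are carried as boolean clinical judgments.

Diagnostic evaluation cross-classifies `score >= cutoff` against
blood-culture status and computes Se, Sp, PLR, NLR, PPV, NPV and accuracy.
Any statistic with a zero denominator — including PLR at perfect
specificity — is represented as an explicit undefined state and rendered
"-", never as an infinity or an exception. Clopper–Pearson exact binomial
intervals are available (`clopper_pearson_ci`) but are an add-on: the
published analysis reports point estimates only, so no interval is attached
to reconstructed results by default.

## Reconstruction from published summaries

The patient-level cohorts were never deposited. The package instead ships
the printed summary counts (per-variable counts by group and timepoint,
whole-cohort score distributions, septic-subgroup band counts, the
diagnostic summary, and the demographic composition) as constants in
`neosps.published`. For a cutoff on a band boundary (3 or 5), the 2×2 table
of each cohort-timepoint is exactly determined: tp and fn come from the
septic band counts, fp and tn from subtracting them from the whole-cohort
score distribution. Cells implied negative raise an inconsistency error
naming the cell; patient-level data support any cutoff 1–8.

Comparison with printed cells is done at each cell's printed precision.
Two display conventions coexist in the source tables and are both
implemented: diagnostic percentages are rounded half-up to two decimals
(82.5397 → "82.54"), while the septic-band percentages are truncated toward
zero (36.507 → "36.50", 21.019 → "21.01") — empirically the only rule that
reproduces every printed band cell. One diagnostic cell prints no decimals
("65%"); it is reproduced as 65.00%.

The reconstruction deliberately does not "fix" the source. Cells that
cannot be reproduced are flagged in a discrepancy report: the two
prospective sensitivity cells (printed 63.8 and 85.1, decimal shifts of the
derivable 6.38 and 8.51 — their own rows' NPV, accuracy and NLR reproduce
exactly from the small values), seven of the eight 48 h derivation
p-values (the printed column appears scrambled relative to its own counts),
and one frequency cell (printed 87.5 where 54/63 = 85.7).

## The exact association test

Per-variable comparisons use the two-sided Fisher exact test under the
point-probability rule: conditioning on both margins, the p-value sums the
hypergeometric probabilities of all tables whose point probability does not
exceed the observed one (ties included, with a 1e-7 relative float
tolerance so exact ties are never split by rounding). The implementation
computes the whole-support pmf via `scipy.stats.hypergeom` and vectorises
the rule by sorting, which makes exhaustive sweeps over margin sets cheap;
tests verify it against both an exact integer-arithmetic enumeration (no
floating point in the tie decision) and `scipy.stats.fisher_exact`.

Printed p-values are treated as soft cross-checks only, at a tolerance of
one unit in the third decimal: several printed cells are smaller than the
recomputed value by exactly 0.001, consistent with truncation by the
original statistics software, and the scrambled 48 h column cannot follow
from its own counts at any tolerance. Rendering follows the source: three
decimals, "<0.001" below 0.0005. No multiple-testing correction is applied,
matching the original analysis.

## The synthetic cohort generator

The generator emulates the *statistical structure the analysis assumes*:
two culture groups of configurable size, eight Bernoulli indicators per
neonate per timepoint, with per-(group, timepoint, indicator) prevalences.
The packaged presets `derivation2010` (63/57) and `validation2017` (94/51)
use the exact count-based frequencies of the published cohorts as
prevalences, and sample sex / gestational-age class / birth-weight class
metadata from the published per-group demographic proportions (metadata
never influences indicators — no interaction is quantified in the source).

Dependence, about which the published marginals say nothing, is modelled by
a single latent severity variable per neonate-timepoint: indicator *i* is
true iff `sqrt(rho)·u + sqrt(1-rho)·e_i < Φ⁻¹(p_i)` with shared `u` and
idiosyncratic `e_i`, standard normal. This latent-threshold (Gaussian
copula) construction preserves the configured marginals for any
`rho ∈ [0, 1)` and induces positive pairwise association for `rho > 0`;
`rho = 0` (the default, and the analytic case) gives independence. Temporal
persistence is likewise synthetic: with probability `persistence` an
indicator true at the previous timepoint stays true before the fresh draw,
which *inflates* later marginals above the configured prevalences — it
defaults to 0 and is intended only for stress-testing downstream code
against within-neonate correlation.

What the generator does **not** emulate: continuous raw-value kinetics
(temperature curves, CRP dynamics — `backfill_raw` produces only two-point
raw values for round-trip testing of the dichotomiser), realistic
within-neonate correlation structure over time, and any
demographics-indicator interaction. Tests passing on synthetic cohorts
therefore validate the *computational pipeline* under the published
marginal structure, not clinical transportability of the score.

Randomness: one `numpy` Generator seeded per cohort, with a fixed
vectorised draw order (per group: demographics, then indicators per
timepoint), giving byte-for-byte reproducible CSV exports for a fixed
config and seed.

## Analytic oracles

Under independence the score is Poisson-binomial; `poisson_binomial_pmf`
computes the exact pmf by dynamic-programming convolution (O(8²) floats,
verified against full 2⁸ enumeration to 1e-12). `expected_metrics` turns
the two group pmfs into expected Se (upper tail at the cutoff, positive
group), Sp (complementary tail, negative group) and — via Bayes' rule at
prevalence `n_pos/(n_pos+n_neg)` — PPV, NPV and accuracy. Correlated or
persistent configurations are refused with a pointer to Monte-Carlo
estimation, since the closed form holds only under independence.

## Problem sizes and numerical choices

- Exhaustive Fisher verification covers all 164,175 admissible tables with
  every margin ≤ 30, against integer-arithmetic enumeration at 1e-10.
- Generator-vs-oracle agreement uses 200 cohorts of 5,000 per group
  (culture-day validation prevalences, cutoff 3), compared within three
  Monte-Carlo standard errors of the 200-replicate mean.
- Prevalence recovery uses one cohort of 10,000 per group and requires
  every configured probability to lie in the 99.7% Clopper–Pearson interval
  of its re-estimate; exact-zero prevalences recover exactly. With 48
  simultaneous exact intervals the joint pass probability is slightly below
  one by construction; the intervals are deliberately not widened.
- Display rounding is decimal half-up (never banker's) for diagnostics and
  truncation for band percentages, as above; internal computation is never
  rounded.

## Known limitations

- `confusion_from_distributions` supports only band-aligned cutoffs (3 and
  5) because the septic subgroup is published in bands; patient-level data
  support all cutoffs.
- No ROC/AUC, no bootstrap intervals, no optimal-cutoff criterion (Youden);
  the cutoff sweep reports, it does not choose.
- Missing values in cohort CSVs reject the affected row with a logged
  reason; there is no imputation by design.
- The score itself is fixed at eight equally weighted indicators; the
  package evaluates it, it does not re-derive weights.
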