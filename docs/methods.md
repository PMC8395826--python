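# Methods

`trecscreen` models a national TREC-based newborn-screening programme for
severe combined immunodeficiency (SCID) end to end: a synthetic screened
cohort, the multiplex qPCR assay that measures TREC, KREC and ACTB
copies/well from dried-blood-spot (DBS) punches, the per-card screening
decision algorithm, and the programme-level performance statistics. The
reference data are the published aggregates of one screening year in a
population of 115,786 children (115,216 newborns, 570 non-newborns up to two
years of age), in which 73 children were referred, 21 were diagnosed with
T cell lymphopenia and 3 with SCID.

## Cohort model

**Analyte distributions.** Card-level TREC and KREC copies/well are modelled
as lognormal within each gestational-age stratum. The choice is driven by the
data: copies/well are strictly positive and right-skewed, and only the median
and interquartile range are published per stratum, which identify a lognormal
exactly:

    mu = ln(median),    sigma = ln(q3/q1) / (2 * z_0.75),   z_0.75 = 0.674490

The seven strata (3-week blocks from week 22 to 43) carry the reference
medians/IQRs: TREC rises from 25 (14, 47) copies/well at weeks 22–24 to
81 (56, 112) at weeks 40–43, while KREC is flat across gestational age.
Stratum weights are the reference per-stratum child counts, so the default
mixture reproduces the population composition (93.7 % term). Non-newborns
draw TREC from median 104 (64, 151) and KREC from the right-shifted
median 180 (126, 258).

**Spot-to-spot variability.** Each card's four punches vary around the card
truth with multiplicative lognormal noise at CV 10 % (configurable,
`spot_cv`). Intra-card replicate variance is not published; 10 % is a typical
qPCR repeatability figure and the value only matters for how often the
consensus outlier rule fires.

**Sampling age** is lognormal with median 57.1 h and IQR (49.9, 73.0),
truncated at 24 h, matching the all-newborn reference figures.

**Conditions.** Rare conditions are injected per child at configurable rates;
the defaults are the reference-year frequencies:

| condition | default rate | analyte profile |
|---|---|---|
| SCID | 3 / 115,216 newborns | TREC < 1 copy/well on every spot; KREC ~1 for ADA-like genotypes (1/3 of cases) or normal for JAK3-like; CD3 < 0.15×10⁹/L |
| lymphopenia, non-SCID | 18 / 115,216 newborns | TREC uniform on [0, 6]; CD3 < 2×10⁹/L |
| low-TREC false positive | 52 / 115,786 | TREC uniform on [0, 6.4] (the observed range of false-positive referrals); CD3 ≥ 2 |
| technical failure | 27 / 115,786 | global amplification failure: ACTB < 1000 copies/well on all spots, TREC/KREC low |

Lymphopenia is defined as CD3⁺ T cells < 2×10⁹ cells/L, and labels are kept
phenotype-consistent (every SCID/lymphopenia child has CD3 < 2; every
low-TREC false positive has CD3 ≥ 2). Non-failure children always have
ACTB ≥ 1000 copies/well. A small unknown-gestational-age fraction
(5 / 115,216) is carried as missing GA and excluded from stratified
summaries.

**What the generator does not emulate.** Low-TREC cases are injected
independently of gestational age, so the simulated cohort does not reproduce
the strong preterm excess among referrals (0.52 % vs 0.03 % in the reference
year) unless condition rates are made GA-dependent. The healthy lognormal
tails also carry far less mass below the referral cut-off than real data,
which show zero-inflation at low TREC; consequently simulated referral and
reanalysis rates for a case-free cohort are lower than the observed 1.23 %
reanalysis rate (which also includes quality failures), and the term/preterm
percentile-equivalence analysis collapses to the extreme lower tail rather
than to an exact 0. Age trends within non-newborns, seasonality, and maternal
immunosuppression are not modelled. Passing calibration tests therefore
demonstrates that the machinery recovers its configured distributions, not
that the generator is a faithful model of every feature of screening data.

## qPCR model

Quantification uses 5-point standard curves (10–100,000 copies/well for
TREC/KREC, 100–1,000,000 for ACTB). A curve is fitted by ordinary least
squares of Ct on log10(copies) — the kit's proprietary procedure is not
published — and inverted for quantification: copies = 10^((Ct − b) / m).
Amplification efficiency is 10^(−1/slope) − 1. The forward model adds
Gaussian Ct noise and a stochastic detection step at the assay's analytical
limits (LoD 3.41 / 3.13, LoB 0.32 / 0.38 copies/well for TREC / KREC): truths
below the LoB never amplify, truths between LoB and LoD amplify with
probability 0.5 (configurable). "No amplification" quantifies as 0
copies/well.

Plate QC accepts a run iff every curve has r² ≥ 0.98 and efficiency within
90–110 %, the three internal DBS controls (low-TREC/high-KREC,
low-KREC/high-TREC, low-TREC/low-KREC) reproduce their expected patterns
(low ≤ 6, high ≥ 15 copies/well), and the blank well shows no amplification.
The thresholds follow common qPCR practice and are parameters, because the
kit's acceptance requirements are unpublished. Visual inspection of
amplification plots is abstracted to a per-analyte boolean flag.

## Screening algorithm

Per card, with the initial PCR of one punch:

1. **Quality gate**: amplification profile OK and ACTB ≥ 1000 copies/well;
   otherwise the card is reanalysed from all available spots.
2. **Direct negative** if TREC exceeds the epoch's reanalysis cut-off
   (15 copies/well until 2020-03-31; 10 from 2020-04-01, keyed on the card's
   laboratory-arrival date).
3. **Duplicate reanalysis** from new punches if TREC lies between the
   referral and reanalysis cut-offs; **quadruplicate** (all spots) if TREC is
   at or below the referral cut-off (6 copies/well, inclusive).
4. **Consensus**: the verdict uses the mean over all PCRs performed on the
   card (initial + 2, or all four spots). An *extreme-variability rule* may
   iteratively drop the minimum replicate when the retained max/min ratio
   exceeds 10 **and** the remaining mean exceeds the referral cut-off. The
   second condition is essential: SCID cards yield uniformly low TREC, so the
   rule can never rescue a uniformly-low card (the no-SCID-escape property,
   tested exhaustively). The published description ("extreme variability",
   "particularly low") is qualitative; ratio > 10 with single-minimum
   exclusion is our concrete reading and the ratio is configurable.
5. **Verdicts**: referral iff consensus mean ≤ 6 copies/well;
   *inconclusive* iff every replicate has TREC below the referral cut-off
   with ACTB < 1000 (amplification failure) — a new card is requested, and
   non-responders (modelled at rate 7/27) become lost to follow-up, with
   responders screening negative on the fresh card. A discretionary
   borderline-referral band above the cut-off exists as a policy flag,
   default off. KREC is carried and reported with referrals but never enters
   the decision.

Lowering the reanalysis cut-off changes only the reanalysis workload, never
any referral verdict (verified over a TREC grid 0–20 in 0.1 steps at both
epochs): every referral requires a consensus mean ≤ 6, reachable from either
band.

In the default programme run, quantified values equal the card truths (the
zero-noise curve round-trip is exact by construction); Ct noise and
near-limit dropout can be injected by routing cards through the plate
simulator first. This keeps the large calibration runs deterministic and
fast; with unbiased Ct noise the log-scale quantification error is symmetric
and the screening verdicts change only for cards within noise reach of a
cut-off.

## Performance statistics

Proportion CIs use the Wilson score interval (via
`statsmodels.stats.proportion.proportion_confint`); incidence CIs use the
exact Poisson method, rate bounds [χ²(α/2, 2k), χ²(1−α/2, 2k+2)] / 2N.
From the reference counts (TP 3, FP 70, TN 115,704, FN 0 for SCID; TP 21,
FP 52 for lymphopenia): PPV_SCID 4.11 % (1.41–11.40), PPV_lymphopenia
28.77 % (19.65–40.01), sensitivity_SCID 100 % (43.85–100), NPV 100 %, and
SCID incidence 3/115,216 = 1 in 38,405 (95 % CI 1 in 186,231 to 1 in 13,142).

Two numerical caveats are documented rather than resolved. First, the
reference report's printed specificities (99.937 / 99.953 %) do not equal
TN/(TN+FP) from its own printed counts (99.9395 / 99.9551 %); we implement
the standard formula. Second, the exact coverage of the Wilson interval at
p = k/n dips to 0.875 at (k = 2, n = 4) — only the two extreme binomial
outcomes miss p — which is a property of the interval itself; the unit tests
assert this closed-form value by exact enumeration.

**Cut-off sweep.** The post hoc analysis re-thresholds the referred children
at candidate cut-offs, recomputing referral counts (overall and by
term/preterm), PPVs with Wilson CIs, and SCID sensitivity. The per-child mean
TRECs of the 73 referred children were never published, so the package ships
a *synthetic reconstruction* (`published.referred_children`): true-positive
rows carry the published per-case card values (with three values resolved
within their printed rounding so the published cut-off-4 exclusions hold),
and false-positive TRECs are fixed synthetic values constrained to reproduce
every published marginal — 35/33/5 preterm/term/non-newborn referrals, 19
undetectable-TREC children (10 term, 6 preterm, 3 non-newborn; 11 of them
lymphopenic), and at cut-off 4.0 exactly 53 referrals (23 preterm with 6 TP,
25 term with 12 TP) with all three SCID cases retained, giving
PPV_lymphopenia 34.0 % (22.7–47.4).

**Percentile equivalence** maps a term cut-off to the preterm quantile at the
same cumulative probability, quantifying why a single TREC cut-off cannot
equalise term and preterm referral rates.

## Numerical and design choices

- Referral comparison is inclusive (mean ≤ 6.0 refers), matching the
  programme's rule; the reanalysis comparison is strict (> cut-off is
  negative).
- The consensus rule keeps at least one replicate and exclusions only remove
  minima, so the consensus mean always dominates the plain mean.
- Degenerate inputs: an empty cohort is an empty frame, not an error; a card
  with no valid wells is inconclusive; a metric with a zero denominator is
  reported as undefined (None), not an error; quantile ties in
  `percentile_equivalence` follow NumPy's linear interpolation.
- Zero-variance standard series and non-positive concentrations raise an
  invalid-curve error; Wilson CI bounds are clamped to [0, k/n] / [k/n, 1]
  against floating-point spill.
- Problem sizes: calibration checks use 50,000-newborn cohorts, 20 seeds for
  the overall median (mean of per-seed medians rounds to the reference 79
  copies/well) and 500-resample bootstrap CIs for per-stratum medians; these
  sizes put Monte-Carlo error well below the one-copy/well reporting
  precision while keeping a full run in seconds.

## Limitations

- All "reference mode" statistics are arithmetic on published aggregates;
  they validate the statistical machinery, not the data pipeline.
- The synthetic referred-children table is one admissible reconstruction;
  any statistic of it beyond the published marginals (e.g. its mean TREC) is
  not data.
- The simulation's epoch-specific reanalysis rates are not comparable to the
  published 1.55 %/0.68 % because those include amplification-profile
  failures whose frequency is not published.
- The outlier-exclusion ratio, plate-acceptance thresholds, near-LoD
  detection probability and second-card response rate are parameterised
  stand-ins for unpublished operational detail.
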