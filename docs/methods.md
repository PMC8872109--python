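# Methods

## Species table and TEQ

Fifteen US-EPA priority PAHs are modelled; naphthalene is excluded because
its volatility keeps it out of the particulate phase. Each species carries
an aromatic-ring count (3-ring = low molecular weight; 4–6 ring = high
molecular weight, with the 5- and 6-ring classes merged in reports) and a
toxic equivalency factor (TEF) relative to benzo[a]pyrene:

| TEF   | species                          |
|-------|----------------------------------|
| 0.001 | ACY, ACP, FLR, PHE, FLT, PYR     |
| 0.01  | ANT, BgP, CYR                    |
| 0.1   | BaA, BkF, BbF, IcP               |
| 1     | BaP (reference)                  |
| 5     | DhA                              |

The weights sum to 6.436. The toxicity-equivalent concentration is
TEQ = Σ TEF(s)·C(s) in ng m⁻³ of BaP-equivalents. The legacy codes ACE and
IND are accepted on input and canonicalised to ACP and IcP.

Below-detection values in input CSVs (token `<LOD`) are substituted by a
configurable policy — `half_lod` (default, common practice), `zero`, or
`lod` — using a per-species LOD table. Inputs are assumed blank-corrected;
missing species in a profile count as not detected (0 in sums).

## Descriptive stage

Per (school, location) the arithmetic mean and sample SD (n−1) of the total
PAH are reported; a single-observation group gets SD 0 with an explicit
degenerate flag. The indoor/outdoor ratio is computed on site mean totals
(the pairing of individual samples is not modelled) and labelled with both
published heuristics: `indoor_weak` below 1, `indoor_source_present` above
the Long–Sarnat criterion of 1.15, and `indoor_strong_boundary` for the
[1, 1.15] band where the two rules disagree.

## Source diagnostics

Threshold rules as implemented (boundary points resolved deterministically):

| ratio          | rule                                                        |
|----------------|-------------------------------------------------------------|
| ANT/(ANT+PHE)  | < 0.1 petrogenic, else pyrogenic (0.1 → pyrogenic)           |
| IcP/(IcP+BgP)  | > 0.2 pyrogenic, else petrogenic-leaning (0.2 → leaning)     |
| BaA/(BaA+CYR)  | < 0.2 petrogenic, 0.2–0.35 mixed (inclusive), > 0.35 combustion |
| FLR/(FLR+PYR)  | > 0.5 diesel, else gasoline (0.5 → gasoline)                 |

The ≤ 0.2 side of IcP/(IcP+BgP) is labelled "petrogenic-leaning" rather
than "petrogenic" because only the > 0.2 side has a published reading. A
zero denominator yields an undefined ratio (serialised as an empty CSV
field) and is excluded from site percentage denominators, which are
reported with a separate undefined count.

## Risk model

ILCR = TEQ·cf·CSF·(BW/70)^(1/3)·IR·ED·EF/(BW·AT). Defaults: CSF 3.85
(mg kg⁻¹ day⁻¹)⁻¹, IR 12 m³ day⁻¹, ED 6 y, EF 250 day y⁻¹,
AT 25,550 days (70 y × 365 d), cf 10⁻⁶ (ng→mg). The cube-root term is the
standard body-weight adjustment of the BaP slope factor.

Monte-Carlo scenarios (10,000 iterations by default, numpy `default_rng`
seeded explicitly):

- TEQ ~ logistic, location = arithmetic mean (2.32 HT / 1.02 LT ng m⁻³),
  truncated at 0 by rejection resampling. The scale parameter is not part
  of the published scenario; the default is 0.3 × mean. The MC *mean* is
  nearly scale-invariant — the only scale effect on the mean is the
  truncation shift (for scale 0.3·mean the exact conditional mean
  E[X|X>0] is ≈ 4.7% above the location; the shift is tested against a
  numerical-integration oracle, never silent) — while percentiles depend on
  the scale directly and should be read as scale-calibration illustrations.
- BW ~ lognormal parameterised by arithmetic mean and SD
  (33.13/14.54 kg HT, 28.33/10.86 kg LT), moment-matched internally to
  (μ, σ): σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2.
- CSF, IR, ED, EF, AT, cf constant.

Summaries (mean, median, p95 and arbitrary percentiles) come from the
stored draws with numpy's linear interpolation between order statistics, so
results are bit-reproducible given a seed. Sensitivity is the Spearman rank
correlation between each non-constant input's draws and the risk draws;
constants are excluded. An analytic cross-check used in the tests: with
constant TEQ and lognormal BW, E[ILCR] = K·E[BW^(−2/3)] with
E[BW^a] = exp(aμ + a²σ²/2).

## Genotoxicity statistics

Comet tail moments are log10-transformed before any test. Group
comparisons use the pooled-variance two-sample t-test (Welch optional) for
two levels and one-way ANOVA otherwise; per-level mean ± SD are reported on
the log10 scale. No multiple-testing correction is applied across strata by
default. Screening fits one univariate OLS per candidate (categoricals
coded by level index, binary flags 0/1) and flags p < 0.05.

Stepwise multiple regression uses forward entry (smallest p below
`p_enter` = 0.05) with backward removal (p above `p_remove` = 0.10), the
usual SPSS-style convention, plus a tolerance guard barring entry when
1 − R² of the candidate against the selected set falls below 10⁻⁴.
Reported per predictor: B with Wald 95% CI, standardised β = B·SD(x)/SD(y),
p-value, and VIF from the auxiliary regression among retained predictors;
model-level: adjusted R², F(df1, df2), n. An empty selection returns a
flagged intercept-only model rather than an error.

## Synthetic-data generator

The generator's primitive is a species *mixing-weight* vector per school,
so diagnostic-ratio signatures can be set independently of totals. Two
presets: `diesel` (FLR/(FLR+PYR) = 0.60, HMW share 0.85) and `gasoline`
(0.33; 3-ring dominated), both pyrogenic by the other three ratios. Sample
totals are lognormal moment-matched to the configured site mean/SD (4
samples per site and location by default, mirroring the 64-sample design);
species concentrations are total × weight, so every generated profile
satisfies its signature exactly.

Children (113 HT + 115 LT by default) are assigned round-robin to their
group's four schools and inherit the school's *realised* mean indoor and
outdoor total PAH as exposure — no personal monitoring is emulated, so the
cohort carries only eight distinct exposure values and indoor/outdoor
exposures are strongly collinear, exactly as school-level assignment
implies. Body weight is lognormal per group. The outcome model is

    log10(tail moment) = intercept + slope · indoor_tPAH (+ covariate effects) + ε

with defaults intercept 2.734, slope 0.063, covariate effects 0, and
ε ~ N(0, σ) where σ is calibrated from the variance decomposition: the
target adjusted R² (default 0.044) is inverted to the population
R² = 1 − (1 − adjR²)(n−1)/(n−2), then
σ² = slope²·Var(x)·(1 − R²)/R² using the realised variance of the assigned
exposures. A direct `residual_sd` override (e.g. 0 for noiseless recovery
tests) bypasses the calibration.

The canonical scenario encodes the published site means/SDs. Two outdoor
means are not published: L2's is back-derived from its reported I/O ratio
of 0.99 and L1's from a mid-range 0.92, with indoor SDs reused as proxies.
The gasoline preset goes to H3 and L3 (reported as the non-diesel schools).
Covariate prevalences are round-number assumptions (e.g. 40% ETS-exposed,
30% living < 500 m from a highway) — they are not published and do not
enter the outcome model by default.

What the generator does *not* emulate: GC-MS measurement error, blanks and
recovery, within-school exposure heterogeneity, correlated covariates, or
non-Gaussian residuals. Passing tests therefore show the statistical
machinery recovers its generating parameters under the study's design and
effect sizes — not that the published estimates are correct for real
children.

## Problem sizes and numerical choices

Monte-Carlo runs use 10,000 iterations (seconds); replicated
parameter-recovery checks use 200 cohorts of n = 228; the group-contrast
power check uses 1,000 seeded cohorts. All randomness flows through
seeded `numpy.random.default_rng`; identical seeds give byte-identical
CSVs and reports. Truncation uses rejection resampling with an iteration
cap; percentiles use linear interpolation; OLS is delegated to statsmodels
with Wald CIs.

## Known limitations

- Exposure is assigned at school level; the regression's effective exposure
  support is eight values, so replicate-to-replicate selection between the
  collinear indoor/outdoor proxies is genuinely stochastic and the
  single-predictor detection power at the calibrated adjusted R² is ~0.9,
  an intrinsic ceiling for stepwise retention rates.
- The published per-school risk values, SPSS child-level ILCR means,
  95th percentiles and sensitivity magnitudes depend on undeposited
  per-sample and per-child data (and on the unreported logistic scale);
  they are covered by sign, bound and property checks rather than value
  reproduction.
- The logistic TEQ distribution can only be truncated, not re-centred; the
  documented upward mean shift is the price of keeping the published
  location parameter.
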