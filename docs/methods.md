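# Methods

## Problem setting

A pathology group wants to know how consistently its members grade
invasive breast cancer without mounting a conventional agreement study,
in which every rater re-reads the same case set.  For ten pathologists
and ~1,600 resections that would mean ~16,000 re-interpretations.  The
toolkit instead works from *observational* sign-out data: each case was
read once, by one pathologist, and the only comparable quantity across
pathologists is each one's **interpretive rate** — the fraction of their
own cases assigned tubular score 1, nuclear score 2, grade 3, and so on.

Two complementary analyses are built on those rates:

1. **Statistical process control** — are any raters statistical outliers
   relative to the group, given their case volumes?
2. **In silico kappa (ISK)** — how much agreement is *compatible* with
   the observed rate differences, expressed on the familiar kappa scale?

## Data model and eligibility

Input is case-level CSV: one row per resection with a rater id and
ordinal scores TS, NS, MS ∈ {1,2,3} and the Nottingham grade G ∈ {1,2,3}
(sum of components, 3–5 → 1, 6–7 → 2, 8–9 → 3).  Any score may be
absent (e.g. pT0 or pTis resections carry no grade).  Malformed or
out-of-range score cells are treated as absent and counted in a
validation report — never coerced.  A reported grade that disagrees with
its components is kept (the analysis concerns what was reported) and
counted in the report.

Raters are eligible when their total case volume strictly exceeds
`min_cases` (default 35).  Eligibility is measured on total volume; the
per-axis denominator of an eligible rater can be smaller, because only
cases scored on that axis enter it.  Rates are always per-rater,
per-axis: PIR_k = count_k / (count_1 + count_2 + count_3).

## Funnel plots, normalization, outliers

The group centre is the **GMIR**, the median of the eligible raters'
PIRs for one score level (even group size: midpoint of the central order
statistics).  Under the null that a rater's true rate is the GMIR, their
observed rate has binomial standard deviation

    sd_i = sqrt(GMIR·(1−GMIR)/n_i),

and the two-sided level-α funnel limits are GMIR ± z(1−α/2)·sd_i,
truncated to [0, 1].  The normal approximation is the default (it is
what the symmetric-CI construction and the SD-based normalization below
presuppose); an exact-binomial breach test is available via
`classify_outliers(..., exact=True)` for small denominators, where the
two can disagree at extreme levels.

Because each rater has their own funnel width, raw rates of different
raters are not directly comparable on one chart.  The **normalized PIR**
re-expresses each rate at the cohort's maximum volume while preserving
its z-distance to the centre:

    norm = GMIR + (PIR − GMIR)·sqrt(n_i/n_max).

Consequences, all asserted in tests: the z-score (and hence every
outlier classification) is unchanged; deviations of low-volume raters
shrink toward the GMIR, so the normalized range is contained in the raw
range whenever volumes are unequal; and a zero rate maps to
GMIR·(1 − sqrt(n_i/n_max)) > 0 — a zero at low volume is weaker
evidence of a truly low rate than a zero at high volume.

Outliers are classified at the nested two-sided levels
{0.05, 0.001, 1e-6, 1e-12}; each rater gets the most extreme level
breached, and reported counts are cumulative (a p<0.001 breach also
counts at p<0.05).  A score level whose GMIR is 0 or 1 has no binomial
variability at the centre and its funnel analysis is skipped with a
warning rather than fabricating limits.

Control charts plot normalized rates against randomly ordered raters
(seeded; the shuffle also de-emphasises identity), with a centre line at
the GMIR and straight control lines computed with sd at n_max — valid
for every point precisely because normalization preserves z.

## In silico kappa

Both variants are *best-case* constructions: raters with identical rate
vectors are credited with perfect agreement, so an ISK upper-bounds the
conventional kappa the same raters could achieve on the same cases.

**MCOA** (maximal categorical overlap assumption) treats one score level
as binary (level k vs rest).  For two raters with binary rates p_a, p_b
the observed agreement is the maximum compatible with those margins,
p_o = min(p_a,p_b) + min(1−p_a,1−p_b), chance agreement is the Cohen
product p_e = p_a·p_b + (1−p_a)(1−p_b), and κ = (p_o−p_e)/(1−p_e).
This is the two-category kappa-maximum of Sim & Wright; tests verify it
exhaustively against a brute-force maximizer over all 2×2 integer tables
with n ≤ 12.  It is non-negative for every margin pair (the maximizing
table never does worse than chance).

**OMECA** (ordered mutually exclusive category assumption) treats the
full 3-level axis.  Both raters are assumed to order cases identically
on a latent severity scale and to differ only in threshold placement, so
only adjacent categories compete.  Rater r's category k occupies
[C_r(k−1), C_r(k)] of the unit interval (C = cumulative rates); observed
agreement is the total overlap of matching intervals and chance
agreement is Σ_k p_a(k)·p_b(k).  Tests verify the closed form against a
Monte-Carlo oracle that simulates the latent model directly (10⁶ uniform
cases categorized by both threshold sets), to within 3·10⁻³.  OMECA
overlap is bounded by Σ_k min(p_a(k), p_b(k)), so the OMECA kappa never
exceeds the multi-category kappa-maximum.

Conventions: when p_e = 1 (both raters put all mass on the same single
category) agreement is forced, not informative; κ is defined as 1 and
the pair is flagged.  MCOA is reported per score level and OMECA per
axis, which is how the two assumptions pair naturally with binary and
ordinal targets.

**Group statistic.** The group ISK is the unweighted arithmetic mean of
the pairwise kappa over all unordered rater pairs (45 pairs for 10
raters), matching the mean-pairwise-kappa convention of multi-centre
agreement studies; a volume-weighted mean (pair weight n_i + n_j) is
exposed behind `weighting="volume"`.

**Uncertainty.** CIs are parametric bootstrap: each replicate redraws
every rater's counts from a multinomial at the rater's observed rates
and observed denominator and recomputes the group statistic; the 95% CI
is the 2.5/97.5 percentile interval over B = 2000 seeded replicates
(resampling cases within raters is the minimal scheme consistent with
rates-only data).  The reported point estimate is always the statistic
on the observed data; the interval is clamped to cover it in the rare
pathological-skew case.

## Synthetic cohorts

The generator draws, per rater, TS/NS/MS independently per case from
rater-specific multinomials and derives the grade from the component
sum, so component/grade consistency holds by construction (a
`grade_discordance_fraction` can deliberately corrupt reported grades to
exercise validation).  A `missing_grade_fraction` (default 0.059, the
share of ungradeable resections in routine practice) blanks all scores
of the affected cases.  Randomness is hierarchical — a cohort seed
spawns per-rater streams (separate streams for rate jitter and case
draws) — so adding a rater never perturbs existing raters' draws.

The default preset models a ten-pathologist practice with volumes drawn
uniformly in [38, 441] and component rates centred on the group medians
of routine breast grading (TS ≈ 9/23/66%, NS ≈ 5/57/37%,
MS ≈ 57/21/20%, each normalised to sum to 1).  Between-rater
heterogeneity is multiplicative lognormal jitter on each rate vector,
renormalised.  The default jitter 0.30 was calibrated once so the
preset's normalized grade-rate ranges match the widths seen in routine
practice (≈ 9–14 percentage points), which places the grade-level OMECA
ISK near 0.75.

What the generator does *not* emulate: within-case correlation between
the three component scores (they are drawn independently, so the
derived-grade distribution concentrates more on grade 2 than real
cohorts, where component scores co-vary), case-mix differences between
raters, drift over time, and any case-difficulty structure.  Passing
tests therefore demonstrate the statistical machinery under a clean
multinomial world, not that real sign-out data meet these assumptions.

## Numerical and design choices

- Normal quantiles and binomial tails from scipy; medians via
  `np.median`; percent display rounding is half-up (printed-table
  convention), full precision retained internally.
- PIR vectors must sum to 1 within 1e-8 for OMECA; degenerate profiles
  (n_axis = 0) are excluded with a warning wherever ≥2 usable raters
  remain, and are an error otherwise.
- Known finite-volume bias: with identical true rates, sampling noise
  alone holds the group OMECA ISK near 0.92 at volume 400 per rater
  (≈ 0.95 at 1,000; ≈ 0.99 at 40,000), because the statistic is a
  function of *empirical* rates.  The ISK should be read jointly with
  volumes; the convergence to 1 and the monotone decrease with true
  between-rater heterogeneity are both covered by tests.
- False-positive calibration: under identical true rates, ~5.4% of
  rater/level cells breach the p<0.05 funnel and ~0.2% the p<0.001
  funnel (500 simulated cohorts) — close to nominal despite the normal
  approximation and the estimated (median) centre line.
- Simulation sizes in the test suite (cohort counts, bootstrap
  replicates, Monte-Carlo draws) are chosen to make sampling error small
  relative to the asserted tolerances while keeping the suite quick to
  run as a routine check.

## Limitations

ISK is a best-case bound, not an estimate of head-to-head agreement;
rate differences can also reflect genuine case-mix differences, which
this cross-sectional analysis cannot separate from interpretive style.
The funnel analysis assumes independent binomial counts at a common null
rate; the GMIR is itself estimated from the same ten raters.  No
time-ordered charting or risk adjustment is implemented.
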