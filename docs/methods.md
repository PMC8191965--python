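# Methods

## The measurement model

`wellcount` measures multi-dimensional wellbeing with the Alkire–Foster
(AF) dual-cutoff counting methodology. Each respondent answers a battery of
survey items grouped into D = 6 domains; item answers are recoded to binary
achievement indicators x_ij ∈ {0, 1}. Identification uses two cutoffs:

1. **Within-domain cutoff.** A domain with m items is "sufficient" for a
   respondent iff their raw score s_d = Σ_j x_ij reaches
   t(m) = ⌈2m/3⌉ — the smallest integer at least two thirds of m. This
   reproduces both anchor cases of the study configuration: t(9) = 6 and
   t(6) = 4. The alternative "strictly more than 2/3" convention was
   rejected because it contradicts the 9-item case (it would demand 7).
2. **Cross-domain cutoff.** The composite Wellbeing Index W = Σ_d z_d sums
   the domain sufficiency indicators z_d; a respondent has maintained
   overall wellbeing iff W ≥ k, with k = ⌈2D/3⌉ = 4 of 6 by default.

Aggregation over a population of n respondents with q overall-deprived:

- headcount ratio H = q/n;
- intensity A_raw = mean deprivation count c = D − W among the deprived
  (domain units), and A = A_raw/D (share scale). Both are reported because
  the study prints the domain-unit form (3.6 of 6) while the AF literature
  works on the share scale;
- adjusted headcount M₀ = H·A (share scale), so M₀ ≤ H always;
- censored per-domain deprivation: the share deprived in each domain among
  the overall-deprived (the "drivers" table); the uncensored variant
  divides by everyone.

With k = 4 and D = 6, every deprived respondent misses at least 3 domains,
so A_raw ∈ [3, 6] by construction.

The API generalises to positive per-domain weights (normalised to sum to
D, so the counting cutoff keeps domain units) and an arbitrary k; the equal
weights / k = 4-of-6 configuration is the frozen "SA2020" preset and the
weighted form reduces to it exactly when weights are equal.

### Monotonicity

Flipping any indicator 0→1 never decreases s_d, z_d, W or the maintained
flag, and never increases c, H or M₀. Intensity A_raw is deliberately
*excluded* from this list: raising one indicator can move a barely-deprived
respondent (c = 3) out of the censored pool, which can raise the mean
deprivation count among those remaining. This is a known property of the
censored mean in AF measures, not an implementation artefact; M₀ remains
monotone because the removed respondent's whole contribution leaves the
numerator.

## Recoding conventions

- **Missing answers** default to `as_zero` (non-achievement). The study's
  counting arithmetic classifies every one of the 579 respondents, which is
  only possible if item nonresponse is scored as non-achievement. An
  `as_missing` policy is available per item for sensitivity analysis; the
  counting core refuses NaNs, so that policy is for inspection upstream.
- **Hopefulness** is a 1–8 ordinal (1 = not positive/hopeful, 8 = very).
  "Highly positive" is ≥ 7 by default — the published tables never state
  which scale points count as highly positive, and ≥ 7 (top quarter of the
  scale) is the natural reading; the cutoff is a parameter everywhere it is
  used.
- **Weekly income** splits at $600/week with the boundary inclusive in the
  LOW group ("$600 or less"). Respondents reporting "no income" map to LOW
  but carry a distinct flag, because that group is dominated by pension-age
  respondents with secure income and behaves unlike low earners.
- **Gender** keeps "Other/undisclosed" as its own category; male–female
  gap statistics exclude it, since no conclusions can be drawn for a group
  mixing deliberate and inadvertent non-disclosure.
- **Gap statistics** report the point differential a − b and the percent
  difference 100·(a − b)/a with the *first-listed group's rate (female)* as
  the denominator. "Percent difference" is ambiguous in general; this
  denominator is the one consistent with the published arithmetic
  (12/98 = 12.2%, 11/72 = 15.3%) and is undefined (reported as None, never
  an exception) when the denominator rate is 0.
- **Rounding** of reported percentages and intensities is decimal half-up
  at 1 decimal place (0 d.p. where the published tables print integers),
  applied only at the reporting boundary; all internal arithmetic is on raw
  counts and proportions, and printed percentages in report files always
  equal the underlying counts re-divided and re-rounded.

Two small arithmetic discrepancies in the published tables are documented
rather than matched: the overall maintained share prints as 71.2% where
412/579 = 71.16% (we treat 412/579 as the reference computation), and the
regional/metro rates print as 65.5%/70.2% where 53/81 and 310/442 give
65.4%/70.1%. The package reports the recomputed values.

## The logistic maintenance model

`fit_maintenance_model` fits maintained ∈ {0,1} by maximum likelihood on a
design with declared reference categories: income group (reference LOW),
pre-pandemic hopefulness as the 1–8 ordinal treated as numeric, age as the
ordered band index (bands 18–24, 25–34, 35–49, 50–64, 65+; reference the
youngest), and gender as a three-level categorical with Male reference
(entering with 2 df, reported through an aggregate Wald chi-square row).
The hopefulness coding (ordinal-as-numeric vs binary) is not fixed by the
published table; ordinal-as-numeric is the default because the term is
printed with a single degree of freedom, and a binary coding is available
by recoding upstream.

Reported per-term quantities: B, SE, Wald = (B/SE)² for 1-df terms,
p from χ², Exp(B), and 95% CI = exp(B ± 1.96·SE). Model-level quantities:
Nagelkerke pseudo-R² = [1 − exp(2(ll₀ − ll₁)/n)] / [1 − exp(2·ll₀/n)]
(None when the null likelihood is already 1) and classification accuracy at
probability cutoff 0.5 (ties at the cutoff predict the positive class).
Perfect separation is raised as an explicit diagnostic — either caught from
the optimiser's separation warning or inferred from a singular information
matrix / diverging coefficients (|B| > 30) — never returned as a silent
non-convergence.

The published regression coefficients are *not* reproduction targets: the
microdata are unavailable, so the model is validated by formula-level
oracles (a hand-written log-likelihood maximised independently agrees to
4 significant figures on small instances) and by parameter recovery against
the synthetic generator's known coefficients (estimation error shrinking
from n = 500 to n = 5000; ~95% CI coverage of a zero-effect term over 200
replicates).

## The synthetic survey generator

The generator emulates the study conditions, not any particular
respondent-level data: n = 579; gender marginals 74.8/17.6/7.6%
(female/male/other-undisclosed); region 76/14/10% (Greater Adelaide /
regional / not stated); age bands 10/17/27/26/20% across
18–24…65+ (the sample's band shares are not published; this is a fixed,
plausibly older-skewed online-survey composition); weekly income lognormal
with median $600 (so the $600 regrouping splits the sample almost evenly)
plus an 8% "no income" group; hopefulness-before on 1–8 with ~48% at 7–8,
and hopefulness-during = before − drop with a drop distribution producing
roughly a 30-point fall in the highly-positive share.

Each item indicator is Bernoulli with
logit p = b_d + β·x_i + u_i, where x_i are the respondent's covariates
(income HIGH +0.30, age +0.10 per band from the middle, hopefulness +0.10
per point from the midpoint, gender Male −0.15 / Other +0.25 — modest
effects in the direction of the published associations) and
u_i ~ N(0, 0.8²) is a single shared respondent latent. The latent is what
makes deprivations cluster in the same people — the feature the intensity
statistic measures; a full inter-domain copula was rejected as needless for
that purpose and much harder to calibrate.

**Calibration.** The domain intercepts b_d are solved deterministically so
that each domain's post-threshold sufficiency share equals the published
all-respondents column (44.0, 65.0, 83.5, 87.6, 82.0, 64.8%): the covariate
linear predictor has enumerable support (3 gender × 5 age × 2 income × 8
hopefulness levels), so E[P(Binom(m, expit(b + η + σu)) ≥ t)] is evaluated
exactly over that support with 25-node Gauss–Hermite quadrature over u, and
b_d is found by Brent root-finding. No stochastic search; the calibration
is bit-reproducible. At n = 5000 the simulated domain shares land within
Monte-Carlo noise of the targets, and the simulated overall maintained
share comes out near the published 71% without being targeted directly.

Only the counting structure of the instrument is reconstructed: per-domain
item counts are 8/8/8/8/7/9 (only the Ecology count, 9, is published; the
rest are a documented synthetic reconstruction totalling 48 wellbeing items
within the 56-question instrument), and item wordings/answer vocabularies
are synthetic (alternating yes/no and 1–5 agreement items). Consequently,
passing tests demonstrate the correctness of the measurement pipeline and
the internal consistency of the published counting arithmetic — not
cell-level reproduction of tables that require the unreleased microdata.
The generator also does not simulate free-text answers, structured item
nonresponse (a single uniform missingness rate is available), or panel
structure.

**Fixture.** `sa2020_fixture()` is not a random draw: it is the unique
deterministic output of a Gale–Ryser-style construction realising the
published margins — 167 deprived respondents with deprivation counts
{6: 4, 5: 16, 4: 61, 3: 86} and censored per-domain counts
(159, 139, 112, 77, 74, 45) chosen to reproduce the published drivers
ranking, plus 412 maintained respondents with a fixed documented
c = 0/1/2 split of 131/161/120 (that split is unpublished; no test depends
on it). Rows are processed in descending deprivation count and each row's
deprivations are placed in the domains with the largest remaining demand,
which realises any feasible margin pair deterministically.

## Margin of error

The representativeness calculator uses the normal approximation at maximum
variance: MOE = z_{(1+conf)/2}·√(0.25/n), with the finite-population
correction √((N−n)/(N−1)) when a population size is supplied. This
convention reproduces the study's printed claims for the metro (n = 442:
4.66% ≤ 5% at 95%) and regional (n = 81: 9.14% ≈ 9% at 90%) samples; for
the full sample (n = 579) it gives 5.35% at 99% confidence, slightly above
the claimed 5%, and the calculator reports the computed value rather than
forcing agreement. Exact binomial intervals are out of scope.

## Problem sizes and numerics

The test suite exercises the counting core against brute-force enumeration
on random instances up to 12 respondents × 4 domains × cutoffs 1..D;
calibration checks use n = 5,000–20,000 draws; parameter recovery uses 40
replicates each at n = 500 and 5,000 plus 200 replicates at n = 400 for CI
coverage. These sizes put Monte-Carlo noise well below the asserted
tolerances while keeping the whole suite in the tens of seconds. Brent
root-finding runs to xtol = 1e-10 on [−10, 10]; all randomness flows
through `numpy.random.default_rng` seeded explicitly, and equal-weight
classification uses exact integer arithmetic (ties at the cutoff count as
maintained, i.e. the ≥ in W ≥ k is inclusive, matching the "at least four
domains" rule).

## Known limitations

- Published regression-table and gender-breakdown cell values cannot be
  reproduced without the unreleased microdata; they are used only where
  they are arithmetic functions of printed counts.
- The weighted generalisation covers M₀ only; inequality-sensitive AF
  variants (M₁/M₂) need continuous deprivation depths that a binary
  instrument does not provide.
- No survey weighting or post-stratification: the study reports raw sample
  percentages, and so does the package.
- Suburb/council-level analysis is intentionally unsupported (samples too
  small to be representative).
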