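# Methods

## Measurement model

All analysis rests on the partial credit model (PCM), the Rasch-family model
for ordered polytomous items: the log-odds of scoring `k` rather than `k−1`
on item *i* is `θ − δ_ik`, so every item has unit slope and only its category
thresholds δ are free. Thresholds live on the same metric as the person
trait θ (here: involvement in physical health care planning).

**Calibration.** Bock–Aitkin EM marginal maximum likelihood over a fixed
rectangular quadrature (default 61 nodes on [−6, 6]; EM tolerance 1e-4 on the
largest parameter change, maximum 500 iterations). The latent location is
fixed at 0 for identification; the latent SD is *estimated* in the EM loop.
Because the PCM slope is pinned at 1, the latent scale is a genuine parameter
of the data, not a normalisation convention — pinning it at 1 when the
population SD is near 2 (as in this instrument's development sample) produces
spurious misfit in every downstream statistic. Missing responses simply
contribute nothing to the likelihood. Within an item, a never-observed
category is merged into its lower neighbour before estimation and the merge
is logged.

**Scoring.** Expected a posteriori (EAP): posterior mean with the posterior
SD as the SE, computed on the quadrature grid. With no responses the
posterior is the prior, so the estimate is (prior mean, prior SD) exactly.

**Information and reliability.** Item information is `Var(X_i | θ)` (equal to
the negative expected second derivative of the log-likelihood for the PCM);
the test SE curve is `1/√I(θ)`. Marginal reliability is
`(V − E[SE²(θ)])/V` with the expectation taken by quadrature over the chosen
population; the headline bank value uses a standard normal population with
SE² = 1/I(θ).

**Item fit.** Persons are stratified into deciles of their *rest* EAP — the
posterior excluding the item under test — and observed category counts are
compared with counts expected under each person's rest posterior (not a
plugged-in point estimate). This keeps the Pearson statistic near its nominal
chi-square behaviour; the naive plug-in version rejected up to 70% of truly
fitting dichotomous items in our null simulations. Adjacent strata are merged
until every expected cell reaches 5; df = (strata × (K−1)) − (K−1). The
scale-level statistic is a limited-information discrepancy over univariate
and bivariate category margins (the full contingency table is hopeless at
n ≈ 267), with RMSEA from the usual noncentrality transform. Degrees-of-
freedom conventions for these statistics vary across software, so published
fit values are matched only loosely.

## Screening and purification

Stages run in the order used to develop the instrument: non-parametric
screen → dimensionality gate → calibration → threshold rescoring → local
dependency → DIF → misfit, refitting the PCM after every set of removals.
Every action is a ledger entry carrying the triggering statistic.

* **Loevinger scalability**: H at pair, item and scale level, with `cov_max`
  from the comonotonic (sorted) arrangement of the two observed margins;
  pairwise-complete cases; items kept when item-H ≥ .30. Zero-variance items
  get an undefined H, reported as such.
* **Monotonicity**: rest-score groups of at least `max(50, n/10)` persons
  (tied rest scores never split); every ordered pair of groups is compared on
  every step proportion `P(X ≥ k)`. Decreases > .03 count as violations; an
  item is flagged when a violation is both statistically significant
  (one-sided two-proportion z at α = .05) and material (≥ .08). The
  materiality floor matters: without it, chance wobbles in the flat tails of
  well-behaved step curves flagged ~0.3 items per clean 19-item dataset,
  which would make a clean scale impossible to pass through the pipeline.
* **Parallel analysis**: eigenvalues of the polychoric correlation matrix
  (own two-step ML estimator: thresholds from the margins, correlation by
  bounded scalar ML, rectangle probabilities through an Owen's-T bivariate
  normal CDF; Pearson fallback for degenerate tables) against rank-wise 95th
  percentiles of 20 column-permuted reference datasets, which preserve the
  marginals and the missingness pattern. (The mean rule is available, but
  retains spurious components on structure-free data about half the time,
  which would wrongly halt the pipeline.) Retention stops at the first rank
  where the observed eigenvalue fails to exceed its reference; more than one
  retained component halts the pipeline.
* **Threshold disorder**: an item is disordered when some category is never
  the modal response along θ — for the PCM this is exactly non-ascending
  thresholds, and both diagnostics are computed and cross-checked. The remedy
  is a single uniform rescoring map for all items (default 0-1-1-2-2, which
  only ever merges adjacent categories); the final bank carries the map so
  raw data can be scored against it.
* **Local dependency**: Yen's Q3 — correlations of the per-person response
  residuals `x − E[X|θ̂]` — with the adaptive threshold `.2 + mean(Q3)`.
  Missing cells are first completed by modal IRT imputation (pairwise-
  complete mode available). Items dependent on ≥ 2 partners are removed
  first, highest partner count first (ties to the less informative item),
  with partner counts recomputed after each removal; each surviving isolated
  pair then loses the member with less prior-integrated information.
* **DIF**: per item, nested cumulative-logit models `item ~ θ̂`, `+ group`,
  `+ θ̂ × group` (statsmodels' proportional-odds fits); total-DIF LR test (2
  df) Bonferroni-corrected across items; magnitude as McFadden
  `ΔR² = R²(M2) − R²(M0)` against the thresholds-only null. Flagging requires
  *both* corrected significance and ΔR² > .035. θ̂ is re-estimated from
  unflagged items between rounds until the flagged set stabilises.
  Non-converged fits (e.g. separation from an empty group × category cell)
  are reported as unstable, never flagged.
* **Misfit**: items with Bonferroni-significant fit chi-squares are removed
  one at a time, worst first, refitting in between.

## Test–retest and CAT

Agreement between occasions uses Pearson r on paired EAP scores (both
occasions scored with the same final bank, calibration frozen at baseline)
and Bland–Altman limits `mean ± 1.96 SD` of the baseline-minus-follow-up
differences, with the percentage of pairs inside the limits.

CAT simulation is post hoc and fixed-length: simulee traits are drawn from a
Gaussian, one full response vector per simulee is generated from the PCM, and
tests of each length replay those responses with maximum posterior weighted
information (MPWI) selection — the next item maximises `∫ I_i(θ) π(θ) dθ`
against the current posterior, ties broken by bank order — and EAP updates on
an 81-node grid spanning the scoring prior ± 4 SD. The full-length CAT
estimate therefore equals the full-bank EAP exactly, and the reported
correlation at full length is 1 by construction. The whole study is
vectorised across simulees (a 1000-simulee, four-length study takes seconds).

### Conventions behind the published-table reproduction

Two conventions materially affect the CAT summary numbers, and the sources
leave both open:

1. **"N(−0.08, 1.90)"** is read as mean and *SD* (the R `rnorm` convention of
   the simulation script the study used). A variance reading is available
   via `theta_sd=sqrt(1.90)`.
2. **The EAP scoring prior** defaults to the standard normal of the
   calibration metric (the simulation script's default), not to the simulee
   distribution. The matched prior is available via `prior="matched"`.

Measured sensitivity (mean final SE at 19/15/10/5 items, 1000+ simulees,
published row .36/.41/.43/.66):

| convention                        | 19   | 15   | 10   | 5    |
|-----------------------------------|------|------|------|------|
| SD reading, standard prior (ours) | .39  | .41  | .47  | .58  |
| SD reading, matched prior         | .45  | .49  | .57  | .75  |
| variance reading, standard prior  | .37  | .40  | .46  | .58  |
| variance reading, matched prior   | .39  | .43  | .50  | .65  |

No convention reproduces the published 5-item row (SE .66 with correlation
.87) together with the other three rows; under the default convention the
5-item test comes out *more* precise (SE ≈ .58, r ≈ .95) than published,
while every longer-length number lands within a few hundredths. We report
the defaults above and flag the 5-item row as not reproducible from the
printed parameters alone.

## Synthetic data

The generator emulates the development study: 67 five-category items with
sorted uniform[−2.5, 2.5] thresholds, n = 267, θ ~ N(−0.08, SD 1.90), 16%
missingness (completely at random — no mechanism is documented, so MAR/MNAR
structure is deliberately out of scope), a 67-person retest with latent
correlation .75 (which attenuates to an observed score correlation of ≈ .68
across replicates, matching the study's .70), and a service-user/carer/both/
unreported mix of 66/15/12/7%.

Injectable pathologies, with magnitudes calibrated by Monte-Carlo so each is
detectable by its pipeline stage at the stated sample size:

* *disordered thresholds* — generating thresholds reversed;
* *low scalability* — generalized-PCM slope (0.10 puts item-H near .20 at
  n = 267, against ≈ .7 for healthy items at this trait spread);
* *non-monotone* — a mid-range θ band responds at one depressed effective
  trait level, placed so a step probability sits `magnitude` below its level
  just under the band (a dip of .15 is detected in 50/50 replicates at
  n = 1000 with a 20-item rest score);
* *reversed* — the item runs against the trait, a gross violation detectable
  even at n = 267 (used in the study emulation);
* *local dependency* — one item becomes a probabilistic copy of its partner
  (strength .7 is detected by Q3 in ≥ 45/50 replicates at n = 2000);
* *uniform DIF* — a per-group threshold shift. A 1.5-logit shift yields
  McFadden ΔR² ≈ .06 — the effect size the study reported for its flagged
  item — and is detected in ≥ 45/50 replicates at 500 per group. Shifts near
  0.8 logits produce ΔR² ≈ .02 and are intentionally *not* flaggable under
  the .035 magnitude rule.

What passing on these data does *not* show: robustness to informative
missingness, response styles (acquiescence, extreme responding), multi-
dimensional traits, or person misfit — none of which the generator emulates.

## Numerical choices and edge cases

Quadrature grids are rectangular with normal weights; EAP agreement between
61- and 121-node grids is < 1e-3 in θ. PCM probabilities are max-subtracted
before exponentiation, so extreme θ and thresholds are safe. Degenerate
situations have defined, reported outcomes rather than silent repair:
zero-variance items (undefined H), non-PSD polychoric matrices (eigenvalue
clipping, warned), untestable monotonicity (too few complete cases), DIF
non-convergence (unstable, unflagged), empty response vectors (prior
returned, flagged in imputation), degenerate Bland–Altman limits (all pairs
within). Ties: MPWI selection and LD removal order break ties by bank order
and item id respectively, so runs are deterministic; all simulation entry
points take explicit seeds and reruns are byte-identical.

## Problem sizes used in the shipped checks

The test suite runs the pipeline at the study's own scale (67 × 267) once,
power studies at 50 replicates of their stated designs (n = 1000–2000), and
the CAT reproduction at 1000 simulees; these sizes were chosen as the
smallest at which the Monte-Carlo margins above are stable.

## Known limitations

* Rasch-family only: no discrimination parameters (2PL/GPCM generalisations
  are out of scope by design) and no multidimensional models.
* The limited-information scale fit statistic follows our df conventions;
  cross-software comparison of its absolute value is not meaningful.
* DIF handles exactly two groups per contrast; age or other covariates must
  be dichotomised by the caller.
* The published 5-item CAT row is not reproducible from the printed bank
  under any prior/spread convention we tried (see the sensitivity table).
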