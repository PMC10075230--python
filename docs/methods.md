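# Methods

This note documents the statistical procedures implemented in `rsgkit`,
the choices made where several conventions were defensible, and what the
synthetic-data generator does and does not emulate.

## Data model and failed trials

The unit of scoring is a block: nominally 200 binary choices (H/T) with
per-trial success flags. Participants occasionally fail to respond in
time; such trials are flagged unsuccessful. All sequence statistics
operate on the *effective* sequence — the successful trials concatenated
in order. Blocks may therefore be slightly shorter than 200 trials; they
are analysed as-is rather than padded or truncated to a fixed length.
At the observed failure rates (~0.7% of trials) the effect on any score
is negligible; the accounting invariant
`len(effective) + n_failed == len(raw)` holds per block and is property-
tested.

## Markov scoring

**Transition estimation.** For order k, counts c(s, c) are accumulated
over the n − k subsequences of length k + 1 and normalised per context.
Contexts that never occur are absent from the model (zero weight). A
`TransitionModel` can also be specified exactly from probabilities and
context weights, which is how the analytic endpoints (fair coin → 1 bit,
deterministic → 0 bits) are evaluated.

**Likelihood and BIC.** The self-fit log-likelihood is Σ c·ln p̂ with
0·ln 0 := 0. The order selector minimises

    BIC(k) = −2·log L(k) + 2^k · ln(N_k),   N_k = n − k,

over k = 0…k_max (default 5), breaking ties toward the smaller order
(parsimony). Choices fixed here, since BIC for Markov chains admits
variants: the parameter count is 2^k (one free probability per context
for a binary alphabet) and the sample-size argument is the number of
predicted positions N_k = n − k, i.e. each order is scored on its own
prediction set. A common-prediction-set variant (all orders predict
positions k_max…n−1) exists behind a flag; on a common set the self-fit
likelihood is non-decreasing in k (nested models), which the property
suite verifies against a brute-force refit oracle. With per-order sets
that monotonicity need not hold exactly, which is why the flag exists.
Consistency of the selector (recovery of the true order → 1 as n grows)
is exercised in the acceptance suite at length 10,000 for true orders
0–3 with conditional probabilities 0.25 away from uniform.

**Conditional entropy rate.** At fixed order k (default 3),

    Ĥ = Σ_c w(c) · H₂(p̂(·|c)),   w(c) = count(c) / Σ count,

in bits. The order is fixed rather than BIC-optimal so the estimator's
plug-in bias — estimated distributions look less entropic when data are
split over many contexts — is comparable across participants and
conditions. Using k above the true order leaves the estimand unchanged
(conditioning on additional irrelevant history loses no entropy); the
test suite checks that k = 3 and k = 1 estimates agree within 0.01 bits
at length 10⁵ for order-1 data. At 200 trials and k = 3 (8 contexts,
~25 transitions each) the plug-in bias is downward, roughly 0.03 bits
for a fair iid sequence; tests assert the resulting range rather than
the unbiased value.

**Participant scores.** Both outcomes are computed per block and averaged
over the five blocks. Blocks too short to score at the fixed order
contribute a missing value and a warning; the participant mean is over
the available blocks.

## Descriptive statistics

The proportion value max(n_H, n_T)/n is computed per block (0.5 =
balanced, 1 = constant responding); it is invariant to the H↔T
relabelling, which matters because coin-to-key assignment is
counterbalanced across participants. Run lengths are maximal streaks of
identical choices; the final run of each block is omitted from averages
because it is right-censored by the end of the block. A block whose
omit-last rule leaves no runs (constant responding) yields a missing
mean run length rather than 0, so participant averages are not biased
by degenerate blocks. The pseudorandom baseline generates iid fair
sequences (any high-quality seeded PRNG; distributional summaries are
all that is compared), splits them into 5 blocks of 200, applies exactly
the human pipeline's per-block rules, and averages within then across
sequences. For fair sequences the expected omit-last mean run length is
2.0 and the expected per-block proportion ≈ 0.528 (mean absolute excess
of a Binomial(200, ½)), so the reference summary rounds to 2.00 / 0.53.

## Exclusion screen

Nine criteria: instruction reading time < 60 s; more than 2 quiz
questions wrong on the first try; any wrong on the second try; failed
post-task probe; more than 15 *consecutive* failed trials in any block;
more than 50 failed trials overall; more than 3 browser interactions in
any block; any constant-button block (single distinct symbol in the
effective sequence); and, in the perceptual-guessing condition only,
detection of the manipulation. Inequalities are strict exactly as
worded — 15 consecutive failures is acceptable, 16 is not. A
participant failing several criteria is listed under each; per-criterion
counts can be tallied in "all-failures" mode (default; categories may
overlap) or "first-failure" mode (disjoint, attribution in screening
order), recorded in the report, since sequential-versus-parallel
application changes the per-category bookkeeping but never the kept set.

## Between-condition inference

**Omnibus.** Tie-corrected Kruskal–Wallis H with a χ²(g−1) reference
distribution; a completely constant pooled sample returns H = 0, p = 1
by convention. The rank-based effect size is η²_H = (H − g + 1)/(N − g),
clipped below at 0; this formula is fixed because it exactly reproduces
both printed-precision effect sizes from their H statistics. Cohen's d
is obtained from the *unrounded* η² via f = √(η²/(1−η²)), d = 2f
(rounding η² first would change the second decimal of d). The η² CI is
a seeded percentile bootstrap (default 1,000 resamples, within-group
resampling), chosen as a serviceable default where no canonical method
exists.

**Post hoc.** Pairwise comparisons operate on group mean ranks of the
pooled sample, the natural follow-up to a rank-based omnibus test:
standard error √(S²(1/nᵢ + 1/nⱼ)) with S² = N(N+1)/12 reduced by the
usual tie factor, referred to the studentized-range distribution with
g groups and infinite error degrees of freedom (the large-sample rank
ANOVA convention). The Tukey–Kramer form of the SE handles unequal group
sizes. Simulation tests check that family-wise error at the null stays
within 2 points of nominal.

**Two-stage block analysis.** To separate condition effects from drift
across the session (fatigue), stage 1 fits each participant an OLS line
of outcome on block number centred at block 3, so the intercept is the
fitted mid-experiment level; stage 2 submits the intercepts to a one-way
ANOVA on condition. This implements the described procedure literally as
two stages; a simultaneous mixed model is out of scope.

**Power.** The a-priori sample-size calculator inverts noncentral-F
power, P(F′(g−1, N−g, λ = f²N) > F_crit) ≥ target, scanning balanced
sizes (multiples of g) upward. At f = 0.25, α = 0.05, power = 0.8,
g = 5 it returns N = 200 (power 0.810; N = 195 gives 0.798).

## Synthetic-study generator

`gen_study` produces a full dataset: per participant, 5 blocks × 200
choices, iid failed-trial flags at rate 0.007 (the observed ~0.7%
failure rate), quality metadata, and per-participant RNG substreams
spawned from the master seed (regeneration is byte-identical; one
participant's data is independent of how many precede them).

Condition presets are first-order repeat-probability processes — the
next choice repeats the previous one with probability r — with r drawn
per participant from a condition-specific Beta distribution: central
values ER 0.67, IR 0.35, MC 0.47, PG 0.737, and for FC a mixture of a
broad component (mean 0.70) with a small near-degenerate one
(mean 0.93) reproducing that condition's wide spread. The centres are
chosen so the generating chain's analytic entropy H₂(r) and mean run
length 1/(1−r) match the per-condition summaries reported for human
data (e.g. r = 0.737 gives 0.833 bits and runs of 3.80; r = 0.35 gives
0.934 bits and runs of 1.54). These presets are distributional
*emulations* of summary statistics, not fits: with Beta heterogeneity
(entropy is concave in r) and the k = 3 plug-in bias at 200 trials, the
synthetic medians shift relative to the analytic centres (e.g. PG
median ≈ 0.76 rather than 0.83 at n = 78). The qualitative ordering —
MC/IR most random, FC least, ER/PG intermediate — is what the presets
guarantee, and what passing tests demonstrate. Real data differ in ways
the generator does not model: within-participant strategy changes,
nonstationarity beyond linear drift, higher-order dependencies, and any
coupling between failures and the choice process.

Metadata violations are injected per criterion with configurable
fractions (defaults mirror the per-category rejection rates of a large
online study of this design, ~1–7%, with manipulation detection at 45%
in PG). Failed-trial violations are injected into the success flags
themselves (a 16–30-trial burst, or a diffusely elevated failure rate),
so metadata and sequences stay mutually consistent.

`parameter_recovery` closes the loop: for declared iid/Markov generators
it reports order-recovery fractions and entropy bias/RMSE against the
analytic entropy rate of the generating chain (computed from the
stationary distribution of the context chain).

## Numerical choices and problem sizes

Natural logarithms inside likelihood and BIC; base-2 logarithms for
entropy (bits). 0·log 0 := 0 throughout. Probability normalisation is
exact to 1e-12 and property-tested. Monte-Carlo checks in the test
suite use sizes chosen to keep the full suite under a minute while
leaving comfortable statistical margins: 100 replicates per order for
BIC consistency at length 10,000, 5,000 null studies for type-I
calibration, 400 for post-hoc family-wise error, exhaustive enumeration
of all binary sequences up to length 12 for likelihood verification.

## Known limitations

* Binary alphabets only; the estimators generalise but are not exposed
  for larger alphabets.
* The η² bootstrap CI is a pragmatic default, not a validated canonical
  method.
* The post-hoc convention (mean ranks, infinite-df studentized range) is
  one of several in use after a Kruskal–Wallis test; with raw-value
  Tukey–Kramer the adjusted p values would differ.
* The exclusion screen needs the quality metadata; datasets read without
  a metadata file are screened only on the behavioural criteria
  (constant-button blocks), since the remaining fields default to clean.
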