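# Methods

## Scoring conventions

**Eligibility and windows.** A female enters the focal male's paternity and
mating-order computations only if, at some point over the four observation
days, she has mated both the focal male and at least one rival. Her
*competition start day* is the earliest day by whose end both conditions
hold; offspring batches laid before that day cannot reflect sperm
competition and are excluded from paternity share. Laying day *d* refers to
the 20-h interval following day *d*'s observation session, so the window
condition is simply `lay_day >= start_day`.

**Paternity share pooling.** The default pools raw counts
(`Σ wt / Σ (wt + spa)`) across all eligible female-days, which is what a
summed-count formula computes; `per_female_mean` (mean of per-female
proportions) is provided because the two readings differ whenever females
contribute unequal offspring numbers. Share is undefined (NaN in the table)
when no window batch contains offspring — a data state, not an error.

**Order index.** For each eligible female and each day from her competition
start day to day 4, an indicator records whether the most recent mating in
her history (ordered by day, then by the within-day sequence number `seq`)
was with the focal male; the status persists automatically through days on
which she does not remate. The vial's index is the mean over all scored
female-days pooled with equal weight, not a mean of per-female means:
females scored on more days carry proportionally more information, and
pooling keeps the index an unweighted average of identically defined
Bernoulli observations. The alternative `from_first_mating` start (scoring
begins at the female's first mating rather than at competition start) is
exposed as an option; under it, days on which the focal male is the only
male so far score 1.

**Repetitive matings.** Default (`total`) counts every focal copulation
with eligible partners, so each eligible female contributes at least 1;
`rematings` subtracts that first copulation per female. Both are exposed
because either reading is consistent with "repeated mating with the same
females"; all shipped analyses use `total`.

**Standardization** is a z-score with the n−1 denominator, applied to the
order index and repetitive count (not to fecundity covariates) and always
*within* experiment, since the three experiments are analysed separately.

## Commonality analysis

The decomposition is implemented from first principles rather than through
a wrapper: subset R² values come from ordinary least squares with an
intercept, and the commonality components C(S) are the unique solution of
R²(W) = Σ_{S∩W≠∅} C(S), computed by the Möbius/inclusion–exclusion closed
form C(S) = Σ_{T⊆S} (−1)^{|S|−|T|} [R²(all) − R²(all∖T)]. After every
decomposition the defining linear system is re-verified to 1e-10 and a
violation raises, so the identity is asserted on every run rather than
assumed. Negative components (suppression) are reported verbatim with a
warning flag. The subset enumeration is guarded at 15 predictors.

**Buckets.** The three-way report (mating order / repetitive mating /
remaining) is assembled as: order = unique component of the order
predictor, repeat = unique component of the repeat predictor, remaining =
everything else (all common components plus covariate-unique variance).
This is the most conservative attribution — shared variance is never
credited to either focal predictor. An alternative `shared_split` rule
divides each common component equally among its members. The fecundity
covariate (eligible-mate mean by default, group mean as an option) enters
the model but never receives its own bucket. Per-treatment partitions
refit the model within each treatment cell, with a minimum of
predictors + 3 rows.

## Quasi-GLM inference

Order index is modelled as a continuous proportion with a quasi-binomial
GLM (logit link), repetitive matings with a quasi-Poisson GLM (log link);
the dispersion is the Pearson χ²/df of the full model. Term tests are
type-II F tests on scaled deviance: F = (ΔD/Δdf)/φ̂ with denominator df
equal to the full model's residual df, interactions tested against the full
model and main effects compared between models that both exclude
interactions containing them. Per-vial denominators (scored female-days)
vary, so the order-index fit is unweighted by default with a
`weight_by_days` option.

AIC-based backward selection cannot use the quasi-likelihood directly (it
has no AIC), so the criterion is evaluated on the paired ordinary binomial
or Poisson fit; a QAIC option (−2ℓ/ĉ + 2k, ĉ fixed from the full model)
is provided. Interactions are always dropped before the main effects they
contain, and a single-term model is returned unchanged — selection never
reduces to the intercept-only model.

The post-hoc procedure is all pairwise Welch-t contrasts with Holm
correction, triggered in the pipeline when any term's F-test p-value falls
below a configurable threshold (default 0.07).

**Assortative mating.** The layout differs by experiment because the
female-size factor lives at different levels. F experiment: one-way ANOVA
of the focal male's copulation count across homogeneous-female vials with
female size as the factor (each such vial has a single female size).
FM experiment: heterogeneous vials contribute one row per female size class
(focal copulations with large vs. small females), analysed as a two-way
ANOVA of count on female size × focal male size; the interaction is the
assortative signal. The M experiment has a single female size class and is
reported as degenerate by construction.

**Median split.** Within each (experiment, social) group, vials are split
at the group median of the order index; ties go to the "≤ median" side.
Each side reports the mean, SE (sd/√n) and n of paternity share; a group
with a constant index yields a one-sided row with a warning.

## The synthetic generator

Each vial-day provides `slots_per_session` courtship opportunities. A slot
draws a male with probability proportional to his size weight and a female
uniformly; she accepts with `virgin_receptivity` if unmated, else
`remated_receptivity_base`, multiplied by `receptivity_size_mod` when a
small male courts a mated large female (mated females resist small males
more). An accepted copulation updates her stored-sperm shares by
proportional displacement: the newest male takes fraction `p_disp`, all
previous shares shrink by 1 − `p_disp` (remating with the same male
consolidates his share; shares always sum to 1). After each session every
mated female lays a Poisson(`fecundity_mean`) batch whose sires are a
multinomial draw from her end-of-day shares — matching the 20-h laying
interval between sessions. The `raffle` variant replaces displacement with
one equal ticket per copulation (shares = mating-count proportions),
removing order information while preserving repetition information; it
provides the low-precedence contrast in recovery studies.

**Defaults as study conditions.** `p_disp = 0.85` (second-male paternity in
*D. melanogaster* double-mating studies is typically ~0.8–0.9);
`male_weight_large : male_weight_small = 1.5 : 1` (a moderate large-male
courtship advantage); `virgin_receptivity = 0.9`,
`remated_receptivity_base = 0.25`, `receptivity_size_mod = 0.7` (high virgin
willingness, much lower remating willingness, extra resistance of mated
large females to small males); `slots_per_session = 20` (≈5 courtships per
female per 4-h session, yielding ~2–4 matings per female over four days —
realistic polyandry for freely interacting groups); `fecundity_mean = 20`
offspring per female per 20-h interval. Experiment builders produce
`n_het + 2 n_hom` vials (40 at the defaults: 20 heterogeneous, 10 of each
homogeneous composition), with heterogeneous male vials composed of the
focal male, one same-size rival and two rivals of the other size, and
heterogeneous focal sizes split evenly.

**What the generator does not emulate.** Sperm ageing and depletion,
seminal-fluid effects on oviposition and remating latency, cryptic female
choice, time-decaying (rather than two-state) receptivity, male ejaculate
partitioning, and any larval-density physiology beyond the size labels.
Passing recovery tests therefore demonstrate that the pipeline detects the
displacement structure it assumes, not that real groups obey that
structure.

## Numerical and testing choices

- R² values are clipped to [0, 1] against floating-point underflow;
  rank-deficient designs raise a singularity error rather than returning a
  pseudo-inverse fit.
- Commonality identities are checked to 1e-10 at run time; unit tests
  compare the closed form against an independent brute-force solve of the
  2^k−1 linear system.
- Datasets are written with fixed column order, canonical row sort and
  `\n` line endings, making fixed-seed pipelines byte-identical.
- The sampled problem sizes in the test suite (40-vial experiments,
  100-replicate recovery grids, 500-replicate null calibrations) mirror the
  replication structure of the emulated design while keeping the default
  test run desk-scale.

## Realized operating characteristics

Under the generator's conditions, the calibration and recovery tests
measure (rather than assume) the following, all recomputed by the suite:

- the mating-order bucket exceeds the repetitive-mating bucket in ≥95% of
  40-vial FM replicates at `p_disp = 0.95`, and the mean order-bucket share
  increases from the raffle model through `p_disp = 0.8` to `0.95`;
- the type-I error of the quasi-binomial and quasi-Poisson focal-size
  F tests under null simulations lies within the 95% binomial band around
  0.05 at 500 replicates;
- a 2:1 large-male courtship weight is recovered directionally (negative
  small-male coefficient within heterogeneous groups, where the within-vial
  size contrast exists; homogeneous vials pit the focal against same-size
  rivals, so they carry no such contrast by construction) in ≥80% of
  replicates. Detection at α = 0.05 of the marginal size effect is much
  rarer at this effect size and 30 vials — a genuine power limit of the
  marginal contrast, documented here so users do not over-read
  non-significant size effects at this scale.

## Known limitations

- Rival males share one phenotypic marker, so only focal paternity is
  measurable; rival-level precedence cannot be scored.
- The order index conditions on eligibility (females who mated the focal),
  which over-represents the focal male among sparse maters; between-vial
  comparisons of the index inherit that selection effect.
- Quasi-GLM F tests on a continuous proportion response are approximate;
  their realized size is verified by simulation rather than assumed.
- The ingestion adapter maps user-described column layouts onto the
  documented schema; it does not guess foreign layouts.
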