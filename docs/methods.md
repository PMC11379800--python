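# Methods

## Statistical model

Outcomes are modelled as standardized continuous measures: comparator
participants draw from Normal(μ, σ) and a challenger with true effect
*d* (Cohen's d) from Normal(μ + dσ, σ). Defaults are μ = 0, σ = 1, so arm
means are directly on the standardized scale. This is the only outcome
structure the design analysis assumes; real trials with covariates,
clustering or missing data need their own outcome model and Bayes-factor
extraction, which are out of scope here.

The carrier statistic is the **pooled-variance two-sample t** (equal
variances assumed, matching the standard two-sample JZS test; Welch is not
offered). Under a true standardized effect δ, t follows a noncentral-t
distribution with ν = n₁ + n₂ − 2 degrees of freedom and noncentrality
δ·√n_eff, n_eff = n₁n₂/(n₁ + n₂).

### The directional JZS Bayes factor

Under H₁ the effect has a Cauchy(0, rscale) prior; directional alternatives
truncate it to δ > 0 (`greater`) or δ < 0 (`less`). The Bayes factor
against the point null δ = 0 is the ratio of the prior-marginalized
noncentral-t density of the observed t to the central-t density:

BF = ∫ f_nct(t; ν, δ√n_eff) π(δ) dδ / f_t(t; ν).

Sign convention: δ = (challenger mean − comparator mean)/σ and higher
outcomes are better, so "superiority" is δ > 0 and the default direction is
`greater`. For lower-is-better measures set the prior direction to `less`
(or negate the outcome).

Two identities follow from the symmetric prior and are used as tests:
BF₊(t) = BF₋(−t), and BF₊ + BF₋ = 2·BF_two-sided. The directional BF is
strictly monotone in t (the noncentral-t family has a monotone likelihood
ratio and the mixture over one-signed noncentralities preserves it), which
underpins the boundary inversion below.

## Numerical choices

* **Noncentral-t density.** Computed from the representation
  T = (Z + μ)/W, W = √(χ²_ν/ν), as a one-dimensional integral over W whose
  log-integrand is strictly concave with a closed-form mode; a 96-node
  Gauss–Legendre rule on mode ± 8 Laplace standard deviations,
  log-stabilized, evaluates it to ≈1e−12 relative error (validated against
  a high-precision reference). This keeps the engine accurate at the
  degrees of freedom a sequential trial actually reaches (ν ≈ 300–900 and
  beyond), where library implementations of the noncentral-t pdf overflow.
* **Prior integration.** The δ integral is mapped through the prior CDF
  (δ = rscale·tan(πu/2) for the truncated case), giving a quadrature over
  u ∈ (0, 1) with no infinite limits and no truncated tail mass outside
  the integration range; adaptive quadrature (scipy QUADPACK) runs at
  relative tolerance 1e−8 with the likelihood peak supplied as a split
  point. Non-convergence raises a numerical error carrying the estimate
  and error bound; boundary decisions at BF 1/5 and 3 therefore carry
  numerical error orders of magnitude below Monte-Carlo noise.
* **Monte-Carlo oracle.** `oracle_bf_mc` re-estimates the same ratio by
  averaging the noncentral-t density over prior draws (≥10⁴), reporting a
  standard error; the test suite requires quadrature–oracle agreement
  within 3 SE across a grid of t, n and rscale, and pins the two-sided case
  against an independent library implementation.
* **Boundary inversion.** Because the directional BF is strictly monotone
  in t, each BF boundary maps to one critical t per (n₁, n₂). The
  vectorized simulator inverts the boundaries once per design (Brent root
  finding, warm-started along the look schedule, cached) and then compares
  cumulative t statistics against the critical curves — identical decisions
  to per-look quadrature (pinned replication-for-replication in tests) at a
  small fraction of the cost. A boundary unreachable at a given n (the
  directional BF is bounded below in its unfavourable tail) maps to ±∞ and
  simply never triggers.
* **Degenerate inputs.** Groups with fewer than 2 observations or zero
  pooled variance raise explicit errors; t must be finite; rscale > 0.

## Simulation machinery

* **Accrual.** Pairwise simulations interleave challenger and comparator
  1:1 (challenger first); general integer ratios are honoured by the
  per-trace simulator. Looks start once both arms hold N_min and repeat
  every `step` participants per arm, with a final mandatory look at N_max.
  Boundaries are absorbing: the first crossing ends the comparison, and
  cumulative crossing probabilities are reported *after the look at exactly
  that n*.
* **RNG policy.** Every replication uses a named stream seeded by
  (seed, replication index); results are reproducible and the per-trace and
  vectorized paths see identical data. Across effect sizes the same streams
  are reused (common random numbers), which couples rows of the OC table
  monotonically in d.
* **Multi-arm engine.** Permuted-block randomization over the active arms,
  block size = number of active arms, blocks re-formed whenever the active
  set changes. A challenger is analysed when an allocation lands on it at a
  look point and its contemporaneous comparator subset holds ≥ N_min
  participants. Promotions retire the old comparator immediately; other
  challengers meet the new comparator at their *next* look (never
  retroactively). The sitting comparator is exempt from the N_max cap by
  default (`comparator_nmax_exempt`). When the final decision ends the
  trial, the in-progress block is completed (those participants are already
  concurrently randomized), so a 2-arm trial running to the cap accrues
  exactly 2·N_max.
* **Contemporaneous comparison.** A challenger's comparator subset is every
  comparator-arm participant with randomization index ≥ the challenger's
  entry index — *including* participants the current comparator accrued
  while still a challenger. This is the reading under which the narrated
  five-method trajectory totals 1,250 participants; the conservative
  alternative (count only comparator-phase participants) is available via
  `contemporaneous_includes_prepromotion=False`. A retired comparator's
  data are never reused.
* **Arm entry triggers.** `start`, an explicit global randomization index,
  or `on_drop` (the default for scheduled arms): one queued arm enters per
  drop (failure or cap), first-in-first-out. Promotions do not by
  themselves admit queued arms. If the last challenger leaves while
  scheduled arms remain, the next one enters immediately so the roster is
  exhausted rather than stranded.
* **Replay.** `replay_scenario` re-enacts the bookkeeping deterministically
  (round-robin allocation in entry order, no outcome simulation) with
  boundary events forced by a script of (arm, decision, n) triples — the
  decision sequence is the sufficient input for auditing participant
  accounting. Scripts are validated against the decision rules (decisions
  only within [N_min, N_max], only with ≥ N_min contemporaneous comparator
  participants, at most one decision per arm; a scripted event that never
  becomes due is an error naming the arm).

## Default parameters

| Parameter | Default | Meaning |
|---|---|---|
| `n_min` | 150 /arm | first analysis; below this no evidence is examined |
| `n_max` | 450 /arm | cap; an undecided challenger is dropped here |
| `bf_fail` | 1/5 | evidence for the null strong enough to drop an arm |
| `bf_success` | 3 | evidence for superiority strong enough to promote |
| `rscale` | 0.5 | Cauchy prior scale on δ (SD units) |
| `direction` | greater | one-sided superiority alternative |
| `step` | 1 /arm | analysis cadence between looks |
| `allocation_ratio` | 1:1 | challenger:comparator accrual |

The sample-size/boundary defaults are the reference configuration for
detecting d = 0.2 with ≈80% pairwise power and a ≈5% pairwise
false-positive rate; they were chosen by exactly the simulation-first
search that `search_parameters` implements (filter candidates on power at
the target effect and false-positive rate at d = 0, both at N_max, then
rank by expected sample size).

## Look cadence and published operating characteristics

Cumulative boundary-crossing probabilities depend on the analysis cadence:
more looks spend more boundary-crossing opportunities, so step = 1
(continuous monitoring, the package default and the finest reading of
"sequential") crosses absorbing boundaries slightly more often than coarser
cadences. Measured precisely (10⁵ replications), the reference design under
step = 1 has a cumulative false-positive rate of ≈5.3% by 450/arm and power
≈80.8% at d = 0.2; at step = 10 the corresponding values are ≈4.8% and
≈80.2%. First-look cells are cadence-independent. OC tables quoted for this
design elsewhere are consistent with a coarser cadence (intermediate
cumulative cells match a step = 10 schedule closely, while step = 1 sits
2–4 percentage points above them on the failure side), so when comparing
against externally computed grids the cadence must be matched or allowed
for. The test suite holds first-look cells to tight Monte-Carlo tolerance
and cumulative cells to an explicit cadence allowance, and reports in
`scripts/acceptance.py` are computed at step = 1 (10,000 replications per
effect; the three reported cumulative cells are insensitive to cadence at
the tolerance of interest).

A related knife-edge: with the error-rate filter set exactly at
power ≥ 80% and false-positive ≤ 5%, the reference design's survival is not
stable under resampling — at step = 1 its true false-positive rate (5.3%)
sits just above the ceiling, at step = 10 its true power (80.2%) sits just
above the floor. The parameter-search tests therefore exercise filtering
and ranking semantics on candidates with clear margins.

## What the generator does and does not emulate

The synthetic outcome generator draws i.i.d. Normal outcomes with a fixed
between-arm shift — precisely the assumption under which the design's
operating characteristics are defined. It does not model attrition or
missing data, covariates or stratification, site/therapist clustering,
outcome drift over calendar time, or delayed outcome availability
(recruitment-speed effects). Passing tests certify the decision machinery
and its error rates under the stated model, not the behaviour of any of
those real-data complications.

## Known limitations

* Sequentially stopped effect-size estimates are biased toward the
  boundary that stopped them; the package reports decision probabilities
  and sample sizes, not debiased effect estimates.
* Only two-sample continuous outcomes with equal variances; no
  non-inferiority boundaries, informed/shifted priors, mixed-model or
  approximate Bayes factors.
* The expected-sample-size ranking in `search_parameters` is a Monte-Carlo
  estimate; near-tied candidates can swap ranks across seeds.
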