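# Methods

`rpskit` re-implements, as executable and testable code, a behavioral
decision-science workflow built around repeated Rock–Paper–Scissors
(RPS) play: the computer opponents of a two-experiment within-subject
design, synthetic participants that stand in for human players, and the
complete first-order sequential-dependency analysis (conditional
strategy tables, individual bias classification, success
classification, repeated-measures ANOVA, Tukey HSD, a random-intercept
mixed model with estimated marginal means, and a BIC-approximation
Bayes factor).

## The game algebra

The three items form a 3-cycle under "beats" (paper > rock,
scissors > paper, rock > scissors).  Trial-to-trial transitions of one
player's choices are coded into three strategy classes that partition
all ordered item pairs:

* `stay` — repeat the previous item,
* `upgrade` — play the item that beats the previous item,
* `downgrade` — play the item the previous item beats.

A first-order opponent rule is a strategy class applied by the opponent
to its *own* previous item.  For any such rule the winning reply to the
opponent's next move is unique, and the strategy class that carries the
player's previous item onto that winning reply depends only on the
previous round's *outcome* — the cyclic symmetry collapses the nine
item pairs to three outcome rows.  `derive_optimal_map` performs this
derivation by exhaustive enumeration and asserts the collapse.  The
resulting outcome → strategy maps are:

| opponent rule | after win | after loss | after draw |
|---------------|-----------|------------|------------|
| downgrade (experiment 1) | downgrade | upgrade | stay |
| upgrade (experiment 2)   | upgrade   | stay    | downgrade |
| stay                      | stay      | downgrade | upgrade |

Experiment 2's opponent rule is not stated verbally in the source
design; it is fixed to `upgrade` by back-derivation, since that is the
only first-order rule whose optimal counter-map is
win-upgrade / lose-stay / draw-downgrade.

One documented inconsistency: a prose example in the source material
describes opponent downgrading as "moving from Rock to Paper", which
contradicts the design description and the optimal-strategy table.  The
package adopts the table-consistent definition (downgrade(rock) =
scissors); it is the only reading under which the tabulated strategies
are actually optimal (verified by enumeration).

## Opponents

* **Unexploitable**: draws its 90 block moves without replacement from
  an equal deck (30 per item).  The equal deck removes item bias by
  construction.
* **Exploitable**: on 63 of 90 trials (70%) applies its rule to its own
  previous *actual* move (whatever that move's provenance); on the
  remaining 27 trials draws without replacement from an equal 27-card
  deck.  Trial 1 is always a deck draw (the rule needs a previous own
  move).  The rule/random schedule is fixed before play; the source
  design does not state how the 27 random trials were placed, so they
  are placed uniformly at random among trials 2–90 — the
  least-structured reading that preserves the 70/30 split exactly.

Every opponent move carries a provenance flag (`rule`/`random`) written
to the optional `opp_rule_trial` CSV column, making generated logs
auditable post hoc.

### Win-rate expectations, exactly and approximately

An agent playing the optimal contingency map wins **every** rule trial
after trial 1 — this is exact and is asserted structurally in tests.
Treating the 27 deck trials as independent uniform draws gives the
baseline expectation (63 + 27/3)/90 = 0.8 wins per block.

That baseline is *not* exact.  Because deck draws are without
replacement, an agent whose move depends on past outcomes holds a small
card-counting edge on deck trials: past outcomes reveal which cards
have left the deck.  The effect is provable by exact enumeration at
small deck sizes — against a three-card equal deck the map agent
expects 4/3 wins in three trials, not 1 — and shrinks with deck size.
At the design's 9 cards per item the Monte-Carlo mean over 10,000
blocks is ≈ 0.8013 (SE 0.0003): about 0.13 percentage points above the
baseline, and statistically distinguishable from it.  The acceptance
tests therefore assert the exactly provable facts (all rule trials won;
mean never below the baseline) plus an upper bound of 0.25 percentage
points on the counting edge derived from that analysis.  By the same
argument the often-quoted claim that *any* strategy earns exactly 1/3
against the equal deck holds only for history-independent agents; for
the uniform (mixed-strategy) agent it is exact and is tested as such.

## Synthetic participants

The generator emulates the *structure* of human play, not a claimed
human mechanism: the design (40 participants × four 90-trial blocks
crossing opponent {unexploitable, exploitable} × incentive value
{low, high}, orders semi-counterbalanced so that no two consecutive
blocks share an opponent type), and first-order outcome-conditioned
choice.

* `ConditionalStrategyAgent` — a fixed Markov policy: one probability
  vector over (stay, upgrade, downgrade) per previous outcome, uniform
  first move.  The uniform agent is the mixed-strategy benchmark; a
  degenerate agent built from a contingency map plays it perfectly.
* `LearningAgent` — softmax/delta-rule learner over the same
  outcome → strategy structure.  Values update toward the game points
  (+1 win, −1 loss, 0 draw); choice is softmax(q/temperature).
  Per-outcome learning rates allow valence-weighted learning; the
  default profiles update more slowly in the loss context, which
  reproduces the observed ordering of optimal-response rates
  (win > draw > lose) — losses inhibiting learning is the emulation
  target here, not a mechanistic claim.

Default profile mix for 40 participants: 17 consistent learners
(learning rates win .40 / draw .30 / lose .12, temperature .18),
15 intermediate learners (.12/.09/.04, temperature .60), 8 uniform
non-learners, mirroring the reported successful / partly-successful /
unsuccessful spread.  Parameters were chosen once so that consistent
learners pass the per-block success test almost always and
intermediates roughly half the time; the incentive-value factor is
design metadata only (no behavioral value effect is modelled, since
none was observed).

What the generator does **not** emulate: item biases (the small
rock preference), confidence probes, block-order fatigue, and any
higher-order (lag ≥ 2) dependence.  Passing tests on simulated data
therefore validate the pipeline's correctness and power, not any claim
about human behavior.

Every block draws from an independent stream seeded by
`(master_seed, participant, block)`, so any block is reproducible in
isolation and a whole dataset is byte-identical given the same seed.

## Sequential descriptives

Conditional strategy tables use the last 89 trials of a 90-trial block
(the first trial has no history); the transition at n → n+1 is
attributed to the outcome at n.  Rows for outcomes never experienced
are flagged and excluded from downstream averaging, never imputed.
Optimal-response rates score the same transitions against a contingency
map.  Extreme outliers are values more than three interquartile ranges
outside [Q1, Q3], with quartiles by linear interpolation between order
statistics (the convention of mainstream statistics tooling); the
multiplier and quartile method are configurable because outlier counts
depend on them.

## Bias and success classification

A participant has a bias toward a strategy after an outcome when a
two-tailed exact binomial test rejects the null rate of 1/3 **and** the
observed proportion exceeds 1/3.  The two-sided p-value uses
minimum-likelihood summation (sum of all pmf values no larger than the
observed one); the tail-doubling variant is selectable since
classification counts can depend on the convention.  Upgrade and
downgrade biases collapse into a general shift bias.  No
multiple-testing correction is applied across the nine per-participant
tests — deliberately, matching the original procedure; the labels carry
raw per-test alpha semantics.

Success against an exploitable block is a one-tailed one-sample
proportions test of the win rate against 1/3: continuity-corrected
normal approximation by default, exact binomial selectable.  For 90
trials at α = .05 both variants first reject at 38 wins, so the choice
rarely matters at this design size.  Participants aggregate over their
two exploitable blocks into successful-both / failed-one / failed-both.

## Inference

**Repeated-measures ANOVA.**  Implemented in-package for balanced,
fully-crossed within-participant designs with any number of within
factors and an optional equal-n between-participants factor, because no
installed Python package covers the 3- and 4-way within designs used
here together with sphericity handling.  Sums of squares come from the
exact Möbius (inclusion–exclusion) decomposition of cell means; each
within effect is tested against its interaction with participants.
Greenhouse–Geisser epsilon per within effect is computed from the
orthonormal-contrast covariance (Kronecker products of Helmert
contrasts), pooled within groups when a between factor is present;
Mauchly's test uses the standard two-term asymptotic expansion.
Corrected degrees of freedom are *reported* whenever Mauchly rejects at
.05 (the conditional policy of the original analyses); both corrected
and uncorrected p-values are retained.  The implementation is verified
in the test suite against pingouin (one- and two-way), statsmodels
AnovaRM (three-way F), pingouin's mixed ANOVA, and reproduces R car's
GG epsilons and Mauchly statistics on reference datasets.  Degenerate
effects — e.g. margins of compositional proportion data, which are
constant by construction — are reported as NaN rather than dropped
silently.

**Tukey HSD** uses the studentized-range distribution on cell means
given an error term; at two levels it reduces exactly to the unadjusted
t test.

**Mixed model.**  Optimal-response rates (one row per participant ×
outcome × exploitable block) are modelled with fixed effects of outcome
and experiment and a random participant intercept (no random slopes),
via statsmodels MixedLM.  Estimates and EMMs come from the REML fit;
the interaction and main-effects models are refitted by maximum
likelihood for BIC comparison, since exp(ΔBIC/2) is meaningful only for
ML fits.  BIC counts fixed effects plus variance parameters.
Denominator degrees of freedom use the between-within (inner-outer)
partition: within-varying effects are tested on
N − participants − (within columns) df and between effects on
participants − 1 − (between columns) df.  For this balanced
random-intercept design that partition coincides with the Satterthwaite
values reported by dedicated mixed-model tooling (398 and 78 at the
full design size), which statsmodels does not itself provide.  The
analysis frame keeps one row per exploitable block rather than
averaging the two value blocks — this is what reproduces the 398
within-df of the published analysis.

**Cross-experiment t test** is the pooled-variance two-sample t on
participant-level exploitable win rates (df = n₁ + n₂ − 2).

## Problem sizes and numerical choices

Monte-Carlo checks use 10,000 blocks for the optimal-agent win-rate
verification (MC SE ≈ 3·10⁻⁴), 3,000 for the uniform-agent chance-level
checks, 1,000 blocks for the classifier-size experiment, and n = 80
participants for planted-effect recovery (means win .60 / draw .50 /
lose .43, participant SD .10, residual SD .10 — residual noise chosen
to match the sampling error of a rate estimated from ~40 transitions).
Probability rows are validated to sum to 1 within 1e-12; softmax is
computed with max-subtraction; empty conditional rows propagate as
flags, not NaN arithmetic.

## Known limitations

* The classical ANOVA path requires complete balanced cells and
  whole-participant exclusion, as in the original workflow; it does not
  handle unbalanced between groups.
* The mixed model implements only the simple random-intercept
  structure used for the headline comparison; the exploratory
  "random intercepts within each effect" variants are out of scope, as
  are robust and fully Bayesian refits.
* The reproduction harness (`rpskit reproduce`, `rpskit.reference`)
  compares recomputed statistics against the published group values,
  but the deposited participant-level CSVs must be supplied by the
  user; they are not shipped.
* Synthetic participants are first-order by construction; analyses of
  higher-order dependence would need a richer generator.
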