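# rpskit

Simulation and sequential-dependency analysis of repeated
Rock–Paper–Scissors (RPS) play against **exploitable** and
**unexploitable** computer opponents.

Repeated zero-sum games are a standard probe of two competing modes of
human choice: *mixed-strategy* play (choosing uniformly at random, the
loss-minimizing strategy when the opponent cannot be exploited) and
*reinforcement-driven* play (win-stay / lose-shift, conditioning the
next choice on the previous trial's outcome).  `rpskit` implements the
full experimental engine and analysis pipeline for a two-experiment
design that pits these modes against each other:

* an **unexploitable** opponent drawing without replacement from an
  equal deck (30 rock / 30 paper / 30 scissors per 90-trial block), so
  no strategy changes expected outcomes;
* an **exploitable** opponent that on 70% of trials (63 of 90) applies
  a fixed first-order rule to its own previous move — *downgrade* in
  experiment 1, *upgrade* in experiment 2 — and draws from an equal
  27-card deck on the rest.

Coding each transition of the player's own choices as **stay**,
**upgrade** (play what beats your previous item) or **downgrade** (play
what your previous item beats), the optimal reply to the exploitable
opponent collapses to an outcome → strategy contingency map:

| | after win | after loss | after draw |
|---|---|---|---|
| experiment 1 (opponent downgrades) | downgrade | upgrade | stay |
| experiment 2 (opponent upgrades)   | upgrade   | stay    | downgrade |

The package provides, as separately usable modules: the game algebra
and optimal-map derivation (`rpskit.game`), the opponent policies
(`rpskit.opponents`), synthetic participants — fixed outcome-conditioned
Markov agents and softmax/delta-rule learners — with full-experiment
simulation (`rpskit.agents`, `rpskit.simulate`), trial-log CSV I/O with
validation and a column map for deposited data (`rpskit.io`),
outcome-conditioned strategy tables, optimal-response rates and the
extreme-outlier rule (`rpskit.sequential`), exact-binomial bias
classification and the success split (`rpskit.bias`), and the
inferential machinery — multi-way repeated-measures ANOVA with
Greenhouse–Geisser correction and Mauchly's test, Tukey HSD, a
random-intercept mixed model with estimated marginal means, BIC Bayes
factors and the pooled t test (`rpskit.inference`), orchestrated by
`rpskit.pipeline` and a CLI (`rpskit.cli`).

## Worked example

Simulate both experiments (40 synthetic participants each: 17
consistent learners, 15 intermediate learners, 8 random players) and
run the cross-experiment comparison:

```sh
rpskit simulate --experiment 1 --seed 3 --out exp1.csv
rpskit simulate --experiment 2 --seed 4 --out exp2.csv
rpskit compare --data1 exp1.csv --data2 exp2.csv --out-dir results
```

prints

```
Win-rate t test: t(78) = 0.857, p = 0.394 (51.10% vs 48.76%)
BIC Bayes factor (interaction vs main effects): 0.00328
Outcome EMMs (%): win = 59.9, lose = 47.9, draw = 56.2
```

Reading: the two simulated cohorts win 51.1% and 48.8% of exploitable
trials (chance is 33.3%; the pooled t test on 40 + 40 participants
finds no cohort difference).  The Bayes factor of 0.003 says the
outcome × experiment interaction model is ~300 times worse than the
main-effects model — how previous-trial outcome drives optimal play
does not differ between the two rule sets.  The estimated marginal
means show optimal responding ordered win > draw > lose: the learners
update most after wins and least after losses.

The same bundle is available in the library:

```python
from rpskit import ExperimentDesign, simulate_experiment
from rpskit.pipeline import analyze_experiment

ds = simulate_experiment(ExperimentDesign(experiment=1), master_seed=3)
res = analyze_experiment(ds)
print(res["success_split"])          # {'successful_both': 21, 'failed_one': 8, 'failed_both': 11}
print(res["optimal_rate_means"])     # win 0.613, draw 0.570, lose 0.477
```

`rpskit analyze --data exp1.csv --out-dir bundle` writes the full
single-experiment bundle (condition summary, the three
repeated-measures ANOVAs, bias-classification and success tables,
optimal-response rates, and a text report in
`F(df1, df2) = …, MSE = …, p = …, eta_p^2 = …` form).  Deposited
trial logs in a different column layout are adapted with a
`column_map` in the YAML config; `rpskit reproduce --experiment 1
--data S1.csv` then tabulates every recomputed group statistic against
the published values with per-quantity tolerances.

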