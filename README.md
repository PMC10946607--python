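# polyprec

Variance partitioning of focal-male paternity share in freely mating
*Drosophila melanogaster* groups: behavioural-log scoring of male mating
order and repetitive mating, all-possible-subsets commonality analysis,
quasi-GLM inference, and a synthetic mating-group simulator with tunable
last-male sperm precedence.

## The problem

In many insects the *last* male to mate a female sires most of her
subsequent offspring (last-male sperm precedence). In freely interacting
groups — here vials of four males and four females observed 4 h/day over
four days, with one genetically marked (wild-type) focal male among
*spa*-marked rivals and females — a male's paternity share can come from two
behavioural routes: mating *late* in each female's queue, or mating
*repeatedly* with the same females to stack his ejaculate representation.
This package separates those routes and asks how their relative importance
shifts with the body-size composition of the group (homogeneous vs.
heterogeneous, large vs. small focal males).

## Core statistics and model

For each vial the focal male gets, over his *eligible* mates (females that
mated him **and** at least one rival, so sperm competition is possible):

- **Paternity share** `PS = Σ wt / Σ (wt + spa)` over offspring laid on days
  at or after each female's first day of possible sperm competition;
- **Mating-order index**: the mean over eligible female-days of an indicator
  that he was the most recent male to mate that female (last-male status
  carries forward through non-mating days);
- **Repetitive-mating count**: his number of copulations with eligible
  females.

The explained variance of the linear model

```
PS ~ order_index* + repetitive_count* + mate_fecundity      (* = z-scored)
```

is decomposed by **commonality analysis**: R² is split into 2^k − 1
components C(S), one per predictor subset S, defined by
`R²(W) = Σ_{S∩W≠∅} C(S)` for every subset W and computed in closed form by
inclusion–exclusion. The reported three-bucket partition is
unique(order) / unique(repeat) / remaining. Treatment effects on the scores
are tested with quasi-binomial (order index) and quasi-Poisson (repetitive
matings) GLMs with dispersion-scaled deviance F tests, plus per-experiment
linear models with score × treatment interactions and a median-split
summary of paternity above/below each group's median mating order.

The simulator generates the same design generatively: courtship slots with
size-weighted male success, two-state female receptivity, proportional
last-male sperm displacement with strength `p_disp` (1 = complete
precedence; a "raffle" mode removes precedence entirely), and Poisson
fecundity with sires drawn from each female's current sperm shares.

## Worked example

```python
import numpy as np
from polyprec import (simulate_experiment, score_dataset, CommonalityModel)

ds = simulate_experiment("FM", n_het=20, n_hom=10,
                         rng=np.random.default_rng(1))   # 40 vials
scores = score_dataset(ds)
print(CommonalityModel(scores).fit().summary())
```

prints (abridged):

```
Commonality analysis of paternity share
=======================================================
n vials:        40
predictors:     order_index, repetitive_count, mate_mean_fecundity
total R²:       0.9354
...
mating order                        0.8748       93.53
repetitive mating                   0.0044        0.47
remaining                           0.0561       6.00
```

i.e. with strong simulated displacement (`p_disp = 0.85` by default) the
mating-order index uniquely accounts for the overwhelming share of the
explained variance in paternity, and repetitive mating for almost none —
the qualitative signature the analysis is designed to detect.

The same pipeline runs from the shell:

```
polyprec simulate --experiment FM --seed 1 --out data/
polyprec score --data data/ --out scores.csv
polyprec partition --scores scores.csv --out out/
polyprec fit --scores scores.csv --out out/
polyprec report --config config.yaml --seed 1
```

## Layout

- `polyprec.records` — domain types, validated dataset container, CSV I/O,
  column-mapping ingestion adapter
- `polyprec.scoring` — eligibility, competition windows, the three focal
  statistics, fecundity covariates
- `polyprec.commonality` — `CommonalityModel` / `CommonalityResults`,
  subset R², inclusion–exclusion coefficients, Table-style bucket reports
- `polyprec.inference` — quasi-GLMs, AIC backward selection, interaction
  models, median split, correlation and assortative-mating ANOVA
- `polyprec.simulate` — `SimulationParams`, sperm-displacement dynamics,
  experiment builders, parameter-recovery harness
- `polyprec.pipeline` / `polyprec.cli` — config-driven orchestration and the
  `polyprec` command

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
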