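# heurevo

Individual-based simulation of the evolution of **social heuristics**:
simple cooperation strategies that ignore information about the social
situation at hand, evolving because that information is unreliable.

## The problem

Individuals face many kinds of social interactions, and they often cannot
tell exactly which one they are in. `heurevo` models a population playing
repeated two-player cooperation games in which cooperating confers a fixed
benefit *b* = 2 on the partner at a variable consequence *c* to the actor,
drawn fresh for every interaction from Uniform(−3, 1). Depending on *c*
the stage game is a harmony game (*c* > 0), a prisoner's dilemma
(−2 < *c* < 0) or a spiteful game in which even mutual cooperation is a
loss (*c* < −2).

Players never see *c*. They see a private perception *c*ₚ drawn from a
beta distribution (rescaled to [−3, 1]) with mode *c* and unit-scale
variance *u*/12, where the uncertainty *u* interpolates between perfect
information (*u* = 0, *c*ₚ = *c*) and no information (*u* = 1, uniform
*c*ₚ).

Each individual carries a 17-gene genotype: a switch locus *S* selecting
**heuristic** behaviour (always play substrategy H) or
**context-dependent** behaviour (play C1 when *c*ₚ < *T*, else C2, for a
threshold gene *T*), and three memory-one substrategies of five genes
each — a continuous first-move cooperation probability and four Boolean
responses to the previous round's outcome (CC, CD, DC, DD). Actions are
executed with an implementation error ε = 0.01. After ten interactions of
ten rounds each, individuals reproduce by roulette-wheel selection on
baseline-plus-accumulated payoff, with mutation at rate μ = 0.001 per
unit; the four response genes of a substrategy mutate jointly through a
16×16 mutation matrix in which every substrategy can turn into exactly
four others (probability 0.25 each).

The headline phenomenon: as *u* rises, evolution abandons context-dependent
strategies for heuristics — most prominently **grim** (cooperate only
after mutual cooperation) with a first-move probability near 0.99 — and
population-wide cooperation rises with it, nearly doubling between the
low- and high-uncertainty regimes.

## Worked example

Exact self-play cooperation rate of the two heuristics that dominate
high-uncertainty populations, from the outcome-state Markov chain:

```python
>>> from heurevo import named_strategy, monoculture_cooperation
>>> grim = named_strategy("GRIM", first_move=0.99)
>>> round(monoculture_cooperation(grim, epsilon=0.01, n_rounds=10), 4)
0.8901
>>> tft = named_strategy("TFT", first_move=1.0)
>>> round(monoculture_cooperation(tft, epsilon=0.01, n_rounds=10), 4)
0.9482
```

A grim monoculture sustains mutual cooperation until someone errs, and a
ten-round game rarely lasts long enough for that, so ~89% of actions are
cooperative; tit-for-tat recovers from single errors and does slightly
better.

A small evolutionary run and an uncertainty sweep from the shell:

```
$ heurevo run --u 0.8 --pop 200 --generations 2500 --seed 2 --out traj.csv
final cooperation=0.914 heuristic_fraction=1.000

$ heurevo experiment --pop 200 --generations 2500 --seed 1 \
    --u-grid 0.1,0.3,0.5,0.7,0.9 --matrices 5 --replicates 10 --out exp.csv
$ heurevo fit --table exp.csv --column heuristic_fraction
```

Single replicates are bimodal — evolution sometimes fixes a defecting
heuristic instead of grim, especially at this reduced scale — so the
analyses always average over mutation matrices and replicates.

The experiment table has one row per (u, mutation matrix, replicate) with
the final cooperation level, heuristic fraction and dominant strategy
(>80% of the population); `fit` summarises the heuristic fraction as a
four-parameter logistic curve in *u* with per-matrix asymptotes and a
shared slope. Other subcommands: `fixed-c` (benchmark sweep with a
constant consequence), `invasion` (rare-mutant invasion fitness of
heuristic grim vs. the context-dependent grim/pavlov strategy),
`monoculture`, `make-matrix`.

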