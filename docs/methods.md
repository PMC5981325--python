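# Methods

## Model

A well-mixed population of N individuals (default 1000) evolves over
discrete generations. Each generation every individual has
`n_interactions` (10) repeated interactions, each lasting `n_rounds`
(10) simultaneous rounds. Per interaction one true consequence
c ~ Uniform(−3, 1) is shared by the pair; cooperating adds c to one's
own payoff and b = 2 to the partner's, so the stage payoffs are b+c
(CC), c (CD), b (DC) and 0 (DD). Payoffs always use the true c.

Each player privately perceives the consequence once per interaction:
c_p is drawn from a beta distribution on [−3, 1] with mode c, and the
perception (hence the active substrategy) stays fixed for all ten
rounds. The two partners' perceptions are independent; the model text
describes subjective perception and never a shared signal, so private
draws are the natural reading.

Genotypes carry a symbolic switch locus S (heuristic vs.
context-dependent; the two printed descriptions of the 0/1 encoding
disagree, so the package never stores a bare 0/1 internally — file
output uses 0 = heuristic), a threshold T, and three substrategies H,
C1, C2, each a first-move probability in [0, 1] plus four Boolean
responses to the previous outcome. Context-dependent individuals play
C1 when c_p < T and C2 otherwise; the printed sources also disagree on
this inequality's direction, and since the C1/C2 labels are symmetric
the choice only affects reporting order. The comparison direction is a
config switch (`tie_to_c2`). Every action, including the first move, is
flipped with the implementation-error probability ε = 0.01.

Fitness is a baseline of 100 plus accumulated payoff. With c as low as
−3 accumulated payoff can push fitness negative, which roulette-wheel
selection cannot handle; fitness is floored at 0 (configurable) before
selection. Reproduction is asexual: N parents drawn with probability
proportional to fitness, each offspring mutated.

## Perception parametrisation

The constraints on the perception distribution are: mode c, variance
proportional to u, a point mass at u = 0 and the uniform distribution
at u = 1. The package uses the unique one-parameter family through
those endpoints with a fixed mode: Beta(1 + κm, 1 + κ(1−m)) on the unit
scale, where m = (c+3)/4, with κ ≥ 0 solved by bisection so the
variance equals u/12 (tolerance 1e−10). u = 1 then gives κ = 0 =
Beta(1, 1) exactly, and variance is linear in u. The proportionality
constant 1/12 is pinned by the uniform endpoint; other constants would
satisfy "proportional" but break that endpoint. Absolute simulation
outcomes could shift under a different mode-preserving family; the
qualitative uncertainty effect should not, since only the
informativeness ordering in u matters.

The compiled simulation kernel tabulates κ(m) on a 4097-point regular
grid in m per uncertainty level and interpolates linearly; the induced
variance error is orders of magnitude below Monte-Carlo noise. The
Python API (`beta_shape_params`, `perceive`) always bisects exactly.

## Mutation

Eight independent mutation lotteries per offspring at rate μ = 0.001:
S flips; T and each of the three first moves receive N(0, 0.1)
perturbations (first moves clamped to [0, 1]; T unclamped — the switch
saturates outside [−3, 1] anyway); each substrategy's four response
genes mutate as one block, redrawn from the mutation-matrix row of the
current code. Block mutation is the only granularity consistent with a
16×16 substrategy-to-substrategy matrix. Matrices are generated by
sampling, for each of the 16 codes, four distinct targets uniformly
from the other 15 (probability 0.25 each); self-mutation is impossible.
One matrix is shared by all three substrategy blocks of a simulation.

## Pairing

Partners are re-matched for every one of the ten interaction bouts by
an independent uniform random perfect matching, so each individual
plays exactly once per bout. Repeat partners across bouts occur with
probability ≈ 1/(N−1) per pair and bout; the source model states only
"different interaction partners", and round-robin schemes would add
structure the text does not support. This and the fitness floor are the
two quantitatively (not qualitatively) consequential free choices.

## Engines and determinism

Two implementations of the generation loop coexist: a pure-Python
reference (`engine="python"`) that produces per-interaction records and
is used in unit tests, and a numba-compiled kernel (`engine="numba"`,
default) used for experiment grids. They are statistically equivalent
but consume randomness differently; determinism (identical trajectory
from identical seed, config and matrix) holds within each engine. All
experiment-grid seeds derive from a master seed via
`numpy.random.SeedSequence` keyed on (u index, matrix id, replicate),
so any row can be reproduced in isolation.

## Monoculture cooperation oracle

Self-play of one memory-one substrategy with errors is a Markov chain
on the four joint outcomes: from outcome o the focal intends
response[o], the partner intends response[mirror(o)], and each executed
action flips independently with probability ε. With the first-move
lottery as the initial distribution, the expected per-action
cooperation probability over a finite game follows in closed form
(`monoculture_cooperation`). A vectorised Monte-Carlo route through the
actual repeated-game code (`monoculture_cooperation_mc`) cross-checks
the chain and is what the acceptance script runs, so the reported
values exercise the simulation path rather than the algebra. For grim
with first move 0.99 and ε = 0.01 the chain gives 0.8901 over ten
rounds; for tit-for-tat with first move 1.00, 0.9482.

## Four-parameter logistic summaries

Uncertainty sweeps are summarised by
y = y_min + (y_max − y_min)/(1 + exp((u_mid − u)/β)). Mutation-matrix
variation is handled by per-matrix (y_min, y_max, u_mid) with a shared
slope β, fitted by least squares (β through a log-parametrisation to
keep its sign fixed during optimisation); the reported curve is the
across-matrix mean with bootstrap-over-matrices 95% intervals. This is
a deliberate simplification of a nonlinear mixed model with AIC-based
random-effects selection; the shared-slope structure mirrors the final
model reported for the original analysis (only the slope did not vary
between matrices). Fits are canonicalised to y_min ≤ y_max (flipping
β's sign), and essentially flat data are flagged unidentifiable rather
than trusted for u_mid.

## Invasion analysis

Rare-mutant limit: the mutant meets only residents, the resident meets
residents. Expected lifetime fitness (baseline 100 + payoff over ten
interactions, each with fresh c and private perceptions) is estimated
by vectorised Monte-Carlo; invasion fitness is the ratio
mutant-vs-resident over resident-vs-resident, with a delta-method
standard error. The baseline is included because the evolutionary model
selects on baseline-plus-payoff; excluding it rescales the ratio away
from 1 but cannot move the crossing point. The reference pair is
heuristic grim (first move 0.99) versus the context-dependent
grim/pavlov strategy: grim with first move 0 below the threshold (an
absorbing defection regime) and pavlov with first move 1 at or above
it, threshold T = −0.5 — one of the two evolved threshold values; the
exact evolved loci are only available graphically in the original
figures, so these settings are exposed as arguments.

## Scaled study conditions

The full-scale conditions (N = 1000, 10,000 generations, 11 u levels ×
100 matrices × 50 replicates) are the package defaults and run from the
CLI. The shipped replications (test suite) use a desk-scale preset:
N = 200, 2500 generations, u ∈ {0.1, 0.3, 0.5, 0.7, 0.9}, 5 matrices ×
10 replicates; the fixed-c benchmark uses 21 consequence values × 3
replicates at 2000 generations, with cooperation averaged over the
last 500 generations to damp terminal noise. At this scale drift is
stronger and convergence less complete, so the tests assert orderings
and approximate magnitudes (heuristics dominant at high u, context
strategies at low u, cooperation higher under high u, the logistic
trend, the fixed-c transition near c ≈ −1.2) rather than the full-scale
point values.

What the synthetic regime does not establish: the simulations generate
their own data by construction, so passing tests show internal
consistency of the evolutionary mechanism, not that real social
behaviour follows it; and the desk-scale magnitudes are expected to be
biased toward 0.5 (more drift, less convergence) relative to the
full-scale values.

## Known limitations

- Single heterogeneous payoff dimension (c); pure memory-one
  substrategies only; no spatial structure, overlapping generations or
  recombination.
- The perception variance constant beyond its two pinned endpoints is a
  modelling choice (see above).
- The 4PL group model approximates, not reproduces, a full nonlinear
  mixed-effects analysis.
- The published set of 100 mutation matrices is not recoverable;
  matrices are regenerated by the stated recipe, so matrix-specific
  outcomes differ while the distribution over matrices matches.
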