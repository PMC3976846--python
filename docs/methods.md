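# Methods

## Hierarchical feature representation

The data model is a samples × symptoms table of non-negative integers plus
one non-negative real positive score per sample. Symptoms are partitioned
into named groups; each group yields one syndrome feature:

* **Concurrent groups** (members can co-occur): the syndrome is the row sum
  of its members — a cumulative positive strength.
* **Mutually-exclusive groups** (at most one member positive per patient;
  members must be binary indicators): the syndrome is a categorical code.
  0 means no member positive; codes 1..m are assigned so the symptom
  positive in **more patients** receives the **larger** code. Frequency
  ties are broken by the larger mean positive score over that symptom's
  positive patients; a remaining tie goes to the earlier column. The
  direction of the final tie-break is a package convention — with real data
  a double tie is vanishingly unlikely, but the rule must be total for
  reproducibility.

Exclusivity violations and non-binary exclusive members raise errors rather
than being coerced: silently summing a supposedly exclusive group would
change the feature's meaning. Learned code maps are persisted with the
grouping JSON so that a serialized grouping reproduces identical syndrome
values on re-read.

## LS-SVR

The regression model is least-squares SVR with RBF kernel
`k(x, z) = exp(−‖x − z‖² / σ²)` — σ² is the direct divisor, consistent with
a search range extending to 10⁵. Fitting solves the standard dual system

    [[0, 1ᵀ], [1, K + I/γ]] · [b; α] = [0; y]

implemented by eliminating the bias against the SPD block `H = K + I/γ`
(one Cholesky factorization, two right-hand sides), with a dense bordered
solve as fallback if H is numerically indefinite. The equality constraint
`Σαᵢ = 0` is verified to <1e−8 in tests, and the solver is checked against
an independent dense `numpy.linalg.solve` of the full bordered system to
1e−10.

Hyperparameters (σ², γ) are grid-searched over logarithmic grids of 7
points per axis spanning σ² ∈ [0.1, 10⁵] and γ ∈ [0.1, 10⁴] (the grid
density is a package choice; only the ranges are prescribed), scored by
seeded shuffled 10-fold CV MSE; ties go to the smaller σ², then smaller γ.
Subset evaluation and the pe score use 5-fold CV with the same seeding.

## Feature ranking

Per syndrome fᵢ:

* `mcc(fᵢ) = 1 − |Pearson r(fᵢ, ps)|`. The source material specifies only
  "correlation coefficient, smaller is more important"; `1 − |r|` is the
  simplest form meeting that contract and is documented as an assumption.
  Zero-variance features score 1 (worst) with a warning.
* `pe(fᵢ)` = 5-fold CV MSE of the LS-SVR trained on all features except fᵢ
  (leave-one-feature-out error; large pe ⇒ fᵢ was carrying information).
* `fr(fᵢ) = (mcc(fᵢ) + (1 − pe(fᵢ)/max_j pe(f_j))) / 2 ∈ [0, 1]`. This
  combination rule reproduces every row of the published 27-syndrome
  ranking table from its printed mcc/pe columns to 4 decimals (max
  |Δ| ≈ 6e−5) and the printed ranks exactly — the mandatory regression test
  of this module.

Ranks are ascending in fr with ties kept in input order. Threshold subsets
take fr strictly below θ (θ = 0.8 and 0.9 give the 13- and 19-syndrome
filter baselines). The correlation filter baseline (CFM) takes the
⌈fraction·D⌉ symptom columns with the largest |r|; the ceiling convention
reproduces the published 30 % subset size (45 of 147). No single rounding
convention reproduces both published CFM sizes (22 and 45), so the ceiling
rule is applied uniformly.

## Chaotic binary PSO

Particles are binary subset indicators over the D = 27 syndromes. Study
constants: V ∈ [−6, 6], ws = 1.2 → wl = 0.4 with shape c₃ = 10
(`w = wl·(ws/wl)^(1/(1+c₃ t/t_max))`), reinitialization gate rk = 0.3,
chaotic series length k = 500 (N < k), logistic control μ = 4, gbest
mutation after 10 stagnant generations. Choices the source leaves open,
fixed here once:

* c₁ = c₂ = 2.0 (the conventional acceleration constants).
* Per-particle reinitialization probability = `rk · p_c(t)` with
  `p_c(t) = 1 − 1/(1 + ln t)` — the small gate rk scales the growing
  schedule. Reinitialized particles keep their pbest record, updating it
  (and gbest) only on improvement.
* gbest mutation flips each bit with probability 1/D and adopts the mutant
  only on strict improvement, so gbest never worsens.
* Elitism triggers at twice the mutation stagnation threshold (20
  generations) and replaces the worst 20 % of particles (by pbest fitness)
  with fresh chaotic candidates, never touching the gbest holder.
* Logistic seeds in {0.25, 0.5, 0.75} and the endpoints are resampled
  (degenerate orbits at μ = 4); iterates ≥ 0.5 map to bit 1.
* Fitness ties keep the first achiever of the value.

Fitness = 5-fold CV LS-SVR MSE of the selected columns + p · mean fr of the
selected features (p = 0.2 default; the empty subset gets +∞ so it can
never be adopted). (σ², γ) are grid-searched once on the full syndrome set
and frozen for all fitness evaluations — re-searching per particle would
multiply the cost ~50× for no documented benefit; the frozen pair is
configurable. Fitness values are memoized per position within a run (the
fitness is a pure function of the bitstring given the frozen
hyperparameters and CV seed), and the RBF exponent of a subset is assembled
from precomputed per-feature pairwise squared distances; neither shortcut
changes any computed value.

All randomness flows from one `numpy` generator seeded per run; a fixed
seed reproduces the initial swarm, the trajectory and the trace exactly.
With chaotic initialization, reinitialization, mutation and elitism all
disabled, the engine follows the textbook binary-PSO trajectory step for
step (verified against an independent reference loop on a shared seed) —
this is the plain-wrapper baseline.

## Discrete Bayesian networks

Syndrome columns with more than four distinct values are floor-binned into
`itvnum = ⌊log₂(#unique)⌋ + 1` equal-width intervals of [0, max] with the
top edge clamped, so exactly itvnum labels are producible and 0 maps to bin
0; columns with ≤4 distinct values (including constants) pass through.

Structure learning is a two-phase greedy search over DAGs with a
decomposable BIC score (family log-likelihood − ½·ln n · free parameters):
forward edge additions while any improves the score, then backward
deletions, with lexicographic tie-breaking and a parent limit (default 4)
bounding CPT size. This is a deliberate simplification of
equivalence-class search (GES): the moves operate on DAGs, not CPDAGs.
CPTs are maximum-likelihood frequency tables; parent configurations never
observed get uniform rows.

Inference is exact variable elimination with a min-degree ordering —
answers identical to a junction tree at these scales, verified against
brute-force joint enumeration (≤10-node nets, 1e−9). Zero-probability
evidence is flagged rather than raised.

## Synthetic data

The generator emulates the reference dataset's structure: 300 samples, 147
symptoms in the 27 published group sizes, with lip color, tongue color and
coated tongue color exclusive (the documented one-hot groups; exclusivity
of the remaining groups is not published, so they default to concurrent).
Exclusive groups draw a categorical state with "none" probability 0.4 (so
zero codes occur); concurrent symptoms are independently positive with
probability 0.25, with per-symptom ordinal ceilings drawn from {1, 2, 3}
(matching the binary / 0–3 ranges of documented symptoms). The positive
score is a weighted sum (unit weights) of five planted syndrome values —
complexion, facial features, sternocostal/abdominal pain, diet, skin of the
limbs, i.e. large informative groups — plus N(0, 0.5²) noise, clipped at 0.
Noise sd 0.5 is small relative to the planted signal (sd ≈ 5), emulating a
score instrument that tracks true positivity closely.

What the generator does **not** emulate: empirical symptom marginals and
inter-symptom correlations of real patients, nonlinear score instruments,
and within-group dependence beyond exclusivity. Passing recovery tests
therefore shows the search machinery works under the stated generative
assumptions, not that the published clinical error rates are reproduced —
those depend on the unavailable patient data.

## Problem sizes and verification

The test suite verifies, among others: the fr/rank recomputation of the
full reference table; the 13/19 threshold dimensions; decoding of the
reference optimal bitstring (24 syndromes, excluding the three color
syndromes); LS-SVR against a dense-solve oracle; CBPSO against exhaustive
enumeration on ≤4-feature problems; a 20-seed recovery experiment
(reference-shaped data, swarm 50, 50 generations, p = 0.2) requiring the
planted set inside the selected subset in ≥18/20 runs; variable elimination
against joint enumeration; and 3-node chain skeleton recovery in ≥9/10
seeded replicates at n = 1000. The recovery experiment dominates the suite
runtime (~8 minutes on one CPU).
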