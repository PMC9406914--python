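# Methods

## Problem setting

The package targets wrapper feature-subset selection on dysphonia feature
tables: one row per sustained-vowel recording, ~750 numeric columns in
six families (baseline jitter/shimmer/F0/harmonicity/RPDE/DFA/PPE,
time-frequency intensity/formant/bandwidth, MFCC, wavelet, vocal-fold,
TQWT), a binary case/control label, and repeated recordings per subject.
The goal is a small column subset on which a downstream classifier
performs at least as well as on the full table.

## Search dynamics

Candidate masks are encoded as points in the unit hypercube `[0,1]^d`.
The continuous dynamics are classic grey wolf optimization: per
iteration, each wolf computes one encircling step toward each of the
three best solutions found so far (alpha, beta, delta) with fresh
stochastic coefficients `A = 2a·r₁ − a`, `C = 2·r₂`, and moves to the
mean of the three candidates. The control scalar decays linearly,
`a(t) = 2 − 2t/T`, shifting the pack from exploration (|A| can exceed 1,
wolves overshoot leaders) to exploitation (wolves settle onto leaders).
Positions are hard-clipped to the box after every move; clipping is the
entire constraint-handling story.

Two exploration mechanisms are layered on top, each applied per wolf per
iteration:

- **Random triplet** (probability `explore_prob`, default 0.2): the wolf
  jumps to the mean of three distinct pack members chosen uniformly at
  random, replacing the leader-guided move.
- **Levy perturbation** (probability `levy_prob`, default 0.5): after
  the move, the wolf is resampled at `Y_α + α_step ⊗ Levy(β)` around the
  current alpha, with step size `α_step = 0.1` and tail index `β = 0.5`.
  Steps use the Mantegna construction `u/|v|^{1/β}`,
  `u ~ N(0, σ_u²)`, `v ~ N(0,1)`, with

      σ_u = { Γ(1+β)·sin(πβ/2) / [ Γ((1+β)/2)·β·2^{(β−1)/2} ] }^{1/β},

  which equals 1 exactly at β = 1 (the closed-form oracle the tests pin).

The schedule by which the three mechanisms coexist is not fixed by the
method's literature; here it is explicit configuration
(`explore_prob`, `levy_prob`) with the defaults above, chosen so the
baseline leader-guided dynamics remain dominant while both enhancements
fire often enough to matter. Both probabilities are exposed on the CLI.

## Binary layer and fitness

Each coordinate is squashed by the steep sigmoid
`s(x) = 1/(1+e^{−10(x−0.5)})` — the −10(x−0.5) form presumes the unit
interval encoding, which is why bounds default to [0,1] — and a uniform
draw per coordinate yields the mask. Mask fitness is

    fitness = α·ER(D) + (1−α)·|R|/|C|,  α = 0.99 (configurable),

with `ER(D)` the error rate of a k-NN induction classifier (k = 5, odd to
avoid vote ties) on an internal validation scheme. The default scheme is
a stratified 80/20 holdout **inside the training partition**, with a seed
resolved once per selection run: fitness is then a pure, cached function
of the mask, which makes the best-so-far trace monotone and the whole run
bit-reproducible from one seed. Stratified k-fold is available as an
alternative scheme.

Degenerate cases: the empty mask receives a +inf fitness sentinel; if the
final best mask were somehow empty, the single best feature by univariate
wrapper fitness is forced, so a selection result always contains at least
one column. Fitness ties break toward fewer features, then toward the
earlier-evaluated wolf.

## Preprocessing and data contract

Tables are z-score standardized with the population standard-deviation
convention (divide by n); columns with zero variance map to zero rather
than erroring, so degenerate synthetic columns cannot kill a run.
Missing cells are a hard parse error naming the row and column — the
reference tables contain none, so absence signals corruption, and no
imputation path exists.

The stratified splitter apportions per-class test counts by largest
remainder so that the total is exactly `round(n × fraction)`: a 756-row
table at 0.25 always yields 567/189, and the 564 positive rows always
contribute 141 to the test partition. Remainder ties go to the smaller
class (never emptying it when a valid apportionment exists). The default
splits recordings independently, matching the common protocol for this
table even though one subject owns three rows; `group_by_subject=True`
keeps subjects intact across the partition for leakage-aware analyses.

The pipeline fits standardization on the training partition only and
applies it to both sides; `standardize_first=True` reproduces the
standardize-then-split variant. Selection sees only the training
partition — a canary test garbles every test row and asserts the mask is
unchanged.

## Synthetic cohort

The generator emulates the reference cohort's geometry, not its
acoustics: 188 case + 64 control subjects (rows inherit their subject's
label), 3 recordings each, 752 vocal columns plus a gender column
(Bernoulli per subject at the observed male rates, 107/188 cases and
23/64 controls, carried as an ordinary numeric feature). Note the
published feature-family counts sum to 752 although the table is
elsewhere described as 754 columns wide; the schema emits the documented
752 + gender rather than inventing two unnamed columns, and the loader
imposes no fixed width.

Each column is unit-variance Gaussian, decomposed as
`√ρ·subject + √(1−ρ)·recording` so repeated recordings correlate at
`ρ` (`within_subject_rho`, default 0.5 — repeated phonations of one
speaker are similar but not identical). `n_informative` randomly chosen
vocal columns (default 40, roughly 5% of the table — a sparse-signal
regime appropriate for a redundant acoustic feature set) get a mean
shift of `effect_size` standard deviations in cases (default 1.0, a
large but clinically plausible marker effect). What the generator does
**not** emulate: inter-column covariance within feature families,
non-Gaussian tails of energy/entropy features, and age structure.
Passing tests therefore demonstrate the search and evaluation machinery
on well-posed planted-signal problems, not performance on real voice
recordings.

## Problem sizes used in the test suite

The statistical end-to-end checks run on 50-column cohorts at the full
756-row geometry: planted recovery uses 5 informative columns at effect
2.0 with pack 10 and 100 iterations over 10 seeds; the null-signal guard
uses effect 0.0 with 60 iterations over 3 seeds. These sizes make the
wrapper loop's behaviour measurable in seconds per run while keeping the
row geometry and class imbalance of the full problem.

The null-signal guard deserves one note: a wrapper search adaptively
maximizes its own fixed validation holdout, so on pure noise the
*internal* validation accuracy of the winning mask is biased above the
majority rate (winner's curse) even when the implementation is correct.
The guard therefore evaluates the selected mask on the untouched test
partition, where any systematic edge over the majority classifier would
indicate label leakage into the fitness; the observed accuracies sit
within two binomial standard errors of the majority rate.

## Known limitations

- Wrapper selection with a fixed internal holdout can overfit that
  holdout on small tables; the k-fold scheme trades determinism cost for
  lower variance if needed.
- The selected-feature count on a real ~750-column table is seed- and
  data-dependent; roughly halving the dimension is a typical outcome,
  not a contract.
- Wall-clock columns in reports are informational only and
  hardware-dependent.
- LightGBM on very small cohorts (< ~40 rows per class) may underfit at
  its default `min_child_samples`; the hyperparameter map is exposed.
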