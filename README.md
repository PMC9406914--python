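# ebgwo — Levy-enhanced binary grey wolf wrapper feature selection

`ebgwo` selects informative columns from high-dimensional vocal-biomarker
tables — the kind used to separate people with Parkinson's disease (PWP)
from healthy controls by sustained-vowel dysphonia measures (jitter,
shimmer, MFCC, wavelet and TQWT energies; ~750 numeric columns, three
recordings per subject, heavy class imbalance). It is a wrapper method: a
population metaheuristic searches the space of feature masks, scoring each
candidate by how well a small induction classifier generalizes on it.

## The method

**Grey wolf optimization (GWO).** A pack of candidate solutions moves
toward its three best members (alpha, beta, delta). Each wolf encircles
each leader,

    D = |C ∘ X_p − X|,    X′ = X_p − A ∘ D,
    A = 2a·r₁ − a,        C = 2·r₂,        a(t) = 2 − 2t/T,

and takes the mean of the three candidate points; `a` decays linearly
from 2 (exploration) to 0 (exploitation) over `T` iterations.

**Levy-flight enhancement.** After the leader-guided move each wolf may
jump around the current alpha with a heavy-tailed step,
`Y′ = Y_α + α_step ⊗ Levy(β)`, generated by the Mantegna construction
`u / |v|^(1/β)` with `u ~ N(0, σ_u²)`, `v ~ N(0, 1)` and a Gamma-function
closed form for `σ_u`. Occasional long jumps keep exploration alive late
in the schedule. A random-triplet move (mean of three random pack
members) adds a further exploration mode.

**Binary layer.** Positions live in `[0,1]^d`. A steep sigmoid transfer
function `s(x) = 1/(1 + e^{−10(x−0.5)})` converts each coordinate into an
inclusion probability; stochastic thresholding yields a 0/1 mask. Mask
quality is the wrapper fitness

    fitness = α·ER(D) + (1 − α)·|R|/|C|,      α = 0.99,

where `ER(D)` is the validation error rate of a k-nearest-neighbour
induction classifier (k = 5) on the masked columns, `|R|` the number of
selected features, `|C|` the total. Lower is better: classification error
dominates, with gentle parsimony pressure on mask size.

The package also ships a synthetic cohort generator that reproduces the
geometry of the reference table (188 case + 64 control subjects × 3
recordings = 756 rows; 752 vocal columns in the standard feature families
plus a gender column) with planted class-informative columns, so the
whole pipeline is testable end to end without any data download, and an
evaluation layer (confusion-matrix metrics, Mann–Whitney rank AUC, and
k-NN / RBF-SVM / decision-tree / LightGBM baseline-vs-proposed
comparisons).

## Worked example

Fifty-column cohort with five planted columns at effect size 2.0 SD,
stratified 75/25 split, selection with pack 10 for 100 iterations:

```python
import numpy as np
from ebgwo import *
from ebgwo.synthetic_cohort import FeatureSchema

schema = FeatureSchema(groups=[("vocal", "vocal", 49), ("gender", "demographic", 1)])
table, truth = generate_cohort(schema, CohortSpec(n_informative=5, effect_size=2.0, seed=11))
train, test = stratified_split(table, 0.25, seed=0)
params = standardize_fit(train)
train, test = standardize_apply(train, params), standardize_apply(test, params)

result = select_features(train, GWOConfig(dim=50, pack_size=10, max_iter=100, seed=0),
                         FitnessSpec())
print(f"selected {result.n_selected}/50 features, best fitness {result.best_fitness:.4f}")
print(f"planted columns recovered: {len(set(result.selected_names) & truth)}/5")
```

prints

```
selected 8/50 features, best fitness 0.0016
planted columns recovered: 4/5
```

The best fitness 0.0016 = 0.99 × 0 + 0.01 × 8/50: the selected mask
classifies the internal validation holdout perfectly, and only the
feature-ratio term remains. Evaluating k-NN and LightGBM on the held-out
test partition, baseline (all 50 columns) versus proposed (the 8
selected):

```
knn       baseline  acc=0.989 recall=0.993 auc=0.999
knn       proposed  acc=0.989 recall=0.993 auc=1.000
lightgbm  baseline  acc=0.989 recall=1.000 auc=0.999
lightgbm  proposed  acc=0.989 recall=0.993 auc=0.999
```

— an 84% reduction in dimensionality at no accuracy cost.

## Command line

```sh
ebgwo synth --cases 188 --controls 64 --reps 3 --informative 40 --effect 1.0 --seed 1 --out cohort/
ebgwo run --synthetic --seed 1 --iters 200 --out results/      # full pipeline
ebgwo select --data cohort/cohort.csv --iters 1000 --pack 10 --out sel/
ebgwo evaluate --data cohort/cohort.csv --mask sel/selection.json --out eval/
```

`run` writes `report.csv` (classifier × variant metric rows), the
selection mask, the convergence trace, and per-classifier confusion
matrices; everything is reproducible from the single `--seed`.

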