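"""Enhanced binary grey wolf optimization for wrapper feature selection.

Wolves live in the unit hypercube; a steep sigmoid transfer function,
sigmoid(x) = 1 / (1 + exp(-10 (x - 0.5))), converts each coordinate into
an inclusion probability and stochastic thresholding yields a binary
feature mask.  Mask quality is the wrapper fitness

    fitness = alpha * ER(D) + (1 - alpha) * |R| / |C|

where ER(D) is the validation error rate of a k-nearest-neighbour
induction classifier restricted to the masked columns, |R| the number of
selected features and |C| the total.  With alpha = 0.99 the error term
dominates and the feature-ratio term applies gentle parsimony pressure.

Position updates mix three mechanisms per wolf per iteration: with
probability ``explore_prob`` the wolf jumps to the mean of three random
pack members (exploration); otherwise it takes the leader-guided
encircling move; either way a Levy perturbation around the current alpha
follows with probability ``levy_prob``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.neighbors import KNeighborsClassifier

from .feature_io import FeatureTable, FeatureTableError, stratified_split
from .gwo_engine import GWOConfig, a_schedule, leader_guided_position, levy_perturb

__all__ = [
    "ValidationScheme",
    "FitnessSpec",
    "FitnessResult",
    "SelectionResult",
    "sigmoid_transfer",
    "binarize",
    "random_triplet_position",
    "wrapper_fitness",
    "select_features",
]


def sigmoid_transfer(x):
    """Steep sigmoid mapping a unit-interval coordinate to an inclusion
    probability: 1 / (1 + exp(-10 (x - 0.5))).  Accepts scalars or arrays."""
    from scipy.special import expit

    return expit(10.0 * (np.asarray(x, dtype=float) - 0.5))


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic thresholding of a continuous position into a 0/1 mask:
    dimension i is included when sigmoid(position[i]) >= U(0,1)."""
    position = np.asarray(position, dtype=float)
    return (sigmoid_transfer(position) >= rng.random(position.shape[0])).astype(
        np.int8
    )


def random_triplet_position(
    positions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exploration move: the mean of three distinct pack members chosen
    uniformly at random."""
    positions = np.asarray(positions)
    if positions.shape[0] < 3:
        raise ValueError("random triplet needs a pack of at least 3 wolves")
    idx = rng.choice(positions.shape[0], size=3, replace=False)
    return positions[idx].mean(axis=0)


@dataclass
class ValidationScheme:
    """How the induction classifier's error rate is estimated inside the
    training partition: a stratified holdout (``kind='holdout'``, ``param``
    is the held-out fraction) or stratified k-fold (``kind='kfold'``,
    ``param`` is the fold count).  ``seed=None`` means "resolve from the
    selection run's seed", which keeps fitness a deterministic function
    of the mask within one run."""

    kind: str = "holdout"
    param: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("holdout", "kfold"):
            raise ValueError("validation kind must be 'holdout' or 'kfold'")
        if self.kind == "holdout" and not 0.0 < self.param < 1.0:
            raise ValueError("holdout fraction must lie in (0, 1)")
        if self.kind == "kfold" and int(self.param) < 2:
            raise ValueError("k-fold needs at least 2 folds")

    def resolved(self, fallback_seed: int) -> "ValidationScheme":
        if self.seed is not None:
            return self
        return ValidationScheme(self.kind, self.param, fallback_seed)


@dataclass
class FitnessSpec:
    """Weights and induction classifier for the wrapper fitness."""

    alpha_weight: float = 0.99
    induction_k: int = 5
    validation: ValidationScheme = field(default_factory=ValidationScheme)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_weight <= 1.0:
            raise ValueError("alpha_weight must lie in [0, 1]")
        if self.induction_k < 1 or self.induction_k % 2 == 0:
            raise ValueError("induction_k must be a positive odd integer")

    @property
    def beta_weight(self) -> float:
        return 1.0 - self.alpha_weight


@dataclass
class FitnessResult:
    """One wrapper-fitness evaluation.  An empty mask carries the +inf
    sentinel (worst possible) with an undefined error rate."""

    error_rate: float
    n_selected: int
    n_total: int
    fitness: float

    @property
    def is_empty_mask(self) -> bool:
        return self.n_selected == 0


def _holdout_error(
    sub: FeatureTable, k: int, fraction: float, seed: int
) -> float:
    try:
        inner_train, inner_val = stratified_split(sub, fraction, seed)
    except FeatureTableError as exc:
        raise FeatureTableError(
            f"validation split failed ({exc}); try a different validation "
            "seed or scheme"
        ) from exc
    if len(np.unique(inner_val.labels)) < 2 or len(np.unique(inner_train.labels)) < 2:
        raise FeatureTableError(
            "single-class validation fold; try a different validation seed or scheme"
        )
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(inner_train.values, inner_train.labels)
    pred = clf.predict(inner_val.values)
    return float(np.mean(pred != inner_val.labels))


def _kfold_error(sub: FeatureTable, k: int, n_folds: int, seed: int) -> float:
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for tr, va in skf.split(sub.values, sub.labels):
        if len(np.unique(sub.labels[tr])) < 2:
            raise FeatureTableError(
                "single-class validation fold; try a different validation "
                "seed or scheme"
            )
        clf = KNeighborsClassifier(n_neighbors=k)
        clf.fit(sub.values[tr], sub.labels[tr])
        errors.append(np.mean(clf.predict(sub.values[va]) != sub.labels[va]))
    return float(np.mean(errors))


def wrapper_fitness(
    mask: np.ndarray,
    train: FeatureTable,
    spec: FitnessSpec,
    rng: np.random.Generator | None = None,
) -> FitnessResult:
    """Evaluate one feature mask on the training partition.

    The validation scheme's seed must either be set on the spec or be
    derivable from ``rng`` (drawn once per call in that case — prefer a
    resolved seed for deterministic fitness).
    """
    mask = np.asarray(mask).astype(bool)
    n_total = train.n_features
    if mask.shape != (n_total,):
        raise ValueError("mask length must equal the training feature count")
    n_sel = int(mask.sum())
    if n_sel == 0:
        return FitnessResult(math.nan, 0, n_total, math.inf)

    scheme = spec.validation
    if scheme.seed is None:
        if rng is None:
            raise ValueError("validation seed unresolved and no rng given")
        scheme = scheme.resolved(int(rng.integers(2**31)))

    sub = train.select_features(mask)
    if scheme.kind == "holdout":
        er = _holdout_error(sub, spec.induction_k, scheme.param, scheme.seed)
    else:
        er = _kfold_error(sub, spec.induction_k, int(scheme.param), scheme.seed)
    fitness = spec.alpha_weight * er + spec.beta_weight * n_sel / n_total
    return FitnessResult(er, n_sel, n_total, fitness)


@dataclass
class SelectionResult:
    """Outcome of one selection run."""

    mask: np.ndarray
    selected_names: list[str]
    best_fitness: float
    trace: np.ndarray  # per-iteration best-so-far fitness
    trace_n_selected: np.ndarray  # per-iteration best-so-far mask size
    config: dict[str, Any]
    seed: int

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    def to_dict(self) -> dict[str, Any]:
        return {
            "selected": self.selected_names,
            "mask": "".join(str(int(b)) for b in self.mask),
            "best_fitness": self.best_fitness,
            "n_iterations": int(self.trace.shape[0]),
            "seed": self.seed,
            "config": self.config,
        }


def _rank_key(fit: FitnessResult, index: int) -> tuple[float, int, int]:
    # ties: better fitness, then fewer features, then lower wolf index
    return (fit.fitness, fit.n_selected, index)


def _best_single_feature(
    train: FeatureTable, spec: FitnessSpec
) -> tuple[np.ndarray, FitnessResult]:
    best = None
    for j in range(train.n_features):
        mask = np.zeros(train.n_features, dtype=np.int8)
        mask[j] = 1
        res = wrapper_fitness(mask, train, spec)
        if best is None or res.fitness < best[1].fitness:
            best = (mask, res)
    return best  # type: ignore[return-value]


def select_features(
    train: FeatureTable,
    gwo_config: GWOConfig,
    fitness_spec: FitnessSpec,
) -> SelectionResult:
    """Run the full binary selection loop on a (standardized) training table.

    Each iteration: binarize every wolf and evaluate the wrapper fitness,
    refresh the best-so-far leader triple, then move every wolf by the
    exploration / leader-guided / Levy mix.  Fitness evaluations are
    cached by mask, and the validation seed is resolved once per run, so
    fitness is a pure function of the mask.  The returned mask always
    contains at least one feature.
    """
    if gwo_config.dim != train.n_features:
        raise ValueError(
            f"gwo_config.dim={gwo_config.dim} != feature count {train.n_features}"
        )
    if len(np.unique(train.labels)) < 2:
        raise FeatureTableError("training table must contain both classes")

    rng = np.random.default_rng(gwo_config.seed)
    spec = FitnessSpec(
        alpha_weight=fitness_spec.alpha_weight,
        induction_k=fitness_spec.induction_k,
        validation=fitness_spec.validation.resolved(
            int(np.random.SeedSequence(gwo_config.seed).generate_state(1)[0] % 2**31)
        ),
    )

    lo, hi = gwo_config.bounds
    positions = rng.uniform(lo, hi, (gwo_config.pack_size, gwo_config.dim))

    cache: dict[bytes, FitnessResult] = {}

    def evaluate(mask: np.ndarray) -> FitnessResult:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = wrapper_fitness(mask, train, spec)
        return cache[key]

    leaders: list[tuple[np.ndarray, FitnessResult, tuple]] = []
    best_mask: np.ndarray | None = None
    best_fit: FitnessResult | None = None
    trace = np.empty(gwo_config.max_iter)
    trace_n = np.empty(gwo_config.max_iter, dtype=int)
    counter = 0  # global evaluation index for deterministic tie-breaks

    for t in range(gwo_config.max_iter):
        evals: list[tuple[np.ndarray, FitnessResult, tuple]] = []
        for i in range(gwo_config.pack_size):
            mask = binarize(positions[i], rng)
            res = evaluate(mask)
            evals.append((positions[i].copy(), res, _rank_key(res, counter)))
            counter += 1
            if (
                res.n_selected > 0
                and (
                    best_fit is None
                    or (res.fitness, res.n_selected)
                    < (best_fit.fitness, best_fit.n_selected)
                )
            ):
                best_fit, best_mask = res, mask.copy()
        leaders = sorted(leaders + evals, key=lambda e: e[2])[:3]
        trace[t] = best_fit.fitness if best_fit is not None else math.inf
        trace_n[t] = best_fit.n_selected if best_fit is not None else 0

        if t == gwo_config.max_iter - 1:
            break
        a = a_schedule(t, gwo_config.max_iter)
        leader_positions = [e[0] for e in leaders]
        alpha_position = leaders[0][0]
        for i in range(gwo_config.pack_size):
            if rng.random() < gwo_config.explore_prob:
                x = np.clip(random_triplet_position(positions, rng), lo, hi)
            else:
                x = leader_guided_position(
                    positions[i], leader_positions, a, rng, gwo_config.bounds
                )
            if rng.random() < gwo_config.levy_prob:
                x = levy_perturb(
                    x,
                    alpha_position,
                    gwo_config.levy_alpha,
                    gwo_config.levy_beta,
                    rng,
                    gwo_config.bounds,
                )
            positions[i] = x

    if best_mask is None:  # every evaluated mask was empty (pathological)
        best_mask, best_fit = _best_single_feature(train, spec)
        trace[:] = np.minimum.accumulate(
            np.where(np.isfinite(trace), trace, best_fit.fitness)
        )
        trace_n[:] = best_fit.n_selected

    selected = [n for n, b in zip(train.feature_names, best_mask) if b]
    config_snapshot = {
        "pack_size": gwo_config.pack_size,
        "max_iter": gwo_config.max_iter,
        "dim": gwo_config.dim,
        "levy_beta": gwo_config.levy_beta,
        "levy_alpha": gwo_config.levy_alpha,
        "levy_prob": gwo_config.levy_prob,
        "explore_prob": gwo_config.explore_prob,
        "alpha_weight": spec.alpha_weight,
        "induction_k": spec.induction_k,
        "validation": {
            "kind": spec.validation.kind,
            "param": spec.validation.param,
            "seed": spec.validation.seed,
        },
    }
    return SelectionResult(
        mask=best_mask.astype(np.int8),
        selected_names=selected,
        best_fitness=float(best_fit.fitness),
        trace=trace,
        trace_n_selected=trace_n,
        config=config_snapshot,
        seed=gwo_config.seed,
    )
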