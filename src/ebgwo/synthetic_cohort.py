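"""Seeded synthetic vocal-biomarker cohorts.

Emulates the geometry of the Istanbul Parkinson's speech table: 252
subjects (188 cases, 64 controls), three sustained-vowel recordings per
subject, and ~750 numeric columns organised into the standard dysphonia
feature families (baseline jitter/shimmer/F0, time-frequency, MFCC,
wavelet, vocal-fold, TQWT) plus a demographic gender column.  Features
are Gaussian blocks; a configurable subset of "informative" columns gets
a between-class mean shift so wrapper selection has a planted truth to
recover.  No acoustic signal processing is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_io import FeatureTable

__all__ = [
    "FeatureSchema",
    "CohortSpec",
    "default_schema",
    "generate_cohort",
    "planted_column_audit",
]

# (subgroup name, family tag, column count); family sizes: baseline 21,
# time-frequency 11, MFCC 84 (14 base signals x 3 derivative orders x 2
# statistics), WT 182, vocal-fold 22, TQWT 432 -> 752 vocal columns,
# plus one demographic column.
_DEFAULT_SUBGROUPS: list[tuple[str, str, int]] = [
    ("jitter", "baseline", 5),
    ("shimmer", "baseline", 6),
    ("f0", "baseline", 5),
    ("harmonicity", "baseline", 2),
    ("rpde", "baseline", 1),
    ("dfa", "baseline", 1),
    ("ppe", "baseline", 1),
    ("intensity", "time_frequency", 3),
    ("formant", "time_frequency", 4),
    ("bandwidth", "time_frequency", 4),
    ("mfcc", "mfcc", 84),
    ("wt", "wt", 182),
    ("gq", "vocal_fold", 3),
    ("gne", "vocal_fold", 6),
    ("vfer", "vocal_fold", 7),
    ("emd", "vocal_fold", 6),
    ("tqwt", "tqwt", 432),
    ("gender", "demographic", 1),
]

# male fractions observed in the source cohort (107/188 cases, 23/64 controls)
_MALE_RATE_CASE = 107 / 188
_MALE_RATE_CONTROL = 23 / 64


@dataclass
class FeatureSchema:
    """Named feature groups with column counts.

    ``groups`` is an ordered list of (subgroup_name, family_tag, count).
    """

    groups: list[tuple[str, str, int]] = field(
        default_factory=lambda: list(_DEFAULT_SUBGROUPS)
    )

    def __post_init__(self) -> None:
        names = [g[0] for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if any(g[2] < 1 for g in self.groups):
            raise ValueError("every group needs at least one column")

    def group_count(self, family_or_name: str) -> int:
        """Total columns whose subgroup name or family tag matches."""
        return sum(c for n, fam, c in self.groups if family_or_name in (n, fam))

    @property
    def column_names(self) -> list[str]:
        names = []
        for sub, _fam, count in self.groups:
            if count == 1:
                names.append(sub)
            else:
                names.extend(f"{sub}_{i}" for i in range(1, count + 1))
        return names

    @property
    def group_of(self) -> dict[str, str]:
        out = {}
        for sub, fam, count in self.groups:
            cols = [sub] if count == 1 else [f"{sub}_{i}" for i in range(1, count + 1)]
            out.update({c: fam for c in cols})
        return out

    @property
    def n_columns(self) -> int:
        return sum(c for _, _, c in self.groups)


@dataclass
class CohortSpec:
    """Cohort geometry and planted signal strength.

    Defaults reproduce the source cohort: 188 case and 64 control
    subjects, each contributing 3 recordings.  ``effect_size`` is the
    standardized between-class mean difference planted in
    ``n_informative`` randomly chosen vocal columns;
    ``within_subject_rho`` is the correlation between a subject's
    repeated recordings of the same column.
    """

    n_cases: int = 188
    n_controls: int = 64
    recordings_per_subject: int = 3
    n_informative: int = 40
    effect_size: float = 1.0
    within_subject_rho: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.recordings_per_subject) < 1:
            raise ValueError("cohort counts must be positive")
        if not 0.0 <= self.within_subject_rho < 1.0:
            raise ValueError("within_subject_rho must lie in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.n_informative < 0:
            raise ValueError("n_informative must be non-negative")


def default_schema() -> FeatureSchema:
    """The standard dysphonia feature taxonomy used by the source table."""
    return FeatureSchema()


def generate_cohort(
    schema: FeatureSchema | None = None,
    spec: CohortSpec | None = None,
) -> tuple[FeatureTable, set[str]]:
    """Draw a seeded synthetic cohort.

    Each feature column has unit marginal variance, decomposed into a
    subject-level component (variance ``within_subject_rho``) shared by a
    subject's recordings and an independent per-recording residual.
    Informative columns add ``effect_size`` to case rows, so the planted
    shift is in standard-deviation units.  The gender column is Bernoulli
    per subject at the source cohort's male rates and is never
    informative by construction (its class association comes only from
    those rates).

    Returns the table and the set of informative column names.
    """
    schema = schema or default_schema()
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)

    names = schema.column_names
    group_of = schema.group_of
    vocal_cols = [j for j, n in enumerate(names) if group_of[n] != "demographic"]
    if spec.n_informative > len(vocal_cols):
        raise ValueError(
            f"n_informative={spec.n_informative} exceeds the "
            f"{len(vocal_cols)} vocal columns"
        )
    informative = sorted(
        rng.choice(vocal_cols, size=spec.n_informative, replace=False).tolist()
    )

    n_subj = spec.n_cases + spec.n_controls
    reps = spec.recordings_per_subject
    n_rows = n_subj * reps
    p = schema.n_columns

    subj_labels = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    subj_ids = np.array(
        [f"case_{i + 1:03d}" for i in range(spec.n_cases)]
        + [f"ctrl_{i + 1:03d}" for i in range(spec.n_controls)]
    )
    row_subject = np.repeat(np.arange(n_subj), reps)

    rho = spec.within_subject_rho
    subject_part = rng.standard_normal((n_subj, p))
    residual = rng.standard_normal((n_rows, p))
    values = np.sqrt(rho) * subject_part[row_subject] + np.sqrt(1 - rho) * residual

    labels = subj_labels[row_subject]
    values[np.ix_(labels == 1, informative)] += spec.effect_size

    male = np.empty(n_subj)
    male[: spec.n_cases] = rng.random(spec.n_cases) < _MALE_RATE_CASE
    male[spec.n_cases :] = rng.random(spec.n_controls) < _MALE_RATE_CONTROL
    gender_col = names.index("gender")
    values[:, gender_col] = male[row_subject]

    table = FeatureTable(
        feature_names=names,
        values=values,
        labels=labels,
        subject_ids=subj_ids[row_subject],
        group_of=group_of,
    )
    return table, {names[j] for j in informative}


def planted_column_audit(
    table: FeatureTable, truth: set[str]
) -> dict[str, float]:
    """Observed standardized mean difference (case minus control, pooled
    SD) for each named column; the audit set is whatever columns the
    caller asks about."""
    labels = table.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("audit needs both classes present")
    out: dict[str, float] = {}
    pos = labels == 1
    for name in sorted(truth):
        j = table.feature_names.index(name)
        col = table.values[:, j]
        a, b = col[pos], col[~pos]
        va = a.var(ddof=1) * (a.size - 1)
        vb = b.var(ddof=1) * (b.size - 1)
        pooled = np.sqrt((va + vb) / (a.size + b.size - 2))
        out[name] = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
    return out
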