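import numpy as np
import pytest

from ebgwo.feature_io import FeatureTable, standardize_apply, standardize_fit
from ebgwo.synthetic_cohort import CohortSpec, FeatureSchema, generate_cohort


@pytest.fixture(scope="session")
def small_schema() -> FeatureSchema:
    """A 50-column schema (49 vocal + gender) for fast wrapper loops."""
    return FeatureSchema(groups=[("vocal", "vocal", 49), ("gender", "demographic", 1)])


@pytest.fixture(scope="session")
def planted_cohort(small_schema):
    """Full-size cohort geometry (756 rows) with 5 planted columns at
    effect 2.0 on 50 features."""
    spec = CohortSpec(n_informative=5, effect_size=2.0, seed=42)
    table, truth = generate_cohort(small_schema, spec)
    return table, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 188 cases + 64 controls, 3 recordings
    each, full 753-column schema."""
    table, truth = generate_cohort(spec=CohortSpec(seed=7))
    return table, truth


@pytest.fixture()
def toy_table() -> FeatureTable:
    rng = np.random.default_rng(0)
    n = 24
    labels = np.repeat([1, 0], n // 2)
    values = rng.standard_normal((n, 4))
    values[:, 0] += 3.0 * labels  # one strongly separating column
    return FeatureTable(
        feature_names=["sep", "noise1", "noise2", "noise3"],
        values=values,
        labels=labels,
        subject_ids=np.array([f"s{i}" for i in range(n)]),
    )


@pytest.fixture()
def separable_table() -> FeatureTable:
    """40 rows, 2 features, classes at (-5,-5) vs (5,5): trivially separable."""
    rng = np.random.default_rng(1)
    labels = np.repeat([0, 1], 20)
    values = rng.standard_normal((40, 2)) * 0.3 + np.where(labels[:, None] == 1, 5.0, -5.0)
    return FeatureTable(
        feature_names=["f1", "f2"],
        values=values,
        labels=labels,
        subject_ids=np.arange(40),
    )


def standardized(table: FeatureTable) -> FeatureTable:
    return standardize_apply(table, standardize_fit(table))
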