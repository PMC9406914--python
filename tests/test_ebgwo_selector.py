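"""Binary transfer, wrapper fitness, and the full selection loop."""

import math

import numpy as np
import pytest

from conftest import standardized
from ebgwo.ebgwo_selector import (
    FitnessSpec,
    ValidationScheme,
    binarize,
    random_triplet_position,
    select_features,
    sigmoid_transfer,
    wrapper_fitness,
)
from ebgwo.feature_io import FeatureTable, FeatureTableError
from ebgwo.gwo_engine import GWOConfig


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_transfer(0.5) == pytest.approx(0.5)

    def test_direct_evaluation(self):
        assert sigmoid_transfer(0.6) == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-9)

    def test_limits(self):
        assert sigmoid_transfer(100.0) == pytest.approx(1.0)
        assert sigmoid_transfer(-100.0) == pytest.approx(0.0, abs=1e-12)


class TestBinarize:
    def test_extreme_positions_are_deterministic(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            assert np.all(binarize(np.full(20, 10.0), rng) == 1)
            assert np.all(binarize(np.full(20, -10.0), rng) == 0)

    def test_midpoint_inclusion_frequency(self):
        rng = np.random.default_rng(0)
        draws = np.array([binarize(np.full(10, 0.5), rng) for _ in range(1000)])
        assert abs(draws.mean() - 0.5) < 0.02


class TestRandomTriplet:
    def test_coincident_pack(self):
        pack = np.tile([0.2, 0.8], (6, 1))
        out = random_triplet_position(pack, np.random.default_rng(0))
        np.testing.assert_allclose(out, [0.2, 0.8])

    def test_mean_of_three_member_pack(self):
        pack = np.array([[0.0], [3.0], [6.0]])
        out = random_triplet_position(pack, np.random.default_rng(1))
        np.testing.assert_allclose(out, [3.0])

    def test_record_and_replay(self):
        pack = np.random.default_rng(2).random((8, 3))
        seed = 4
        out = random_triplet_position(pack, np.random.default_rng(seed))
        idx = np.random.default_rng(seed).choice(8, size=3, replace=False)
        np.testing.assert_allclose(out, pack[idx].mean(axis=0))

    def test_small_pack_rejected(self):
        with pytest.raises(ValueError):
            random_triplet_position(np.zeros((2, 1)), np.random.default_rng(0))


def separable_wide_table(n_features: int, n_rows: int = 60) -> FeatureTable:
    """Column 0 separates the classes perfectly; the rest is noise."""
    rng = np.random.default_rng(0)
    labels = np.repeat([1, 0], n_rows // 2)
    values = rng.standard_normal((n_rows, n_features)) * 0.1
    values[:, 0] = np.where(labels == 1, 5.0, -5.0) + rng.standard_normal(n_rows) * 0.1
    return FeatureTable(
        feature_names=[f"f{j}" for j in range(n_features)],
        values=values,
        labels=labels,
        subject_ids=np.arange(n_rows),
    )


class TestWrapperFitness:
    def test_combination_identity(self, toy_table):
        spec = FitnessSpec(validation=ValidationScheme(seed=3))
        mask = np.array([1, 1, 0, 0])
        res = wrapper_fitness(mask, standardized(toy_table), spec)
        assert res.fitness == pytest.approx(
            spec.alpha_weight * res.error_rate
            + spec.beta_weight * res.n_selected / res.n_total,
            abs=1e-12,
        )
        assert res.n_selected == 2 and res.n_total == 4

    def test_alpha_one_reduces_to_error_rate(self, toy_table):
        spec = FitnessSpec(alpha_weight=1.0, validation=ValidationScheme(seed=3))
        res = wrapper_fitness(np.array([1, 0, 1, 0]), standardized(toy_table), spec)
        assert res.fitness == pytest.approx(res.error_rate)

    def test_zero_error_single_column_of_754(self):
        # ER = 0 on the separating column: fitness = 0.01 * (1/754)
        table = separable_wide_table(754)
        mask = np.zeros(754, dtype=int)
        mask[0] = 1
        res = wrapper_fitness(
            mask, table, FitnessSpec(validation=ValidationScheme(seed=1))
        )
        assert res.error_rate == 0.0
        assert res.fitness == pytest.approx(0.01 * (1 / 754), abs=1e-12)

    def test_printed_ratio_arithmetic(self):
        # alpha 0.99, ER 0.10, 367 of 754 selected -> 0.99*0.10 + 0.01*367/754
        fitness = 0.99 * 0.10 + 0.01 * 367 / 754
        assert fitness == pytest.approx(0.10387, abs=5e-6)

    def test_empty_mask_is_worst_sentinel(self, toy_table):
        res = wrapper_fitness(
            np.zeros(4, dtype=int),
            standardized(toy_table),
            FitnessSpec(validation=ValidationScheme(seed=0)),
        )
        assert math.isinf(res.fitness) and res.is_empty_mask
        assert math.isnan(res.error_rate)

    def test_parsimony_pressure_for_fixed_error(self):
        table = separable_wide_table(20)
        spec = FitnessSpec(validation=ValidationScheme(seed=2))
        fits = []
        for extra in (0, 4, 8):
            mask = np.zeros(20, dtype=int)
            mask[0] = 1
            mask[1 : 1 + extra] = 1
            res = wrapper_fitness(mask, table, spec)
            assert res.error_rate == 0.0  # column 0 dominates
            fits.append(res.fitness)
        assert fits[0] < fits[1] < fits[2]

    def test_error_pressure_for_fixed_size(self):
        table = separable_wide_table(20)
        spec = FitnessSpec(validation=ValidationScheme(seed=2))
        good = np.zeros(20, dtype=int)
        good[0] = 1
        bad = np.zeros(20, dtype=int)
        bad[5] = 1  # noise column
        res_good = wrapper_fitness(good, table, spec)
        res_bad = wrapper_fitness(bad, table, spec)
        assert res_bad.error_rate > res_good.error_rate
        assert res_bad.fitness > res_good.fitness

    def test_kfold_validation_scheme(self, toy_table):
        spec = FitnessSpec(validation=ValidationScheme("kfold", 3, seed=5))
        res = wrapper_fitness(np.array([1, 1, 1, 1]), standardized(toy_table), spec)
        assert 0.0 <= res.error_rate <= 1.0

    def test_degenerate_fold_advises_new_scheme(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(
            ["f0"],
            rng.standard_normal((10, 1)),
            np.array([1] * 8 + [0] * 2),
            np.arange(10),
        )
        spec = FitnessSpec(validation=ValidationScheme("holdout", 0.1, seed=0))
        with pytest.raises(FeatureTableError, match="seed or scheme"):
            wrapper_fitness(np.array([1]), table, spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            FitnessSpec(alpha_weight=1.5)
        with pytest.raises(ValueError):
            FitnessSpec(induction_k=4)
        with pytest.raises(ValueError):
            ValidationScheme("bootstrap")


class TestSelectFeatures:
    def test_single_feature_table_selects_it(self):
        rng = np.random.default_rng(0)
        table = FeatureTable(
            ["only"],
            rng.standard_normal((40, 1)),
            np.repeat([0, 1], 20),
            np.arange(40),
        )
        cfg = GWOConfig(dim=1, pack_size=4, max_iter=5, seed=0)
        res = select_features(table, cfg, FitnessSpec())
        assert res.mask.tolist() == [1]
        assert res.selected_names == ["only"]

    def test_trace_monotone_and_result_consistent(self):
        table = separable_wide_table(15)
        cfg = GWOConfig(dim=15, pack_size=6, max_iter=25, seed=3)
        res = select_features(table, cfg, FitnessSpec())
        assert np.all(np.diff(res.trace) <= 1e-15)
        assert res.n_selected == len(res.selected_names) >= 1
        # reported fitness must reproduce under the stored validation scheme
        spec = FitnessSpec(
            validation=ValidationScheme(**res.config["validation"])
        )
        recomputed = wrapper_fitness(res.mask, table, spec)
        assert recomputed.fitness == pytest.approx(res.best_fitness, abs=1e-12)

    def test_bit_reproducible_under_equal_seeds(self):
        table = separable_wide_table(12)
        cfg = GWOConfig(dim=12, pack_size=5, max_iter=15, seed=21)
        a = select_features(table, cfg, FitnessSpec())
        b = select_features(table, cfg, FitnessSpec())
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_array_equal(a.trace, b.trace)
        assert a.best_fitness == b.best_fitness

    def test_finds_the_separating_column(self):
        table = separable_wide_table(15)
        cfg = GWOConfig(dim=15, pack_size=8, max_iter=40, seed=1)
        res = select_features(table, cfg, FitnessSpec())
        assert "f0" in res.selected_names

    def test_dim_mismatch_rejected(self, toy_table):
        cfg = GWOConfig(dim=99, pack_size=4, max_iter=2, seed=0)
        with pytest.raises(ValueError, match="dim"):
            select_features(standardized(toy_table), cfg, FitnessSpec())
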