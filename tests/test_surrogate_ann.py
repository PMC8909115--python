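"""Surrogate pipeline: splits, normalization, ensemble training, persistence."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tribochar._errors import (
    DegenerateNormalizationError,
    ExtrapolationWarning,
    InvalidParameterError,
)
from tribochar.particle_tracking import TrackingConfig, run_condition
from tribochar.surrogate_ann import (
    FEATURES,
    MinMaxNormalizer,
    SurrogateDataset,
    assign_splits,
    build_database,
    latin_hypercube_plan,
    neuron_sweep,
    train_ensemble,
)
from tribochar.io_fixtures import derive_seed
from tribochar.surrogate_ann import _condition_from_row

from conftest import synthetic_dataset


class TestSplits:
    def test_canonical_197_split(self):
        split = assign_splits(197, seed=0)
        assert (split == "train").sum() == 137
        assert (split == "validation").sum() == 30
        assert (split == "test").sum() == 30

    def test_floor_rule_on_100(self):
        split = assign_splits(100, seed=1)
        assert [(split == s).sum() for s in ("train", "validation", "test")] == [70, 15, 15]

    def test_partition_is_exhaustive_and_disjoint(self):
        split = assign_splits(197, seed=2)
        assert len(split) == 197  # every index appears exactly once by construction
        assert set(split) == {"train", "validation", "test"}

    def test_seeded_reproducibility(self):
        np.testing.assert_array_equal(assign_splits(50, seed=3), assign_splits(50, seed=3))


class TestNormalizer:
    def test_endpoints_map_to_unit_interval(self):
        ds = synthetic_dataset(60, seed=4)
        x_tr, _ = ds.subset("train")
        xn = ds.normalizer.transform(x_tr)
        assert xn.min() == pytest.approx(0.0, abs=1e-12)
        assert xn.max() == pytest.approx(1.0, abs=1e-12)

    def test_round_trip_identity(self):
        ds = synthetic_dataset(60, seed=5)
        x = ds.features.to_numpy(float)
        back = ds.normalizer.inverse_transform(ds.normalizer.transform(x, warn=False))
        np.testing.assert_allclose(back, x, rtol=1e-12)
        y = ds.targets
        np.testing.assert_allclose(
            ds.normalizer.inverse_transform_target(ds.normalizer.transform_target(y)),
            y, rtol=1e-12,
        )

    def test_constant_feature_rejected_by_name(self):
        x = np.random.default_rng(0).random((20, 6))
        x[:, 2] = 0.004  # constant pipe diameter
        with pytest.raises(DegenerateNormalizationError, match="pipe_diameter_m"):
            MinMaxNormalizer.fit(x, np.arange(20.0))

    def test_out_of_range_point_warns(self):
        ds = synthetic_dataset(60, seed=6)
        outside = ds.normalizer.feature_max * 1.5
        with pytest.warns(ExtrapolationWarning):
            xn = ds.normalizer.transform(outside[None, :])
        assert (xn > 1).any()


class TestBuildDatabase:
    def test_singleton_plan_equals_direct_simulation(self):
        plan = latin_hypercube_plan(1, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ds = build_database(plan=plan, n_particles=20, seed=7)
            cond = _condition_from_row(plan.iloc[0])
            direct = run_condition(
                cond,
                config=TrackingConfig(n_particles=20, rng_seed=derive_seed(7, "db-point", 0)),
            )
        assert len(ds) == 1
        assert ds.targets[0] == direct.mean_collision_number

    def test_same_seed_same_database(self):
        plan = latin_hypercube_plan(3, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = build_database(plan=plan, n_particles=10, seed=8)
            b = build_database(plan=plan, n_particles=10, seed=8)
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(a.split, b.split)

    def test_plan_missing_columns_rejected(self):
        with pytest.raises(InvalidParameterError, match="feature column"):
            build_database(plan=pd.DataFrame({"particle_size_um": [100.0]}))

    def test_full_database_shape_and_provenance(self, database):
        assert len(database) == 197
        assert database.provenance["n_failed"] == 0
        frame = database.to_frame()
        assert set(FEATURES) < set(frame.columns)
        assert frame["mean_collision_number"].between(0, 200).all()


class TestEnsemble:
    def test_constant_target_is_learned_exactly(self):
        ds = synthetic_dataset(60, seed=9, constant=5.0)
        ens = train_ensemble(ds, hidden_neurons=3, n_members=3, seed=9)
        assert ens.mean_rmse <= 1e-3

    def test_prediction_is_member_mean(self):
        ds = synthetic_dataset(80, seed=10)
        ens = train_ensemble(ds, hidden_neurons=4, n_members=4, seed=10)
        pts = ds.features.iloc[:5]
        np.testing.assert_allclose(
            ens.predict(pts), ens.predict_members(pts).mean(axis=0), rtol=1e-12
        )

    def test_beats_train_mean_baseline(self):
        ds = synthetic_dataset(120, seed=11)
        ens = train_ensemble(ds, hidden_neurons=6, n_members=5, seed=11)
        x_te, y_te = ds.subset("test")
        _, y_tr = ds.subset("train")
        baseline = float(np.sqrt(np.mean((y_tr.mean() - y_te) ** 2)))
        pred = ens.predict(ds.features[ds.split == "test"])
        rmse = float(np.sqrt(np.mean((pred - y_te) ** 2)))
        assert rmse < baseline

    def test_json_round_trip(self, tmp_path):
        ds = synthetic_dataset(80, seed=12)
        ens = train_ensemble(ds, hidden_neurons=4, n_members=3, seed=12)
        path = tmp_path / "model.json"
        ens.to_json(path)
        from tribochar.surrogate_ann import SurrogateEnsemble

        loaded = SurrogateEnsemble.from_json(path)
        pts = ds.features.iloc[:7]
        np.testing.assert_allclose(loaded.predict(pts), ens.predict(pts), rtol=1e-12)
        assert loaded.hidden_neurons == ens.hidden_neurons

    def test_training_determinism(self):
        ds = synthetic_dataset(80, seed=13)
        a = train_ensemble(ds, hidden_neurons=4, n_members=2, seed=13)
        b = train_ensemble(ds, hidden_neurons=4, n_members=2, seed=13)
        pts = ds.features.iloc[:5]
        np.testing.assert_allclose(a.predict(pts), b.predict(pts), rtol=1e-12)


class TestNeuronSweep:
    def test_table_shape_and_determinism(self):
        ds = synthetic_dataset(80, seed=14)
        a = neuron_sweep(ds, candidates=range(1, 11), repeats=1, seed=14)
        b = neuron_sweep(ds, candidates=range(1, 11), repeats=1, seed=14)
        assert len(a) == 10
        assert list(a.hidden_neurons) == list(range(1, 11))
        np.testing.assert_allclose(a.mean_rmse, b.mean_rmse, rtol=1e-12)
        assert a.is_best.sum() >= 1
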