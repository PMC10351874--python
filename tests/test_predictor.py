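"""Splitting, target alignment, LSTM training and prediction."""

import dataclasses

import numpy as np
import pytest

from myoankle import (
    FeatureSet,
    ModelSpec,
    MuscleSet,
    WindowSpec,
    align_targets,
    extract_feature_matrix,
    generate_dataset,
    hidden_unit_sweep,
    load_predictor,
    make_split,
    predict_series,
    save_predictor,
    train_predictor,
)
from myoankle.errors import AlignmentError, ContractError, ValidationError
from myoankle.features import FeatureMatrix
from myoankle.predictor import Scaler

SMALL = dict(hidden_units=8, epochs=2, seed=11)


@pytest.fixture(scope="module")
def tiny_dataset(quiet_config):
    config = dataclasses.replace(quiet_config, n_strides_per_trial=4)
    return generate_dataset(config, 6, seed=2)


@pytest.fixture(scope="module")
def mg_iemg_model(tiny_dataset, wspec):
    spec = ModelSpec(target="position", **SMALL)
    return train_predictor(tiny_dataset[:4], MuscleSet(["MG"]), FeatureSet(["IEMG"]), wspec, spec)


class TestMakeSplit:
    def test_fraction_080_on_ten_trials(self):
        plan = make_split([f"T{i}" for i in range(10)], fraction=0.8, seed=0)
        assert len(plan.train_ids) == 8 and len(plan.valid_ids) == 2

    def test_same_seed_same_split(self):
        ids = [f"T{i}" for i in range(30)]
        assert make_split(ids, seed=4) == make_split(ids, seed=4)

    def test_844_trials_yield_675_training(self):
        plan = make_split([f"T{i}" for i in range(844)], fraction=0.8, seed=0)
        assert len(plan.train_ids) == 675

    def test_sides_disjoint_and_exhaustive(self):
        ids = [f"T{i}" for i in range(13)]
        plan = make_split(ids, seed=1)
        assert set(plan.train_ids) | set(plan.valid_ids) == set(ids)
        assert not set(plan.train_ids) & set(plan.valid_ids)

    def test_fewer_than_two_trials_rejected(self):
        with pytest.raises(ValidationError):
            make_split(["T0"])


class TestAlignTargets:
    def test_linear_ramp_interpolates_exactly(self, trial, wspec):
        fm = extract_feature_matrix(trial, ["TA"], ["MAV"], wspec)
        ramp_trial = dataclasses.replace(
            trial, angle=np.arange(len(trial.angle), dtype=float)
        )
        y = align_targets(ramp_trial, fm, "position")
        # ramp value at time t is t * fs_mech
        assert np.allclose(y, fm.window_end_times * trial.fs_mech, rtol=1e-12)

    def test_phase_locked_hop_equals_sample_pick(self, trial, wspec):
        # hop 10 ms at 1 kHz = one 100 Hz mechanical period: window ends land
        # exactly on mechanical samples
        fm = extract_feature_matrix(trial, ["TA"], ["MAV"], wspec)
        y = align_targets(trial, fm, "position")
        first = int(round(fm.window_end_times[0] * trial.fs_mech))
        picked = trial.angle[first : first + len(y)]
        assert np.allclose(y, picked, atol=1e-9)

    def test_one_target_per_feature_row(self, trial, wspec):
        fm = extract_feature_matrix(trial, ["TA"], ["MAV"], wspec)
        assert len(align_targets(trial, fm, "moment")) == fm.n_windows

    def test_window_time_outside_span_raises(self, trial, wspec):
        fm = extract_feature_matrix(trial, ["TA"], ["MAV"], wspec)
        bad = FeatureMatrix(
            values=fm.values,
            columns=fm.columns,
            window_end_times=fm.window_end_times + 1e4,
            trial_ref=fm.trial_ref,
        )
        with pytest.raises(AlignmentError):
            align_targets(trial, bad, "position")


class TestTraining:
    def test_seeded_training_reproduces_weights(self, tiny_dataset, wspec):
        spec = ModelSpec(target="moment", **SMALL)
        ms, fs = MuscleSet(["SO", "BF"]), FeatureSet(["RMS"])
        a = train_predictor(tiny_dataset[:3], ms, fs, wspec, spec)
        b = train_predictor(tiny_dataset[:3], ms, fs, wspec, spec)
        assert a.weights_checksum == b.weights_checksum
        assert a.training_log == b.training_log

    def test_loss_decreases_on_learnable_data(self, tiny_dataset, wspec):
        spec = ModelSpec(target="position", hidden_units=16, epochs=4, seed=0)
        model = train_predictor(
            tiny_dataset, MuscleSet(["MG", "TA"]), FeatureSet(["IEMG", "WL"]), wspec, spec
        )
        assert len(model.training_log) == spec.epochs
        assert model.training_log[-1] < model.training_log[0]

    def test_zero_variance_column_warns_and_uses_unit_scale(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            scaler = Scaler.fit(np.column_stack([np.ones(50), np.arange(50.0)]))
        assert scaler.scale[0] == 1.0
        z = scaler.transform(np.array([[1.0, 0.0]]))
        assert np.isfinite(z).all()

    def test_column_scaling_cancels_after_refit(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(200, 3))
        scaled = x.copy()
        scaled[:, 1] *= 37.5
        za = Scaler.fit(x).transform(x)
        zb = Scaler.fit(scaled).transform(scaled)
        assert np.allclose(za, zb, rtol=1e-12)


class TestPrediction:
    def test_output_length_and_determinism(self, tiny_dataset, wspec, mg_iemg_model):
        fm = extract_feature_matrix(tiny_dataset[4], ["MG"], ["IEMG"], wspec)
        y1 = predict_series(mg_iemg_model, fm)
        y2 = predict_series(mg_iemg_model, fm)
        assert len(y1) == fm.n_windows
        assert np.array_equal(y1, y2)

    def test_predictions_bounded_by_training_range(self, tiny_dataset, wspec, mg_iemg_model):
        fm = extract_feature_matrix(tiny_dataset[5], ["MG"], ["IEMG"], wspec)
        y = predict_series(mg_iemg_model, fm)
        train_targets = np.concatenate(
            [t.angle for t in tiny_dataset[:4]]
        )
        span = np.ptp(train_targets)
        mid = (train_targets.max() + train_targets.min()) / 2
        assert np.all(np.abs(y - mid) <= 3.0 * span)

    def test_column_mismatch_rejected(self, tiny_dataset, wspec, mg_iemg_model):
        fm = extract_feature_matrix(tiny_dataset[4], ["MG"], ["RMS"], wspec)
        with pytest.raises(ContractError):
            predict_series(mg_iemg_model, fm)

    def test_archive_round_trip(self, tiny_dataset, wspec, mg_iemg_model, tmp_path):
        path = tmp_path / "model.npz"
        save_predictor(mg_iemg_model, path)
        loaded = load_predictor(path)
        fm = extract_feature_matrix(tiny_dataset[4], ["MG"], ["IEMG"], wspec)
        assert np.array_equal(predict_series(loaded, fm), predict_series(mg_iemg_model, fm))
        assert loaded.weights_checksum == mg_iemg_model.weights_checksum


class TestHiddenUnitSweep:
    def test_single_candidate_returned(self, tiny_dataset, wspec):
        spec = ModelSpec(target="position", **SMALL)
        best, table = hidden_unit_sweep(
            tiny_dataset[:4], tiny_dataset[4:], MuscleSet(["MG"]), FeatureSet(["IEMG"]),
            wspec, [8], spec,
        )
        assert best == 8 and len(table) == 1

    def test_best_attains_table_maximum(self, tiny_dataset, wspec):
        spec = ModelSpec(target="position", **SMALL)
        best, table = hidden_unit_sweep(
            tiny_dataset[:4], tiny_dataset[4:], MuscleSet(["MG", "SO"]), FeatureSet(["WL"]),
            wspec, [4, 12], spec,
        )
        assert len(table) == 2
        best_row = table.loc[table["hidden_units"] == best, "mean_valid_r"].iloc[0]
        assert best_row == table["mean_valid_r"].max()

    def test_candidate_above_250_rejected(self, tiny_dataset, wspec):
        spec = ModelSpec(target="position", **SMALL)
        with pytest.raises(ValidationError):
            hidden_unit_sweep(
                tiny_dataset[:4], tiny_dataset[4:], MuscleSet(["MG"]), FeatureSet(["IEMG"]),
                wspec, [300], spec,
            )


class TestModelSpec:
    def test_default_hidden_units_per_target(self):
        assert ModelSpec(target="position").hidden_units == 200
        assert ModelSpec(target="moment").hidden_units == 50

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(target="position", hidden_units=251)
        with pytest.raises(ValidationError):
            ModelSpec(target="position", epochs=0)
        with pytest.raises(ValidationError):
            ModelSpec(target="velocity")
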