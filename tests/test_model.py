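"""Architecture arithmetic, training protocol and prediction contracts."""

import numpy as np
import pytest

from ms2pred.errors import InvalidInputError, InvalidSpecError
from ms2pred.evaluation import safe_cosine
from ms2pred.features import featurize_batch, n_features
from ms2pred.model import (
    ModelSpec,
    audit_no_leakage,
    build_model,
    five_fold_cv,
    load_model,
    max_feasible_depth,
    predict,
    predict_matrix,
    save_model,
    shape_trace,
    train,
    train_mix,
)
from ms2pred.synthetic import SyntheticConfig, generate_peptides, true_intensities

from conftest import random_tryptic


def _dataset(n, length, charge, seed):
    config = SyntheticConfig(
        n_peptides=n, min_length=length, max_length=length, charges=(charge,),
        sigma=0.0, noise_peak_rate=0.0, seed=seed,
    )
    peptides = generate_peptides(config)
    targets = np.array([true_intensities(p).values for p in peptides])
    matrix, _ = featurize_batch(peptides)
    return peptides, matrix, targets


def _oracle_shapes(length, depth, pool=2):
    """Closed-form layer arithmetic, independent of the implementation."""
    signal = 30 + 20 * (length - 1)
    for _ in range(depth):
        signal //= pool
        if signal < 1:
            return None
    output = 4 * (length - 1)
    return {"flat": 10 * signal, "dense": 2 * output, "output": output}


class TestArchitecture:
    def test_default_spec_dimensions(self):
        spec = ModelSpec(length=14, charge_mode=2, n_conv_pool=4)
        assert spec.output_dim == 52
        assert spec.dense_nodes == 104
        assert spec.feature_dim == 290

    @pytest.mark.parametrize("length", range(9, 20))
    @pytest.mark.parametrize("depth", range(2, 8))
    def test_shape_oracle_all_slots(self, length, depth):
        expected = _oracle_shapes(length, depth)
        if expected is None:
            with pytest.raises(InvalidSpecError, match="maximum feasible depth"):
                ModelSpec(length=length, charge_mode=2, n_conv_pool=depth)
            return
        spec = ModelSpec(length=length, charge_mode=2, n_conv_pool=depth)
        network = build_model(spec, np.random.default_rng(0))
        dense, output = network.layers[-3], network.layers[-1]
        assert dense.params[0].shape == (expected["flat"], expected["dense"])
        assert output.params[0].shape == (expected["dense"], expected["output"])

    def test_shape_trace_matches_forward_pass(self):
        spec = ModelSpec(length=9, charge_mode=2, n_conv_pool=4)
        network = build_model(spec, np.random.default_rng(0))
        out = network.forward(np.zeros((2, 1, spec.feature_dim)))
        assert out.shape == (2, spec.output_dim)
        assert shape_trace(spec)[-1] == spec.feature_dim // 16

    def test_max_feasible_depth(self):
        assert max_feasible_depth(190) == 7  # 190 -> 95 -> 47 -> 23 -> 11 -> 5 -> 2 -> 1
        assert max_feasible_depth(8) == 3

    def test_seeded_builds_identical(self):
        spec = ModelSpec(length=9, charge_mode=2)
        a = build_model(spec, np.random.default_rng(3))
        b = build_model(spec, np.random.default_rng(3))
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_invalid_charge_mode(self):
        with pytest.raises(InvalidSpecError):
            ModelSpec(length=9, charge_mode=5)


class TestTraining:
    def test_constant_targets_learned(self):
        _, matrix, _ = _dataset(60, 9, 2, seed=1)
        constant = np.tile(np.linspace(0.1, 1.0, 32), (60, 1))
        trained = train(
            ModelSpec(length=9, charge_mode=2), matrix, constant, seed=0,
            max_epochs=400, min_delta=None, learning_rate=1e-2, monitor="loss",
            batch_size=16,
        )
        pred = predict_matrix(trained, matrix[:5])
        assert np.max(np.abs(pred - constant[:5])) < 0.05
        # validation error driven to ~0
        assert -max(trained.meta["validation_trace"]) < 1e-3

    def test_reproducible_traces(self):
        _, matrix, targets = _dataset(50, 9, 2, seed=2)
        a = train(ModelSpec(length=9, charge_mode=2), matrix, targets, seed=9, max_epochs=5)
        b = train(ModelSpec(length=9, charge_mode=2), matrix, targets, seed=9, max_epochs=5)
        assert a.meta["validation_trace"] == b.meta["validation_trace"]

    def test_early_stopping_rule(self):
        _, matrix, targets = _dataset(50, 9, 2, seed=3)
        trained = train(ModelSpec(length=9, charge_mode=2), matrix, targets, seed=1)
        trace = trained.meta["validation_trace"]
        assert trained.meta["epochs_run"] <= 200
        if trained.meta["epochs_run"] < 200:
            # stopped exactly when the min-delta rule first failed
            assert trace[-1] - trace[-2] < 1e-3
            for i in range(1, len(trace) - 1):
                assert trace[i] - trace[i - 1] >= 1e-3

    def test_empty_training_set_rejected(self):
        with pytest.raises(InvalidInputError):
            train(ModelSpec(length=9, charge_mode=2), np.empty((0, 190)), np.empty((0, 32)), 0)

    def test_overfit_sanity_on_training_peptides(self):
        peptides, matrix, targets = _dataset(80, 9, 2, seed=4)
        trained = train(
            ModelSpec(length=9, charge_mode=2), matrix, targets, seed=0,
            max_epochs=150, min_delta=1e-6,
        )
        pred = predict_matrix(trained, matrix)
        cosines = [safe_cosine(p, t) for p, t in zip(pred, targets)]
        assert np.median(cosines) >= 0.95


class TestPredict:
    def test_nonnegative_outputs(self):
        peptides, matrix, targets = _dataset(40, 9, 2, seed=5)
        trained = train(ModelSpec(length=9, charge_mode=2), matrix, targets, seed=0, max_epochs=5)
        vectors = predict(trained, peptides[:5])
        assert all(np.all(v.values >= 0) for v in vectors)
        assert all(len(v) == 32 for v in vectors)

    def test_wrong_slot_rejected(self, rng):
        _, matrix, targets = _dataset(40, 9, 2, seed=6)
        trained = train(ModelSpec(length=9, charge_mode=2), matrix, targets, seed=0, max_epochs=3)
        with pytest.raises(InvalidInputError, match="slot"):
            predict(trained, [random_tryptic(rng, 10)])
        with pytest.raises(InvalidInputError, match="slot"):
            predict(trained, [random_tryptic(rng, 9, charge=3)])

    def test_save_load_round_trip(self, tmp_path):
        peptides, matrix, targets = _dataset(40, 9, 2, seed=7)
        trained = train(ModelSpec(length=9, charge_mode=2), matrix, targets, seed=0, max_epochs=3)
        save_model(trained, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        assert np.allclose(
            predict_matrix(trained, matrix), predict_matrix(loaded, matrix)
        )


class TestCrossValidation:
    def test_partition_and_no_leakage(self):
        peptides, _, targets = _dataset(100, 9, 2, seed=8)
        frame, partitions = five_fold_cv(
            peptides, targets, ModelSpec(length=9, charge_mode=2), seed=0, max_epochs=3
        )
        assert len(frame) == 5
        test_union = np.concatenate([p["test"] for p in partitions])
        assert sorted(test_union.tolist()) == list(range(100))  # each peptide once
        assert audit_no_leakage(partitions)
        assert all(frame["n_test"] == 20)
        assert all(frame["n_val"] == 8)
        assert all(frame["n_train"] == 72)

    def test_seeded_determinism(self):
        peptides, _, targets = _dataset(40, 9, 2, seed=9)
        spec = ModelSpec(length=9, charge_mode=2)
        a, _ = five_fold_cv(peptides, targets, spec, seed=5, max_epochs=3)
        b, _ = five_fold_cv(peptides, targets, spec, seed=5, max_epochs=3)
        assert a.equals(b)

    def test_too_few_peptides_rejected(self):
        peptides, _, targets = _dataset(8, 9, 2, seed=10)
        with pytest.raises(InvalidInputError):
            five_fold_cv(peptides, targets, ModelSpec(length=9, charge_mode=2), seed=0)


class TestMix:
    def test_union_and_per_charge_evaluation(self):
        p2, _, t2 = _dataset(40, 9, 2, seed=11)
        p3, _, t3 = _dataset(30, 9, 3, seed=12)
        trained = train_mix({2: (p2, t2), 3: (p3, t3)}, seed=0, max_epochs=5)
        assert trained.spec.charge_mode == "mix"
        # one merged model predicts both charges
        v2 = predict(trained, p2[:3])
        v3 = predict(trained, p3[:3])
        assert len(v2) == 3 and len(v3) == 3

    def test_requires_both_charges(self):
        p2, _, t2 = _dataset(20, 9, 2, seed=13)
        with pytest.raises(InvalidInputError):
            train_mix({2: (p2, t2)}, seed=0)
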