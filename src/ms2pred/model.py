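"""The per-(length, charge) convolutional intensity regressor.

One model serves one peptide length L and one charge mode (2+, 3+, or the
merged "mix" model trained on the union of both charges). The network is a
LeNet-style stack: n repeats of (stride-1 same-padded Conv1D with 10
filters, ReLU, width-2 max pooling) over the feature vector treated as a
1-channel signal, then flatten, a ReLU dense layer with twice the output
width, and a linear output layer of 4*(L-1) nodes — one per grid ion.
Outputs are clipped at zero after prediction.

Training minimizes mean squared error with Adam on z-scored features (the
scaler is fitted on the training split only and stored with the model).
Early stopping monitors mean validation cosine similarity with a min-delta
of 0.001 and patience 1: the first epoch that fails to improve on its
predecessor by at least 0.001 ends training, and the parameters from the
best-validation epoch are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .chem import PeptideIon
from .errors import (
    InvalidInputError,
    InvalidSpecError,
    TrainingFailureError,
)
from .evaluation import mean_cosine, safe_cosine, pearson
from .features import featurize_batch, n_features, LAYOUT_VERSION
from .nn import Adam, Conv1D, Dense, Flatten, MaxPool1D, Network, ReLU, mse_loss
from .spectra_io import IonIntensityVector

ChargeMode = Literal[2, 3, "mix"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description for one (length, charge-mode) slot."""

    length: int
    charge_mode: ChargeMode
    n_conv_pool: int = 4
    conv_nodes: int = 10
    kernel_size: int = 3
    pool_size: int = 2

    def __post_init__(self) -> None:
        if not 9 <= self.length <= 19:
            raise InvalidSpecError(f"length {self.length} outside modeled range 9..19")
        if self.charge_mode not in (2, 3, "mix"):
            raise InvalidSpecError(f"charge_mode {self.charge_mode!r} not in {{2, 3, mix}}")
        if not 2 <= self.n_conv_pool <= 7:
            raise InvalidSpecError(f"n_conv_pool {self.n_conv_pool} outside 2..7")
        shape_trace(self)  # raises if pooling exhausts the signal

    @property
    def feature_dim(self) -> int:
        return n_features(self.length)

    @property
    def output_dim(self) -> int:
        return 4 * (self.length - 1)

    @property
    def dense_nodes(self) -> int:
        return 2 * self.output_dim


def max_feasible_depth(feature_dim: int, pool_size: int = 2) -> int:
    """Largest conv-pool depth before repeated floor-pooling reaches 0."""
    depth, length = 0, feature_dim
    while length // pool_size >= 1:
        length //= pool_size
        depth += 1
    return depth


def shape_trace(spec: ModelSpec) -> list[int]:
    """Signal length after each pooling step; errors if any reaches 0."""
    lengths = []
    length = n_features(spec.length)
    for _ in range(spec.n_conv_pool):
        length //= spec.pool_size  # same-padded conv preserves length
        if length < 1:
            raise InvalidSpecError(
                f"pooling depth {spec.n_conv_pool} exhausts the {n_features(spec.length)}"
                f"-slot signal; maximum feasible depth is "
                f"{max_feasible_depth(n_features(spec.length), spec.pool_size)}"
            )
        lengths.append(length)
    return lengths


def build_model(spec: ModelSpec, rng: np.random.Generator) -> Network:
    """Instantiate the untrained network for a spec with seeded weights."""
    layers = []
    c_in = 1
    for _ in range(spec.n_conv_pool):
        layers += [
            Conv1D(c_in, spec.conv_nodes, spec.kernel_size, rng),
            ReLU(),
            MaxPool1D(spec.pool_size),
        ]
        c_in = spec.conv_nodes
    final_len = shape_trace(spec)[-1]
    layers += [
        Flatten(),
        Dense(spec.conv_nodes * final_len, spec.dense_nodes, rng),
        ReLU(),
        Dense(spec.dense_nodes, spec.output_dim, rng, relu_gain=False),
    ]
    return Network(layers)


@dataclass
class Scaler:
    """Per-column z-scoring fitted on the training split only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "Scaler":
        std = matrix.std(axis=0)
        std[std == 0] = 1.0
        return cls(matrix.mean(axis=0), std)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean) / self.std


@dataclass
class TrainedModel:
    spec: ModelSpec
    network: Network
    scaler: Scaler
    meta: dict = field(default_factory=dict)


def _as_signal(x: np.ndarray) -> np.ndarray:
    return x[:, None, :]  # (N, 1, feature_dim) for the 1-D convolution


def train(
    spec: ModelSpec,
    features: np.ndarray,
    targets: np.ndarray,
    seed: int,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    val_fraction: float = 0.1,
    max_epochs: int = 200,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    min_delta: float | None = 1e-3,
    monitor: Literal["cos", "loss"] = "cos",
) -> TrainedModel:
    """Fit one slot model with Adam, MSE and min-delta early stopping.

    If no explicit validation split is passed, ``val_fraction`` of the rows
    (seeded shuffle) is held out. The returned model carries the parameters
    of the epoch with the best validation metric and a ``meta`` record of
    the full validation trace.
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if features.ndim != 2 or len(features) == 0:
        raise InvalidInputError("empty or non-2D training feature matrix")
    if len(features) != len(targets):
        raise InvalidInputError("features and targets are not row-aligned")
    if features.shape[1] != spec.feature_dim or targets.shape[1] != spec.output_dim:
        raise InvalidInputError(
            f"expected {spec.feature_dim} features / {spec.output_dim} targets, "
            f"got {features.shape[1]} / {targets.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    if validation is None:
        n = len(features)
        n_val = max(1, int(round(val_fraction * n)))
        if n - n_val < 1:
            raise InvalidInputError("training set too small for a validation split")
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        x_train, y_train = features[train_idx], targets[train_idx]
        x_val, y_val = features[val_idx], targets[val_idx]
    else:
        x_train, y_train = features, targets
        x_val, y_val = validation

    scaler = Scaler.fit(x_train)
    x_train_s = _as_signal(scaler.transform(x_train))
    x_val_s = _as_signal(scaler.transform(x_val))
    network = build_model(spec, rng)
    optimizer = Adam(network.parameters(), lr=learning_rate)

    def val_metric() -> float:
        pred = np.clip(network.forward(x_val_s), 0.0, None)
        if monitor == "cos":
            return mean_cosine(pred, y_val)
        return -mse_loss(network.forward(x_val_s), y_val)[0]

    trace: list[float] = []
    best_metric, best_state, best_epoch = -np.inf, network.get_state(), -1
    n_train = len(x_train_s)
    epochs_run = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, batch_size):
            batch = order[start : start + batch_size]
            pred = network.forward(x_train_s[batch])
            loss, grad = mse_loss(pred, y_train[batch])
            if not np.isfinite(loss):
                raise TrainingFailureError(f"non-finite loss at epoch {epoch}")
            network.backward(grad)
            optimizer.step(network.gradients())
        metric = val_metric()
        trace.append(metric)
        epochs_run = epoch + 1
        if metric > best_metric:
            best_metric, best_state, best_epoch = metric, network.get_state(), epoch
        # min_delta=None trains to the epoch cap (no early stopping)
        if min_delta is not None and epoch >= 1 and trace[-1] - trace[-2] < min_delta:
            break
    network.set_state(best_state)
    meta = {
        "epochs_run": epochs_run,
        "selected_epoch": best_epoch,
        "validation_trace": trace,
        "seed": seed,
        "monitor": monitor,
        "min_delta": min_delta,
        "layout_version": LAYOUT_VERSION,
    }
    return TrainedModel(spec, network, scaler, meta)


def predict_matrix(trained: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Predicted ion-grid intensities for pre-computed feature rows."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != trained.spec.feature_dim:
        raise InvalidInputError(
            f"expected {trained.spec.feature_dim} feature columns"
        )
    signal = _as_signal(trained.scaler.transform(features))
    return np.clip(trained.network.forward(signal), 0.0, None)


def predict(
    trained: TrainedModel, peptides: Sequence[PeptideIon]
) -> list[IonIntensityVector]:
    """Predict the b/y intensity vector for each peptide ion."""
    spec = trained.spec
    allowed = (2, 3) if spec.charge_mode == "mix" else (spec.charge_mode,)
    for peptide in peptides:
        if len(peptide) != spec.length or peptide.charge not in allowed:
            raise InvalidInputError(
                f"peptide {peptide.sequence}/{peptide.charge} does not fit model slot "
                f"(length {spec.length}, charge {spec.charge_mode})"
            )
    if not peptides:
        return []
    matrix, ordered = featurize_batch(peptides)
    values = predict_matrix(trained, matrix)
    return [
        IonIntensityVector(peptide, row) for peptide, row in zip(ordered, values)
    ]


def five_fold_cv(
    peptides: Sequence[PeptideIon],
    targets: np.ndarray,
    spec: ModelSpec,
    seed: int,
    **train_kwargs,
) -> tuple[pd.DataFrame, list[dict[str, np.ndarray]]]:
    """Five-fold cross validation with a three-way train/validation/test split.

    Each fold holds out 20% as an untouched test set; 10% of the remaining
    training rows (seeded shuffle) become the validation set that drives
    early stopping and model selection, so the test set never influences
    training. Returns per-fold mean COS/PCC plus the index partitions for a
    leakage audit.
    """
    peptides = list(peptides)
    targets = np.asarray(targets, dtype=float)
    if len(peptides) < 10:
        raise InvalidInputError(f"need at least 10 peptides for 5-fold CV, got {len(peptides)}")
    if len(peptides) != len(targets):
        raise InvalidInputError("peptides and targets are not row-aligned")
    matrix, _ = featurize_batch(peptides)
    seeds = np.random.SeedSequence(seed).generate_state(6) % (2**31)
    splitter = KFold(n_splits=5, shuffle=True, random_state=int(seeds[0]))
    rows, partitions = [], []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(matrix)):
        fold_rng = np.random.default_rng(int(seeds[fold + 1]))
        order = fold_rng.permutation(len(train_idx))
        n_val = max(1, int(round(0.1 * len(train_idx))))
        val_idx = train_idx[order[:n_val]]
        fit_idx = train_idx[order[n_val:]]
        trained = train(
            spec,
            matrix[fit_idx],
            targets[fit_idx],
            seed=int(seeds[fold + 1]),
            validation=(matrix[val_idx], targets[val_idx]),
            **train_kwargs,
        )
        pred = predict_matrix(trained, matrix[test_idx])
        cos = [safe_cosine(p, t) for p, t in zip(pred, targets[test_idx])]
        pccs = []
        for p, t in zip(pred, targets[test_idx]):
            try:
                pccs.append(pearson(p, t))
            except Exception:
                pccs.append(np.nan)
        rows.append(
            {
                "fold": fold,
                "n_train": len(fit_idx),
                "n_val": len(val_idx),
                "n_test": len(test_idx),
                "mean_cos": float(np.mean(cos)),
                "mean_pcc": float(np.nanmean(pccs)),
            }
        )
        partitions.append(
            {"train": fit_idx.copy(), "val": val_idx.copy(), "test": test_idx.copy()}
        )
    frame = pd.DataFrame(rows)
    summary = frame[["mean_cos", "mean_pcc"]].mean()
    frame.attrs["mean_cos"] = float(summary["mean_cos"])
    frame.attrs["mean_pcc"] = float(summary["mean_pcc"])
    return frame, partitions


def audit_no_leakage(partitions: list[dict[str, np.ndarray]]) -> bool:
    """True iff every fold's test set is disjoint from its train+validation."""
    for part in partitions:
        test = set(part["test"].tolist())
        seen = set(part["train"].tolist()) | set(part["val"].tolist())
        if test & seen:
            return False
    return True


def train_mix(
    datasets: dict[int, tuple[Sequence[PeptideIon], np.ndarray]],
    seed: int,
    **train_kwargs,
) -> TrainedModel:
    """Train one merged-charge model on the union of 2+ and 3+ data.

    The same peptide at two charges contributes two distinct rows. The
    returned model has ``charge_mode="mix"``; per-charge evaluation is the
    caller's job (the union is only a training-time merge).
    """
    if set(datasets) != {2, 3}:
        raise InvalidInputError(f"mix training needs charges {{2, 3}}, got {sorted(datasets)}")
    lengths = {len(p) for charge in datasets for p in datasets[charge][0]}
    if len(lengths) != 1:
        raise InvalidInputError(f"mixed peptide lengths across charges: {sorted(lengths)}")
    blocks, target_blocks = [], []
    for charge in (2, 3):
        peptides, targets = datasets[charge]
        matrix, _ = featurize_batch(list(peptides))
        blocks.append(matrix)
        target_blocks.append(np.asarray(targets, dtype=float))
    features = np.vstack(blocks)
    targets = np.vstack(target_blocks)
    spec = ModelSpec(length=lengths.pop(), charge_mode="mix", **{
        k: v for k, v in train_kwargs.pop("spec_kwargs", {}).items()
    })
    return train(spec, features, targets, seed, **train_kwargs)


def save_model(trained: TrainedModel, directory) -> None:
    """Persist a model bundle: spec + scaler + weights + training log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "spec.json").write_text(json.dumps(asdict(trained.spec), indent=2))
    (directory / "training_log.json").write_text(json.dumps(trained.meta, indent=2))
    np.savez(
        directory / "weights.npz",
        scaler_mean=trained.scaler.mean,
        scaler_std=trained.scaler.std,
        **{f"param_{i}": p for i, p in enumerate(trained.network.parameters())},
    )


def load_model(directory) -> TrainedModel:
    """Load a model bundle written by :func:`save_model`."""
    directory = Path(directory)
    spec_dict = json.loads((directory / "spec.json").read_text())
    if spec_dict["charge_mode"] != "mix":
        spec_dict["charge_mode"] = int(spec_dict["charge_mode"])
    spec = ModelSpec(**spec_dict)
    meta = json.loads((directory / "training_log.json").read_text())
    archive = np.load(directory / "weights.npz")
    scaler = Scaler(archive["scaler_mean"], archive["scaler_std"])
    network = build_model(spec, np.random.default_rng(0))
    state = [archive[f"param_{i}"] for i in range(len(network.parameters()))]
    network.set_state(state)
    return TrainedModel(spec, network, scaler, meta)
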