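"""1-D CNN age regressor, training protocol and stratified cross-validation.

The default architecture maps the 144-sample normalized pulse through two
1-D convolutional layers (16 filters of size 10, then 32 of size 8, stride
1, no pooling or padding, ReLU), a flatten, and two 1024-node fully
connected ReLU layers each followed by 0.2 dropout, into a single linear
output neuron giving age in years.  Training minimizes MSE with
Adam(lr 1e-4, beta1 0.9, beta2 0.999) in batches of 50, with early
stopping on validation MSE (patience 100 epochs by default) and
restoration of the best-validation weights.

Evaluation uses age-stratified tenfold cross-validation: per fold a 1:9
test:train split, with 25% of the training portion held out as the
validation set, all decade-stratified so each fold sees the full age range.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, TrainingError
from .nn import Adam, Conv1D, Dense, Dropout, Flatten, Network, ReLU, mse_loss
from .preprocess import PULSE_LENGTH

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Fold",
    "FoldPlan",
    "TrainedAgeModel",
    "stratified_folds",
    "build_model",
    "train",
    "predict",
    "cross_validate",
    "grid_search",
    "default_grid",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_layers`` is a list of (n_filters, kernel_size, stride) with
    stride fixed at 1; ``fc_layers`` the fully connected widths before the
    single-output head.
    """

    conv_layers: tuple = ((16, 10, 1), (32, 8, 1))
    fc_layers: tuple = (1024, 1024)
    dropout_rate: float = 0.2
    input_length: int = PULSE_LENGTH

    def validate(self) -> None:
        if self.input_length != PULSE_LENGTH:
            raise ConfigurationError(f"input_length must be {PULSE_LENGTH}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        length = self.input_length
        for n_f, k, stride in self.conv_layers:
            if stride != 1:
                raise ConfigurationError("stride must be 1")
            length = length - k + 1
            if length < 1:
                raise ConfigurationError(
                    f"kernel {k} larger than remaining length")

    def conv_output_length(self) -> int:
        length = self.input_length
        for _, k, _ in self.conv_layers:
            length = length - k + 1
        return length


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults follow the training protocol."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 50
    patience: int = 100
    patience_unit: str = "epoch"   # or "step"
    max_epochs: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")
        if self.patience_unit not in ("epoch", "step"):
            raise ConfigurationError("patience_unit must be 'epoch' or 'step'")


@dataclass
class Fold:
    """Index sets for one cross-validation fold (indices into the dataset)."""

    test: np.ndarray
    inner_train: np.ndarray
    validation: np.ndarray

    @property
    def train(self) -> np.ndarray:
        return np.concatenate([self.inner_train, self.validation])


@dataclass
class FoldPlan:
    k: int
    folds: list
    bin_labels: np.ndarray      # decade label per subject

    def validate(self, n: int) -> None:
        all_test = np.concatenate([f.test for f in self.folds])
        if len(all_test) != n or len(np.unique(all_test)) != n:
            raise ConfigurationError("test folds do not partition the subjects")
        for f in self.folds:
            overlap = (set(f.test) & set(f.inner_train)) | \
                      (set(f.test) & set(f.validation)) | \
                      (set(f.inner_train) & set(f.validation))
            if overlap:
                raise ConfigurationError(f"leaky fold: shared indices {overlap}")


@dataclass
class TrainedAgeModel:
    """A trained regressor with its configuration and training history."""

    network: Network
    model_config: ModelConfig
    train_config: TrainConfig
    history: pd.DataFrame
    best_epoch: int
    fold_id: int = -1


def _decade_labels(ages: np.ndarray) -> np.ndarray:
    return (np.asarray(ages, dtype=float) // 10).astype(int)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        out = np.zeros(len(weights), dtype=int)
        out[: total] = 1
        return out
    quotas = weights / weights.sum() * total
    base = np.floor(quotas).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    base[order[:rem]] += 1
    return base


def stratified_folds(ages, k: int = 10, val_frac: float = 0.25,
                     seed: int = 0) -> FoldPlan:
    """Age-decade-stratified k-fold plan with inner validation split.

    Subjects are dealt to folds round-robin within each decade bin, with
    the dealing pointer carried across bins, so global fold sizes differ
    by at most one and per-fold decade counts stay within one subject of
    the proportional share.  Per fold, ``round(val_frac * train size)``
    subjects are drawn decade-stratified from the training portion as the
    validation set.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if n < k:
        raise ConfigurationError(f"need at least k={k} subjects, got {n}")
    rng = np.random.default_rng(seed)
    labels = _decade_labels(ages)

    fold_members: list[list[int]] = [[] for _ in range(k)]
    pointer = 0
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        rng.shuffle(members)
        for idx in members:
            fold_members[pointer % k].append(int(idx))
            pointer += 1

    folds = []
    for i in range(k):
        test = np.array(sorted(fold_members[i]), dtype=int)
        train = np.array(sorted(set(range(n)) - set(test)), dtype=int)
        val_n = int(round(val_frac * len(train)))
        train_labels = labels[train]
        bins = np.unique(train_labels)
        counts = np.array([(train_labels == b).sum() for b in bins])
        alloc = _largest_remainder(counts.astype(float), val_n)
        val_idx = []
        for b, a in zip(bins, alloc):
            members = train[train_labels == b].copy()
            rng.shuffle(members)
            val_idx.extend(members[:a].tolist())
        val = np.array(sorted(val_idx), dtype=int)
        inner = np.array(sorted(set(train) - set(val)), dtype=int)
        folds.append(Fold(test=test, inner_train=inner, validation=val))

    plan = FoldPlan(k=k, folds=folds, bin_labels=labels)
    plan.validate(n)
    return plan


def build_model(config: ModelConfig | None = None, seed: int = 0) -> Network:
    """Instantiate the CNN with seeded parameter initialization."""
    config = config or ModelConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = 1
    for n_f, kern, _ in config.conv_layers:
        layers.append(Conv1D(in_ch, n_f, kern, rng))
        layers.append(ReLU())
        in_ch = n_f
    layers.append(Flatten())
    n_in = config.conv_output_length() * in_ch
    for width in config.fc_layers:
        layers.append(Dense(n_in, width, rng))
        layers.append(ReLU())
        layers.append(Dropout(config.dropout_rate))
        n_in = width
    layers.append(Dense(n_in, 1, rng))
    return Network(layers)


def _check_pulses(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != PULSE_LENGTH:
        raise InputError(f"pulses must have length {PULSE_LENGTH}, got {X.shape[1]}")
    if X.min() < -1e-6 or X.max() > 1.0 + 1e-6:
        raise InputError("pulse values must lie in [0, 1]")
    return X


def _eval_mse(network: Network, X3: np.ndarray, y: np.ndarray,
              batch: int = 256) -> float:
    preds = []
    for i in range(0, len(X3), batch):
        preds.append(network.forward(X3[i:i + batch], train=False).reshape(-1))
    loss, _ = mse_loss(np.concatenate(preds), y)
    return loss


def train(network: Network, X: np.ndarray, y: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray,
          config: TrainConfig | None = None,
          model_config: ModelConfig | None = None,
          fold_id: int = -1) -> TrainedAgeModel:
    """Fit with Adam + early stopping on validation MSE.

    Stops when validation MSE has not improved for ``patience`` monitored
    units (epochs by default, optimizer steps optionally) and restores the
    best-validation weights.  Fully deterministic given the config seed.
    """
    config = config or TrainConfig()
    config.validate()
    X = _check_pulses(X)
    X_val = _check_pulses(X_val)
    y = np.asarray(y, dtype=float).reshape(-1)
    y_val = np.asarray(y_val, dtype=float).reshape(-1)
    X3 = X[:, None, :]
    X3_val = X_val[:, None, :]

    rng = np.random.default_rng(config.seed)
    opt = Adam(network.params, lr=config.learning_rate,
               beta1=config.beta1, beta2=config.beta2)

    best_val = np.inf
    best_weights = network.get_weights()
    best_epoch = 0
    since_best = 0
    history = []
    n = len(X3)
    per_epoch_steps = max(1, int(np.ceil(n / config.batch_size)))

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        stop = False
        for s in range(per_epoch_steps):
            idx = order[s * config.batch_size:(s + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            pred = network.forward(X3[idx], train=True, rng=rng)
            loss, dpred = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            network.backward(dpred)
            opt.step(network.grads)
            if config.patience_unit == "step":
                val = _eval_mse(network, X3_val, y_val)
                if val < best_val - 1e-12:
                    best_val, best_weights = val, network.get_weights()
                    best_epoch, since_best = epoch, 0
                else:
                    since_best += 1
                    if since_best >= config.patience:
                        stop = True
                        break
        train_mse = epoch_loss / n
        val_mse = _eval_mse(network, X3_val, y_val)
        history.append({"epoch": epoch, "train_mse": train_mse,
                        "val_mse": val_mse})
        if config.patience_unit == "epoch":
            if val_mse < best_val - 1e-12:
                best_val, best_weights = val_mse, network.get_weights()
                best_epoch, since_best = epoch, 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        if stop:
            break

    network.set_weights(best_weights)
    return TrainedAgeModel(network=network,
                           model_config=model_config or ModelConfig(),
                           train_config=config,
                           history=pd.DataFrame(history),
                           best_epoch=best_epoch, fold_id=fold_id)


def predict(model: TrainedAgeModel | Network, X: np.ndarray,
            batch: int = 256) -> np.ndarray:
    """Estimated ages (years), one finite scalar per pulse, order preserved."""
    network = model.network if isinstance(model, TrainedAgeModel) else model
    X = _check_pulses(X)
    X3 = X[:, None, :]
    out = []
    for i in range(0, len(X3), batch):
        out.append(network.forward(X3[i:i + batch], train=False).reshape(-1))
    preds = np.concatenate(out)
    if not np.all(np.isfinite(preds)):
        raise TrainingError("model produced non-finite predictions")
    return preds


def cross_validate(X: np.ndarray, y: np.ndarray, plan: FoldPlan,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None,
                   subject_ids=None, keep_models: bool = False):
    """Run the full k-fold protocol and pool out-of-fold predictions.

    Every subject receives exactly one out-of-fold prediction.  Per-fold
    training failures are recorded and the remaining folds continue; the
    result reports partial coverage in that case.

    Returns (predictions DataFrame, list of TrainedAgeModel or None).
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    X = _check_pulses(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    if subject_ids is None:
        subject_ids = np.array([f"S{i:04d}" for i in range(len(y))])
    subject_ids = np.asarray(subject_ids)

    ss = np.random.SeedSequence(train_config.seed)
    fold_seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(plan.k)]

    rows, models, failures = [], [], []
    for fid, fold in enumerate(plan.folds):
        seed = fold_seeds[fid]
        net = build_model(model_config, seed=seed)
        cfg = replace(train_config, seed=seed)
        try:
            trained = train(net, X[fold.inner_train], y[fold.inner_train],
                            X[fold.validation], y[fold.validation],
                            cfg, model_config, fold_id=fid)
        except TrainingError as exc:
            failures.append((fid, str(exc)))
            models.append(None)
            continue
        preds = predict(trained, X[fold.test])
        for idx, p in zip(fold.test, preds):
            rows.append({"subject_id": subject_ids[idx], "age": y[idx],
                         "predicted_age": float(p), "fold": fid})
        models.append(trained if keep_models else trained)
    preds_df = pd.DataFrame(rows)
    preds_df.attrs["failures"] = failures
    return preds_df, models


def default_grid() -> list[tuple[ModelConfig, TrainConfig]]:
    """The full hyperparameter grid explored during model selection:
    conv depth 2-6, 1-2 FC layers, widths {512, 1024, 2048}, dropout
    0-0.5, learning rate {1e-3, 1e-4}."""
    filters = (16, 32, 64, 128, 256, 512)
    kernels = (10, 8, 8, 8, 8, 8)
    grid = []
    for depth in (2, 3, 4, 5, 6):
        conv = tuple((filters[i], kernels[i], 1) for i in range(depth))
        for n_fc in (1, 2):
            for width in (512, 1024, 2048):
                for drop in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
                    for lr in (1e-3, 1e-4):
                        grid.append((
                            ModelConfig(conv_layers=conv,
                                        fc_layers=(width,) * n_fc,
                                        dropout_rate=drop),
                            TrainConfig(learning_rate=lr),
                        ))
    return grid


def grid_search(X: np.ndarray, y: np.ndarray, plan: FoldPlan,
                grid: list[tuple[ModelConfig, TrainConfig]],
                fold_id: int = 0) -> pd.DataFrame:
    """Rank configurations by validation MSE on one fold's inner split."""
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    fold = plan.folds[fold_id]
    X = _check_pulses(X)
    y = np.asarray(y, dtype=float).reshape(-1)
    rows = []
    for gi, (mcfg, tcfg) in enumerate(grid):
        net = build_model(mcfg, seed=tcfg.seed)
        try:
            trained = train(net, X[fold.inner_train], y[fold.inner_train],
                            X[fold.validation], y[fold.validation],
                            tcfg, mcfg, fold_id=fold_id)
            val = float(trained.history["val_mse"].min())
            err = ""
        except TrainingError as exc:
            val, err = np.inf, str(exc)
        rows.append({"grid_index": gi,
                     "conv_layers": len(mcfg.conv_layers),
                     "fc_layers": len(mcfg.fc_layers),
                     "fc_width": mcfg.fc_layers[0],
                     "dropout": mcfg.dropout_rate,
                     "learning_rate": tcfg.learning_rate,
                     "val_mse": val, "error": err})
    out = pd.DataFrame(rows).sort_values("val_mse", kind="stable")
    return out.reset_index(drop=True)


def save_model(model: TrainedAgeModel, outdir: str) -> None:
    """Persist weights (npz), config snapshot (json), and history (csv)."""
    os.makedirs(outdir, exist_ok=True)
    np.savez(os.path.join(outdir, "weights.npz"),
             **{f"p{i:03d}": p for i, p in enumerate(model.network.params)})
    snapshot = {
        "model_config": asdict(model.model_config),
        "train_config": asdict(model.train_config),
        "best_epoch": model.best_epoch,
        "fold_id": model.fold_id,
    }
    with open(os.path.join(outdir, "config.json"), "w") as fh:
        json.dump(snapshot, fh, indent=2)
    model.history.to_csv(os.path.join(outdir, "history.csv"), index=False)


def load_model(outdir: str) -> TrainedAgeModel:
    with open(os.path.join(outdir, "config.json")) as fh:
        snapshot = json.load(fh)
    mcfg_d = snapshot["model_config"]
    mcfg = ModelConfig(
        conv_layers=tuple(tuple(c) for c in mcfg_d["conv_layers"]),
        fc_layers=tuple(mcfg_d["fc_layers"]),
        dropout_rate=mcfg_d["dropout_rate"],
        input_length=mcfg_d["input_length"])
    tcfg = TrainConfig(**snapshot["train_config"])
    network = build_model(mcfg, seed=0)
    with np.load(os.path.join(outdir, "weights.npz")) as data:
        weights = [data[f"p{i:03d}"] for i in range(len(data.files))]
    network.set_weights(weights)
    history = pd.read_csv(os.path.join(outdir, "history.csv")) \
        if os.path.exists(os.path.join(outdir, "history.csv")) else pd.DataFrame()
    return TrainedAgeModel(network=network, model_config=mcfg,
                           train_config=tcfg, history=history,
                           best_epoch=snapshot.get("best_epoch", 0),
                           fold_id=snapshot.get("fold_id", -1))
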