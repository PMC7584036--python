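"""BP regression models: residual stacked-LSTM family and baselines.

The four sequence models share one topology — a BiLSTM front layer, a
stack of LSTM layers, a fully connected layer, and a two-unit linear
regression head (SBP, DBP) — and differ only in depth and in whether
each stacked LSTM layer carries an identity residual shortcut:

========  ===========  ========
model_id  LSTM layers  residual
========  ===========  ========
1         4            no
2         4            yes
3         5            yes
4         6            yes
========  ===========  ========

Training minimizes MSE on the normalized (SBP, DBP) pair at every time
step, with Adam, an initial learning rate of 0.003 dropped by a factor
of 0.2 every 125 iterations, dropout 0.2 on each recurrent layer's
output, and at most 50 epochs.  Long cycle streams are cut into
fixed-length subsequences (``sequence_length``) with state reset per
subsequence, which is also exactly how batch and streaming prediction
traverse a record — so the two agree to machine precision.

Baselines: ordinary least squares (one fit per target), bootstrap-
aggregated regression trees, least-squares boosting of shallow trees,
and a five-layer residual fully-connected network (the memory-free
comparator), via scikit-learn where a standard estimator exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pulsebp import nn
from pulsebp.dataset import FeatureDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "predict_windows",
    "fit_mlr",
    "fit_ensemble",
    "build_dnn_baseline",
    "MLRModel",
    "EnsembleModel",
]

_MODEL_TOPOLOGY = {1: (4, False), 2: (4, True), 3: (5, True), 4: (6, True)}


@dataclass
class ModelConfig:
    """Architecture and sequence-handling settings for one regressor."""

    model_id: int | str = 2
    n_lstm_layers: int | None = None
    residual: bool | None = None
    hidden_units: int = 256
    dropout: float = 0.2
    sequence_length: int = 200
    n_features: int = 7
    output_dim: int = 2

    def __post_init__(self) -> None:
        if self.model_id in _MODEL_TOPOLOGY:
            layers, residual = _MODEL_TOPOLOGY[self.model_id]
            if self.n_lstm_layers is None:
                self.n_lstm_layers = layers
            if self.residual is None:
                self.residual = residual
            if (self.n_lstm_layers, self.residual) != (layers, residual):
                raise ValueError(
                    f"model {self.model_id} requires {layers} LSTM layers, "
                    f"residual={residual}"
                )
        elif self.model_id == "dnn":
            self.n_lstm_layers = 0
            self.residual = True
        else:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.hidden_units <= 0:
            raise ValueError("hidden_units must be positive")
        if self.sequence_length < 1:
            raise ValueError("sequence_length must be positive")
        if self.output_dim != 2:
            raise ValueError("the regression head emits exactly (SBP, DBP)")


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    initial_lr: float = 0.003
    lr_drop_factor: float = 0.2
    lr_drop_period: int = 125
    lr_schedule_unit: str = "iteration"  # or "epoch"
    max_epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr_schedule_unit not in ("iteration", "epoch"):
            raise ValueError("lr_schedule_unit must be 'iteration' or 'epoch'")

    def lr_at(self, steps: int) -> float:
        """Learning rate after `steps` completed schedule units."""
        return self.initial_lr * self.lr_drop_factor ** (steps // self.lr_drop_period)


@dataclass
class TrainedModel:
    """A fitted network plus the normalization statistics it expects."""

    config: ModelConfig
    network: nn.Sequential
    dataset_stats: FeatureDataset
    training_history: list[float] = field(default_factory=list)


def build_model(config: ModelConfig, seed: int = 0) -> nn.Sequential:
    """Assemble the layer stack for one ModelConfig (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    if config.model_id == "dnn":
        return build_dnn_baseline(
            n_features=config.n_features, hidden_units=config.hidden_units, seed=seed
        )
    d = config.hidden_units
    layers: list[nn.Layer] = [nn.BiLSTM(config.n_features, d, rng)]
    if config.dropout > 0:
        layers.append(nn.Dropout(config.dropout, rng))
    for _ in range(config.n_lstm_layers):
        lstm: nn.Layer = nn.LSTM(d, d, rng)
        if config.residual:
            lstm = nn.Residual(lstm)
        layers.append(lstm)
        if config.dropout > 0:
            layers.append(nn.Dropout(config.dropout, rng))
    layers.append(nn.Dense(d, d, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(d, config.output_dim, rng))
    return nn.Sequential(layers)


def _make_subsequences(
    features: np.ndarray, targets: np.ndarray, length: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut (7, T)/(2, T) column streams into (T_i, 7)/(T_i, 2) blocks."""
    t = features.shape[1]
    blocks = []
    for start in range(0, t, length):
        end = min(start + length, t)
        blocks.append((features[:, start:end].T, targets[:, start:end].T))
    return blocks


def train(
    model: nn.Sequential,
    dataset: FeatureDataset,
    tcfg: TrainConfig,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Fit a sequence model on the training columns of a normalized dataset."""
    if not dataset.normalized:
        raise ValueError("normalize the dataset before training")
    config = config or ModelConfig()
    cols = dataset.train_columns
    feats = dataset.features[:, cols]
    targs = dataset.targets[:, cols]
    blocks = _make_subsequences(feats, targs, config.sequence_length)

    rng = np.random.default_rng(tcfg.seed)
    opt = nn.Adam(
        model.params(),
        lr=tcfg.initial_lr,
        lr_drop_factor=tcfg.lr_drop_factor,
        lr_drop_period=tcfg.lr_drop_period,
    )
    history: list[float] = []
    iteration = 0
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(len(blocks))
        epoch_losses = []
        # batch together blocks of identical length (the trailing short
        # block, if any, rides in its own mini-batch)
        by_len: dict[int, list[int]] = {}
        for idx in order:
            by_len.setdefault(len(blocks[idx][0]), []).append(idx)
        for _, indices in sorted(by_len.items(), reverse=True):
            for start in range(0, len(indices), tcfg.batch_size):
                chunk = indices[start : start + tcfg.batch_size]
                x = np.stack([blocks[i][0] for i in chunk])
                y = np.stack([blocks[i][1] for i in chunk])
                pred = model.forward(x, train=True)
                loss, dpred = nn.mse_loss(pred, y)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, iteration {iteration}"
                    )
                model.backward(dpred)
                steps = iteration if tcfg.lr_schedule_unit == "iteration" else epoch
                opt.step(model.grads(), decay_steps=steps)
                epoch_losses.append(loss)
                iteration += 1
        history.append(float(np.mean(epoch_losses)))
    return TrainedModel(
        config=config, network=model, dataset_stats=dataset, training_history=history
    )


def predict_windows(
    network: nn.Sequential, features_normalized: np.ndarray, sequence_length: int
) -> np.ndarray:
    """Per-step normalized outputs, processing consecutive windows.

    The stream is traversed in non-overlapping windows of
    ``sequence_length`` with recurrent state reset at each boundary —
    identical to how :func:`pulsebp.pipeline.stream_predict` consumes a
    live cycle stream, so batch and streaming outputs coincide.
    """
    k = features_normalized.shape[1]
    outputs = np.empty((2, k))
    for start in range(0, k, sequence_length):
        end = min(start + sequence_length, k)
        x = features_normalized[:, start:end].T[None]  # (1, T_w, 7)
        outputs[:, start:end] = network.forward(x, train=False)[0].T
    return outputs


def predict(model: TrainedModel, features_normalized: np.ndarray) -> np.ndarray:
    """Denormalized (SBP, DBP) in mmHg per cycle for a normalized 7xk input."""
    feats = np.asarray(features_normalized, dtype=float)
    if feats.ndim != 2 or feats.shape[0] != model.config.n_features:
        raise ValueError(
            f"expected a {model.config.n_features}xk feature matrix, got {feats.shape}"
        )
    scaled = predict_windows(model.network, feats, model.config.sequence_length)
    return model.dataset_stats.denormalize_targets(scaled)


# ---------------------------------------------------------------------------
# classical baselines
# ---------------------------------------------------------------------------


@dataclass
class MLRModel:
    """Per-target ordinary-least-squares fit: y = b0 + sum_j b_j x_j."""

    coef: np.ndarray  # (2, 7)
    intercept: np.ndarray  # (2,)
    stats: FeatureDataset

    def predict(self, features_normalized: np.ndarray) -> np.ndarray:
        scaled = self.coef @ features_normalized + self.intercept[:, None]
        return self.stats.denormalize_targets(scaled)


def fit_mlr(dataset: FeatureDataset) -> MLRModel:
    """OLS on the training columns; rank deficiency is a named error."""
    from sklearn.linear_model import LinearRegression

    cols = dataset.train_columns
    x = dataset.features[:, cols].T
    y = dataset.targets[:, cols].T
    p = x.shape[1]
    if x.shape[0] < p + 1:
        raise ValueError(f"need at least {p + 1} training rows for {p} features")
    design = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [
            dataset.row_names[j - 1]
            for j in range(1, p + 1)
            if diag[j] < 1e-10 * diag.max()
        ]
        raise ValueError(f"rank-deficient design; collinear features: {bad or 'intercept'}")
    ols = LinearRegression().fit(x, y)
    return MLRModel(coef=ols.coef_, intercept=ols.intercept_, stats=dataset)


@dataclass
class EnsembleModel:
    kind: str
    estimators: list  # one fitted estimator per target row
    stats: FeatureDataset

    def predict(self, features_normalized: np.ndarray) -> np.ndarray:
        x = features_normalized.T
        scaled = np.vstack([est.predict(x) for est in self.estimators])
        return self.stats.denormalize_targets(scaled)


def fit_ensemble(
    dataset: FeatureDataset,
    kind: str,
    n_estimators: int = 100,
    seed: int = 0,
    bootstrap: bool = True,
) -> EnsembleModel:
    """Bagged regression trees or least-squares boosting, one per target.

    ``kind='bagging'`` averages trees grown on bootstrap resamples;
    ``kind='lsboost'`` stage-wise fits shallow trees to residuals
    (0 stages degenerates to the training-mean predictor).
    """
    from sklearn.dummy import DummyRegressor
    from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor
    from sklearn.tree import DecisionTreeRegressor

    cols = dataset.train_columns
    if len(cols) < 50:
        raise ValueError("ensemble baselines need at least 50 training rows")
    x = dataset.features[:, cols].T
    y = dataset.targets[:, cols]

    estimators = []
    for row in range(2):
        if kind == "bagging":
            est = BaggingRegressor(
                estimator=DecisionTreeRegressor(random_state=seed),
                n_estimators=n_estimators,
                bootstrap=bootstrap,
                random_state=seed,
            )
        elif kind == "lsboost":
            if n_estimators == 0:
                est = DummyRegressor(strategy="mean")
            else:
                est = GradientBoostingRegressor(
                    loss="squared_error",
                    n_estimators=n_estimators,
                    max_depth=3,
                    random_state=seed,
                )
        else:
            raise ValueError(f"unknown ensemble kind {kind!r}")
        estimators.append(est.fit(x, y[row]))
    return EnsembleModel(kind=kind, estimators=estimators, stats=dataset)


def build_dnn_baseline(
    n_features: int = 7, hidden_units: int = 256, seed: int = 0
) -> nn.Sequential:
    """Five fully connected layers, 256 units in layers 1-4, identity
    shortcuts on every layer whose input and output widths match, two
    linear outputs.  No recurrence — the memory-free comparator."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Dense(n_features, hidden_units, rng), nn.ReLU()]
    for _ in range(3):  # layers 2-4: width-preserving, residual-wrapped
        block = nn.Sequential([nn.Dense(hidden_units, hidden_units, rng), nn.ReLU()])
        layers.append(nn.Residual(block))
    layers.append(nn.Dense(hidden_units, 2, rng))  # layer 5: regression head
    return nn.Sequential(layers)


def count_lstm_params(n_in: int, n_hidden: int) -> int:
    """Closed-form LSTM parameter count: 4 * (d*(d + n_in) + d)."""
    return 4 * (n_hidden * (n_hidden + n_in) + n_hidden)
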