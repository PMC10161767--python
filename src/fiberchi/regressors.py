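"""Regressors mapping corrupted I(chi) curves to encoded orientation labels.

Two scikit-learn-style estimators:

* :class:`FCNNRegressor` — a fully connected network trained with MAE loss and
  Adam, with early stopping on validation MAE and learning-rate decay on
  plateau. Exposes exact input gradients for saliency analysis.
* :class:`BaselineRegressor` — KNN / random-forest / SVR classical baselines
  (scikit-learn under the hood) with an optional validation-set
  hyperparameter grid search.

Features are the flattened ``[intensity; mask]`` concatenation (length
2 * n_bins); targets are 17-value encoded label vectors. Module-level helpers
``train_fcnn`` / ``train_baseline`` / ``predict_params`` operate directly on
:class:`~fiberchi.sampling.Dataset` objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.multioutput import MultiOutputRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import codec
from .nn import MLP
from .sampling import Dataset

__all__ = ["TrainConfig", "FCNNRegressor", "BaselineRegressor",
           "train_fcnn", "train_baseline", "predict_params", "predict"]


@dataclass
class TrainConfig:
    """Training settings for the FCNN (defaults are the package's study conditions)."""

    hidden_layer_sizes: tuple = (512, 256, 128)
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 200
    patience: int = 20
    loss: str = "mae"
    optimizer: str = "adam"
    seed: int = 0
    n_repetitions: int = 5
    #: re-corrupt the training curves every epoch (fresh noise/mask/scale
    #: realizations from the stored clean curves), the curve analogue of
    #: re-masking image patches each iteration; falls back to the stored
    #: corruption when the dataset kept no clean curves
    online_corruption: bool = True

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        if self.loss != "mae" or self.optimizer != "adam":
            raise ValueError("only MAE loss with the Adam optimizer is supported")


class FCNNRegressor(BaseEstimator, RegressorMixin):
    """Fully connected network regressor (MAE loss, Adam, early stopping).

    Parameters follow scikit-learn conventions; fitted attributes carry a
    trailing underscore. ``fit`` accepts an optional explicit validation set
    (``X_val``, ``y_val``); otherwise ``validation_fraction`` of the training
    data is held out internally for early stopping.
    """

    def __init__(self, hidden_layer_sizes=(512, 256, 128), learning_rate=1e-3,
                 batch_size=256, max_epochs=200, patience=20,
                 validation_fraction=0.1, lr_decay_factor=0.5,
                 lr_decay_patience=5, standardize_targets=True,
                 random_state=None, verbose=0):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_patience = lr_decay_patience
        self.standardize_targets = standardize_targets
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y, X_val=None, y_val=None, x_sampler=None):
        """Fit the network.

        ``x_sampler``, if given, is a callable ``rng -> X`` returning a fresh
        feature matrix aligned with ``y`` each epoch (training-time
        re-corruption); ``X`` then only seeds shapes/validation.
        """
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True, dtype=np.float32)
        if y.ndim == 1:
            y = y[:, None]
        rng = np.random.default_rng(self.random_state)
        if X_val is None and self.validation_fraction and len(X) >= 10:
            n_val = max(1, int(round(self.validation_fraction * len(X))))
            perm = rng.permutation(len(X))
            X_val, y_val = X[perm[:n_val]], y[perm[:n_val]]
            X, y = X[perm[n_val:]], y[perm[n_val:]]
        if self.standardize_targets:
            # narrow-range angle coordinates (e.g. cos 2*beta for small tilts)
            # span tiny intervals; z-scoring evens out their share of the MAE
            # gradient. Predictions are mapped back to the encoded scale.
            self.y_mean_ = y.mean(axis=0)
            self.y_scale_ = np.maximum(y.std(axis=0), 1e-3)
        else:
            self.y_mean_ = np.zeros(y.shape[1], dtype=np.float32)
            self.y_scale_ = np.ones(y.shape[1], dtype=np.float32)
        y = (y - self.y_mean_) / self.y_scale_
        if y_val is not None:
            y_val = (np.asarray(y_val, dtype=np.float32) - self.y_mean_) / self.y_scale_
        sizes = (X.shape[1], *self.hidden_layer_sizes, y.shape[1])
        net = MLP(sizes, seed=int(rng.integers(2**31)))
        lr = float(self.learning_rate)
        best_val = np.inf
        best_weights = None
        bad_epochs = plateau = 0
        history = {"train_mae": [], "val_mae": [], "lr": []}
        n = len(X)
        bs = min(self.batch_size, n)
        for epoch in range(self.max_epochs):
            if x_sampler is not None:
                X = np.asarray(x_sampler(rng), dtype=np.float32)
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                loss, gW, gb = net.loss_and_grads(X[idx], y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged (NaN loss) at epoch {epoch}")
                net.adam_step(gW, gb, lr)
                ep_loss += loss * len(idx)
            ep_loss /= n
            if X_val is not None and len(X_val):
                val = float(np.abs(net.forward(X_val) - y_val).mean())
            else:
                val = ep_loss
            history["train_mae"].append(ep_loss)
            history["val_mae"].append(val)
            history["lr"].append(lr)
            if self.verbose:
                print(f"epoch {epoch:3d}  train {ep_loss:.4f}  val {val:.4f}  lr {lr:.2e}")
            if val < best_val - 1e-6:
                best_val = val
                best_weights = net.get_weights()
                bad_epochs = plateau = 0
            else:
                bad_epochs += 1
                plateau += 1
                if plateau >= self.lr_decay_patience:
                    lr *= self.lr_decay_factor
                    plateau = 0
                if bad_epochs >= self.patience:
                    break
        if best_weights is not None:
            net = MLP.from_weights(best_weights)
        self.net_ = net
        self.history_ = history
        self.best_val_mae_ = float(best_val)
        self.n_features_in_ = X.shape[1]
        self.n_outputs_ = y.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=np.float32)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}")
        out = np.asarray(self.net_.forward(X), dtype=float)
        return out * self.y_scale_ + self.y_mean_

    def input_gradient(self, X, output_index):
        """Exact gradient of output ``output_index`` wrt each input feature
        (on the encoded-label scale, consistent with :meth:`predict`)."""
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=np.float32)
        g = np.asarray(self.net_.input_gradient(X, output_index), dtype=float)
        return g * float(self.y_scale_[output_index])


_BASELINES = {
    "knn": lambda hp, seed: KNeighborsRegressor(**{"n_neighbors": 5, **hp}),
    "rf": lambda hp, seed: RandomForestRegressor(
        **{"n_estimators": 100, "random_state": seed, "n_jobs": 1, **hp}),
    "svr": lambda hp, seed: MultiOutputRegressor(SVR(**{"C": 1.0, **hp})),
}

#: Documented search bounds for the validation grid search.
DEFAULT_SEARCH = {
    "knn": [{"n_neighbors": k} for k in (1, 3, 5, 10, 20)],
    "rf": [{"n_estimators": n, "max_depth": d}
           for n in (50, 100) for d in (None, 20)],
    "svr": [{"C": c} for c in (0.1, 1.0, 10.0)],
}


class BaselineRegressor(BaseEstimator, RegressorMixin):
    """Classical multi-output baseline (KNN, random forest or SVR)."""

    def __init__(self, algo="knn", hyperparams=None, random_state=None):
        self.algo = algo
        self.hyperparams = hyperparams
        self.random_state = random_state

    def fit(self, X, y):
        if self.algo not in _BASELINES:
            raise ValueError(f"unsupported algo {self.algo!r}; choose from "
                             f"{sorted(_BASELINES)}")
        X, y = check_X_y(X, y, multi_output=True, y_numeric=True, dtype=np.float32)
        hp = dict(self.hyperparams or {})
        self.model_ = _BASELINES[self.algo](hp, self.random_state)
        self.model_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=np.float32)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}")
        return np.asarray(self.model_.predict(X), dtype=float)


# --------------------------------------------------------------- dataset API

def _split_xy(dataset: Dataset, split: str):
    idx = dataset.indices(split)
    return dataset.X[idx], dataset.labels[idx]


def train_fcnn(dataset: Dataset, config: TrainConfig = None) -> FCNNRegressor:
    """Fit an FCNN on the dataset's train split, early-stopped on its val split.

    With ``config.online_corruption`` (default) and a dataset built with
    ``keep_clean=True`` under a corruption config, the training curves are
    re-corrupted every epoch; validation uses the stored (fixed) corruption.
    """
    if config is None:
        config = TrainConfig()
    X_tr, y_tr = _split_xy(dataset, "train")
    X_va, y_va = _split_xy(dataset, "val")
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("dataset needs nonempty train and val splits")
    sampler = None
    corr_dict = (dataset.provenance or {}).get("corruption")
    if config.online_corruption and dataset.clean is not None and corr_dict:
        from .corruption import BatchCorruptor, CorruptionConfig
        cfg = CorruptionConfig(**{k: tuple(v) if isinstance(v, list) else v
                                  for k, v in corr_dict.items()})
        corruptor = BatchCorruptor(dataset.clean[dataset.indices("train")],
                                   cfg, seed=config.seed)
        sampler = corruptor.sample
    model = FCNNRegressor(hidden_layer_sizes=config.hidden_layer_sizes,
                          learning_rate=config.learning_rate,
                          batch_size=config.batch_size,
                          max_epochs=config.max_epochs,
                          patience=config.patience,
                          random_state=config.seed)
    return model.fit(X_tr, y_tr, X_val=X_va, y_val=y_va, x_sampler=sampler)


def train_baseline(dataset: Dataset, algo: str, hyperparams: dict = None,
                   search: bool = False, seed: int = 0) -> BaselineRegressor:
    """Fit a classical baseline; with ``search=True`` pick hyperparameters by
    validation MAE over the documented grid (DEFAULT_SEARCH)."""
    X_tr, y_tr = _split_xy(dataset, "train")
    if search and hyperparams is None:
        X_va, y_va = _split_xy(dataset, "val")
        best, best_mae = None, np.inf
        for hp in DEFAULT_SEARCH[algo]:
            m = BaselineRegressor(algo, hp, random_state=seed).fit(X_tr, y_tr)
            mae = float(np.abs(m.predict(X_va) - y_va).mean())
            if mae < best_mae:
                best, best_mae = hp, mae
        hyperparams = best
    return BaselineRegressor(algo, hyperparams, random_state=seed).fit(X_tr, y_tr)


def predict_params(model, X) -> np.ndarray:
    """Predict and decode to the nine physical parameters, (n, 9)."""
    X = np.atleast_2d(np.asarray(X))
    if X.shape[0] == 0:
        return np.empty((0, 9))
    return codec.decode_batch(model.predict(X))


def predict(model, curves) -> list:
    """Predict a list of IChiCurve objects -> list of OrientationParams."""
    from .forward import OrientationParams
    if not curves:
        return []
    n_bins = curves[0].grid.n_bins
    if 2 * n_bins != getattr(model, "n_features_in_", 2 * n_bins):
        raise ValueError("curve grid length does not match model input size")
    X = np.stack([np.concatenate([c.intensity, c.valid_mask.astype(float)])
                  for c in curves])
    return [OrientationParams.from_array(r) for r in predict_params(model, X)]
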