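"""Feed-forward ANN species classification with specimen-level CV.

Features are z-scored with parameters estimated on training fragments only,
then fed to a feed-forward network with two sigmoid hidden layers of 50
nodes and a softmax output.  Training uses early stopping on a random
70:20:10 division of the training fragments (70 gradient updates, 20
validation for stopping, 10 monitored hold-out).  Cross-validation holds
out one randomly chosen specimen per species per round, so no fragment of
a test specimen ever influences training ("leave one specimen out").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .datasets import SpecimenDataset, feature_set_columns


@dataclass
class NormalizationParams:
    """Per-column location/scale fitted on training rows only.

    Zero-variance columns get scale 1 (their normalized value is 0) and
    are listed in ``constant_columns``.
    """

    scaler: object
    columns: list[str]
    constant_columns: list[str]


def fit_normalizer(train: pd.DataFrame, method: str = "zscore") -> NormalizationParams:
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty matrix")
    X = np.asarray(train, dtype=float)
    if method == "zscore":
        scaler = StandardScaler().fit(X)
        constant = np.flatnonzero(scaler.var_ == 0)
    elif method == "minmax":
        scaler = MinMaxScaler().fit(X)
        constant = np.flatnonzero(scaler.data_range_ == 0)
    else:
        raise ValueError("method must be 'zscore' or 'minmax'")
    cols = list(train.columns) if hasattr(train, "columns") else list(range(X.shape[1]))
    return NormalizationParams(scaler=scaler, columns=cols,
                               constant_columns=[cols[i] for i in constant])


def apply_normalizer(params: NormalizationParams, matrix: pd.DataFrame) -> np.ndarray:
    return params.scaler.transform(np.asarray(matrix, dtype=float))


@dataclass
class ANNConfig:
    """Network and training-protocol configuration."""

    hidden_layers: tuple[int, int] = (50, 50)
    activation: str = "logistic"
    split: tuple[float, float, float] = (0.7, 0.2, 0.1)
    patience: int = 6
    max_epochs: int = 1000
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


class ElytraNet(BaseEstimator, ClassifierMixin):
    """Two-hidden-layer sigmoid network with loss-monitored early stopping.

    An estimator around :class:`sklearn.neural_network.MLPClassifier`
    implementing the training protocol: the fit rows are randomly divided
    70:20:10 into a gradient set, a validation set and a monitored hold-out
    (scored into ``monitor_accuracy_``).  The network trains one epoch at a
    time; training halts when the validation cross-entropy loss has failed
    to improve for ``patience`` consecutive epochs, and the weights of the
    best validation epoch are restored.  Monitoring the loss rather than
    the validation accuracy matters here: with few training specimens the
    validation accuracy saturates within a handful of epochs while the
    loss — and the network's generalization — keeps improving.
    Deterministic per ``random_state``.
    """

    #: minimum validation-loss improvement that resets the patience counter
    _LOSS_TOL = 1e-4

    def __init__(self, hidden_layers=(50, 50), activation="logistic",
                 split=(0.7, 0.2, 0.1), patience=6, max_epochs=1000,
                 learning_rate=0.01, random_state=0):
        self.hidden_layers = hidden_layers
        self.activation = activation
        self.split = split
        self.patience = patience
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        from copy import deepcopy

        from sklearn.metrics import log_loss

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain at least 2 classes")
        train_frac, val_frac, monitor_frac = self.split
        if monitor_frac > 0:
            X_fit, X_mon, y_fit, y_mon = train_test_split(
                X, y, test_size=monitor_frac, random_state=self.random_state)
        else:
            X_fit, y_fit = X, y
            X_mon = y_mon = None
        X_tr, X_val, y_tr, y_val = train_test_split(
            X_fit, y_fit, test_size=val_frac / (train_frac + val_frac),
            random_state=self.random_state)

        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_layers),
            activation=self.activation,
            max_iter=1,
            learning_rate_init=self.learning_rate,
            random_state=self.random_state,
        )
        best_loss = np.inf
        marked_loss = np.inf  # last loss that reset the patience counter
        best_weights = None
        stall = 0
        self.validation_losses_ = []
        import warnings as _warnings

        for _epoch in range(self.max_epochs):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # per-epoch convergence noise
                self.mlp_.partial_fit(X_tr, y_tr, classes=classes)
            val_loss = log_loss(y_val, self.mlp_.predict_proba(X_val),
                                labels=classes)
            self.validation_losses_.append(float(val_loss))
            if val_loss < best_loss:  # track the strict minimum for restore
                best_loss = val_loss
                best_weights = (deepcopy(self.mlp_.coefs_),
                                deepcopy(self.mlp_.intercepts_))
            if val_loss < marked_loss - self._LOSS_TOL:
                marked_loss = val_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_weights is not None:
            self.mlp_.coefs_, self.mlp_.intercepts_ = best_weights
        self.best_validation_loss_ = float(best_loss)
        self.n_epochs_ = len(self.validation_losses_)
        self.classes_ = self.mlp_.classes_
        self.monitor_accuracy_ = (float(self.mlp_.score(X_mon, y_mon))
                                  if X_mon is not None and len(X_mon) else None)
        return self

    def predict(self, X):
        # argmax of class scores; sklearn breaks ties by lowest class index
        return self.mlp_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.mlp_.predict_proba(np.asarray(X, dtype=float))


def train_ann(train: pd.DataFrame, labels, cfg: ANNConfig | None = None) -> ElytraNet:
    """Fit the ANN on a (normalized) training matrix."""
    if cfg is None:
        cfg = ANNConfig()
    net = ElytraNet(hidden_layers=cfg.hidden_layers, activation=cfg.activation,
                    split=cfg.split, patience=cfg.patience,
                    max_epochs=cfg.max_epochs, learning_rate=cfg.learning_rate,
                    random_state=cfg.seed)
    return net.fit(train, labels)


@dataclass
class CVResult:
    """Cross-validation summary across rounds."""

    rounds: int
    overall_accuracy: float
    overall_std: float
    per_species: pd.DataFrame  # index species, columns mean/std
    confusion: pd.DataFrame    # summed over rounds
    round_accuracies: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "overall_accuracy": self.overall_accuracy,
            "overall_std": self.overall_std,
            "per_species": self.per_species.to_dict(orient="index"),
            "confusion": self.confusion.values.tolist(),
            "round_accuracies": self.round_accuracies,
        }


def loso_splits(labels, groups, rounds: int, seed: int = 0) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Round-wise leave-one-specimen-out splits.

    Each round independently reserves one random specimen per species; all
    its fragments form the test set.  Yields (train_idx, test_idx) pairs of
    row indices.  A species with a single specimen cannot be split and
    raises.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    species = np.unique(labels)
    for sp in species:
        if np.unique(groups[labels == sp]).size < 2:
            raise ValueError(f"species {sp} has only one specimen; "
                             "leave-one-specimen-out needs at least two")
    rng = np.random.default_rng(seed)
    for _ in range(rounds):
        held = []
        for sp in species:
            specimens = np.unique(groups[labels == sp])
            held.append(specimens[rng.integers(specimens.size)])
        test = np.isin(groups, held)
        yield np.flatnonzero(~test), np.flatnonzero(test)


def loso_cv(
    dataset: SpecimenDataset,
    feature_set: str = "all",
    rounds: int = 100,
    cfg: ANNConfig | None = None,
    seed: int = 0,
    normalization: str = "zscore",
) -> CVResult:
    """Specimen-level cross-validation of the ANN on one feature set.

    Per round: hold out one specimen per species, fit the normalizer and
    the network on the remaining fragments only, and score the held-out
    fragments.  Overall accuracy is fragment-level; per-species accuracy is
    computed over that species' test fragments.  The reported std is the
    across-round sample standard deviation.
    """
    if cfg is None:
        cfg = ANNConfig()
    X = dataset.matrix(feature_set)
    y = np.asarray(dataset.labels)
    groups = np.asarray(dataset.groups)
    species = np.unique(y)

    accs: list[float] = []
    per_species_accs: dict[int, list[float]] = {int(sp): [] for sp in species}
    confusion = np.zeros((species.size, species.size), dtype=int)
    round_seed = np.random.SeedSequence([seed, rounds]).generate_state(1)[0] % (2**31)

    for rnd, (train_idx, test_idx) in enumerate(
            loso_splits(y, groups, rounds, seed=int(round_seed))):
        train_specimens = set(groups[train_idx])
        test_specimens = set(groups[test_idx])
        assert not train_specimens & test_specimens, "specimen leakage between splits"

        params = fit_normalizer(X.iloc[train_idx], method=normalization)
        Xtr = apply_normalizer(params, X.iloc[train_idx])
        Xte = apply_normalizer(params, X.iloc[test_idx])
        net_cfg = ANNConfig(hidden_layers=cfg.hidden_layers, activation=cfg.activation,
                            split=cfg.split, patience=cfg.patience,
                            max_epochs=cfg.max_epochs, learning_rate=cfg.learning_rate,
                            seed=cfg.seed + rnd)
        net = train_ann(Xtr, y[train_idx], net_cfg)
        pred = net.predict(Xte)
        truth = y[test_idx]
        accs.append(float((pred == truth).mean()))
        for sp in species:
            m = truth == sp
            if m.any():
                per_species_accs[int(sp)].append(float((pred[m] == sp).mean()))
        confusion += confusion_matrix(truth, pred, labels=species)

    per_species = pd.DataFrame({
        "mean": {sp: float(np.mean(v)) if v else np.nan
                 for sp, v in per_species_accs.items()},
        "std": {sp: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
                for sp, v in per_species_accs.items()},
    })
    return CVResult(
        rounds=rounds,
        overall_accuracy=float(np.mean(accs)),
        overall_std=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        per_species=per_species,
        confusion=pd.DataFrame(confusion, index=species, columns=species),
        round_accuracies=accs,
    )
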