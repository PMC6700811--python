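"""Relating plot color features to 1-5 visual severity scores.

The three per-plot features — proportions of green, yellow and brown canopy
pixels — are related to ordinal 1-5 visual IDC scores with two classifiers,
both treating the score as an unordered category:

* a random forest (100 trees, minimum node size 10 to attempt a split, all
  three features searched at every split since p = 3);
* a small neural network: one hidden layer of 3 tanh units, softmax output,
  cross-entropy loss, full-batch gradient descent at learning rate 0.1.

Evaluation uses 5x5 confusion matrices on a held-out validation split, plus
a high/low-stress binning (scores 4-5 vs 1-3) that reflects how a breeder
culls susceptible lines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

FEATURES = ["prop_green", "prop_yellow", "prop_brown"]
CLASSES = (1, 2, 3, 4, 5)
HIGH_STRESS_MIN = 4  # scores 4 and 5 bin to "high stress"

_SPLIT_RETRIES = 20


@dataclass
class ConfusionMatrix:
    """5x5 reference-vs-predicted confusion table.

    ``counts``: rows = reference score, columns = predicted score.
    ``row_percent`` normalises each reference row to 100, i.e. entry (r, p)
    is the percentage of reference-class-r plots that were predicted p.
    """

    counts: pd.DataFrame
    row_percent: pd.DataFrame
    overall_accuracy: float  # percent

    def report(self) -> str:
        lines = ["Confusion matrix: rows reference, columns predicted (%)", ""]
        lines.append(self.row_percent.round(1).to_string())
        lines.append("")
        lines.append(f"Overall accuracy (%) = {self.overall_accuracy:.1f}")
        return "\n".join(lines)


def split_train_validation(
    data: pd.DataFrame,
    validation_fraction: float = 0.33,
    seed: int = 0,
    stratify: bool = True,
    score_col: str = "score",
) -> pd.DataFrame:
    """Partition plots into train/validation sets, stratified by score class.

    Returns a copy of ``data`` with a ``partition`` column ("train" /
    "validation").  If after a draw some score class is absent from the
    training set, the draw is retried (bounded) with a warning.
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError(f"validation_fraction must be in (0,1), got {validation_fraction}")
    rng = np.random.default_rng(seed)
    classes = sorted(data[score_col].unique())
    for attempt in range(_SPLIT_RETRIES):
        val_idx = []
        if stratify:
            for _, grp in data.groupby(score_col):
                n_val = int(round(len(grp) * validation_fraction))
                n_val = min(max(n_val, 0), len(grp))
                val_idx.extend(rng.choice(grp.index.to_numpy(), size=n_val,
                                          replace=False).tolist())
        else:
            n_val = int(round(len(data) * validation_fraction))
            val_idx = rng.choice(data.index.to_numpy(), size=n_val,
                                 replace=False).tolist()
        out = data.copy()
        out["partition"] = "train"
        out.loc[val_idx, "partition"] = "validation"
        train_classes = set(out.loc[out["partition"] == "train", score_col])
        if train_classes.issuperset(classes):
            return out
        logger.warning("split left classes %s out of training (attempt %d); redrawing",
                       sorted(set(classes) - train_classes), attempt + 1)
    logger.warning("could not place every class in training after %d retries",
                   _SPLIT_RETRIES)
    return out


def _check_training(train: pd.DataFrame, score_col: str) -> None:
    if train[score_col].nunique() < 2:
        raise ValueError("training data must contain at least 2 score classes")


def train_random_forest(
    train: pd.DataFrame,
    n_trees: int = 100,
    min_split_size: int = 10,
    seed: int = 0,
    max_features=None,
    score_col: str = "score",
) -> RandomForestClassifier:
    """Fit the random forest on (prop_green, prop_yellow, prop_brown).

    ``min_split_size`` is the minimum node size at which a split is still
    attempted; with only three features every split searches all of them
    unless ``max_features`` overrides that.
    """
    _check_training(train, score_col)
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        min_samples_split=min_split_size,
        max_features=max_features,
        criterion="gini",
        random_state=int(seed),
    )
    clf.fit(train[FEATURES].to_numpy(), train[score_col].to_numpy())
    return clf


class NeuralNetClassifier:
    """Single-hidden-layer tanh network trained by full-batch gradient descent.

    Architecture: 3 inputs -> ``hidden_units`` tanh units -> softmax over the
    score classes; loss is mean cross-entropy.  Inputs are standardized to
    zero mean and unit variance internally (the usual conditioning step for
    small networks on proportion-scale features).  Training runs plain
    gradient descent at the configured learning rate for at most
    ``max_epochs`` epochs, with early stopping when an internally held-out
    slice of the training data shows no loss improvement for ``patience``
    epochs; the best-so-far weights are kept.
    """

    def __init__(
        self,
        hidden_units: int = 3,
        learning_rate: float = 0.1,
        max_epochs: int = 500,
        patience: int = 25,
        holdout_fraction: float = 0.15,
        seed: int = 0,
    ) -> None:
        if learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.holdout_fraction = holdout_fraction
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self.n_epochs_: int = 0
        self.converged_: bool = False

    # -- internals ---------------------------------------------------------
    def _forward(self, X, W1, b1, W2, b2):
        h = np.tanh(X @ W1 + b1)
        z = h @ W2 + b2
        z -= z.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        return h, p

    def _loss(self, p, Y):
        return float(-(Y * np.log(np.clip(p, 1e-12, None))).sum() / len(Y))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NeuralNetClassifier":
        X = np.asarray(X, dtype=np.float64)
        self.input_mean_ = X.mean(axis=0)
        self.input_sd_ = X.std(axis=0)
        self.input_sd_[self.input_sd_ == 0] = 1.0
        X = (X - self.input_mean_) / self.input_sd_
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data must contain at least 2 score classes")
        n, d = X.shape
        k = len(self.classes_)
        Y = (y[:, None] == self.classes_[None, :]).astype(np.float64)
        rng = np.random.default_rng(self.seed)

        # internal holdout for early stopping
        n_hold = int(round(n * self.holdout_fraction))
        perm = rng.permutation(n)
        hold, fit_idx = perm[:n_hold], perm[n_hold:]
        if len(fit_idx) == 0:
            fit_idx, hold = perm, perm[:0]
        Xf, Yf = X[fit_idx], Y[fit_idx]
        Xh, Yh = X[hold], Y[hold]

        W1 = rng.normal(0.0, 0.5, size=(d, self.hidden_units))
        b1 = np.zeros(self.hidden_units)
        W2 = rng.normal(0.0, 0.5, size=(self.hidden_units, k))
        b2 = np.zeros(k)

        best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
        best_loss = np.inf
        stall = 0
        lr = self.learning_rate
        for epoch in range(1, self.max_epochs + 1):
            h, p = self._forward(Xf, W1, b1, W2, b2)
            grad_z = (p - Yf) / len(Xf)
            gW2 = h.T @ grad_z
            gb2 = grad_z.sum(axis=0)
            grad_h = grad_z @ W2.T * (1.0 - h**2)
            gW1 = Xf.T @ grad_h
            gb1 = grad_h.sum(axis=0)
            W1 -= lr * gW1
            b1 -= lr * gb1
            W2 -= lr * gW2
            b2 -= lr * gb2

            Xm, Ym = (Xh, Yh) if len(Xh) else (Xf, Yf)
            _, pm = self._forward(Xm, W1, b1, W2, b2)
            monitor = self._loss(pm, Ym)
            if monitor < best_loss - 1e-9:
                best_loss = monitor
                best = (W1.copy(), b1.copy(), W2.copy(), b2.copy())
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    self.converged_ = True
                    break
        else:
            warnings.warn(
                "neural network reached max_epochs without early stopping; "
                "returning best-so-far weights",
                stacklevel=2,
            )
        self.n_epochs_ = epoch
        self.W1_, self.b1_, self.W2_, self.b2_ = best
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=np.float64) - self.input_mean_) / self.input_sd_
        _, p = self._forward(X, self.W1_, self.b1_, self.W2_, self.b2_)
        return p

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_neural_network(
    train: pd.DataFrame,
    hidden_units: int = 3,
    learning_rate: float = 0.1,
    max_epochs: int = 500,
    patience: int = 25,
    seed: int = 0,
    score_col: str = "score",
) -> NeuralNetClassifier:
    """Fit the 3-tanh-unit network on the color-proportion features."""
    _check_training(train, score_col)
    nn = NeuralNetClassifier(
        hidden_units=hidden_units,
        learning_rate=learning_rate,
        max_epochs=max_epochs,
        patience=patience,
        seed=seed,
    )
    nn.fit(train[FEATURES].to_numpy(), train[score_col].to_numpy())
    return nn


def evaluate(
    classifier,
    validation: pd.DataFrame,
    classes: tuple = CLASSES,
    score_col: str = "score",
) -> ConfusionMatrix:
    """Confusion matrix of a fitted classifier on the validation split."""
    if len(validation) == 0:
        raise ValueError("validation set is empty")
    y_true = validation[score_col].to_numpy()
    y_pred = classifier.predict(validation[FEATURES].to_numpy())
    return confusion_from_predictions(y_true, y_pred, classes=classes)


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, classes: tuple = CLASSES
) -> ConfusionMatrix:
    counts = pd.crosstab(pd.Series(y_true, name="reference"),
                         pd.Series(y_pred, name="predicted"))
    counts = counts.reindex(index=list(classes), columns=list(classes),
                            fill_value=0).astype(int)
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    row_percent = 100.0 * counts.div(row_tot, axis=0)
    grand = counts.to_numpy().sum()
    overall = 100.0 * np.diag(counts.to_numpy()).sum() / grand
    return ConfusionMatrix(counts=counts, row_percent=row_percent,
                           overall_accuracy=float(overall))


def bin_scores(scores) -> np.ndarray:
    """Map 1-5 scores to "low" (1-3) / "high" (4-5) stress bins."""
    arr = np.asarray(scores)
    if not np.isin(arr, CLASSES).all():
        raise ValueError("scores must be in 1..5")
    return np.where(arr >= HIGH_STRESS_MIN, "high", "low")


def binned_accuracy(y_true, y_pred) -> tuple[float, pd.DataFrame]:
    """2-class (high/low stress) accuracy and its 2x2 confusion table.

    Coarsening to two bins can only turn mismatches into matches, so the
    binned accuracy is never below the 5-class accuracy.
    """
    bt, bp = bin_scores(y_true), bin_scores(y_pred)
    counts = pd.crosstab(pd.Series(bp, name="predicted"),
                         pd.Series(bt, name="reference"))
    counts = counts.reindex(index=["low", "high"], columns=["low", "high"],
                            fill_value=0).astype(int)
    acc = 100.0 * float((bt == bp).mean())
    return acc, counts


def adjacent_misclassification_fraction(cm: ConfusionMatrix) -> float:
    """Fraction of misclassified plots whose prediction is an adjacent class.

    The well-known confusion pattern for ordinal stress scales is that errors
    concentrate at |predicted - reference| = 1.
    """
    counts = cm.counts.to_numpy()
    classes = np.array(cm.counts.index, dtype=float)
    pred, ref = np.meshgrid(classes, classes, indexing="ij")
    off = pred != ref
    n_off = counts[off].sum()
    if n_off == 0:
        return float("nan")
    adjacent = off & (np.abs(pred - ref) == 1)
    return float(counts[adjacent].sum() / n_off)
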