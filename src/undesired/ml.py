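"""Random-forest and feed-forward-network classification of binary outcomes.

The network is a hand-rolled single-hidden-layer perceptron with sigmoid
activations throughout; each node computes ``M = sum(x w) - b`` and emits
``1 / (1 + exp(-M))``.  Training is full-batch gradient descent on the
cross-entropy.  The forest delegates to scikit-learn's bagged-tree
ensemble behind the module's own surface (seeded, tree count from
config).  Variable importance comes in two flavours: permutation-based
mean decrease in accuracy (both models) and impurity-based mean decrease
in Gini (forest only).  The positive class is outcome = 1 and the
probability-to-class threshold is 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

DEFAULTS = {
    "split_fraction": 0.7,
    "n_trees": 500,
    "hidden_size": 8,
    "epochs": 200,
    "learning_rate": 0.1,
    "threshold": 0.5,
}


def split_train_test(
    table: pd.DataFrame,
    fraction: float = DEFAULTS["split_fraction"],
    seed: int = 0,
    stratify: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded, disjoint, exhaustive train/test split.

    Stratified by ``stratify`` when given; strata with fewer than two rows
    trigger a warning and an unstratified fallback.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(table))
    if stratify is not None:
        counts = table[stratify].value_counts()
        if (counts < 2).any():
            warnings.warn(f"stratum of {stratify!r} too small; unstratified split")
            stratify = None
    if stratify is None:
        perm = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        train_parts, test_parts = [], []
        for _, grp in table.groupby(stratify, sort=True):
            perm = rng.permutation(grp.index.to_numpy())
            n_train = int(round(fraction * len(perm)))
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
        train_idx = np.sort(np.concatenate(train_parts))
        test_idx = np.sort(np.concatenate(test_parts))
        return table.loc[train_idx], table.loc[test_idx]
    return table.iloc[train_idx], table.iloc[test_idx]


def _sigmoid(m: np.ndarray) -> np.ndarray:
    out = np.empty_like(m)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-m[pos]))
    em = np.exp(m[~pos])
    out[~pos] = em / (1.0 + em)
    return out


@dataclass
class MlpModel:
    """One-hidden-layer sigmoid network: node input ``M = x.W - b``."""

    W1: np.ndarray  # (p, h)
    b1: np.ndarray  # (h,)
    W2: np.ndarray  # (h,)
    b2: float
    feature_names: list[str] = field(default_factory=list)
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"input has {x.shape[1]} features, model expects {self.W1.shape[0]}"
            )
        if self.x_mean is not None:
            x = (x - self.x_mean) / self.x_scale
        hidden = _sigmoid(x @ self.W1 - self.b1)
        return _sigmoid(hidden @ self.W2 - self.b2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def predict(self, X: np.ndarray, threshold: float = DEFAULTS["threshold"]) -> np.ndarray:
        return (self.forward(X) >= threshold).astype(int)


def mlp_forward(model: MlpModel, x: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; output in (0, 1)."""
    return model.forward(x)


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    hidden_size: int = DEFAULTS["hidden_size"],
    epochs: int = DEFAULTS["epochs"],
    learning_rate: float = DEFAULTS["learning_rate"],
    seed: int = 0,
    feature_names: list[str] | None = None,
    standardize: bool = True,
) -> MlpModel:
    """Full-batch gradient descent on cross-entropy; seeded initialization.

    Inputs are standardized internally by default (the scaling is stored
    in the model, so prediction accepts raw features).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, p = X.shape
    if standardize:
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale[x_scale == 0] = 1.0
        Xs = (X - x_mean) / x_scale
    else:
        x_mean = x_scale = None
        Xs = X
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0.0, 0.5, size=(p, hidden_size))
    b1 = rng.normal(0.0, 0.5, size=hidden_size)
    W2 = rng.normal(0.0, 0.5, size=hidden_size)
    b2 = float(rng.normal(0.0, 0.5))
    for epoch in range(epochs):
        hidden = _sigmoid(Xs @ W1 - b1)
        out = _sigmoid(hidden @ W2 - b2)
        loss = -np.mean(
            y * np.log(np.clip(out, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - out, 1e-12, 1))
        )
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        delta_out = (out - y) / n                     # dL/dM_out
        grad_W2 = hidden.T @ delta_out
        grad_b2 = -delta_out.sum()                    # minus-bias convention
        delta_hidden = np.outer(delta_out, W2) * hidden * (1 - hidden)
        grad_W1 = Xs.T @ delta_hidden
        grad_b1 = -delta_hidden.sum(axis=0)
        W1 -= learning_rate * grad_W1
        b1 -= learning_rate * grad_b1
        W2 -= learning_rate * grad_W2
        b2 -= learning_rate * grad_b2
    return MlpModel(
        W1=W1,
        b1=b1,
        W2=W2,
        b2=b2,
        feature_names=list(feature_names or []),
        x_mean=x_mean,
        x_scale=x_scale,
    )


@dataclass
class RfModel:
    """Seeded bagged-tree ensemble (majority vote over trees)."""

    estimator: RandomForestClassifier
    feature_names: list[str] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))[:, 1]

    def predict(self, X: np.ndarray, threshold: float = DEFAULTS["threshold"]) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def train_rf(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = DEFAULTS["n_trees"],
    seed: int = 0,
    feature_names: list[str] | None = None,
    max_features: str | float = "sqrt",
) -> RfModel:
    """Bootstrap tree ensemble with random feature subsets at each split."""
    y = np.asarray(y).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("training outcome is single-class")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    est.fit(np.asarray(X, dtype=float), y.astype(int))
    return RfModel(estimator=est, feature_names=list(feature_names or []))


def importance(
    model: RfModel | MlpModel,
    X: np.ndarray,
    y: np.ndarray,
    method: str = "mean_decrease_accuracy",
    seed: int = 0,
    repeats: int = 5,
) -> pd.DataFrame:
    """Ranked variable-importance table (descending, top-2 highlighted).

    ``mean_decrease_accuracy``: accuracy drop (percentage points) when the
    feature column is permuted on the evaluation data, averaged over
    ``repeats`` seeded permutations.  ``mean_decrease_gini``: total
    impurity decrease per feature across the forest's trees (forest only),
    reported as percent of the total.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel().astype(int)
    names = model.feature_names or [f"x{i}" for i in range(X.shape[1])]
    if method == "mean_decrease_gini":
        if not isinstance(model, RfModel):
            raise ValueError("mean_decrease_gini is only defined for the forest")
        scores = 100.0 * model.estimator.feature_importances_
    elif method == "mean_decrease_accuracy":
        rng = np.random.default_rng(seed)
        base = float((model.predict(X) == y).mean())
        scores = np.zeros(X.shape[1])
        for i in range(X.shape[1]):
            drops = []
            for _ in range(repeats):
                Xp = X.copy()
                Xp[:, i] = Xp[rng.permutation(len(X)), i]
                drops.append(base - float((model.predict(Xp) == y).mean()))
            scores[i] = 100.0 * float(np.mean(drops))
    else:
        raise ValueError(f"unsupported importance method {method!r}")
    df = (
        pd.DataFrame({"variable": names, "importance": scores})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)
    df["top2"] = df["rank"] <= 2
    return df


def evaluate(model, X: np.ndarray, y: np.ndarray) -> dict:
    """Confusion counts and accuracy/sensitivity/specificity percentages."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel().astype(int)
    if len(y) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return {
        "tp": tp,
        "tn": tn,
        "fp": fp,
        "fn": fn,
        "accuracy": 100.0 * (tp + tn) / len(y),
        "sensitivity": 100.0 * tp / (tp + fn) if tp + fn else None,
        "specificity": 100.0 * tn / (tn + fp) if tn + fp else None,
    }
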