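"""Gradient-boosted behaviour classification.

Boosted tree ensembles are trained on labelled captive epochs to
recognise the four behaviours (foraging, travelling, grooming,
resting).  Training balances classes by down-sampling, grid-searches
boosted-tree hyperparameters by stratified k-fold cross-validation on
a stratified 75/25 train/test split, and reports out-of-sample
accuracy and Cohen's kappa.  Fitted models emit per-epoch class
probabilities for wild data; epochs classified with low confidence can
be cross-tabulated against their runner-up class to show where the
model confuses behaviours.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold, train_test_split

from .features import COVARIATE_COLUMNS, FEATURE_NAMES
from .types import BEHAVIOURS

logger = logging.getLogger(__name__)

#: Default hyperparameter grid: small and reproducible at desk scale.
DEFAULT_GRID: dict[str, tuple] = {
    "max_depth": (3, 5, 7),
    "learning_rate": (0.05, 0.1, 0.3),
    "n_estimators": (50, 200),
    "subsample": (0.8, 1.0),
}

#: Reduced grid for quick runs (pipeline default).
SMALL_GRID: dict[str, tuple] = {
    "max_depth": (3, 5),
    "learning_rate": (0.1, 0.3),
    "n_estimators": (50, 150),
    "subsample": (1.0,),
}

CATEGORICAL_COVARIATES = ("attachment", "age_class", "sex", "species")


@dataclass
class TrainConfig:
    epoch_samples: int = 21
    class_balance_n: int = 250
    parameter_grid: dict = field(default_factory=lambda: dict(DEFAULT_GRID))
    cv_folds: int = 5
    test_fraction: float = 0.25
    include_covariates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.parameter_grid:
            raise ValueError("parameter_grid must be non-empty")
        if self.class_balance_n < self.cv_folds:
            raise ValueError("class_balance_n must be >= cv_folds")


@dataclass
class ModelReport:
    cross_validation_accuracy: float
    out_of_sample_accuracy: float
    kappa: float
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    chosen_hyperparameters: dict

    def to_dict(self) -> dict:
        return {
            "cross_validation_accuracy": self.cross_validation_accuracy,
            "out_of_sample_accuracy": self.out_of_sample_accuracy,
            "kappa": self.kappa,
            "confusion": self.confusion.to_dict(),
            "chosen_hyperparameters": self.chosen_hyperparameters,
        }


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a K x K confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o = trace/total and
    p_e = sum_i row_i * col_i / total^2.  Returns 1.0 in the degenerate
    case where both observed and expected agreement are 1.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion must be a square matrix")
    if np.any(c < 0):
        raise ValueError("confusion counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        return 1.0 if p_o >= 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def downsample_balanced(
    epochs: pd.DataFrame,
    n_per_class: int,
    seed: int,
    classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Randomly select ``n_per_class`` epochs per behaviour, without
    replacement.  If the rarest class has fewer, n is lowered to that
    count (logged).  ``classes`` lists the categories that must be
    present (default: those observed in the data)."""
    if "label" not in epochs.columns:
        raise ValueError("epochs must carry a 'label' column")
    counts = epochs["label"].value_counts()
    if classes is not None:
        empty = [b for b in classes if counts.get(b, 0) == 0]
        if empty:
            raise ValueError(f"no examples for class(es): {', '.join(empty)}")
        counts = counts[list(classes)]
    min_count = int(counts.min())
    if n_per_class > min_count:
        logger.warning(
            "n_per_class=%d exceeds the rarest class count %d; lowering",
            n_per_class, min_count,
        )
        n_per_class = min_count
    rng = np.random.default_rng(seed)
    picks = []
    for b in sorted(counts.index):
        idx = epochs.index[epochs["label"] == b].to_numpy()
        picks.append(rng.choice(idx, size=n_per_class, replace=False))
    sel = np.sort(np.concatenate(picks))
    return epochs.loc[sel]


def _design_matrix(
    epochs: pd.DataFrame, include_covariates: bool,
    feature_columns: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Numeric design matrix: 52 features + one-hot covariates + location."""
    x = epochs[list(FEATURE_NAMES)].copy()
    cat = pd.get_dummies(
        epochs["location"].astype(
            pd.CategoricalDtype(["land", "surface", "underwater"])
        ),
        prefix="location",
    ).astype(float)
    x = pd.concat([x, cat], axis=1)
    if include_covariates:
        for col in CATEGORICAL_COVARIATES:
            d = pd.get_dummies(epochs[col].astype(str), prefix=col).astype(float)
            x = pd.concat([x, d], axis=1)
        x["mass_kg"] = epochs["mass_kg"].astype(float)
    if feature_columns is not None:
        missing = [c for c in feature_columns if c not in x.columns]
        extra = [c for c in x.columns if c not in feature_columns]
        # one-hot levels absent from a prediction set are legitimately zero
        for c in missing:
            if any(c.startswith(p + "_") for p in CATEGORICAL_COVARIATES + ("location",)):
                x[c] = 0.0
        missing = [c for c in feature_columns if c not in x.columns]
        extra = [c for c in x.columns if c not in feature_columns]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch; missing={missing} extra={extra}"
            )
        x = x[feature_columns]
    bad = x.columns[~np.isfinite(x.to_numpy(dtype=float)).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite values in feature column(s): {list(bad)}")
    return x


class BehaviourModel:
    """A fitted boosted-tree classifier plus its feature schema."""

    def __init__(
        self,
        booster: xgb.Booster,
        feature_columns: list[str],
        classes: Sequence[str],
        config: TrainConfig,
    ) -> None:
        self.booster = booster
        self.feature_columns = list(feature_columns)
        self.classes = list(classes)
        self.config = config

    def predict_proba(self, epochs: pd.DataFrame) -> np.ndarray:
        x = _design_matrix(
            epochs, self.config.include_covariates, self.feature_columns
        )
        proba = self.booster.predict(xgb.DMatrix(x.to_numpy(dtype=float)))
        return np.asarray(proba).reshape(len(x), len(self.classes))

    def save(self, path: str) -> None:
        """Save the model (JSON) plus a schema manifest."""
        os.makedirs(path, exist_ok=True)
        self.booster.save_model(os.path.join(path, "model.json"))
        cfg = {
            k: v for k, v in self.config.__dict__.items()
        }
        manifest = {
            "feature_columns": self.feature_columns,
            "classes": self.classes,
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
        }
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    @classmethod
    def load(cls, path: str) -> "BehaviourModel":
        with open(os.path.join(path, "manifest.json")) as fh:
            manifest = json.load(fh)
        cfg_d = manifest["config"]
        cfg_d["parameter_grid"] = {
            k: tuple(v) for k, v in cfg_d["parameter_grid"].items()
        }
        cfg = TrainConfig(**cfg_d)
        booster = xgb.Booster()
        booster.load_model(os.path.join(path, "model.json"))
        return cls(booster, manifest["feature_columns"], manifest["classes"], cfg)


def _grid_points(grid: dict) -> list[dict]:
    keys = sorted(grid)
    points = [{}]
    for k in keys:
        points = [dict(p, **{k: v}) for p in points for v in grid[k]]
    return points


def _make_xgb(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        objective="multi:softprob",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
        **params,
    )


def train_gbm(
    epochs: pd.DataFrame, cfg: TrainConfig
) -> tuple[BehaviourModel, ModelReport]:
    """Grid-searched boosted-tree training on labelled epochs.

    The data are split 75/25 (stratified by behaviour); the training
    split is balanced by down-sampling and grid-searched with
    stratified k-fold cross-validation; the winning grid point is
    refit on the full balanced training split and scored on the
    held-out test split (accuracy, kappa, per-class confusion).
    Deterministic for a fixed seed and grid.
    """
    labels = epochs["label"]
    present = sorted(labels.unique())
    if len(present) < 2:
        raise ValueError("need at least 2 behaviour classes to train")
    x_all = _design_matrix(epochs, cfg.include_covariates)
    feature_columns = list(x_all.columns)
    class_to_int = {c: i for i, c in enumerate(present)}

    idx_train, idx_test = train_test_split(
        np.arange(len(epochs)),
        test_size=cfg.test_fraction,
        stratify=labels,
        random_state=cfg.seed,
    )
    train_df = epochs.iloc[idx_train].reset_index(drop=True)
    test_df = epochs.iloc[idx_test].reset_index(drop=True)
    train_df = downsample_balanced(train_df, cfg.class_balance_n, cfg.seed)

    x_tr = _design_matrix(
        train_df, cfg.include_covariates, feature_columns
    ).to_numpy(dtype=float)
    y_tr = train_df["label"].map(class_to_int).to_numpy()

    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(x_tr, y_tr))

    best_acc, best_params = -1.0, None
    for params in _grid_points(cfg.parameter_grid):
        accs = []
        for tr, va in folds:
            clf = _make_xgb(params, cfg.seed)
            clf.fit(x_tr[tr], y_tr[tr])
            accs.append(float((clf.predict(x_tr[va]) == y_tr[va]).mean()))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_acc, best_params = mean_acc, params

    final = _make_xgb(best_params, cfg.seed)
    final.fit(x_tr, y_tr)
    model = BehaviourModel(final.get_booster(), feature_columns, present, cfg)

    x_te = _design_matrix(
        test_df, cfg.include_covariates, feature_columns
    ).to_numpy(dtype=float)
    y_te = test_df["label"].map(class_to_int).to_numpy()
    y_hat = final.predict(x_te)
    oos_acc = float((y_hat == y_te).mean())
    k = len(present)
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_te, y_hat):
        confusion[t, p] += 1
    report = ModelReport(
        cross_validation_accuracy=best_acc,
        out_of_sample_accuracy=oos_acc,
        kappa=cohens_kappa(confusion),
        confusion=pd.DataFrame(confusion, index=present, columns=present),
        chosen_hyperparameters=dict(best_params),
    )
    return model, report


def predict_epochs(model: BehaviourModel, epochs: pd.DataFrame) -> pd.DataFrame:
    """Per-epoch class probabilities, argmax label and runner-up.

    Returns a frame with epoch_index, start_s, one probability column
    per class (``p_<class>``), predicted, runner_up and max_prob.
    """
    if len(epochs) == 0:
        cols = (
            ["epoch_index", "start_s"]
            + [f"p_{c}" for c in model.classes]
            + ["predicted", "runner_up", "max_prob"]
        )
        return pd.DataFrame(columns=cols)
    proba = model.predict_proba(epochs)
    order = np.argsort(-proba, axis=1)
    classes = np.asarray(model.classes)
    out = pd.DataFrame(
        {
            "epoch_index": epochs["epoch_index"].to_numpy(),
            "start_s": epochs["start_s"].to_numpy(),
        }
    )
    for j, c in enumerate(model.classes):
        out[f"p_{c}"] = proba[:, j]
    out["predicted"] = classes[order[:, 0]]
    out["runner_up"] = classes[order[:, 1]]
    out["max_prob"] = proba[np.arange(len(proba)), order[:, 0]]
    return out


def low_confidence_audit(
    predictions: pd.DataFrame, threshold: float = 0.80
) -> pd.DataFrame:
    """Cross-tabulate predicted vs runner-up for low-confidence epochs.

    Restricted to epochs whose top probability is below ``threshold``;
    this summarises which behaviour pairs the model confuses.
    """
    if len(predictions) == 0:
        raise ValueError("predictions must be non-empty")
    low = predictions[predictions["max_prob"] < threshold]
    if len(low) == 0:
        return pd.DataFrame(columns=["predicted", "runner_up", "count"])
    tab = (
        low.groupby(["predicted", "runner_up"], observed=True)
        .size()
        .reset_index(name="count")
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return tab
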