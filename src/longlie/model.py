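"""Soft-voting ensemble over a cross-validated candidate pool.

Five lightweight classifiers (KNN, SVC, MLP, decision tree, logistic
regression) are scored by stratified k-fold cross-validation; the top
three by mean F1 (ties broken by precision, then recall, then name) are
refit on the full training split and fused by averaging their class
probability vectors:

    P_ens(c | x) = (1/N) sum_k P_k(c | x),   N = 3
    y_hat        = argmax_c P_ens(c | x)

Normalization statistics are always learned inside the training data
(per fold during selection, on the full training split for the final
model) and reused unchanged at prediction time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (confusion_matrix, f1_score, precision_score,
                             recall_score, roc_auc_score)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import NormalizationModel, zscore_apply, zscore_fit

log = logging.getLogger(__name__)

POSITIVE_LABEL = "fall"


@dataclass
class CandidateSpec:
    """A named candidate classifier; must expose predict_proba."""

    name: str
    params: dict = field(default_factory=dict)
    supports_probabilities: bool = True

    _FACTORIES = {
        "knn": lambda p, seed: KNeighborsClassifier(**{"n_neighbors": 5, **p}),
        "svc": lambda p, seed: CalibratedClassifierCV(
            SVC(**{"kernel": "rbf", "C": 1.0, "random_state": seed, **p}),
            cv=3, ensemble=False),
        "mlp": lambda p, seed: MLPClassifier(**{"hidden_layer_sizes": (100,),
                                                "max_iter": 500,
                                                "random_state": seed, **p}),
        "dt": lambda p, seed: DecisionTreeClassifier(**{"random_state": seed, **p}),
        "lr": lambda p, seed: LogisticRegression(**{"max_iter": 1000, **p}),
    }

    def build(self, seed: int = 42):
        if self.name not in self._FACTORIES:
            raise ValueError(f"unknown candidate {self.name!r}")
        est = self._FACTORIES[self.name](self.params, seed)
        if not self.supports_probabilities or not hasattr(est, "predict_proba"):
            raise ValueError(f"candidate {self.name!r} must expose "
                             "class-probability estimates")
        return est


def default_candidates() -> list[CandidateSpec]:
    return [CandidateSpec(name) for name in ("knn", "svc", "mlp", "dt", "lr")]


def _split_xy(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    feat_cols = [c for c in dataset.columns if c.startswith("f_")]
    x = dataset[feat_cols].to_numpy(dtype=float)
    y = dataset["label"].to_numpy()
    return x, y


@dataclass
class SelectionReport:
    """Cross-validated metrics per candidate and the selected trio."""

    metrics: pd.DataFrame  # rows: candidates; columns: metric mean/sd
    ranking: list[str]
    selected: list[str]

    def __post_init__(self) -> None:
        if len(self.selected) != 3:
            raise ValueError("exactly three candidates must be selected")


def cross_validate_candidates(dataset: pd.DataFrame,
                              candidates: Sequence[CandidateSpec] | None = None,
                              k: int = 5, seed: int = 42) -> SelectionReport:
    """Stratified k-fold scoring of every candidate.

    Normalization is fit on each fold's training part only. Candidates
    are ranked by mean F1, ties broken by precision, recall, then name.
    """
    candidates = list(candidates) if candidates is not None else default_candidates()
    if k < 2:
        raise ValueError("need k >= 2 folds")
    x, y = _split_xy(dataset)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < k:
        raise ValueError("need at least k examples of each class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    rows = []
    for spec in candidates:
        per_fold = {"precision": [], "recall": [], "f1": []}
        for train_idx, test_idx in folds:
            norm = zscore_fit(x[train_idx])
            xtr = zscore_apply(norm, x[train_idx])
            xte = zscore_apply(norm, x[test_idx])
            est = spec.build(seed)
            est.fit(xtr, y[train_idx])
            pred = est.predict(xte)
            per_fold["precision"].append(
                precision_score(y[test_idx], pred, pos_label=POSITIVE_LABEL,
                                zero_division=0))
            per_fold["recall"].append(
                recall_score(y[test_idx], pred, pos_label=POSITIVE_LABEL,
                             zero_division=0))
            per_fold["f1"].append(
                f1_score(y[test_idx], pred, pos_label=POSITIVE_LABEL,
                         zero_division=0))
        row = {"candidate": spec.name}
        for m, vals in per_fold.items():
            row[f"{m}_mean"] = float(np.mean(vals))
            row[f"{m}_sd"] = float(np.std(vals))
        rows.append(row)
    metrics = pd.DataFrame(rows).set_index("candidate")
    ranking = sorted(
        metrics.index,
        key=lambda n: (-metrics.loc[n, "f1_mean"],
                       -metrics.loc[n, "precision_mean"],
                       -metrics.loc[n, "recall_mean"], n),
    )
    return SelectionReport(metrics=metrics, ranking=ranking,
                           selected=ranking[:3])


@dataclass
class EnsembleModel:
    """Three fitted members sharing one normalization and class order."""

    members: dict[str, object]
    classes: np.ndarray
    normalization: NormalizationModel
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Unweighted mean of member probability vectors."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.normalization.mean.shape[0]:
            raise ValueError(
                f"expected {self.normalization.mean.shape[0]} features, "
                f"got {x.shape[1]}")
        xn = zscore_apply(self.normalization, x)
        probs = np.mean([m.predict_proba(xn) for m in self.members.values()],
                        axis=0)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax of the ensemble probabilities; exact ties go to the
        lowest-index class (logged)."""
        probs = self.predict_proba(x)
        ties = np.isclose(probs.max(axis=1, keepdims=True), probs).sum(axis=1) > 1
        if ties.any():
            log.info("resolved %d probability tie(s) to the lowest-index class",
                     int(ties.sum()))
        return self.classes[np.argmax(probs, axis=1)]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "members": self.members,
            "classes": self.classes,
            "normalization": self.normalization,
            "manifest": self.manifest,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        payload = joblib.load(path)
        return cls(members=payload["members"], classes=payload["classes"],
                   normalization=payload["normalization"],
                   manifest=payload.get("manifest", {}))


def fit_ensemble(dataset: pd.DataFrame, selection: SelectionReport,
                 seed: int = 42,
                 candidates: Sequence[CandidateSpec] | None = None
                 ) -> EnsembleModel:
    """Refit the three selected candidates on the full training split."""
    specs = {s.name: s for s in (candidates or default_candidates())}
    x, y = _split_xy(dataset)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    norm = zscore_fit(x)
    xn = zscore_apply(norm, x)
    members = {}
    mechanisms = {}
    for name in selection.selected:
        est = specs[name].build(seed)
        est.fit(xn, y)
        members[name] = est
        mechanisms[name] = ("Platt calibration (sigmoid, internal CV)"
                            if isinstance(est, CalibratedClassifierCV)
                            else "native predict_proba")
    manifest = {
        "members": selection.selected,
        "probability_mechanism": mechanisms,
        "classes": classes.tolist(),
        "seed": seed,
        "n_training_rows": int(len(y)),
    }
    return EnsembleModel(members=members, classes=classes,
                         normalization=norm, manifest=manifest)


@dataclass
class EvalReport:
    """Confusion matrix (fall positive) and the derived metric suite."""

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float
    confusion: dict[str, int]  # tn, fp, fn, tp

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def evaluate(model: EnsembleModel, test: pd.DataFrame,
             positive_label: str = POSITIVE_LABEL) -> EvalReport:
    """Held-out metric suite: accuracy, precision, recall, specificity,
    F1, and AUC from the ensemble probability of the positive class."""
    x, y = _split_xy(test)
    if len(y) == 0:
        raise ValueError("empty test set")
    if len(np.unique(y)) < 2:
        raise ValueError("test set must contain both classes "
                         "(specificity and AUC are undefined otherwise)")
    pred = model.predict(x)
    labels = [c for c in model.classes if c != positive_label] + [positive_label]
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=labels).ravel()
    pos_col = int(np.flatnonzero(model.classes == positive_label)[0])
    scores = model.predict_proba(x)[:, pos_col]
    auc = roc_auc_score((y == positive_label).astype(int), scores)
    n = tn + fp + fn + tp
    return EvalReport(
        accuracy=(tp + tn) / n,
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
        auc=float(auc),
        confusion={"tn": int(tn), "fp": int(fp), "fn": int(fn), "tp": int(tp)},
    )


def split_dataset(dataset: pd.DataFrame, test_size: float = 0.2,
                  seed: int = 42) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of a windowed dataset table."""
    train, test = train_test_split(dataset, test_size=test_size,
                                   random_state=seed,
                                   stratify=dataset["label"])
    return train.reset_index(drop=True), test.reset_index(drop=True)


def train_ensemble(dataset: pd.DataFrame, k: int = 5, seed: int = 42
                   ) -> tuple[EnsembleModel, SelectionReport]:
    """Convenience: cross-validate, select the top three, refit."""
    selection = cross_validate_candidates(dataset, k=k, seed=seed)
    return fit_ensemble(dataset, selection, seed=seed), selection
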