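"""Maximal-margin peptide panel: fitting, leave-one-out cross-validation,
greedy backward feature elimination and Youden cutoff selection.

Intensities are transformed as ``ln(1 + x)`` then standardized per feature
on the training data; a linear soft-margin SVM provides the scalar decision
score. A sample is classified as a case when its score is >= the stored
cutoff. All transform constants live in the serialized panel so scoring is
deterministic and leakage-free (per-fold constants are re-estimated inside
every cross-validation fold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .data import DataError, IntensityDataset


@dataclass
class TrainedPanel:
    """Fitted linear panel: ordered features, transform constants, hyperplane
    and (once chosen) the diagnosis cutoff."""

    features: list[str]
    center: np.ndarray          # per-feature mean of ln(1+x) on training data
    scale: np.ndarray           # per-feature sd of ln(1+x) on training data
    weights: np.ndarray
    intercept: float
    cutoff: float | None = None
    hyper: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.log1p(np.asarray(X, dtype=float))
        return (Z - self.center) / self.scale

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Scalar score per row of the raw intensity matrix ``X`` (columns in
        ``self.features`` order)."""
        return self.transform(X) @ self.weights + self.intercept

    def classify(self, scores: np.ndarray) -> np.ndarray:
        if self.cutoff is None:
            raise DataError("panel has no cutoff; run youden_cutoff first")
        return np.asarray(scores) >= self.cutoff

    def to_json(self) -> str:
        payload = {
            "features": self.features,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "cutoff": self.cutoff,
            "hyper": self.hyper,
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedPanel":
        payload = json.loads(text)
        return cls(
            features=payload["features"],
            center=np.asarray(payload["center"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
            weights=np.asarray(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            cutoff=payload.get("cutoff"),
            hyper=payload.get("hyper", {}),
            metadata=payload.get("metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedPanel":
        return cls.from_json(Path(path).read_text())


@dataclass
class CrossValidationRecord:
    """Held-out scores from leave-one-out CV plus an optional elimination
    trace of ``(removed_feature, cv_auc_after_removal)`` rounds."""

    sample_ids: list[str]
    labels: np.ndarray           # True = case
    held_out_scores: np.ndarray
    elimination_trace: list[tuple[str | None, float]] = field(default_factory=list)

    def auc(self) -> float:
        from .evalstats import auc

        return auc(self.held_out_scores[self.labels],
                   self.held_out_scores[~self.labels])


def _case_control_matrix(
    data: IntensityDataset,
    features: Sequence[str],
    case_group: str = "pFSGS",
    control_group: str = "sFSGS",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    idx = {p: i for i, p in enumerate(data.peptide_ids)}
    missing = [f for f in features if f not in idx]
    if missing:
        raise DataError(f"features not in dataset: {missing[:5]}")
    cols = [idx[f] for f in features]
    mask = data.group_mask(case_group) | data.group_mask(control_group)
    X = data.intensities[np.ix_(mask, cols)]
    y = data.group_mask(case_group)[mask]
    ids = [s for s, m in zip(data.sample_ids, mask) if m]
    return X, y, ids


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    C: float = 1.0,
) -> TrainedPanel:
    """Fit a linear soft-margin SVM on log-transformed, standardized
    intensities. ``y`` is boolean (True = case). No cutoff is set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if len(features) == 0:
        raise DataError("empty feature set")
    if y.all() or not y.any():
        raise DataError("both classes required to fit")
    if X.shape[1] != len(features):
        raise DataError("feature list does not match matrix width")
    Z = np.log1p(X)
    center = Z.mean(axis=0)
    scale = Z.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    Zs = (Z - center) / scale
    clf = SVC(kernel="linear", C=C)
    clf.fit(Zs, y.astype(int))
    return TrainedPanel(
        features=list(features),
        center=center,
        scale=scale,
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        hyper={"kernel": "linear", "C": C},
    )


def loo_cv_scores(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    C: float = 1.0,
    sample_ids: Sequence[str] | None = None,
) -> CrossValidationRecord:
    """Leave-one-out held-out scores; per-fold transform constants are
    re-estimated without the held-out sample (no leakage)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n = X.shape[0]
    if y.sum() < 3 or (~y).sum() < 3:
        raise DataError("leave-one-out CV requires >= 3 samples per class")
    scores = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if y[keep].all() or not y[keep].any():
            raise DataError(f"class vanishes when holding out sample {i}")
        panel = fit_svm(X[keep], y[keep], features, C=C)
        scores[i] = panel.decision_scores(X[i : i + 1])[0]
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(n)]
    return CrossValidationRecord(sample_ids=ids, labels=y, held_out_scores=scores)


def _loo_auc(X: np.ndarray, y: np.ndarray, features: Sequence[str], C: float) -> float:
    return loo_cv_scores(X, y, features, C=C).auc()


def take_one_out_elimination(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[str],
    C: float = 1.0,
    tie_break_pvalues: Mapping[str, float] | None = None,
    tol: float = 1e-6,
) -> tuple[list[str], CrossValidationRecord]:
    """Greedy backward elimination scored by leave-one-out CV AUC.

    Each round evaluates the panel without each remaining feature and drops
    the one whose removal gives the largest AUC, provided that removal does
    not reduce the current AUC by more than ``tol`` (further reduction must
    cost performance before elimination stops). AUC ties are broken toward
    the feature with the largest tie-break p-value (least individually
    significant), falling back to list order. Stops when every single
    removal strictly reduces the AUC, or when one feature remains.
    """
    features = list(features)
    if len(features) < 2:
        record = loo_cv_scores(X, y, features, C=C) if len(features) == 1 else None
        if record is None:
            raise DataError("need at least 1 feature")
        record.elimination_trace = [(None, record.auc())]
        return features, record

    feat_idx = {f: i for i, f in enumerate(features)}
    current = list(features)
    current_auc = _loo_auc(X[:, [feat_idx[f] for f in current]], y, current, C)
    trace: list[tuple[str | None, float]] = [(None, current_auc)]

    while len(current) > 1:
        best_auc = -np.inf
        removal_aucs: dict[str, float] = {}
        for f in current:
            reduced = [g for g in current if g != f]
            cols = [feat_idx[g] for g in reduced]
            a = _loo_auc(X[:, cols], y, reduced, C)
            removal_aucs[f] = a
            best_auc = max(best_auc, a)
        if best_auc < current_auc - tol:
            break
        tied = [f for f, a in removal_aucs.items() if a >= best_auc - 1e-12]
        if tie_break_pvalues is not None and len(tied) > 1:
            tied.sort(key=lambda f: -tie_break_pvalues.get(f, 0.0))
        drop = tied[0]
        current = [g for g in current if g != drop]
        current_auc = removal_aucs[drop]
        trace.append((drop, current_auc))

    record = loo_cv_scores(X[:, [feat_idx[f] for f in current]], y, current, C=C)
    record.elimination_trace = trace
    return current, record


def youden_cutoff(
    case_scores: Sequence[float], control_scores: Sequence[float]
) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J over midpoints between distinct scores.

    Returns ``(cutoff, sensitivity, specificity)`` with sensitivity and
    specificity as fractions in [0, 1]. J ties are broken toward higher
    specificity, then toward the higher cutoff.
    """
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise DataError("both classes required for cutoff selection")
    distinct = np.unique(np.concatenate([cases, controls]))
    if distinct.size == 1:
        t = distinct[0]
        sens = float((cases >= t).mean())
        spec = float((controls < t).mean())
        return float(t), sens, spec
    thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for t in thresholds:
        sens = float((cases >= t).mean())
        spec = float((controls < t).mean())
        j = sens + spec - 1.0
        key = (j, spec, t)
        if best is None or key > best[0]:
            best = (key, (float(t), sens, spec))
    return best[1]


def train_panel(
    data: IntensityDataset,
    features: Sequence[str],
    C: float = 1.0,
    eliminate: bool = True,
    tie_break_pvalues: Mapping[str, float] | None = None,
    case_group: str = "pFSGS",
    control_group: str = "sFSGS",
) -> tuple[TrainedPanel, CrossValidationRecord]:
    """End-to-end: optional backward elimination, final fit on all training
    samples, Youden cutoff from the held-out LOO scores."""
    X, y, ids = _case_control_matrix(data, features, case_group, control_group)
    if eliminate and len(features) >= 2:
        final_features, record = take_one_out_elimination(
            X, y, features, C=C, tie_break_pvalues=tie_break_pvalues
        )
        idx = {f: i for i, f in enumerate(features)}
        X = X[:, [idx[f] for f in final_features]]
    else:
        final_features = list(features)
        record = loo_cv_scores(X, y, final_features, C=C)
        record.elimination_trace = [(None, record.auc())]
    record.sample_ids = ids
    panel = fit_svm(X, y, final_features, C=C)
    cutoff, sens, spec = youden_cutoff(
        record.held_out_scores[y], record.held_out_scores[~y]
    )
    panel.cutoff = cutoff
    panel.metadata.update(
        {
            "cv_auc": record.auc(),
            "cv_sensitivity": sens,
            "cv_specificity": spec,
            "n_cases": int(y.sum()),
            "n_controls": int((~y).sum()),
            "case_group": case_group,
            "control_group": control_group,
        }
    )
    return panel, record


def score_samples(
    panel: TrainedPanel, data: IntensityDataset
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Score every sample of ``data`` with a trained panel.

    Panel peptides absent from the dataset contribute intensity 0 and are
    returned in the third element as a flag list.
    """
    idx = {p: i for i, p in enumerate(data.peptide_ids)}
    missing = [f for f in panel.features if f not in idx]
    X = np.zeros((data.n_samples, len(panel.features)))
    for j, f in enumerate(panel.features):
        if f in idx:
            X[:, j] = data.intensities[:, idx[f]]
    scores = panel.decision_scores(X)
    classified = panel.classify(scores) if panel.cutoff is not None else np.zeros(
        data.n_samples, dtype=bool
    )
    return scores, classified, missing
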