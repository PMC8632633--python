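"""Multi-sub-model voting ensemble, cutoff fitting, and evaluation.

The retained feature combinations from the search are composed into one
scoring ensemble per diagnosis: each sub-model (default 20) is a linear SVM
refit on the full training split, and a subject's score is the fraction of
sub-models that vote amyloid-positive — 1.0 when all vote positive, 0.5 when
half do, 0 when none.  The score is compared against a diagnosis-specific
cutoff (fit by maximising Youden's J on training-side scores, or fixed by
the user) to classify, and performance is reported as a confusion matrix
with sensitivity, specificity, accuracy and balanced accuracy.

Leakage policy: by default sub-model selection and cutoff fitting never see
the holdout; ``selection="holdout"`` reproduces the alternative protocol of
ranking sub-models by their holdout accuracy, and is labelled as such in the
returned objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold

from .core import POSITIVE, lineage_groups, sort_features
from .search import ModelRecord, SearchConfig, fit_linear_svm


@dataclass
class SubModel:
    """One fitted linear classifier over a feature combination.

    Stores the per-feature standardisation (fit on the training split) and
    the hyperplane, so it is trivially JSON-serialisable.
    """

    combo: tuple[str, ...]
    mean: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    intercept: float
    cv_accuracy: float | None = None
    selection_accuracy: float | None = None

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Boolean positive-votes for rows of a (n, len(combo)) raw matrix."""
        Z = (X - self.mean) / self.scale
        return (Z @ self.weights + self.intercept) > 0

    def to_dict(self) -> dict:
        return {
            "combo": list(self.combo),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "cv_accuracy": self.cv_accuracy,
            "selection_accuracy": self.selection_accuracy,
        }


def _fit_submodel(
    table: pd.DataFrame, combo: Sequence[str], C: float, record: ModelRecord | None = None
) -> SubModel:
    combo = sort_features(combo)
    X = table[list(combo)].to_numpy(dtype=np.float64)
    y = (table["amyloid_label"] == POSITIVE).to_numpy()
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    w, b = fit_linear_svm(np.ascontiguousarray((X - mean) / scale), y, C)
    return SubModel(
        combo=combo,
        mean=mean,
        scale=scale,
        weights=w,
        intercept=b,
        cv_accuracy=record.cv_accuracy if record else None,
    )


@dataclass
class EnsembleModel:
    """An ordered set of fitted sub-models producing a vote-fraction score."""

    submodels: list[SubModel]
    diagnosis: str | None = None
    selection: str = "inner"
    train_subjects: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.submodels:
            raise ValueError("an ensemble needs at least one sub-model")

    @property
    def n(self) -> int:
        return len(self.submodels)

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis,
            "selection": self.selection,
            "submodels": [s.to_dict() for s in self.submodels],
        }


@dataclass(frozen=True)
class CutoffConfig:
    """A score threshold in [0, 1]; scores >= cutoff classify as positive."""

    cutoff: float
    method: str = "fixed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError("cutoff must lie in [0, 1]")


def select_submodels(
    candidates: Sequence[ModelRecord],
    train_table: pd.DataFrame,
    cfg: SearchConfig | None = None,
    n: int = 20,
    selection: str = "inner",
    holdout_table: pd.DataFrame | None = None,
    diagnosis: str | None = None,
) -> EnsembleModel:
    """Pick the top-``n`` candidate combinations and refit them as sub-models.

    Candidates are ranked by the mean of their CV accuracy and their accuracy
    on selection data: an inner validation split carved out of the training
    rows (default, leakage-free) or the holdout itself
    (``selection="holdout"``, the protocol that consults test data during
    selection — clearly tagged on the result).  Ties break by CV accuracy,
    then canonical combo order.  Fewer than ``n`` candidates triggers a
    warning and uses them all.
    """
    cfg = cfg or SearchConfig()
    if not candidates:
        raise ValueError("empty candidate list")
    if selection not in ("inner", "holdout"):
        raise ValueError("selection must be 'inner' or 'holdout'")
    dedup: dict[tuple[str, ...], ModelRecord] = {}
    for m in candidates:
        prev = dedup.get(m.combo)
        if prev is None or m.cv_accuracy > prev.cv_accuracy:
            dedup[m.combo] = m
    records = sorted(dedup.values(), key=ModelRecord.sort_key)

    if selection == "holdout":
        if holdout_table is None:
            raise ValueError("selection='holdout' requires holdout_table")
        fit_tbl, sel_tbl = train_table, holdout_table
    else:
        fit_tbl, sel_tbl = _inner_split(train_table, cfg)

    y_sel = (sel_tbl["amyloid_label"] == POSITIVE).to_numpy()
    scored: list[tuple[float, ModelRecord]] = []
    for m in records:
        sub = _fit_submodel(fit_tbl, m.combo, cfg.C, m)
        pred = sub.votes(sel_tbl[list(sub.combo)].to_numpy(dtype=np.float64))
        scored.append((float((pred == y_sel).mean()), m))
    ranked = sorted(
        scored,
        key=lambda t: (
            -(t[1].cv_accuracy + t[0]) / 2.0,
            -t[1].cv_accuracy,
            tuple(t[1].combo),
        ),
    )
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} candidates available for an ensemble of {n}",
            stacklevel=2,
        )
    chosen = ranked[:n]
    submodels = []
    for sel_acc, m in chosen:
        sub = _fit_submodel(train_table, m.combo, cfg.C, m)
        sub.selection_accuracy = sel_acc
        submodels.append(sub)
    return EnsembleModel(
        submodels=submodels,
        diagnosis=diagnosis,
        selection=selection,
        train_subjects=frozenset(lineage_groups(train_table)),
    )


def _inner_split(
    train_table: pd.DataFrame, cfg: SearchConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carve a grouped, stratified validation quarter out of the training rows."""
    y = (train_table["amyloid_label"] == POSITIVE).to_numpy()
    groups = pd.factorize(lineage_groups(train_table))[0]
    splitter = StratifiedGroupKFold(n_splits=4, shuffle=True, random_state=cfg.seed)
    fit_idx, val_idx = next(splitter.split(np.zeros(len(y)), y, groups))
    return train_table.iloc[fit_idx], train_table.iloc[val_idx]


def ensemble_score(ens: EnsembleModel, features: pd.Series | pd.DataFrame) -> float:
    """Vote-fraction score of a single subject: k positive votes / n sub-models."""
    if isinstance(features, pd.DataFrame):
        if len(features) != 1:
            raise ValueError("pass one row; use score_table for many subjects")
        features = features.iloc[0]
    votes = 0
    for sub in ens.submodels:
        try:
            x = features[list(sub.combo)].to_numpy(dtype=np.float64)[None, :]
        except KeyError as err:
            raise ValueError(f"missing feature values: {err}") from err
        votes += int(sub.votes(x)[0])
    return votes / ens.n


def score_table(ens: EnsembleModel, table: pd.DataFrame) -> np.ndarray:
    """Vote-fraction scores for every row of a feature table."""
    votes = np.zeros(len(table), dtype=np.int64)
    for sub in ens.submodels:
        votes += sub.votes(table[list(sub.combo)].to_numpy(dtype=np.float64))
    return votes / ens.n


def out_of_fold_scores(
    ens: EnsembleModel,
    train_aug: pd.DataFrame,
    originals: pd.DataFrame,
    cfg: SearchConfig | None = None,
) -> np.ndarray:
    """Cross-validated vote scores of the training subjects.

    The fitted ensemble scores its own training rows optimistically (every
    sub-model has seen them), which would bias a cutoff fit toward extreme
    thresholds.  Here the augmented training table is split into grouped,
    stratified folds; the ensemble's combinations are refit without each
    fold and used to score the *original* (unaugmented) training subjects
    held out in that fold.  Returns one score per row of ``originals``,
    aligned with its order.
    """
    cfg = cfg or SearchConfig()
    y = (train_aug["amyloid_label"] == POSITIVE).to_numpy()
    groups = lineage_groups(train_aug)
    codes = pd.factorize(groups)[0]
    splitter = StratifiedGroupKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    scores = np.full(len(originals), np.nan)
    orig_groups = lineage_groups(originals).to_numpy()
    for tr_idx, va_idx in splitter.split(np.zeros(len(y)), y, codes):
        fit_tbl = train_aug.iloc[tr_idx]
        held_groups = set(groups.iloc[va_idx])
        mask = np.isin(orig_groups, list(held_groups))
        if not mask.any():
            continue
        votes = np.zeros(int(mask.sum()), dtype=np.int64)
        for sub in ens.submodels:
            refit = _fit_submodel(fit_tbl, sub.combo, cfg.C)
            votes += refit.votes(
                originals.loc[mask, list(refit.combo)].to_numpy(dtype=np.float64)
            )
        scores[mask] = votes / ens.n
    if np.isnan(scores).any():
        # a training subject absent from the augmented table (should not
        # happen in the standard pipeline): fall back to in-sample scoring
        missing = np.isnan(scores)
        scores[missing] = score_table(ens, originals.loc[missing])
    return scores


def fit_cutoff(
    scores: np.ndarray,
    labels: np.ndarray,
    method: str = "youden",
    fixed: float | None = None,
) -> CutoffConfig:
    """Choose the score threshold.

    ``method="youden"`` maximises J = sensitivity + specificity - 1 over the
    observed score grid (prediction rule: score >= cutoff), breaking ties
    toward the lower cutoff (favouring sensitivity); if no cutoff beats
    J = 0 the neutral 0.5 is returned.  ``method="fixed"`` echoes ``fixed``.
    """
    if method == "fixed":
        if fixed is None:
            raise ValueError("method='fixed' requires a cutoff value")
        return CutoffConfig(cutoff=float(fixed), method="fixed")
    if method != "youden":
        raise ValueError("method must be 'youden' or 'fixed'")
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("cutoff fitting needs scores from both classes")
    best_c, best_j = 0.5, 0.0
    for c in np.unique(scores):  # ascending: ties keep the lowest cutoff
        pred = scores >= c
        sens = pred[labels].mean()
        spec = (~pred[~labels]).mean()
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_c, best_j = float(c), float(j)
    return CutoffConfig(cutoff=best_c, method="youden")


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion-matrix counts and the derived classification metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ValueError("both true classes must be represented")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    def as_percentages(self, ndigits: int = 1) -> dict[str, float]:
        return {
            "sensitivity": round(100 * self.sensitivity, ndigits),
            "specificity": round(100 * self.specificity, ndigits),
            "accuracy": round(100 * self.accuracy, ndigits),
            "balanced_accuracy": round(100 * self.balanced_accuracy, ndigits),
        }

    def confusion_frame(self) -> pd.DataFrame:
        """Confusion matrix in report layout (predicted x true)."""
        return pd.DataFrame(
            {"true_positive": [self.tp, self.fn], "true_negative": [self.fp, self.tn]},
            index=["predicted_positive", "predicted_negative"],
        )


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> EvaluationReport:
    """Sensitivity, specificity, accuracy and balanced accuracy from counts."""
    return EvaluationReport(tp=tp, fp=fp, fn=fn, tn=tn)


def evaluate_ensemble(
    ens: EnsembleModel,
    cutoff: CutoffConfig,
    test_table: pd.DataFrame,
    strict: bool = True,
) -> tuple[EvaluationReport, pd.DataFrame]:
    """Score and classify every test subject; report confusion metrics.

    In strict mode (default) the test table is audited against leakage: rows
    must be unaugmented, tagged ``split == "test"`` when a split column is
    present, and disjoint from the subjects the ensemble was trained on.
    Returns the report plus a per-subject table (id, score, prediction,
    truth) — the data behind a score-by-group box plot.
    """
    if strict:
        if "split" in test_table.columns and (test_table["split"] != "test").any():
            raise ValueError("strict mode: test table contains non-test rows")
        if "lineage" in test_table.columns:
            lin = test_table["lineage"]
            if (lin.notna() & (lin != "")).any():
                raise ValueError("strict mode: test rows must not be augmented")
        overlap = set(lineage_groups(test_table)) & set(ens.train_subjects)
        if overlap:
            raise ValueError(f"strict mode: test subjects seen in training: {sorted(overlap)[:5]}")
    scores = score_table(ens, test_table)
    pred = scores >= cutoff.cutoff
    truth = (test_table["amyloid_label"] == POSITIVE).to_numpy()
    report = metrics_from_confusion(
        tp=int((pred & truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
    )
    detail = pd.DataFrame(
        {
            "subject_id": test_table["subject_id"].to_numpy(),
            "diagnosis": test_table.get("diagnosis"),
            "score": scores,
            "prediction": np.where(pred, "positive", "negative"),
            "truth": test_table["amyloid_label"].to_numpy(),
        }
    )
    return report, detail
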