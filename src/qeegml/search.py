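"""Generational combinatorial feature search ("genetic-algorithm heuristic").

The search treats each of the 152 band-power features as a gene:

1. enumerate *every* k-feature combination of the current pool and score each
   with stratified, lineage-grouped 5-fold cross-validation of a linear SVM;
2. keep the best-performing models of the generation and tally how often
   each feature occurs in them;
3. restrict the next (k+1)-dimensional generation to the most frequent
   features, shrinking the pool so the enumeration stays tractable.

There is no crossover or mutation — the "genetic" part is purely this
frequency-based propagation of good genes into higher-dimensional
generations.  With no pool budget the procedure degenerates to exhaustive
search, which is exactly the property used to validate it against a
brute-force oracle on small pools.

The per-combination evaluator is deliberately lean: fold assignments and
per-fold feature standardisation are computed once per table and cached,
and the linear SVM is fit through liblinear directly (identical coefficients
to :class:`sklearn.svm.LinearSVC`, without per-call estimator overhead),
because a single search evaluates 10^4-10^6 combinations.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold

from .core import (
    POSITIVE,
    feature_columns,
    feature_index,
    lineage_groups,
    sort_features,
)

def fit_linear_svm(
    X: np.ndarray,
    y01: np.ndarray,
    C: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """L2-regularised squared-hinge linear SVM; returns ``(weights, intercept)``.

    Solves the primal problem

        min_{w,b}  0.5 (||w||^2 + b^2) + C * sum_i max(0, 1 - y_i (w.x_i + b))^2

    by damped Newton iteration — the objective is strictly convex and
    piecewise quadratic, so a handful of Newton steps solve it to machine
    precision.  This is the same objective ``LinearSVC(C=C, dual=False)``
    minimises (the bias enters the regulariser there too); coefficients
    agree to optimiser tolerance, which the test suite asserts.  A direct
    solver is used because the combinatorial search fits this model ~10^6
    times on matrices of a few columns, where per-call estimator overhead
    dominates runtime.

    Predict class 1 where ``X @ w + b > 0``.
    """
    n, d = X.shape
    Xa = np.empty((n, d + 1))
    Xa[:, :d] = X
    Xa[:, d] = 1.0
    y = np.where(y01, 1.0, -1.0)
    Xy = Xa * y[:, None]
    theta = np.zeros(d + 1)
    for _ in range(max_iter):
        m = 1.0 - Xy @ theta
        act = m > 0
        grad = theta - 2.0 * C * (Xy[act].T @ m[act])
        if np.linalg.norm(grad) < tol:
            break
        H = np.eye(d + 1) + 2.0 * C * (Xy[act].T @ Xy[act])
        step = np.linalg.solve(H, grad)
        f0 = 0.5 * theta @ theta + C * np.sum(m[act] ** 2)
        t = 1.0
        for _ in range(20):  # backtracking; the full step is almost always taken
            theta_new = theta - t * step
            m_new = 1.0 - Xy @ theta_new
            f1 = 0.5 * theta_new @ theta_new + C * np.sum(np.clip(m_new, 0.0, None) ** 2)
            if f1 <= f0 - 1e-4 * t * (grad @ step):
                break
            t *= 0.5
        theta = theta_new
    return theta[:d], float(theta[d])


def count_combinations(p: int, k: int) -> int:
    """Exact number of k-feature subsets of a p-feature pool, C(p, k)."""
    if p < 0 or k < 0:
        raise ValueError("pool size and dimension must be non-negative")
    if k > p:
        raise ValueError(f"cannot choose {k} features from a pool of {p}")
    return math.comb(p, k)


@dataclass(frozen=True)
class SearchConfig:
    """Tuning knobs of the generational search.

    ``k_exhaustive`` generations run on the full feature pool; generations
    above it (and any generation with an entry in ``pool_sizes``) run on a
    frequency-reduced pool.  "Good models" per generation are the top
    ``top_fraction`` by CV accuracy with a floor of ``top_floor`` models.
    Candidates are retained when their CV accuracy exceeds
    ``retention_accuracy``.
    """

    k_max: int = 5
    k_exhaustive: int = 3
    top_fraction: float = 0.01
    top_floor: int = 50
    pool_sizes: Mapping[int, int] = field(default_factory=lambda: {4: 40, 5: 30})
    retention_accuracy: float = 0.75
    folds: int = 5
    C: float = 1.0
    seed: int = 0
    max_evaluations: int = 700_000
    features: tuple[str, ...] | None = None  # restrict the initial pool
    classifier_factory: Callable[[], object] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k_exhaustive <= self.k_max:
            raise ValueError("need 1 <= k_exhaustive <= k_max")
        if not 0.5 < self.retention_accuracy <= 1.0:
            raise ValueError("retention_accuracy must be in (0.5, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")

    def top_count(self, n_models: int) -> int:
        return min(n_models, max(math.ceil(self.top_fraction * n_models), self.top_floor))


@dataclass(frozen=True)
class ModelRecord:
    """One evaluated feature combination and its cross-validated performance."""

    combo: tuple[str, ...]
    cv_accuracy: float
    cv_sensitivity: float
    cv_specificity: float
    test_accuracy: float | None = None

    def sort_key(self) -> tuple:
        """Better models sort first: accuracy desc, sensitivity desc, then
        canonical combo order (reproducible tie-break)."""
        return (
            -self.cv_accuracy,
            -self.cv_sensitivity,
            tuple(feature_index(f) for f in self.combo),
        )


@dataclass
class Generation:
    """One completed generation: pool, evaluated models, winners, gene tally."""

    k: int
    pool: tuple[str, ...]
    models: list[ModelRecord]
    top_models: list[ModelRecord]
    freq: dict[str, int]

    @property
    def mean_top_accuracy(self) -> float:
        return float(np.mean([m.cv_accuracy for m in self.top_models]))

    @property
    def max_accuracy(self) -> float:
        return float(max(m.cv_accuracy for m in self.top_models))

    def summary(self) -> dict:
        return {
            "k": self.k,
            "pool_size": len(self.pool),
            "n_models": len(self.models),
            "n_top": len(self.top_models),
            "mean_top_accuracy": self.mean_top_accuracy,
            "max_accuracy": self.max_accuracy,
        }


class FoldCache:
    """Precomputed CV folds and per-fold standardised feature matrices.

    Folds are stratified by amyloid label and grouped by augmentation lineage
    (a subject's split halves always share a fold).  Standardisation (zero
    mean, unit variance) is fit on each fold's training rows for *all*
    features at once, so scoring a combination only slices columns.
    """

    def __init__(self, table: pd.DataFrame, cfg: SearchConfig):
        feats = feature_columns(table)
        if cfg.features is not None:
            missing = set(cfg.features) - set(feats)
            if missing:
                raise ValueError(f"config restricts to unknown features: {sorted(missing)}")
        self.feature_names = feats
        self.col = {f: i for i, f in enumerate(feats)}
        X = table[feats].to_numpy(dtype=np.float64)
        y = (table["amyloid_label"] == POSITIVE).to_numpy()
        if y.all() or not y.any():
            raise ValueError("training table must contain both amyloid classes")
        groups = pd.factorize(lineage_groups(table))[0]
        self.y = y
        self.groups = groups
        self.folds: list[tuple[np.ndarray, np.ndarray]] = []
        last_err: Exception | None = None
        for attempt in range(5):  # reshuffle on a degenerate (single-class) fold
            splitter = StratifiedGroupKFold(
                n_splits=cfg.folds, shuffle=True, random_state=cfg.seed + attempt
            )
            try:
                folds = list(splitter.split(X, y, groups))
            except ValueError as err:
                last_err = err
                continue
            if all(
                y[tr].any() and not y[tr].all() and y[va].any() and not y[va].all()
                for tr, va in folds
            ):
                self.folds = folds
                break
        else:
            raise ValueError(
                f"could not build {cfg.folds} folds with both classes present"
            ) from last_err
        self.Xtr: list[np.ndarray] = []
        self.Xva: list[np.ndarray] = []
        self.ytr: list[np.ndarray] = []
        self.yva: list[np.ndarray] = []
        for tr, va in self.folds:
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd < 1e-12] = 1.0
            self.Xtr.append(np.ascontiguousarray((X[tr] - mu) / sd))
            self.Xva.append(np.ascontiguousarray((X[va] - mu) / sd))
            self.ytr.append(y[tr])
            self.yva.append(y[va])


def evaluate_combination(
    combo: Sequence[str],
    table: pd.DataFrame | None = None,
    cfg: SearchConfig | None = None,
    cache: FoldCache | None = None,
) -> ModelRecord:
    """Score one feature combination by stratified grouped k-fold CV.

    The classifier (linear SVM by default, per-fold standardisation) is fit
    on each fold's training rows restricted to the combination's columns;
    accuracy, sensitivity and specificity are averaged over folds.
    """
    cfg = cfg or SearchConfig()
    if cache is None:
        if table is None:
            raise ValueError("provide either a table or a prebuilt FoldCache")
        cache = FoldCache(table, cfg)
    combo = sort_features(combo)
    cols = [cache.col[f] for f in combo]
    acc = sens = spec = 0.0
    use_factory = cfg.classifier_factory is not None
    for Xtr, Xva, ytr, yva in zip(cache.Xtr, cache.Xva, cache.ytr, cache.yva):
        Xtr_c, Xva_c = Xtr[:, cols], Xva[:, cols]
        if use_factory:
            clf = cfg.classifier_factory()
            clf.fit(Xtr_c, ytr)
            pred = np.asarray(clf.predict(Xva_c), dtype=bool)
        else:
            w, b = fit_linear_svm(Xtr_c, ytr, cfg.C)
            pred = (Xva_c @ w + b) > 0
        acc += float((pred == yva).mean())
        sens += float(pred[yva].mean())
        spec += float((~pred[~yva]).mean())
    n = len(cache.folds)
    return ModelRecord(combo, acc / n, sens / n, spec / n)


def run_generation(
    pool: Sequence[str],
    k: int,
    table: pd.DataFrame | None = None,
    cfg: SearchConfig | None = None,
    cache: FoldCache | None = None,
) -> Generation:
    """Exhaustively evaluate all C(|pool|, k) combinations of a pool."""
    cfg = cfg or SearchConfig()
    if cache is None:
        if table is None:
            raise ValueError("provide either a table or a prebuilt FoldCache")
        cache = FoldCache(table, cfg)
    pool = sort_features(pool)
    n_models = count_combinations(len(pool), k)
    if n_models > cfg.max_evaluations:
        raise RuntimeError(
            f"generation k={k} over {len(pool)} features needs {n_models:,} "
            f"evaluations (> budget {cfg.max_evaluations:,}); reduce the pool "
            "via pool_sizes or raise max_evaluations"
        )
    models = [evaluate_combination(c, cfg=cfg, cache=cache) for c in combinations(pool, k)]
    order = sorted(models, key=ModelRecord.sort_key)
    top = order[: cfg.top_count(len(models))]
    freq = Counter(f for m in top for f in m.combo)
    return Generation(k=k, pool=pool, models=models, top_models=top, freq=dict(freq))


def next_pool(
    generations: Generation | Sequence[Generation], budget: int
) -> tuple[str, ...]:
    """The ``budget`` most frequent features among the top models.

    Accepts one generation or several (their tallies are merged).  Ranking is
    by occurrence count among top models, then by the best CV accuracy of any
    top model containing the feature, then canonical feature order; the
    result is returned in canonical order.
    """
    if isinstance(generations, Generation):
        generations = [generations]
    if budget < 1:
        raise ValueError("budget must be >= 1")
    freq: Counter[str] = Counter()
    best_acc: dict[str, float] = {}
    pool_union: set[str] = set()
    for gen in generations:
        pool_union.update(gen.pool)
        freq.update(gen.freq)
        for m in gen.top_models:
            for f in m.combo:
                if m.cv_accuracy > best_acc.get(f, -1.0):
                    best_acc[f] = m.cv_accuracy
    ranked = sorted(
        pool_union,
        key=lambda f: (-freq.get(f, 0), -best_acc.get(f, -1.0), feature_index(f)),
    )
    return sort_features(ranked[:budget])


@dataclass
class SearchResult:
    """Outcome of :func:`run_heuristic`."""

    generations: list[Generation]
    candidates: list[ModelRecord]
    best: ModelRecord | None

    def summary_table(self) -> pd.DataFrame:
        """Per-generation report (the accuracy-vs-dimension curve)."""
        return pd.DataFrame([g.summary() for g in self.generations])


def run_heuristic(
    table: pd.DataFrame,
    cfg: SearchConfig | None = None,
    checkpoint_dir: str | Path | None = None,
) -> SearchResult:
    """Run the full generational search on a prepared training table.

    Generations ``k = 1 .. k_exhaustive`` run on the full feature pool unless
    ``pool_sizes`` caps them; the first reduced generation draws its pool
    from the merged gene tallies of all exhaustive generations, and later
    generations from their immediate predecessor.  Returns every evaluated
    model whose CV accuracy exceeds ``retention_accuracy`` (deduplicated),
    the per-generation history, and the best model overall.
    """
    cfg = cfg or SearchConfig()
    cache = FoldCache(table, cfg)
    initial_pool = sort_features(cfg.features) if cfg.features else tuple(cache.feature_names)
    generations: list[Generation] = []
    retained: dict[tuple[str, ...], ModelRecord] = {}
    pool = initial_pool
    for k in range(1, cfg.k_max + 1):
        budget = cfg.pool_sizes.get(k)
        if k > 1:
            if k == cfg.k_exhaustive + 1:
                source: Generation | Sequence[Generation] = generations
            else:
                source = generations[-1]
            if budget is not None:
                pool = next_pool(source, budget)
            elif k > cfg.k_exhaustive:
                pool = generations[-1].pool
            else:
                pool = initial_pool
        elif budget is not None:
            pool = initial_pool[:budget]
        if len(pool) < k:
            warnings.warn(f"pool smaller than k={k}; stopping early", stacklevel=2)
            break
        gen = run_generation(pool, k, cfg=cfg, cache=cache)
        generations.append(gen)
        for m in gen.models:
            if m.cv_accuracy > cfg.retention_accuracy:
                prev = retained.get(m.combo)
                if prev is None or m.cv_accuracy > prev.cv_accuracy:
                    retained[m.combo] = m
        if checkpoint_dir is not None:
            _write_checkpoint(Path(checkpoint_dir), gen)
    candidates = sorted(retained.values(), key=ModelRecord.sort_key)
    best = min(
        (m for g in generations for m in g.top_models),
        key=ModelRecord.sort_key,
        default=None,
    )
    if not candidates:
        warnings.warn(
            f"no model exceeded the retention accuracy {cfg.retention_accuracy}; "
            "returning an empty candidate set",
            stacklevel=2,
        )
    return SearchResult(generations=generations, candidates=candidates, best=best)


def _write_checkpoint(directory: Path, gen: Generation) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"generation_k{gen.k}.jsonl"
    with path.open("w") as fh:
        fh.write(json.dumps({"summary": gen.summary(), "pool": list(gen.pool)}) + "\n")
        for m in gen.top_models:
            fh.write(
                json.dumps(
                    {
                        "combo": list(m.combo),
                        "cv_accuracy": m.cv_accuracy,
                        "cv_sensitivity": m.cv_sensitivity,
                        "cv_specificity": m.cv_specificity,
                    }
                )
                + "\n"
            )
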