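"""Cohort preparation: stratified holdout, positive-class split-half
augmentation, and split-half reliability screening.

The positive class is roughly 2.5x rarer than the negative class in the
target population, so the training positives are doubled by splitting each
positive subject's recording into its first and second temporal halves and
treating each half as a separate sample.  Test rows are never augmented, and
a subject's halves never straddle the train/test boundary (or, downstream, a
CV fold) — the ``lineage`` column records the parent subject of every
augmented row so that grouping can be enforced everywhere.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .core import (
    CHANNELS,
    POSITIVE,
    EEGRecording,
    feature_columns,
)
from .spectral import extract_features, welch_psd

TRAIN = "train"
TEST = "test"


def holdout_split(
    table: pd.DataFrame, fraction: float = 0.2, seed: int = 0
) -> pd.DataFrame:
    """Assign each subject to train or test, stratified by (diagnosis, label).

    The total test count is ``round(fraction * n)``, apportioned across
    strata by largest remainder so per-stratum counts track ``fraction``
    as closely as integers allow.  Deterministic under ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if "split" in table.columns:
        raise ValueError("table already carries a split assignment")
    strata = list(table.groupby(["diagnosis", "amyloid_label"], sort=True).groups.items())
    for key, idx in strata:
        if len(idx) < 2:
            raise ValueError(f"stratum {key} has fewer than 2 subjects; cannot split")
    n_total = len(table)
    n_test = int(round(fraction * n_total))
    ideals = [fraction * len(idx) for _, idx in strata]
    base = [int(np.floor(v)) for v in ideals]
    base = [min(b, len(idx) - 1) for b, (_, idx) in zip(base, strata)]
    remainder = n_test - sum(base)
    order = sorted(
        range(len(strata)),
        key=lambda i: (-(ideals[i] - base[i]), strata[i][0]),
    )
    counts = list(base)
    for i in order:
        if remainder <= 0:
            break
        if counts[i] < len(strata[i][1]) - 1:  # keep >= 1 training subject
            counts[i] += 1
            remainder -= 1
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["split"] = TRAIN
    for (key, idx), k in zip(strata, counts):
        chosen = rng.choice(np.asarray(idx), size=k, replace=False)
        out.loc[chosen, "split"] = TEST
    return out


def augment_positives(
    table: pd.DataFrame,
    recordings: Mapping[str, EEGRecording] | None = None,
    feature_fn: Callable[..., object] = extract_features,
) -> pd.DataFrame:
    """Double the positive training rows by split-half augmentation.

    Every amyloid-positive *training* subject is replaced by two rows: the
    feature vectors of the first and second temporal half of its recording,
    each carrying ``lineage = parent subject id``.  Negative and test rows
    pass through untouched.

    If ``recordings`` lacks a subject (feature-table-only workflows), that
    subject's row is duplicated verbatim instead — a degraded mode that still
    rebalances the classes but adds no new spectral information; a warning is
    emitted once.
    """
    if "split" not in table.columns:
        raise ValueError("run holdout_split before augmentation")
    feats = feature_columns(table)
    recordings = recordings or {}
    warned = False
    rows: list[pd.Series | dict] = []
    for _, row in table.iterrows():
        is_target = row["split"] == TRAIN and row["amyloid_label"] == POSITIVE
        if not is_target:
            rows.append(row)
            continue
        sid = row["subject_id"]
        rec = recordings.get(sid)
        if rec is None:
            if not warned:
                warnings.warn(
                    "no recording available for some positive training subjects; "
                    "falling back to jitter-free row duplication (degraded augmentation)",
                    stacklevel=2,
                )
                warned = True
            for half in ("h1", "h2"):
                dup = row.copy()
                dup["subject_id"] = f"{sid}__{half}"
                dup["lineage"] = sid
                rows.append(dup)
            continue
        first, second = rec.halves()
        for half, sub in (("h1", first), ("h2", second)):
            fv = feature_fn(
                sub,
                subject_id=f"{sid}__{half}",
                diagnosis=row.get("diagnosis"),
                amyloid_label=row["amyloid_label"],
                lineage=sid,
            )
            new = row.copy()
            new["subject_id"] = fv.subject_id
            new["lineage"] = sid
            new[feats] = fv.values
            rows.append(new)
    out = pd.DataFrame(rows).reset_index(drop=True)
    if "lineage" not in out.columns:
        out["lineage"] = pd.NA
    return out


def split_half_reliability(
    rec: EEGRecording,
    resolution: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 45.0,
) -> np.ndarray:
    """Per-channel Pearson correlation between first- and second-half PSDs.

    The PSD of each temporal half is estimated with the same Welch scheme as
    feature extraction but at a coarser default resolution (0.5 Hz, i.e. 2 s
    windows): a stability screen wants a low-variance spectral estimate, not
    fine frequency detail, and halving the window doubles the number of
    averaged periodograms per half.  Spectra are restricted to
    [fmin, fmax]; a high correlation on every channel indicates a
    stationary, artifact-free record whose split-half features are
    interchangeable.
    """
    first, second = rec.halves()
    nperseg = int(round(rec.fs / resolution))
    if first.n_samples < nperseg:
        raise ValueError("recording too short for two PSD-valid halves")
    f1, p1 = welch_psd(first.samples, rec.fs, resolution)
    _, p2 = welch_psd(second.samples, rec.fs, resolution)
    keep = (f1 >= fmin) & (f1 <= fmax)
    a, b = p1[:, keep], p2[:, keep]
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
    if (denom == 0).any():
        raise ValueError("degenerate (constant) PSD on at least one channel")
    return (a * b).sum(axis=1) / denom


def reliability_screen(
    rec: EEGRecording, threshold: float = 0.90, strict: bool = False
) -> tuple[np.ndarray, bool]:
    """Apply the split-half screen: all 19 channel correlations > threshold.

    Advisory by default (returns the flag and warns on failure); in strict
    mode a failing recording raises instead, for pipelines that drop
    unreliable subjects.
    """
    corr = split_half_reliability(rec)
    ok = bool((corr > threshold).all())
    if not ok:
        bad = [CHANNELS[i] for i in np.where(corr <= threshold)[0]]
        msg = f"split-half reliability <= {threshold} on channel(s) {bad}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return corr, ok
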