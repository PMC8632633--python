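"""Univariate screening of band-power features between amyloid groups.

Each of the 152 features is compared between the amyloid-positive and
-negative groups with Welch's two-sample t-test (unequal variances; the
groups are independent subjects).  Augmented half-subject rows are collapsed
to one row per subject (parent mean) before testing so each subject counts
once.  No multiple-testing correction is applied by default — the screening
topography is reported feature-wise — but Benjamini-Hochberg adjusted
p-values are available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    BANDS,
    CHANNELS,
    NEGATIVE,
    POSITIVE,
    collapse_lineage,
    feature_columns,
    feature_matrix,
)
from .prep import TRAIN

HIGHER = "higher"
LOWER = "lower"
EQUAL = "equal"


def feature_group_tests(
    table: pd.DataFrame,
    on: str = "train",
    fdr: bool = False,
) -> pd.DataFrame:
    """Welch t-test per feature, positive vs negative group.

    Parameters
    ----------
    table
        Feature table; if it has a ``split`` column and ``on="train"``, only
        training rows enter the tests.
    on
        ``"train"`` or ``"all"``.
    fdr
        Add a Benjamini-Hochberg adjusted p-value column ``p_adj``.

    Returns a DataFrame with one row per feature: ``feature, channel, band,
    t, p, direction`` where ``direction`` says whether the positive group's
    mean is higher or lower.
    """
    if on not in ("train", "all"):
        raise ValueError("on must be 'train' or 'all'")
    if on == "train" and "split" in table.columns:
        table = table[table["split"] == TRAIN]
    table = collapse_lineage(table)
    feats = feature_columns(table)
    X = feature_matrix(table)
    is_pos = (table["amyloid_label"] == POSITIVE).to_numpy()
    is_neg = (table["amyloid_label"] == NEGATIVE).to_numpy()
    if is_pos.sum() == 0 or is_neg.sum() == 0:
        raise ValueError("both amyloid groups must be non-empty")
    a, b = X[is_pos], X[is_neg]
    var_a, var_b = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    dead = np.where((var_a == 0) & (var_b == 0))[0]
    if dead.size:
        raise ValueError(
            f"zero within-group variance on feature(s) {[feats[i] for i in dead]}"
        )
    res = sps.ttest_ind(a, b, axis=0, equal_var=False)
    diff = a.mean(axis=0) - b.mean(axis=0)
    direction = np.where(diff > 0, HIGHER, np.where(diff < 0, LOWER, EQUAL))
    t = np.where(diff == 0, 0.0, res.statistic)
    p = np.where(diff == 0, 1.0, res.pvalue)
    out = pd.DataFrame(
        {
            "feature": feats,
            "channel": [f.split(".")[0] for f in feats],
            "band": [f.split(".")[1] for f in feats],
            "t": t,
            "p": p,
            "direction": direction,
        }
    )
    if fdr:
        out["p_adj"] = sps.false_discovery_control(out["p"], method="bh")
    return out


def significant_topography(
    stats: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = False
) -> dict[str, list[tuple[str, str]]]:
    """Per band, the channels whose group difference is significant.

    Returns ``{band: [(channel, direction), ...]}`` in canonical channel
    order — the tabular content of a topographic significance map.  Bands
    with no significant channel map to an empty list.
    """
    col = "p_adj" if use_adjusted else "p"
    if col not in stats.columns:
        raise ValueError(f"stats table has no {col!r} column")
    topo: dict[str, list[tuple[str, str]]] = {band: [] for band in BANDS}
    sig = stats[stats[col] < alpha]
    order = {ch: i for i, ch in enumerate(CHANNELS)}
    for band in BANDS:
        rows = sig[sig["band"] == band]
        topo[band] = [
            (r.channel, r.direction)
            for r in sorted(rows.itertuples(), key=lambda r: order[r.channel])
        ]
    return topo


def topography_table(topo: dict[str, list[tuple[str, str]]]) -> pd.DataFrame:
    """Flatten a topography map to a (band, channel, direction) table."""
    rows = [
        {"band": band, "channel": ch, "direction": d}
        for band, entries in topo.items()
        for ch, d in entries
    ]
    return pd.DataFrame(rows, columns=["band", "channel", "direction"])
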