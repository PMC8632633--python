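"""Shared domain objects: the 10-20 montage, the band scheme, recordings, feature tables.

Every module in the package speaks in terms of the objects defined here:

* 19 scalp channels of the International 10-20 system, in one canonical order;
* eight classical frequency bands tiling 1-45 Hz;
* ``EEGRecording`` -- one subject's multichannel time series;
* a *feature table* -- a :class:`pandas.DataFrame` with one row per subject
  (or augmented half-subject) carrying the 152 relative band-power features
  plus a small set of reserved metadata columns.

Feature columns are named ``"<channel>.<band>"`` (e.g. ``"Fp1.delta"``) and
are ordered channel-major, band-minor; that ordering is the canonical feature
order used for tie-breaking everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The 19 scalp electrodes of the International 10-20 system, canonical order.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

N_CHANNELS = len(CHANNELS)

#: Classical qEEG bands, name -> (low Hz, high Hz).  Intervals are half-open
#: [low, high); the topmost band (gamma) is closed at its upper edge so the
#: eight bands tile [1, 45] Hz exactly.
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 12.0),
    "beta1": (12.0, 15.0),
    "beta2": (15.0, 20.0),
    "beta3": (20.0, 30.0),
    "gamma": (30.0, 45.0),
}

BANDS: tuple[str, ...] = tuple(DEFAULT_BAND_EDGES)
N_BANDS = len(BANDS)

#: Canonical feature names, channel-major / band-minor: 19 x 8 = 152.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}.{band}" for ch in CHANNELS for band in BANDS
)
N_FEATURES = len(FEATURE_NAMES)

_FEATURE_INDEX: dict[str, int] = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: Reserved metadata columns of a feature table.  ``split`` and ``lineage``
#: only appear once the cohort-preparation steps have run.
META_COLUMNS = ("subject_id", "diagnosis", "amyloid_label", "split", "lineage")

POSITIVE = "positive"
NEGATIVE = "negative"


def feature_index(name: str) -> int:
    """Canonical position of a feature name (used for deterministic tie-breaks)."""
    try:
        return _FEATURE_INDEX[name]
    except KeyError:
        raise KeyError(f"unknown feature {name!r}; expected '<channel>.<band>'") from None


def sort_features(names: Sequence[str]) -> tuple[str, ...]:
    """Sort feature names into canonical channel-major, band-minor order."""
    return tuple(sorted(names, key=feature_index))


@dataclass(frozen=True)
class BandScheme:
    """An ordered set of contiguous frequency bands tiling a closed interval.

    Bands are half-open ``[low, high)`` except the last, which is closed at
    its upper edge.  The default scheme is the eight-band clinical split of
    1-45 Hz (delta through gamma).
    """

    edges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )

    def __post_init__(self) -> None:
        names = list(self.edges)
        if not names:
            raise ValueError("band scheme must define at least one band")
        prev_high = None
        for name in names:
            low, high = self.edges[name]
            if not low < high:
                raise ValueError(f"band {name!r}: low must be < high, got [{low}, {high})")
            if prev_high is not None and low != prev_high:
                raise ValueError(
                    f"bands must be contiguous; {name!r} starts at {low} but the "
                    f"previous band ends at {prev_high}"
                )
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.edges)

    @property
    def fmin(self) -> float:
        return next(iter(self.edges.values()))[0]

    @property
    def fmax(self) -> float:
        return list(self.edges.values())[-1][1]

    def bin_masks(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Boolean masks assigning frequency bins to bands.

        Bins fall in ``[low, high)``; the last band also takes bins exactly at
        its upper edge, so a flat spectrum splits in proportion to bandwidth
        and every bin in ``[fmin, fmax]`` belongs to exactly one band.
        """
        masks: dict[str, np.ndarray] = {}
        last = self.names[-1]
        for name, (low, high) in self.edges.items():
            m = (freqs >= low) & (freqs < high)
            if name == last:
                m |= np.isclose(freqs, high)
            masks[name] = m
        return masks


DEFAULT_SCHEME = BandScheme()

AS_RECORDED = "as-recorded"
COMMON_AVERAGE = "common-average"


@dataclass
class EEGRecording:
    """One subject's multichannel resting-state EEG.

    Parameters
    ----------
    samples
        ``(19, n_samples)`` array of channel voltages in microvolts, rows in
        the canonical :data:`CHANNELS` order.
    fs
        Sampling frequency in Hz.
    channels
        Channel labels; must be exactly the canonical 19-name tuple.
    reference
        ``"as-recorded"`` or ``"common-average"``.
    subject_id
        Optional identifier carried along for bookkeeping.
    """

    samples: np.ndarray
    fs: float
    channels: tuple[str, ...] = CHANNELS
    reference: str = AS_RECORDED
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        self.channels = tuple(self.channels)
        if self.channels != CHANNELS:
            unknown = set(self.channels) - set(CHANNELS)
            if unknown:
                raise ValueError(f"unknown channel labels: {sorted(unknown)}")
            raise ValueError("channels must be the 19 10-20 labels in canonical order")
        if self.samples.shape[0] != N_CHANNELS:
            raise ValueError(
                f"expected {N_CHANNELS} channel rows, got {self.samples.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.reference not in (AS_RECORDED, COMMON_AVERAGE):
            raise ValueError(f"unknown reference tag {self.reference!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def halves(self) -> tuple["EEGRecording", "EEGRecording"]:
        """Split into first/second temporal halves (used for augmentation and
        split-half reliability)."""
        mid = self.n_samples // 2
        first = replace(self, samples=self.samples[:, :mid].copy())
        second = replace(self, samples=self.samples[:, mid : 2 * mid].copy())
        return first, second


# ---------------------------------------------------------------------------
# Feature-table helpers
# ---------------------------------------------------------------------------

def feature_columns(table: pd.DataFrame) -> list[str]:
    """The canonical feature columns present in a table, in canonical order."""
    present = [c for c in FEATURE_NAMES if c in table.columns]
    if not present:
        raise ValueError("table contains no '<channel>.<band>' feature columns")
    return present


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """``(n_rows, n_features)`` float matrix in canonical feature order."""
    return table[feature_columns(table)].to_numpy(dtype=np.float64)


def lineage_groups(table: pd.DataFrame) -> pd.Series:
    """Grouping key per row: the augmentation parent if any, else the subject.

    Rows produced by split-half augmentation carry their parent's id in the
    ``lineage`` column; all leakage-sensitive grouping (CV folds, lineage
    collapsing) uses this key so a subject and its halves always travel
    together.
    """
    if "lineage" in table.columns:
        lin = table["lineage"]
        return lin.where(lin.notna() & (lin != ""), table["subject_id"])
    return table["subject_id"].copy()


def collapse_lineage(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse augmented halves back to one row per original subject.

    Feature values of a lineage group are averaged; metadata is taken from the
    first row of the group.  Tables without augmented rows pass through
    unchanged (up to row order, which stays first-appearance stable).
    """
    key = lineage_groups(table)
    if key.is_unique:
        return table.copy()
    feats = feature_columns(table)
    meta = [c for c in table.columns if c not in feats]
    grouped = table.groupby(key, sort=False)
    out = grouped[feats].mean()
    out_meta = grouped[meta].first()
    out_meta["subject_id"] = out.index
    if "lineage" in out_meta.columns:
        out_meta["lineage"] = pd.NA
    merged = pd.concat([out_meta, out], axis=1).reset_index(drop=True)
    return merged[[c for c in table.columns if c in merged.columns]]


def validate_feature_table(table: pd.DataFrame, *, atol: float = 1e-9) -> None:
    """Check structural invariants: 152 features, per-channel simplex rows."""
    feats = feature_columns(table)
    if len(feats) != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} feature columns, found {len(feats)}")
    for col in ("subject_id", "amyloid_label"):
        if col not in table.columns:
            raise ValueError(f"missing required metadata column {col!r}")
    X = feature_matrix(table)
    if (X < -atol).any():
        raise ValueError("negative relative power encountered")
    per_channel = X.reshape(len(table), N_CHANNELS, N_BANDS).sum(axis=2)
    if not np.allclose(per_channel, 1.0, atol=atol):
        worst = float(np.abs(per_channel - 1.0).max())
        raise ValueError(
            f"relative band powers must sum to 1 per channel (worst deviation {worst:.2e})"
        )
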