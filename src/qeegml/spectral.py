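"""Relative band-power feature extraction from resting-state EEG.

The pipeline per subject is:

1. re-reference to a common average (makes features montage-independent),
2. Welch power spectral density at 0.25 Hz resolution (4 s Hann windows,
   50% overlap, per-window mean removal),
3. integrate the PSD over the eight clinical bands per channel,
4. normalise each channel's band powers to sum to one (relative power),
5. flatten channel-major / band-minor into the 152-feature vector.

Relative rather than absolute power is used throughout so that inter-subject
amplitude differences (skull conductivity, electrode impedance, amplifier
gain) cancel out.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .core import (
    AS_RECORDED,
    BANDS,
    CHANNELS,
    COMMON_AVERAGE,
    DEFAULT_SCHEME,
    N_BANDS,
    N_CHANNELS,
    BandScheme,
    EEGRecording,
)

DEFAULT_RESOLUTION_HZ = 0.25

ABSOLUTE = "absolute"
RELATIVE = "relative"


@dataclass
class BandPowerMatrix:
    """Per-channel band powers: ``values`` is 19 channels x 8 bands.

    ``kind`` is ``"absolute"`` (uV^2, PSD integrated over each band) or
    ``"relative"`` (each channel row normalised to sum to 1).
    """

    values: np.ndarray
    kind: str
    channels: tuple[str, ...] = CHANNELS
    bands: tuple[str, ...] = BANDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.channels), len(self.bands)):
            raise ValueError(
                f"values must be {len(self.channels)}x{len(self.bands)}, "
                f"got {self.values.shape}"
            )
        if self.kind not in (ABSOLUTE, RELATIVE):
            raise ValueError(f"kind must be 'absolute' or 'relative', got {self.kind!r}")
        if self.kind == ABSOLUTE and (self.values < 0).any():
            raise ValueError("absolute band powers must be non-negative")
        if self.kind == RELATIVE:
            rows = self.values.sum(axis=1)
            if not np.allclose(rows, 1.0, atol=1e-9):
                raise ValueError("relative band-power rows must sum to 1")

    def flatten(self) -> np.ndarray:
        """Channel-major, band-minor 1-D vector (length 152 for the default montage)."""
        return self.values.reshape(-1).copy()


@dataclass
class FeatureVector:
    """One subject's 152 relative band powers plus labels and lineage."""

    subject_id: str
    values: np.ndarray
    diagnosis: str | None = None
    amyloid_label: str = "unknown"
    lineage: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_CHANNELS * N_BANDS,):
            raise ValueError(f"expected {N_CHANNELS * N_BANDS} values, got {self.values.shape}")

    def to_row(self) -> dict:
        from .core import FEATURE_NAMES

        row = {
            "subject_id": self.subject_id,
            "diagnosis": self.diagnosis,
            "amyloid_label": self.amyloid_label,
            "lineage": self.lineage,
        }
        row.update(zip(FEATURE_NAMES, self.values))
        return row


def rereference_common_average(rec: EEGRecording, *, force: bool = False) -> EEGRecording:
    """Subtract the instantaneous mean of all 19 channels from every channel.

    After re-referencing the channel mean is 0 at every sample, so the result
    does not depend on the recording reference used at acquisition.  The
    operation is idempotent; a recording already tagged common-average is
    refused unless ``force`` is set.
    """
    if rec.reference == COMMON_AVERAGE and not force:
        raise ValueError(
            "recording is already common-average referenced; pass force=True to redo"
        )
    centered = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return replace(rec, samples=centered, reference=COMMON_AVERAGE)


def _welch_params(fs: float, resolution: float) -> int:
    nperseg = fs / resolution
    if abs(nperseg - round(nperseg)) > 1e-9:
        raise ValueError(
            f"fs/resolution must be an integer window length; fs={fs}, "
            f"resolution={resolution} gives {nperseg}"
        )
    return int(round(nperseg))


def welch_psd(
    samples: np.ndarray, fs: float, resolution: float = DEFAULT_RESOLUTION_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodograms (Hann, 50% overlap, constant detrend).

    Window length is ``fs / resolution`` samples (4 s at the default 0.25 Hz),
    so PSD bins land exactly on multiples of the requested resolution.
    Returns ``(freqs, psd)`` with ``psd`` in uV^2/Hz, one row per channel.
    """
    nperseg = _welch_params(fs, resolution)
    if samples.shape[-1] < nperseg:
        raise ValueError(
            f"recording too short: {samples.shape[-1]} samples < one "
            f"{nperseg}-sample PSD window"
        )
    return signal.welch(
        samples,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
    )


def compute_band_powers(
    rec: EEGRecording,
    scheme: BandScheme = DEFAULT_SCHEME,
    resolution: float = DEFAULT_RESOLUTION_HZ,
) -> BandPowerMatrix:
    """Integrate the Welch PSD over each band: absolute power in uV^2.

    Band intervals are half-open ``[low, high)``; the top band is closed at
    its upper edge (45 Hz), so the bands tile [1, 45] Hz and the per-channel
    sum of band powers equals the total PSD integral over that range.
    """
    if rec.reference != COMMON_AVERAGE:
        raise ValueError(
            "recording must be common-average referenced first "
            "(use rereference_common_average)"
        )
    freqs, psd = welch_psd(rec.samples, rec.fs, resolution)
    masks = scheme.bin_masks(freqs)
    df = freqs[1] - freqs[0]
    values = np.column_stack([psd[:, masks[b]].sum(axis=1) * df for b in scheme.names])
    return BandPowerMatrix(values=values, kind=ABSOLUTE, bands=scheme.names)


def relative_band_powers(abs_powers: BandPowerMatrix) -> BandPowerMatrix:
    """Normalise each channel's band powers by the channel total.

    The denominator is the sum over the defined bands, i.e. total 1-45 Hz
    power under the default scheme.  A channel with zero total power has no
    defined relative power and raises.
    """
    if abs_powers.kind != ABSOLUTE:
        raise ValueError("input must be an absolute band-power matrix")
    totals = abs_powers.values.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        dead = [abs_powers.channels[i] for i in np.where(totals.ravel() <= 0)[0]]
        raise ValueError(f"zero total power on channel(s) {dead}; relative power undefined")
    return BandPowerMatrix(
        values=abs_powers.values / totals,
        kind=RELATIVE,
        channels=abs_powers.channels,
        bands=abs_powers.bands,
    )


def extract_features(
    rec: EEGRecording,
    subject_id: str | None = None,
    diagnosis: str | None = None,
    amyloid_label: str = "unknown",
    lineage: str | None = None,
    scheme: BandScheme = DEFAULT_SCHEME,
    resolution: float = DEFAULT_RESOLUTION_HZ,
) -> FeatureVector:
    """Raw recording -> 152-dimensional relative band-power feature vector.

    Re-references to common average if needed, then composes the PSD, band
    integration and per-channel normalisation steps.
    """
    if rec.reference == AS_RECORDED:
        rec = rereference_common_average(rec)
    rel = relative_band_powers(compute_band_powers(rec, scheme, resolution))
    sid = subject_id or rec.subject_id or "subject"
    return FeatureVector(
        subject_id=sid,
        values=rel.flatten(),
        diagnosis=diagnosis,
        amyloid_label=amyloid_label,
        lineage=lineage,
    )
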