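"""Synthetic cohorts with the spectral group structure of amyloid-positive EEG.

The study data behind this package (clinical EEG plus amyloid-PET labels)
are not publicly deposited, so everything downstream is exercised on
synthetic cohorts generated here.  The generator is specified purely by its
*band-power template contract*: every subject has a per-channel relative
band-power template (a probability vector over the eight bands per channel),
and a generated recording's expected relative band powers equal that
template.

Group structure follows the reported direction of effects in amyloid-positive
pre-dementia patients: relative delta power elevated over frontal/central
channels, beta1 elevated frontally, alpha and gamma reduced.  Magnitudes are
free parameters (no magnitudes are published); the defaults plant a moderate,
recoverable effect (absolute relative-power shift 0.02 against a
between-subject SD of 0.02).

Signals are synthesised in the frequency domain: each channel is a dense sum
of sinusoids on the recording's Fourier grid with a pink (1/f^1.2) magnitude
profile inside 1-45 Hz plus a 9 Hz posterior-rhythm peak in the alpha1
band, rescaled band-by-band so each band's total variance matches the
template, and randomised in phase.  Band powers per realisation
are therefore exact up to PSD-estimation leakage, which keeps the
generator -> feature-extraction round trip tight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import (
    BANDS,
    CHANNELS,
    DEFAULT_BAND_EDGES,
    FEATURE_NAMES,
    N_CHANNELS,
    NEGATIVE,
    POSITIVE,
    EEGRecording,
)

#: Baseline relative band powers of an eyes-closed resting adult EEG:
#: alpha-dominant, substantial low-frequency power, little gamma.  Sums to 1.
BASELINE_BAND_POWER: dict[str, float] = {
    "delta": 0.22,
    "theta": 0.16,
    "alpha1": 0.19,
    "alpha2": 0.13,
    "beta1": 0.10,
    "beta2": 0.08,
    "beta3": 0.08,
    "gamma": 0.04,
}

#: Posterior channels get an alpha boost (posterior dominant rhythm).
_POSTERIOR = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")

#: Channel lists of the reported relative-power group differences
#: (amyloid-positive vs negative): delta and beta1 up, alpha and gamma down.
POSITIVE_EFFECT_CHANNELS: dict[str, tuple[str, ...]] = {
    "delta": ("Fp2", "F3", "Fz", "F4", "F7", "C3", "Cz", "C4", "Pz", "P4", "T6", "O1"),
    "beta1": ("Fp1", "Fp2", "F3", "Fz", "F4", "C3"),
    "alpha1": ("Fp1", "F3", "Fz", "C3", "Cz", "C4", "Pz", "T6"),
    "alpha2": ("Fp1", "F3", "Fz", "C3", "Cz", "C4", "Pz", "T6"),
    "gamma": ("Fp2", "F7", "F8", "C4", "T3", "T4"),
}

DEFAULT_EFFECT = 0.02
DEFAULT_NOISE_SD = 0.02
DEFAULT_TOTAL_POWER_UV2 = 400.0  # ~20 uV rms per channel
_MIN_BAND_POWER = 1e-3
#: In-band spectral decline exponent (1/f^slope pink background).
PINK_SLOPE = 1.2
#: Height, centre and width of the posterior-dominant-rhythm peak added to
#: the in-band shape of the alpha1 band.  The peak sits mid-band (9 Hz) so
#: its energy stays clear of the 8 and 10 Hz band edges, where window
#: leakage would otherwise bleed into neighbouring bands.
ALPHA_PEAK_GAIN = 1.0
ALPHA_PEAK_HZ = 9.0
ALPHA_PEAK_WIDTH_HZ = 0.6


@dataclass(frozen=True)
class GroupProfile:
    """Spectral template of one amyloid-status group.

    ``band_shift`` adds to the baseline relative power of a band, optionally
    restricted to the channels listed in ``shift_channels``; rows are then
    renormalised to sum to 1 per channel.  ``noise_sd`` is the
    between-subject SD of each band's relative power before renormalisation.
    """

    label: str
    band_shift: Mapping[str, float] = field(default_factory=dict)
    shift_channels: Mapping[str, Sequence[str]] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be 'positive' or 'negative', got {self.label!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for band in self.band_shift:
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r} in band_shift")
        for band, chans in self.shift_channels.items():
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r} in shift_channels")
            unknown = set(chans) - set(CHANNELS)
            if unknown:
                raise ValueError(f"unknown channel names {sorted(unknown)} for band {band!r}")

    def template(self) -> np.ndarray:
        """19x8 expected relative band powers: baseline + shifts, renormalised."""
        base = np.array([BASELINE_BAND_POWER[b] for b in BANDS], dtype=np.float64)
        tpl = np.tile(base, (N_CHANNELS, 1))
        # posterior-dominant alpha: mild regional modulation of the baseline
        ia1, ia2 = BANDS.index("alpha1"), BANDS.index("alpha2")
        for ch in _POSTERIOR:
            i = CHANNELS.index(ch)
            tpl[i, ia1] += 0.04
            tpl[i, ia2] += 0.03
        tpl /= tpl.sum(axis=1, keepdims=True)
        for band, shift in self.band_shift.items():
            j = BANDS.index(band)
            chans = self.shift_channels.get(band, CHANNELS)
            for ch in chans:
                tpl[CHANNELS.index(ch), j] += shift
        if (tpl < 0).any():
            raise ValueError(
                "band shifts drive an expected relative power negative; "
                "templates must stay renormalizable"
            )
        return tpl / tpl.sum(axis=1, keepdims=True)


def default_profiles(
    effect: float = DEFAULT_EFFECT, noise_sd: float = DEFAULT_NOISE_SD
) -> dict[str, GroupProfile]:
    """Positive/negative group profiles encoding the reported effect directions.

    A single scalar ``effect`` scales all planted shifts: delta and beta1 up,
    alpha1/alpha2 and gamma down, each over its reported channel set.
    """
    positive = GroupProfile(
        label=POSITIVE,
        band_shift={
            "delta": effect,
            "beta1": effect,
            "alpha1": -effect,
            "alpha2": -effect / 2,
            "gamma": -effect / 2,
        },
        shift_channels=POSITIVE_EFFECT_CHANNELS,
        noise_sd=noise_sd,
    )
    negative = GroupProfile(label=NEGATIVE, noise_sd=noise_sd)
    return {POSITIVE: positive, NEGATIVE: negative}


def planted_profiles(
    features: Sequence[tuple[str, str]],
    shift: float = 0.05,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> dict[str, GroupProfile]:
    """Profiles planting a strong shift on an explicit list of (channel, band)
    features, for feature-recovery experiments."""
    band_shift: dict[str, float] = {}
    shift_channels: dict[str, tuple[str, ...]] = {}
    for ch, band in features:
        if band in band_shift and band_shift[band] != shift:
            raise ValueError("one shift per band in a planted profile")
        band_shift[band] = shift
        shift_channels[band] = shift_channels.get(band, ()) + (ch,)
    positive = GroupProfile(
        label=POSITIVE,
        band_shift=band_shift,
        shift_channels=shift_channels,
        noise_sd=noise_sd,
    )
    return {POSITIVE: positive, NEGATIVE: GroupProfile(label=NEGATIVE, noise_sd=noise_sd)}


@dataclass(frozen=True)
class CohortDesign:
    """Composition and acquisition parameters of one synthetic cohort.

    Defaults mirror the study conditions: ~3 min eyes-closed recordings at
    200 or 250 Hz and a positive:negative prevalence near 1:2.5 (SCD stratum
    34:146, MCI stratum 29:34).
    """

    n_positive: int
    n_negative: int
    diagnosis: str = "SCD"
    duration_s: float = 180.0
    fs: float = 250.0
    seed: int = 0
    profiles: Mapping[str, GroupProfile] = field(default_factory=default_profiles)
    allow_any_fs: bool = False

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("need at least one subject per group")
        if self.fs not in (200.0, 250.0) and not self.allow_any_fs:
            raise ValueError("fs must be 200 or 250 Hz (set allow_any_fs to override)")
        if set(self.profiles) != {POSITIVE, NEGATIVE}:
            raise ValueError("profiles must map exactly 'positive' and 'negative'")

    def subject_seed(self, index: int) -> np.random.SeedSequence:
        """Per-subject seed derived from (design seed, subject index): cohorts
        are extensible without reshuffling existing subjects."""
        return np.random.SeedSequence(entropy=self.seed, spawn_key=(index,))


def scd_design(seed: int = 0, **kw) -> CohortDesign:
    """The SCD stratum at the study's composition (34 positive, 146 negative)."""
    return CohortDesign(n_positive=34, n_negative=146, diagnosis="SCD", seed=seed, **kw)


def mci_design(seed: int = 0, **kw) -> CohortDesign:
    """The MCI stratum at the study's composition (29 positive, 34 negative)."""
    return CohortDesign(n_positive=29, n_negative=34, diagnosis="MCI", seed=seed, **kw)


def _draw_subject_template(
    template: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """One subject's template: group template + band noise, clipped and
    renormalised per channel."""
    t = template + rng.normal(0.0, noise_sd, size=template.shape)
    t = np.clip(t, _MIN_BAND_POWER, None)
    return t / t.sum(axis=1, keepdims=True)


def generate_recording(
    profile: GroupProfile,
    duration_s: float = 180.0,
    fs: float = 250.0,
    seed: int | np.random.SeedSequence = 0,
    subject_template: np.ndarray | None = None,
    total_power_uv2: float = DEFAULT_TOTAL_POWER_UV2,
    subject_id: str | None = None,
) -> EEGRecording:
    """Synthesise one 19-channel recording realising a band-power template.

    Each channel is an independent random-phase multisine on the record's
    Fourier grid: pink (1/f) magnitude shape inside each band, rescaled so the
    band's variance equals ``total_power_uv2`` times the template's relative
    power.  Expected relative band powers therefore equal the template, and a
    fixed seed fixes every sample.
    """
    if duration_s < 8.0:
        raise ValueError("duration_s must be >= 8 s (at least one PSD window)")
    fmax = DEFAULT_BAND_EDGES["gamma"][1]
    if fs <= 2 * fmax:
        raise ValueError(f"fs={fs} violates Nyquist for content up to {fmax} Hz")
    tpl = profile.template() if subject_template is None else subject_template
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    rng = np.random.default_rng(seed)

    band_bins = {
        band: np.where(
            (freqs >= lo) & ((freqs < hi) | ((band == BANDS[-1]) & np.isclose(freqs, hi)))
        )[0]
        for band, (lo, hi) in DEFAULT_BAND_EDGES.items()
    }
    samples = np.empty((N_CHANNELS, n), dtype=np.float64)
    spec = np.zeros(len(freqs), dtype=np.complex128)
    for ci in range(N_CHANNELS):
        spec[:] = 0.0
        for bi, band in enumerate(BANDS):
            bins = band_bins[band]
            target = total_power_uv2 * tpl[ci, bi]
            if target <= 0 or bins.size == 0:
                continue
            shape = freqs[bins] ** -PINK_SLOPE  # pink profile in-band
            if band == "alpha1":  # posterior-dominant-rhythm peak
                shape = shape + ALPHA_PEAK_GAIN * np.exp(
                    -0.5 * ((freqs[bins] - ALPHA_PEAK_HZ) / ALPHA_PEAK_WIDTH_HZ) ** 2
                )
            amp_sq = shape * (target / shape.sum())  # per-bin variance a_k^2/2
            phases = rng.uniform(0.0, 2.0 * np.pi, size=bins.size)
            # x(t) = sum_k a_k cos(2 pi f_k t + phi_k); via irfft, |X_k| = n*a_k/2
            spec[bins] = (n / 2.0) * np.sqrt(2.0 * amp_sq) * np.exp(1j * phases)
        samples[ci] = np.fft.irfft(spec, n=n)
    return EEGRecording(samples=samples, fs=fs, subject_id=subject_id)


class CohortSubject(NamedTuple):
    subject_id: str
    diagnosis: str
    label: str
    recording: EEGRecording


def _subject_ids(design: CohortDesign) -> list[tuple[str, str]]:
    ids = [
        (f"{design.diagnosis}-pos-{i:03d}", POSITIVE) for i in range(design.n_positive)
    ]
    ids += [
        (f"{design.diagnosis}-neg-{i:03d}", NEGATIVE) for i in range(design.n_negative)
    ]
    return ids


def generate_cohort(design: CohortDesign) -> list[CohortSubject]:
    """Generate ``n_positive + n_negative`` labelled recordings.

    Positives come first; per-subject randomness (template jitter and signal
    phases) derives from ``design.subject_seed(index)``.
    """
    out: list[CohortSubject] = []
    for idx, (sid, label) in enumerate(_subject_ids(design)):
        profile = design.profiles[label]
        ss = design.subject_seed(idx)
        rng = np.random.default_rng(ss)
        tpl = _draw_subject_template(profile.template(), profile.noise_sd, rng)
        rec = generate_recording(
            profile,
            duration_s=design.duration_s,
            fs=design.fs,
            seed=rng,
            subject_template=tpl,
            subject_id=sid,
        )
        out.append(CohortSubject(sid, design.diagnosis, label, rec))
    return out


def generate_feature_table(design: CohortDesign) -> pd.DataFrame:
    """Feature-space shortcut: draw the 152 relative powers directly.

    Each subject's per-channel 8-band relative powers are the group template
    plus Gaussian between-subject noise, clipped and renormalised to the
    per-channel simplex.  Uses the same per-subject seed stream as
    :func:`generate_cohort` (but consumes it differently, so the two routes
    give different — individually reproducible — cohorts).
    """
    rows = []
    for idx, (sid, label) in enumerate(_subject_ids(design)):
        profile = design.profiles[label]
        rng = np.random.default_rng(design.subject_seed(idx))
        tpl = _draw_subject_template(profile.template(), profile.noise_sd, rng)
        row = {"subject_id": sid, "diagnosis": design.diagnosis, "amyloid_label": label}
        row.update(zip(FEATURE_NAMES, tpl.reshape(-1)))
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_to_feature_table(cohort: Sequence[CohortSubject]) -> pd.DataFrame:
    """Extract the 152-feature table from a list of generated recordings."""
    from .spectral import extract_features

    rows = [
        extract_features(
            s.recording, subject_id=s.subject_id, diagnosis=s.diagnosis,
            amyloid_label=s.label,
        ).to_row()
        for s in cohort
    ]
    return pd.DataFrame(rows)
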