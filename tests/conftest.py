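"""Shared fixtures: small synthetic tables, recordings, and an EDF writer."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qeegml.core import CHANNELS, FEATURE_NAMES, N_BANDS, N_CHANNELS, EEGRecording
from qeegml.synthetic import CohortDesign, GroupProfile, generate_feature_table


@pytest.fixture
def null_profiles():
    """Positive/negative profiles with no planted effect (exchangeable groups)."""
    return {
        "positive": GroupProfile(label="positive"),
        "negative": GroupProfile(label="negative"),
    }


@pytest.fixture
def small_table():
    """20+30 subjects with the default planted group effect."""
    design = CohortDesign(n_positive=20, n_negative=30, seed=42)
    return generate_feature_table(design)


@pytest.fixture
def null_table(null_profiles):
    design = CohortDesign(n_positive=20, n_negative=30, seed=7, profiles=null_profiles)
    return generate_feature_table(design)


@pytest.fixture
def sine_recording():
    """19 channels of a pure 9 Hz tone (random phases), zero channel mean."""
    fs, dur = 250.0, 20.0
    t = np.arange(int(fs * dur)) / fs
    rng = np.random.default_rng(0)
    phases = rng.uniform(0, 2 * np.pi, N_CHANNELS)
    samples = 30.0 * np.cos(2 * np.pi * 9.0 * t[None, :] + phases[:, None])
    return EEGRecording(samples=samples, fs=fs)


def make_separable_table(n_per_class: int = 30, seed: int = 0) -> pd.DataFrame:
    """A feature table where one feature ('Fp1.delta') separates the classes
    perfectly and the rest are noise on the per-channel simplex."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(2 * n_per_class):
        positive = i < n_per_class
        tpl = rng.dirichlet(np.ones(N_BANDS) * 20.0, size=N_CHANNELS)
        # plant a disjoint range for the first channel's first band
        tpl[0, 0] = rng.uniform(0.55, 0.65) if positive else rng.uniform(0.05, 0.15)
        tpl[0] /= tpl[0].sum()
        row = {
            "subject_id": f"s{i:03d}",
            "diagnosis": "SCD",
            "amyloid_label": "positive" if positive else "negative",
        }
        row.update(zip(FEATURE_NAMES, tpl.reshape(-1)))
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def separable_table():
    return make_separable_table()


def write_minimal_edf(path, samples_uv: np.ndarray, fs: float) -> None:
    """Write a minimal but standard-conforming EDF file (test fixture only).

    One data record per second, 19 signals labelled with 10-20 names,
    physical range +/-1000 uV mapped onto the full int16 digital range.
    """
    n_ch, n_samp = samples_uv.shape
    assert n_ch == N_CHANNELS and fs == int(fs)
    spr = int(fs)
    n_rec = n_samp // spr
    header_bytes = 256 + 256 * n_ch

    def fixed(text, width):
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join(
        [
            fixed("0", 8),
            fixed("X X X X", 80),
            fixed("Startdate 01-JAN-2020 X X X", 80),
            fixed("01.01.20", 8),
            fixed("00.00.00", 8),
            fixed(header_bytes, 8),
            fixed("", 44),
            fixed(n_rec, 8),
            fixed("1", 8),
            fixed(n_ch, 4),
        ]
    )
    fields = [
        (16, [f"EEG {ch}" for ch in CHANNELS]),
        (80, ["AgAgCl electrode"] * n_ch),
        (8, ["uV"] * n_ch),
        (8, ["-1000"] * n_ch),
        (8, ["1000"] * n_ch),
        (8, ["-32768"] * n_ch),
        (8, ["32767"] * n_ch),
        (80, ["HP:0.1Hz LP:100Hz"] * n_ch),
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ]
    for width, values in fields:
        hdr += b"".join(fixed(v, width) for v in values)
    gain = 32767.0 / 1000.0
    digital = np.clip(np.round(samples_uv * gain), -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())
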