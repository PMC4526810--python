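"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from tempotag.beat_response import EEGRecording
from tempotag.io import PipelineConfig
from tempotag.synthetic import SyntheticConfig


@pytest.fixture
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def fast_synth_config() -> SyntheticConfig:
    """Short recordings at a reduced sampling rate for Monte-Carlo tests."""
    return SyntheticConfig(duration_s=20.0, sample_rate_hz=250.0, seed=0)


def make_recording(
    signals: dict[str, np.ndarray], sample_rate_hz: float = 1000.0, **meta
) -> EEGRecording:
    labels = tuple(signals)
    data = np.vstack([signals[c] for c in labels])
    return EEGRecording(data=data, sample_rate_hz=sample_rate_hz,
                        channel_labels=labels, meta=meta)


def cosine(f_hz: float, amp: float, duration_s: float, fs: float, phase: float = 0.0):
    t = np.arange(int(round(duration_s * fs))) / fs
    return amp * np.cos(2 * np.pi * f_hz * t + phase)


def write_minimal_edf(
    path: Path,
    data_uv: np.ndarray,
    labels: list[str],
    fs: int,
) -> None:
    """Write a minimal valid EDF file (int16 records, physical units uV).

    Built byte-by-byte here so the repository needs no binary fixture; one
    data record per second.
    """
    n_ch, n_samp = data_uv.shape
    assert n_samp % fs == 0
    n_records = n_samp // fs
    phys_min, phys_max = -3200.0, 3200.0
    dig_min, dig_max = -32768, 32767

    def pad(value: str, width: int) -> bytes:
        return value.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate 01-JAN-2020 X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + n_ch)), 8), pad("EDF", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(n_ch), 4),
    ])
    fields = [
        ("".join, [pad(l, 16) for l in labels]),
        ("".join, [pad("AgAgCl electrode", 80)] * n_ch),
        ("".join, [pad("uV", 8)] * n_ch),
        ("".join, [pad(str(phys_min), 8)] * n_ch),
        ("".join, [pad(str(phys_max), 8)] * n_ch),
        ("".join, [pad(str(dig_min), 8)] * n_ch),
        ("".join, [pad(str(dig_max), 8)] * n_ch),
        ("".join, [pad("", 80)] * n_ch),
        ("".join, [pad(str(fs), 8)] * n_ch),
        ("".join, [pad("", 32)] * n_ch),
    ]
    signal_header = b"".join(b"".join(parts) for _, parts in fields)

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data_uv - phys_min) * gain + dig_min),
                      dig_min, dig_max).astype("<i2")
    body = b""
    for r in range(n_records):
        for ch in range(n_ch):
            body += digital[ch, r * fs : (r + 1) * fs].tobytes()
    path.write_bytes(header + signal_header + body)
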