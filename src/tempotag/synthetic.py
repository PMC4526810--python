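"""Synthetic EEG with a known beat response, for end-to-end pipeline testing.

Each simulated channel carries a 6-Hz cosine whose amplitude follows a
frontal-dominant scalp topography, multiplied by a per-trial lognormal gain
and a per-condition effect, plus band-limited (0.1-100 Hz) 1/f^alpha noise.
Ground truth (per-channel amplitude and phase) is returned alongside every
recording so that estimator bias, channel-selection calibration, the
statistical ladder and the classifier can all be validated against known
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .beat_response import CHANNELS_10_10, EEGRecording
from .errors import InvalidInputError

__all__ = [
    "DEFAULT_TOPOGRAPHY",
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedTrial",
    "simulate_recording",
    "simulate_experiment",
    "CONDITIONS",
]

#: Relative beat-response gain per channel: strongest frontally/centrally,
#: weakest at the occipital pole, mirroring the measured scalp topography.
DEFAULT_TOPOGRAPHY: dict[str, float] = {
    "Fpz": 0.80, "F5": 0.75, "Fz": 1.00, "F6": 0.95,
    "T7": 0.50, "C3": 0.70, "Cz": 0.80, "C4": 0.70, "T8": 0.50,
    "P5": 0.40, "Pz": 0.55, "P6": 0.40, "Oz": 0.15,
}

#: Condition pairs (A, B) per paradigm; paired differences are B - A
#: (scrambled - original, expected positive; ignored - attended, expected
#: negative since the response is stronger when scrambled and when attended).
CONDITIONS: dict[str, tuple[str, str]] = {
    "comprehension": ("original", "scrambled"),
    "attention": ("attended", "ignored"),
}

_CONDITION_CODE = {"original": 1, "scrambled": 2, "attended": 3, "ignored": 4}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate the recording conditions.

    ``base_amplitude`` is the beat-response amplitude (volts) at the
    topography-gain-1 channel; ``noise_rms`` is the broadband RMS of the pink
    background per channel.  ``effect_multiplier`` scales the response in the
    stronger condition (scrambled or attended).  ``trial_cv`` is the lognormal
    coefficient of variation of a per-trial gain shared by both recordings of
    a trial (slow drifts of overall response strength).
    """

    n_subjects: int = 8
    trials_per_subject: int = 4
    beat_frequency_hz: float = 6.0
    sample_rate_hz: float = 1000.0
    duration_s: float = 120.0
    channel_topography: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOPOGRAPHY)
    )
    base_amplitude: float = 1e-6
    effect_multiplier: float = 1.25
    noise_exponent: float = 1.0
    noise_rms: float = 1e-5
    noise_band_hz: tuple[float, float] = (0.1, 100.0)
    trial_cv: float = 0.2
    phase_rad: float = 3.5
    correlated_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise InvalidInputError("sample_rate_hz must be positive")
        if self.effect_multiplier <= 0:
            raise InvalidInputError("effect_multiplier must be positive")
        if any(g < 0 for g in self.channel_topography.values()):
            raise InvalidInputError("topography gains must be non-negative")
        n = self.duration_s * self.sample_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise InvalidInputError("duration_s x sample_rate_hz must be an integer")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(self.channel_topography)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters of one simulated recording."""

    subject: int
    trial: int
    condition: str
    channel_amplitude: dict[str, float]
    phase_rad: float
    trial_gain: float
    condition_gain: float


@dataclass
class SimulatedTrial:
    """One paired trial: two recordings of the same subject/trial/tune."""

    subject: int
    trial: int
    paradigm: str
    recording_a: EEGRecording  # condition A (original / attended)
    recording_b: EEGRecording  # condition B (scrambled / ignored)
    truth_a: GroundTruth
    truth_b: GroundTruth
    presentation_order: tuple[str, str]


def _pink_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    sample_rate_hz: float,
    exponent: float,
    rms: float,
    band_hz: tuple[float, float],
) -> np.ndarray:
    """Band-limited 1/f^alpha noise via spectral shaping of white noise.

    The output is scaled analytically (not empirically) so that its expected
    RMS equals ``rms``; the realized RMS fluctuates as real noise would.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate_hz)
    w = np.zeros_like(freqs)
    lo, hi = band_hz
    in_band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    w[in_band] = freqs[in_band] ** (-exponent / 2.0)
    # E[sample variance] of irfft(W * rfft(white)) with unit white noise:
    n = n_samples
    mid = w[1:-1] if n % 2 == 0 else w[1:]
    expected_var = (w[0] ** 2 + 2 * np.sum(mid**2) + (w[-1] ** 2 if n % 2 == 0 else 0.0)) / n
    if expected_var == 0:
        return np.zeros((n_channels, n_samples))
    scale = rms / math.sqrt(expected_var)
    white = rng.standard_normal((n_channels, n_samples))
    return np.fft.irfft(np.fft.rfft(white, axis=1) * (w * scale), n=n_samples, axis=1)


def _trial_gain(config: SyntheticConfig, subject: int, trial: int) -> float:
    """Lognormal per-trial gain (mean 1, CV = trial_cv), shared within a pair."""
    if config.trial_cv == 0:
        return 1.0
    ss = np.random.SeedSequence([config.seed, subject, trial, 99])
    rng = np.random.default_rng(ss)
    sigma2 = math.log(1.0 + config.trial_cv**2)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2)))


def simulate_recording(
    config: SyntheticConfig,
    condition: str,
    subject: int = 0,
    trial: int = 0,
) -> tuple[EEGRecording, GroundTruth]:
    """Simulate one recording; deterministic given (seed, subject, trial, condition)."""
    if condition not in _CONDITION_CODE:
        raise InvalidInputError(
            f"unknown condition {condition!r}; one of {sorted(_CONDITION_CODE)}"
        )
    cond_gain = (
        config.effect_multiplier if condition in ("scrambled", "attended") else 1.0
    )
    trial_gain = _trial_gain(config, subject, trial)
    ss = np.random.SeedSequence([config.seed, subject, trial, _CONDITION_CODE[condition]])
    rng = np.random.default_rng(ss)

    labels = config.channel_labels
    n = config.n_samples
    t = np.arange(n) / config.sample_rate_hz
    carrier = np.cos(2 * np.pi * config.beat_frequency_hz * t + config.phase_rad)
    gains = np.array([config.channel_topography[c] for c in labels])
    amplitudes = config.base_amplitude * gains * cond_gain * trial_gain
    data = amplitudes[:, None] * carrier[None, :]

    if config.noise_rms > 0:
        if config.correlated_noise:
            # one shared pink source mixed by topography, plus channel noise
            shared = _pink_noise(rng, 1, n, config.sample_rate_hz,
                                 config.noise_exponent, config.noise_rms,
                                 config.noise_band_hz)
            own = _pink_noise(rng, len(labels), n, config.sample_rate_hz,
                              config.noise_exponent, config.noise_rms,
                              config.noise_band_hz)
            data += (gains[:, None] * shared + own) / math.sqrt(2.0)
        else:
            data += _pink_noise(rng, len(labels), n, config.sample_rate_hz,
                                config.noise_exponent, config.noise_rms,
                                config.noise_band_hz)

    rec = EEGRecording(
        data=data,
        sample_rate_hz=config.sample_rate_hz,
        channel_labels=labels,
        meta={"subject": subject, "trial": trial, "condition": condition},
    )
    truth = GroundTruth(
        subject=subject,
        trial=trial,
        condition=condition,
        channel_amplitude={c: float(a) for c, a in zip(labels, amplitudes)},
        phase_rad=config.phase_rad,
        trial_gain=trial_gain,
        condition_gain=cond_gain,
    )
    return rec, truth


def simulate_experiment(
    config: SyntheticConfig, paradigm: str
) -> list[SimulatedTrial]:
    """Simulate a full paired experiment (n_subjects x trials_per_subject trials).

    For each trial both conditions of the paradigm are generated with a shared
    per-trial gain; the presentation order is randomized per trial (recorded in
    metadata, since the analysis itself is order-blind).
    """
    if paradigm not in CONDITIONS:
        raise InvalidInputError(f"unknown paradigm {paradigm!r}; one of {sorted(CONDITIONS)}")
    cond_a, cond_b = CONDITIONS[paradigm]
    trials: list[SimulatedTrial] = []
    for subject in range(config.n_subjects):
        for trial in range(config.trials_per_subject):
            rec_a, truth_a = simulate_recording(config, cond_a, subject, trial)
            rec_b, truth_b = simulate_recording(config, cond_b, subject, trial)
            order_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, subject, trial, 7])
            )
            order = (cond_a, cond_b) if order_rng.integers(2) == 0 else (cond_b, cond_a)
            trials.append(
                SimulatedTrial(
                    subject=subject,
                    trial=trial,
                    paradigm=paradigm,
                    recording_a=rec_a,
                    recording_b=rec_b,
                    truth_a=truth_a,
                    truth_b=truth_b,
                    presentation_order=order,
                )
            )
    return trials
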