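"""Extraction of the steady-state beat response from multi-channel EEG.

The analysis treats the beat as a frequency tag: every channel's full-length
Fourier spectrum is inspected at the beat frequency (6 Hz), channels whose
beat-bin amplitude exceeds the 5-7-Hz neighborhood mean by more than two
neighborhood SDs are declared beat-responsive, the responsive channels are
averaged sample-wise, and the averaged series is cut into 1-s segments whose
complex Fourier coefficients at the beat bin give the amplitude mean, its SEM
and the response phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidInputError
from .stimuli import _amplitude_normalized_rfft

__all__ = [
    "CHANNELS_10_10",
    "EEGRecording",
    "ChannelSpectrum",
    "BeatResponseSummary",
    "ArtifactReport",
    "screen_artifacts",
    "channel_spectrum",
    "beat_responsive_channels",
    "average_beat_response",
    "per_channel_beat_amplitudes",
    "ks_normality",
    "phase_to_latency",
    "latency_to_phase",
]

#: The 13-electrode 10/10 montage used by the recording setup.
CHANNELS_10_10 = (
    "Fpz", "F5", "Fz", "F6", "T7", "C3", "Cz", "C4", "T8", "P5", "Pz", "P6", "Oz",
)


@dataclass
class EEGRecording:
    """One multi-channel EEG recording (voltages in volts, channels x samples)."""

    data: np.ndarray
    sample_rate_hz: float
    channel_labels: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise InvalidInputError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise InvalidInputError("row count must match the number of channel labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise InvalidInputError("channel labels must be unique")
        if self.sample_rate_hz <= 0:
            raise InvalidInputError("sample_rate_hz must be positive")
        if self.duration_s < 1.0:
            raise InvalidInputError("recording must be at least 1 s long")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sample_rate_hz

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as exc:
            raise InvalidInputError(f"channel {label!r} not in recording") from exc


@dataclass
class ChannelSpectrum:
    """Full-length amplitude-normalized complex spectrum per channel."""

    freqs_hz: np.ndarray
    coefficients: np.ndarray  # channels x bins, |coeff| = sinusoid amplitude
    channel_labels: tuple[str, ...]

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def bin_index(self, freq_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - freq_hz)))


@dataclass
class BeatResponseSummary:
    """Beat-frequency response of one recording, over beat-responsive channels."""

    responsive_channels: tuple[str, ...]
    mean_amplitude: float
    sem_amplitude: float
    mean_phase: float
    n_segments: int
    per_segment_coefficients: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def per_segment_amplitudes(self) -> np.ndarray:
        return np.abs(self.per_segment_coefficients)


@dataclass
class ArtifactReport:
    """Spike-screening outcome; verdict 'repeat' mirrors discarding a recording."""

    flagged_fraction: dict[str, float]
    flagged_indices: dict[str, np.ndarray]
    verdict: str  # "pass" | "repeat"
    warnings: list[str] = field(default_factory=list)


def screen_artifacts(
    rec: EEGRecording,
    spike_k: float = 8.0,
    max_flagged_fraction: float = 0.01,
) -> ArtifactReport:
    """Flag short large-amplitude spikes with a per-channel median/MAD rule.

    A sample is flagged when its absolute deviation from the channel median
    exceeds ``spike_k`` times the channel MAD.  The verdict is ``"repeat"``
    (i.e. the recording should be discarded and the experiment repeated) iff
    any channel's flagged fraction exceeds ``max_flagged_fraction``.
    """
    fractions: dict[str, float] = {}
    indices: dict[str, np.ndarray] = {}
    notes: list[str] = []
    for label, x in zip(rec.channel_labels, rec.data):
        med = np.median(x)
        mad = sps.median_abs_deviation(x)
        if mad == 0:
            fractions[label] = 0.0
            indices[label] = np.array([], dtype=int)
            notes.append(f"channel {label}: degenerate (zero MAD) signal")
            continue
        flagged = np.flatnonzero(np.abs(x - med) > spike_k * mad)
        fractions[label] = flagged.size / x.size
        indices[label] = flagged
    verdict = "repeat" if any(f > max_flagged_fraction for f in fractions.values()) else "pass"
    return ArtifactReport(fractions, indices, verdict, notes)


def channel_spectrum(rec: EEGRecording) -> ChannelSpectrum:
    """Full-length DFT per channel, normalized so an exact-bin cosine of
    amplitude A and phase phi yields a coefficient ``A * exp(i*phi)``."""
    if not np.all(np.isfinite(rec.data)):
        raise InvalidInputError("recording contains NaN or infinite samples")
    coeffs = _amplitude_normalized_rfft(rec.data)
    freqs = np.fft.rfftfreq(rec.n_samples, d=1.0 / rec.sample_rate_hz)
    return ChannelSpectrum(freqs_hz=freqs, coefficients=coeffs, channel_labels=rec.channel_labels)


def beat_responsive_channels(
    spec: ChannelSpectrum,
    f_beat_hz: float = 6.0,
    band_hz: tuple[float, float] = (5.0, 7.0),
    k_sd: float = 2.0,
    exclusion_halfwidth_hz: float = 0.1,
) -> list[str]:
    """Channels whose beat-bin amplitude exceeds the neighborhood mean + k SDs.

    Neighbors are all bins inside ``band_hz`` (inclusive) further than
    ``exclusion_halfwidth_hz`` from the beat frequency; the mean and SD are
    taken across those bins of the full-length spectrum.
    """
    lo, hi = band_hz
    if not lo < f_beat_hz < hi:
        raise InvalidInputError("neighbor band must contain the beat frequency")
    freqs = spec.freqs_hz
    in_band = (freqs >= lo) & (freqs <= hi)
    neighbors = in_band & (np.abs(freqs - f_beat_hz) > exclusion_halfwidth_hz)
    if neighbors.sum() < 10:
        raise InvalidInputError(
            f"only {int(neighbors.sum())} neighbor bins in {band_hz}; need >= 10 "
            "(recording too short for the criterion)"
        )
    i_beat = spec.bin_index(f_beat_hz)
    amps = spec.amplitude
    selected = []
    for ch, label in enumerate(spec.channel_labels):
        neigh = amps[ch, neighbors]
        sd = neigh.std(ddof=1)
        if sd == 0:
            warnings.warn(f"channel {label}: zero-variance neighbor bins; excluded")
            continue
        if amps[ch, i_beat] > neigh.mean() + k_sd * sd:
            selected.append(label)
    return selected


def _wrap_phase(phi: float) -> float:
    """Map an angle to (-pi, pi]."""
    phi = (phi + math.pi) % (2 * math.pi) - math.pi
    return math.pi if phi == -math.pi else phi


def segment_coefficients(
    signal: np.ndarray,
    sample_rate_hz: float,
    f_hz: float,
    segment_seconds: float = 1.0,
) -> np.ndarray:
    """Complex amplitude-normalized coefficients at ``f_hz`` per 1-s segment."""
    seg_len = int(round(segment_seconds * sample_rate_hz))
    if seg_len < 2 or signal.size < seg_len:
        raise InvalidInputError("signal shorter than one segment")
    n_seg = signal.size // seg_len
    segments = signal[: n_seg * seg_len].reshape(n_seg, seg_len)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / sample_rate_hz)
    i_f = int(np.argmin(np.abs(freqs - f_hz)))
    coeffs = _amplitude_normalized_rfft(segments)
    return coeffs[:, i_f]


def average_beat_response(
    rec: EEGRecording,
    channels: Sequence[str],
    f_beat_hz: float = 6.0,
    segment_seconds: float = 1.0,
    amplitude_mode: str = "segment_mean",
) -> BeatResponseSummary:
    """Summarize the beat response over the given (responsive) channels.

    The selected channels are averaged sample-wise, the average is cut into
    ``floor(T/segment_seconds)`` segments, and the complex coefficient at the
    beat bin is extracted per segment.  With ``amplitude_mode="segment_mean"``
    (default) the amplitude is the mean of the per-segment moduli with its SEM
    across segments; ``"coherent"`` reports the modulus of the complex mean,
    which is the lower-bias estimator when the per-segment SNR is small.  The
    phase is the argument of the complex mean in either mode.
    """
    channels = list(channels)
    if not channels:
        raise InvalidInputError("channel set is empty")
    if amplitude_mode not in ("segment_mean", "coherent"):
        raise InvalidInputError(f"unknown amplitude_mode {amplitude_mode!r}")
    avg = np.mean([rec.channel(c) for c in channels], axis=0)
    coeffs = segment_coefficients(avg, rec.sample_rate_hz, f_beat_hz, segment_seconds)
    moduli = np.abs(coeffs)
    n = coeffs.size
    mean_coeff = coeffs.mean()
    if amplitude_mode == "segment_mean":
        mean_amp = float(moduli.mean())
    else:
        mean_amp = float(abs(mean_coeff))
    sem = float(moduli.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return BeatResponseSummary(
        responsive_channels=tuple(channels),
        mean_amplitude=mean_amp,
        sem_amplitude=sem,
        mean_phase=_wrap_phase(float(np.angle(mean_coeff))),
        n_segments=n,
        per_segment_coefficients=coeffs,
        meta=dict(rec.meta),
    )


def per_channel_beat_amplitudes(
    rec: EEGRecording,
    f_beat_hz: float = 6.0,
    segment_seconds: float = 1.0,
    amplitude_mode: str = "segment_mean",
) -> dict[str, float]:
    """Beat-frequency amplitude of every individual channel (for topography
    export and for difference-feature classification)."""
    out: dict[str, float] = {}
    for label in rec.channel_labels:
        coeffs = segment_coefficients(
            rec.channel(label), rec.sample_rate_hz, f_beat_hz, segment_seconds
        )
        if amplitude_mode == "coherent":
            out[label] = float(abs(coeffs.mean()))
        else:
            out[label] = float(np.abs(coeffs).mean())
    return out


def ks_normality(per_segment_coefficients: np.ndarray) -> tuple[float, float]:
    """One-sample KS test of the standardized real/imaginary coefficient parts.

    Both quadratures are centered and scaled to unit SD and compared with the
    standard normal; returns ``(p_real, p_imag)``.  A normal outcome validates
    the use of t statistics on the per-segment coefficients.
    """
    coeffs = np.asarray(per_segment_coefficients, dtype=complex)
    if coeffs.size < 20:
        raise InvalidInputError("need at least 20 per-segment coefficients")
    pvals = []
    for part in (coeffs.real, coeffs.imag):
        sd = part.std(ddof=1)
        if sd == 0:
            raise DegenerateInputError("zero variance in a quadrature")
        pvals.append(float(sps.kstest((part - part.mean()) / sd, "norm").pvalue))
    return pvals[0], pvals[1]


def phase_to_latency(phase_rad: float, f_hz: float) -> float:
    """Convert a response phase (cosine convention, positive = lag) to seconds."""
    if f_hz <= 0:
        raise InvalidInputError("frequency must be positive")
    return phase_rad / (2 * math.pi * f_hz)


def latency_to_phase(latency_s: float, f_hz: float) -> float:
    """Inverse of :func:`phase_to_latency`."""
    if f_hz <= 0:
        raise InvalidInputError("frequency must be positive")
    return 2 * math.pi * f_hz * latency_s
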