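"""Musical stimuli: note sequences, scrambling, synthesis, and envelope spectra.

The stimulus design tags the musical beat at a fixed frequency (6 Hz by
default, one note per beat) so that the cortical steady-state response can be
read out at a single spectral bin.  A scrambled control version of each tune
is produced by cutting the note sequence into short segments (2-6 notes) and
permuting them: this destroys the recognizable melody while conserving the
low-level structure (note count, pitch statistics, and the envelope spectrum
at the beat frequency and its harmonics), which this module can verify.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import hilbert

from .errors import FormatError, InvalidInputError

__all__ = [
    "Note",
    "NoteSequence",
    "ScrambleSpec",
    "Envelope",
    "AmplitudeSpectrum",
    "EquivalenceReport",
    "scramble_notes",
    "pitch_change_stats",
    "synthesize_audio",
    "compute_envelope",
    "segmented_spectrum",
    "spectra_equivalent",
    "read_note_json",
    "write_note_json",
    "read_musicxml",
    "write_musicxml",
    "write_wav",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Note:
    """A single note on the beat grid (MIDI pitch convention, 60 = middle C)."""

    pitch: int
    onset_beat: int
    duration_beats: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.pitch <= 127:
            raise InvalidInputError(f"pitch {self.pitch} outside MIDI range [0, 127]")
        if self.onset_beat < 0:
            raise InvalidInputError("onset_beat must be non-negative")
        if self.duration_beats <= 0:
            raise InvalidInputError("duration_beats must be positive")


@dataclass(frozen=True)
class NoteSequence:
    """An ordered single-line score with one note per beat."""

    notes: tuple[Note, ...]
    beat_frequency_hz: float = 6.0
    name: str = ""

    def __init__(self, notes: Sequence[Note], beat_frequency_hz: float = 6.0, name: str = ""):
        notes = tuple(notes)
        if not notes:
            raise InvalidInputError("NoteSequence must contain at least one note")
        if beat_frequency_hz <= 0:
            raise InvalidInputError("beat_frequency_hz must be positive")
        for i, n in enumerate(notes):
            if n.onset_beat != i:
                raise InvalidInputError("onset_beat values must be consecutive from 0")
        object.__setattr__(self, "notes", notes)
        object.__setattr__(self, "beat_frequency_hz", float(beat_frequency_hz))
        object.__setattr__(self, "name", name)

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def pitches(self) -> np.ndarray:
        return np.array([n.pitch for n in self.notes], dtype=int)

    @property
    def duration_s(self) -> float:
        return len(self.notes) / self.beat_frequency_hz

    @classmethod
    def from_pitches(
        cls, pitches: Sequence[int], beat_frequency_hz: float = 6.0, name: str = ""
    ) -> "NoteSequence":
        notes = [Note(pitch=int(p), onset_beat=i) for i, p in enumerate(pitches)]
        return cls(notes, beat_frequency_hz=beat_frequency_hz, name=name)


@dataclass(frozen=True)
class ScrambleSpec:
    """Segment-length bounds and RNG seed for melody scrambling."""

    min_segment: int = 2
    max_segment: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.min_segment <= self.max_segment:
            raise InvalidInputError("require 1 <= min_segment <= max_segment")


@dataclass(frozen=True)
class Envelope:
    """Amplitude envelope of an audio waveform (magnitude of the analytic signal)."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise InvalidInputError("sample_rate_hz must be positive")
        if np.any(np.asarray(self.samples) < 0):
            raise InvalidInputError("envelope samples must be non-negative")


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Mean +/- SEM amplitude spectrum over non-overlapping signal segments."""

    freqs_hz: np.ndarray
    mean_amplitude: np.ndarray
    sem_amplitude: np.ndarray
    n_segments: int

    def __post_init__(self) -> None:
        if not (len(self.freqs_hz) == len(self.mean_amplitude) == len(self.sem_amplitude)):
            raise InvalidInputError("freqs, mean and sem must have equal length")
        if self.n_segments < 1:
            raise InvalidInputError("n_segments must be >= 1")
        if np.any(self.sem_amplitude < 0):
            raise InvalidInputError("SEM must be non-negative")

    def amplitude_at(self, freq_hz: float) -> tuple[float, float]:
        """(mean, sem) at the bin nearest ``freq_hz``."""
        i = int(np.argmin(np.abs(self.freqs_hz - freq_hz)))
        return float(self.mean_amplitude[i]), float(self.sem_amplitude[i])


@dataclass
class EquivalenceReport:
    """Per-frequency equivalence margins between two amplitude spectra.

    ``margin = k_sem * pooled_sem - |mean_a - mean_b|``; a non-negative margin
    at a frequency means the two spectra agree there within the noise.
    """

    freqs_hz: np.ndarray
    mean_a: np.ndarray
    sem_a: np.ndarray
    mean_b: np.ndarray
    sem_b: np.ndarray
    margin: np.ndarray
    equivalent: np.ndarray
    k_sem: float

    @property
    def all_equivalent(self) -> bool:
        return bool(np.all(self.equivalent))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "freq_hz": self.freqs_hz,
                "mean_a": self.mean_a,
                "sem_a": self.sem_a,
                "mean_b": self.mean_b,
                "sem_b": self.sem_b,
                "margin": self.margin,
                "equivalent": self.equivalent,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def scramble_notes(seq: NoteSequence, spec: ScrambleSpec) -> NoteSequence:
    """Scramble a melody by permuting random 2-6-note segments.

    The score is cut sequentially into segments whose lengths are drawn
    uniformly from ``[min_segment, max_segment]``; the final segment may be
    shorter if the note count does not divide evenly.  Segments are then
    rearranged by a uniformly random permutation and onsets renumbered from 0.
    Deterministic given ``spec.seed``.
    """
    n = len(seq)
    if n < spec.min_segment:
        raise InvalidInputError(
            f"sequence of {n} notes is shorter than min_segment={spec.min_segment}"
        )
    rng = np.random.default_rng(spec.seed)
    bounds = [0]
    while bounds[-1] < n:
        length = int(rng.integers(spec.min_segment, spec.max_segment + 1))
        bounds.append(min(bounds[-1] + length, n))
    segments = [seq.notes[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    order = rng.permutation(len(segments))
    scrambled_pitches = [note.pitch for i in order for note in segments[i]]
    return NoteSequence.from_pitches(
        scrambled_pitches,
        beat_frequency_hz=seq.beat_frequency_hz,
        name=f"{seq.name}-scrambled" if seq.name else "scrambled",
    )


def pitch_change_stats(seq: NoteSequence) -> tuple[float, float]:
    """Mean and SD of the relative pitch change between successive notes.

    For adjacent pitches separated by ``d`` semitones the relative frequency
    change is ``2**(d/12) - 1`` (the frequency interval divided by the lower
    tone's frequency).  Returns the mean and the sample SD over all adjacent
    pairs (SD is 0.0 when only one pair exists).
    """
    pitches = seq.pitches
    if len(pitches) < 2:
        raise InvalidInputError("need at least two notes for pitch-change statistics")
    d = np.abs(np.diff(pitches))
    r = 2.0 ** (d / 12.0) - 1.0
    sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    return float(np.mean(r)), sd


def _midi_to_hz(pitch: int | float) -> float:
    return 440.0 * 2.0 ** ((pitch - 69) / 12.0)


def synthesize_audio(
    seq: NoteSequence,
    sample_rate_hz: float = 44100.0,
    n_harmonics: int = 4,
    attack_s: float = 0.010,
    decay_time_constant_s: float | None = None,
    rms_target: float = 0.1,
) -> np.ndarray:
    """Render a note sequence as audio, one harmonic complex tone per beat slot.

    Each note is a sum of ``n_harmonics`` partials with 1/k amplitude roll-off,
    shaped by a linear attack of ``attack_s`` followed by an exponential decay
    confined to the note's beat slot (slot length 1/beat_frequency).  The
    overall waveform is scaled to ``rms_target`` RMS; ``rms_target=0`` yields
    an all-zero waveform of the correct length.
    """
    if sample_rate_hz <= 0:
        raise InvalidInputError("sample_rate_hz must be positive")
    slot_s = 1.0 / seq.beat_frequency_hz
    n_total = int(round(len(seq) * slot_s * sample_rate_hz))
    out = np.zeros(n_total)
    if rms_target == 0:
        return out
    if decay_time_constant_s is None:
        decay_time_constant_s = slot_s / 3.0

    # Per-slot amplitude shape shared by all notes (attack then decay).
    slot_n = int(round(slot_s * sample_rate_hz))
    t = np.arange(slot_n) / sample_rate_hz
    shape = np.exp(-(t - attack_s) / decay_time_constant_s)
    n_attack = max(int(round(attack_s * sample_rate_hz)), 1)
    shape[:n_attack] = np.linspace(0.0, 1.0, n_attack, endpoint=False)

    for note in seq.notes:
        start = int(round(note.onset_beat * slot_s * sample_rate_hz))
        stop = min(start + slot_n, n_total)
        f0 = _midi_to_hz(note.pitch)
        tone = np.zeros(stop - start)
        for k in range(1, n_harmonics + 1):
            if k * f0 >= sample_rate_hz / 2:
                break
            tone += np.sin(2 * np.pi * k * f0 * t[: stop - start]) / k
        out[start:stop] += shape[: stop - start] * tone

    rms = np.sqrt(np.mean(out**2))
    if rms > 0:
        out *= rms_target / rms
    return out


def compute_envelope(waveform: np.ndarray, sample_rate_hz: float) -> Envelope:
    """Amplitude envelope as the magnitude of the analytic (Hilbert) signal."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise InvalidInputError("waveform is empty")
    if not np.all(np.isfinite(waveform)):
        raise InvalidInputError("waveform contains non-finite values")
    env = np.abs(hilbert(waveform))
    return Envelope(samples=env, sample_rate_hz=float(sample_rate_hz))


def _amplitude_normalized_rfft(segments: np.ndarray) -> np.ndarray:
    """Single-sided amplitude-normalized complex spectra of row-wise segments.

    Normalization is chosen so a cosine of amplitude A at an exact bin gives a
    coefficient of modulus A and argument equal to the cosine phase.
    """
    n = segments.shape[-1]
    coeffs = np.fft.rfft(segments, axis=-1) * (2.0 / n)
    coeffs[..., 0] /= 2.0
    if n % 2 == 0:
        coeffs[..., -1] /= 2.0
    return coeffs


def segmented_spectrum(
    signal: np.ndarray,
    sample_rate_hz: float,
    segment_seconds: float = 1.0,
) -> AmplitudeSpectrum:
    """Mean/SEM amplitude spectrum over non-overlapping rectangular segments.

    The signal is cut into ``floor(T / segment_seconds)`` segments; each
    segment's single-sided amplitude spectrum is computed with the
    sinusoid-amplitude normalization, then averaged bin-wise.  With 1-s
    segments the 6-Hz beat falls on an exact bin, so no taper is applied.
    """
    signal = np.asarray(signal, dtype=float)
    if sample_rate_hz <= 0:
        raise InvalidInputError("sample_rate_hz must be positive")
    seg_len = int(round(segment_seconds * sample_rate_hz))
    if seg_len < 2 or signal.size < seg_len:
        raise InvalidInputError("signal shorter than one segment")
    n_seg = signal.size // seg_len
    segments = signal[: n_seg * seg_len].reshape(n_seg, seg_len)
    amps = np.abs(_amplitude_normalized_rfft(segments))
    mean = amps.mean(axis=0)
    sem = amps.std(axis=0, ddof=1) / math.sqrt(n_seg) if n_seg > 1 else np.zeros_like(mean)
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / sample_rate_hz)
    return AmplitudeSpectrum(freqs_hz=freqs, mean_amplitude=mean, sem_amplitude=sem, n_segments=n_seg)


def spectra_equivalent(
    a: AmplitudeSpectrum,
    b: AmplitudeSpectrum,
    test_freqs_hz: Sequence[float] | None = None,
    k_sem: float = 2.0,
) -> EquivalenceReport:
    """Test whether two segment-averaged spectra agree within the noise.

    At each tested frequency (the 6-Hz beat and its first two harmonics by
    default) the spectra are declared equivalent iff
    ``|mean_a - mean_b| <= k_sem * sqrt(sem_a**2 + sem_b**2)``.
    """
    if a.freqs_hz.shape != b.freqs_hz.shape or not np.allclose(a.freqs_hz, b.freqs_hz):
        raise InvalidInputError("spectra must share identical frequency bins")
    if test_freqs_hz is None:
        test_freqs_hz = (6.0, 12.0, 18.0)
    idx = [int(np.argmin(np.abs(a.freqs_hz - f))) for f in test_freqs_hz]
    mean_a = a.mean_amplitude[idx]
    mean_b = b.mean_amplitude[idx]
    sem_a = a.sem_amplitude[idx]
    sem_b = b.sem_amplitude[idx]
    pooled = np.sqrt(sem_a**2 + sem_b**2)
    margin = k_sem * pooled - np.abs(mean_a - mean_b)
    return EquivalenceReport(
        freqs_hz=a.freqs_hz[idx],
        mean_a=mean_a,
        sem_a=sem_a,
        mean_b=mean_b,
        sem_b=sem_b,
        margin=margin,
        equivalent=margin >= 0,
        k_sem=k_sem,
    )


# ---------------------------------------------------------------------------
# I/O: JSON note lists, minimal MusicXML, WAV
# ---------------------------------------------------------------------------

def write_note_json(seq: NoteSequence, path: str | Path) -> None:
    """Write the JSON note-list dialect {name, beat_frequency_hz, pitches}."""
    payload = {
        "name": seq.name,
        "beat_frequency_hz": seq.beat_frequency_hz,
        "pitches": [int(p) for p in seq.pitches],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_note_json(path: str | Path) -> NoteSequence:
    try:
        payload = json.loads(Path(path).read_text())
        return NoteSequence.from_pitches(
            payload["pitches"],
            beat_frequency_hz=float(payload.get("beat_frequency_hz", 6.0)),
            name=str(payload.get("name", "")),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise FormatError(f"not a valid note-list JSON file: {path}: {exc}") from exc


_STEP_TO_SEMITONE = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_SEMITONE_TO_STEP = {0: ("C", 0), 1: ("C", 1), 2: ("D", 0), 3: ("D", 1), 4: ("E", 0),
                     5: ("F", 0), 6: ("F", 1), 7: ("G", 0), 8: ("G", 1), 9: ("A", 0),
                     10: ("A", 1), 11: ("B", 0)}


def read_musicxml(path: str | Path) -> NoteSequence:
    """Read a minimal MusicXML subset: part / measure / note / pitch.

    Only pitched notes are read; each note occupies one beat regardless of the
    written duration (the stimulus grid has one note per beat).
    """
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"cannot parse MusicXML: {path}: {exc}") from exc
    pitches: list[int] = []
    for note_el in root.iter("note"):
        pitch_el = note_el.find("pitch")
        if pitch_el is None:  # rests not supported on the beat grid
            continue
        step = pitch_el.findtext("step")
        octave = pitch_el.findtext("octave")
        if step is None or octave is None:
            raise FormatError(f"note without step/octave in {path}")
        alter = int(float(pitch_el.findtext("alter") or 0))
        midi = 12 * (int(octave) + 1) + _STEP_TO_SEMITONE[step] + alter
        pitches.append(midi)
    if not pitches:
        raise FormatError(f"no pitched notes found in {path}")
    name = root.findtext(".//work-title") or Path(path).stem
    return NoteSequence.from_pitches(pitches, name=name)


def write_musicxml(seq: NoteSequence, path: str | Path, notes_per_measure: int = 6) -> None:
    """Write a minimal score-partwise MusicXML file (single part, quarter notes)."""
    root = ET.Element("score-partwise", version="3.1")
    work = ET.SubElement(root, "work")
    ET.SubElement(work, "work-title").text = seq.name or "untitled"
    part_list = ET.SubElement(root, "part-list")
    score_part = ET.SubElement(part_list, "score-part", id="P1")
    ET.SubElement(score_part, "part-name").text = "melody"
    part = ET.SubElement(root, "part", id="P1")
    pitches = seq.pitches
    for m_start in range(0, len(pitches), notes_per_measure):
        measure = ET.SubElement(part, "measure", number=str(m_start // notes_per_measure + 1))
        if m_start == 0:
            attrs = ET.SubElement(measure, "attributes")
            ET.SubElement(attrs, "divisions").text = "1"
        for p in pitches[m_start : m_start + notes_per_measure]:
            note_el = ET.SubElement(measure, "note")
            pitch_el = ET.SubElement(note_el, "pitch")
            step, alter = _SEMITONE_TO_STEP[int(p) % 12]
            ET.SubElement(pitch_el, "step").text = step
            if alter:
                ET.SubElement(pitch_el, "alter").text = str(alter)
            ET.SubElement(pitch_el, "octave").text = str(int(p) // 12 - 1)
            ET.SubElement(note_el, "duration").text = "1"
            ET.SubElement(note_el, "type").text = "quarter"
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def write_wav(waveform: np.ndarray, sample_rate_hz: float, path: str | Path) -> None:
    """Write a float32 PCM WAV file."""
    wavfile.write(str(path), int(round(sample_rate_hz)), np.asarray(waveform, dtype=np.float32))
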