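"""Built-in single-line melodies used as stimulus fixtures.

Each melody is the main theme of a public-domain tune, reduced to a single
melodic line with exactly one note per beat, following the stimulus design:
a 6-Hz beat and notes centred within one octave range. Themes are tiled to
the requested number of beats so that a two-minute presentation (720 beats
at 6 Hz) can be produced from a short encoded theme.

Pitches use the MIDI convention (60 = middle C).
"""

from __future__ import annotations

from .stimuli import Note, NoteSequence

DEFAULT_BEAT_HZ = 6.0

#: Main-theme pitch sequences, one entry per beat.
THEMES: dict[str, list[int]] = {
    # Beethoven, "Für Elise" (A section)
    "FE": [
        76, 75, 76, 75, 76, 71, 74, 72, 69,
        60, 64, 69, 71,
        64, 68, 71, 72,
        64, 76, 75, 76, 75, 76, 71, 74, 72, 69,
        60, 64, 69, 71,
        64, 72, 71, 69,
    ],
    # Mozart, "Eine Kleine Nachtmusik" (first movement opening, adapted)
    "EKN": [
        67, 62, 67, 62, 67, 62, 67, 71, 74,
        72, 69, 72, 69, 72, 69, 66, 69, 62,
        67, 67, 71, 69, 67, 67, 66, 66, 71, 74,
        67, 67, 71, 69, 67, 67, 66, 66, 71, 74,
        66, 67, 69, 69, 67, 66, 64, 64, 66, 67,
        66, 64, 62,
    ],
    # Beethoven, "Ode to Joy" (Ninth Symphony excerpt)
    "OTJ": [
        64, 64, 65, 67, 67, 65, 64, 62, 60, 60, 62, 64, 64, 62, 62,
        64, 64, 65, 67, 67, 65, 64, 62, 60, 60, 62, 64, 62, 60, 60,
        62, 62, 64, 60, 62, 64, 65, 64, 60, 62, 64, 65, 64, 62, 60, 62, 55,
        64, 64, 65, 67, 67, 65, 64, 62, 60, 60, 62, 64, 62, 60, 60,
    ],
    # "Twinkle Twinkle Little Star" (traditional)
    "TT": [
        60, 60, 67, 67, 69, 69, 67,
        65, 65, 64, 64, 62, 62, 60,
        67, 67, 65, 65, 64, 64, 62,
        67, 67, 65, 65, 64, 64, 62,
        60, 60, 67, 67, 69, 69, 67,
        65, 65, 64, 64, 62, 62, 60,
    ],
}

MELODY_NAMES = tuple(THEMES)


def fixture_melody(
    name: str,
    n_beats: int = 720,
    beat_frequency_hz: float = DEFAULT_BEAT_HZ,
) -> NoteSequence:
    """Return a built-in melody tiled/truncated to ``n_beats`` notes.

    The default of 720 beats at 6 Hz yields a two-minute stimulus.
    """
    if name not in THEMES:
        raise KeyError(f"unknown melody {name!r}; choose from {MELODY_NAMES}")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    theme = THEMES[name]
    reps = -(-n_beats // len(theme))
    pitches = (theme * reps)[:n_beats]
    notes = [Note(pitch=p, onset_beat=i, duration_beats=1.0) for i, p in enumerate(pitches)]
    return NoteSequence(notes=notes, beat_frequency_hz=beat_frequency_hz, name=name)
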