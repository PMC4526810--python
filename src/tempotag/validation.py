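"""Calibration and recovery studies run against the synthetic generator.

These routines exercise the full pipeline on simulated experiments with known
ground truth: false-inclusion calibration of the beat-responsive-channel
criterion, amplitude/phase parameter recovery, type-I error and power of the
population-level test, and end-to-end replication of the experiment structure
(direction-correct population significance plus subject-average
classification).  They are used by the test suite and by the reproduction
script; every function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .beat_response import average_beat_response, beat_responsive_channels, channel_spectrum
from .io import PipelineConfig, analyze_trials, classify_pairs
from .melodies import fixture_melody
from .stats import run_ladder
from .stimuli import (
    EquivalenceReport,
    ScrambleSpec,
    compute_envelope,
    scramble_notes,
    segmented_spectrum,
    spectra_equivalent,
    synthesize_audio,
)
from .synthetic import SyntheticConfig, simulate_experiment, simulate_recording

__all__ = [
    "stimulus_segment_count",
    "scramble_conservation_rate",
    "envelope_equivalence",
    "channel_false_inclusion_rate",
    "parameter_recovery",
    "ladder_rejection_rate",
    "end_to_end_replicate",
    "cv_accuracy_vs_effect",
]


def stimulus_segment_count(
    melody: str = "FE", n_beats: int = 720, sample_rate_hz: float = 8000.0
) -> int:
    """Number of 1-s analysis segments of a full two-minute stimulus envelope."""
    seq = fixture_melody(melody, n_beats)
    wave = synthesize_audio(seq, sample_rate_hz=sample_rate_hz)
    env = compute_envelope(wave, sample_rate_hz)
    return segmented_spectrum(env.samples, sample_rate_hz, 1.0).n_segments


def scramble_conservation_rate(n_seeds: int = 20, n_beats: int = 720) -> float:
    """Fraction of (melody, seed) scrambles conserving count, pitch multiset,
    duration and beat frequency; 1.0 when scrambling is lossless."""
    from .melodies import MELODY_NAMES

    ok = total = 0
    for name in MELODY_NAMES:
        seq = fixture_melody(name, n_beats)
        for seed in range(n_seeds):
            out = scramble_notes(seq, ScrambleSpec(seed=seed))
            total += 1
            ok += (
                len(out) == len(seq)
                and sorted(out.pitches) == sorted(seq.pitches)
                and out.duration_s == seq.duration_s
                and out.beat_frequency_hz == seq.beat_frequency_hz
            )
    return ok / total


def envelope_equivalence(
    melody: str = "OTJ",
    seed: int = 0,
    n_beats: int = 720,
    sample_rate_hz: float = 8000.0,
    test_freqs_hz=(6.0, 12.0, 18.0),
) -> EquivalenceReport:
    """Compare the envelope spectra of a tune and its scrambled version.

    Both are synthesized identically; scrambling should leave the amplitudes at
    the beat frequency and its harmonics statistically indistinguishable.
    """
    seq = fixture_melody(melody, n_beats)
    scr = scramble_notes(seq, ScrambleSpec(seed=seed))

    def env_spectrum(s):
        wave = synthesize_audio(s, sample_rate_hz=sample_rate_hz)
        env = compute_envelope(wave, sample_rate_hz)
        return segmented_spectrum(env.samples, sample_rate_hz, 1.0)

    return spectra_equivalent(env_spectrum(seq), env_spectrum(scr), test_freqs_hz)


def channel_false_inclusion_rate(
    n_replicates: int = 1000,
    seed: int = 0,
    duration_s: float = 120.0,
    sample_rate_hz: float = 250.0,
) -> float:
    """Per-channel false-inclusion rate of the 2-SD criterion under pure noise.

    Recordings contain only the pink background (no beat component); the rate
    is pooled over all channels and replicates.
    """
    base = SyntheticConfig(base_amplitude=0.0, trial_cv=0.0,
                           duration_s=duration_s, sample_rate_hz=sample_rate_hz)
    included = total = 0
    for rep in range(n_replicates):
        rec, _ = simulate_recording(base.with_(seed=seed + rep), "original")
        sel = beat_responsive_channels(channel_spectrum(rec))
        included += len(sel)
        total += rec.n_channels
    return included / total


def parameter_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    duration_s: float = 120.0,
    sample_rate_hz: float = 250.0,
) -> tuple[float, float]:
    """Bias of the recovered beat amplitude and phase at the default SNR.

    Each replicate simulates one recording with the generator defaults,
    selects its beat-responsive channels, and summarizes them with the
    coherent (complex-mean) amplitude estimator, whose bias is not limited by
    the per-segment SNR.  Returns ``(mean relative amplitude error, mean
    circular phase error in radians)`` against the known ground truth.
    """
    base = SyntheticConfig(duration_s=duration_s, sample_rate_hz=sample_rate_hz)
    amp_errors, phase_errors = [], []
    for rep in range(n_replicates):
        cfg = base.with_(seed=seed + rep)
        rec, gt = simulate_recording(cfg, "original")
        sel = beat_responsive_channels(channel_spectrum(rec))
        if not sel:
            sel = list(rec.channel_labels)
        s = average_beat_response(rec, sel, amplitude_mode="coherent")
        true_amp = np.mean([gt.channel_amplitude[c] for c in sel])
        amp_errors.append(s.mean_amplitude / true_amp - 1.0)
        d = s.mean_phase - gt.phase_rad
        phase_errors.append((d + np.pi) % (2 * np.pi) - np.pi)
    return float(np.mean(amp_errors)), float(np.mean(phase_errors))


def ladder_rejection_rate(
    n_replicates: int,
    seed: int = 0,
    effect_multiplier: float = 1.0,
    duration_s: float = 10.0,
    sample_rate_hz: float = 250.0,
    paradigm: str = "comprehension",
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated experiments with population p below ``alpha``.

    With ``effect_multiplier=1`` this estimates the type-I error of the
    population-level one-tailed test; with the default generator effect it
    estimates power.
    """
    pc = PipelineConfig()
    rejections = 0
    for rep in range(n_replicates):
        cfg = SyntheticConfig(seed=seed + rep, effect_multiplier=effect_multiplier,
                              duration_s=duration_s, sample_rate_hz=sample_rate_hz)
        sims = simulate_experiment(cfg, paradigm)
        pairs = analyze_trials(sims, pc, compute_channel_amplitudes=False)
        ladder = run_ladder(pairs, paradigm)
        rejections += ladder.population_p < alpha
    return rejections / n_replicates


def end_to_end_replicate(
    seed: int,
    paradigm: str,
    synth_config: SyntheticConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> dict:
    """One full pipeline replicate: ladder plus classification outcomes."""
    cfg = (synth_config or SyntheticConfig()).with_(seed=seed)
    pc = pipeline_config or PipelineConfig(selection_iterations=20)
    sims = simulate_experiment(cfg, paradigm)
    pairs = analyze_trials(sims, pc)
    ladder = run_ladder(pairs, paradigm)
    classification = classify_pairs(pairs, paradigm, pc)
    direction_ok = (
        ladder.population_mean_diff > 0
        if paradigm == "comprehension"
        else ladder.population_mean_diff < 0
    )
    return {
        "population_p": ladder.population_p,
        "direction_ok": bool(direction_ok),
        "significant": bool(ladder.population_p < 0.05 and direction_ok),
        "trial_cv_accuracy": classification["trial_cv_mean_accuracy"],
        "subject_average_accuracy": classification["subject_average_accuracy"],
        "selected_channels": classification["selected_channels"],
    }


def cv_accuracy_vs_effect(
    effects=(1.0, 1.1, 1.2, 1.4),
    n_replicates: int = 20,
    seed: int = 0,
    duration_s: float = 15.0,
    sample_rate_hz: float = 250.0,
    channels=("Fz", "F6"),
) -> dict[float, float]:
    """Mean cross-validated accuracy at a fixed channel pair per effect size.

    Uses the two highest-gain channels of the default topography so that the
    monotonicity of accuracy in the condition effect is probed without the
    extra variance of channel selection.
    """
    from .classify import build_difference_dataset, cross_validate

    pc = PipelineConfig()
    out: dict[float, float] = {}
    for effect in effects:
        accs = []
        for rep in range(n_replicates):
            cfg = SyntheticConfig(seed=seed + rep, effect_multiplier=effect,
                                  duration_s=duration_s,
                                  sample_rate_hz=sample_rate_hz)
            sims = simulate_experiment(cfg, "comprehension")
            pairs = analyze_trials(sims, pc)
            ds = build_difference_dataset(pairs, "comprehension")
            res = cross_validate(ds.columns(list(channels)), ds.y, folds=10,
                                 iterations=50, seed=seed + rep,
                                 pair_ids=ds.pair_ids)
            accs.append(res.mean_accuracy)
        out[effect] = float(np.mean(accs))
    return out
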