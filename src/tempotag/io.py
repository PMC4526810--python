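"""File formats, pipeline configuration, and the end-to-end experiment runner.

EEG recordings are read from EDF (via :mod:`mne`) or from a delimited matrix
(CSV/TSV with a header row of channel labels and an optional leading time
column); recordings are written as CSV.  The experiment runner ties the stages
together: artifact screening -> per-channel spectra -> beat-responsive channel
selection -> beat-response summaries -> the three-level statistical ladder ->
difference-feature LDA classification, and writes a reproducible report
bundle (JSON/CSV plus a provenance log with seeds and a config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beat_response import (
    CHANNELS_10_10,
    EEGRecording,
    average_beat_response,
    beat_responsive_channels,
    channel_spectrum,
    per_channel_beat_amplitudes,
    screen_artifacts,
)
from .classify import build_difference_dataset, cross_validate, evaluate_on_subject_averages, forward_select, lda_fit
from .errors import FormatError, InvalidInputError
from .stats import TrialPair, run_ladder
from .synthetic import CONDITIONS, SimulatedTrial, SyntheticConfig, simulate_experiment

logger = logging.getLogger("tempotag")

__all__ = [
    "PipelineConfig",
    "read_eeg",
    "write_eeg",
    "analyze_recording",
    "analyze_trials",
    "run_experiment_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis settings in one serializable, hashable object."""

    beat_frequency_hz: float = 6.0
    neighbor_band_hz: tuple[float, float] = (5.0, 7.0)
    k_sd: float = 2.0
    exclusion_halfwidth_hz: float = 0.1
    segment_seconds: float = 1.0
    amplitude_mode: str = "segment_mean"
    channel_amplitude_mode: str = "coherent"
    scramble_min: int = 2
    scramble_max: int = 6
    folds: int = 10
    iterations: int = 100
    max_features: int = 2
    selection_iterations: int = 100
    seed: int = 0
    spike_k: float = 8.0
    max_flagged_fraction: float = 0.01

    def __post_init__(self) -> None:
        for name in ("beat_frequency_hz", "k_sd", "segment_seconds", "folds",
                     "iterations", "max_features", "spike_k"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["neighbor_band_hz"] = list(self.neighbor_band_hz)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise FormatError(f"config file {path} is not a mapping")
        if "neighbor_band_hz" in d:
            d["neighbor_band_hz"] = tuple(d["neighbor_band_hz"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# EEG file I/O
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"V": 1.0, "v": 1.0, "uV": 1e-6, "µV": 1e-6, "mV": 1e-3}


def read_eeg(
    path: str | Path,
    dialect: str | None = None,
    sample_rate_hz: float | None = None,
    units: str = "V",
    meta: dict | None = None,
) -> EEGRecording:
    """Read a recording from EDF or a delimited matrix, normalized to volts.

    The delimited dialect expects a header row of channel labels, optionally
    preceded by a time column (auto-detected by name or by strictly increasing
    values, and used to infer the sampling rate).  ``units`` rescales delimited
    values ('uV' multiplies by 1e-6); EDF data arrive in volts from the reader.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect is None:
        dialect = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if dialect == "edf":
        return _read_edf(path, meta or {})
    scale = _UNIT_SCALE.get(units)
    if scale is None:
        raise InvalidInputError(f"unknown units {units!r}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse delimited matrix {path}: {exc}") from exc
    if df.empty or df.shape[1] < 1:
        raise FormatError(f"empty table in {path}")
    first = df.columns[0]
    has_time = first.strip().lower() in ("time", "time_s", "t") or (
        df[first].is_monotonic_increasing and first not in CHANNELS_10_10
    )
    if has_time:
        time = df[first].to_numpy(dtype=float)
        if sample_rate_hz is None:
            dt = np.median(np.diff(time))
            if dt <= 0:
                raise FormatError(f"non-increasing time column in {path}")
            sample_rate_hz = 1.0 / dt
        df = df.drop(columns=[first])
    if sample_rate_hz is None:
        raise InvalidInputError("sample_rate_hz required for a matrix without a time column")
    labels = tuple(df.columns)
    unknown = [c for c in labels if c not in CHANNELS_10_10]
    if unknown:
        warnings.warn(f"labels not in the 10/10 montage set: {unknown}")
    data = df.to_numpy(dtype=float).T * scale
    return EEGRecording(data=data, sample_rate_hz=float(sample_rate_hz),
                        channel_labels=labels, meta=meta or {})


def _read_edf(path: Path, meta: dict) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        size = path.stat().st_size
        raise FormatError(
            f"corrupt or truncated EDF {path} (file size {size} bytes): {exc}"
        ) from exc
    return EEGRecording(
        data=raw.get_data(),
        sample_rate_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        meta=meta,
    )


def write_eeg(rec: EEGRecording, path: str | Path, units: str = "V") -> None:
    """Write a recording as CSV: a time column plus one column per channel."""
    scale = _UNIT_SCALE.get(units)
    if scale is None:
        raise InvalidInputError(f"unknown units {units!r}")
    time = np.arange(rec.n_samples) / rec.sample_rate_hz
    df = pd.DataFrame(rec.data.T / scale, columns=list(rec.channel_labels))
    df.insert(0, "time_s", time)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-recording analysis and the experiment pipeline
# ---------------------------------------------------------------------------

@dataclass
class RecordingAnalysis:
    """All beat-response quantities extracted from one recording."""

    summary: "object"
    channel_amplitudes: dict[str, float]
    responsive_channels: list[str]
    artifact_verdict: str


def analyze_recording(
    rec: EEGRecording, config: PipelineConfig, compute_channel_amplitudes: bool = True
) -> RecordingAnalysis:
    """Screen artifacts, select beat-responsive channels, and summarize.

    When no channel passes the responsiveness criterion the summary falls back
    to all channels and the condition is recorded in the summary metadata (the
    trial can then be discarded downstream, mirroring a non-responsive trial).
    """
    report = screen_artifacts(rec, config.spike_k, config.max_flagged_fraction)
    spec = channel_spectrum(rec)
    responsive = beat_responsive_channels(
        spec,
        f_beat_hz=config.beat_frequency_hz,
        band_hz=config.neighbor_band_hz,
        k_sd=config.k_sd,
        exclusion_halfwidth_hz=config.exclusion_halfwidth_hz,
    )
    channels = responsive if responsive else list(rec.channel_labels)
    summary = average_beat_response(
        rec, channels,
        f_beat_hz=config.beat_frequency_hz,
        segment_seconds=config.segment_seconds,
        amplitude_mode=config.amplitude_mode,
    )
    summary.meta["beat_responsive"] = bool(responsive)
    amps: dict[str, float] = {}
    if compute_channel_amplitudes:
        # classification features: full-recording beat-bin amplitude per
        # channel (the coherent estimator over segments equals the full-length
        # spectral amplitude at an exact bin)
        amps = per_channel_beat_amplitudes(
            rec,
            f_beat_hz=config.beat_frequency_hz,
            segment_seconds=config.segment_seconds,
            amplitude_mode=config.channel_amplitude_mode,
        )
    return RecordingAnalysis(
        summary=summary,
        channel_amplitudes=amps,
        responsive_channels=responsive,
        artifact_verdict=report.verdict,
    )


def analyze_trials(
    trials: Sequence[SimulatedTrial],
    config: PipelineConfig,
    compute_channel_amplitudes: bool = True,
) -> list[TrialPair]:
    """Run the per-recording analysis over paired trials, yielding TrialPairs.

    Within a trial the two recordings are summarized over a COMMON channel
    set: the union of the two recordings' beat-responsive channels.  Averaging
    different subsets per condition would make the paired difference reflect
    subset composition rather than the condition, and channels selected by an
    upward noise excursion would bias the difference systematically.
    """
    pairs = []
    for tr in trials:
        ana_a = analyze_recording(tr.recording_a, config, compute_channel_amplitudes)
        ana_b = analyze_recording(tr.recording_b, config, compute_channel_amplitudes)
        union = [c for c in tr.recording_a.channel_labels
                 if c in set(ana_a.responsive_channels) | set(ana_b.responsive_channels)]
        if union:
            for rec, ana in ((tr.recording_a, ana_a), (tr.recording_b, ana_b)):
                responsive = bool(ana.responsive_channels)
                ana.summary = average_beat_response(
                    rec, union,
                    f_beat_hz=config.beat_frequency_hz,
                    segment_seconds=config.segment_seconds,
                    amplitude_mode=config.amplitude_mode,
                )
                ana.summary.meta = dict(rec.meta)
                ana.summary.meta["beat_responsive"] = responsive
        pairs.append(
            TrialPair(
                subject=tr.subject,
                trial=tr.trial,
                paradigm=tr.paradigm,
                summary_a=ana_a.summary,
                summary_b=ana_b.summary,
                channel_amplitudes_a=ana_a.channel_amplitudes or None,
                channel_amplitudes_b=ana_b.channel_amplitudes or None,
            )
        )
    return pairs


def classify_pairs(pairs: Sequence[TrialPair], paradigm: str, config: PipelineConfig) -> dict:
    """Forward-select channels, cross-validate on trials, test subject averages."""
    trial_set = build_difference_dataset(pairs, paradigm, level="trial")
    subject_set = build_difference_dataset(pairs, paradigm, level="subject_average")
    selected = forward_select(
        trial_set.X, trial_set.y,
        max_features=config.max_features,
        folds=config.folds,
        iterations=config.selection_iterations,
        seed=config.seed,
        pair_ids=trial_set.pair_ids,
        channel_labels=trial_set.channel_labels,
    )
    cv = cross_validate(
        trial_set.columns(selected), trial_set.y,
        folds=config.folds, iterations=config.iterations,
        seed=config.seed, pair_ids=trial_set.pair_ids,
    )
    model = lda_fit(trial_set.columns(selected), trial_set.y, channel_labels=selected)
    subject_accuracy = evaluate_on_subject_averages(model, subject_set)
    return {
        "selected_channels": list(selected),
        "trial_cv_mean_accuracy": cv.mean_accuracy,
        "subject_average_accuracy": subject_accuracy,
        "folds": cv.folds,
        "iterations": cv.iterations,
        "seed": config.seed,
        "lda_weights": [float(w) for w in model.weights],
        "lda_bias": model.bias,
    }


def _load_trials_from_dir(input_dir: Path, paradigm: str, config: PipelineConfig):
    """Pair recordings named ``sub<S>_trial<T>_<condition>.csv`` in a directory."""
    cond_a, cond_b = CONDITIONS[paradigm]
    files: dict[tuple[int, int], dict[str, Path]] = {}
    for path in sorted(input_dir.glob("*.csv")) + sorted(input_dir.glob("*.edf")):
        parts = path.stem.split("_")
        if len(parts) != 3 or not parts[0].startswith("sub") or not parts[1].startswith("trial"):
            warnings.warn(f"skipping unrecognized file name {path.name}")
            continue
        key = (int(parts[0][3:]), int(parts[1][5:]))
        files.setdefault(key, {})[parts[2]] = path
    trials, skipped = [], []
    for (subject, trial), conds in sorted(files.items()):
        if cond_a not in conds or cond_b not in conds:
            skipped.append({"subject": subject, "trial": trial,
                            "present": sorted(conds)})
            warnings.warn(f"unpaired trial sub{subject}_trial{trial}: skipped")
            continue
        rec_a = read_eeg(conds[cond_a], meta={"subject": subject, "trial": trial,
                                              "condition": cond_a})
        rec_b = read_eeg(conds[cond_b], meta={"subject": subject, "trial": trial,
                                              "condition": cond_b})
        trials.append(SimulatedTrial(subject=subject, trial=trial, paradigm=paradigm,
                                     recording_a=rec_a, recording_b=rec_b,
                                     truth_a=None, truth_b=None,
                                     presentation_order=(cond_a, cond_b)))
    return trials, skipped


def run_experiment_pipeline(
    config: PipelineConfig,
    paradigm: str,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    synth_config: SyntheticConfig | None = None,
) -> dict:
    """Run analysis -> ladder -> classification and write a report bundle.

    Input is either a directory of paired recordings or a synthetic-experiment
    configuration.  The bundle contains per-recording summaries (CSV), ladder
    and classification results (JSON), and a provenance log sufficient to
    reproduce the run (seeds, config hash, package version).
    """
    if (input_dir is None) == (synth_config is None):
        raise InvalidInputError("provide exactly one of input_dir or synth_config")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    skipped: list[dict] = []
    if synth_config is not None:
        trials = simulate_experiment(synth_config, paradigm)
    else:
        trials, skipped = _load_trials_from_dir(Path(input_dir), paradigm, config)
    if not trials:
        raise InvalidInputError("no paired trials to analyze")

    pairs = analyze_trials(trials, config)
    # a trial with no beat-responsive channels in either recording is discarded
    usable, discarded = [], []
    for p in pairs:
        if p.summary_a.meta.get("beat_responsive", True) and p.summary_b.meta.get(
            "beat_responsive", True
        ):
            usable.append(p)
        else:
            discarded.append({"subject": p.subject, "trial": p.trial,
                              "reason": "no beat-responsive channels"})
    ladder = run_ladder(usable, paradigm)
    classification = classify_pairs(usable, paradigm, config)

    rows = []
    for p in usable:
        for cond, summary in (("A", p.summary_a), ("B", p.summary_b)):
            rows.append({
                "subject": p.subject, "trial": p.trial,
                "condition": summary.meta.get("condition", cond),
                "mean_amplitude": summary.mean_amplitude,
                "sem_amplitude": summary.sem_amplitude,
                "mean_phase": summary.mean_phase,
                "n_segments": summary.n_segments,
                "responsive_channels": ";".join(summary.responsive_channels),
            })
    pd.DataFrame(rows).to_csv(out_dir / "summaries.csv", index=False)
    (out_dir / "ladder.json").write_text(
        json.dumps(ladder.to_dict(), indent=1, sort_keys=True) + "\n")
    (out_dir / "classification.json").write_text(
        json.dumps(classification, indent=1, sort_keys=True) + "\n")
    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "paradigm": paradigm,
        "n_trials_analyzed": len(usable),
        "n_trials_discarded": len(discarded),
        "discarded": discarded,
        "skipped_unpaired": skipped,
        "synthetic": synth_config is not None,
    }
    if synth_config is not None:
        provenance["synthetic_config"] = {
            **{k: v for k, v in dataclasses.asdict(synth_config).items()
               if k != "channel_topography"},
            "channel_topography": synth_config.channel_topography,
            "note": "all generator magnitudes are assumptions, not measured values",
        }
        truth = [dataclasses.asdict(t.truth_a) | {"which": "A"} for t in trials] + [
            dataclasses.asdict(t.truth_b) | {"which": "B"} for t in trials
        ]
        (out_dir / "ground_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True) + "\n")
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True) + "\n")
    logger.info("pipeline bundle written to %s (%d trials)", out_dir, len(usable))
    return {"ladder": ladder, "classification": classification,
            "n_trials": len(usable), "out_dir": str(out_dir)}
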