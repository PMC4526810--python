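"""Three-level difference statistics for paired beat-response recordings.

Each trial yields two recordings (original vs scrambled tune, or attended vs
ignored music).  Differences in beat-response amplitude are tested at three
levels: per trial (paired t-test across the 1-s analysis segments), per
subject (one-tailed one-sample t-test of the subject's trial differences
against zero), and across the population (one-tailed one-sample t-test of the
per-subject mean differences).  The expected direction is positive for the
comprehension paradigm (scrambled - original) and negative for attention
(ignored - attended).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .beat_response import BeatResponseSummary
from .errors import InvalidInputError

__all__ = ["TrialPair", "LadderResult", "trial_test", "one_tailed_one_sample_test", "run_ladder"]

#: One-sided alternative for the subject/population tests, per paradigm.
PARADIGM_ALTERNATIVE = {"comprehension": "greater", "attention": "less"}


@dataclass
class TrialPair:
    """The two analyzed recordings of one trial.

    ``summary_a`` is the weaker-expected condition (original tune / attended
    music as baseline A), ``summary_b`` the paired condition (scrambled /
    ignored); the analysis convention is difference = B - A.  Optional
    per-channel beat amplitudes feed the classifier.
    """

    subject: int
    trial: int
    paradigm: str
    summary_a: BeatResponseSummary
    summary_b: BeatResponseSummary
    channel_amplitudes_a: dict[str, float] | None = None
    channel_amplitudes_b: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGM_ALTERNATIVE:
            raise InvalidInputError(f"unknown paradigm {self.paradigm!r}")
        if self.summary_a.n_segments != self.summary_b.n_segments:
            raise InvalidInputError("both summaries must share the segment count")

    @property
    def difference(self) -> float:
        """Mean amplitude difference, condition B minus condition A."""
        return self.summary_b.mean_amplitude - self.summary_a.mean_amplitude


@dataclass
class LadderResult:
    """Trial, subject and population level outcomes of one paradigm."""

    paradigm: str
    direction: str  # expected sign of B - A: "greater" or "less"
    trial_results: list[dict] = field(default_factory=list)
    subject_results: dict[int, dict] = field(default_factory=dict)
    population_mean_diff: float = float("nan")
    population_sem: float = float("nan")
    population_t: float = float("nan")
    population_p: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "paradigm": self.paradigm,
            "direction": self.direction,
            "trial_results": self.trial_results,
            "subject_results": {str(k): v for k, v in self.subject_results.items()},
            "population_mean_diff": self.population_mean_diff,
            "population_sem": self.population_sem,
            "population_t": self.population_t,
            "population_p": self.population_p,
        }


def trial_test(pair: TrialPair) -> tuple[float, float]:
    """Paired two-sample t-test on the per-segment amplitudes of one trial.

    Segments are paired by index across the trial's two recordings; returns the
    classical paired t statistic (mean of A - B over its standard error) and
    the two-tailed p-value.  Zero-variance differences yield ``(nan, nan)``
    with a warning rather than a silent p of 0 or 1.
    """
    a = pair.summary_a.per_segment_amplitudes
    b = pair.summary_b.per_segment_amplitudes
    if a.size != b.size:
        raise InvalidInputError("per-segment amplitude arrays differ in length")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:  # identical recordings: no difference at all
            return 0.0, 1.0
        warnings.warn("degenerate trial test: zero-variance paired differences")
        return float("nan"), float("nan")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def one_tailed_one_sample_test(
    values: Sequence[float], alternative: str
) -> tuple[float, float]:
    """One-sample t-test of the mean against zero with a one-sided alternative.

    Used per subject (that subject's trial differences) and at the population
    level (per-subject mean differences).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("need at least two values")
    if alternative not in ("greater", "less"):
        raise InvalidInputError("alternative must be 'greater' or 'less'")
    if values.std(ddof=1) == 0:
        warnings.warn("degenerate one-sample test: zero variance")
        return float("nan"), float("nan")
    res = sps.ttest_1samp(values, 0.0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def run_ladder(pairs: Sequence[TrialPair], paradigm: str) -> LadderResult:
    """Run the full three-level ladder over the trials of one paradigm.

    Differences are B - A per trial; the one-sided alternative is "greater"
    for comprehension and "less" for attention.  Subjects need at least two
    usable trials (a discarded trial may leave three).
    """
    if paradigm not in PARADIGM_ALTERNATIVE:
        raise InvalidInputError(f"unknown paradigm {paradigm!r}")
    if not pairs:
        raise InvalidInputError("no trial pairs supplied")
    if any(p.paradigm != paradigm for p in pairs):
        raise InvalidInputError("mixed paradigms in one ladder call")
    alternative = PARADIGM_ALTERNATIVE[paradigm]
    result = LadderResult(paradigm=paradigm, direction=alternative)

    by_subject: dict[int, list[float]] = {}
    for pair in pairs:
        t, p = trial_test(pair)
        result.trial_results.append(
            {"subject": pair.subject, "trial": pair.trial,
             "difference": pair.difference, "t": t, "p": p}
        )
        by_subject.setdefault(pair.subject, []).append(pair.difference)

    subject_means = []
    for subject, diffs in sorted(by_subject.items()):
        mean = float(np.mean(diffs))
        subject_means.append(mean)
        if len(diffs) >= 2:
            t, p = one_tailed_one_sample_test(diffs, alternative)
        else:
            t, p = float("nan"), float("nan")
        result.subject_results[subject] = {
            "mean_diff": mean, "n_trials": len(diffs), "t": t, "p": p,
        }

    subject_means = np.asarray(subject_means)
    result.population_mean_diff = float(subject_means.mean())
    if subject_means.size >= 2:
        result.population_sem = float(
            subject_means.std(ddof=1) / np.sqrt(subject_means.size)
        )
        result.population_t, result.population_p = one_tailed_one_sample_test(
            subject_means, alternative
        )
    return result
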