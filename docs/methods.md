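# Methods

`tempotag` implements an analysis of the cortical steady-state response to
the beat of music, together with the synthetic data needed to validate every
stage of that analysis without access to human recordings.

## The experimental design being modelled

Subjects listen to single-line melodies with exactly one note per beat at a
beat frequency f_b = 6 Hz, for two minutes per presentation. Because the beat
dominates the stimulus envelope, the EEG contains a steady-state response at
exactly 6 Hz that can be read out at a single spectral bin (frequency
tagging). Two paired paradigms are analysed:

- **comprehension** — each trial pairs a familiar tune with a *scrambled*
  version of the same tune (segments of 2–6 notes permuted at random); the
  beat response is expected to be *larger* for the scrambled piece.
- **attention** — each trial pairs an attended presentation of a piece with
  an ignored one (the subject reads text instead); the response is expected
  to be *larger* when attending.

Scrambling is designed to destroy the recognizable melody while conserving
low-level structure. The package verifies this: note count, pitch multiset,
total duration and beat frequency are conserved exactly, and the amplitude
spectra of the Hilbert envelopes of a tune and its scrambled version agree at
the beat frequency and its harmonics within the segment-to-segment noise
(`spectra_equivalent`, pooled-SEM criterion with k = 2, chosen for ~95%
pointwise coverage of a "within the noise" judgement).

### Stimulus fixtures and synthesis

The four melodies (FE, EKN, OTJ, TT) are encoded from their public-domain
main themes, one pitch per beat, and tiled to 720 beats (two minutes at
6 Hz); the exact editions used in the original recordings are not available,
so these are the package's own reductions. The audio renderer produces a
harmonic complex per note (fundamental plus three harmonics with 1/k
roll-off, 10-ms linear attack, exponential decay with time constant of a
third of the 1/6-s beat slot). The timbre is a free choice; what matters for
the analysis is a strong 6-Hz envelope component, which this voice provides.

The literal per-adjacent-pair pitch-change statistic
(r = 2^(d/12) − 1 for d semitones) is implemented as defined; on the
fixtures the per-melody means range from 0.09 (TT) to 0.27 (FE), averaging
0.16, with per-pair SDs of 0.11–0.23. Note that a per-pair SD is necessarily
of the same order as the mean when repeated notes (r = 0) coexist with
leaps, so summaries of this statistic that show SDs far below the mean are
likely dispersions across pieces rather than across note pairs; the package
reports the per-pair definition and leaves the interpretation to the user.

## Beat-response extraction

1. **Artifact screening.** Samples deviating from the channel median by more
   than `spike_k` (default 8) channel MADs are flagged; a recording whose
   flagged fraction exceeds 1% on any channel receives a "repeat" verdict.
   This automates what is usually a visual screen; thresholds are
   configurable.
2. **Channel criterion.** For each channel the full-length spectrum is
   computed (rectangular window; amplitude normalized so an exact-bin cosine
   of amplitude A gives bin amplitude A). A channel is *beat-responsive* iff
   its 6-Hz amplitude exceeds the mean of the 5–7-Hz neighbor bins
   (excluding bins within 0.1 Hz of the beat) by more than two SDs of those
   neighbor amplitudes. The SD is taken across neighbor bins of the
   full-length spectrum.
3. **Summary.** The responsive channels are averaged sample-wise; the
   average is cut into 1-s segments (120 for a full recording; 6 Hz is an
   exact bin of a 1-s rectangular window, so no taper is needed); the complex
   coefficient at 6 Hz is extracted per segment. The default amplitude is
   the mean of per-segment moduli with its SEM across segments — the scalar
   per-segment series the t-tests below require. The modulus of the complex
   mean (`amplitude_mode="coherent"`) is exposed as the low-bias alternative:
   per-segment moduli follow a Rice distribution whose mean exceeds the true
   amplitude by an amount set by the per-segment SNR (roughly +30–40% at the
   default synthetic SNR), and that bias does not shrink with recording
   length, whereas the coherent estimator's bias does. Parameter-recovery
   checks therefore use the coherent estimator. The phase is the argument of
   the complex mean (cosine convention, positive = lag, reported in
   (−π, π]); phase φ at frequency f corresponds to a latency φ/(2πf), e.g.
   3.5 rad at 6 Hz ≈ 93 ms.
4. **Pairing.** Within a trial the two recordings are summarized over a
   *common* channel set (the union of their responsive sets). Averaging
   different subsets per condition would let the paired difference reflect
   subset composition, and channels admitted by an upward noise excursion
   would bias the difference systematically — an effect that is negligible
   at full two-minute recordings but dominates scaled-down ones.
5. **Distributional check.** A one-sample Kolmogorov–Smirnov test on the
   standardized real and imaginary parts of the per-segment coefficients
   validates the normality assumption behind the t statistics.
   Standardization is required: raw coefficients with signal present cannot
   be standard normal.

## Three-level statistics

Per-trial differences are defined as (scrambled − original) for comprehension
(expected > 0) and (ignored − attended) for attention (expected < 0).

- **Trial level**: paired two-sample t-test across the per-segment
  amplitudes of the trial's two recordings (segments paired by index — the
  only pairing the data admit).
- **Subject level**: one-tailed one-sample t-test of the subject's trial
  differences against zero (≥ 2 trials required; a discarded non-responsive
  trial may leave three).
- **Population level**: the same one-tailed test on the per-subject mean
  differences.

Zero-variance inputs yield an explicitly flagged degenerate result (NaN with
a warning), never a silent p of 0; identical recordings give t = 0, p = 1.
No multiple-testing correction is applied across trials or subjects,
matching how such results are conventionally reported at these levels.

## Classification

Per-channel beat-amplitude differences between a trial's two recordings form
category +1; their sign-inverted copies form category −1. The construction
is antisymmetric, so the optimal boundary passes through the origin and the
fitted bias is zero to machine precision. The classifier is a
pooled-covariance linear discriminant (w = Σ⁻¹(μ₊ − μ₋), boundary midway
between projected class means, diagonal ridge of `eps·trace/dim` for
near-singular pooled covariance). Channels are chosen by greedy forward
selection on mean cross-validated accuracy (ties broken by channel order;
`max_features` defaults to 2, matching the observation that two frontal
channels suffice). Cross-validation is 100 iterations of random 10-fold
partitions; a difference vector and its mirror image are always assigned to
the same fold, since either member determines the other and splitting them
would leak the training set into the test set. The iteration accuracy is the
pooled correct fraction over held-out folds. A classifier trained on
trial-level rows is additionally evaluated, with its weights frozen, on the
per-subject average difference vectors.

The selection method is plain greedy forward selection; no evolutionary
search is involved. The selection criterion (cross-validated LDA accuracy)
is the package's choice; it matches how the results are ultimately scored.

## Synthetic EEG generator

Each simulated channel carries

    x_ch(t) = A · g_ch · c · γ · cos(2π f_b t + φ) + n_ch(t)

with base amplitude A = 1 µV at the gain-1 channel, a frontal-dominant
topography g_ch (Fz = 1.00, F6 = 0.95 down to Oz = 0.15 across the 13-channel
10/10 montage), condition gain c (`effect_multiplier`, default 1.25, applied
to the scrambled and the attended condition), a per-trial lognormal gain γ
(CV 0.2, shared by both recordings of a trial — slow drifts of overall
response strength), response phase φ = 3.5 rad, and independent per-channel
pink noise n_ch: 1/f^α with α = 1, band-limited to 0.1–100 Hz, broadband RMS
10 µV, generated by spectral shaping of white noise with an analytic (not
empirical) RMS normalization. A correlated-noise option mixes a shared pink
source through the topography for robustness checks. All randomness derives
from `(seed, subject, trial, condition)` seed sequences, so recordings are
bit-reproducible and the two members of a trial share their trial gain.

The amplitude and noise scales were fixed analytically from the recording
conditions the generator emulates: at these values the full-recording 6-Hz
bin of a frontal channel exceeds its neighbor bins roughly fivefold, the
lowest-gain occipital channel sits near the detection threshold (so the
criterion typically admits 11–12 of 13 channels), and at effect 1.25 roughly
half of single trials reach p < 0.05 — the qualitative regime the design
targets. The effect multiplier is a configuration knob, not a measured
value.

What the generator does **not** emulate: volume-conduction correlations (by
default), eye-blink/EMG artifacts beyond optional spikes, non-stationary
baselines, and any hemispheric asymmetry. Passing tests therefore
demonstrate the pipeline's correctness and calibration under a known model,
not the physiological effect itself.

## Problem sizes and numerical choices

Monte-Carlo studies use sizes chosen to keep the whole validation suite
runnable on a laptop CPU while leaving estimator noise well below the
margins being asserted: the channel-criterion calibration uses 1000
pure-noise replicates of full two-minute recordings at 250 samples/s (the
noise band ends at 100 Hz, so 250 samples/s loses nothing); parameter
recovery uses 100 two-minute replicates; type-I calibration uses 500
experiments with 10-s recordings and power 200 experiments with 20-s
recordings; the end-to-end replication runs full-scale (8 subjects × 4
trials × 2 conditions, 120 s at 1000 samples/s) with 8 replicates per
paradigm. Short recordings change one thing qualitatively: channel
detection becomes marginal (full-length bin noise scales as 1/√T), which is
why recovery and calibration of the *selection* stage are run at full
duration while the ladder calibration, which averages over channels anyway,
uses short recordings.

Numerical conventions: rectangular windows throughout (6 Hz is an exact bin
of every window used); single-sided 2/N spectral normalization (DC and
Nyquist unhalved); phases wrapped to (−π, π]; sample SDs with ddof = 1; SEM
= SD/√n across segments; LDA ridge 1e-10·trace/dim; forward-selection ties
broken by montage order; all fold assignments and segment-length draws from
`numpy.random.default_rng` seeded explicitly.

## Known limitations

- EDF files are read (via mne) but not written; simulated experiments are
  written as CSV matrices.
- The MusicXML support is deliberately minimal: single part, pitched quarter
  notes on the beat grid.
- The scramble partition draws segment lengths uniformly from {2,…,6}
  sequentially and permutes segments uniformly; the final segment may be
  shorter than 2 notes when the count does not divide. Other distributions
  over partitions are possible and not distinguishable from the stimulus
  description alone.
- With per-recording channel selection on very short recordings, selection
  and estimation interact (see Pairing above); analyses of sub-minute
  recordings should prefer a fixed channel set.
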