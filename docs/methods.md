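# Methods

## Signal model and synthetic generator

The generator produces phenomenological surrogates of chronic hippocampal
LFP recordings; there is no biophysical modelling.

**Background.** White Gaussian noise of SD `noise_sd` passed once
(causally) through a 2nd-order Butterworth bandpass, 1 Hz to
min(5 kHz, 0.45·fs), emulating the bandwidth of a typical recording chain.
The output SD is `noise_sd` times the filter's RMS noise-bandwidth gain
(√mean|H(f)|²), which tests evaluate analytically from the designed
response. The default sampling rate is 10 kHz, the acquisition rate the
package targets; validation runs often use 2 kHz, which preserves every
feature the detectors use (interictal spikes are 4–40 Hz events).
Band-limited *white* noise is used rather than a 1/f spectrum so that this
noise-bandwidth oracle is exact; consequences are noted under Limitations.

**Interictal spikes.** Biphasic template: a sharp negative Gaussian
transient (SD 4 ms) followed by a slower positive rebound (delay 30 ms,
SD 10 ms, 0.4 of the negative amplitude), total width ≈ 75 ms. The rebound
is placed far enough from the main lobe that the waveform's extremum stays
within one sample of the nominal spike time, so ground-truth spike times
are exactly recoverable from the noiseless signal. Spike amplitudes are
drawn uniformly from 6–12× the background SD: comfortably above the
detection threshold, as real interictal spikes are, while varying enough to
exercise the amplitude path.

**Bursts.** Within a burst, ISIs are truncated-normal (floor 1 ms) — this
directly controls the SD-of-ISI feature dimension. Three load classes
differ in spike count and ISI statistics (log10-normal draws):

| class  | count median | mean ISI median (s) | ISI SD (s) |
|--------|--------------|---------------------|------------|
| low    | 5            | 1.2                 | 0.30       |
| medium | 30           | 0.5                 | 0.12       |
| high   | 180          | 0.25                | 0.05       |

The count medians put three well-separated modes on the log₁₀-count axis
(0.7 / 1.5 / 2.3); ISI medians are slow enough that each spike is
individually resolvable at the detectors' ±25 ms matching tolerance.
Bursts are placed by a Poisson draw per (sub-session, class) with a 4 s
collision margin — larger than the 2.5 s grouping gap, so distinct
generated bursts can never merge during grouping. On a collision the onset
is re-drawn up to 100 times, then the generator errors
(`collision_policy="error"`) or drops the burst with a log entry
(`"skip"`); the scaled-session constructor `make_lfs_plan` defaults to
`"skip"` because short sub-sessions are easily crowded by ~45 s high-load
bursts.

**Session structure.** `make_lfs_plan` builds the standard
pre / stim / post1 / post2 sequence. Default pre (and post) burst rates are
low 6·10⁻³, medium 3·10⁻³, high 5·10⁻³ bursts/s, giving an expected
pre-hour high-load burst ratio of ≈ 0.2 — the burden typical of chronically
epileptic reference recordings in this model. During the stimulation
sub-session all rates are scaled by (1 − `stim_suppression`), default 0.95,
emulating near-complete suppression by 1 Hz stimulation.

**Evoked responses.** A stereotyped negative field deflection (onset 4 ms
after the pulse, peak ≈ 20 ms, small positive rebound) added after every
pulse onset, amplitude 30× the background SD (population responses dominate
the trace in these recordings). Amplitude follows
`p + (1−p)·exp(−i/τ)` over pulse index `i`, plateau `p` = 0.3 and
τ = one tenth of the stimulation span — the fast rundown within the first
sixth of the stimulation period. With two channels, the contralateral
channel receives the same waveform shifted by the propagation delay
(default 9 ms, inside the physiological 8–12 ms range). When `noise_sd = 0`
the amplitude unit falls back to 1 so noiseless sessions remain non-trivial.

**Reference corpus.** Burst feature vectors are drawn directly from the
class mixture above (not from signals). This stands in for a corpus of
classified bursts from reference animals; it is synthetic and carries its
generating labels, which the SOM's node-labelling step may use.

## Detection

The spectrogram uses 0.25 s Hann windows with 90 % overlap: sub-second
frames localize 20–80 ms events while retaining 4 Hz resolution. Each
frequency bin is min–max normalized over the whole recording (constant bins
map to 0), making the 4–40 Hz band score — the mean of the normalized bins —
scale-free; local maxima with prominence ≥ 0.25 become candidates, refined
to the nearest raw-signal extremum within half a window (frame centers are
too coarse for ISI statistics). The amplitude path thresholds |x| at
`k_mad` = 5 times the MAD-based SD equivalent (1.4826·MAD), keeping the
larger peak within the 0.1 s refractory span. The merge collapses
candidates within 50 ms, preferring the amplitude-path time; spectral-only
candidates must also pass an amplitude plausibility gate of 0.8 × the
amplitude threshold — the realization of the "spike sorting" clean-up step,
which suppresses spectral false positives in plain noise. Spikes within
(−10 ms, +100 ms) of a stimulation pulse are blanked so evoked responses
are not counted as epileptic spikes. All thresholds are configuration; none
is derivable from first principles.

## Burst classification

Grouping uses a strict `gap < 2.5 s` rule (a gap of exactly 2.5 s splits;
configurable). Runs with fewer than 3 spikes carry no feature vector (the
ISI SD needs ≥ 2 intervals) and count only toward the spike rate. ISI SD
and the reference σₓ both use the sample convention (ddof = 1): small-n
bursts dominate and the sample SD is the conservative default. The weights
w = [2, 2, 1] are applied *in the feature space* (y′ = (y − x̄)/σₓ · w), so
the SOM's Euclidean matching is automatically weight-aware; after
self-normalization the corpus has per-dimension SD exactly equal to w.

The SOM is an online Kohonen map: 10×10 hexagonal grid, Gaussian
neighborhood, learning rate 0.5 → 0.01 and radius (half the grid diagonal)
→ 0.5, both decaying linearly over 50 epochs; prototypes initialized from
random corpus samples; fully deterministic per seed. Node classes come from
the majority label of the reference vectors mapping to each node; nodes
with no mapped vectors fall back to thresholds on the back-transformed
prototype spike count (cut points 12 and 80, the approximate geometric
midpoints between the class count medians). Classification is the class of
the argmin-distance node, ties broken toward the lowest row-major node
index.

## Metrics

Sub-sessions are half-open `[start, end)` intervals; bursts spanning a
boundary are clipped so the per-sub-session ratios are exactly additive
(whether the original analysis clipped or assigned whole bursts is
unknown; clipping is the convention here). Burst duration is last spike −
first spike — the only definition consistent with summing high-load burst
durations. Suppression efficacy is (1 − stim/pre)·100 and is undefined
(session flagged) when the pre value is not positive. Session exclusion
uses a strict `pre ratio < 0.05` test. Reference-burden averaging over
mixed-length recordings is duration-weighted by default (a plain mean is
available).

## Evoked responses and latency

The smoothing filter is a 4th-order Chebyshev-I low-pass, 300 Hz cut-off,
1 dB passband ripple (a required design parameter left open by the original
description), applied forward–backward: zero phase preserves peak times and
onset alignment; the effective magnitude response is |H|², placing the
bidirectional DC gain of this even-order design at exactly −2 dB (the
ripple trough). AUC is the trapezoidal integral over the peri-pulse window;
the default mode subtracts the pre-onset baseline mean and integrates the
absolute value. For *trend* analyses (delta-AUC fits) the
baseline-subtracted *signed* mode is preferable and is what the validation
uses: rectifying noise gives E|n| > 0 over the signal-free part of the
window, a floor that biases the absolute-mode plateau upward, while the
signed integral of zero-mean noise is unbiased. Delta AUC divides by the
first defined AUC (flagged pulses — those overlapping high-load bursts —
are excluded); the trend fit is an ordinary least-squares polynomial,
default degree 3, in ascending powers of time.

Latency z-scores each snippet (making the estimate invariant to per-channel
gain and offset) and takes the first |z| ≥ 2 crossing inside (0, 50 ms]
after the pulse — a window that covers the physiological 8–12 ms range with
margin while excluding the stimulus onset. The original threshold was set
by visual inspection and is unrecoverable; 2.0 in magnitude mode is the
documented default, with a signed mode available. Per-pulse delay is the
contralateral minus ipsilateral crossing (negative values reported as-is);
sub-sessions are summarized by the median over defined delays.

## Validation problem sizes

The package validates itself on scaled-down sessions: pre/stim/post spans
of 100–300 s (vs. 1 h), sampling at 2 kHz for burden metrics (every
spectral feature the detectors use lies far below that Nyquist) and at the
full 10 kHz for latency and rundown analyses, 60–600 pulses per
stimulation span, and reference corpora of ~300 bursts. Detection
recall/precision and class-recovery rates are pooled across the 10
validation seeds, since individual scaled sessions can contain fewer than
ten events. The delta-AUC plateau check uses 600-pulse sessions because a
cubic-fit endpoint over much shorter series scatters more than the 10 %
recovery band.

## Limitations

- The background is band-limited white noise, not 1/f; detector thresholds
  are validated against a flatter noise floor than real LFP. The MAD-based
  scale and per-bin spectrogram normalization are designed to transfer, but
  passing tests here do not certify performance on real recordings.
- Burst waveforms, evoked templates, and the reference corpus are
  parametric stand-ins; the spontaneous-burst morphology of real recordings
  is not characterized quantitatively anywhere, so template parameters are
  free configuration.
- The SOM is re-trained on the synthetic reference corpus; no attempt is
  made to reproduce any previously published map's weights, only the
  mechanics (normalization, training, node labelling, nearest-node
  classification).
- Inferential statistics on animal-level data (ANOVA, correlation) are out
  of scope; the package stops at per-session metrics.
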