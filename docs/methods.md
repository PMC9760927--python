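# Methods

## Signal model

The sensing pad converts body-surface motion into an optical path length
difference (OPLD) between the two arms of a fiber interferometer, treated
throughout as a phase `φ(t)` in radians (conversion to physical length would
require the source wavelength and is out of scope). The simulator composes
`φ(t)` from:

- a breathing component: a cosine at `rr_bpm/60` Hz with amplitude
  `breath_amp_rad` (default 2.0 rad) plus harmonics at relative amplitudes
  `breath_harmonics` (default `[0.2, 0.1]` at 2× and 3× the fundamental);
- a cardiac (ballistocardiographic) component: a cosine at `hr_bpm/60` Hz
  with amplitude `cardiac_amp_rad` (default 0.5 rad, a quarter of the
  breathing amplitude — breathing is the mechanically stronger phenomenon)
  plus one harmonic at relative amplitude 0.4, so the heart-rate rule's
  harmonic-presence criterion is satisfiable by construction;
- baseline wander: one slow sinusoid (default 0.5 rad at 0.05 Hz), the
  simplest structure that exercises the 0.5 Hz high-pass floor of the
  analysis band;
- optional white Gaussian phase noise and motion-artifact transients (steps,
  or Hann-shaped bursts confined to their support).

Amplitude ordering matters: the cardiac fundamental (relative amplitude
0.25) deliberately exceeds every breathing harmonic (0.2, 0.1). When an
integer-rate cardiac fundamental falls within one spectral bin of a breathing
harmonic, the two merge into a single local maximum; with this ordering the
merged maximum sits on the cardiac bin and rate recovery stays exact. The
reverse ordering mislocates the merged peak by one per-minute unit whenever
`hr ≈ 2·rr`.

The 3×3 coupler maps phase to three detector intensities
`u_k = C_k + A_k·cos(φ + 2πk/3 + δ_k)`, `k = 1..3`, with optional additive
detector noise. The asymmetries `δ_k` are modeled as constants: no dynamics
are needed to probe the demodulator's tolerance, which is the only role they
play here. Default sampling is 250 Hz — far above all physiological
harmonics (the generator refuses `fs` below 4× the highest simulated
frequency) and small enough that a 3-minute record is ~45k samples; data
acquisition hardware rates in the tens of kS/s add nothing to the
algorithmics.

## Demodulation

Channels are equalized to zero offset and unit amplitude with
`Ĉ_k = (max+min)/2`, `Â_k = (max−min)/2` over the whole record, valid as soon
as each channel sweeps at least one full fringe and assumption-free about
fringe statistics; a percentile variant (0.5%/99.5% by default) is available
against isolated outliers. A channel whose peak-to-peak span is below 10% of
the largest channel's raises a degenerate-channel error — the pad saw no
modulation on that channel, and offset/amplitude estimates would be
meaningless. Equalization is idempotent: a second pass maps min/max of ±1
onto themselves.

The wrapped phase is the two-argument arctangent
`atan2(√3(u₂−u₃), u₂+u₃−2u₁)`; a principal-branch arctan would fold the
fringe in half and break unwrapping. For an ideal coupler the result equals
`φ − π/3` modulo 2π; the constant offset is irrelevant downstream. Samples
where numerator and denominator both vanish (singular points) hold the
previous value and log a warning. Standard unwrapping (no jump above π)
completes the recovery; at 250 Hz the per-sample phase change of
physiological signals is far below π. The asymmetries `δ_k` are not
calibrated out; their effect is tolerated and bounded by test (RMS phase
error < 0.05 rad for `|δ_k| ≤ 0.1` rad and 1% detector noise).

## Spectral analysis and rate rules

Frames are non-overlapping and minute-aligned — estimates are reported per
whole minute and no overlap scheme is assumed. Each 60 s frame is
mean-removed (otherwise drift dominates), multiplied by a periodic Hamming
window, and transformed to a one-sided magnitude spectrum with 1/60 Hz
resolution, i.e. exactly one per-minute unit per bin, so integer rates sit on
single bins and `round(f·60)` is exact for on-grid truths. Zero-padding (4×)
is available for sub-bin interpolation but off by default. Local maxima are
strict 3-point maxima; plateaus count once at their leftmost bin; ties rank
the lower frequency first.

**Distortion handling.** A minute is distorted when any 1 s window of the
first-differenced phase has an RMS above `threshold_k` (default 8) times the
record's median 1 s RMS. For a distorted minute the earliest 30 s sub-window
(whole-second aligned) containing no bad second is analyzed instead, at
halved resolution; a minute with no clean 30 s is kept as a row but marked
invalid. The earliest-clean-window placement is a stipulation — any clean
placement is equally defensible.

**RR rule.** The RR is the frequency of the global magnitude maximum in
(0.5, 2.5] Hz, times 60, rounded to an integer. The estimate is invalid when
the band maximum does not exceed 3× the median in-band magnitude — a flat
spectrum must not yield a rate.

**HR rule.** The search band starts at 1.5 Hz, or at the RR frequency plus
0.25 Hz when the RR reaches 1.5 Hz, and ends at 5.5 Hz (= 330 beats/min, the
physiological ceiling for the neonate-sized subjects targeted). Candidates
are the five largest local maxima in the band, excluding bins below 5% of
the in-band maximum (noise-floor bins would otherwise fill the candidate
list on very clean spectra). A candidate qualifies when a local maximum
exists within ±0.05 Hz of twice its frequency with magnitude between 0.05×
and 1.0× its own; among qualifying candidates the lowest frequency wins.
Three numerical choices here deserve justification:

- *Harmonic tolerance 0.05 Hz* (three bins): wide enough for leakage and for
  the ≤2-bin shift of a merged peak, narrow enough that a breathing harmonic
  does not acquire a spurious "harmonic" from an unrelated cardiac harmonic
  two frequency bins further out.
- *Upper relative-amplitude cap 1.0*: a candidate whose claimed harmonic is
  stronger than itself is not a fundamental — it is itself a harmonic of a
  lower rate. Without the cap, whenever `hr ≈ 4·rr` the breathing 2nd
  harmonic at `2·rr` claims the cardiac fundamental near `4·rr` as its
  harmonic and, being lower in frequency, wins. With the cap, exact recovery
  holds for **every** integer pair with `rr ∈ [39, 129]`,
  `hr ∈ [101, 224]`, `hr ≥ rr + 20` (verified exhaustively, 10,108 pairs).
  The cap assumes cardiac harmonics weaker than the cardiac fundamental; on
  real ballistocardiograms with dominant harmonics it should be raised via
  `BandConfig.harmonic_max_rel_amp`.
- *"Five maxima" are the top five by magnitude*, not the first five in
  frequency order; the alternative reading is noted as plausible.

RR < HR is a physiological fact, not an algorithmic constraint: a violation
is logged, never corrected, since silently swapping estimates would mask
failures.

## Agreement statistics

Differences are oriented reference − sensor. Bland–Altman summaries are
nonparametric: median, quartiles, and 2.5%/97.5% empirical quantiles as
limits of agreement (linear-interpolation quantiles, the common "type 7"
estimator). Reliability is ICC(2,1) — two-way random effects, absolute
agreement, single measurement: two fixed methods measure the same subjects
and absolute agreement is the clinically relevant question. The estimate
comes from the subjects × methods mean-squares decomposition; the 95% CI
uses the Shrout–Fleiss F-based formula. Non-positive subject variance
returns 0 with a warning rather than a negative estimate.

The paired Wilcoxon signed-rank test drops zero differences and uses
mid-ranks for ties; p-values are exact by dynamic-programming enumeration
over all sign assignments for n ≤ 20, otherwise the normal approximation
with continuity correction. Mann–Whitney U is exact by enumeration of all
group assignments for pooled n ≤ 12, otherwise asymptotic with tie
correction. Levene's test uses the Brown–Forsythe (median-centered) variant.
Spearman's ρ is the Pearson correlation of mid-ranks with a t-approximation
p-value and a Fisher-z CI with variance 1.06/(n−3).

Repeated pairs per subject (three per vital in the emulated study design)
are not independent; `agreement_report` accepts a per-subject-median mode
for the ICC and Wilcoxon test, and both usages are supported because the
original treatment is unknowable from the outside.

## Synthetic data: what it does and does not emulate

The paired-cohort generator draws a per-subject base rate uniformly from the
cohort range (RR 39–129, HR 122–202 per minute), jitters it per minute, and
adds zero-mean Gaussian sensor error (default SD 2 per-minute units). Sex
(P(female) = 10/29) and weight (uniform 1.5–4.15 kg) mirror the emulated
cohort's composition. The phase simulator produces stationary sinusoidal
physiology; real records have rate variability within a minute, non-harmonic
broadband components, posture-dependent coupling, and artifacts far more
varied than steps and smooth bursts. Passing tests therefore demonstrate the
correctness of the demodulation and extraction rules under the stated model,
not field performance of a physical pad.

## Problem sizes and determinism

Default simulations are 3 min at 250 Hz (45,000 samples); the exhaustive
rate sweep uses 1-minute records, and sampled sweeps of 50 pairs use full
3-minute records. All randomness flows through explicit integer seeds into
`numpy.random.default_rng`; identical seeds give bitwise-identical outputs,
and the CLI embeds the seed in file metadata so simulate → vitals → agree
chains are byte-reproducible.

## Known limitations

- The harmonic-amplitude cap (see above) trades robustness on real
  ballistocardiograms for exactness in the harmonic-collision family; it is
  a config knob, not a constant.
- Equalization assumes at least one full fringe per channel over the record;
  shallow breathing with a low-sensitivity pad would violate this and raise
  a degenerate-channel error rather than produce silently wrong phase.
- The 30 s distorted-window placement and the non-overlapping minute frames
  are stipulations; other placements change which seconds contribute but not
  the rules themselves.
- No beat-to-beat variability, apnea logic, or real-time operation.
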