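# Methods

## Protocol model

A training programme is fully described by `ProtocolConfig`: baseline
180 s, contextualisation 60 s, five 180-s active-training blocks (30 s
induction + 150 s regulation), prompts every 30 s, eight sessions grouped
into four stages (Adaptation, Symptom Identification, Refinement,
Conditioning), a 40-phrase induction pool, a 200-phrase control pool, and a
19-item exposure hierarchy. All timeline timestamps are integer-valued
seconds; sample-level alignment happens downstream at the recording's
sampling rate.

Within a block, the induction prompt sits at the block start and regulation
prompts follow at 30-s intervals starting at the end of the induction
segment, up to but excluding the block end — 5 regulation prompts per
block. This placement makes the arithmetic close exactly: 8 sessions × 5
blocks = 40 induction prompts and 8 × 25 = 200 regulation prompts, a
bijection onto the 240-phrase pool. "Controlled randomization" is realized
as a single seeded shuffle of each pool dealt to prompts in session order:
no phrase ever repeats within a programme, and the assignment is a pure
function of (config, pool, seed).

Hierarchy ranking sorts situations by anxiety rating ascending, ties broken
by situation identifier (stable sort), so shuffled input yields the same
hierarchy. Sessions map onto hierarchy ranks by linear interpolation from
the lowest-ranked situation (session 1) to the highest (final session);
a compact 4-session programme therefore visits ranks 0, 6, 12, 18 of 19.

## Forward model

The neural drive is piecewise constant: induction segments at gain 1.0,
regulation segments at gain 0.5, other phases zero. On top of the sustained
level, every verbal prompt evokes a 5-s phasic burst at the segment gain.
The phasic component matters: after the 0.01–0.1 Hz analysis bandpass, a
purely sustained segment contributes almost no in-band energy to epochs cut
in the middle of a regulation segment, whereas prompt-locked transients
give each epoch an event-related response whose amplitude carries the
condition contrast.

The hemodynamic response is the canonical double-gamma kernel (peak 6 s,
undershoot 16 s, undershoot ratio 1/6, unit dispersions), area-normalized
at convolution time so that `response_amplitude` (default 1 µM) is the HbO
change under sustained unit drive. HbR is a fixed negative multiple of HbO
(default −1/3), the simplest coupling consistent with neurovascular
physiology. Per-session learning is a multiplier on the regulation-segment
drive only (default: 1.0 → 1.5 → 2.0 then plateau for S3-D2, S3-D5, S5-D4;
1.0 → 1.45 → 1.9 → 2.4 for S5-D5, still rising in session 4). A
whole-signal multiplier would be invisible to the analysis — both the RMS
normalization and the within-session ratio denominator cancel global scale
— so the learning effect is expressed, as it must be, in the balance
between conditions.

Optical density at 760/850 nm follows the modified Beer–Lambert law with
per-channel source–detector separations (30–35 mm) and DPF 7.25/6.38. The
extinction matrix uses the printed HbO coefficients (645.5, 1669.0) and
standard compiled HbR values (1548.52, 691.32) in the same unit system;
because the final series are RMS-normalized, every downstream energy ratio
is invariant to the unit convention, which is why absolute concentrations
are never reported.

Noise is added in OD space: cardiac 1.1 Hz (0.010 OD), respiratory 0.25 Hz
(0.008), Mayer 0.1 Hz (0.005) with random phases per channel/wavelength;
linear drift 1e-5 OD/s plus a 0.002-Hz slow oscillation (0.005);
white noise (0.002); and Poisson motion spikes (0.5/min, 0.05 OD,
1-s exponential decay) shared across both wavelengths of a channel, as real
optode motion is. Intensity is I₀·10^(−OD), strictly positive for any
finite draw. These amplitudes put the prompt-evoked response (~0.01 OD) at
the same order as the physiological nuisance terms, a realistic prefrontal
fNIRS regime; the preprocessing chain removes the out-of-band components
essentially completely.

What the generator does **not** emulate: superficial/systemic physiology as
a separate compartment (no short-separation channels), photon-transport
anatomy, optode coupling changes, or serially correlated (1/f) measurement
noise. Passing tests therefore demonstrate correctness of the analysis
chain and recoverability of condition-contrast learning effects under this
noise model — not robustness to scalp physiology confounds in real data.

## Preprocessing

Stages run in the fixed order crop → FIR bandpass → wavelet denoise →
optical density → Beer–Lambert inversion → demean + RMS normalize, each
recorded in the output's provenance list.

- **FIR bandpass.** "Order 1000" is read as 1001 taps (order = taps − 1),
  windowed-sinc with a Blackman window, applied forward–backward
  (`filtfilt`) for exact zero phase; effective attenuation doubles in dB.
  At 10.2 Hz the Blackman transition width (≈ 5.5·fs/1001 ≈ 0.056 Hz) is
  comparable to the 0.01–0.1 Hz band, so passband gain is below unity and
  all spectral checks are relative (passband vs stopband), never absolute.
  An odd order is rounded up to even with a warning.
- **Wavelet denoise.** `sym4`, 10 levels, symmetric padding, detail levels
  D1–D5 zeroed (covering ≈ 0.16–5.1 Hz at fs 10.2), reconstruction trimmed
  to the input length. If a series is too short for 10 levels the level
  count is reduced with a warning, never silently. Symmetric padding makes
  the operator exactly idempotent only away from a boundary zone of a few
  hundred samples per end; this is documented behaviour, not a defect.
- **Optical density after filtering.** The stated order filters intensity
  before OD conversion, so each channel's pre-filter temporal mean is
  stored at crop time and reintroduced inside the log ratio:
  ΔOD = −log10((filtered + mean)/mean). This keeps the log defined, makes
  the chain invariant to any positive rescaling of raw intensity, and
  honours the stage order. Log arguments at or below a floor (1e-6 of the
  mean) are clipped and counted in QC.
- **Beer–Lambert inversion** solves the per-sample 2×2 system with the
  per-channel montage separation; it is the exact inverse of the forward
  model (round-trip error ~1e-14).
- **Normalization** enforces |mean| ≤ 1e-9 and |RMS − 1| ≤ 1e-9 per
  channel; constant channels raise a degenerate-channel flag in QC rather
  than passing silently.

A consequence of the narrow passband worth stating: a block response's
sustained component lies largely below 0.01 Hz, so the recovered series
reproduces *band-limited* ground truth almost perfectly (r > 0.99
noise-free) while correlation with raw ground truth saturates around
0.7–0.8. Fidelity claims are therefore made against the band-limited
reference.

## Energy-ratio analysis

Epochs are 15 s (153 samples at 10.2 Hz) from prompt onsets; stressor
epochs at induction prompts, control epochs at each regulation prompt.
Epochs overrunning the recording are discarded and counted. Energy is the
sum of squared samples, accumulated in sample order so independent
reimplementations agree bit-for-bit. The ratio denominator pools both
conditions within a (channel, chromophore, session) group, making the
group mean of ratios exactly 1 and the statistic a within-session relative
measure; alternative denominator scopes would break that identity. Both
chromophores are analyzed; HbO is the default for trend classification.

Trend classification uses successive relative changes with a 5% plateau
tolerance: all within tolerance → flat; all above → rising_throughout; one
or more rises followed only by within-tolerance changes →
rising_then_plateau; anything else → other. The 5% tolerance is an
explicit, testable stand-in for a verbal description; with ratio noise of
similar magnitude, roughly one in ten null trajectories mimics a rising
pattern by chance, which bounds the classifier's specificity (~91% per
channel over 20 seeds).

## Online feedback

The real-time path cannot be zero-phase, so the online filter is a causal
4th-order Butterworth bandpass over 0.01–0.3 Hz (the hemodynamic band of
the feedback software), implemented in second-order sections with
streaming state; causality is verified by truncation equivalence. The
thermometer maps the baseline z-score linearly over [−2, +2] onto the
level range, clipped at the ends, with the baseline mean at the middle
level. The closed loop steps the session in update intervals (default 1 s):
a responder maps the displayed level to the next interval's regulation
drive, the ROI concentration is accumulated by causal convolution with the
HRF kernel, and levels are emitted once per interval after the baseline
window. The responder abstraction deliberately models nothing about
participant psychology beyond a level→gain map.

## Problem sizes and numerical choices

Default test and acceptance runs use 4-session programmes on a 6-channel
sub-montage (the four reported channels plus two unaffected controls) and
2-session runs for the end-to-end determinism check; the full 20-channel
montage is the library default. Parameter recovery is assessed over 20
seeds. Sub-seeds for every stage and session derive from one top-level
seed via SHA-256, so partial reruns agree with full runs and all artifacts
are byte-reproducible (no timestamps are written into hashed files).

## Known limitations

- The simulator's learning profile is a stylized two-parameter pattern
  (rise slope, plateau onset); real training trajectories are noisier and
  participant-specific.
- Channel region labels are annotations only; no anatomical registration
  is modelled or implied.
- The SNIRF reader/writer covers the minimal layout this package emits
  (one data block, per-channel measurement lists, stim groups); it is not
  a general-purpose SNIRF validator.
- Inferential statistics are deliberately absent from the analysis module:
  the statistic of interest is descriptive (per-session ratio summaries
  and a rule-based trend label).
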