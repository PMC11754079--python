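# Methods

This note documents the quantification models, the defaults and why,
the synthetic-data models the tests run against, and the numerical
choices made where the procedure was genuinely open.

## Voltage-clamp conventions

Sweeps are current traces digitized at 10 kHz (2 kHz low-pass in the
emulated acquisition).  Polarity is metadata, never inferred: inward
currents are negative.  Excitatory responses are measured at −55 mV
(inward), inhibitory at +10 mV (outward), without junction-potential
compensation.  Analysis code never mutates sweep metadata.

## Mini-PSC analysis

*Noise.* The RMS baseline noise is estimated after removing a slow
baseline (per-100-ms segment medians, linearly interpolated) by
iterative exclusion of samples beyond 3× the current RMS until the
estimate changes < 1%.  Truncating a Gaussian at ±k SD shrinks its SD by
a known factor; the converged estimate is divided by the fixed point of
that shrinkage so pure noise is estimated without bias.  Cells pass QC
strictly below 2 pA (mEPSC) / 4 pA (mIPSC).

*Detection.* The polarity-rectified trace is smoothed with a 0.5 ms
boxcar (suppresses single-sample spikes at 10 kHz without distorting
sub-millisecond rise times), the slow baseline subtracted, and local
maxima above 3× RMS (prominence ≥ half the threshold, ≥ 0.5 ms apart)
taken as peaks.  Overlapping events are split at the valley between
adjacent peaks.  Onset is the threshold crossing before the peak (or the
valley, for riding events); the local baseline for the amplitude is the
median of the 5 ms preceding onset, and the measured amplitude must
itself clear the threshold.  Rise time is 10–90% of baseline-to-peak
(the convention is not fixed by the emulated criteria; 10–90% is the
common choice).

*Selection and summary.* Events with rise time ≥ 3 ms (mEPSC) / 5 ms
(mIPSC) are dropped; the first 300 by onset are kept (chronological,
hence deterministic — random subsampling would not reproduce).
Frequency is (n − 1)/(last − first onset) of the *selected* events,
since selection truncates the record; users preferring n/duration can
compute it from the returned fields.  Averaged waveforms use only events
with no neighbor onset within ±50 ms (≥ 5 decay constants of the 5 ms
default kernel).

## Evoked E/I

Peaks are measured from a 20 ms pre-stimulus baseline within a 50 ms
post-stimulus window, after 0.5 ms artifact blanking and a 1 ms boxcar
(the slight peak attenuation is shared by both holding potentials and
cancels in the ratio).  The *first* local peak is used; when a later,
larger peak follows without a trough dipping ≥ 20% of the first peak,
the first peak is deemed unresolved and the intensity discarded.  A
measured peak that fails to clear 4× the pre-stimulus noise (MAD-based)
is discarded as no-response — sub-threshold stimulation yields no
interpretable ratio.  Both the 20% trough rule and the CV rule below are
this package's operationalizations of qualitative criteria ("clearly
resolved", "stable") and are exposed as configuration.

The stable range is found by exhaustive search over contiguous runs of
valid intensities: the longest run of length ≥ 3 with ratio CV ≤ 0.2
wins, ties going to the highest intensities (matching the saturation
plateau of synaptic recruitment).  The cell's E/I is the mean ratio over
that run.  Phase pooling maps ZT {0, 18} → dark and {6, 12} → light and
rejects any other time point rather than guessing.

## sIPSC unit charge

Per 500 ms segment the baseline is the 10th percentile of the samples —
a robust floor under outward events — and the per-segment series is
median-filtered over 3 segments so a segment fully occupied by a large
deflection borrows its neighbors' baseline.  Charge is the integral of
the positive residual; *unit charge* divides by the quantified duration
(3–4 min enforced), giving a duration-invariant mean current in nA.
Rectifying noise adds a small positive bias (the robust floor leaves the
noise mean slightly above zero); the noise center is re-estimated as the
mode of the residual with its spread from the uncontaminated lower half,
and the expected rectified-noise rate E[max(N(δ, σ), 0)] is subtracted.
A median baseline (50th percentile) is available via configuration.

## Sleep

Architecture is computed from 4-s epoch hypnograms: percent time per
state per bin (bins must tile the record; a flag admits partial trailing
bins), bouts as maximal runs of one label (minimum one epoch — no
minimum-duration rule is imposed), and transition counts at label
changes.  Per-mouse values are the arithmetic mean over the recording
days (3 by default) before any statistics.

Spectra use 2-s Hann windows (0.5 Hz resolution at 500 Hz sampling), two
per epoch and never crossing an epoch boundary since one state's epochs
need not be contiguous; periodograms are averaged within state and
normalized so the 0.5–80 Hz sum is 1.  Band defaults are conventional
rodent values bounded by the 80 Hz normalization ceiling — delta 0.5–4,
theta 5–9, gamma 30–80 Hz — and configurable, as the band edges are a
reporting convention, not a measurement.  Band selection is inclusive on
both edges; bands should be chosen disjoint.  Animals excluded from
spectral analysis (e.g. for electrode placement) carry an
`exclude_spectral` flag rather than a rule.

The rule-based scorer labels an epoch WAKE when EMG RMS exceeds 15 µV,
otherwise REM when the theta/delta power ratio exceeds 1, else NREM.  It
stands in for a trained human scorer and is validated only against the
synthetic generator, where it reaches ≥ 90% (typically ≈ 100%) epoch
accuracy; real recordings with artifacts, transitional epochs and
drifting EMG baselines would require retuned thresholds and human
review.

## Intrinsic imaging

Responses are single-bin DFT coefficients at the stimulus frequency over
a whole number of cycles, scaled so a cosine of amplitude A yields
magnitude A; the frequency must fall on the frame grid.  Maps are
smoothed with a 5×5 Gaussian (σ = 1 px, reflection at edges) *before*
ROI selection; the binocular ROI is the ⌈70%⌉ highest-magnitude pixels
of the smoothed ipsilateral map, ties broken row-major for determinism.
ODI averages (contra − ipsi)/(contra + ipsi) over the ROI, excluding
zero-sum pixels.  The activated-pixel count (a relative V1-size proxy)
thresholds at the map's median + 3 robust SD (1.4826 × MAD): robust
background statistics stay anchored as long as the active patch is a
minority of pixels, which a lowest-decile mean + SD rule does not (the
SD of a decile is ~0.3× the population SD, putting such a threshold
inside the background bulk).

## Statistics

Standard tests are delegated: pooled-variance t (scipy), Kruskal-Wallis
(scipy), Type-III two-way ANOVA on Sum-coded contrasts (statsmodels;
Type III matches the commercial package this battery emulates for
unbalanced designs), mixed/RM ANOVA (pingouin; incomplete subjects are
dropped with a warning), Holm-Sidak (statsmodels), Lilliefors-corrected
KS normality (statsmodels; a naive-KS mode exists).  Mann-Whitney
reports U = min(U1, U2); p is exact by enumeration for tie-free samples
with n1 + n2 ≤ 20, otherwise a tie-corrected normal approximation
*without* continuity correction, which preserves the identity
H = z² between the two-group Kruskal-Wallis and the Mann-Whitney
deviate to numerical precision (as does F = t² for a two-level
one-factor ANOVA).  Dunn's post-hoc z-tests use pooled mid-ranks with
tie correction over an explicitly declared contrast family (never
inferred), Holm-adjusted by default.

ROUT-style outlier flagging fits a constant robustly (median; scale =
lower-interpolated 68.27th percentile of |residuals| with an n/(n−1)
small-sample factor), converts residuals to t probabilities on n − 1 df
and applies Benjamini-Hochberg thresholds q·i/n outermost-first, at
Q = 0.1%.  Normality gating selects the nonparametric branch when any
group fails the KS test; groups with n < 5 are noted and not gated.
Every gating and outlier decision is written to the run log.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (parameters, seed).  Defaults were
chosen once as realistic for the emulated preparations:

* **Minis** — homogeneous Poisson events (2 Hz), log-normal amplitudes
  (mean 25 pA, CV 0.25; positive support and right skew match empirical
  mini distributions), biexponential kernel τr 0.5 / τd 5 ms, Gaussian
  noise 1.5 pA RMS.  Overlap is allowed; ground truth records all events.
* **Evoked** — excitatory and inhibitory peaks on Hill curves (n = 3)
  sharing half-saturation 30 (e_max 200, i_max 400 pA → true ratio 0.5),
  so a single plateau exists; multiplicative log-normal jitter (SD 0.15)
  below half-saturation creates the unstable low-intensity region that
  exercises the stable-range logic; an optional second peak at +15 ms
  (50% of the first) exercises the first-peak rule; noise 5 pA RMS.
* **sIPSC** — 12 Hz Poisson outward events, 0.15 nA mean (CV 0.4),
  τr 1 / τd 15 ms, on a 10 pA, 60 s-period sinusoidal drift with 3 pA
  noise over 200 s: a heavily summating inhibitory barrage, which is why
  charge rather than event counting is the readout.
* **Sleep** — per-epoch Markov chains with separate light/dark rows
  (nocturnal pattern: more sleep in the light phase); EEG is a sum of
  band-limited noise components with per-state power weights (NREM
  delta-dominated, REM theta-dominated with EMG atonia), EMG white noise
  at per-state RMS.  Stationary occupancies and their asymptotic SEs are
  computed from the chain's fundamental matrix for calibration tests.
* **Imaging** — per-pixel cosines at the stimulus frequency (0.125 Hz,
  10 fps) with eye-specific amplitudes on a shared Gaussian spatial
  profile (contra 1.0 / ipsi 0.5 → true ODI 1/3), a smooth phase
  gradient as retinotopy surrogate, Gaussian noise 0.05.

What passing these tests shows is that the *quantification* recovers
known ground truth under clean statistical assumptions.  The generators
deliberately omit: 1/f aperiodic EEG background, movement and chewing
artifacts, transitional sleep epochs, electrode drift, series-resistance
changes, stimulus artifacts beyond a blanking window, hemodynamic
nonlinearities and vessel noise in imaging.  Results on real recordings
therefore still require the usual visual sanity checks.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale versions of the study:
50 seeds × 120 s sweeps for mini recovery, 100 seeds for E/I, 50 seeds ×
200 s for charge, one 3 h-equivalent (2700-epoch) sleep record, 20
imaging stacks, and 1000 null simulations per test for type-I
calibration (n = 24 per group for t/Mann-Whitney/Kruskal-Wallis so the
rank tests operate in their continuous regime; balanced 2×2 with 10 per
cell for the ANOVA interaction).  The orchestrated `run-study` demo uses
1 h sleep "days" and small cell counts by default; every size is
configuration.  All randomness flows from explicit seeds;
`numpy.random.default_rng` streams are derived per stage, and identical
config + seed reproduces output files byte for byte.

## Known limitations

* The EDF writer is minimal (2 channels, 1 s records, integer sampling
  rates); it exists because the environment provides an EDF reader (mne)
  but no writer.  Round-trips are exact to 16-bit quantization.
* The rule-based sleep scorer is a stand-in for manual scoring, not a
  validated autoscorer.
* ROUT here fits a constant (group location), the case the statistical
  battery needs; regression-model ROUT is out of scope.
* The stable-range and first-peak-resolution thresholds are declared
  surrogates for qualitative experimenter judgment; sensitivity to their
  settings should be reported when applying the pipeline to real data.
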