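# Methods

`oriband` simulates, end to end, a noise-in-noise orientation-summation study:
detection of orientation-band-limited Gaussian noise targets embedded in
Gaussian white-noise masks, measured with adaptive 2-IFC staircases, and
characterization of the detecting mechanism with power-spectrum classification
images fitted by constrained difference-of-Gaussians (DoG) orientation
channels.  This note documents the models, the defaults and their units, the
numerical choices, and what the synthetic observers do and do not emulate.

## Stimuli

Targets are two-dimensional Gaussian white-noise fields filtered in the
Fourier domain with ideal (hard-edged) filters.  A `FilterSpec` gives the
passband: center spatial frequency 5 cy/deg; SF bandwidth 1 or 2 octaves
(the passband spans `f0 * 2^(+-b/2)`); center orientation horizontal (0 deg);
two-sided orientation bandwidth 2-180 deg (a 16-deg filter passes -8 to
+8 deg).  Both passbands are closed: a Fourier bin exactly on an edge is
included, and a conjugate pair is included whenever either member is.  DC and
the Nyquist row/column are excluded from every band (no orientation is defined
at DC; Nyquist bins have no distinct conjugate partner).

Orientation convention: 0 deg denotes a horizontally oriented grating, whose
frequency vector lies on the vertical frequency axis; the orientation of bin
`(fx, fy)` is `(atan2(fy, fx) + 90) mod 180` degrees.  Export/display code may
rotate images for presentation; the library never does.

The synthesized target is scaled so its *sample* RMS contrast equals the
nominal contrast exactly, then (for display realism) multiplied by a centered
circular Gaussian envelope of SD 1.08 deg.  Thresholds are reported on the
nominal (pre-envelope) RMS-contrast scale.  Masks are i.i.d. Gaussian pixel
noise with contrast variance 0.32 (RMS contrast 0.57 — high for a Weber
contrast; the value is kept as a configurable default and all results are
scale-consistent with it).  Fresh mask and signal samples are drawn on every
interval of every trial, with seeds logged for exact replay.

Grids: the full-scale default is 512x512 px at 94.8 px/deg.  Analyses and
tests run on reduced 128x128 grids at 32 px/deg (a 4-deg patch, 0.25 cy/deg
per bin), chosen once so that the one-octave 5 cy/deg annulus (3.54-7.07
cy/deg) sits inside both the Nyquist limit (16 cy/deg) and the central 64-bin
crop used for classification images.  The number of independent Fourier
components in the band — the abscissa of the threshold-versus-bandwidth (TvB)
analysis — is counted directly on the grid (conjugate pairs counted once).

## Observers

All observers are linear templates on the stimulus power spectrum: the
decision variable of an interval is the template-weighted sum of DFT power
(each conjugate pair once) plus optional zero-mean Gaussian internal noise;
the observer chooses the interval with the larger value, ties toward
interval 1.

*Ideal observer*: uniform weights on the signal band, no internal noise.  For
Gaussian signal-in-Gaussian-noise with flat in-band spectra, the likelihood
ratio is monotone in in-band power, so the band-energy sum is the optimal
statistic.

*Human proxies*: DoG orientation profiles (below) extruded over the signal SF
annulus, with a fixed 2:1 excitatory:inhibitory amplitude ratio, optionally
plus a negative low-SF disk.  The *adjustable* proxy uses per-condition SDs
(20/60, 25/75, 30/90 deg for the 2/48/90-deg conditions — both SDs grow 50%
from narrowest to widest); the *fixed* proxy uses one template (25/75)
everywhere.  These two generative hypotheses are exactly what the
classification-image pipeline is built to discriminate.

Because each DFT coefficient of a Gaussian field is complex Gaussian, per-bin
power is exponential, giving closed forms for the decision variable's mean
and variance and hence for d', percent correct, detection threshold, and
small-signal ("matched-template") efficiency
`(sum_band w)^2 / (K * sum w^2)`.  These closed forms are the package's
independent oracle: measured accuracy at the closed-form 75% threshold is
within a point of 75% at every condition tested, and unwindowed Monte-Carlo
thresholds reproduce the closed-form TvB exponent to three decimals.

## Trial engine

Each condition block interleaves four transformed up-down staircases on log10
contrast — two 2-down/1-up (fixed point 70.7% correct) and two 4-down/1-up
(84.1%) — 75 trials each, 300 per block.  The rule chosen on each trial is
drawn at random from the unfinished staircases; signal intervals are
balanced-random.  Steps are 0.1 log10 units until the second reversal, 0.05
thereafter; the 71% tracks start 0.6 log10 units above the observer's
closed-form threshold (clearly visible), the 84% tracks 0.3 log10 lower.
Contrast is clamped to [1e-5, 1].

Thresholds (RMS contrast at 75% correct) come from a maximum-likelihood
cumulative-normal fit on log10 contrast over all trials of a condition, with
the guessing rate fixed at 0.5 and, by default, a free lapse rate bounded at
6% (a standard guard against occasional high-contrast errors inflating the
fitted spread; a fixed lapse is available).  The SE of the fitted location —
which is the SE of log10 threshold — supplies the inverse-variance weights of
the TvB fit.  The likelihood is aggregated over unique contrast levels, which
makes the 999-replicate bootstrap cheap.

The ideal-observer TvB simulations default to *unwindowed* targets.  The
Gaussian envelope smears each signal component by ~0.15 cy/deg; for narrow
orientation bands (arc length ~1.4 cy/deg at 16 deg) several percent of
signal energy leaks outside the hard band, which elevates narrow-band
thresholds for a hard-band template by ~3% and flattens the measured exponent
by ~0.01.  The quarter-root prediction is a matched-template property, so the
ideal is evaluated on the ensemble its template matches; the windowed
configuration remains available via `envelope_signal=True`.

## TvB fit and efficiency

"Weighted maximum likelihood" is realized as weighted least squares of log10
threshold on log10 component count with the inverse-variance weights above.
The narrowest bandwidth is excluded by default (critical-band flattening is
out of scope).  Bootstrap CIs resample trials with replacement within
condition, refit the psychometric function and the power law, and take the
2.5/97.5 percentiles of 999 replicate exponents.  Absolute efficiency is
`(c_ideal / c_observer)^2` with both thresholds measured on identically
parameterized stimuli.

## Classification images

At a fixed contrast (the observer's closed-form 75% threshold; 2500 trials
per condition), the power spectrum of each interval's noise mask (mask alone
by default; mask-plus-signal available) is computed, the difference
`P(signal interval) - P(non-signal interval)` formed, and the difference
binned by (signal interval x correctness).  Bin means are combined as
`mean(correct bins) - mean(incorrect bins)` and the map normalized to peak
magnitude 1 with the sign anchored positive over the signal band (anchoring
at the global extremum is unstable when the inhibitory surround is strong).
For a linear-template observer this estimate is proportional to the
generating template; at 2500 trials the raw map correlates with the template
at r ~ 0.6 and the smoothed map at r ~ 0.9.

Maps are cropped to the central 64x64 bins around DC (the retained frequency
range is reported from the grid geometry) and smoothed with the separable
5-tap triangular kernel (1,2,3,2,1)/9 per axis (reflection at edges).
Profiles are obtained by summing CI values in 1-deg orientation steps over
one conjugate half-plane across an SF band — by default the stimulus annulus,
since the generating template is zero outside it; orientation bins with no
Fourier component on a coarse grid are reported as zero with a warning.

## Constrained DoG fitting

The channel model is
`w(theta) = 2 A_i exp(-d^2/2 sigma_e^2) - A_i exp(-d^2/2 sigma_i^2)` with `d`
the 180-deg-wrapped distance to the shared center.  Constraints: common
center, amplitude ratio exactly 2:1, and `sigma_e < sigma_i`, enforced by
optimizing `sigma_i = sigma_e + delta` with `delta > 0` (a smooth
parameterization needing no penalty tuning).  Profiles are normalized to
their peak response before fitting.  The least-squares fit multi-starts over
a coarse (sigma_e, sigma_i) grid and over two center starts (the empirical
peak and the signal orientation); tolerances 1e-12 so noiseless profiles are
recovered to ~1e-6.  A fit ending on the `delta` boundary (surround no wider
than center) is flagged with a warning — that is the signature of data
violating the channel model, e.g. a pure single-Gaussian profile.

Bootstrap CIs resample *trials*, recompute CI -> profile -> fit per replicate
(999 by default), and take percentile intervals; per-trial cropped difference
spectra are cached in float32 so a replicate costs only a binned average, a
smoothing pass, and one warm-started fit.  The bandwidth trend regresses each
fitted SD on stimulus bandwidth (weighted LS, weights `1/(CI half-width)^2`
when CIs exist), and the narrowest-to-widest percent increase is read from
the fitted line.

## What the synthetic observers do and do not emulate

The proxies reproduce the *decision structure* attributed to observers — a
linear template on the power spectrum with center/surround orientation
tuning — and the procedures are exactly those of the simulated experiments,
so passing tests show the pipeline recovers known generative structure
(template shapes, bandwidth adjustment, efficiency levels) through the full
measurement chain.  They do not emulate nonlinear transduction, contrast
gain control, uncertainty/max-rule decisions, attention lapses tied to
stimulus history, or learning; recovered parameters from real observers would
additionally reflect those processes.  Display nonlinearity, timing, and
fixation behavior are out of scope.

## Problem sizes and determinism

Default analysis sizes: TvB runs pool 24-32 sessions (7,200-9,600 trials) per
condition, chosen to put the Monte-Carlo SE of the exponent near 0.005;
classification images use the study's 2,500 trials per condition; bootstraps
use 999 replicates (tests use fewer).  Every random quantity descends from a
caller-supplied seed; identical seeds give bit-identical trial logs.
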