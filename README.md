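# oriband

Simulation and analysis of **orientation summation in noise-in-noise
detection**: how observers detect band-limited visual noise targets whose
orientation content varies, embedded in white-noise masks, and whether the
mechanism doing the detecting behaves like a *fixed*- or an
*adjustable*-bandwidth orientation channel.

The package is for visual psychophysicists and computational modelers who
want a complete, seeded, testable implementation of this paradigm:

- **Stimuli** — Gaussian noise targets filtered with ideal spatial-frequency x
  orientation filters (center 5 cy/deg, 1-2 octaves, two-sided orientation
  bandwidths 2-180 deg about horizontal), Gaussian-windowed, in white-noise
  masks of contrast variance 0.32.
- **Observers** — the ideal band-energy observer and human-proxy linear
  templates on the power spectrum (difference-of-Gaussians orientation
  tuning, 2:1 amplitude ratio), with closed-form d', thresholds and
  efficiency as oracles.
- **Procedure** — 2-IFC trials under four interleaved transformed up-down
  staircases (2-down/1-up -> 70.7%, 4-down/1-up -> 84.1%), 75 trials each;
  ML cumulative-normal psychometric fits on log contrast; thresholds = RMS
  contrast at 75% correct.
- **TvB analysis** — weighted power-law fits of log threshold versus the
  log number of stimulus Fourier components `N`.  The ideal observer predicts
  the quarter-root law `c_rms ∝ N^(1/4)`; absolute efficiency is
  `η = (c_rms(ideal) / c_rms(observer))²`.
- **Classification images** — power-spectrum reverse correlation from
  fixed-contrast trials (difference spectra binned by signal interval x
  correctness), 64x64 crop, 5x5 triangular smoothing, circular summation to
  1-deg orientation profiles, and constrained DoG channel fits
  `w(θ) = 2A_i e^{-θ²/2σ_e²} - A_i e^{-θ²/2σ_i²}` (shared center,
  σ_e < σ_i) with percentile-bootstrap CIs and bandwidth trends.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

Recover a known adjustable channel structure through the full
classification-image pipeline (a few minutes on one CPU):

```python
import numpy as np
from oriband import experiments

rng = np.random.default_rng(42)
# 2500 fixed-contrast trials per condition (2, 48, 90 deg bandwidth) from a
# proxy whose DoG template SDs grow 50% across conditions: (20,60) -> (30,90)
sessions = experiments.run_classification_experiment(size=128, n_trials=2500, rng=rng)
rec = experiments.channel_recovery(sessions, n_boot=199, rng=rng)
for bw, fit in sorted(rec.fits.items()):
    p = fit.params
    print(f"bw {bw:3g} deg: sigma_e = {p.sigma_e:4.1f}, sigma_i = {p.sigma_i:5.1f}")
print(f"sigma_e increase: {rec.pct_increase_e:.1f}%  (95% CI {rec.increase_ci('e')})")
```

Output from this exact run:

```
bw   2 deg: sigma_e = 20.0, sigma_i =  66.6
bw  48 deg: sigma_e = 25.0, sigma_i =  79.9
bw  90 deg: sigma_e = 30.5, sigma_i =  87.8
sigma_e increase: 52.4%  (95% CI (42.4, 62.5))
```

The fitted excitatory SDs (20.0, 25.0, 30.5 deg) track the generating values
(20, 25, 30) and the recovered narrowest-to-widest increase brackets the
generating 50% — the signature of an adjustable-bandwidth channel.  Running
the same pipeline with `sigmas=experiments.FIXED_SIGMAS` (one template
everywhere) yields a flat trend instead.

The ideal-observer TvB experiment is one call:

```python
df, fit = experiments.ideal_tvb_experiment(size=128, sessions=8, n_boot=199, rng=0)
print(fit.exponent)   # ~0.24, the quarter-root law
```

A thin CLI wraps the two experiments:
`oriband exp1 --seed 0 --out results_exp1` and
`oriband exp2 --seed 0 --out results_exp2`.

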