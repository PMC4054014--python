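"""Threshold-versus-bandwidth power laws and absolute efficiency.

Thresholds are regressed on the number of independent Fourier components in
the stimulus: a weighted least-squares fit of log10 threshold on log10
component count, with weights taken as the inverse variance of each log10
threshold (the SE of the psychometric fit's location parameter).  The ideal
noise-in-noise observer predicts an exponent of 1/4 (the quarter-root law).
The narrowest bandwidth condition is excluded by default: at sufficiently
narrow bandwidths the TvB function flattens into a critical band, which is
outside the scope of the power-law description.

Absolute efficiency compares an observer to the ideal on identical stimuli:
``eta = (c_ideal / c_observer)**2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .trials import fit_psychometric

__all__ = ["TvBFit", "fit_power_law", "bootstrap_tvb", "efficiency"]


@dataclass
class TvBFit:
    """Weighted log-log power-law fit of threshold versus component count."""

    exponent: float
    intercept: float
    se_exponent: float
    component_counts: np.ndarray
    thresholds: np.ndarray
    weights: np.ndarray
    included: np.ndarray
    ci: tuple[float, float] | None = None
    boot_exponents: np.ndarray | None = None

    def predict(self, component_counts):
        """Predicted threshold at the given component counts."""
        return 10.0 ** (self.intercept + self.exponent * np.log10(component_counts))


def fit_power_law(
    thresholds,
    component_counts,
    weights=None,
    *,
    exclude_narrowest: bool = True,
) -> TvBFit:
    """WLS fit of ``log10 threshold = intercept + exponent * log10 N``.

    ``weights`` are inverse variances of the log10 thresholds (equal weights
    when omitted).  The point with the smallest component count is excluded by
    default (critical-band flattening); at least 3 points must remain.
    """
    thr = np.asarray(thresholds, dtype=float)
    cnt = np.asarray(component_counts, dtype=float)
    if thr.shape != cnt.shape or thr.ndim != 1:
        raise ValueError("thresholds and component_counts must be 1-D with equal length")
    if np.any(thr <= 0) or np.any(cnt <= 0):
        raise ValueError("thresholds and component counts must be positive")
    w = np.ones_like(thr) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    included = np.ones(thr.size, dtype=bool)
    if exclude_narrowest:
        included[np.argmin(cnt)] = False
    if included.sum() < 3:
        raise ValueError("need at least 3 included points for the power-law fit")

    X = sm.add_constant(np.log10(cnt[included]))
    res = sm.WLS(np.log10(thr[included]), X, weights=w[included]).fit()
    return TvBFit(
        exponent=float(res.params[1]),
        intercept=float(res.params[0]),
        se_exponent=float(res.bse[1]),
        component_counts=cnt,
        thresholds=thr,
        weights=w,
        included=included,
    )


def bootstrap_tvb(
    trials_by_condition: dict,
    component_counts: dict,
    n_boot: int = 999,
    rng=None,
    *,
    exclude_narrowest: bool = True,
    max_failure_frac: float = 0.10,
) -> TvBFit:
    """Trial-resampling bootstrap of the TvB exponent (percentile 95% CI).

    Per replicate, trials are resampled with replacement within each
    condition, the psychometric function refit, and the power law refit.
    Replicates whose psychometric fit degenerates are skipped; more than
    ``max_failure_frac`` failures raises.
    """
    rng = np.random.default_rng(rng)
    names = list(trials_by_condition)
    cnt = np.array([component_counts[n] for n in names], dtype=float)

    def fit_once(trials_map):
        thr = np.empty(len(names))
        w = np.empty(len(names))
        for i, name in enumerate(names):
            pf = fit_psychometric(trials_map[name])
            thr[i] = pf.threshold_75
            w[i] = 1.0 / pf.se_mu**2 if np.isfinite(pf.se_mu) and pf.se_mu > 0 else 1.0
        return fit_power_law(thr, cnt, w, exclude_narrowest=exclude_narrowest)

    point = fit_once(trials_by_condition)
    if n_boot <= 0:
        return point

    reps = []
    failures = 0
    for _ in range(n_boot):
        try:
            resampled = {}
            for name in names:
                trials = trials_by_condition[name]
                idx = rng.integers(0, len(trials), size=len(trials))
                resampled[name] = [trials[i] for i in idx]
            reps.append(fit_once(resampled).exponent)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    if failures > max_failure_frac * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap replicates failed (> {max_failure_frac:.0%})")
    reps = np.asarray(reps)
    point.boot_exponents = reps
    point.ci = tuple(np.percentile(reps, [2.5, 97.5]))
    return point


def efficiency(c_ideal: float, c_observer: float) -> float:
    """Absolute efficiency: squared ratio of ideal to observer threshold."""
    if c_ideal <= 0 or c_observer <= 0:
        raise ValueError("thresholds must be positive")
    return (c_ideal / c_observer) ** 2
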