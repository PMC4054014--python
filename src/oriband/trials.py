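"""2-IFC sessions: transformed up-down staircases, trial logs, psychometric fits.

Each session interleaves four staircases - two 2-down/1-up tracks converging
on the ~71% correct point and two 4-down/1-up tracks converging on ~84% - with
75 trials per staircase (300 per condition).  Fresh mask and signal noise are
drawn on every interval of every trial; trial records store the generating
seeds so stimuli (and classification-image spectra) can be replayed exactly.

Thresholds are the RMS contrast at 75% correct, obtained from a
maximum-likelihood cumulative-normal fit on log10 contrast with the guessing
rate anchored at 0.5.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr, ndtri

from .conditions import Condition
from .observers import TemplateObserver, analytic_threshold, decide_2ifc
from .stimulus import power_spectrum_half

__all__ = [
    "TrialRecord",
    "StaircaseState",
    "SessionConfig",
    "PsychometricFit",
    "make_staircase",
    "staircase_update",
    "staircase_convergence",
    "present_trial",
    "run_session",
    "run_fixed_contrast_session",
    "fit_psychometric",
    "trials_to_frame",
    "save_trials",
    "load_trials",
]

_SEED_MAX = 2**31 - 1


@dataclass(frozen=True)
class TrialRecord:
    """One 2-IFC trial; ``correct`` iff the choice equals the signal interval."""

    condition: str
    staircase: int
    contrast: float
    signal_interval: int
    choice: int
    correct: bool
    seed1: int
    seed2: int
    signal_seed: int


@dataclass(frozen=True)
class StaircaseState:
    """State of one n-down/1-up transformed up-down track on log10 contrast."""

    n_down: int
    log_contrast: float
    step: float
    final_step: float = 0.05
    reversals_to_final: int = 2
    n_reversals: int = 0
    n_trials: int = 0
    max_trials: int | None = 75
    run_correct: int = 0
    last_direction: int = 0
    min_log_contrast: float = -5.0
    max_log_contrast: float = 0.0

    @property
    def finished(self) -> bool:
        return self.max_trials is not None and self.n_trials >= self.max_trials


def make_staircase(
    n_down: int,
    start_log_contrast: float,
    *,
    initial_step: float = 0.1,
    final_step: float = 0.05,
    max_trials: int | None = 75,
) -> StaircaseState:
    return StaircaseState(
        n_down=n_down,
        log_contrast=start_log_contrast,
        step=initial_step,
        final_step=final_step,
        max_trials=max_trials,
    )


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance an n-down/1-up staircase by one trial outcome.

    Contrast moves one step down after ``n_down`` consecutive correct
    responses and one step up after any error.  The step size shrinks from its
    initial value to ``final_step`` after ``reversals_to_final`` reversals.
    """
    if state.finished:
        raise ValueError("staircase has already completed its trials")
    n_trials = state.n_trials + 1
    run = state.run_correct + 1 if correct else 0
    direction = 0
    if not correct:
        direction = +1
    elif run >= state.n_down:
        direction = -1
        run = 0
    log_c = state.log_contrast
    n_rev = state.n_reversals
    last = state.last_direction
    step = state.step
    if direction != 0:
        if last != 0 and direction != last:
            n_rev += 1
            if n_rev >= state.reversals_to_final:
                step = state.final_step
        log_c = float(
            np.clip(log_c + direction * step, state.min_log_contrast, state.max_log_contrast)
        )
        last = direction
    return replace(
        state,
        log_contrast=log_c,
        step=step,
        n_reversals=n_rev,
        n_trials=n_trials,
        run_correct=run,
        last_direction=last,
    )


def staircase_convergence(
    n_down: int,
    pc_fn,
    *,
    n_trials: int = 12_000,
    burn_in: int = 1_000,
    step: float = 0.02,
    start_log_contrast: float = 0.0,
    rng=None,
) -> float:
    """Long-run percent correct of an n-down/1-up track on a known psychometric function.

    ``pc_fn(log_contrast)`` gives the true probability correct.  The staircase
    runs with a small constant step; outcomes after the burn-in are averaged.
    The theoretical fixed point satisfies ``pc**n_down = 0.5`` (70.7% for
    2-down/1-up, 84.1% for 4-down/1-up).
    """
    rng = np.random.default_rng(rng)
    state = StaircaseState(
        n_down=n_down,
        log_contrast=start_log_contrast,
        step=step,
        final_step=step,
        max_trials=None,
    )
    n_correct = 0
    for t in range(n_trials):
        correct = bool(rng.random() < pc_fn(state.log_contrast))
        if t >= burn_in:
            n_correct += correct
        state = staircase_update(state, correct)
    return 100.0 * n_correct / (n_trials - burn_in)


@dataclass
class SessionConfig:
    """Tunables of one 300-trial session (four interleaved staircases)."""

    n_per_staircase: int = 75
    start_log_contrast: float | None = None  # None: 0.6 log10 above analytic threshold
    start_offset_84: float = -0.3
    initial_step: float = 0.1
    final_step: float = 0.05


def _draw_seeds(rng: np.random.Generator, n: int = 3):
    return [int(s) for s in rng.integers(0, _SEED_MAX, size=n)]


def present_trial(
    observer: TemplateObserver,
    condition: Condition,
    contrast: float,
    signal_interval: int,
    rng: np.random.Generator,
    *,
    staircase: int = -1,
) -> TrialRecord:
    """Generate both intervals' stimuli, query the observer, record the trial."""
    seed1, seed2, sseed = _draw_seeds(rng)
    mask1 = condition.mask_patch(seed1).data
    mask2 = condition.mask_patch(seed2).data
    signal = condition.signal_patch(contrast, sseed).data
    stim1 = mask1 + signal if signal_interval == 1 else mask1
    stim2 = mask2 + signal if signal_interval == 2 else mask2
    choice = decide_2ifc(observer, power_spectrum_half(stim1), power_spectrum_half(stim2), rng)
    return TrialRecord(
        condition=condition.name,
        staircase=staircase,
        contrast=float(contrast),
        signal_interval=int(signal_interval),
        choice=int(choice),
        correct=bool(choice == signal_interval),
        seed1=seed1,
        seed2=seed2,
        signal_seed=sseed,
    )


def _balanced_intervals(n: int, rng: np.random.Generator) -> np.ndarray:
    intervals = np.array([1, 2] * (n // 2) + [1] * (n % 2))
    rng.shuffle(intervals)
    return intervals


def run_session(
    observer: TemplateObserver,
    condition: Condition,
    config: SessionConfig | None = None,
    rng=None,
) -> list[TrialRecord]:
    """One condition block: four interleaved staircases, 75 trials each.

    The staircase presented on each trial is drawn at random from the
    unfinished ones; the signal interval is balanced-random over the session.
    Identical seeds reproduce bit-identical trial logs.
    """
    config = config or SessionConfig()
    rng = np.random.default_rng(rng)
    if config.start_log_contrast is None:
        start = math.log10(analytic_threshold(observer, condition)) + 0.6
    else:
        start = config.start_log_contrast
    start = min(start, 0.0)
    staircases = [
        make_staircase(2, start, initial_step=config.initial_step,
                       final_step=config.final_step, max_trials=config.n_per_staircase),
        make_staircase(2, start, initial_step=config.initial_step,
                       final_step=config.final_step, max_trials=config.n_per_staircase),
        make_staircase(4, start + config.start_offset_84, initial_step=config.initial_step,
                       final_step=config.final_step, max_trials=config.n_per_staircase),
        make_staircase(4, start + config.start_offset_84, initial_step=config.initial_step,
                       final_step=config.final_step, max_trials=config.n_per_staircase),
    ]
    n_total = 4 * config.n_per_staircase
    intervals = _balanced_intervals(n_total, rng)
    records: list[TrialRecord] = []
    for t in range(n_total):
        active = [i for i, s in enumerate(staircases) if not s.finished]
        i = active[rng.integers(len(active))]
        state = staircases[i]
        rec = present_trial(
            observer,
            condition,
            10.0**state.log_contrast,
            int(intervals[t]),
            rng,
            staircase=i,
        )
        records.append(rec)
        staircases[i] = staircase_update(state, rec.correct)
    return records


def run_fixed_contrast_session(
    observer: TemplateObserver,
    condition: Condition,
    contrast: float,
    n_trials: int,
    rng=None,
) -> list[TrialRecord]:
    """Constant-contrast trials for classification imaging (typically 2500)."""
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    rng = np.random.default_rng(rng)
    intervals = _balanced_intervals(n_trials, rng)
    return [
        present_trial(observer, condition, contrast, int(intervals[t]), rng)
        for t in range(n_trials)
    ]


# ---------------------------------------------------------------------------
# psychometric fitting
# ---------------------------------------------------------------------------


@dataclass
class PsychometricFit:
    """Cumulative-normal fit on log10 contrast, guessing rate anchored at 0.5."""

    mu: float
    sigma: float
    threshold_75: float
    se_mu: float
    n_trials: int
    converged: bool
    log_likelihood: float
    guess: float = 0.5
    lapse: float = 0.0

    def predict(self, contrast):
        z = (np.log10(np.asarray(contrast, dtype=float)) - self.mu) / self.sigma
        return self.guess + (1.0 - self.guess - self.lapse) * ndtr(z)


_MAX_LAPSE = 0.06


def _nll_factory(x, y, guess, lapse):
    # aggregate to unique contrast levels: the Bernoulli likelihood depends on
    # the data only through per-level (n, k), and staircases revisit few levels
    levels, inverse = np.unique(np.round(x, 12), return_inverse=True)
    n_per = np.bincount(inverse).astype(float)
    k_per = np.bincount(inverse, weights=y)
    free_lapse = lapse == "free"

    def nll(theta):
        mu, log_sigma = theta[0], theta[1]
        lam = _MAX_LAPSE * expit(theta[2]) if free_lapse else lapse
        sigma = np.exp(np.clip(log_sigma, -12.0, 6.0))
        p = guess + (1.0 - guess - lam) * ndtr((levels - mu) / sigma)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return -float(np.sum(k_per * np.log(p) + (n_per - k_per) * np.log(1 - p)))

    return nll


def _fd_hessian(f, theta, h=1e-4):
    theta = np.asarray(theta, dtype=float)
    k = theta.size
    H = np.zeros((k, k))
    steps = h * (1.0 + np.abs(theta))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def fit_psychometric(
    trials: list[TrialRecord], guess: float = 0.5, lapse: float | str = "free"
) -> PsychometricFit:
    """ML cumulative-normal fit of proportion correct versus log10 contrast.

    ``lapse`` is either a fixed value or ``"free"`` (default), in which case a
    lapse rate bounded at 6% is estimated jointly with location and spread;
    a free lapse keeps occasional high-contrast errors from inflating the
    fitted spread and biasing the threshold.  The 75% threshold inverts the
    fitted curve (it equals the location when ``guess=0.5`` and the lapse is
    0).  Degenerate data (all correct, all incorrect, or a single contrast
    level) raise ``ValueError``.
    """
    x = np.log10([t.contrast for t in trials])
    y = np.array([t.correct for t in trials], dtype=float)
    if len(trials) == 0:
        raise ValueError("no trials to fit")
    if y.min() == y.max():
        raise ValueError("degenerate data: all responses are identical")
    if np.unique(np.round(x, 12)).size < 2:
        raise ValueError("need at least 2 distinct contrast levels")
    free_lapse = lapse == "free"

    nll = _nll_factory(x, y, guess, lapse)
    sig0 = max(float(np.std(x)), 0.05)
    best = None
    for mu0 in (float(np.median(x)), float(np.quantile(x, 0.75))):
        x0 = [mu0, np.log(sig0)] + ([float(logit(0.2))] if free_lapse else [])
        res = minimize(nll, np.array(x0), method="Nelder-Mead",
                       options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x[0], best.x[1]
    sigma = float(np.exp(log_sigma))
    lam = float(_MAX_LAPSE * expit(best.x[2])) if free_lapse else float(lapse)

    # SE of the location from the (mu, log sigma) Hessian block, conditioning
    # on the fitted lapse: the lapse is weakly identified on staircase data
    # and makes the full Hessian near-singular
    se_mu = np.nan
    nll2 = _nll_factory(x, y, guess, lam)
    try:
        H = _fd_hessian(nll2, best.x[:2])
        cov = np.linalg.inv(H)
        if np.isfinite(cov[0, 0]) and cov[0, 0] > 0:
            se_mu = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        pass

    target = (0.75 - guess) / (1.0 - guess - lam)
    if not (0.0 < target < 1.0):
        raise ValueError("75% point lies outside the fitted curve's range")
    threshold = 10.0 ** (mu + sigma * float(ndtri(target)))
    return PsychometricFit(
        mu=float(mu),
        sigma=sigma,
        threshold_75=threshold,
        se_mu=se_mu,
        n_trials=len(trials),
        converged=bool(best.success),
        log_likelihood=-float(best.fun),
        guess=guess,
        lapse=lam,
    )


# ---------------------------------------------------------------------------
# trial-log I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "condition", "staircase", "contrast", "signal_interval",
    "choice", "correct", "seed1", "seed2", "signal_seed",
]


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(t, c) for c in _COLUMNS} for t in trials])


def save_trials(trials: list[TrialRecord], path: str | Path | io.IOBase) -> None:
    trials_to_frame(trials).to_csv(path, index=False)


def load_trials(path: str | Path | io.IOBase) -> list[TrialRecord]:
    df = pd.read_csv(path)
    return [
        TrialRecord(
            condition=str(r.condition),
            staircase=int(r.staircase),
            contrast=float(r.contrast),
            signal_interval=int(r.signal_interval),
            choice=int(r.choice),
            correct=bool(r.correct),
            seed1=int(r.seed1),
            seed2=int(r.seed2),
            signal_seed=int(r.signal_seed),
        )
        for r in df.itertuples()
    ]
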