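"""Synthetic observers for the 2-IFC noise-in-noise detection task.

Every observer is a linear template on the stimulus *power spectrum*: the
decision variable for an interval is the template-weighted sum of DFT power
(each conjugate pair counted once) plus optional zero-mean Gaussian internal
noise, and the observer chooses the interval with the larger value.

The ideal observer for detecting flat-spectrum Gaussian signal noise in
Gaussian white noise is the in-band energy detector: uniform positive weights
on the signal band, no internal noise.  (For Gaussian stimuli with flat
in-band spectra the likelihood ratio is a monotone function of in-band power,
so the energy sum is the optimal statistic.)  Human-proxy observers use
difference-of-Gaussians orientation templates extruded over the signal's SF
annulus, optionally with an inhibitory low-SF disk.

Because each DFT coefficient of a Gaussian field is complex Gaussian, per-bin
power is exponentially distributed, which gives closed forms for the decision
variable's mean and variance.  These power analytic predictions (percent
correct, detection threshold, matched-template efficiency) serve as the
independent oracle against which the Monte-Carlo machinery is checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .conditions import Condition
from .dog import DoGParams, dog_eval
from .stimulus import FilterSpec, FourierGrid, band_mask, gaussian_envelope

__all__ = [
    "TemplateObserver",
    "DoGTemplateSpec",
    "ideal_template",
    "dog_template",
    "decide_2ifc",
    "analytic_dprime",
    "analytic_percent_correct",
    "analytic_threshold",
    "matched_template_efficiency",
    "calibrate_internal_noise",
]


@dataclass
class TemplateObserver:
    """Linear template over power-spectrum bins plus internal decision noise.

    ``weights`` is conjugate-symmetric and laid out in FFT order.  The
    response to a power spectrum sums each conjugate pair once, implemented as
    half the full weighted sum (self-conjugate bins carry zero weight in every
    template built here).
    """

    weights: np.ndarray
    internal_noise_sd: float = 0.0
    label: str = ""

    def response(self, power: np.ndarray) -> float:
        if power.shape != self.weights.shape:
            raise ValueError(
                f"power spectrum shape {power.shape} does not match template {self.weights.shape}"
            )
        return 0.5 * float(np.sum(self.weights * power))

    def _folded_weights(self) -> np.ndarray:
        """Weights folded onto the rfft half-spectrum (conjugate columns doubled)."""
        cached = getattr(self, "_folded", None)
        if cached is None:
            n = self.weights.shape[0]
            fw = self.weights[:, : n // 2 + 1].copy()
            fw[:, 1 : n // 2] *= 2.0
            object.__setattr__(self, "_folded", fw)
            cached = fw
        return cached

    def response_half(self, power_half: np.ndarray) -> float:
        """Template response from the non-redundant rfft2 power half-spectrum."""
        return 0.5 * float(np.sum(self._folded_weights() * power_half))


def ideal_template(grid: FourierGrid, spec: FilterSpec) -> TemplateObserver:
    """The in-band energy detector: weight 1 on the signal band, 0 elsewhere."""
    mask = band_mask(grid, spec)
    if not mask.any():
        raise ValueError("signal band is empty on this grid")
    return TemplateObserver(weights=mask.astype(float), label="ideal")


@dataclass(frozen=True)
class DoGTemplateSpec:
    """A DoG orientation profile extruded over an SF annulus.

    ``low_sf_weight`` (typically negative) optionally fills a disk of radius
    ``low_sf_radius`` cy/deg around (but excluding) DC, emulating suppression
    from uninformative low spatial frequencies.
    """

    dog: DoGParams
    center_sf: float = 5.0
    sf_bandwidth: float = 1.0
    low_sf_weight: float = 0.0
    low_sf_radius: float = 0.0


def dog_template(
    grid: FourierGrid, spec: DoGTemplateSpec, internal_noise_sd: float = 0.0, label: str = "dog"
) -> TemplateObserver:
    """Template whose weight at each in-annulus bin is the DoG at that bin's orientation."""
    annulus = band_mask(
        grid,
        FilterSpec(
            center_sf=spec.center_sf,
            sf_bandwidth=spec.sf_bandwidth,
            ori_bandwidth_2sided=180.0,
        ),
    )
    weights = np.zeros((grid.size, grid.size))
    weights[annulus] = dog_eval(spec.dog, grid.orientation[annulus])
    if spec.low_sf_weight != 0.0 and spec.low_sf_radius > 0.0:
        disk = (grid.sf <= spec.low_sf_radius) & grid.valid
        weights[disk] = spec.low_sf_weight
    return TemplateObserver(weights=weights, internal_noise_sd=internal_noise_sd, label=label)


def decide_2ifc(
    observer: TemplateObserver,
    power_spec_1: np.ndarray,
    power_spec_2: np.ndarray,
    rng: np.random.Generator | None = None,
) -> int:
    """Choose the interval with the larger noisy template response.

    Ties break toward interval 1 so that replays are deterministic.  With
    ``internal_noise_sd == 0`` the decision is fully determined by the spectra.
    Spectra may be given on the full FFT grid or as rfft2 half-spectra.
    """
    if power_spec_1.shape != power_spec_2.shape:
        raise ValueError("the two power spectra must share one shape")
    n = observer.weights.shape[0]
    if power_spec_1.shape == (n, n // 2 + 1):
        v1 = observer.response_half(power_spec_1)
        v2 = observer.response_half(power_spec_2)
    else:
        v1 = observer.response(power_spec_1)
        v2 = observer.response(power_spec_2)
    if observer.internal_noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when internal_noise_sd > 0")
        noise = rng.normal(0.0, observer.internal_noise_sd, size=2)
        v1 += noise[0]
        v2 += noise[1]
    return 1 if v1 >= v2 else 2


# ---------------------------------------------------------------------------
# closed-form performance of template observers
# ---------------------------------------------------------------------------


def _signal_power_per_bin(condition: Condition, contrast: float) -> float:
    """Mean per-bin DFT power the signal adds inside its band.

    The filtered noise is scaled to sample RMS ``contrast`` and then (by
    default) windowed; the envelope multiplies total signal energy by the mean
    squared envelope.  Total DFT power ``N^2 * sum(x^2)`` is spread evenly over
    the ``2K`` band bins (the filtered spectrum is flat in band).
    """
    n = condition.size
    if condition.envelope_signal:
        env = gaussian_envelope(n, condition.envelope_sd_deg, condition.px_per_deg)
        energy_factor = float(np.mean(env**2))
    else:
        energy_factor = 1.0
    total_power = n**4 * contrast**2 * energy_factor
    return total_power / (2.0 * condition.n_components)


def analytic_dprime(observer: TemplateObserver, condition: Condition, contrast: float) -> float:
    """Closed-form d' of a template observer at a given signal contrast.

    Per half-plane bin the power is exponential with mean ``m`` (mask) or
    ``m + s`` (mask plus signal, both Gaussian and independent), so the
    template sum has mean ``sum(w * mean)`` and variance ``sum(w^2 * mean^2)``.
    """
    w = observer.weights
    band = condition.band
    n = condition.size
    m = n**2 * condition.mask_variance
    s = _signal_power_per_bin(condition, contrast)
    mean_diff = 0.5 * s * float(np.sum(w * band))
    var_blank = 0.25 * float(np.sum(w**2)) * m**2
    var_signal = 0.25 * float(np.sum(w**2 * (m + s * band) ** 2))
    var = var_blank + var_signal + 2.0 * observer.internal_noise_sd**2
    return mean_diff / np.sqrt(var)


def analytic_percent_correct(
    observer: TemplateObserver, condition: Condition, contrast: float
) -> float:
    """2-IFC proportion correct from the analytic d': ``Phi(d'/sqrt(2))``."""
    return float(ndtr(analytic_dprime(observer, condition, contrast) / np.sqrt(2.0)))


def analytic_threshold(
    observer: TemplateObserver, condition: Condition, pc: float = 0.75
) -> float:
    """RMS contrast at which the analytic proportion correct equals ``pc``."""
    if not (0.5 < pc < 1.0):
        raise ValueError("pc must lie in (0.5, 1)")
    if float(np.sum(observer.weights * condition.band)) <= 0:
        raise ValueError("template has no net positive weight on the signal band")

    def f(log_c):
        return analytic_percent_correct(observer, condition, 10.0**log_c) - pc

    lo, hi = -6.0, 1.0
    if f(hi) < 0:
        raise ValueError("observer cannot reach the target accuracy at contrast 10")
    return 10.0 ** brentq(f, lo, hi, xtol=1e-10)


def matched_template_efficiency(weights: np.ndarray, band: np.ndarray) -> float:
    """Small-signal efficiency of a template relative to the in-band ideal.

    In the weak-signal limit the squared d' ratio reduces to
    ``(sum_band w)^2 / (K * sum w^2)`` with ``K`` the number of independent
    band components; a matched template (w proportional to the band mask)
    gives exactly 1.
    """
    k = int(band.sum()) / 2.0
    num = float(np.sum(weights * band)) ** 2
    den = k * 2.0 * float(np.sum(weights**2))
    return num / den


def calibrate_internal_noise(
    observer: TemplateObserver,
    condition: Condition,
    contrast: float,
    target_pc: float,
    *,
    sd_hi: float | None = None,
) -> float:
    """Internal-noise SD at which the observer's analytic accuracy hits ``target_pc``."""
    noiseless = TemplateObserver(observer.weights, 0.0, observer.label)
    pc0 = analytic_percent_correct(noiseless, condition, contrast)
    if target_pc >= pc0:
        raise ValueError(
            f"target accuracy {target_pc:.3f} is not below the noiseless accuracy {pc0:.3f}"
        )
    if sd_hi is None:
        # variance of the noiseless decision variable sets the natural scale
        n = condition.size
        m = n**2 * condition.mask_variance
        sd_hi = 100.0 * np.sqrt(0.25 * float(np.sum(observer.weights**2)) * m**2)

    def f(sd):
        probe = TemplateObserver(observer.weights, sd, observer.label)
        return analytic_percent_correct(probe, condition, contrast) - target_pc

    return float(brentq(f, 0.0, sd_hi, xtol=1e-12))
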