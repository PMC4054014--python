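"""Figure helpers: TvB functions, classification images, profiles, trends."""

from __future__ import annotations

import numpy as np
import matplotlib.pyplot as plt

from .classimg import ClassificationImage, OrientationProfile
from .dog import BandwidthTrend, DoGFit, dog_eval

__all__ = [
    "plot_tvb",
    "plot_classification_image",
    "plot_profile_fit",
    "plot_bandwidth_trend",
]


def plot_tvb(df, fit, ax=None):
    """Log-log threshold versus component count with the fitted power law."""
    if ax is None:
        _, ax = plt.subplots()
    ax.loglog(df.n_components, df.threshold, "ko", label="thresholds")
    xs = np.geomspace(df.n_components.min(), df.n_components.max(), 50)
    ax.loglog(xs, fit.predict(xs), "b-", label=f"slope {fit.exponent:.3f}")
    if fit.ci is not None:
        ax.set_title(f"TvB exponent {fit.exponent:.3f} (95% CI {fit.ci[0]:.3f}-{fit.ci[1]:.3f})")
    ax.set_xlabel("number of Fourier components")
    ax.set_ylabel("RMS contrast threshold")
    ax.legend()
    return ax


def plot_classification_image(ci: ClassificationImage, ax=None):
    """Gray map of a CI, median gray = 0, display rotated so the center row is horizontal."""
    if ax is None:
        _, ax = plt.subplots()
    # display convention: horizontal stimulus orientations along the central
    # horizontal row requires rotating the frequency-plane image by 90 deg
    img = np.rot90(ci.weights)
    v = np.max(np.abs(img))
    ax.imshow(img, cmap="gray", vmin=-v, vmax=v)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def plot_profile_fit(profile: OrientationProfile, fit: DoGFit | None = None, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    w = profile.weights
    peak = w.max() if w.max() > 0 else 1.0
    ax.plot(profile.angles, w / peak, "k:", label="profile")
    if fit is not None:
        xs = np.linspace(-90, 90, 361)
        ax.plot(xs, dog_eval(fit.params, xs), "r-", label="DoG fit")
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel("weight (peak-normalized)")
    ax.legend()
    return ax


def plot_bandwidth_trend(fits_by_bandwidth: dict, trend: BandwidthTrend, ax=None):
    if ax is None:
        _, ax = plt.subplots()
    bws = sorted(fits_by_bandwidth)
    for name, color in (("sigma_e", "tab:blue"), ("sigma_i", "tab:red")):
        vals = [getattr(fits_by_bandwidth[bw].params, name) for bw in bws]
        ax.plot(bws, vals, "o", color=color, label=name)
        for bw in bws:
            fit = fits_by_bandwidth[bw]
            if fit.ci is not None:
                lo, hi = fit.ci[name]
                ax.plot([bw, bw], [lo, hi], "-", color=color, alpha=0.5)
    xs = np.linspace(min(bws), max(bws), 20)
    ax.plot(xs, trend.predict_e(xs), "-", color="tab:blue")
    ax.plot(xs, trend.predict_i(xs), "-", color="tab:red")
    ax.set_xlabel("stimulus orientation bandwidth (deg)")
    ax.set_ylabel("fitted SD (deg)")
    ax.legend()
    return ax
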