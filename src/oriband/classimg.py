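"""Power-spectrum classification images from fixed-contrast 2-IFC trials.

On each trial the power spectrum of the noise mask in each interval is
computed (mask alone by default; optionally mask plus signal), the difference
``P(signal interval) - P(non-signal interval)`` is formed, and the difference
spectrum is accumulated into one of four bins defined by the signal interval
(1 or 2) and the correctness of the response.  The per-bin averages are then
combined - the two correct-bin averages averaged, likewise the two
incorrect-bin averages - and the classification image is the correct minus
incorrect average, normalized to a peak magnitude of one.  For a linear
template observer this estimate is proportional to the generating template.

Images are stored in *centered* layout (DC at index ``size//2``) so that
cropping, smoothing, and display are straightforward; the conjugate symmetry
of real-field power spectra makes the two half-planes redundant, and the 1-D
orientation profile is accumulated over one half-plane only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve1d

from .conditions import Condition
from .stimulus import power_spectrum

__all__ = [
    "ClassificationImage",
    "OrientationProfile",
    "GridMaps",
    "compute_classification_image",
    "difference_spectra",
    "raw_classification_image",
    "crop_center",
    "smooth",
    "smooth_array",
    "make_collapse_operator",
    "collapse_to_orientation",
    "TRIANGULAR5",
]

#: the separable 5-tap triangular smoothing kernel (sums to 1 per axis)
TRIANGULAR5 = np.array([1.0, 2.0, 3.0, 2.0, 1.0]) / 9.0


@dataclass(frozen=True)
class GridMaps:
    """Coordinate maps in centered layout, cropped alongside the image."""

    sf: np.ndarray
    orientation: np.ndarray
    half_plane: np.ndarray
    px_per_deg: float

    @property
    def size(self) -> int:
        return self.sf.shape[0]

    @property
    def max_axis_sf(self) -> float:
        """Highest spatial frequency retained along a frequency axis (cy/deg)."""
        c = self.size // 2
        return float(max(self.sf[c, 0], self.sf[0, c]))


def _centered_maps(condition: Condition) -> GridMaps:
    g = condition.grid
    return GridMaps(
        sf=np.fft.fftshift(g.sf),
        orientation=np.fft.fftshift(g.orientation),
        half_plane=np.fft.fftshift(g.half_plane),
        px_per_deg=g.px_per_deg,
    )


def _crop_slice(size: int, out_size: int) -> slice:
    if out_size > size:
        raise ValueError(f"crop size {out_size} exceeds image size {size}")
    c = size // 2
    return slice(c - out_size // 2, c - out_size // 2 + out_size)


@dataclass
class ClassificationImage:
    """2-D per-component decision-weight map (centered layout)."""

    weights: np.ndarray
    maps: GridMaps
    n_per_bin: dict[tuple[int, bool], int]
    smoothed: bool = False
    normalized: bool = True
    se: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.weights.shape[0]

    @property
    def max_axis_sf(self) -> float:
        return self.maps.max_axis_sf

    @property
    def n_trials(self) -> int:
        return sum(self.n_per_bin.values())


@dataclass
class OrientationProfile:
    """1-D circular sum of a classification image: 180 one-degree orientation bins.

    ``angles`` are bin lower edges in degrees relative to the center
    orientation, running from -90 to +89.
    """

    angles: np.ndarray
    weights: np.ndarray
    counts: np.ndarray
    sf_band: tuple[float, float]


# ---------------------------------------------------------------------------
# per-trial difference spectra
# ---------------------------------------------------------------------------


def difference_spectra(
    trials,
    condition: Condition,
    *,
    include_signal: bool = False,
    crop: int | None = None,
    dtype=np.float32,
):
    """Recompute every trial's difference spectrum from its stored seeds.

    Returns ``(diffs, sig, correct, maps)`` where ``diffs`` is an
    ``(n, h, w)`` array of centered (optionally cropped) difference spectra
    ``P(signal interval) - P(non-signal interval)``, and ``sig``/``correct``
    give each trial's signal interval and outcome.  ``include_signal=True``
    adds the regenerated signal to the signal interval's mask before the
    transform (the on-screen stimulus); the default follows the mask-alone
    convention.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials supplied")
    maps = _centered_maps(condition)
    sl = _crop_slice(condition.size, crop) if crop is not None else slice(None)
    if crop is not None:
        maps = GridMaps(
            sf=maps.sf[sl, sl],
            orientation=maps.orientation[sl, sl],
            half_plane=maps.half_plane[sl, sl],
            px_per_deg=maps.px_per_deg,
        )
    out_size = maps.size
    n = len(trials)
    diffs = np.empty((n, out_size, out_size), dtype=dtype)
    sig = np.empty(n, dtype=np.int8)
    correct = np.empty(n, dtype=bool)
    for k, t in enumerate(trials):
        m1 = condition.mask_patch(t.seed1).data
        m2 = condition.mask_patch(t.seed2).data
        if include_signal:
            s = condition.signal_patch(t.contrast, t.signal_seed).data
            if t.signal_interval == 1:
                m1 = m1 + s
            else:
                m2 = m2 + s
        p1 = np.fft.fftshift(power_spectrum(m1))[sl, sl]
        p2 = np.fft.fftshift(power_spectrum(m2))[sl, sl]
        d = p1 - p2 if t.signal_interval == 1 else p2 - p1
        diffs[k] = d
        sig[k] = t.signal_interval
        correct[k] = t.correct
    return diffs, sig, correct, maps


def raw_classification_image(
    diffs: np.ndarray, sig: np.ndarray, correct: np.ndarray, idx=None
) -> np.ndarray:
    """Unnormalized CI from cached difference spectra (optionally resampled).

    The four (signal interval x correctness) bin means are combined as
    ``(mean(correct bins) - mean(incorrect bins))``; an empty bin raises with
    the bin named.
    """
    if idx is not None:
        diffs, sig, correct = diffs[idx], sig[idx], correct[idx]
    halves = []
    for want_correct in (True, False):
        parts = []
        for interval in (1, 2):
            m = (sig == interval) & (correct == want_correct)
            if not m.any():
                raise ValueError(
                    f"empty classification-image bin: signal interval {interval}, "
                    f"{'correct' if want_correct else 'incorrect'} responses"
                )
            parts.append(diffs[m].mean(axis=0, dtype=np.float64))
        halves.append(0.5 * (parts[0] + parts[1]))
    return halves[0] - halves[1]


def _normalize(ci: np.ndarray, band: np.ndarray | None = None) -> np.ndarray:
    """Scale to peak magnitude 1 with the signal band forced positive.

    The sign is set so that the mean value over the signal-band bins is
    positive (falling back to the sign of the global extremum when no band is
    given); the magnitude is the absolute extremum.
    """
    peak = float(np.max(np.abs(ci)))
    if peak == 0:
        raise ValueError("classification image is identically zero")
    if band is not None and band.any():
        sign = 1.0 if float(ci[band].mean()) >= 0 else -1.0
    else:
        sign = 1.0 if ci.ravel()[int(np.argmax(np.abs(ci)))] >= 0 else -1.0
    return ci * (sign / peak)


def compute_classification_image(
    trials,
    condition: Condition,
    *,
    include_signal: bool = False,
    normalize: bool = True,
    with_se: bool = False,
    crop: int | None = None,
) -> ClassificationImage:
    """Full pipeline from trial records to a (peak-normalized) 2-D CI."""
    diffs, sig, correct, maps = difference_spectra(
        trials, condition, include_signal=include_signal, crop=crop
    )
    ci = raw_classification_image(diffs, sig, correct)
    n_per_bin = {
        (interval, want): int(((sig == interval) & (correct == want)).sum())
        for interval in (1, 2)
        for want in (True, False)
    }
    se = None
    scale = 1.0
    if normalize:
        scale = float(np.max(np.abs(ci)))
        band = np.fft.fftshift(condition.band)
        if crop is not None:
            sl = _crop_slice(condition.size, crop)
            band = band[sl, sl]
        ci = _normalize(ci, band=band)
    if with_se:
        var = np.zeros_like(ci, dtype=np.float64)
        for interval in (1, 2):
            for want in (True, False):
                m = (sig == interval) & (correct == want)
                var += diffs[m].var(axis=0, dtype=np.float64, ddof=1) / m.sum() / 4.0
        se = np.sqrt(var) / scale
    return ClassificationImage(
        weights=ci, maps=maps, n_per_bin=n_per_bin, normalized=normalize, se=se
    )


# ---------------------------------------------------------------------------
# crop / smooth / collapse
# ---------------------------------------------------------------------------


def crop_center(ci: ClassificationImage, out_size: int = 64) -> ClassificationImage:
    """Retain the central ``out_size x out_size`` region around DC."""
    sl = _crop_slice(ci.size, out_size)
    maps = GridMaps(
        sf=ci.maps.sf[sl, sl],
        orientation=ci.maps.orientation[sl, sl],
        half_plane=ci.maps.half_plane[sl, sl],
        px_per_deg=ci.maps.px_per_deg,
    )
    return replace(
        ci,
        weights=ci.weights[sl, sl],
        maps=maps,
        se=None if ci.se is None else ci.se[sl, sl],
    )


def smooth_array(a: np.ndarray, kernel: np.ndarray = TRIANGULAR5) -> np.ndarray:
    """Separable 2-D convolution with the triangular kernel, reflecting at edges."""
    out = convolve1d(a, kernel, axis=0, mode="reflect")
    return convolve1d(out, kernel, axis=1, mode="reflect")


def smooth(ci: ClassificationImage, kernel: str | np.ndarray = "triangular5") -> ClassificationImage:
    """Smooth a CI with the 5x5 triangular kernel (linear interpolation)."""
    if isinstance(kernel, str):
        if kernel != "triangular5":
            raise ValueError(f"unknown kernel {kernel!r}")
        k = TRIANGULAR5
    else:
        k = np.asarray(kernel, dtype=float)
        if not np.isclose(k.sum(), 1.0):
            raise ValueError("kernel must be normalized to sum 1")
    return replace(ci, weights=smooth_array(ci.weights, k), smoothed=True, se=None)


class _CollapseOperator:
    """Precomputed mapping from a 2-D CI to its 1-D orientation profile."""

    def __init__(self, maps: GridMaps, sf_band: tuple[float, float], center_ori: float):
        self.angles = np.arange(-90.0, 90.0)
        self.sf_band = sf_band
        sel = (
            maps.half_plane
            & (maps.sf >= sf_band[0])
            & (maps.sf <= sf_band[1])
            & (maps.sf > 0)
        )
        rel = (maps.orientation - center_ori + 90.0) % 180.0 - 90.0
        idx = np.floor(rel).astype(int) + 90
        idx = np.clip(idx, 0, 179)
        self._sel = sel.ravel()
        self._idx = idx.ravel()[self._sel]
        self.counts = np.bincount(self._idx, minlength=180)

    def __call__(self, ci_array: np.ndarray) -> np.ndarray:
        return np.bincount(self._idx, weights=ci_array.ravel()[self._sel], minlength=180)


def make_collapse_operator(
    maps: GridMaps, sf_band=None, center_ori: float = 0.0
) -> _CollapseOperator:
    if sf_band is None:
        sf_band = (0.0, maps.max_axis_sf)
    return _CollapseOperator(maps, tuple(sf_band), center_ori)


def collapse_to_orientation(
    ci: ClassificationImage, sf_band=None, center_ori: float = 0.0
) -> OrientationProfile:
    """Sum CI values in 1-deg orientation steps across an SF band.

    Only one conjugate half-plane is accumulated.  ``sf_band`` defaults to the
    full retained range (DC to the crop's maximum axis frequency).  Orientation
    bins containing no Fourier bin (possible on coarse grids) are reported as 0
    with a warning.
    """
    op = make_collapse_operator(ci.maps, sf_band, center_ori)
    weights = op(ci.weights)
    if (op.counts == 0).any():
        warnings.warn(
            f"{int((op.counts == 0).sum())} orientation bins contain no Fourier "
            "component on this grid; their profile values are 0",
            stacklevel=2,
        )
    return OrientationProfile(
        angles=op.angles, weights=weights, counts=op.counts, sf_band=op.sf_band
    )
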