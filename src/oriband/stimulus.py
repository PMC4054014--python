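"""Fourier-domain synthesis of band-limited noise targets and white-noise masks.

The stimuli are two-dimensional Gaussian white-noise fields, optionally passed
through ideal (hard-edged) spatial-frequency and orientation filters in the
Fourier domain.  All geometry lives on a :class:`FourierGrid`, which maps every
DFT bin of a square ``size x size`` patch to a radial spatial frequency (cy/deg)
and a grating orientation (degrees).

Orientation convention
----------------------
``0 deg`` denotes a *horizontally oriented grating*, i.e. a grating whose bars
are horizontal and whose frequency vector points along the vertical frequency
axis.  Orientation of the bin with frequency vector ``(fx, fy)`` is therefore
``(atan2(fy, fx) + 90) mod 180`` degrees - a fixed 90 deg rotation relative to
the geometric angle of the frequency vector.  The convention is applied once
here; display/export code may rotate for presentation but the library never
does.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "FourierGrid",
    "FilterSpec",
    "NoisePatch",
    "make_fourier_grid",
    "band_mask",
    "component_count",
    "synthesize_filtered_noise",
    "gaussian_envelope",
    "apply_gaussian_envelope",
    "make_white_noise_mask",
    "power_spectrum",
    "wrapped_ori_distance",
]

#: tolerance used when comparing a bin's coordinates against a passband edge;
#: a bin lying exactly on the edge is included (closed passband).
_EDGE_TOL = 1e-9


def wrapped_ori_distance(a, b):
    """Absolute orientation difference wrapped to the 180-deg orientation circle."""
    return np.abs((np.asarray(a, dtype=float) - b + 90.0) % 180.0 - 90.0)


@dataclass(frozen=True)
class FourierGrid:
    """Spatial-frequency / orientation coordinates of a square DFT.

    Arrays are laid out in numpy FFT order (DC at index ``[0, 0]``); use
    ``np.fft.fftshift`` for display.  ``size`` must be even so that the
    Nyquist row/column is unambiguous.
    """

    size: int
    px_per_deg: float

    def __post_init__(self):
        if self.size <= 0 or self.size % 2 != 0:
            raise ValueError(f"size must be a positive even integer, got {self.size}")
        if self.px_per_deg <= 0:
            raise ValueError(f"px_per_deg must be positive, got {self.px_per_deg}")

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in cy/deg."""
        return self.px_per_deg / 2.0

    @property
    def resolution(self) -> float:
        """Frequency step between adjacent bins, cy/deg."""
        return self.px_per_deg / self.size

    @cached_property
    def fy(self) -> np.ndarray:
        """Vertical frequency component per bin (cy/deg), FFT layout."""
        f = np.fft.fftfreq(self.size) * self.px_per_deg
        return np.broadcast_to(f[:, None], (self.size, self.size)).copy()

    @cached_property
    def fx(self) -> np.ndarray:
        """Horizontal frequency component per bin (cy/deg), FFT layout."""
        f = np.fft.fftfreq(self.size) * self.px_per_deg
        return np.broadcast_to(f[None, :], (self.size, self.size)).copy()

    @cached_property
    def sf(self) -> np.ndarray:
        """Radial spatial frequency per bin (cy/deg); 0 at DC."""
        return np.hypot(self.fx, self.fy)

    @cached_property
    def orientation(self) -> np.ndarray:
        """Grating orientation per bin, degrees in [0, 180); 0 = horizontal grating.

        The DC bin has no defined orientation; it is reported as 0 but is
        excluded from every band mask.
        """
        ori = (np.degrees(np.arctan2(self.fy, self.fx)) + 90.0) % 180.0
        ori[0, 0] = 0.0
        return ori

    @cached_property
    def valid(self) -> np.ndarray:
        """Bins usable in band masks: DC and the Nyquist row/column excluded.

        No orientation is defined at DC, and Nyquist bins lack distinct
        conjugate partners.
        """
        v = np.ones((self.size, self.size), dtype=bool)
        v[0, 0] = False
        v[self.size // 2, :] = False
        v[:, self.size // 2] = False
        return v

    @cached_property
    def half_plane(self) -> np.ndarray:
        """One representative bin per conjugate pair (fy > 0, or fy == 0 and fx > 0)."""
        return (self.fy > 0) | ((self.fy == 0) & (self.fx > 0))


def make_fourier_grid(size: int, px_per_deg: float) -> FourierGrid:
    """Construct the frequency/orientation coordinate maps for a square patch."""
    return FourierGrid(size=size, px_per_deg=px_per_deg)


@dataclass(frozen=True)
class FilterSpec:
    """Geometry of an ideal (hard-edged) SF x orientation passband.

    ``ori_bandwidth_2sided`` is the *two-sided* orientation bandwidth: a 16 deg
    filter centered on horizontal passes orientations from -8 to +8 deg.  The
    SF passband spans ``center_sf * 2**(+-sf_bandwidth/2)`` (closed at both
    edges).
    """

    center_sf: float
    sf_bandwidth: float
    center_ori: float = 0.0
    ori_bandwidth_2sided: float = 180.0

    def __post_init__(self):
        if self.center_sf <= 0:
            raise ValueError("center_sf must be positive")
        if self.sf_bandwidth <= 0:
            raise ValueError("sf_bandwidth (octaves) must be positive")
        if not (0.0 < self.ori_bandwidth_2sided <= 180.0):
            raise ValueError(
                "ori_bandwidth_2sided must lie in (0, 180] degrees, "
                f"got {self.ori_bandwidth_2sided}"
            )

    @property
    def sf_lo(self) -> float:
        return self.center_sf * 2.0 ** (-self.sf_bandwidth / 2.0)

    @property
    def sf_hi(self) -> float:
        return self.center_sf * 2.0 ** (self.sf_bandwidth / 2.0)


def _conjugate(mask: np.ndarray) -> np.ndarray:
    """Mask evaluated at the negated-frequency bin of every bin."""
    return np.roll(mask[::-1, ::-1], (1, 1), axis=(0, 1))


def band_mask(grid: FourierGrid, spec: FilterSpec) -> np.ndarray:
    """Binary map of Fourier bins passed by an ideal SF x orientation filter.

    A bin is included iff its radial frequency lies in the closed SF passband
    and its orientation lies within +-``ori_bandwidth_2sided/2`` of the center
    orientation (180-deg wrapped, closed).  DC and Nyquist bins are always
    excluded, so the mask is exactly conjugate-symmetric.
    """
    if spec.sf_hi > grid.nyquist + _EDGE_TOL:
        raise ValueError(
            f"SF passband upper edge {spec.sf_hi:.4g} cy/deg exceeds the "
            f"Nyquist frequency {grid.nyquist:.4g} cy/deg"
        )
    sf_ok = (grid.sf >= spec.sf_lo - _EDGE_TOL) & (grid.sf <= spec.sf_hi + _EDGE_TOL)
    half_bw = spec.ori_bandwidth_2sided / 2.0
    ori_ok = wrapped_ori_distance(grid.orientation, spec.center_ori) <= half_bw + _EDGE_TOL
    mask = sf_ok & ori_ok & grid.valid
    # symmetrize: floating round-off at a passband edge must never split a
    # conjugate pair
    return mask | _conjugate(mask)


def component_count(mask: np.ndarray) -> int:
    """Number of independent Fourier components (conjugate pairs counted once)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("mask must be a square 2-D array")
    if not np.array_equal(mask, _conjugate(mask)):
        raise ValueError("mask is not conjugate-symmetric")
    n = mask.shape[0]
    self_idx = [(0, 0)]
    if n % 2 == 0:
        h = n // 2
        self_idx += [(0, h), (h, 0), (h, h)]
    n_self = sum(int(mask[i, j]) for i, j in self_idx)
    return (int(mask.sum()) - n_self) // 2 + n_self


@dataclass
class NoisePatch:
    """A noise image in Weber-contrast units with its provenance seed."""

    data: np.ndarray
    seed: int | None = None

    @property
    def rms(self) -> float:
        """Sample RMS contrast (root mean square about zero)."""
        return float(np.sqrt(np.mean(self.data**2)))

    @property
    def variance(self) -> float:
        return float(np.var(self.data))


def synthesize_filtered_noise(
    grid: FourierGrid,
    spec: FilterSpec | np.ndarray,
    target_rms: float,
    rng: np.random.Generator,
    *,
    seed: int | None = None,
) -> NoisePatch:
    """Band-limited Gaussian noise with sample RMS contrast exactly ``target_rms``.

    A white Gaussian field is transformed, zeroed outside the band mask,
    inverted, and rescaled so that the *sample* RMS equals the target.
    ``spec`` may be a :class:`FilterSpec` or a precomputed mask.
    """
    if target_rms < 0:
        raise ValueError("target_rms must be non-negative")
    mask = spec if isinstance(spec, np.ndarray) else band_mask(grid, spec)
    if target_rms == 0.0:
        return NoisePatch(np.zeros((grid.size, grid.size)), seed=seed)
    if not mask.any():
        raise ValueError("band mask is empty; cannot synthesize nonzero noise")
    n = grid.size
    white = rng.standard_normal((n, n))
    # conjugate symmetry of the mask makes the half-spectrum transform exact
    spectrum = np.fft.rfft2(white)
    spectrum[~mask[:, : n // 2 + 1]] = 0.0
    patch = np.fft.irfft2(spectrum, s=(n, n))
    rms = np.sqrt(np.mean(patch**2))
    patch *= target_rms / rms
    return NoisePatch(patch, seed=seed)


def gaussian_envelope(size: int, sd_deg: float, px_per_deg: float) -> np.ndarray:
    """Centered circular Gaussian window, peak 1 at pixel (size//2, size//2)."""
    if sd_deg <= 0:
        raise ValueError("sd_deg must be positive")
    sd_px = sd_deg * px_per_deg
    coords = np.arange(size) - size // 2
    r2 = coords[:, None] ** 2 + coords[None, :] ** 2
    return np.exp(-r2 / (2.0 * sd_px**2))


def apply_gaussian_envelope(patch: NoisePatch, sd_deg: float, px_per_deg: float) -> NoisePatch:
    """Modulate patch contrast with a circularly symmetric Gaussian envelope."""
    env = gaussian_envelope(patch.data.shape[0], sd_deg, px_per_deg)
    return NoisePatch(patch.data * env, seed=patch.seed)


def make_white_noise_mask(
    size: int,
    contrast_variance: float,
    rng: np.random.Generator,
    *,
    seed: int | None = None,
) -> NoisePatch:
    """I.i.d. Gaussian pixel noise with mean 0 and the given contrast variance."""
    if contrast_variance < 0:
        raise ValueError("contrast_variance must be non-negative")
    if contrast_variance == 0.0:
        return NoisePatch(np.zeros((size, size)), seed=seed)
    data = rng.standard_normal((size, size)) * np.sqrt(contrast_variance)
    return NoisePatch(data, seed=seed)


def power_spectrum(data: np.ndarray) -> np.ndarray:
    """Unnormalized DFT power |FFT(x)|^2, FFT layout.

    With this convention Parseval's relation reads
    ``sum(power) == size**2 * sum(data**2)``.
    """
    return np.abs(np.fft.fft2(data)) ** 2


def power_spectrum_half(data: np.ndarray) -> np.ndarray:
    """Power over the non-redundant half-spectrum (real input), rfft2 layout."""
    return np.abs(np.fft.rfft2(data)) ** 2
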