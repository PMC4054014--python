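"""Experimental conditions: the stimulus parameters of one bandwidth block.

A :class:`Condition` bundles everything needed to regenerate a trial's stimuli
from stored seeds: grid geometry, the signal filter, the white-noise mask
variance, and the signal envelope.  The study defaults are a 5 cy/deg center
frequency, one- or two-octave SF bandwidth, two-sided orientation bandwidths
between 2 and 180 deg about horizontal, a mask contrast variance of 0.32, and a
1.08-deg Gaussian signal envelope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import numpy as np
import yaml

from .stimulus import (
    FilterSpec,
    FourierGrid,
    NoisePatch,
    band_mask,
    component_count,
    make_white_noise_mask,
    synthesize_filtered_noise,
)

__all__ = [
    "Condition",
    "ORI_BANDWIDTHS",
    "CI_BANDWIDTHS",
    "study_conditions",
    "scaled_condition",
    "white_noise_condition",
    "load_conditions",
]

#: the seven two-sided orientation bandwidths of the threshold experiment (deg)
ORI_BANDWIDTHS = (2.0, 8.0, 16.0, 32.0, 64.0, 128.0, 180.0)

#: the three bandwidths of the classification-image experiment (deg)
CI_BANDWIDTHS = (2.0, 48.0, 90.0)


@dataclass(frozen=True)
class Condition:
    """One stimulus condition of the noise-in-noise detection task."""

    name: str
    ori_bandwidth: float
    sf_bandwidth: float = 1.0
    center_sf: float = 5.0
    center_ori: float = 0.0
    size: int = 512
    px_per_deg: float = 94.8
    mask_variance: float = 0.32
    envelope_sd_deg: float = 1.08
    envelope_signal: bool = True

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(
            center_sf=self.center_sf,
            sf_bandwidth=self.sf_bandwidth,
            center_ori=self.center_ori,
            ori_bandwidth_2sided=self.ori_bandwidth,
        )

    @cached_property
    def grid(self) -> FourierGrid:
        return FourierGrid(size=self.size, px_per_deg=self.px_per_deg)

    @cached_property
    def band(self) -> np.ndarray:
        return band_mask(self.grid, self.filter_spec)

    @property
    def n_components(self) -> int:
        """Independent Fourier components in the signal band (the BW axis)."""
        return component_count(self.band)

    @cached_property
    def envelope(self) -> np.ndarray:
        from .stimulus import gaussian_envelope

        return gaussian_envelope(self.size, self.envelope_sd_deg, self.px_per_deg)

    def mask_patch(self, seed: int) -> NoisePatch:
        """Regenerate the white-noise mask of one interval from its seed."""
        return make_white_noise_mask(
            self.size, self.mask_variance, np.random.default_rng(seed), seed=seed
        )

    def signal_patch(self, contrast: float, seed: int) -> NoisePatch:
        """Regenerate the (optionally enveloped) signal noise from its seed.

        ``contrast`` is the nominal RMS contrast of the filtered noise before
        the envelope is applied; thresholds are reported on this scale.
        """
        patch = synthesize_filtered_noise(
            self.grid, self.band, contrast, np.random.default_rng(seed), seed=seed
        )
        if self.envelope_signal and contrast > 0:
            patch = NoisePatch(patch.data * self.envelope, seed=patch.seed)
        return patch


def study_conditions(
    bandwidths=ORI_BANDWIDTHS,
    *,
    sf_bandwidth: float = 1.0,
    size: int = 512,
    px_per_deg: float | None = None,
    **kwargs,
) -> list[Condition]:
    """Conditions for one session: one per two-sided orientation bandwidth.

    When ``px_per_deg`` is omitted it defaults to the display geometry at full
    size (94.8 px/deg for 512-px patches) and to ``size/4`` on reduced grids
    (a 4-deg patch), which keeps the one-octave 5 cy/deg annulus inside both
    the Nyquist limit and the central 64-bin crop used for classification
    images.
    """
    if px_per_deg is None:
        px_per_deg = 94.8 if size == 512 else size / 4.0
    return [
        Condition(
            name=f"ori{bw:g}",
            ori_bandwidth=float(bw),
            sf_bandwidth=sf_bandwidth,
            size=size,
            px_per_deg=px_per_deg,
            **kwargs,
        )
        for bw in bandwidths
    ]


def scaled_condition(bandwidth: float, size: int = 128, **kwargs) -> Condition:
    """A single study condition on a reduced grid (see :func:`study_conditions`)."""
    return study_conditions([bandwidth], size=size, **kwargs)[0]


def white_noise_condition(size: int = 512, px_per_deg: float | None = None, **kwargs) -> Condition:
    """Control condition whose target is (nearly) unfiltered white noise.

    The filter passes all orientations and spatial frequencies from one grid
    step up to just below Nyquist, approximating "all frequencies and
    orientations" while keeping the passband representable.
    """
    if px_per_deg is None:
        px_per_deg = 94.8 if size == 512 else size / 4.0
    lo = px_per_deg / size * 1.5
    hi = px_per_deg / 2.0 * 0.99
    return Condition(
        name="white",
        ori_bandwidth=180.0,
        sf_bandwidth=float(np.log2(hi / lo)),
        center_sf=float(np.sqrt(lo * hi)),
        size=size,
        px_per_deg=px_per_deg,
        **kwargs,
    )


def load_conditions(path: str | Path) -> list[Condition]:
    """Load a list of conditions from a YAML or JSON config file.

    The file holds a mapping with optional ``defaults`` (shared keyword
    arguments) and a ``conditions`` list of per-condition mappings.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    defaults = cfg.get("defaults", {})
    out = []
    for entry in cfg["conditions"]:
        params = {**defaults, **entry}
        out.append(Condition(**params))
    return out
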