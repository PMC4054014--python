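"""Unit and property tests for Fourier-domain stimulus synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oriband.stimulus import (
    FilterSpec,
    apply_gaussian_envelope,
    band_mask,
    component_count,
    gaussian_envelope,
    make_fourier_grid,
    make_white_noise_mask,
    power_spectrum,
    synthesize_filtered_noise,
    wrapped_ori_distance,
)


def brute_force_band_mask(grid, spec):
    """Independent per-bin oracle: classify every DFT bin from first principles."""
    n = grid.size
    mask = np.zeros((n, n), dtype=bool)
    half_bw = spec.ori_bandwidth_2sided / 2.0
    for i in range(n):
        for j in range(n):
            if (i, j) == (0, 0) or i == n // 2 or j == n // 2:
                continue
            fy = (i if i <= n // 2 else i - n) * grid.px_per_deg / n
            fx = (j if j <= n // 2 else j - n) * grid.px_per_deg / n
            sf = np.hypot(fx, fy)
            if not (spec.sf_lo - 1e-9 <= sf <= spec.sf_hi + 1e-9):
                continue
            ori = (np.degrees(np.arctan2(fy, fx)) + 90.0) % 180.0
            d = abs((ori - spec.center_ori + 90.0) % 180.0 - 90.0)
            if d <= half_bw + 1e-9:
                mask[i, j] = True
    # same closure convention as the implementation: a conjugate pair is
    # included when either member lands inside the (closed) passband
    return mask | np.roll(mask[::-1, ::-1], (1, 1), axis=(0, 1))


class TestFourierGrid:
    def test_dc_bin_has_zero_frequency(self):
        grid = make_fourier_grid(512, 94.8)
        assert grid.sf[0, 0] == 0.0

    def test_hand_computed_coordinates(self):
        # one step along the vertical-frequency axis encodes a horizontal
        # grating: 1 cy/deg at orientation 0 on a 64-px, 64 px/deg grid
        grid = make_fourier_grid(64, 64.0)
        assert grid.sf[1, 0] == pytest.approx(1.0)
        assert grid.orientation[1, 0] == pytest.approx(0.0)
        # one step along the horizontal-frequency axis is a vertical grating
        assert grid.orientation[0, 1] == pytest.approx(90.0)

    def test_orientation_conjugate_symmetry(self, small_grid):
        ori = small_grid.orientation
        conj = np.roll(ori[::-1, ::-1], (1, 1), axis=(0, 1))
        d = wrapped_ori_distance(ori, conj)
        assert np.all(d[small_grid.valid] < 1e-9)

    def test_nyquist(self, small_grid):
        assert small_grid.nyquist == pytest.approx(8.0)

    @pytest.mark.parametrize("size", [0, -2, 63])
    def test_rejects_bad_size(self, size):
        with pytest.raises(ValueError):
            make_fourier_grid(size, 10.0)

    def test_rejects_bad_px_per_deg(self):
        with pytest.raises(ValueError):
            make_fourier_grid(64, 0.0)


class TestBandMask:
    def test_full_bandwidth_is_annulus(self, small_grid):
        spec180 = FilterSpec(5.0, 1.0, ori_bandwidth_2sided=180.0)
        mask = band_mask(small_grid, spec180)
        annulus = (
            (small_grid.sf >= spec180.sf_lo)
            & (small_grid.sf <= spec180.sf_hi)
            & small_grid.valid
        )
        assert np.array_equal(mask, annulus)

    def test_sixteen_degree_band_passes_plus_minus_eight(self, small_grid, study_filter):
        mask = band_mask(small_grid, study_filter)
        d = wrapped_ori_distance(small_grid.orientation[mask], 0.0)
        assert d.max() <= 8.0 + 1e-6
        assert d.min() >= 0.0

    def test_nested_bandwidths_nest(self, small_grid):
        prev = None
        for bw in (2.0, 8.0, 32.0, 90.0, 180.0):
            mask = band_mask(small_grid, FilterSpec(5.0, 1.0, ori_bandwidth_2sided=bw))
            if prev is not None:
                assert np.all(mask[prev]), f"mask at {bw} deg does not contain narrower mask"
            prev = mask

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        bw=st.floats(min_value=1.0, max_value=180.0),
        center=st.floats(min_value=0.0, max_value=180.0),
    )
    def test_matches_brute_force_oracle(self, bw, center):
        grid = make_fourier_grid(32, 16.0)
        spec = FilterSpec(5.0, 1.0, center_ori=center, ori_bandwidth_2sided=bw)
        assert np.array_equal(band_mask(grid, spec), brute_force_band_mask(grid, spec))

    def test_rejects_band_beyond_nyquist(self, small_grid):
        with pytest.raises(ValueError, match="Nyquist"):
            band_mask(small_grid, FilterSpec(7.0, 1.0))

    def test_excludes_dc_and_nyquist(self, small_grid):
        # a near-full-spectrum band: from below one grid step up to just
        # under Nyquist (8 cy/deg); DC and the Nyquist row/column stay out
        broad = FilterSpec(np.sqrt(0.1 * 7.9), np.log2(7.9 / 0.1))
        mask = band_mask(small_grid, broad)
        assert mask.sum() > 2000
        assert not mask[0, 0]
        assert not mask[32, :].any()
        assert not mask[:, 32].any()


class TestComponentCount:
    def test_empty_mask(self):
        assert component_count(np.zeros((16, 16), dtype=bool)) == 0

    def test_full_annulus_twice_half_band(self, small_grid):
        full = component_count(band_mask(small_grid, FilterSpec(5.0, 1.0)))
        half = component_count(
            band_mask(small_grid, FilterSpec(5.0, 1.0, ori_bandwidth_2sided=90.0))
        )
        assert full == pytest.approx(2 * half, rel=0.1)

    def test_monotone_in_bandwidth(self, small_grid):
        counts = [
            component_count(band_mask(small_grid, FilterSpec(5.0, 1.0, ori_bandwidth_2sided=bw)))
            for bw in (2, 8, 16, 45, 90, 135, 180)
        ]
        assert counts == sorted(counts)

    def test_counts_conjugate_pairs_once(self, small_grid):
        mask = band_mask(small_grid, FilterSpec(5.0, 1.0))
        assert component_count(mask) == int(mask.sum()) // 2

    def test_rejects_asymmetric_mask(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[1, 2] = True  # conjugate partner (15, 14) missing
        with pytest.raises(ValueError, match="symmetric"):
            component_count(mask)


class TestFilteredNoise:
    def test_zero_target_rms_is_zero_patch(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.0, rng)
        assert not patch.data.any()

    def test_spectrum_zero_outside_band(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.2, rng)
        mask = band_mask(small_grid, study_filter)
        power = power_spectrum(patch.data)
        assert np.all(power[~mask] < 1e-16 * power.max())

    def test_sample_rms_exact(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.123, rng)
        assert patch.rms == pytest.approx(0.123, rel=1e-10)

    def test_parseval(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.3, rng)
        n = small_grid.size
        assert np.sum(power_spectrum(patch.data)) == pytest.approx(
            n**2 * np.sum(patch.data**2), rel=1e-10
        )

    def test_empty_band_raises(self, small_grid, rng):
        empty = np.zeros((64, 64), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            synthesize_filtered_noise(small_grid, empty, 0.1, rng)

    def test_mean_near_zero(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.3, rng)
        # DC is excluded from every band, so the sample mean is exactly 0
        assert abs(patch.data.mean()) < 1e-12


class TestEnvelope:
    def test_center_pixel_unchanged(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.3, rng)
        enveloped = apply_gaussian_envelope(patch, 1.08, small_grid.px_per_deg)
        c = small_grid.size // 2
        assert enveloped.data[c, c] == pytest.approx(patch.data[c, c])

    def test_value_at_one_sd(self):
        env = gaussian_envelope(64, 0.5, 16.0)  # SD = 8 px
        assert env[32 + 8, 32] == pytest.approx(np.exp(-0.5))

    def test_envelope_reduces_rms(self, small_grid, study_filter, rng):
        patch = synthesize_filtered_noise(small_grid, study_filter, 0.3, rng)
        enveloped = apply_gaussian_envelope(patch, 1.08, small_grid.px_per_deg)
        assert enveloped.rms < patch.rms


class TestWhiteNoise:
    def test_zero_variance(self, rng):
        assert not make_white_noise_mask(32, 0.0, rng).data.any()

    def test_negative_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            make_white_noise_mask(32, -0.1, rng)

    def test_sample_variance_near_target(self, rng):
        # variance of the sample variance of n iid normals is ~2 var^2 / n
        patch = make_white_noise_mask(512, 0.32, rng)
        se = 0.32 * np.sqrt(2.0 / 512**2)
        assert abs(patch.variance - 0.32) < 3 * se

    def test_flat_spectrum(self, rng):
        from scipy.stats import chi2

        patch = make_white_noise_mask(128, 0.32, rng)
        power = np.fft.fftshift(power_spectrum(patch.data))
        sf = np.fft.fftshift(np.hypot(*np.meshgrid(*(np.fft.fftfreq(128),) * 2)))
        # bin power into 8 radial annuli; each bin power is ~exponential with a
        # common mean iff the spectrum is flat: chi-square on bin totals
        edges = np.linspace(0.05, 0.5, 9)
        totals, counts = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (sf >= lo) & (sf < hi)
            totals.append(power[sel].sum())
            counts.append(sel.sum())
        totals, counts = np.array(totals), np.array(counts)
        mean_per_bin = totals.sum() / counts.sum()
        # sum of k exponentials ~ Gamma(k); normal approx for large k
        z = (totals - counts * mean_per_bin) / (mean_per_bin * np.sqrt(counts))
        stat = float(np.sum(z**2))
        assert stat < chi2.ppf(0.99, df=len(totals) - 1)
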