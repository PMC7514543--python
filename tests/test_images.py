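"""Image construction: band extraction, window selection, resize, stacking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavemi.cwt import FrequencyGrid, MotherWavelet, Scalogram, cwt_forward
from wavemi.images import (
    BETA_BAND_GRID,
    MU_BAND_GRID,
    MIImage,
    build_image_dual,
    build_image_mu,
    build_trial_image,
    extract_band,
    normalize_image,
    resize_spline,
    select_min_power_window,
)
from wavemi.synthetic import CHANNELS, ERDParams, generate_epoch

WAV = MotherWavelet("morlet")
FS = 250.0


def _scalogram(values, channel="C3", freqs=None, fs=FS):
    values = np.asarray(values, dtype=float)
    freqs = np.asarray(freqs) if freqs is not None else \
        np.linspace(8, 13, values.shape[0])
    return Scalogram(channel, freqs, np.arange(values.shape[1]) / fs, values, WAV)


def _triple(values, freqs=None):
    return [_scalogram(values, ch, freqs) for ch in CHANNELS]


class TestExtractBand:
    def test_full_range_grid_yields_26_mu_and_37_beta_rows(self, tone_500):
        """Cutting the sensorimotor bands out of a wide scalogram."""
        x, fs = tone_500
        full = cwt_forward(x, fs, FrequencyGrid.linear(0.2, 50.0, step=0.2), WAV)
        assert extract_band(full, 8.0, 13.0).values.shape[0] == 26
        beta = cwt_forward(x, fs, BETA_BAND_GRID, WAV)
        assert beta.values.shape[0] == 37

    def test_full_band_is_identity(self):
        sc = _scalogram(np.random.default_rng(0).random((5, 20)))
        out = extract_band(sc, sc.freqs[0], sc.freqs[-1])
        assert np.array_equal(out.values, sc.values)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            extract_band(_scalogram(np.ones((5, 20))), 100.0, 110.0)


class TestWindowSelection:
    def test_width_is_half_second_of_columns(self):
        start, end = select_min_power_window(_triple(np.ones((4, 500))), 0.5)
        assert end - start == 125

    def test_constant_input_tie_breaks_to_first_window(self):
        start, _ = select_min_power_window(_triple(np.ones((4, 300))), 0.5)
        assert start == 0

    def test_finds_the_quiet_interval(self):
        """Power dip confined to 1.0-1.5 s: window overlaps it >= 50%."""
        values = np.ones((4, 500))
        dip = slice(int(1.0 * FS), int(1.5 * FS))
        values[:, dip] = 0.1
        start, end = select_min_power_window(_triple(values), 0.5)
        overlap = min(end, dip.stop) - max(start, dip.start)
        assert overlap >= 0.5 * 125

    def test_agrees_with_coarse_scan(self):
        rng = np.random.default_rng(3)
        values = rng.random((4, 500))
        bands = _triple(values)
        start, end = select_min_power_window(bands, 0.5)
        total = sum(sc.values.sum(axis=0) for sc in bands)
        coarse = [total[s:s + 125].sum() for s in range(0, 376, 5)]
        assert total[start:end].sum() <= min(coarse) + 1e-9

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            select_min_power_window(_triple(np.ones((4, 100))), 0.5)


class TestResize:
    def test_same_shape_is_identity(self):
        m = np.random.default_rng(0).random((7, 9))
        assert np.allclose(resize_spline(m, 7, 9), m, atol=1e-10)

    def test_constant_reproduced(self):
        out = resize_spline(np.full((5, 125), 3.25), 4, 32)
        assert np.allclose(out, 3.25)

    def test_linear_ramp_reproduced_exactly(self):
        ramp = np.tile(np.linspace(0, 1, 125), (4, 1))
        out = resize_spline(ramp, 4, 32)
        assert np.allclose(out, np.tile(np.linspace(0, 1, 32), (4, 1)), atol=1e-12)

    def test_non_finite_rejected(self):
        m = np.ones((4, 4))
        m[1, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            resize_spline(m, 3, 3)


class TestBuildImages:
    def test_dual_band_geometry(self):
        rng = np.random.default_rng(1)
        mu = _triple(rng.random((26, 500)), MU_BAND_GRID.freqs)
        beta = _triple(rng.random((37, 500)), BETA_BAND_GRID.freqs)
        img = build_image_dual(mu, beta)
        assert img.values.shape == (93, 32)
        per_block = [r for r in img.row_map if r[0] == "C3"]
        assert len(per_block) == 31
        assert len(img.row_map) == 93

    def test_constant_scalograms_give_constant_rows(self):
        mu = _triple(np.full((26, 500), 2.0), MU_BAND_GRID.freqs)
        beta = _triple(np.full((37, 500), 5.0), BETA_BAND_GRID.freqs)
        img = build_image_dual(mu, beta)
        mu_rows = [i for i, r in enumerate(img.row_map) if r[1] == "mu"]
        beta_rows = [i for i, r in enumerate(img.row_map) if r[1] == "beta"]
        assert np.allclose(img.values[mu_rows], 2.0)
        assert np.allclose(img.values[beta_rows], 5.0)

    def test_mu_variant_keeps_native_frequency_rows(self):
        mu = _triple(np.random.default_rng(2).random((26, 500)),
                     MU_BAND_GRID.freqs)
        img = build_image_mu(mu)
        assert img.values.shape == (78, 32)
        assert np.allclose(build_image_mu(_triple(np.zeros((26, 500)),
                                                  MU_BAND_GRID.freqs)).values, 0.0)

    def test_wrong_electrode_order_rejected(self):
        mu = _triple(np.ones((26, 500)), MU_BAND_GRID.freqs)
        with pytest.raises(ValueError, match="electrodes"):
            build_image_mu(mu[::-1])

    def test_row_map_attributes_every_row_once(self, clean_left_epoch):
        img = build_trial_image(clean_left_epoch, WAV, "dual")
        assert len(img.row_map) == img.Nv
        for electrode, band, freq in img.row_map:
            assert electrode in CHANNELS and band in ("mu", "beta")
        # each electrode block: 15 mu rows then 16 beta rows
        assert [r[1] for r in img.row_map[:31]] == ["mu"] * 15 + ["beta"] * 16

    def test_shape_contract_independent_of_sampling_rate(self):
        """The dual image is 93 x 32 at 128 Hz too: resizing fixes the size."""
        params = ERDParams(fs=128.0, noise_sigma=0.2)
        ep = generate_epoch("right", params, seed=6)
        img = build_trial_image(ep, WAV, "dual")
        assert img.values.shape == (93, 32)

    def test_left_epoch_encodes_contralateral_mu_suppression(self, clean_left_epoch):
        img = build_trial_image(clean_left_epoch, WAV, "dual")
        c3 = [i for i, r in enumerate(img.row_map) if r[0] == "C3" and r[1] == "mu"]
        c4 = [i for i, r in enumerate(img.row_map) if r[0] == "C4" and r[1] == "mu"]
        assert img.values[c4].mean() < img.values[c3].mean()


class TestNormalize:
    def test_output_spans_unit_interval(self):
        img = MIImage(np.random.default_rng(0).random((4, 6)) * 7 + 3,
                      [("C3", "mu", 10.0)] * 4, (0.0, 0.5))
        out = normalize_image(img)
        assert out.normalized
        assert out.values.min() == 0.0 and out.values.max() == 1.0

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50), b=st.floats(-20, 20))
    def test_affine_invariance(self, a, b):
        base = np.random.default_rng(1).random((4, 6))
        row_map = [("C3", "mu", 10.0)] * 4
        x = normalize_image(MIImage(base, row_map, (0.0, 0.5)))
        y = normalize_image(MIImage(a * base + b, row_map, (0.0, 0.5)))
        assert np.allclose(x.values, y.values, atol=1e-9)

    def test_constant_image_warns_and_zeroes(self):
        img = MIImage(np.full((3, 3), 2.0), [("C3", "mu", 10.0)] * 3, (0.0, 0.5))
        with pytest.warns(RuntimeWarning, match="constant"):
            out = normalize_image(img)
        assert np.all(out.values == 0.0)
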