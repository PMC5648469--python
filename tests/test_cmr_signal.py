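"""Saturation-recovery signal chain: Bloch LUT, T2* correction, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duoflow import (
    ConcentrationSeries, RelaxationParams, SRProtocol, build_lut, extract_aif,
    signal_to_concentration, sr_flash_signal, t2star_correct,
)


@pytest.fixture(scope="module")
def protocol():
    return SRProtocol.default_myocardial()


@pytest.fixture(scope="module")
def relax():
    return RelaxationParams.myocardium_1p5T()


class TestSRFlashSignal:
    def test_single_line_matches_closed_form(self, relax):
        """With one phase-encode line the simulation must equal the textbook
        saturation-recovery expression sin(a)(1-e^{-TS R1})e^{-TE R2*}/PD."""
        prot = SRProtocol(n_pe_lines=1, saturation_delay=80.0)
        for gd in (0.0, 0.5, 2.0):
            r1 = 1000.0 / relax.T1_native + relax.r1 * gd
            r2s = 1000.0 / relax.T2star_native + relax.r2star * gd
            expected = (np.sin(np.radians(prot.flip_angle))
                        * (1 - np.exp(-(prot.saturation_delay / 1000) * r1))
                        * np.exp(-(prot.te1 / 1000) * r2s)
                        / np.sin(np.radians(prot.pd_flip_angle)))
            got = sr_flash_signal(gd, prot, relax, te=prot.te1)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_approach_to_recovered_bound(self, protocol, relax):
        """High [Gd] drives R1 up: signal rises monotonically toward the
        fully-recovered bound sin(flip)/sin(pd_flip), never exceeding it."""
        gd = np.linspace(0, 20, 400)
        sig = sr_flash_signal(gd, protocol, relax, te=None)
        bound = (np.sin(np.radians(protocol.flip_angle))
                 / np.sin(np.radians(protocol.pd_flip_angle)))
        assert np.all(np.diff(sig) > 0)
        assert np.all(sig <= bound + 1e-12)
        # slow approach: FLASH pulses keep Mz slightly below M0 until
        # recovery between lines is instantaneous
        assert sig[-1] > 0.9 * bound

    def test_negative_gd_rejected(self, protocol, relax):
        with pytest.raises(ValueError):
            sr_flash_signal(-0.1, protocol, relax)


class TestBuildLUT:
    def test_round_trip_of_1_mmol(self, protocol, relax):
        lut = build_lut(protocol, relax)
        sig = sr_flash_signal(1.0, protocol, relax, te=None)
        gd, sat = lut.invert(sig)
        assert not sat
        assert gd == pytest.approx(1.0, rel=1e-3)

    def test_degenerate_grid_rejected(self, protocol, relax):
        with pytest.raises(ValueError):
            build_lut(protocol, relax, grid_spec=np.array([0.0]))

    def test_no_t2star_gives_full_monotone_domain(self, protocol, relax):
        """TE=0 removes the T2*-induced rollover: valid to the grid end."""
        lut = build_lut(protocol, relax, grid_spec=(20.0, 0.01), te=None)
        assert lut.valid_max_gd == pytest.approx(20.0)
        assert np.all(np.diff(lut.normalized_signal[: lut.n_valid]) > 0)

    def test_t2star_rollover_limits_valid_domain(self, relax):
        """A long-TE readout rolls over; the valid domain must stop there."""
        prot = SRProtocol(te1=1.2, te2=1.8)
        lut = build_lut(prot, relax, grid_spec=(20.0, 0.01), te=prot.te1)
        assert lut.valid_max_gd < 20.0
        assert np.all(np.diff(lut.normalized_signal[: lut.n_valid]) > 0)


class TestT2StarCorrect:
    def test_equal_echoes_mean_no_decay(self):
        res = t2star_correct(100.0, 100.0, 0.6, 1.6)
        assert res.s0 == pytest.approx(100.0)
        assert res.r2star_apparent == pytest.approx(0.0)

    def test_halving_over_one_ms(self):
        res = t2star_correct(100.0, 50.0, 1.0, 2.0)
        assert res.r2star_apparent == pytest.approx(np.log(2))
        assert res.s0 == pytest.approx(200.0)

    def test_recovers_synthetic_decay_exactly(self):
        s0, r2s = 340.0, 0.3
        res = t2star_correct(s0 * np.exp(-r2s * 0.6), s0 * np.exp(-r2s * 1.6),
                             0.6, 1.6)
        assert res.s0 == pytest.approx(s0, rel=1e-12)
        assert res.r2star_apparent == pytest.approx(r2s, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(s0=st.floats(1.0, 1e4), r2s=st.floats(0.0, 2.0))
    def test_exact_on_monoexponential_inputs(self, s0, r2s):
        res = t2star_correct(s0 * np.exp(-r2s * 0.6), s0 * np.exp(-r2s * 1.6),
                             0.6, 1.6)
        assert np.isclose(res.s0, s0, rtol=1e-9)
        assert np.isclose(res.r2star_apparent, r2s, rtol=1e-9, atol=1e-12)

    def test_noise_inverted_echoes_pass_through(self):
        res = t2star_correct(np.array([50.0]), np.array([60.0]), 0.6, 1.6)
        assert res.n_flagged == 1
        assert res.s0[0] == pytest.approx(50.0)
        assert res.r2star_apparent[0] == 0.0


class TestSignalToConcentration:
    def test_all_baseline_series_gives_zero_delta(self, protocol, relax):
        lut = build_lut(protocol, relax)
        base = float(sr_flash_signal(0.0, protocol, relax, te=None))
        series = np.full((10, 4, 4), base * 100.0)
        pd_ref = np.full((4, 4), 100.0)
        conv = signal_to_concentration(np.arange(10.0), series, lut, pd_ref,
                                       baseline_frames=3)
        np.testing.assert_allclose(conv.series.concentration, 0.0, atol=1e-9)

    def test_forward_then_invert_round_trip(self, protocol, relax):
        lut = build_lut(protocol, relax)
        gd_true = 0.5
        sig = float(sr_flash_signal(gd_true, protocol, relax, te=None))
        series = np.full((5, 2, 2), sig * 250.0)
        conv = signal_to_concentration(np.arange(5.0), series, lut,
                                       np.full((2, 2), 250.0))
        np.testing.assert_allclose(conv.series.concentration, gd_true, rtol=1e-3)

    def test_pd_normalization_consistency(self, protocol, relax):
        """Doubling the PD reference halves the normalized signal, so the
        recovered [Gd] must match the forward model of that halved signal."""
        lut = build_lut(protocol, relax)
        sig = float(sr_flash_signal(1.5, protocol, relax, te=None))
        series = np.full((3, 1, 1), sig * 100.0)
        conv_ok = signal_to_concentration(np.arange(3.0), series, lut,
                                          np.full((1, 1), 100.0))
        conv_2x = signal_to_concentration(np.arange(3.0), series, lut,
                                          np.full((1, 1), 200.0))
        assert conv_ok.series.concentration[0, 0, 0] == pytest.approx(1.5, rel=1e-3)
        half_sig_gd, _ = lut.invert(sig / 2)
        assert conv_2x.series.concentration[0, 0, 0] == pytest.approx(
            float(half_sig_gd), rel=1e-9)

    def test_saturated_pixels_flagged_and_zero_pd_masked(self, protocol, relax):
        lut = build_lut(protocol, relax, grid_spec=(2.0, 0.01))
        hot = float(sr_flash_signal(3.0, protocol, relax, te=None))
        series = np.full((2, 2, 1), hot * 50.0)
        pd_ref = np.array([[50.0], [0.0]])
        conv = signal_to_concentration(np.arange(2.0), series, lut, pd_ref)
        assert conv.n_saturated == 2  # one valid pixel, two frames
        assert np.isnan(conv.series.concentration[:, 1, 0]).all()
        np.testing.assert_allclose(conv.series.concentration[:, 0, 0], 2.0)


class TestExtractAIF:
    def _series(self, curves):
        arr = np.stack(curves, axis=1)[:, :, None]  # (t, n_pix, 1)
        return ConcentrationSeries(times=np.arange(arr.shape[0], dtype=float),
                                   concentration=arr)

    def test_single_pixel_mask_returns_that_curve(self):
        c = np.linspace(0, 5, 8)
        series = self._series([c, 10 * c])
        mask = np.array([[True], [False]])
        aif = extract_aif(series, mask)
        np.testing.assert_allclose(aif.values, c)

    def test_mean_of_two_pixels(self):
        c = np.linspace(0, 5, 8)
        series = self._series([c, 3 * c])
        aif = extract_aif(series, np.array([[True], [True]]))
        np.testing.assert_allclose(aif.values, 2 * c)

    def test_empty_mask_rejected(self):
        series = self._series([np.zeros(4)])
        with pytest.raises(ValueError):
            extract_aif(series, np.array([[False]]))
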