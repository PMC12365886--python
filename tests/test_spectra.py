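"""Tauc transform, band-gap extraction and size-law tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanoscreen.spectra import (
    EV_NM,
    NoRisingEdgeError,
    Spectrum,
    SpectrumError,
    TaucConfig,
    analyze_spectrum,
    energy_axis,
    estimate_band_gap,
    size_from_gap,
    tauc_transform,
    truncate_to_decimals,
)


def line_spectrum(slope=4.0, eg=1.97, e_lo=2.0, e_hi=2.6, n=61):
    """Spectrum whose Tauc curve (n=1/2) is exactly y = slope*(E - eg)."""
    energy = np.linspace(e_lo, e_hi, n)
    y = slope * (energy - eg)
    absorbance = np.sqrt(np.clip(y, 0, None)) / energy
    wl = EV_NM / energy[::-1]
    return Spectrum(wl, absorbance[::-1])


class TestEnergyAxis:
    def test_reference_wavelengths(self):
        spec = Spectrum(np.linspace(400, 800, 20), np.ones(20))
        e = energy_axis(spec)
        assert e.shape == (20,)
        assert np.all(np.diff(e) < 0)
        # 520 nm photon is 2.3843 eV; the conversion constant itself maps to 1 eV
        assert EV_NM / 520.0 == pytest.approx(2.3843, abs=5e-5)
        assert EV_NM / 1239.842 == pytest.approx(1.0, abs=1e-4)

    def test_reciprocal_and_roundtrip(self):
        wl = np.linspace(300, 600, 31)
        spec = Spectrum(wl, np.ones_like(wl))
        spec2 = Spectrum(2 * wl, np.ones_like(wl))
        np.testing.assert_allclose(energy_axis(spec), 2 * energy_axis(spec2), rtol=1e-12)
        np.testing.assert_allclose(EV_NM / energy_axis(spec), wl[::-1].copy()[::-1], rtol=1e-9)

    @pytest.mark.parametrize(
        "wl,ab",
        [
            (np.linspace(400, 800, 5), np.ones(5)),  # too short
            (np.linspace(-1, 800, 20), np.ones(20)),  # non-positive wavelength
            (np.r_[np.linspace(400, 600, 10), np.linspace(500, 800, 10)], np.ones(20)),
            (np.linspace(400, 800, 20), -np.ones(20)),  # negative absorbance
        ],
    )
    def test_invalid_spectra_rejected(self, wl, ab):
        with pytest.raises(SpectrumError):
            Spectrum(wl, ab)


class TestTaucTransform:
    def test_pointwise_values(self):
        wl = np.linspace(EV_NM / 2.5, EV_NM / 1.5, 11)
        spec = Spectrum(wl, np.full(11, 2.0))
        curve = tauc_transform(spec)
        # with n = 1/2, y = (alpha*E)^2; at alpha=2 and the E=2 sample y=16
        idx = np.argmin(np.abs(curve.energy_eV - 2.0))
        assert curve.y[idx] == pytest.approx(
            (2.0 * curve.energy_eV[idx]) ** 2, rel=1e-12
        )
        zero = tauc_transform(Spectrum(wl, np.zeros(11)))
        assert np.all(zero.y == 0)

    def test_intercept_invariant_to_absorbance_scaling(self):
        cfg = TaucConfig(fit_window_eV=(2.0, 2.6), window_strategy="manual")
        base = line_spectrum()
        scaled = Spectrum(base.wavelength_nm, 7.3 * base.absorbance)
        eg1, _ = estimate_band_gap(tauc_transform(base), cfg)
        eg2, _ = estimate_band_gap(tauc_transform(scaled), cfg)
        assert eg1 == pytest.approx(1.97, abs=1e-9)
        assert eg2 == pytest.approx(eg1, abs=1e-9)


class TestEstimateBandGap:
    def test_exact_line_recovers_intercept(self):
        cfg = TaucConfig(fit_window_eV=(2.0, 2.6), window_strategy="manual")
        eg, diag = estimate_band_gap(tauc_transform(line_spectrum()), cfg)
        assert eg == pytest.approx(1.97, abs=1e-9)
        assert diag["fit_r2"] == pytest.approx(1.0, abs=1e-9)
        assert eg == pytest.approx(-diag["intercept"] / diag["slope"], rel=1e-12)

    def test_decreasing_curve_raises(self):
        energy = np.linspace(2.0, 2.6, 31)
        absorbance = (3.0 - energy) / energy  # alpha*E decreasing in E
        wl = EV_NM / energy[::-1]
        spec = Spectrum(wl, absorbance[::-1])
        cfg = TaucConfig(fit_window_eV=(2.0, 2.6), window_strategy="manual")
        with pytest.raises(NoRisingEdgeError):
            estimate_band_gap(tauc_transform(spec), cfg)

    def test_manual_window_outside_range(self):
        cfg = TaucConfig(fit_window_eV=(5.0, 6.0), window_strategy="manual")
        with pytest.raises(SpectrumError):
            estimate_band_gap(tauc_transform(line_spectrum()), cfg)


class TestSizeFromGap:
    def test_printed_gap_values(self):
        r1, d1, ok1, _ = size_from_gap(1.97)
        r2, d2, ok2, _ = size_from_gap(1.92)
        assert r1 == pytest.approx((5.0 / 1.97) ** (1 / 1.4), rel=1e-12)
        assert d1 == pytest.approx(2 * r1, rel=1e-12)
        assert (truncate_to_decimals(r1), truncate_to_decimals(d1)) == (1.94, 3.89)
        assert (truncate_to_decimals(r2), truncate_to_decimals(d2)) == (1.98, 3.96)
        assert ok1 and ok2

    @pytest.mark.parametrize("ns", [1.3, 1.4, 1.5])
    def test_unit_ratio_gives_unit_radius(self, ns):
        cfg = TaucConfig(size_constant_A=5.0, size_exponent_n=ns)
        r, d, _, _ = size_from_gap(5.0, cfg)
        assert r == pytest.approx(1.0, rel=1e-12)
        assert d == pytest.approx(2.0, rel=1e-12)

    def test_applicability_flag_beyond_confinement(self):
        r, d, ok, reason = size_from_gap(0.5)
        assert d >= 5.0 and not ok and "5 nm" in reason

    def test_gap_below_bulk_rejected(self):
        with pytest.raises(ValueError):
            size_from_gap(0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        eg1=st.floats(0.5, 3.0),
        eg2=st.floats(0.5, 3.0),
        a1=st.floats(4.5, 6.0),
        a2=st.floats(4.5, 6.0),
        ns=st.floats(1.3, 1.5),
    )
    def test_monotonicity(self, eg1, eg2, a1, a2, ns):
        # radius shrinks as the gap widens; grows with the size constant
        cfg1 = TaucConfig(size_constant_A=a1, size_exponent_n=ns)
        if eg1 < eg2:
            assert size_from_gap(eg1, cfg1)[0] > size_from_gap(eg2, cfg1)[0]
        if a1 < a2:
            cfg2 = TaucConfig(size_constant_A=a2, size_exponent_n=ns)
            assert size_from_gap(eg1, cfg1)[0] < size_from_gap(eg1, cfg2)[0]


def test_analyze_spectrum_composes_stages():
    from nanoscreen.simulate import SpectrumSpec, generate_spectrum

    spec = generate_spectrum(
        SpectrumSpec(eg_eV=1.97, plasmon_amplitude=0.0, noise_sd_fraction=0.0)
    )
    res = analyze_spectrum(spec)
    assert res.band_gap_eV == pytest.approx(1.97, abs=1e-6)
    assert res.diameter_nm == pytest.approx(2 * res.radius_nm, rel=1e-12)
    assert res.applicable
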