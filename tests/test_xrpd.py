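"""XRPD peak integration, binary calibration curves, phase quantitation."""

import numpy as np
import pytest

from polymon.errors import IndeterminateCompositionError, InputDataError
from polymon.simulate import simulate_xrpd_pattern
from polymon.spectra import XRPDPattern
from polymon.xrpd import (
    BinaryCalCurve,
    build_binary_curve,
    integrate_peak,
    load_curves,
    quantify_process_sample,
    save_curves,
)


def _triangle_pattern(height=2.0, base=1.0, center=10.0):
    x = np.arange(5.0, 15.0, 0.01)
    y = np.clip(height * (1.0 - np.abs(x - center) / (base / 2.0)), 0.0, None)
    return XRPDPattern(x, y)


class TestIntegratePeak:
    def test_triangle_area(self):
        pattern = _triangle_pattern(height=2.0, base=1.0)
        area = integrate_peak(pattern, (9.0, 11.0))
        assert area == pytest.approx(2.0 * 1.0 / 2.0, abs=1e-3)

    def test_zero_signal(self):
        x = np.arange(0.0, 10.0, 0.02)
        assert integrate_peak(XRPDPattern(x, np.zeros_like(x)), (2.0, 8.0)) == 0.0

    def test_linear_background_subtracted_exactly(self):
        pattern = _triangle_pattern()
        ramped = XRPDPattern(pattern.two_theta, pattern.counts + 3.0 + 0.5 * pattern.two_theta)
        a = integrate_peak(pattern, (9.0, 11.0))
        b = integrate_peak(ramped, (9.0, 11.0))
        assert b == pytest.approx(a, abs=1e-6)

    def test_window_outside_axis_raises(self):
        with pytest.raises(InputDataError):
            integrate_peak(_triangle_pattern(), (100.0, 110.0))


def _binary_mixtures(lib, forms=("salt", "V"), n=11, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    comps = np.linspace(0.0, 1.0, n)
    return [
        (
            c,
            simulate_xrpd_pattern(
                {forms[0]: c, forms[1]: 1.0 - c}, lib,
                rng=rng if noise > 0 else None, noise_rel_sd=noise,
            ),
        )
        for c in comps
    ]


class TestBinaryCurve:
    def test_noiseless_curve_is_exact(self, small_library):
        mixtures = _binary_mixtures(small_library)
        windows = {f: small_library.xrpd_windows(f) for f in ("salt", "V")}
        curve = build_binary_curve(mixtures, windows, ("salt", "V"))
        assert curve.r2["salt"] == pytest.approx(1.0, abs=1e-9)
        assert curve.r2["V"] == pytest.approx(1.0, abs=1e-9)
        assert curve.intercept["salt"] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_compositions_rejected(self, small_library):
        mixtures = _binary_mixtures(small_library)[:2]
        windows = {f: small_library.xrpd_windows(f) for f in ("salt", "V")}
        with pytest.raises(InputDataError):
            build_binary_curve(mixtures, windows, ("salt", "V"))

    def test_narrow_span_rejected(self, small_library):
        mixtures = [
            (c, simulate_xrpd_pattern({"salt": c, "V": 1.0 - c}, small_library))
            for c in (0.4, 0.5, 0.6)
        ]
        windows = {f: small_library.xrpd_windows(f) for f in ("salt", "V")}
        with pytest.raises(InputDataError):
            build_binary_curve(mixtures, windows, ("salt", "V"))

    def test_training_mixtures_recovered(self, small_library):
        mixtures = _binary_mixtures(small_library)
        windows = {f: small_library.xrpd_windows(f) for f in ("salt", "V")}
        curve = build_binary_curve(mixtures, windows, ("salt", "V"))
        resid = [
            quantify_process_sample(p, [curve])["salt"] - c for c, p in mixtures[1:-1]
        ]
        assert np.sqrt(np.mean(np.square(resid))) <= 0.02

    def test_serialization_round_trip(self, small_library, tmp_path):
        mixtures = _binary_mixtures(small_library)
        windows = {f: small_library.xrpd_windows(f) for f in ("salt", "V")}
        curve = build_binary_curve(mixtures, windows, ("salt", "V"))
        path = tmp_path / "curves.json"
        save_curves([curve], path)
        restored = load_curves(path)[0]
        assert restored.slope == curve.slope and restored.windows == curve.windows


def _all_curves(lib, noise=0.0, seed=0):
    pairs = [("salt", "II"), ("salt", "V"), ("II", "V")]
    curves = []
    for a, b in pairs:
        mixtures = _binary_mixtures(lib, forms=(a, b), noise=noise, seed=seed)
        windows = {f: lib.xrpd_windows(f) for f in (a, b)}
        curves.append(build_binary_curve(mixtures, windows, (a, b)))
    return curves


class TestQuantifyProcessSample:
    def test_pure_form_recovered(self, small_library):
        curves = _all_curves(small_library)
        pattern = simulate_xrpd_pattern({"V": 1.0}, small_library)
        fractions = quantify_process_sample(pattern, curves)
        assert fractions["V"] == pytest.approx(1.0, abs=1e-6)
        assert fractions["salt"] == pytest.approx(0.0, abs=1e-6)

    def test_three_form_composition_noiseless(self, small_library):
        curves = _all_curves(small_library)
        truth = {"salt": 0.5, "II": 0.2, "V": 0.3}
        pattern = simulate_xrpd_pattern(truth, small_library)
        fractions = quantify_process_sample(pattern, curves)
        for form, value in truth.items():
            assert fractions[form] == pytest.approx(value, abs=0.01)

    def test_three_form_composition_noisy(self, small_library):
        rng = np.random.default_rng(5)
        curves = _all_curves(small_library, noise=0.04, seed=5)
        truth = {"salt": 0.5, "II": 0.2, "V": 0.3}
        pattern = simulate_xrpd_pattern(truth, small_library, rng=rng, noise_rel_sd=0.04)
        fractions = quantify_process_sample(pattern, curves)
        for form, value in truth.items():
            assert fractions[form] == pytest.approx(value, abs=0.05)

    def test_output_always_closes(self, small_library):
        curves = _all_curves(small_library)
        pattern = simulate_xrpd_pattern({"salt": 0.7, "II": 0.3}, small_library)
        fractions = quantify_process_sample(pattern, curves)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_global_intensity_scale_cancelled(self, small_library):
        curves = _all_curves(small_library)
        truth = {"salt": 0.4, "II": 0.25, "V": 0.35}
        pattern = simulate_xrpd_pattern(truth, small_library)
        scaled = XRPDPattern(pattern.two_theta, 3.0 * pattern.counts)
        a = quantify_process_sample(pattern, curves)
        b = quantify_process_sample(scaled, curves)
        for form in truth:
            assert b[form] == pytest.approx(a[form], abs=1e-3)

    def test_empty_pattern_indeterminate(self, small_library):
        curves = _all_curves(small_library)
        axis = small_library.two_theta()
        with pytest.raises(IndeterminateCompositionError):
            quantify_process_sample(XRPDPattern(axis, np.zeros_like(axis)), curves)
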