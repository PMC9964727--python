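"""Synthetic-run generator: kinetics, mixture spectra, XRPD patterns."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from polymon.errors import InputDataError, ParameterError
from polymon.library import (
    FormLibrary,
    FormSignature,
    KineticEdge,
    KineticParams,
    RamanPeak,
    RunConfig,
    XRPDPeak,
    default_kinetics,
    default_library,
)
from polymon.simulate import (
    mixture_spectrum,
    pure_form_profile,
    simulate_kinetics,
    simulate_run,
    simulate_xrpd_pattern,
)


class TestKinetics:
    def test_no_conversion_identity(self):
        params = KineticParams(edges=[KineticEdge("salt", "V", 0.0)])
        traj = simulate_kinetics(params, np.arange(0.0, 100.0, 2.0))
        assert np.all(traj.fractions["salt"].to_numpy() == 1.0)

    def test_zero_order_linear_depletion(self):
        params = KineticParams(edges=[KineticEdge("salt", "V", 0.14, "zero")])
        times = np.arange(0.0, 21.0, 1.0)
        traj = simulate_kinetics(params, times)
        salt = traj.fractions["salt"].to_numpy()
        expected = np.clip(1.0 - 0.14 * times, 0.0, 1.0)
        assert np.allclose(salt, expected, atol=1e-6)
        assert salt[8] == pytest.approx(0.0, abs=1e-6)  # depleted by ~7.14 min
        assert np.allclose(traj.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_first_order_matches_analytic_exponential(self):
        k = 0.3
        params = KineticParams(edges=[KineticEdge("salt", "V", k)])
        times = np.arange(0.0, 61.0, 1.0)
        traj = simulate_kinetics(params, times)
        assert np.abs(traj.fractions["salt"].to_numpy() - np.exp(-k * times)).max() < 1e-8

    def test_two_species_cascade_matches_bateman(self):
        k1, k2 = 0.05, 0.02
        params = KineticParams(
            edges=[KineticEdge("salt", "II", k1), KineticEdge("II", "V", k2)]
        )
        times = np.arange(0.0, 201.0, 1.0)
        traj = simulate_kinetics(params, times)
        intermediate = k1 / (k2 - k1) * (np.exp(-k1 * times) - np.exp(-k2 * times))
        assert np.abs(traj.fractions["II"].to_numpy() - intermediate).max() < 1e-6

    def test_terminal_fraction_caps_conversion(self):
        params = default_kinetics("maleate")
        traj = simulate_kinetics(params, np.arange(0.0, 2001.0, 10.0))
        assert traj.fractions["salt"].iloc[-1] == pytest.approx(0.81, abs=1e-3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ParameterError):
            KineticEdge("salt", "V", -0.1)

    def test_times_must_start_at_zero(self):
        params = KineticParams(edges=[KineticEdge("salt", "V", 0.1)])
        with pytest.raises(ParameterError):
            simulate_kinetics(params, np.array([1.0, 2.0]))

    @given(
        k1=st.floats(0.0, 0.5), k2=st.floats(0.0, 0.5),
        order=st.sampled_from(["first", "zero"]),
    )
    def test_mass_conservation(self, k1, k2, order):
        params = KineticParams(
            edges=[KineticEdge("salt", "II", k1, order), KineticEdge("II", "V", k2)]
        )
        traj = simulate_kinetics(params, np.arange(0.0, 120.0, 4.0))
        sums = traj.fractions.sum(axis=1).to_numpy()
        assert np.abs(sums - 1.0).max() < 1e-9
        vals = traj.fractions.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestMixtureSpectrum:
    def test_single_form_equals_pure_profile(self, small_library):
        spec = mixture_spectrum({"V": 1.0}, 25.0, small_library)
        expected = pure_form_profile("V", 25.0, small_library)
        assert np.array_equal(spec.intensity, expected)

    def test_linearity_in_fractions(self, small_library):
        mix = mixture_spectrum({"salt": 0.5, "V": 0.5}, 20.0, small_library)
        pure_a = mixture_spectrum({"salt": 1.0}, 20.0, small_library)
        pure_b = mixture_spectrum({"V": 1.0}, 20.0, small_library)
        assert np.abs(
            mix.intensity - 0.5 * pure_a.intensity - 0.5 * pure_b.intensity
        ).max() < 1e-10

    def test_fractions_must_close(self, small_library):
        with pytest.raises(InputDataError):
            mixture_spectrum({"salt": 0.6, "V": 0.5}, 20.0, small_library)

    def test_concentration_peak_shift(self):
        # 0.1 cm⁻¹ per mg/mL → apex moves 3.75 cm⁻¹ between 12.5 and 50 mg/mL
        lib = FormLibrary(
            forms={
                "salt": FormSignature(
                    raman_peaks=[RamanPeak(500.0, 10.0, 1.0)],
                    xrpd_peaks=[XRPDPeak(6.0, 0.1, 1.0), XRPDPeak(12.0, 0.1, 1.0)],
                    shift_per_conc=0.1,
                )
            },
            salt_form="salt",
            raman_axis=(400.0, 600.0, 0.05),
        )
        apex = {
            conc: lib.raman_shift()[
                np.argmax(mixture_spectrum({"salt": 1.0}, conc, lib).intensity)
            ]
            for conc in (12.5, 50.0)
        }
        assert apex[50.0] - apex[12.5] == pytest.approx(3.75, abs=0.1)

    def test_noise_requires_rng(self, small_library):
        with pytest.raises(ParameterError):
            mixture_spectrum({"V": 1.0}, 20.0, small_library, noise_sd=0.1)


class TestSimulateRun:
    def test_table_cadence_gives_226_spectra(self, small_library, cascade_params):
        cfg = RunConfig(
            salt_id="hcl", conc=16.7, duration=450.0, cadence=2.0,
            xrpd_times=[10.0, 100.0, 400.0], seed=0,
        )
        run = simulate_run(cfg, cascade_params, small_library)
        assert run.n_spectra == 226
        assert run.times[0] == 0.0 and run.times[-1] == 450.0

    def test_reference_rows_and_closure(self, small_library, cascade_params):
        times = list(np.linspace(0.0, 440.0, 15))
        cfg = RunConfig(
            salt_id="hcl", conc=25.0, duration=450.0, cadence=2.0,
            xrpd_times=times, ref_rel_sd=0.04, seed=3,
        )
        run = simulate_run(cfg, cascade_params, small_library)
        wide = run.reference_wide()
        assert len(wide) == 15
        assert np.allclose(wide.sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_noiseless_references_equal_truth(self, small_library, cascade_params):
        cfg = RunConfig(
            salt_id="hcl", conc=25.0, duration=100.0, cadence=2.0,
            xrpd_times=[0.0, 20.0, 60.0], ref_rel_sd=0.0, seed=1,
        )
        run = simulate_run(cfg, cascade_params, small_library)
        wide = run.reference_wide()
        for t in (0.0, 20.0, 60.0):
            truth = run.truth.at(t)
            for form, value in truth.items():
                assert wide.loc[t, form] == pytest.approx(value, abs=1e-12)

    def test_seed_reproducibility(self, small_library, cascade_params):
        cfg = dict(
            salt_id="hcl", conc=25.0, duration=60.0, cadence=2.0,
            xrpd_times=[10.0, 30.0], ref_rel_sd=0.04, noise_sd=0.05,
        )
        a = simulate_run(RunConfig(**cfg, seed=7), cascade_params, small_library)
        b = simulate_run(RunConfig(**cfg, seed=7), cascade_params, small_library)
        c = simulate_run(RunConfig(**cfg, seed=8), cascade_params, small_library)
        assert np.array_equal(a.spectra, b.spectra)
        assert a.references.equals(b.references)
        assert not np.array_equal(a.spectra, c.spectra)


class TestXRPDSimulation:
    def test_pure_form_has_only_its_signature(self, small_library):
        pattern = simulate_xrpd_pattern({"V": 1.0}, small_library)
        axis = pattern.two_theta
        outside = np.ones_like(axis, dtype=bool)
        for lo, hi in small_library.xrpd_windows("V"):
            outside &= (axis < lo) | (axis > hi)
        # all intensity concentrated in form V windows (tails are tiny)
        assert pattern.counts[outside].max() < 0.05 * pattern.counts.max()

    def test_binary_mixture_halves_signature_area(self, small_library):
        from polymon.xrpd import integrate_peak

        pure = simulate_xrpd_pattern({"V": 1.0}, small_library)
        mix = simulate_xrpd_pattern({"V": 0.5, "salt": 0.5}, small_library)
        for window in small_library.xrpd_windows("V"):
            assert integrate_peak(mix, window) == pytest.approx(
                0.5 * integrate_peak(pure, window), abs=1e-8
            )

    def test_signature_areas_affine_in_composition(self, small_library):
        from polymon.xrpd import integrate_peak

        comps = np.arange(0.0, 1.01, 0.1)
        areas = []
        for c in comps:
            p = simulate_xrpd_pattern({"salt": c, "V": 1.0 - c}, small_library)
            areas.append(
                sum(integrate_peak(p, w) for w in small_library.xrpd_windows("salt"))
            )
        fit = stats.linregress(comps, areas)
        assert fit.rvalue**2 == pytest.approx(1.0, abs=1e-9)

    def test_default_library_windows_disjoint(self):
        lib = default_library("hcl")  # validation runs in the constructor
        assert set(lib.forms) == {"salt", "I", "II", "V"}
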