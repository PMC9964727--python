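"""Reference pairing, closure, model-set building and run prediction."""

import numpy as np
import pandas as pd
import pytest

from polymon.calibration import (
    ModelSet,
    build_model_set,
    closure_compositions,
    closure_salt_fraction,
    pair_references,
    predict_run,
)
from polymon.errors import (
    ParameterError,
    SelectionError,
    UnmatchedReferenceError,
)
from polymon.library import KineticEdge, KineticParams, RunConfig
from polymon.runs import ProcessRun
from polymon.simulate import simulate_run


def _toy_run(spectrum_times, ref_rows, n_channels=4):
    times = np.asarray(spectrum_times, dtype=float)
    rng = np.random.default_rng(0)
    return ProcessRun(
        salt_id="hcl",
        conc=16.7,
        shift=np.arange(100.0, 100.0 + n_channels),
        times=times,
        spectra=rng.normal(size=(times.size, n_channels)),
        references=pd.DataFrame(ref_rows, columns=["time_min", "form", "mass_fraction"]),
    )


def _refs_at(times, salt=0.6, II=0.4):
    rows = []
    for t in times:
        rows += [(t, "salt", salt), (t, "II", II)]
    return rows


class TestPairReferences:
    def test_exact_timestamps_identity(self):
        run = _toy_run([0.0, 2.0, 4.0, 6.0], _refs_at([2.0, 6.0]))
        paired = pair_references(run, tolerance=2.0)
        np.testing.assert_array_equal(paired.spectrum_indices, [1, 3])

    def test_tie_goes_to_earlier_spectrum(self):
        run = _toy_run([2.0, 4.0], _refs_at([3.0]))
        paired = pair_references(run, tolerance=2.0)
        assert paired.spectrum_indices[0] == 0  # t = 2 wins the tie

    def test_out_of_reach_reference_raises(self):
        run = _toy_run([0.0, 2.0], _refs_at([500.0]))
        with pytest.raises(UnmatchedReferenceError, match="500"):
            pair_references(run, tolerance=2.0)

    def test_each_spectrum_used_at_most_once(self):
        run = _toy_run([0.0, 2.0, 4.0], _refs_at([1.9, 2.1]))
        paired = pair_references(run, tolerance=2.0)
        assert len(set(paired.spectrum_indices)) == 2


class TestClosure:
    def test_worked_example(self):
        assert closure_salt_fraction({"II": 0.06, "V": 0.13}) == pytest.approx(0.81)

    def test_start_of_run_all_freebase_zero(self):
        assert closure_salt_fraction({"II": 0.0, "V": 0.0}) == 1.0

    def test_overshoot_clipped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="polymon.calibration"):
            salt = closure_salt_fraction({"V": 1.2})
        assert salt == 0.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_composition_rows_always_close(self):
        raw = pd.DataFrame({"II": [-0.1, 0.6, 0.2], "V": [0.05, 0.7, 0.3]})
        out = closure_compositions(raw)
        assert np.allclose(out.sum(axis=1).to_numpy(), 1.0, atol=1e-9)
        assert (out.to_numpy() >= 0.0).all()


def _simulated_pair(small_library, kinetics=None, *, conc_cal=25.0, conc_test=16.7,
                    noise=0.0, ref_sd=0.0, seeds=(11, 12)):
    kinetics = kinetics or KineticParams(
        edges=[KineticEdge("salt", "II", 0.05), KineticEdge("II", "V", 0.01)]
    )
    xrpd = list(np.arange(0.0, 241.0, 20.0))  # 13 references
    mk = lambda conc, seed: simulate_run(
        RunConfig(
            salt_id="x", conc=conc, duration=240.0, cadence=2.0,
            xrpd_times=xrpd, ref_rel_sd=ref_sd, noise_sd=noise, seed=seed,
        ),
        kinetics,
        small_library,
    )
    return mk(conc_cal, seeds[0]), mk(conc_test, seeds[1])


class TestBuildModelSet:
    def test_noiseless_linear_system_near_exact(self, small_library):
        # same solid concentration for calibration and test: no interference,
        # so the linear mixture model is exactly recoverable
        cal, test = _simulated_pair(small_library, conc_cal=16.7)
        mset = build_model_set(
            [cal], test, procedure="cp", recipes=["mean_center"],
            truncation=(100.0, 1100.0),
        )
        series = predict_run(mset, test)
        for form in ("II", "V"):
            assert series.evaluations[form].rmse < 1e-4
        np.testing.assert_array_equal(series.times, test.times)

    def test_absent_form_flagged_unmodelable(self, small_library):
        no_II = KineticParams(edges=[KineticEdge("salt", "V", 0.05)])
        cal, test = _simulated_pair(small_library, kinetics=no_II)
        mset = build_model_set(
            [cal], test, forms=["II", "V"], procedure="cp",
            recipes=["mean_center"], truncation=(100.0, 1100.0),
        )
        assert mset.unmodelable == ["II"]
        assert "II" not in mset.models and "V" in mset.models

    def test_selected_lv_matches_exhaustive_search(self, small_library):
        cal, test = _simulated_pair(small_library, noise=0.02, ref_sd=0.04)
        lv_range = range(1, 5)
        mset = build_model_set(
            [cal], test, procedure="cp", recipes=["mean_center"],
            lv_range=lv_range, truncation=(100.0, 1100.0),
        )
        # independent exhaustive search over the same grid
        from polymon.chemometrics import SIMPLSRegression, evaluate
        from polymon.preprocessing import PreprocessingRecipe, truncate_matrix

        cal_p, test_p = pair_references(cal), pair_references(test)
        _, Xc = truncate_matrix(cal.shift, cal_p.X, 100.0, 1100.0)
        _, Xt = truncate_matrix(test.shift, test_p.X, 100.0, 1100.0)
        recipe = PreprocessingRecipe("mean_center").fit(Xc)
        Xcp, Xtp = recipe.transform(Xc), recipe.transform(Xt)
        for form in ("II", "V"):
            errs = {
                lv: evaluate(
                    test_p.Y[form],
                    SIMPLSRegression(lv).fit(Xcp, cal_p.Y[form]).predict(Xtp),
                ).rmse
                for lv in lv_range
            }
            best = min(errs.values())
            expected_lv = min(l for l, e in errs.items() if e <= best + 1e-6)
            assert mset.selected_lv[form] == expected_lv
            assert mset.selection_errors[form] <= best + 1e-9

    def test_recipe_chosen_by_lower_mean_error(self, small_library):
        cal, test = _simulated_pair(small_library, noise=0.02, ref_sd=0.04)
        mset = build_model_set(
            [cal], test, procedure="cp_conc", recipes=["mean_center", "snv_auto"],
            truncation=(100.0, 1100.0),
        )
        scores = {}
        for name in ("mean_center", "snv_auto"):
            single = build_model_set(
                [cal], test, procedure="cp_conc", recipes=[name],
                truncation=(100.0, 1100.0),
            )
            scores[name] = np.mean(list(single.selection_errors.values()))
        assert mset.recipe.name == min(scores, key=scores.get)

    def test_baseline_uses_cross_validation(self, small_library):
        _, test = _simulated_pair(small_library, noise=0.01, ref_sd=0.04)
        mset = build_model_set(
            None, test, procedure="baseline", recipes=["mean_center"],
            truncation=(100.0, 1100.0), n_splits=10,
        )
        assert mset.selection_metric == "rmsecv"
        assert set(mset.models) == {"II", "V"}

    def test_cp_requires_exactly_one_calibration_run(self, small_library):
        cal, test = _simulated_pair(small_library)
        with pytest.raises(ParameterError):
            build_model_set([cal, cal], test, procedure="cp",
                            truncation=(100.0, 1100.0))

    def test_all_forms_absent_raises(self, small_library):
        none_convert = KineticParams(edges=[KineticEdge("salt", "V", 0.0)])
        cal, test = _simulated_pair(small_library, kinetics=none_convert)
        with pytest.raises(SelectionError):
            build_model_set([cal], test, forms=["II", "V"], procedure="cp",
                            recipes=["mean_center"], truncation=(100.0, 1100.0))


class TestPredictRun:
    def test_reported_composition_closes_everywhere(self, small_library):
        cal, test = _simulated_pair(small_library, noise=0.03, ref_sd=0.04)
        mset = build_model_set([cal], test, procedure="cp", recipes=["mean_center"],
                               truncation=(100.0, 1100.0))
        series = predict_run(mset, test)
        sums = series.clipped.sum(axis=1).to_numpy()
        assert np.abs(sums - 1.0).max() < 1e-9
        assert series.clipped.to_numpy().min() >= 0.0

    def test_salt_closure_matches_raw_freebase(self, small_library):
        cal, test = _simulated_pair(small_library)
        mset = build_model_set([cal], test, procedure="cp", recipes=["mean_center"],
                               truncation=(100.0, 1100.0))
        series = predict_run(mset, test)
        expected = 1.0 - series.raw[["II", "V"]].sum(axis=1)
        assert np.allclose(series.raw["salt"], expected, atol=1e-12)

    def test_model_set_serialization_round_trip(self, small_library, tmp_path):
        cal, test = _simulated_pair(small_library, noise=0.01, ref_sd=0.04)
        mset = build_model_set([cal], test, procedure="cp", recipes=["mean_center"],
                               truncation=(100.0, 1100.0))
        path = tmp_path / "model.json"
        mset.to_json(path)
        restored = ModelSet.from_json(path)
        a, b = predict_run(mset, test), predict_run(restored, test)
        assert np.allclose(a.raw.to_numpy(), b.raw.to_numpy(), atol=1e-12)
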