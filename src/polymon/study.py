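"""End-to-end synthetic study: simulate runs, build model sets, rank salts.

``run_study`` reproduces the full study design on synthetic data: for each
salt it simulates three calibration runs (50.0 / 25.0 / 12.5 mg/mL) and one
test run (16.7 mg/mL), builds the baseline model set, three single-run
calibrations (model sets 1–3) and the pooled-concentration calibration
(model set 4), predicts the test run with every set, estimates the
zero-order disproportionation rate from the pooled-calibration salt time
course, and ranks the salts by physical stability. Because the runs are
synthetic, the report also carries ground-truth recovery errors.

The whole study is deterministic given the master seed: every run draws
from a child of one ``numpy.random.SeedSequence`` and its derived seed is
recorded in the run metadata and the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .calibration import ModelSet, PredictionSeries, build_model_set, predict_run
from .errors import ParameterError
from .kinetics import KineticEstimate, StabilityRanking, compare_salts, fit_zero_order
from .library import (
    FormLibrary,
    KineticParams,
    RunConfig,
    default_kinetics,
    default_library,
)
from .runs import ProcessRun, write_run
from .simulate import simulate_run

logger = logging.getLogger(__name__)

__all__ = ["SaltStudyConfig", "StudyConfig", "run_study", "load_study_config", "default_study_config"]


def _library_from_config(d: Mapping) -> FormLibrary:
    if "forms" in d:
        return FormLibrary.from_dict(d)
    kind = d["kind"]
    return default_library(
        kind,
        shift_per_conc=float(d.get("shift_per_conc", 0.0)),
        alpha=float(d.get("alpha", 1.0)),
        ref_conc=float(d.get("ref_conc", 16.7)),
    )


def _kinetics_from_config(d: Mapping) -> KineticParams:
    if "edges" in d:
        return KineticParams.from_dict(d)
    return default_kinetics(d["kind"], include_form_I=bool(d.get("include_form_I", True)))


@dataclass
class RunOverride:
    """Per-run deviations from the salt-level study conditions."""

    kinetics: KineticParams | None = None
    noise_sd: float | None = None
    baseline_jitter_sd: float | None = None
    ref_rel_sd: float | None = None


@dataclass
class SaltStudyConfig:
    """Per-salt study inputs: signatures, kinetics, sampling plan."""

    salt_id: str
    library: FormLibrary
    kinetics: KineticParams
    xrpd_times: dict[float, list[float]]
    recipes: list[str] = field(default_factory=lambda: ["mean_center"])
    run_overrides: dict[float, RunOverride] = field(default_factory=dict)

    def kinetics_for(self, conc: float) -> KineticParams:
        ov = self.run_overrides.get(conc)
        return ov.kinetics if ov is not None and ov.kinetics is not None else self.kinetics


@dataclass
class StudyConfig:
    """Full study configuration (two salts by default)."""

    salts: dict[str, SaltStudyConfig]
    cal_concs: list[float] = field(default_factory=lambda: [50.0, 25.0, 12.5])
    test_conc: float = 16.7
    duration: float = 450.0
    cadence: float = 2.0
    procedures: list[str] = field(default_factory=lambda: ["baseline", "cp", "cp_conc"])
    lv_max: int = 6
    truncation: tuple[float, float] = (100.0, 1761.0)
    noise_sd: float = 0.04
    baseline_coeffs: list[float] = field(default_factory=list)
    baseline_jitter_sd: float = 0.0
    #: fractional baseline growth per unit conversion (fluorescing solute)
    fluor_conversion_coupling: float = 0.0
    #: exponent q in baseline_scale = (ref_conc/conc)**q — the fluorescence
    #: background relative to the solid signal grows at low suspension density
    fluor_density_exponent: float = 0.0
    ref_rel_sd: float = 0.04
    seed: int = 0

    def __post_init__(self):
        if self.test_conc in self.cal_concs:
            raise ParameterError("test concentration must differ from calibration concentrations")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        salts = {}
        for salt_id, sd in d["salts"].items():
            overrides = {}
            for conc, o in sd.get("run_overrides", {}).items():
                overrides[float(conc)] = RunOverride(
                    kinetics=_kinetics_from_config(o["kinetics"]) if "kinetics" in o else None,
                    noise_sd=float(o["noise_sd"]) if "noise_sd" in o else None,
                    baseline_jitter_sd=(
                        float(o["baseline_jitter_sd"]) if "baseline_jitter_sd" in o else None
                    ),
                    ref_rel_sd=float(o["ref_rel_sd"]) if "ref_rel_sd" in o else None,
                )
            salts[salt_id] = SaltStudyConfig(
                salt_id=salt_id,
                library=_library_from_config(sd["library"]),
                kinetics=_kinetics_from_config(sd["kinetics"]),
                xrpd_times={float(c): [float(t) for t in ts] for c, ts in sd["xrpd_times"].items()},
                recipes=list(sd.get("recipes", ["mean_center"])),
                run_overrides=overrides,
            )
        return cls(
            salts=salts,
            cal_concs=[float(c) for c in d.get("cal_concs", [50.0, 25.0, 12.5])],
            test_conc=float(d.get("test_conc", 16.7)),
            duration=float(d.get("duration_min", 450.0)),
            cadence=float(d.get("cadence_min", 2.0)),
            procedures=list(d.get("procedures", ["baseline", "cp", "cp_conc"])),
            lv_max=int(d.get("lv_max", 6)),
            truncation=tuple(d.get("truncation", (100.0, 1761.0))),
            noise_sd=float(d.get("noise_sd", 0.04)),
            baseline_coeffs=[float(c) for c in d.get("baseline_coeffs", [])],
            baseline_jitter_sd=float(d.get("baseline_jitter_sd", 0.0)),
            fluor_conversion_coupling=float(d.get("fluor_conversion_coupling", 0.0)),
            fluor_density_exponent=float(d.get("fluor_density_exponent", 0.0)),
            ref_rel_sd=float(d.get("ref_rel_sd", 0.04)),
            seed=int(d.get("seed", 0)),
        )


def load_study_config(path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh))


def default_study_config(seed: int | None = None) -> StudyConfig:
    """The packaged default study (two salts, four runs each)."""
    text = resources.files("polymon.config").joinpath("default_study.yaml").read_text()
    cfg = StudyConfig.from_dict(yaml.safe_load(text))
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


# ---------------------------------------------------------------------------
# study execution
# ---------------------------------------------------------------------------

def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study_runs(cfg: StudyConfig) -> dict[str, dict[float, ProcessRun]]:
    """Simulate every run of the study, deterministically from the seed."""
    base = np.random.SeedSequence(cfg.seed)
    runs: dict[str, dict[float, ProcessRun]] = {}
    for salt_id in sorted(cfg.salts):
        sc = cfg.salts[salt_id]
        runs[salt_id] = {}
        for conc in [*cfg.cal_concs, cfg.test_conc]:
            child = base.spawn(1)[0]
            seed = _child_seed(child)
            ov = sc.run_overrides.get(conc)
            rc = RunConfig(
                salt_id=salt_id,
                conc=conc,
                duration=cfg.duration,
                cadence=cfg.cadence,
                xrpd_times=sc.xrpd_times[conc],
                ref_rel_sd=(
                    ov.ref_rel_sd if ov is not None and ov.ref_rel_sd is not None
                    else cfg.ref_rel_sd
                ),
                noise_sd=(
                    ov.noise_sd if ov is not None and ov.noise_sd is not None
                    else cfg.noise_sd
                ),
                baseline_coeffs=cfg.baseline_coeffs,
                baseline_jitter_sd=(
                    ov.baseline_jitter_sd
                    if ov is not None and ov.baseline_jitter_sd is not None
                    else cfg.baseline_jitter_sd
                ),
                # background/signal ratio grows only below the suspension-
                # density threshold (the reference concentration)
                baseline_scale=float(
                    max(1.0, sc.library.ref_conc / conc) ** cfg.fluor_density_exponent
                ),
                fluor_conversion_coupling=cfg.fluor_conversion_coupling,
                seed=seed,
            )
            try:
                runs[salt_id][conc] = simulate_run(rc, sc.kinetics_for(conc), sc.library)
            except Exception as exc:  # noqa: BLE001 - annotate stage and run id
                raise RuntimeError(
                    f"stage 'simulate' failed for run {salt_id}@{conc:g} mg/mL"
                ) from exc
    return runs


def _model_set_plan(cfg: StudyConfig) -> list[tuple[str, str, list[float] | None]]:
    """(set label, procedure, calibration concentrations) in build order."""
    plan: list[tuple[str, str, list[float] | None]] = []
    if "baseline" in cfg.procedures:
        plan.append(("baseline", "baseline", None))
    if "cp" in cfg.procedures:
        for i, conc in enumerate(cfg.cal_concs, start=1):
            plan.append((f"model_set_{i}", "cp", [conc]))
    if "cp_conc" in cfg.procedures:
        plan.append((f"model_set_{len(cfg.cal_concs) + 1}", "cp_conc", list(cfg.cal_concs)))
    return plan


def _truth_recovery(series: PredictionSeries, run: ProcessRun, forms: Sequence[str]) -> dict:
    """RMSE of raw predictions against the noise-free trajectory."""
    if run.truth is None:
        return {}
    out = {}
    truth = run.truth.fractions
    for f in forms:
        if f in truth.columns and f in series.raw.columns:
            resid = series.raw[f].to_numpy() - truth[f].to_numpy()
            out[f] = float(np.sqrt(np.mean(resid**2)))
    return out


def run_study(cfg: StudyConfig, out_dir=None) -> dict:
    """Execute the full study; returns (and optionally writes) the report."""
    runs = simulate_study_runs(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "models").mkdir(exist_ok=True)

    report: dict = {"seed": cfg.seed, "test_conc": cfg.test_conc, "salts": {}}
    estimates: list[KineticEstimate] = []

    for salt_id in sorted(cfg.salts):
        sc = cfg.salts[salt_id]
        test_run = runs[salt_id][cfg.test_conc]
        salt_report: dict = {"runs": {}, "model_sets": {}}
        for conc, run in runs[salt_id].items():
            salt_report["runs"][f"{conc:g}"] = {
                "seed": run.seed,
                "n_spectra": int(run.n_spectra),
                "n_references": int(len(run.reference_wide())),
            }
            if out is not None:
                write_run(run, out / "runs" / salt_id / f"{conc:g}mgml")

        freebase = [f for f in sc.library.freebase_forms]
        for label, procedure, cal_concs in _model_set_plan(cfg):
            cal_runs = None if cal_concs is None else [runs[salt_id][c] for c in cal_concs]
            # the pooled procedure searches the salt's candidate recipes;
            # baseline and single-run calibrations use mean centering
            recipes = sc.recipes if procedure == "cp_conc" else ["mean_center"]
            try:
                mset = build_model_set(
                    cal_runs,
                    test_run,
                    forms=freebase,
                    procedure=procedure,
                    recipes=recipes,
                    lv_range=range(1, cfg.lv_max + 1),
                    truncation=cfg.truncation,
                )
                series = predict_run(mset, test_run)
            except Exception as exc:  # noqa: BLE001 - annotate stage and run id
                raise RuntimeError(
                    f"stage 'calibrate' failed for {salt_id}/{label}"
                ) from exc

            metric = mset.selection_metric
            entry: dict = {
                "procedure": procedure,
                "calibration_concs": cal_concs if cal_concs is not None else "N/A",
                "metric": metric,
                "recipe": mset.recipe.name,
                "forms": {},
                "truth_recovery_rmse": _truth_recovery(series, test_run, freebase),
            }
            for f in freebase:
                if f in mset.unmodelable:
                    entry["forms"][f] = {"rmse": "N/A", "n_lv": "N/A", "r2": "N/A"}
                else:
                    ev = series.evaluations.get(f)
                    rmse = mset.selection_errors[f] if metric == "rmsecv" else ev.rmse
                    entry["forms"][f] = {
                        "rmse": float(rmse),
                        "n_lv": mset.selected_lv[f],
                        "r2": float(ev.r2) if ev is not None else "N/A",
                    }
            salt_report["model_sets"][label] = entry

            if out is not None:
                mset.to_json(out / "models" / f"{salt_id}_{label}.json")
                pred = series.clipped.copy()
                pred.insert(0, "time_min", series.times)
                for f in series.raw.columns:
                    pred[f"raw_{f}"] = series.raw[f].to_numpy()
                pred.to_csv(out / f"predictions_{salt_id}_{label}.csv", index=False)

            if procedure == "cp_conc":
                est = fit_zero_order(
                    series.times, series.clipped["salt"].to_numpy(), salt_id=salt_id
                )
                estimates.append(est)
                salt_report["kinetics"] = est.to_dict()

        report["salts"][salt_id] = salt_report

    if len(estimates) >= 2:
        ranking = compare_salts(estimates)
        report["stability_ranking"] = ranking.to_dict()

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
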