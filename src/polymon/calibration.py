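"""Calibration procedures, model sets, and closure-derived salt fractions.

Three procedures build a *model set* — one PLS model per freebase polymorph,
with the salt fraction always derived by closure (one minus the sum of the
freebase fractions):

``baseline``
    models built from the test run itself and judged by venetian-blinds
    (10-split) RMSECV; a benchmark, not a deployable calibration.
``cp``
    single-run calibration: one calibration run at a solid concentration
    different from the test run; models judged by RMSEP on the test run.
``cp_conc``
    pooled-concentration calibration: reference-matched spectra from all
    calibration runs (several solid concentrations) form one training set,
    so the concentration effect itself is represented in calibration.

Latent-variable counts (and, when several are offered, the preprocessing
recipe) are selected by minimising the procedure's figure of merit; ties go
to the smallest LV count. Freebase forms with fewer than three distinct
reference values in calibration are flagged *unmodelable* rather than
silently dropped. Predictions are never clipped before error computation;
clipping to [0, 1] happens only when composing the reported composition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemometrics import (
    EvaluationResult,
    SIMPLSRegression,
    evaluate,
    venetian_blinds_cv,
)
from .errors import (
    AbsentModelError,
    InputDataError,
    ParameterError,
    SelectionError,
    UnmatchedReferenceError,
)
from .preprocessing import PreprocessingRecipe, truncate_matrix
from .runs import ProcessRun

logger = logging.getLogger(__name__)

__all__ = [
    "PairedData",
    "pair_references",
    "closure_salt_fraction",
    "closure_compositions",
    "ModelSet",
    "build_model_set",
    "predict_run",
    "PredictionSeries",
    "PROCEDURES",
]

PROCEDURES = ("baseline", "cp", "cp_conc")

#: default reference-to-spectrum pairing tolerance: one cadence step
DEFAULT_PAIR_TOLERANCE = 2.0

#: default truncation window emphasising the form-specific fingerprint region
DEFAULT_TRUNCATION = (100.0, 1761.0)

#: a modeled form needs at least this many distinct reference values
MIN_DISTINCT_REFERENCES = 3

#: LV-selection tie tolerance: smallest count within this of the minimum wins
LV_TIE_TOL = 1e-6


# ---------------------------------------------------------------------------
# reference ↔ spectrum pairing
# ---------------------------------------------------------------------------

@dataclass
class PairedData:
    """Reference measurements matched to their nearest-in-time spectra."""

    X: np.ndarray  # (n_refs, n_channels) raw spectra at matched times
    Y: pd.DataFrame  # one row per reference, columns = forms
    spectrum_indices: np.ndarray
    ref_times: np.ndarray
    shift: np.ndarray


def pair_references(run: ProcessRun, tolerance: float = DEFAULT_PAIR_TOLERANCE) -> PairedData:
    """Match each reference to the nearest spectrum within ``tolerance`` min.

    Ties go to the earlier spectrum; each spectrum is used at most once.
    Raises :class:`UnmatchedReferenceError` listing every reference time for
    which no admissible spectrum remains.
    """
    wide = run.reference_wide()
    if wide.empty:
        raise InputDataError("run has no reference measurements")

    used: set[int] = set()
    chosen: list[int] = []
    unmatched: list[float] = []
    for t in wide.index:
        dt = np.abs(run.times - t)
        order = np.lexsort((run.times, dt))  # nearest first, earlier on ties
        pick = next(
            (int(i) for i in order if dt[i] <= tolerance and int(i) not in used), None
        )
        if pick is None:
            unmatched.append(float(t))
        else:
            used.add(pick)
            chosen.append(pick)
    if unmatched:
        raise UnmatchedReferenceError(unmatched)

    idx = np.asarray(chosen, dtype=int)
    return PairedData(
        X=run.spectra[idx],
        Y=wide.reset_index(drop=True),
        spectrum_indices=idx,
        ref_times=wide.index.to_numpy(dtype=float),
        shift=run.shift,
    )


# ---------------------------------------------------------------------------
# closure
# ---------------------------------------------------------------------------

def closure_salt_fraction(freebase: Mapping[str, float]) -> float:
    """Salt fraction by closure: 1 minus the clipped freebase fractions.

    Each freebase prediction is clipped to [0, 1] first (raw PLS output may
    stray outside the physical range); the derived salt fraction is clipped
    to [0, 1] as well. Clipping events are logged.
    """
    total = 0.0
    for form, value in freebase.items():
        clipped = min(max(float(value), 0.0), 1.0)
        if clipped != value:
            logger.warning("clipped %s prediction %.4f to %.4f", form, value, clipped)
        total += clipped
    salt = 1.0 - total
    if salt < 0.0:
        logger.warning("closure salt fraction %.4f clipped to 0", salt)
        salt = 0.0
    return salt


def closure_compositions(raw: pd.DataFrame) -> pd.DataFrame:
    """Reported compositions from raw freebase predictions.

    Freebase columns are clipped to [0, 1]; the salt column is the closure
    remainder. When the clipped freebase fractions exceed unity they are
    rescaled to sum to 1 (salt 0), so every reported row closes exactly.
    """
    clipped = raw.clip(lower=0.0, upper=1.0)
    total = clipped.sum(axis=1)
    over = total > 1.0
    if over.any():
        logger.warning(
            "freebase predictions exceeded unity at %d timestamp(s); rescaled",
            int(over.sum()),
        )
        clipped.loc[over] = clipped.loc[over].div(total[over], axis=0)
        total = clipped.sum(axis=1)
    out = clipped.copy()
    out["salt"] = (1.0 - total).clip(lower=0.0)
    return out


# ---------------------------------------------------------------------------
# model sets
# ---------------------------------------------------------------------------

@dataclass
class PredictionSeries:
    """Per-form prediction time course for one run."""

    times: np.ndarray
    raw: pd.DataFrame  # freebase forms + "salt" (unclipped; salt = 1 − Σ raw)
    clipped: pd.DataFrame  # reported composition, rows sum to 1
    evaluations: dict[str, EvaluationResult] = field(default_factory=dict)


@dataclass
class ModelSet:
    """Per-form PLS models plus the closure rule and selection metadata."""

    procedure: str
    salt_form: str
    truncation: tuple[float, float]
    recipe: PreprocessingRecipe
    models: dict[str, SIMPLSRegression]
    selected_lv: dict[str, int]
    selection_errors: dict[str, float]  # form → RMSEP (RMSECV for baseline)
    unmodelable: list[str] = field(default_factory=list)
    selection_metric: str = "rmsep"
    selection_trace: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def forms(self) -> list[str]:
        return list(self.models)

    def predict_matrix(self, shift: np.ndarray, spectra: np.ndarray) -> pd.DataFrame:
        """Raw per-form predictions for a spectra matrix on axis ``shift``."""
        _, Xt = truncate_matrix(shift, spectra, *self.truncation)
        Xp = self.recipe.transform(Xt)
        return pd.DataFrame({f: m.predict(Xp) for f, m in self.models.items()})

    def predict_run(self, run: ProcessRun, tolerance: float = DEFAULT_PAIR_TOLERANCE) -> PredictionSeries:
        return predict_run(self, run, tolerance=tolerance)

    # ---- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "salt_form": self.salt_form,
            "truncation": list(self.truncation),
            "recipe": self.recipe.to_dict(),
            "models": {f: m.to_dict() for f, m in self.models.items()},
            "selected_lv": self.selected_lv,
            "selection_errors": self.selection_errors,
            "selection_metric": self.selection_metric,
            "unmodelable": self.unmodelable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSet":
        return cls(
            procedure=d["procedure"],
            salt_form=d["salt_form"],
            truncation=tuple(d["truncation"]),
            recipe=PreprocessingRecipe.from_dict(d["recipe"]),
            models={f: SIMPLSRegression.from_dict(m) for f, m in d["models"].items()},
            selected_lv={f: int(v) for f, v in d["selected_lv"].items()},
            selection_errors={f: float(v) for f, v in d["selection_errors"].items()},
            selection_metric=d.get("selection_metric", "rmsep"),
            unmodelable=list(d.get("unmodelable", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _select_lv(errors: dict[int, float]) -> tuple[int, float]:
    """Smallest LV count whose error is within LV_TIE_TOL of the minimum."""
    best = min(errors.values())
    lv = min(k for k, v in errors.items() if v <= best + LV_TIE_TOL)
    return lv, errors[lv]


def build_model_set(
    cal_runs: Sequence[ProcessRun] | None,
    test_run: ProcessRun,
    forms: Iterable[str] | None = None,
    *,
    procedure: str = "cp",
    recipes: Sequence[str] = ("mean_center",),
    lv_range: Iterable[int] = range(1, 7),
    truncation: tuple[float, float] = DEFAULT_TRUNCATION,
    salt_form: str = "salt",
    n_splits: int = 10,
    tolerance: float = DEFAULT_PAIR_TOLERANCE,
    selection: str = "test",
) -> ModelSet:
    """Build one calibration model set.

    Parameters
    ----------
    cal_runs :
        Calibration runs (ignored for ``procedure="baseline"``, which uses
        the test run itself with cross-validation).
    test_run :
        The held-out run on which ``cp``/``cp_conc`` selection errors
        (RMSEP) are computed.
    forms :
        Freebase forms to model; defaults to every non-salt form appearing
        in the calibration references. The salt form never gets its own
        model (closure-derived).
    recipes :
        Candidate preprocessing recipe names; the recipe minimising the
        mean selection error across modeled forms is kept for the whole set.
    selection :
        ``"test"`` selects LV counts on the test run, mirroring the original
        optimisation (optimistic, since the test run steers selection);
        ``"cv"`` is a conservative alternative that selects by
        venetian-blinds RMSECV within calibration and reports test RMSEP
        only for the chosen model.
    """
    if procedure not in PROCEDURES:
        raise ParameterError(f"unknown procedure {procedure!r}; choose from {PROCEDURES}")
    if selection not in ("test", "cv"):
        raise ParameterError("selection must be 'test' or 'cv'")
    lv_range = sorted(set(int(v) for v in lv_range))
    if not lv_range or lv_range[0] < 1:
        raise ParameterError("lv_range must contain positive integers")

    if procedure == "baseline":
        cal_paired = [pair_references(test_run, tolerance)]
    else:
        if not cal_runs:
            raise InputDataError(f"procedure {procedure!r} needs calibration runs")
        if procedure == "cp" and len(cal_runs) != 1:
            raise ParameterError("single-run calibration (cp) takes exactly one calibration run")
        cal_paired = [pair_references(r, tolerance) for r in cal_runs]

    X_cal = np.vstack([p.X for p in cal_paired])
    Y_cal = pd.concat([p.Y for p in cal_paired], ignore_index=True).fillna(0.0)
    if X_cal.shape[0] == 0:
        raise InputDataError("empty calibration reference set")

    test_paired = pair_references(test_run, tolerance)
    shift = cal_paired[0].shift
    _, Xt_cal_raw = truncate_matrix(shift, X_cal, *truncation)
    _, Xt_test_raw = truncate_matrix(test_run.shift, test_paired.X, *truncation)

    candidate_forms = [f for f in Y_cal.columns if f != salt_form]
    if forms is not None:
        forms = list(forms)
        candidate_forms = [f for f in forms if f != salt_form]
    modelable, unmodelable = [], []
    for f in candidate_forms:
        y = Y_cal[f].to_numpy() if f in Y_cal.columns else np.zeros(len(Y_cal))
        if np.unique(y).size >= MIN_DISTINCT_REFERENCES:
            modelable.append(f)
        else:
            unmodelable.append(f)
            logger.info(
                "form %s flagged unmodelable (<%d distinct reference values)",
                f, MIN_DISTINCT_REFERENCES,
            )
    if not modelable:
        raise SelectionError("no freebase form has enough distinct reference values")

    n_cal = Xt_cal_raw.shape[0]
    metric = "rmsecv" if (procedure == "baseline" or selection == "cv") else "rmsep"

    best: dict | None = None
    trace: dict[str, dict[str, float]] = {f: {} for f in modelable}
    for recipe_name in recipes:
        recipe = PreprocessingRecipe(name=recipe_name).fit(Xt_cal_raw)
        Xp_cal = recipe.transform(Xt_cal_raw)
        Xp_test = recipe.transform(Xt_test_raw)
        per_form: dict[str, tuple[int, float]] = {}
        for f in modelable:
            y = Y_cal[f].to_numpy()
            errors: dict[int, float] = {}
            for lv in lv_range:
                if lv > min(n_cal - 1, Xp_cal.shape[1]):
                    continue
                try:
                    if procedure == "baseline" or selection == "cv":
                        err = venetian_blinds_cv(Xp_cal, y, n_splits, lv).rmse
                    else:
                        model = SIMPLSRegression(n_components=lv).fit(Xp_cal, y)
                        err = evaluate(
                            test_paired.Y[f].to_numpy(), model.predict(Xp_test)
                        ).rmse
                except ParameterError:
                    continue
                errors[lv] = err
                trace[f][f"{recipe_name}/lv{lv}"] = float(err)
            if errors:
                per_form[f] = _select_lv(errors)
        if len(per_form) < len(modelable):
            continue  # this recipe could not model every form
        score = float(np.mean([err for _, err in per_form.values()]))
        if best is None or score < best["score"]:
            best = {"score": score, "recipe": recipe, "name": recipe_name, "per_form": per_form}

    if best is None:
        raise SelectionError("every candidate model was degenerate")

    recipe = best["recipe"]
    Xp_cal = recipe.transform(Xt_cal_raw)
    models, selected_lv, selection_errors = {}, {}, {}
    for f, (lv, err) in best["per_form"].items():
        models[f] = SIMPLSRegression(n_components=lv).fit(Xp_cal, Y_cal[f].to_numpy())
        selected_lv[f] = lv
        selection_errors[f] = float(err)

    return ModelSet(
        procedure=procedure,
        salt_form=salt_form,
        truncation=tuple(truncation),
        recipe=recipe,
        models=models,
        selected_lv=selected_lv,
        selection_errors=selection_errors,
        unmodelable=unmodelable,
        selection_metric=metric,
        selection_trace=trace,
    )


def predict_run(
    model_set: ModelSet, run: ProcessRun, tolerance: float = DEFAULT_PAIR_TOLERANCE
) -> PredictionSeries:
    """Predict the full per-form time course of a run, plus its evaluation.

    Raw predictions are kept unclipped (errors against references must
    reflect raw model behaviour); the reported composition applies closure
    clipping. Per-form RMSEP/R² are computed at the reference-matched
    timestamps against the run's reference fractions.
    """
    raw = model_set.predict_matrix(run.shift, run.spectra)
    raw["salt"] = 1.0 - raw[[f for f in model_set.forms]].sum(axis=1)
    clipped = closure_compositions(raw[model_set.forms])

    evaluations: dict[str, EvaluationResult] = {}
    try:
        paired = pair_references(run, tolerance)
    except InputDataError:
        paired = None
    if paired is not None:
        for f in model_set.forms:
            if f in paired.Y.columns:
                y_true = paired.Y[f].to_numpy()
                y_pred = raw[f].to_numpy()[paired.spectrum_indices]
                evaluations[f] = evaluate(y_true, y_pred, metric="rmsep")
        if model_set.salt_form in paired.Y.columns:
            y_pred = raw["salt"].to_numpy()[paired.spectrum_indices]
            evaluations["salt"] = evaluate(
                paired.Y[model_set.salt_form].to_numpy(), y_pred, metric="rmsep"
            )

    return PredictionSeries(
        times=run.times.copy(),
        raw=raw,
        clipped=clipped,
        evaluations=evaluations,
    )
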