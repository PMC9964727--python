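"""Spectral preprocessing: truncation, SNV, column scaling, recipes.

The scatter/baseline correction implemented here is standard normal variate
(SNV): each spectrum is centered at zero by subtracting its own mean
intensity and divided by its own standard deviation. SNV acts row-wise and
therefore needs no fitted state; column scaling (mean centering or
autoscaling) is fitted on calibration data and applied unchanged to test
data. The sample standard deviation (n−1 denominator) is used everywhere.

Transformers follow the scikit-learn fit/transform contract and compose
with :class:`sklearn.pipeline.Pipeline`.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import EmptySelectionError, InputDataError, ParameterError, ZeroVarianceError
from .spectra import RamanSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "truncate",
    "truncate_matrix",
    "snv",
    "snv_matrix",
    "SNVTransformer",
    "ColumnScaler",
    "PreprocessingRecipe",
    "RECIPES",
]


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def truncate_matrix(shift: np.ndarray, X: np.ndarray, lo: float, hi: float):
    """Keep channels with ``lo <= shift <= hi`` (inclusive both ends)."""
    if lo >= hi:
        raise ParameterError("truncation window requires lo < hi")
    shift = np.asarray(shift, dtype=float)
    mask = (shift >= lo) & (shift <= hi)
    if not mask.any():
        raise EmptySelectionError(f"no channels inside window [{lo}, {hi}] cm⁻¹")
    X = np.asarray(X, dtype=float)
    return shift[mask], X[..., mask]


def truncate(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Truncate one spectrum to the window ``[lo, hi]`` cm⁻¹."""
    shift, intensity = truncate_matrix(spectrum.shift, spectrum.intensity, lo, hi)
    return RamanSpectrum(shift, intensity, time_min=spectrum.time_min)


# ---------------------------------------------------------------------------
# SNV
# ---------------------------------------------------------------------------

def snv_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV: subtract each row's mean, divide by its sample SD."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] < 2:
        raise InputDataError("SNV requires at least two channels")
    mean = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd == 0.0):
        raise ZeroVarianceError("SNV undefined for a constant spectrum")
    return (X - mean) / sd


def snv(spectrum: RamanSpectrum) -> RamanSpectrum:
    """SNV-normalize one spectrum (output mean 0, sample SD 1)."""
    return RamanSpectrum(
        spectrum.shift, snv_matrix(spectrum.intensity), time_min=spectrum.time_min
    )


class SNVTransformer(TransformerMixin, BaseEstimator):
    """Stateless row-wise SNV as a scikit-learn transformer."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return snv_matrix(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# column scaling
# ---------------------------------------------------------------------------

class ColumnScaler(TransformerMixin, BaseEstimator):
    """Mean centering or autoscaling fitted on calibration spectra.

    Parameters
    ----------
    mode : {"mean_center", "autoscale"}
        ``mean_center`` subtracts the per-channel training mean;
        ``autoscale`` additionally divides by the per-channel training
        sample SD. Channels with zero training variance are dropped with a
        logged warning in autoscale mode (they carry no usable signal and
        would otherwise divide by zero).

    Attributes
    ----------
    mean_ : ndarray of shape (n_channels,)
    scale_ : ndarray, autoscale only (SD of the kept channels)
    keep_mask_ : boolean ndarray marking the channels retained
    """

    def __init__(self, mode: str = "mean_center"):
        self.mode = mode

    def fit(self, X, y=None):
        if self.mode not in ("mean_center", "autoscale"):
            raise ParameterError(f"unknown scaling mode {self.mode!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise InputDataError("column scaling must be fitted on >= 2 rows")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        self.keep_mask_ = np.ones(X.shape[1], dtype=bool)
        if self.mode == "autoscale":
            sd = X.std(axis=0, ddof=1)
            zero = sd == 0.0
            if zero.any():
                msg = f"dropping {int(zero.sum())} zero-variance channel(s) before autoscaling"
                logger.warning(msg)
                warnings.warn(msg, UserWarning, stacklevel=2)
                self.keep_mask_ = ~zero
            self.scale_ = sd[self.keep_mask_]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise InputDataError(
                f"expected {self.n_features_in_} channels, got {X.shape[-1]}"
            )
        Xc = (X - self.mean_)[..., self.keep_mask_]
        if self.mode == "autoscale":
            Xc = Xc / self.scale_
        return Xc

    def inverse_transform(self, Xt):
        check_is_fitted(self, "mean_")
        Xt = np.asarray(Xt, dtype=float)
        if self.mode == "autoscale":
            Xt = Xt * self.scale_
        X = np.empty(Xt.shape[:-1] + (self.n_features_in_,))
        X[...] = self.mean_  # dropped channels restore to their training mean
        X[..., self.keep_mask_] = Xt + self.mean_[self.keep_mask_]
        return X

    # ---- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "mean_")
        d = {
            "mode": self.mode,
            "mean": self.mean_.tolist(),
            "keep_mask": self.keep_mask_.tolist(),
        }
        if self.mode == "autoscale":
            d["scale"] = self.scale_.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnScaler":
        obj = cls(mode=d["mode"])
        obj.mean_ = np.asarray(d["mean"], dtype=float)
        obj.keep_mask_ = np.asarray(d["keep_mask"], dtype=bool)
        obj.n_features_in_ = obj.mean_.size
        if obj.mode == "autoscale":
            obj.scale_ = np.asarray(d["scale"], dtype=float)
        return obj


# ---------------------------------------------------------------------------
# named recipes
# ---------------------------------------------------------------------------

#: recipe id → (apply_snv, column mode). SNV is row-wise so it precedes
#: column scaling; truncation happens before either, in the calibration layer.
RECIPES: dict[str, tuple[bool, str]] = {
    "mean_center": (False, "mean_center"),
    "snv_auto": (True, "autoscale"),
}


class PreprocessingRecipe(TransformerMixin, BaseEstimator):
    """A named preprocessing chain: optional SNV, then column scaling."""

    def __init__(self, name: str = "mean_center"):
        self.name = name

    def _parts(self):
        if self.name not in RECIPES:
            raise ParameterError(f"unknown recipe {self.name!r}; choose from {sorted(RECIPES)}")
        return RECIPES[self.name]

    def fit(self, X, y=None):
        use_snv, mode = self._parts()
        X = np.asarray(X, dtype=float)
        if use_snv:
            X = snv_matrix(X)
        self.scaler_ = ColumnScaler(mode=mode).fit(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scaler_")
        use_snv, _ = self._parts()
        X = np.asarray(X, dtype=float)
        if use_snv:
            X = snv_matrix(X)
        return self.scaler_.transform(X)

    def to_dict(self) -> dict:
        check_is_fitted(self, "scaler_")
        return {"name": self.name, "scaler": self.scaler_.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessingRecipe":
        obj = cls(name=d["name"])
        obj.scaler_ = ColumnScaler.from_dict(d["scaler"])
        obj.n_features_in_ = obj.scaler_.n_features_in_
        return obj
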