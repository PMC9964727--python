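"""Lightweight containers for single acquisitions.

A :class:`RamanSpectrum` is one in-line acquisition (shift axis in cm⁻¹ plus
intensity counts at a process timestamp); an :class:`XRPDPattern` is one
offline powder diffractogram (2θ axis in degrees plus counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputDataError

__all__ = ["RamanSpectrum", "XRPDPattern"]


def _as_axis(values, name: str) -> np.ndarray:
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1:
        raise InputDataError(f"{name} must be one-dimensional")
    if axis.size >= 2 and not np.all(np.diff(axis) > 0):
        raise InputDataError(f"{name} must be strictly increasing")
    return axis


@dataclass
class RamanSpectrum:
    """One Raman acquisition.

    Parameters
    ----------
    shift : array-like
        Raman shift axis in cm⁻¹, strictly increasing.
    intensity : array-like
        Intensity counts, same length as ``shift``.
    time_min : float
        Process timestamp in minutes (0 for standalone spectra).
    """

    shift: np.ndarray
    intensity: np.ndarray
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.shift = _as_axis(self.shift, "shift axis")
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.shift.shape:
            raise InputDataError("shift axis and intensities must have equal length")

    def __len__(self) -> int:
        return self.shift.size


@dataclass
class XRPDPattern:
    """One powder diffraction pattern on a 2θ axis (degrees)."""

    two_theta: np.ndarray
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.two_theta = _as_axis(self.two_theta, "2θ axis")
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != self.two_theta.shape:
            raise InputDataError("2θ axis and counts must have equal length")

    def __len__(self) -> int:
        return self.two_theta.size
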