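"""XRPD reference quantitation via binary-mixture calibration curves.

The offline reference method works on signature peaks: for every solid form
at least two non-overlapping 2θ windows are integrated (trapezoidal area
above a straight local baseline drawn between the window endpoints). Binary
physical mixtures prepared across the composition range give, per form, a
least-squares line of composition versus summed signature area. A process
sample's composition is then obtained by evaluating each form's calibration
line on its signature areas, flooring negatives at zero, and normalising so
all fractions close to one — the closure also removes any global intensity
scale between patterns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    IndeterminateCompositionError,
    InputDataError,
    ParameterError,
)
from .spectra import XRPDPattern

__all__ = [
    "integrate_peak",
    "BinaryCalCurve",
    "build_binary_curve",
    "quantify_process_sample",
    "read_pattern",
    "write_pattern",
    "save_curves",
    "load_curves",
]


def integrate_peak(pattern: XRPDPattern, window: tuple[float, float]) -> float:
    """Trapezoidal peak area above a local linear baseline.

    The baseline is the straight line between the first and last points
    inside ``window``; the area is floored at zero.
    """
    lo, hi = window
    if lo >= hi:
        raise ParameterError("integration window requires lo < hi")
    mask = (pattern.two_theta >= lo) & (pattern.two_theta <= hi)
    if mask.sum() < 2:
        raise InputDataError(f"window [{lo}, {hi}]° overlaps fewer than two points")
    x = pattern.two_theta[mask]
    y = pattern.counts[mask]
    baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    area = float(np.trapezoid(y - baseline, x))
    return max(area, 0.0)


@dataclass
class BinaryCalCurve:
    """Composition-vs-area lines for one binary pair of forms."""

    form_a: str
    form_b: str
    windows: dict[str, list[tuple[float, float]]]
    slope: dict[str, float] = field(default_factory=dict)
    intercept: dict[str, float] = field(default_factory=dict)
    r2: dict[str, float] = field(default_factory=dict)

    @property
    def forms(self) -> tuple[str, str]:
        return (self.form_a, self.form_b)

    def amount(self, form: str, pattern: XRPDPattern) -> float:
        """Raw composition estimate of ``form`` from its signature areas."""
        if form not in self.slope:
            raise ParameterError(f"curve {self.form_a}/{self.form_b} does not cover {form!r}")
        area = sum(integrate_peak(pattern, w) for w in self.windows[form])
        return self.slope[form] * area + self.intercept[form]

    def to_dict(self) -> dict:
        return {
            "form_a": self.form_a,
            "form_b": self.form_b,
            "windows": {f: [list(w) for w in ws] for f, ws in self.windows.items()},
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryCalCurve":
        return cls(
            form_a=d["form_a"],
            form_b=d["form_b"],
            windows={f: [tuple(w) for w in ws] for f, ws in d["windows"].items()},
            slope={f: float(v) for f, v in d["slope"].items()},
            intercept={f: float(v) for f, v in d["intercept"].items()},
            r2={f: float(v) for f, v in d["r2"].items()},
        )


def build_binary_curve(
    mixtures: Sequence[tuple[float, XRPDPattern]],
    windows: Mapping[str, Sequence[tuple[float, float]]],
    forms: tuple[str, str],
) -> BinaryCalCurve:
    """Fit composition-vs-area lines from binary physical mixtures.

    ``mixtures`` holds ``(composition_of_form_a, pattern)`` pairs; the
    second form's composition is the complement. Requires at least three
    distinct compositions spanning at least half the range.
    """
    form_a, form_b = forms
    comps = np.array([c for c, _ in mixtures], dtype=float)
    if np.unique(comps).size < 3:
        raise InputDataError("binary curve needs >= 3 distinct compositions")
    if comps.max() - comps.min() < 0.5:
        raise InputDataError("binary compositions must span at least 0.5")
    for f in forms:
        if len(windows.get(f, [])) < 2:
            raise InputDataError(f"form {f!r} needs >= 2 signature windows")

    curve = BinaryCalCurve(
        form_a=form_a,
        form_b=form_b,
        windows={f: [tuple(w) for w in windows[f]] for f in forms},
    )
    for f, comp_f in ((form_a, comps), (form_b, 1.0 - comps)):
        areas = np.array(
            [sum(integrate_peak(p, w) for w in curve.windows[f]) for _, p in mixtures]
        )
        if np.allclose(areas.std(), 0.0):
            raise InputDataError(f"degenerate (constant) signature areas for form {f!r}")
        fit = stats.linregress(areas, comp_f)
        curve.slope[f] = float(fit.slope)
        curve.intercept[f] = float(fit.intercept)
        curve.r2[f] = float(fit.rvalue**2)
    return curve


def quantify_process_sample(
    pattern: XRPDPattern, curves: Sequence[BinaryCalCurve], forms: Sequence[str] | None = None
) -> dict[str, float]:
    """Composition of a process sample from the binary calibration curves.

    Every form's raw amount is the average of its calibration-line estimates
    over all curves covering it; negatives are floored at zero and the
    result is normalised so the fractions of all forms sum to one.
    """
    if forms is None:
        forms = sorted({f for c in curves for f in c.forms})
    raw: dict[str, float] = {}
    for f in forms:
        estimates = [c.amount(f, pattern) for c in curves if f in c.slope]
        if not estimates:
            raise ParameterError(f"form {f!r} is covered by no calibration curve")
        raw[f] = max(float(np.mean(estimates)), 0.0)
    total = sum(raw.values())
    if total <= 0.0:
        raise IndeterminateCompositionError(
            "all raw phase amounts are zero; composition indeterminate"
        )
    return {f: v / total for f, v in raw.items()}


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_pattern(pattern: XRPDPattern, path) -> None:
    pd.DataFrame(
        {"two_theta_deg": pattern.two_theta, "counts": pattern.counts}
    ).to_csv(path, index=False)


def read_pattern(path, label: str = "") -> XRPDPattern:
    df = pd.read_csv(path)
    return XRPDPattern(
        two_theta=df["two_theta_deg"].to_numpy(),
        counts=df["counts"].to_numpy(),
        label=label,
    )


def save_curves(curves: Sequence[BinaryCalCurve], path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in curves], fh, sort_keys=True)


def load_curves(path) -> list[BinaryCalCurve]:
    with open(path) as fh:
        return [BinaryCalCurve.from_dict(d) for d in json.load(fh)]
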