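"""Zero-order disproportionation rate estimation and salt ranking.

The physical-stability comparison between candidate salts reduces to the
rate at which each salt's mass fraction declines during suspension. A
zero-order rate is the negative slope of a least-squares line fitted over
the declining segment of the salt time course; the segment runs from where
the fraction first falls below an upper threshold (default 0.95) down to
just above the terminal plateau. A salt that never declines yields a
flagged zero-rate estimate rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = ["KineticEstimate", "fit_zero_order", "StabilityRanking", "compare_salts"]


@dataclass
class KineticEstimate:
    """Zero-order conversion rate of one salt."""

    salt_id: str
    rate: float  # mass fraction per minute
    window: tuple[float, float]  # fitted time span, min
    r2: float
    terminal_fraction: float  # mean of the final 5% of points
    declined: bool = True  # False → no decline detected, rate forced to 0

    @property
    def rate_pct_per_min(self) -> float:
        return 100.0 * self.rate

    def to_dict(self) -> dict:
        return {
            "salt_id": self.salt_id,
            "rate_per_min": self.rate,
            "rate_pct_per_min": self.rate_pct_per_min,
            "window_min": list(self.window),
            "r2": self.r2,
            "terminal_fraction": self.terminal_fraction,
            "declined": self.declined,
        }


def fit_zero_order(
    times,
    salt_fractions,
    *,
    salt_id: str = "",
    start_threshold: float = 0.95,
    end_offset: float = 0.05,
    min_floor: float = 0.05,
) -> KineticEstimate:
    """Zero-order rate from the declining segment of a salt time course.

    The fit window starts at the first point where the fraction falls below
    ``start_threshold`` and ends where it reaches
    ``max(terminal + end_offset, min_floor)``; the terminal fraction is the
    mean of the final 5% of points. Needs at least three points in the
    window, otherwise (or when the slope is non-negative) the estimate is
    flagged as no-decline with rate 0.
    """
    times = np.asarray(times, dtype=float)
    frac = np.asarray(salt_fractions, dtype=float)
    if times.shape != frac.shape or times.ndim != 1:
        raise ParameterError("times and salt_fractions must be equal-length 1-D arrays")
    if times.size < 3:
        raise ParameterError("need at least three points")

    n_tail = max(1, int(np.ceil(0.05 * times.size)))
    terminal = float(frac[-n_tail:].mean())
    lower = max(terminal + end_offset, min_floor)

    below = np.nonzero(frac < start_threshold)[0]
    no_decline = KineticEstimate(
        salt_id=salt_id,
        rate=0.0,
        window=(float(times[0]), float(times[-1])),
        r2=0.0,
        terminal_fraction=terminal,
        declined=False,
    )
    if below.size == 0:
        return no_decline
    i0 = int(below[0])
    reached = np.nonzero(frac[i0:] <= lower)[0]
    i1 = int(i0 + reached[0]) if reached.size else times.size - 1
    if i1 - i0 + 1 < 3:
        return no_decline

    sl = slice(i0, i1 + 1)
    fit = stats.linregress(times[sl], frac[sl])
    if fit.slope >= 0.0:
        return no_decline
    return KineticEstimate(
        salt_id=salt_id,
        rate=float(-fit.slope),
        window=(float(times[i0]), float(times[i1])),
        r2=float(fit.rvalue**2),
        terminal_fraction=terminal,
        declined=True,
    )


@dataclass
class StabilityRanking:
    """Salts ordered from most to least physically stable (slowest first)."""

    order: list[str]
    rate_ratio: float  # fastest rate / slowest rate (inf if slowest is 0)
    table: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "order_most_stable_first": self.order,
            "rate_ratio_fastest_over_slowest": self.rate_ratio,
            "estimates": self.table.to_dict(orient="records"),
        }


def compare_salts(estimates) -> StabilityRanking:
    """Rank salts by ascending conversion rate (slower = more stable).

    Equal rates are tie-broken by the higher terminal salt fraction (the
    salt retaining more of itself is the more stable one).
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ParameterError("ranking requires at least two kinetic estimates")
    ranked = sorted(estimates, key=lambda e: (e.rate, -e.terminal_fraction))
    rates = [e.rate for e in ranked]
    ratio = float("inf") if rates[0] == 0.0 else rates[-1] / rates[0]
    table = pd.DataFrame([e.to_dict() for e in ranked])
    return StabilityRanking(order=[e.salt_id for e in ranked], rate_ratio=ratio, table=table)
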