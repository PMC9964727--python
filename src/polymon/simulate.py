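"""Synthetic disproportionation runs: kinetics, Raman spectra, XRPD patterns.

The generative model is deliberately simple and matches what the calibration
pipeline assumes it must cope with:

* mass-fraction trajectories follow a small conversion network integrated as
  an ODE system (first- and/or zero-order edges, optional terminal salt pool);
* a mixture Raman spectrum is a linear combination of pure-form pseudo-Voigt
  profiles, scaled by a solid-concentration gain ``(conc/ref_conc)**alpha``,
  with peak centers displaced linearly in concentration, plus a smooth
  polynomial baseline and additive Gaussian detector noise;
* reference mass fractions are the true trajectory values perturbed by
  multiplicative Gaussian noise and renormalized to closure, mimicking the
  precision of offline powder-diffraction quantitation;
* XRPD patterns are linear combinations of per-form signature peak profiles.

Everything stochastic draws from one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InputDataError, ParameterError
from .library import FormLibrary, KineticParams, RunConfig
from .runs import ProcessRun
from .spectra import RamanSpectrum, XRPDPattern

__all__ = [
    "Trajectory",
    "simulate_kinetics",
    "pure_form_profile",
    "mixture_spectrum",
    "simulate_run",
    "simulate_xrpd_pattern",
]

#: safety cap on piecewise integration segments (zero-order floor events)
_MAX_SEGMENTS = 256


@dataclass
class Trajectory:
    """Mass fraction of every solid form on a time grid (closure holds)."""

    times: np.ndarray
    fractions: pd.DataFrame  # index = times, columns = forms

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        sums = self.fractions.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise InputDataError("trajectory fractions must sum to 1 at every time")
        vals = self.fractions.to_numpy()
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise InputDataError("trajectory fractions must lie in [0, 1]")

    @property
    def forms(self) -> list[str]:
        return list(self.fractions.columns)

    def at(self, t: float) -> dict[str, float]:
        """Fractions at time ``t`` (must be on the grid)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[idx] - t) > 1e-9:
            raise InputDataError(f"time {t} min not on the trajectory grid")
        return {f: float(v) for f, v in self.fractions.iloc[idx].items()}


def simulate_kinetics(params: KineticParams, times: Sequence[float]) -> Trajectory:
    """Integrate the conversion network and return the closed trajectory.

    The initial state is the pure initial form (mass fraction 1). First-order
    edges drain the donor's convertible pool exponentially; zero-order edges
    drain it linearly until the donor reaches its floor. The floor is
    ``params.terminal_fraction`` for the initial form and 0 elsewhere.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1:
        raise ParameterError("times must be a non-empty 1-D grid")
    if times[0] != 0.0 or (times.size > 1 and not np.all(np.diff(times) > 0)):
        raise ParameterError("times must be strictly increasing and start at 0")

    forms = params.form_order()
    index = {f: i for i, f in enumerate(forms)}
    floors = np.zeros(len(forms))
    floors[index[params.initial_form]] = params.terminal_fraction

    edges = [
        (index[e.source], index[e.target], e.rate, e.order) for e in params.edges
    ]
    y0 = np.zeros(len(forms))
    y0[index[params.initial_form]] = 1.0

    if times.size == 1 or not edges or all(r == 0 for *_, r, _o in edges):
        frac = np.tile(y0, (times.size, 1))
    else:
        frac = _integrate_network(edges, floors, y0, times)

    frac = np.clip(frac, 0.0, 1.0)
    frac /= frac.sum(axis=1, keepdims=True)
    return Trajectory(times=times, fractions=pd.DataFrame(frac, index=times, columns=forms))


def _integrate_network(edges, floors, y0, times) -> np.ndarray:
    """Piecewise integration of the conversion ODEs.

    Zero-order edges have a discontinuous rate law (constant flux that stops
    when the donor reaches its floor), so integration proceeds in smooth
    segments terminated by floor-crossing events; the crossed edge is
    deactivated and reactivated should inflow lift its donor again.
    """
    zero_edges = [i for i, (_, _, _, order) in enumerate(edges) if order == "zero"]
    active = {i: True for i in zero_edges}

    def rhs(_t, y):
        dy = np.zeros_like(y)
        for i, (src, tgt, rate, order) in enumerate(edges):
            if order == "first":
                flux = rate * max(y[src] - floors[src], 0.0)
            else:
                flux = rate if active[i] else 0.0
            dy[src] -= flux
            dy[tgt] += flux
        return dy

    out = np.empty((times.size, y0.size))
    if times[0] == 0.0:
        out[0] = y0
    t0, y = times[0], y0.copy()
    for _ in range(_MAX_SEGMENTS):
        for i in zero_edges:  # reactivate edges whose donor rose off its floor
            src = edges[i][0]
            active[i] = y[src] > floors[src] + 1e-12

        events = []
        for i in zero_edges:
            if active[i]:
                src = edges[i][0]

                def crossing(_t, yy, src=src):
                    return yy[src] - floors[src]

                crossing.terminal = True
                crossing.direction = -1.0
                events.append(crossing)

        sol = solve_ivp(
            rhs, (t0, times[-1]), y, method="LSODA",
            rtol=1e-10, atol=1e-12, dense_output=True, events=events or None,
        )
        if not sol.success:  # pragma: no cover - solver failure is exceptional
            raise RuntimeError(f"kinetic integration failed: {sol.message}")
        seg_end = sol.t[-1]
        mask = (times > t0) & (times <= seg_end)
        if mask.any():
            out[mask] = sol.sol(times[mask]).T
        if seg_end >= times[-1]:
            return out
        t0, y = seg_end, np.clip(sol.y[:, -1], 0.0, 1.0)
    raise RuntimeError(  # pragma: no cover - pathological chattering network
        "kinetic integration exceeded the segment cap"
    )


def _pseudo_voigt(axis: np.ndarray, center: float, fwhm: float, height: float,
                  eta: float = 0.5) -> np.ndarray:
    """Height-normalized pseudo-Voigt: ``eta``·Lorentzian + (1−eta)·Gaussian."""
    x = (axis - center) / fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * x**2)
    lorentz = 1.0 / (1.0 + 4.0 * x**2)
    return height * (eta * lorentz + (1.0 - eta) * gauss)


def pure_form_profile(form: str, conc: float, lib: FormLibrary,
                      axis: np.ndarray | None = None) -> np.ndarray:
    """Noise-free pure-form Raman profile at solid concentration ``conc``.

    Includes the concentration gain and the concentration-dependent peak
    displacement but no baseline.
    """
    if axis is None:
        axis = lib.raman_shift()
    sig = lib.forms[form]
    gain = lib.concentration_gain(conc) * sig.intensity_response
    shift = sig.shift_per_conc * conc
    profile = np.zeros_like(axis)
    for p in sig.raman_peaks:
        profile += _pseudo_voigt(axis, p.center_cm1 + shift, p.fwhm_cm1, p.height)
    return gain * profile


def mixture_spectrum(
    fractions: Mapping[str, float],
    conc: float,
    lib: FormLibrary,
    *,
    noise_sd: float = 0.0,
    baseline_coeffs: Sequence[float] = (),
    rng: np.random.Generator | None = None,
    time_min: float = 0.0,
) -> RamanSpectrum:
    """Raman spectrum of a solid mixture (linear in mass fractions)."""
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > 1e-6:
        raise InputDataError(f"mixture fractions must sum to 1 (got {total:.8f})")
    unknown = set(fractions) - set(lib.forms)
    if unknown:
        raise InputDataError(f"forms not in library: {sorted(unknown)}")

    axis = lib.raman_shift()
    intensity = np.zeros_like(axis)
    for form, frac in fractions.items():
        if frac != 0.0:
            intensity += frac * pure_form_profile(form, conc, lib, axis)
    if len(baseline_coeffs):
        intensity += np.polynomial.polynomial.polyval(axis, np.asarray(baseline_coeffs, float))
    if noise_sd > 0.0:
        if rng is None:
            raise ParameterError("noise_sd > 0 requires a seeded rng")
        intensity = intensity + rng.normal(0.0, noise_sd, size=axis.size)
    return RamanSpectrum(shift=axis, intensity=intensity, time_min=time_min)


def simulate_run(
    cfg: RunConfig,
    params: KineticParams,
    lib: FormLibrary,
    rng: np.random.Generator | None = None,
) -> ProcessRun:
    """Simulate one monitored disproportionation experiment.

    Raman spectra are generated at every cadence step over the duration;
    reference rows at the configured XRPD sampling times carry the true
    fractions perturbed by multiplicative Gaussian noise (relative SD
    ``cfg.ref_rel_sd``) and renormalized to closure. The noise-free
    trajectory is retained as ground truth.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    raman_times = cfg.raman_times()
    all_times = np.unique(np.concatenate([raman_times, np.asarray(cfg.xrpd_times, float), [0.0]]))
    traj = simulate_kinetics(params, all_times)
    forms = traj.forms

    axis = lib.raman_shift()
    base_coeffs = np.asarray(cfg.baseline_coeffs, dtype=float) * cfg.baseline_scale
    spectra = np.empty((raman_times.size, axis.size))
    for i, t in enumerate(raman_times):
        state = traj.at(t)
        coeffs = base_coeffs
        if base_coeffs.size:
            # fluorescence background grows with conversion (dissolved
            # freebase) and fluctuates spectrum to spectrum
            amp = 1.0
            if cfg.fluor_conversion_coupling != 0.0:
                converted = 1.0 - state.get(lib.salt_form, 0.0)
                amp += cfg.fluor_conversion_coupling * converted
            coeffs = base_coeffs * amp
            if cfg.baseline_jitter_sd > 0.0:
                coeffs = coeffs * (
                    1.0 + rng.normal(0.0, cfg.baseline_jitter_sd, size=base_coeffs.size)
                )
        spec = mixture_spectrum(
            state, cfg.conc, lib,
            noise_sd=cfg.noise_sd, baseline_coeffs=coeffs,
            rng=rng, time_min=float(t),
        )
        spectra[i] = spec.intensity

    rows = []
    for t in cfg.xrpd_times:
        true = np.array([traj.at(t)[f] for f in forms])
        if cfg.ref_rel_sd > 0.0:
            noisy = true * (1.0 + rng.normal(0.0, cfg.ref_rel_sd, size=true.size))
            noisy = np.clip(noisy, 0.0, None)
            if noisy.sum() == 0.0:  # pragma: no cover - pathological noise draw
                noisy = true.copy()
            noisy = noisy / noisy.sum()
        else:
            noisy = true
        for f, v in zip(forms, noisy):
            rows.append({"time_min": float(t), "form": f, "mass_fraction": float(v)})
    references = pd.DataFrame(rows, columns=["time_min", "form", "mass_fraction"])

    truth = Trajectory(
        times=raman_times,
        fractions=traj.fractions.loc[raman_times].copy(),
    )
    return ProcessRun(
        salt_id=cfg.salt_id,
        conc=cfg.conc,
        shift=axis,
        times=raman_times,
        spectra=spectra,
        references=references,
        truth=truth,
        seed=cfg.seed,
    )


def simulate_xrpd_pattern(
    fractions: Mapping[str, float],
    lib: FormLibrary,
    rng: np.random.Generator | None = None,
    *,
    noise_rel_sd: float = 0.0,
    label: str = "",
) -> XRPDPattern:
    """Powder pattern of a mixture: weighted sum of signature peak profiles.

    ``noise_rel_sd`` applies multiplicative Gaussian noise to the counts
    (relative SD), matching the relative precision of diffraction
    quantitation; noise therefore vanishes where there is no signal.
    """
    if not lib.forms:
        raise ParameterError("form library is empty")
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > 1e-6:
        raise InputDataError(f"mixture fractions must sum to 1 (got {total:.8f})")

    axis = lib.two_theta()
    counts = np.zeros_like(axis)
    for form, frac in fractions.items():
        if frac == 0.0:
            continue
        for p in lib.forms[form].xrpd_peaks:
            # Gaussian profiles: negligible tails keep signature windows
            # exactly form-specific (the non-overlap invariant)
            counts += frac * _pseudo_voigt(axis, p.center_deg, p.fwhm_deg, p.height, eta=0.0)
    if noise_rel_sd > 0.0:
        if rng is None:
            raise ParameterError("noise_rel_sd > 0 requires a seeded rng")
        counts = counts * (1.0 + rng.normal(0.0, noise_rel_sd, size=axis.size))
    counts = np.clip(counts, 0.0, None)
    return XRPDPattern(two_theta=axis, counts=counts, label=label)
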