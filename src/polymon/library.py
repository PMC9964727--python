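"""Solid-form signature libraries and run/kinetic configuration.

A :class:`FormLibrary` holds, for every solid form that can appear during a
disproportionation (the parent salt plus up to three freebase polymorphs),
its Raman peak list, its powder-diffraction signature peaks, and the two
concentration-response parameters the simulator uses: a multiplicative
intensity response (suspension density scales Raman signal) and a linear
peak-shift coefficient (cm⁻¹ per mg/mL of solid concentration; zero for
HCl-like salts, nonzero for maleate-like salts).

:class:`KineticParams` describes the conversion network between forms
(salt → metastable polymorphs → stable polymorph) with per-edge rate
constants of either first or zero order, and :class:`RunConfig` describes a
single monitored experiment (solid concentration, duration, acquisition
cadence, reference sampling times, noise model, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import InputDataError, ParameterError

__all__ = [
    "RamanPeak",
    "XRPDPeak",
    "FormSignature",
    "FormLibrary",
    "KineticEdge",
    "KineticParams",
    "RunConfig",
    "default_library",
    "default_kinetics",
]

#: half-width of an XRPD signature integration window, in units of peak FWHM
XRPD_WINDOW_FWHM = 2.0


@dataclass(frozen=True)
class RamanPeak:
    center_cm1: float
    fwhm_cm1: float
    height: float

    def __post_init__(self):
        if self.fwhm_cm1 <= 0:
            raise ParameterError("Raman peak FWHM must be > 0")
        if self.height < 0:
            raise ParameterError("Raman peak height must be >= 0")


@dataclass(frozen=True)
class XRPDPeak:
    center_deg: float
    fwhm_deg: float
    height: float

    def __post_init__(self):
        if self.fwhm_deg <= 0:
            raise ParameterError("XRPD peak FWHM must be > 0")
        if self.height < 0:
            raise ParameterError("XRPD peak height must be >= 0")

    def window(self) -> tuple[float, float]:
        """Signature integration window around this peak."""
        half = XRPD_WINDOW_FWHM * self.fwhm_deg
        return (self.center_deg - half, self.center_deg + half)


@dataclass
class FormSignature:
    """Spectral fingerprint and concentration response of one solid form."""

    raman_peaks: list[RamanPeak]
    xrpd_peaks: list[XRPDPeak]
    #: scales Raman intensity per unit relative solid concentration
    intensity_response: float = 1.0
    #: Raman peak displacement in cm⁻¹ per mg/mL solid concentration
    shift_per_conc: float = 0.0

    def __post_init__(self):
        self.raman_peaks = [
            p if isinstance(p, RamanPeak) else RamanPeak(*p) for p in self.raman_peaks
        ]
        self.xrpd_peaks = [
            p if isinstance(p, XRPDPeak) else XRPDPeak(*p) for p in self.xrpd_peaks
        ]
        if self.intensity_response < 0:
            raise ParameterError("intensity_response must be >= 0")


@dataclass
class FormLibrary:
    """Per-form signatures plus the axes and concentration law of a study.

    The Raman intensity of a suspension scales as
    ``(conc / ref_conc) ** alpha`` (``alpha = 1`` is the linear
    suspension-density reading of the expanded Beer–Lambert mixture model).
    """

    forms: dict[str, FormSignature]
    salt_form: str
    ref_conc: float = 16.7
    alpha: float = 1.0
    raman_axis: tuple[float, float, float] = (100.0, 3425.0, 1.0)
    xrpd_axis: tuple[float, float, float] = (2.0, 40.0, 0.02)

    def __post_init__(self):
        if not self.forms:
            raise InputDataError("form library must define at least one form")
        if self.salt_form not in self.forms:
            raise InputDataError(f"salt form {self.salt_form!r} missing from library")
        lo, hi, step = self.raman_axis
        for name, sig in self.forms.items():
            for p in sig.raman_peaks:
                if not (lo <= p.center_cm1 <= hi):
                    raise InputDataError(
                        f"Raman peak at {p.center_cm1} cm⁻¹ of form {name!r} "
                        f"outside axis [{lo}, {hi}]"
                    )
            if len(sig.xrpd_peaks) < 2:
                raise InputDataError(
                    f"form {name!r} needs at least two XRPD signature peaks"
                )
        self._check_xrpd_windows()

    def _check_xrpd_windows(self) -> None:
        """Signature windows of different forms must not overlap."""
        windows = [
            (name, *pk.window())
            for name, sig in self.forms.items()
            for pk in sig.xrpd_peaks
        ]
        windows.sort(key=lambda w: w[1])
        for (na, _, hi_a), (nb, lo_b, _) in zip(windows, windows[1:]):
            if na != nb and hi_a > lo_b:
                raise InputDataError(
                    f"XRPD signature windows of forms {na!r} and {nb!r} overlap"
                )

    # ---- axes -----------------------------------------------------------
    def raman_shift(self) -> np.ndarray:
        lo, hi, step = self.raman_axis
        return np.arange(lo, hi + step / 2, step)

    def two_theta(self) -> np.ndarray:
        lo, hi, step = self.xrpd_axis
        return np.arange(lo, hi + step / 2, step)

    @property
    def freebase_forms(self) -> list[str]:
        return [f for f in self.forms if f != self.salt_form]

    def concentration_gain(self, conc: float) -> float:
        """Intensity multiplier at solid concentration ``conc`` (mg/mL)."""
        if conc <= 0:
            raise ParameterError("solid concentration must be > 0")
        return float((conc / self.ref_conc) ** self.alpha)

    def xrpd_windows(self, form: str) -> list[tuple[float, float]]:
        return [p.window() for p in self.forms[form].xrpd_peaks]

    # ---- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "salt_form": self.salt_form,
            "ref_conc": self.ref_conc,
            "alpha": self.alpha,
            "raman_axis": list(self.raman_axis),
            "xrpd_axis": list(self.xrpd_axis),
            "forms": {
                name: {
                    "raman_peaks": [
                        [p.center_cm1, p.fwhm_cm1, p.height] for p in sig.raman_peaks
                    ],
                    "xrpd_peaks": [
                        [p.center_deg, p.fwhm_deg, p.height] for p in sig.xrpd_peaks
                    ],
                    "intensity_response": sig.intensity_response,
                    "shift_per_conc": sig.shift_per_conc,
                }
                for name, sig in self.forms.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FormLibrary":
        forms = {
            name: FormSignature(
                raman_peaks=[RamanPeak(*p) for p in sig["raman_peaks"]],
                xrpd_peaks=[XRPDPeak(*p) for p in sig["xrpd_peaks"]],
                intensity_response=sig.get("intensity_response", 1.0),
                shift_per_conc=sig.get("shift_per_conc", 0.0),
            )
            for name, sig in d["forms"].items()
        }
        return cls(
            forms=forms,
            salt_form=d["salt_form"],
            ref_conc=d.get("ref_conc", 16.7),
            alpha=d.get("alpha", 1.0),
            raman_axis=tuple(d.get("raman_axis", (100.0, 3425.0, 1.0))),
            xrpd_axis=tuple(d.get("xrpd_axis", (2.0, 40.0, 0.02))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FormLibrary":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class KineticEdge:
    """One conversion pathway ``source → target``.

    ``order`` is ``"first"`` (rate in min⁻¹, flux proportional to the
    convertible donor fraction) or ``"zero"`` (rate in mass-fraction·min⁻¹,
    constant flux while donor remains above its floor).
    """

    source: str
    target: str
    rate: float
    order: str = "first"

    def __post_init__(self):
        if self.rate < 0:
            raise ParameterError("kinetic rate constants must be >= 0")
        if self.order not in ("first", "zero"):
            raise ParameterError(f"unknown kinetic order {self.order!r}")


@dataclass
class KineticParams:
    """Conversion network with an optional terminal (unconverted) salt pool."""

    edges: list[KineticEdge]
    initial_form: str = "salt"
    #: mass fraction of the initial form that never converts (partial
    #: disproportionation); 0 means complete conversion is possible
    terminal_fraction: float = 0.0

    def __post_init__(self):
        self.edges = [
            e if isinstance(e, KineticEdge) else KineticEdge(**e) for e in self.edges
        ]
        if not (0.0 <= self.terminal_fraction <= 1.0):
            raise ParameterError("terminal_fraction must lie in [0, 1]")

    def form_order(self) -> list[str]:
        """Forms in deterministic order: initial form first, then edge order."""
        seen = [self.initial_form]
        for e in self.edges:
            for f in (e.source, e.target):
                if f not in seen:
                    seen.append(f)
        return seen

    def to_dict(self) -> dict:
        return {
            "initial_form": self.initial_form,
            "terminal_fraction": self.terminal_fraction,
            "edges": [
                {"source": e.source, "target": e.target, "rate": e.rate, "order": e.order}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParams":
        return cls(
            edges=[KineticEdge(**e) for e in d["edges"]],
            initial_form=d.get("initial_form", "salt"),
            terminal_fraction=d.get("terminal_fraction", 0.0),
        )


@dataclass
class RunConfig:
    """Configuration of one monitored disproportionation experiment."""

    salt_id: str
    conc: float  # mg/mL solid concentration
    duration: float = 450.0  # min
    cadence: float = 2.0  # min between Raman acquisitions
    xrpd_times: Sequence[float] = field(default_factory=list)
    ref_rel_sd: float = 0.04  # relative SD of reference mass fractions
    noise_sd: float = 0.0  # additive Gaussian SD on Raman counts
    baseline_coeffs: Sequence[float] = field(default_factory=list)  # ascending powers of cm⁻¹
    #: relative SD of a per-spectrum random amplitude on the baseline shape
    #: (fluorescence/background fluctuation, prominent at low suspension density)
    baseline_jitter_sd: float = 0.0
    #: overall multiplier on the baseline shape for this run (fluorescence
    #: background relative to the solid signal grows at low suspension density)
    baseline_scale: float = 1.0
    #: fractional growth of the baseline amplitude per unit conversion
    #: (dissolved freebase fluoresces, so background tracks the process)
    fluor_conversion_coupling: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.cadence <= 0:
            raise ParameterError("Raman cadence must be > 0")
        if self.ref_rel_sd < 0:
            raise ParameterError("reference relative SD must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be >= 0")
        if self.baseline_jitter_sd < 0:
            raise ParameterError("baseline jitter SD must be >= 0")
        if self.baseline_scale < 0:
            raise ParameterError("baseline scale must be >= 0")
        self.xrpd_times = [float(t) for t in self.xrpd_times]
        for t in self.xrpd_times:
            if not (0.0 <= t <= self.duration):
                raise ParameterError(
                    f"XRPD sampling time {t} min outside [0, {self.duration}]"
                )

    def raman_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration + self.cadence / 2, self.cadence)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["xrpd_times"] = list(self.xrpd_times)
        d["baseline_coeffs"] = list(self.baseline_coeffs)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# Default synthetic libraries: two salts with highly overlapping fingerprints
# ---------------------------------------------------------------------------

_FREEBASE_RAMAN = {
    # fingerprint peaks concentrated below 1761 cm⁻¹ plus one C–H stretch
    # band near 2900 cm⁻¹ that truncation removes
    "I": [(460, 12, 0.45), (998, 10, 0.95), (1160, 12, 0.50), (1250, 12, 0.50),
          (1585, 14, 0.70), (2935, 30, 0.30)],
    "II": [(455, 12, 0.50), (995, 10, 1.00), (1155, 12, 0.55), (1268, 12, 0.60),
           (1592, 14, 0.75), (2940, 30, 0.30)],
    "V": [(465, 12, 0.50), (1010, 10, 1.00), (1180, 12, 0.50), (1285, 12, 0.65),
          (1570, 14, 0.80), (2945, 30, 0.30)],
}

_FREEBASE_XRPD = {
    "I": [(7.5, 0.12, 0.9), (14.1, 0.12, 0.7)],
    "II": [(8.8, 0.12, 1.0), (16.2, 0.12, 0.6)],
    "V": [(10.2, 0.12, 1.0), (18.5, 0.12, 0.8)],
}

_SALT_RAMAN = {
    # HCl-like salt: two bands in 1100–1150 and a doublet near 1300
    "hcl": [(480, 12, 0.50), (1005, 10, 1.00), (1118, 11, 0.60), (1142, 11, 0.55),
            (1210, 12, 0.45), (1295, 12, 0.70), (1318, 12, 0.50), (1602, 14, 0.80),
            (2930, 30, 0.30)],
    # maleate-like salt: single band near 1300, distinct high-frequency band
    "maleate": [(470, 12, 0.50), (1002, 10, 1.00), (1135, 11, 0.60), (1170, 12, 0.50),
                (1302, 12, 0.80), (1630, 14, 0.90), (2925, 30, 0.30)],
}

_SALT_XRPD = [(6.0, 0.12, 1.0), (12.3, 0.12, 0.8)]


def default_library(salt_kind: str, *, shift_per_conc: float = 0.0,
                    alpha: float = 1.0, ref_conc: float = 16.7) -> FormLibrary:
    """Synthetic form library for an ``"hcl"``- or ``"maleate"``-like salt.

    ``shift_per_conc`` applies to every form (maleate-like salts show
    concentration-dependent peak shifts in addition to intensity offsets).
    """
    if salt_kind not in _SALT_RAMAN:
        raise ParameterError(f"unknown salt kind {salt_kind!r}")
    forms = {
        "salt": FormSignature(
            raman_peaks=[RamanPeak(*p) for p in _SALT_RAMAN[salt_kind]],
            xrpd_peaks=[XRPDPeak(*p) for p in _SALT_XRPD],
            shift_per_conc=shift_per_conc,
        )
    }
    for name in ("I", "II", "V"):
        forms[name] = FormSignature(
            raman_peaks=[RamanPeak(*p) for p in _FREEBASE_RAMAN[name]],
            xrpd_peaks=[XRPDPeak(*p) for p in _FREEBASE_XRPD[name]],
            shift_per_conc=shift_per_conc,
        )
    return FormLibrary(forms=forms, salt_form="salt", ref_conc=ref_conc, alpha=alpha)


def default_kinetics(salt_kind: str, *, include_form_I: bool = True) -> KineticParams:
    """Default conversion networks.

    HCl-like: fast complete conversion through a transient form I
    (salt → I → II → V first-order cascade). Maleate-like: slow partial
    conversion (salt → II → V with a large terminal salt pool).
    """
    if salt_kind == "hcl":
        if include_form_I:
            edges = [KineticEdge("salt", "I", 0.05), KineticEdge("I", "II", 0.08),
                     KineticEdge("II", "V", 0.012)]
        else:
            edges = [KineticEdge("salt", "II", 0.05), KineticEdge("II", "V", 0.012)]
        return KineticParams(edges=edges, initial_form="salt", terminal_fraction=0.0)
    if salt_kind == "maleate":
        edges = [KineticEdge("salt", "II", 0.01), KineticEdge("II", "V", 0.004)]
        return KineticParams(edges=edges, initial_form="salt", terminal_fraction=0.81)
    raise ParameterError(f"unknown salt kind {salt_kind!r}")
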