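"""ProcessRun container and its plain-text serialization.

A run is written as three files in a directory:

``spectra.csv``
    wide table, first column ``raman_shift_cm1``, one column per timestamp
    named ``t_<minutes>``;
``references.csv``
    long table with columns ``time_min, form, mass_fraction``;
``metadata.json``
    salt id, solid concentration (mg/mL), seed.

Synthetic runs additionally write ``truth.csv`` (the noise-free trajectory),
which is reloaded when present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import InputDataError
from .spectra import RamanSpectrum

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Trajectory

__all__ = ["ProcessRun", "write_run", "read_run"]


@dataclass
class ProcessRun:
    """One disproportionation experiment: spectra series plus references."""

    salt_id: str
    conc: float
    shift: np.ndarray  # common Raman axis, cm⁻¹
    times: np.ndarray  # spectrum timestamps, min, strictly increasing
    spectra: np.ndarray  # (n_times, n_channels) intensities
    references: pd.DataFrame  # columns time_min, form, mass_fraction
    truth: "Trajectory | None" = None
    seed: int | None = None

    def __post_init__(self):
        self.shift = np.asarray(self.shift, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (self.times.size, self.shift.size):
            raise InputDataError("spectra matrix shape must be (n_times, n_channels)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InputDataError("spectrum timestamps must be strictly increasing")
        required = {"time_min", "form", "mass_fraction"}
        if not required.issubset(self.references.columns):
            raise InputDataError(f"reference table needs columns {sorted(required)}")
        sums = self.references.groupby("time_min")["mass_fraction"].sum()
        if len(sums) and not np.allclose(sums.to_numpy(), 1.0, atol=0.02):
            raise InputDataError("reference fractions must sum to 1 within 0.02")

    @property
    def forms(self) -> list[str]:
        """Forms appearing in the reference table, in first-appearance order."""
        return list(dict.fromkeys(self.references["form"]))

    @property
    def n_spectra(self) -> int:
        return self.times.size

    def spectrum(self, i: int) -> RamanSpectrum:
        return RamanSpectrum(self.shift, self.spectra[i], time_min=float(self.times[i]))

    def reference_wide(self) -> pd.DataFrame:
        """References pivoted to one row per sampling time."""
        return self.references.pivot(
            index="time_min", columns="form", values="mass_fraction"
        ).sort_index()


def write_run(run: ProcessRun, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wide = pd.DataFrame({"raman_shift_cm1": run.shift})
    for i, t in enumerate(run.times):
        wide[f"t_{t:g}"] = run.spectra[i]
    wide.to_csv(out / "spectra.csv", index=False)

    run.references.to_csv(out / "references.csv", index=False)

    meta = {"salt_id": run.salt_id, "conc_mg_per_ml": run.conc, "seed": run.seed}
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    if run.truth is not None:
        truth = run.truth.fractions.copy()
        truth.insert(0, "time_min", run.truth.times)
        truth.to_csv(out / "truth.csv", index=False)
    return out


def read_run(run_dir) -> ProcessRun:
    run_dir = Path(run_dir)
    wide = pd.read_csv(run_dir / "spectra.csv")
    shift = wide["raman_shift_cm1"].to_numpy()
    time_cols = [c for c in wide.columns if c.startswith("t_")]
    times = np.array([float(c[2:]) for c in time_cols])
    order = np.argsort(times)
    spectra = wide[time_cols].to_numpy().T[order]
    times = times[order]

    references = pd.read_csv(run_dir / "references.csv")
    meta = json.loads((run_dir / "metadata.json").read_text())

    truth = None
    truth_path = run_dir / "truth.csv"
    if truth_path.exists():
        from .simulate import Trajectory  # deferred: simulate imports this module

        tdf = pd.read_csv(truth_path)
        ttimes = tdf.pop("time_min").to_numpy()
        truth = Trajectory(times=ttimes, fractions=tdf.set_index(ttimes))

    return ProcessRun(
        salt_id=meta["salt_id"],
        conc=meta["conc_mg_per_ml"],
        shift=shift,
        times=times,
        spectra=spectra,
        references=references,
        truth=truth,
        seed=meta.get("seed"),
    )
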