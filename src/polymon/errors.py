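"""Exception types raised across the pipeline."""


class PolymonError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PolymonError, ValueError):
    """An argument violates a precondition (negative rate, bad LV count, ...)."""


class InputDataError(PolymonError, ValueError):
    """Input data violates a contract (fractions not closing, bad shapes, ...)."""


class EmptySelectionError(InputDataError):
    """A truncation or peak window selects no channels."""


class ZeroVarianceError(InputDataError):
    """A spectrum or channel is constant where variance is required."""


class UnmatchedReferenceError(InputDataError):
    """A reference measurement has no spectrum within the pairing tolerance."""

    def __init__(self, times):
        self.times = list(times)
        super().__init__(
            "reference measurement(s) at t = "
            + ", ".join(f"{t:g} min" for t in self.times)
            + " have no spectrum within the pairing tolerance"
        )


class AbsentModelError(PolymonError, KeyError):
    """A prediction was requested for a form flagged unmodelable."""


class SelectionError(PolymonError, RuntimeError):
    """Every candidate model in a calibration search was degenerate."""


class IndeterminateCompositionError(InputDataError):
    """All raw phase amounts from the diffraction curves are zero."""
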