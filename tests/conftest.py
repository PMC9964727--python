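import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polymon.library import (
    FormLibrary,
    FormSignature,
    KineticEdge,
    KineticParams,
    RamanPeak,
    XRPDPeak,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_library():
    """Three-form library on a short axis — fast but structurally complete."""
    forms = {
        "salt": FormSignature(
            raman_peaks=[RamanPeak(300, 10, 1.0), RamanPeak(700, 12, 0.6)],
            xrpd_peaks=[XRPDPeak(6.0, 0.12, 1.0), XRPDPeak(12.3, 0.12, 0.8)],
        ),
        "II": FormSignature(
            raman_peaks=[RamanPeak(420, 10, 1.0), RamanPeak(820, 12, 0.7)],
            xrpd_peaks=[XRPDPeak(8.8, 0.12, 1.0), XRPDPeak(16.2, 0.12, 0.6)],
        ),
        "V": FormSignature(
            raman_peaks=[RamanPeak(540, 10, 1.0), RamanPeak(940, 12, 0.8)],
            xrpd_peaks=[XRPDPeak(10.2, 0.12, 1.0), XRPDPeak(18.5, 0.12, 0.8)],
        ),
    }
    return FormLibrary(
        forms=forms, salt_form="salt", ref_conc=16.7, alpha=1.0,
        raman_axis=(100.0, 1100.0, 1.0), xrpd_axis=(2.0, 25.0, 0.02),
    )


@pytest.fixture
def cascade_params():
    """salt → II → V first-order cascade."""
    return KineticParams(
        edges=[KineticEdge("salt", "II", 0.05), KineticEdge("II", "V", 0.01)],
        initial_form="salt",
    )
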