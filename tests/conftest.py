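import numpy as np
import pytest

from phiflux.calibration import default_curve, fit_calibration
from phiflux.presets import AMMONIUM_PRESETS, BUFFER_MODELS, PhenotypePreset
from phiflux.protocols import ammonium_washout_protocol, sodium_washout_protocol


@pytest.fixture(scope="session")
def curve():
    """Nominal linear instrument curve (ratio = 0.5*pH - 2)."""
    return default_curve()


@pytest.fixture(scope="session")
def fitted_curve():
    """Curve refitted from five exact nigericin points, as the pipeline does."""
    truth = default_curve()
    pts = [(ph, float(truth.predict_ratio(ph))) for ph in (6.2, 6.7, 7.2, 7.7, 8.2)]
    return fit_calibration(pts)


@pytest.fixture(scope="session")
def ammonium_protocol():
    return ammonium_washout_protocol()


@pytest.fixture(scope="session")
def sodium_protocol():
    return sodium_washout_protocol()


def make_preset(
    name="test",
    baseline=7.0,
    sd=0.0,
    j_prod=0.13,
    gain=2.0,
    buffer_class="nMEC",
    **kwargs,
):
    """Construct a small custom preset around a buffer model."""
    model = BUFFER_MODELS[buffer_class]
    return PhenotypePreset(
        name=name,
        ph_baseline_mean=baseline,
        ph_baseline_sd=sd,
        proton_production=j_prod,
        nhe_gain=gain,
        nhe_setpoint=baseline + (j_prod / gain if gain > 0 else 0.0),
        buffer_slope=model.slope,
        buffer_intercept=model.intercept,
        **kwargs,
    )


@pytest.fixture()
def preset_factory():
    return make_preset
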