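import pytest

from capsidmech import (
    AnalysisConfig,
    CalibrationResult,
    CantileverModel,
    IndentationProtocol,
)


@pytest.fixture
def hsv_cantilever() -> CantileverModel:
    """HSV-1 measurement cantilever: 0.06 N/m, 0.05 nN force noise."""
    return CantileverModel(stiffness_kc=0.06, force_noise_sd=0.05)


@pytest.fixture
def hsv_cantilever_clean() -> CantileverModel:
    return CantileverModel(stiffness_kc=0.06, force_noise_sd=0.0)


@pytest.fixture
def lambda_cantilever() -> CantileverModel:
    """Phage-lambda measurement cantilever: 0.03 N/m."""
    return CantileverModel(stiffness_kc=0.03, force_noise_sd=0.025)


@pytest.fixture
def hsv_calibration() -> CalibrationResult:
    return CalibrationResult(stiffness_kc=0.06, deflection_sensitivity_slope=0.06)


@pytest.fixture
def lambda_calibration() -> CalibrationResult:
    return CalibrationResult(stiffness_kc=0.03, deflection_sensitivity_slope=0.03)


@pytest.fixture
def protocol() -> IndentationProtocol:
    return IndentationProtocol(seed=1)


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()
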