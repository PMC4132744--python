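"""Cantilever calibration.

Two calibrations precede every breaking-force measurement:

1. **Thermal fluctuation method** — the cantilever spring constant ``k_c``
   follows from equipartition applied to the free thermal deflection of the
   lever: ``k_c = k_B * T / <x^2>``, with ``<x^2>`` the variance of the
   (detrended) deflection signal in nm^2.  No mode-shape or laser-spot
   correction factors are applied (factor 1.0).

2. **Hard-surface (glass) indentation** — on an effectively infinitely
   stiff substrate the tip does not indent the sample, so the slope of
   force versus piezo extension in calibrated units equals ``k_c``.  This
   slope doubles as the deflection sensitivity used later to convert piezo
   travel into true tip–sample indentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .constants import BOLTZMANN_NN_NM_PER_K
from .curves import ForceCurve
from .errors import CalibrationError, DegenerateTraceError, InsufficientDataError

__all__ = [
    "ThermalTrace",
    "CalibrationResult",
    "thermal_spring_constant",
    "glass_sensitivity",
    "MIN_THERMAL_SAMPLES",
]

MIN_THERMAL_SAMPLES = 1000


@dataclass
class ThermalTrace:
    """Free thermal deflection time series of a cantilever.

    deflection is in nm, sampling_rate in Hz, temperature in kelvin.
    """

    deflection: np.ndarray
    sampling_rate: float
    temperature: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.deflection.ndim != 1:
            raise ValueError("deflection must be a 1-D array")
        if not np.all(np.isfinite(self.deflection)):
            raise ValueError("deflection must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.deflection.size)


@dataclass
class CalibrationResult:
    """Cantilever calibration record.

    stiffness_kc : N/m, from the thermal method (or the glass slope when
        only a hard-surface curve is available).
    deflection_sensitivity_slope : nN/nm, least-squares post-contact slope
        measured on glass; in calibrated units this estimates k_c and is
        the quantity used for the indentation transform.
    """

    stiffness_kc: float
    deflection_sensitivity_slope: float | None = None
    n_samples_used: int = 0
    method: str = "thermal"

    def __post_init__(self) -> None:
        if self.stiffness_kc <= 0:
            raise ValueError("stiffness_kc must be positive")
        if (
            self.deflection_sensitivity_slope is not None
            and self.deflection_sensitivity_slope <= 0
        ):
            raise ValueError("deflection_sensitivity_slope must be positive")

    @property
    def indentation_slope(self) -> float:
        """Slope (nN/nm) used to convert force into cantilever deflection
        for the indentation transform: the glass slope when measured,
        otherwise the thermal k_c."""
        if self.deflection_sensitivity_slope is not None:
            return self.deflection_sensitivity_slope
        return self.stiffness_kc


def thermal_spring_constant(trace: ThermalTrace) -> CalibrationResult:
    """Estimate the cantilever spring constant from thermal fluctuations.

    The deflection series is linearly detrended (removing slow drift that
    would inflate the variance) and equipartition is applied:
    ``k_c = k_B * T / var(x)`` with the unbiased sample variance.

    Raises
    ------
    InsufficientDataError
        If the trace is shorter than ``MIN_THERMAL_SAMPLES``.
    DegenerateTraceError
        If the detrended variance is zero (constant trace).
    """
    n = trace.n_samples
    if n < MIN_THERMAL_SAMPLES:
        raise InsufficientDataError(
            f"thermal trace has {n} samples; calibration requires at least "
            f"{MIN_THERMAL_SAMPLES}"
        )
    t = np.arange(n, dtype=float)
    coeffs = np.polyfit(t, trace.deflection, 1)
    detrended = trace.deflection - np.polyval(coeffs, t)
    var = float(np.var(detrended, ddof=2))  # ddof=2: two trend parameters
    scale = float(np.max(np.abs(trace.deflection)))
    if var <= max(1e-30, 1e-24 * scale**2):
        raise DegenerateTraceError("degenerate trace: zero deflection variance")
    kc = BOLTZMANN_NN_NM_PER_K * trace.temperature / var
    return CalibrationResult(
        stiffness_kc=kc,
        deflection_sensitivity_slope=None,
        n_samples_used=n,
        method="thermal",
    )


def glass_sensitivity(
    curve: ForceCurve,
    thermal: CalibrationResult | None = None,
    config=None,
) -> CalibrationResult:
    """Measure the post-contact force-vs-z slope on a hard substrate.

    The contact point is located with the same changepoint detector used
    for particle curves; the returned slope is the ordinary least-squares
    slope of the baseline-corrected post-contact segment.  When a thermal
    calibration is supplied its k_c is carried through; otherwise the glass
    slope itself is reported as k_c.

    Raises
    ------
    ContactNotFoundError
        If no contact region is present in the curve.
    CalibrationError
        If the fitted slope is not positive.
    """
    from .analysis import AnalysisConfig, detect_contact_point

    if config is None:
        config = AnalysisConfig()
    z0, corrected = detect_contact_point(curve, config)
    mask = corrected.z > z0
    zc = corrected.z[mask]
    fc = corrected.force[mask]
    if zc.size < 10:
        raise CalibrationError("fewer than 10 post-contact samples on glass curve")
    slope = float(np.polyfit(zc, fc, 1)[0])
    if slope <= 0:
        raise CalibrationError(f"non-positive glass contact slope: {slope:.4g}")
    kc = thermal.stiffness_kc if thermal is not None else slope
    return CalibrationResult(
        stiffness_kc=kc,
        deflection_sensitivity_slope=slope,
        n_samples_used=int(zc.size),
        method="thermal+glass" if thermal is not None else "glass",
    )
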