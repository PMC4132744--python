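"""Per-curve analysis: from one force–distance curve to a particle spring
constant and breaking force.

Pipeline for a single curve:

1. locate the contact point as the changepoint minimizing the total squared
   residuals of a two-piece linear model (baseline + rising contact line),
   and remove the fitted baseline offset and tilt;
2. transform piezo extension into tip–sample indentation,
   ``delta = (z - z0) - F / S`` with ``S`` the hard-surface slope from
   calibration (the cantilever deflection is subtracted from the piezo
   travel);
3. fit the spring constant ``k`` as the least-squares slope of force versus
   indentation over a fractional window of the pre-break peak force;
4. detect mechanical failure as the first sufficiently large force drop and
   report the breaking force as the elastic force at the failure point.

Breaking forces are only computed against an explicit calibration record —
curves cannot be analyzed without the calibrate-then-measure order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .calibration import CalibrationResult
from .curves import ForceCurve
from .errors import (
    CalibrationError,
    ContactNotFoundError,
    GlassLikeCurveError,
    InsufficientDataError,
)

__all__ = [
    "AnalysisConfig",
    "IndentationResult",
    "detect_contact_point",
    "fit_spring_constant",
    "detect_break",
    "analyze_curve",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the curve analysis.

    fit_lower_frac, fit_upper_frac : fractions of the pre-break peak force
        bounding the linear-fit window (defaults 0.1–0.9: skips contact
        nonlinearity at the bottom and near-failure softening at the top).
    break_drop_frac : minimum force drop, as a fraction of the running
        peak, registered as failure.
    break_window : samples within which the drop must occur.
    min_drop_nN : absolute floor on the drop size in nN; the effective
        floor is max(min_drop_nN, break_noise_factor * sigma_hat) with
        sigma_hat a robust per-curve noise estimate.
    break_noise_factor : multiple of the estimated force noise a drop must
        exceed (guards against noise-driven false failures).
    min_r_squared : fit-quality gate; poorer fits are flagged.
    max_reduced_chi2 : fit residual variance may exceed the estimated
        noise variance by at most this factor; above it the linear-elastic
        model does not describe the window and the fit is flagged.
    smoothing_halfwidth : halfwidth (samples) of the moving average applied
        before drop scanning.
    contact_sse_ratio_max : a changepoint must reduce the two-piece SSE
        below this fraction of the single-line SSE, else "no contact".
    min_segment_samples : minimum samples on each side of the changepoint.
    min_indentation_nm : minimum indentation span in the fit window; below
        it the curve is glass-like and no particle stiffness exists.
    max_slope_ratio : maximum allowed ratio of the measured force-vs-z
        slope to the calibration (hard-surface) slope; above it the
        series-spring inversion is ill-conditioned and the curve is
        treated as glass-like.
    break_fit_samples : samples in the local pre-break line fit used to
        read off the breaking force.
    """

    fit_lower_frac: float = 0.1
    fit_upper_frac: float = 0.9
    break_drop_frac: float = 0.2
    break_window: int = 12
    min_drop_nN: float = 0.0
    break_noise_factor: float = 2.5
    min_r_squared: float = 0.5
    smoothing_halfwidth: int = 4
    contact_sse_ratio_max: float = 0.8
    min_segment_samples: int = 10
    min_indentation_nm: float = 1.0
    max_slope_ratio: float = 0.95
    max_reduced_chi2: float = 2.0
    break_fit_samples: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.fit_lower_frac < self.fit_upper_frac <= 1.0:
            raise ValueError("need 0 <= fit_lower_frac < fit_upper_frac <= 1")
        if not 0.0 < self.break_drop_frac < 1.0:
            raise ValueError("break_drop_frac must be in (0, 1)")
        if self.break_window < 2:
            raise ValueError("break_window must be >= 2")
        if self.min_drop_nN < 0:
            raise ValueError("min_drop_nN must be non-negative")
        if self.smoothing_halfwidth < 0:
            raise ValueError("smoothing_halfwidth must be >= 0")


@dataclass
class IndentationResult:
    """Per-particle analysis output.

    spring_constant_k is in N/m (slope of force vs indentation),
    breaking_force in nN, indentation_at_break in nm.  Missing quantities
    are None with an explanatory entry in ``flags``.
    """

    contact_z0: float
    spring_constant_k: float | None = None
    fit_r_squared: float | None = None
    fit_window_nm: tuple[float, float] | None = None
    breaking_force: float | None = None
    indentation_at_break: float | None = None
    flags: list[str] = field(default_factory=list)


def _smooth(force: np.ndarray, halfwidth: int) -> np.ndarray:
    if halfwidth <= 0:
        return force
    return uniform_filter1d(force, size=2 * halfwidth + 1, mode="nearest")


def _segment_line_sse(z: np.ndarray, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix and suffix SSEs of per-segment OLS lines.

    prefix[i] = SSE of the best line through samples [0, i);
    suffix[i] = SSE of the best line through samples [i, n).
    Entries for segments of < 2 samples are 0.
    """
    # Center globally: shifting both axes leaves every segment SSE unchanged
    # and avoids cancellation in the cumulative sums.
    zc = z - z.mean()
    fc = f - f.mean()

    def _prefix(zs: np.ndarray, fs: np.ndarray) -> np.ndarray:
        n = np.arange(1, zs.size + 1, dtype=float)
        sx = np.cumsum(zs)
        sy = np.cumsum(fs)
        sxx = np.cumsum(zs * zs)
        sxy = np.cumsum(zs * fs)
        syy = np.cumsum(fs * fs)
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = syy_c - np.where(sxx_c > 0, sxy_c * sxy_c / np.maximum(sxx_c, 1e-300), 0.0)
        sse = np.clip(sse, 0.0, None)
        out = np.zeros(zs.size + 1)
        out[1:] = sse
        out[:2] = 0.0  # <2 samples: exact fit
        return out

    pre = _prefix(zc, fc)[:-1]  # pre[i] = SSE over [0, i)
    suf = _prefix(zc[::-1], fc[::-1])[::-1][:-1]  # suf[i] = SSE over [i, n)
    return pre, suf


def _noise_sd_estimate(force: np.ndarray) -> float:
    """Robust white-noise sd from first differences (MAD-based).

    The piecewise-linear signal contributes only ~slope*dz per step, so
    the median absolute first difference is noise-dominated.
    """
    d = np.diff(force)
    return float(np.median(np.abs(d - np.median(d))) / (0.6744897501960817 * np.sqrt(2.0)))


def _first_drop_index(
    force: np.ndarray, config: AnalysisConfig, start: int = 0
) -> int | None:
    """Index of the sample holding the peak immediately before the first
    qualifying force drop, or None.

    A drop qualifies when the smoothed force falls below the maximum of the
    preceding ``break_window`` smoothed samples by at least
    ``max(break_drop_frac * running_peak, break_noise_factor * sigma_hat,
    min_drop_nN)``.
    """
    f_s = _smooth(force, config.smoothing_halfwidth)
    n = f_s.size
    w = config.break_window
    if n <= w + 1:
        return None
    # 1e-9 nN guards the degenerate exactly-noise-free case where a zero
    # floor would let a flat baseline qualify as a "drop" of zero.
    floor = max(
        config.min_drop_nN,
        config.break_noise_factor * _noise_sd_estimate(force),
        1e-9,
    )
    windows = np.lib.stride_tricks.sliding_window_view(f_s, w)
    prev_max = windows.max(axis=1)  # prev_max[i] = max f_s[i : i + w]
    j = np.arange(w, n)
    drops = prev_max[: n - w] - f_s[j]
    running_peak = np.maximum.accumulate(f_s)[j]
    threshold = np.maximum(config.break_drop_frac * running_peak, floor)
    ok = (drops >= threshold) & (j >= max(start, w))
    if not np.any(ok):
        return None
    j_trig = int(j[np.argmax(ok)])
    lo = max(j_trig - w, 0)
    return lo + int(np.argmax(force[lo : j_trig + 1]))


def detect_contact_point(
    curve: ForceCurve, config: AnalysisConfig | None = None
) -> tuple[float, ForceCurve]:
    """Locate the tip–sample contact point and remove the baseline.

    The changepoint of a two-piece linear model (baseline line, contact
    line) is found by exhaustive scan; the reported z0 is the intersection
    of the two fitted lines when it falls near the changepoint, otherwise
    the midpoint between the straddling samples.  To keep the two-piece
    model valid for breaking curves, the scan runs only on the portion of
    the curve before the first detected force drop.

    Returns
    -------
    (z0, corrected) : contact position in nm, and a copy of the full curve
        with the fitted baseline (offset and tilt) subtracted.

    Raises
    ------
    ContactNotFoundError
        If no changepoint improves over a single-line fit by the
        configured margin, or the post-contact slope does not rise.
    """
    if config is None:
        config = AnalysisConfig()
    asc = curve.ascending()
    z, f = asc.z, asc.force

    p_break = _first_drop_index(f, config)
    end = p_break + 1 if p_break is not None else z.size
    zs, fs = z[:end], f[:end]
    m = config.min_segment_samples
    if end < 2 * m + 2:
        raise ContactNotFoundError("curve too short before first drop")

    pre, suf = _segment_line_sse(zs, fs)
    sse_two = pre + suf
    candidates = np.arange(m, end - m)
    i_best = int(candidates[np.argmin(sse_two[candidates])])
    sse_best = float(sse_two[i_best])

    # single-line reference
    resid = np.polyfit(zs, fs, 1, full=True)[1]
    sse_one = float(resid[0]) if resid.size else 0.0
    if sse_one <= 1e-12 * max(1.0, float(np.sum(fs**2))):
        raise ContactNotFoundError("no contact detected: curve is a single line")
    if sse_best / sse_one >= config.contact_sse_ratio_max:
        raise ContactNotFoundError(
            "no contact detected: changepoint does not improve over a line "
            f"(SSE ratio {sse_best / sse_one:.2f})"
        )

    zb, fb = zs[:i_best], fs[:i_best]
    m1, b1 = np.polyfit(zb, fb, 1)
    m2, b2 = np.polyfit(zs[i_best:], fs[i_best:], 1)
    if m2 <= m1:
        raise ContactNotFoundError(
            "no contact detected: post-changepoint slope does not rise"
        )
    dz = asc.sample_spacing
    z_mid = 0.5 * (zs[i_best - 1] + zs[i_best])
    if abs(m2 - m1) > 1e-12:
        z_x = (b1 - b2) / (m2 - m1)
        z0 = z_x if abs(z_x - z_mid) <= 2.5 * dz else z_mid
    else:
        z0 = z_mid

    # Baseline tilt is subtracted only when statistically significant;
    # removing a noise-fitted tilt would otherwise perturb the elastic
    # slope (and the error is amplified by the series-spring inversion).
    resid_b = fb - (m1 * zb + b1)
    if zb.size > 3:
        sigma_b = float(np.std(resid_b, ddof=2))
        se_m1 = sigma_b / (np.sqrt(zb.size) * max(np.std(zb), 1e-12))
    else:
        se_m1 = 0.0
    if abs(m1) <= 3.0 * se_m1:
        m1, b1 = 0.0, float(np.mean(fb))
    corrected = asc.with_force(f - (m1 * z + b1))
    corrected.metadata["baseline_slope"] = float(m1)
    corrected.metadata["baseline_offset"] = float(b1)
    return float(z0), corrected


def fit_spring_constant(
    curve: ForceCurve,
    calibration: CalibrationResult,
    config: AnalysisConfig | None = None,
) -> IndentationResult:
    """Fit the particle spring constant over the elastic loading regime.

    Cantilever and particle deform in series, so force vs piezo extension
    has slope ``s = S*k/(S+k)`` with ``S`` the calibrated hard-surface
    slope; equivalently, force vs tip–sample indentation
    (``delta = (z - z0) - F/S``) has slope ``k``.  The fit regresses force
    on piezo extension — the axis free of force noise — over the window
    [fit_lower_frac, fit_upper_frac] of the pre-break peak force, then
    inverts the series relation, ``k = s*S/(S - s)``.  (Regressing force
    on the indentation directly is biased downward at finite noise: the
    same noisy force enters both axes, which attenuates the slope.)

    Curves whose fitted slope is too close to the calibration slope, or
    whose implied indentation span over the fit window falls below
    ``min_indentation_nm``, are rejected as glass-like: the tip is not
    measurably indenting the sample and no particle stiffness exists.
    """
    if config is None:
        config = AnalysisConfig()
    if calibration is None:
        raise CalibrationError(
            "no calibration associated with this curve; calibrate before "
            "measuring (thermal + glass indentation)"
        )
    z0, corrected = detect_contact_point(curve, config)
    z, f = corrected.z, corrected.force

    contact = z > z0
    p_break = _first_drop_index(f, config, start=int(np.argmax(contact)))
    pre_break = np.ones(z.size, dtype=bool)
    if p_break is not None:
        pre_break[p_break + 1 :] = False
    usable = contact & pre_break
    if usable.sum() < 10:
        raise InsufficientDataError("fewer than 10 usable post-contact samples")

    # Two-pass window selection.  Selecting samples by their own (noisy)
    # force truncates the noise at both window edges and biases the slope;
    # the first pass uses the smoothed force only to seed a fit, and the
    # second selects by z-position computed from that fitted line, which is
    # independent of each sample's own noise.
    f_s = _smooth(f, config.smoothing_halfwidth)
    peak = float(np.max(f_s[usable]))
    lo, hi = config.fit_lower_frac * peak, config.fit_upper_frac * peak
    window = usable & (f_s >= lo) & (f_s <= hi)
    if window.sum() < 10:
        raise InsufficientDataError("fewer than 10 samples in the fit window")
    slope, intercept = np.polyfit(z[window], f[window], 1)
    if slope > 0:
        z_lo = (lo - intercept) / slope
        z_hi = (hi - intercept) / slope
        window2 = usable & (z >= z_lo) & (z <= z_hi)
        if window2.sum() >= 10:
            window = window2

    z_win, f_win = z[window], f[window]
    slope, intercept = np.polyfit(z_win, f_win, 1)
    fitted = slope * z_win + intercept
    sst = float(np.sum((f_win - f_win.mean()) ** 2))
    sse = float(np.sum((f_win - fitted) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    # model check against the noise level: residual variance should match
    # the per-curve noise estimate; r^2 alone misgrades low-force curves
    # where even pure noise caps it well below 1
    sigma_hat = _noise_sd_estimate(f)
    reduced_chi2 = (
        sse / (max(int(window.sum()) - 2, 1) * sigma_hat**2) if sigma_hat > 0 else 0.0
    )

    flags: list[str] = []
    k_out: float | None = None
    fit_window: tuple[float, float] | None = None
    if slope <= 0:
        flags.append("nonpositive_slope")
    else:
        slope_s = calibration.indentation_slope
        if slope >= config.max_slope_ratio * slope_s:
            raise GlassLikeCurveError(
                "infinite stiffness / glass-like: force-vs-z slope "
                f"{slope:.4g} is within {100 * (1 - config.max_slope_ratio):.0f}% "
                f"of the hard-surface slope {slope_s:.4g}"
            )
        k = slope * slope_s / (slope_s - slope)
        # indentation span over the fit window implied by the fitted line
        delta_span = (hi - lo) / k
        if delta_span < config.min_indentation_nm:
            raise GlassLikeCurveError(
                "infinite stiffness / glass-like: indentation span "
                f"{delta_span:.2f} nm below {config.min_indentation_nm} nm"
            )
        k_out = float(k)
        fit_window = (float(lo / k), float(hi / k))
    if r2 < config.min_r_squared or reduced_chi2 > config.max_reduced_chi2:
        flags.append("poor_fit")
    return IndentationResult(
        contact_z0=z0,
        spring_constant_k=k_out,
        fit_r_squared=float(r2),
        fit_window_nm=fit_window,
        flags=flags,
    )


def detect_break(
    curve: ForceCurve,
    result_so_far: IndentationResult,
    config: AnalysisConfig | None = None,
) -> IndentationResult:
    """Scan post-contact samples for the first mechanical-failure drop.

    The breaking force is the force the particle sustained immediately
    before the first qualifying drop, read off a local line fit to the
    final pre-break samples (robust to single-sample noise).  The
    indentation at break is ``F_break / k``.  Absence of a break is a
    flagged outcome (``no_break``), not an error.
    """
    if config is None:
        config = AnalysisConfig()
    asc = curve.ascending()
    z, f = asc.z, asc.force
    # work on the baseline-corrected signal
    m1 = curve.metadata.get("baseline_slope")
    if m1 is not None:
        f = f - (m1 * z + curve.metadata.get("baseline_offset", 0.0))
    contact = z > result_so_far.contact_z0
    start = int(np.argmax(contact))
    p = _first_drop_index(f, config, start=start)
    result = dataclasses.replace(result_so_far, flags=list(result_so_far.flags))
    if p is None:
        result.flags.append("no_break")
        return result

    lo = max(start, p - config.break_fit_samples + 1)
    if p - lo + 1 >= 5:
        coeffs = np.polyfit(z[lo : p + 1], f[lo : p + 1], 1)
        f_break = float(np.polyval(coeffs, z[p]))
    else:
        f_break = float(np.max(f[start : p + 1]))
    result.breaking_force = f_break
    if result.spring_constant_k is not None:
        result.indentation_at_break = f_break / result.spring_constant_k
    return result


def analyze_curve(
    curve: ForceCurve,
    calibration: CalibrationResult,
    config: AnalysisConfig | None = None,
) -> IndentationResult:
    """Full single-curve analysis: contact, spring constant, break."""
    if config is None:
        config = AnalysisConfig()
    result = fit_spring_constant(curve, calibration, config)
    return detect_break(curve, result, config)
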