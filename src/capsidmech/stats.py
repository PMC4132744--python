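"""Ensemble statistics: Gaussian summaries of particle groups and
pairwise group comparisons.

Each capsid group (15–20 particles in a typical experiment) is summarized
by a Gaussian fit to its per-particle values.  The primary estimator is
the exact maximum-likelihood fit — the sample mean and standard deviation
— with standard error sd/sqrt(n).  A least-squares Gaussian fitted to the
histogram counts is reported alongside, mirroring how such histograms are
usually displayed, but it is secondary: bin-count fitting is unstable at
n ~ 15–20, while the moment fit is exact at any n.

Group differences are expressed as percent changes and fold ratios of the
group means, with first-order error propagation (relative standard errors
added in quadrature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError

__all__ = ["EnsembleSummary", "GroupComparison", "summarize", "compare", "sturges_bins"]

RECOMMENDED_MIN_PARTICLES = 15


def sturges_bins(n: int) -> int:
    return int(np.ceil(np.log2(max(n, 2)))) + 1


@dataclass
class EnsembleSummary:
    """Gaussian summary of one group of per-particle measurements."""

    group_label: str
    n: int
    mean: float
    sd: float
    standard_error: float
    bin_edges: np.ndarray = field(repr=False, default=None)
    counts: np.ndarray = field(repr=False, default=None)
    fit_method: str = "moments"
    histogram_fit_mean: float | None = None
    histogram_fit_sd: float | None = None


@dataclass
class GroupComparison:
    """Difference between two group means for one metric.

    percent_change is 100 * (a - b) / a, positive for a decrease from a
    to b (matching "decreased by N%" phrasing); fold_ratio is b / a.
    """

    group_a: str
    group_b: str
    metric: str
    value_a: float
    value_b: float
    percent_change: float
    fold_ratio: float
    propagated_error_percent: float | None = None
    propagated_error_fold: float | None = None

    @property
    def percent_change_display(self) -> int:
        return int(round(abs(self.percent_change)))

    @property
    def fold_ratio_display(self) -> float:
        return round(self.fold_ratio, 1)

    @property
    def direction(self) -> str:
        if self.percent_change > 0:
            return "decrease"
        if self.percent_change < 0:
            return "increase"
        return "unchanged"


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def summarize(
    values: np.ndarray,
    group_label: str = "",
    n_bins: int | None = None,
) -> EnsembleSummary:
    """Gaussian summary of a group of per-particle values.

    Moment estimates (sample mean, unbiased sd, SE = sd/sqrt(n)) are the
    primary output; a least-squares Gaussian on the histogram counts is
    attached when the fit converges.

    Raises
    ------
    InsufficientDataError
        For n < 3.  A warning is emitted for n below 15, the practical
        floor for per-group particle counts.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n < 3:
        raise InsufficientDataError(f"insufficient particles: n={n} < 3")
    if n < RECOMMENDED_MIN_PARTICLES:
        warnings.warn(
            f"group '{group_label}': only {n} particles; at least "
            f"{RECOMMENDED_MIN_PARTICLES}-20 are recommended per group",
            stacklevel=2,
        )
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    se = sd / np.sqrt(n)

    if n_bins is None:
        n_bins = sturges_bins(n)
    counts, edges = np.histogram(values, bins=n_bins)
    summary = EnsembleSummary(
        group_label=group_label,
        n=n,
        mean=mean,
        sd=sd,
        standard_error=float(se),
        bin_edges=edges,
        counts=counts,
        fit_method="moments",
    )

    if sd > 0 and n_bins >= 3:
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _gaussian,
                    centers,
                    counts.astype(float),
                    p0=[counts.max(), mean, sd],
                    maxfev=5000,
                )
            if popt[2] != 0 and np.isfinite(popt).all():
                summary.histogram_fit_mean = float(popt[1])
                summary.histogram_fit_sd = float(abs(popt[2]))
        except (RuntimeError, ValueError):
            pass  # unstable at small n; the moment fit stands alone
    return summary


def compare(a: EnsembleSummary, b: EnsembleSummary, metric: str = "") -> GroupComparison:
    """Compare two group means: percent change (a to b) and fold ratio b/a.

    Propagated uncertainties combine the two relative standard errors in
    quadrature (first order); the underlying measurements report no
    uncertainty on percent changes, so these are informational.
    """
    if a.mean == 0:
        raise ValueError("reference group mean is zero; comparison undefined")
    percent = 100.0 * (a.mean - b.mean) / a.mean
    fold = b.mean / a.mean
    err_pct = err_fold = None
    if a.mean != 0 and b.mean != 0:
        rel = np.sqrt(
            (a.standard_error / a.mean) ** 2 + (b.standard_error / b.mean) ** 2
        )
        err_fold = float(abs(fold) * rel)
        err_pct = float(100.0 * abs(b.mean / a.mean) * rel)
    return GroupComparison(
        group_a=a.group_label,
        group_b=b.group_label,
        metric=metric,
        value_a=a.mean,
        value_b=b.mean,
        percent_change=float(percent),
        fold_ratio=float(fold),
        propagated_error_percent=err_pct,
        propagated_error_fold=err_fold,
    )
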