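# Methods

This note records the models, estimators, defaults and numerical choices
behind capsidmech, and what the synthetic benchmarks do and do not show
about real instrument data.

## Units

Lengths are in nm, forces in nN throughout. With this pairing a stiffness
in N/m is numerically a slope in nN/nm, and `k·R/h²` lands directly in
GPa (1 nN/nm² = 10⁹ N/m²). File formats declare these units; nothing in
the code converts.

## Measurement model

The cantilever (stiffness `k_c`) and the particle (stiffness `k`) deform
in series: compliances add, so the force-vs-piezo slope in the elastic
regime is `s = k_c·k/(k_c+k)`, and the tip–sample indentation is the
piezo travel minus the cantilever's own deflection,
`δ = (z − z0) − F/S`, with `S` the hard-surface (glass) slope from
calibration. Loading is treated as linear-elastic up to an abrupt failure
event — the regime where these experiments are performed; no Hertzian or
nonlinear shell corrections are applied.

## Calibration

**Thermal spring constant.** Equipartition applied to the free deflection
variance: `k_c = k_B·T / var(x)`, `k_B = 1.380649×10⁻²³ J/K`
(= 1.380649×10⁻⁵ nN·nm/K). The trace is linearly detrended first — slow
drift otherwise inflates the variance and biases `k_c` low — and the
variance uses ddof = 2 for the two trend parameters. No mode-shape or
laser-spot correction factors are applied (factor 1.0); power-spectral
(SHO) fitting is a non-goal. Traces shorter than 1000 samples are
refused; at 10⁵ samples the estimator is reliable to a few percent.

**Glass sensitivity.** The post-contact least-squares slope on a glass
curve. On an infinitely stiff substrate in calibrated units this slope
equals `k_c`, and it is the quantity used in the indentation transform:
it is measured from hundreds of samples and is an order of magnitude more
precise than the thermal estimate, which matters because the series
inversion amplifies calibration error by roughly `(1 + k/k_c)` — a factor
~7 for a 0.35 N/m capsid on a 0.06 N/m lever. The analysis therefore uses
the glass slope for compliance subtraction and keeps the thermal value as
the reported `k_c`. Analysis refuses to run without a calibration record
(calibrate-then-measure order).

## Contact-point detection

Exhaustive changepoint scan of a two-piece linear model (baseline line,
contact line), minimizing the summed per-segment OLS residuals; both
segment SSE profiles are computed in O(n) from cumulative sums after
global centering (centering leaves segment SSEs unchanged and avoids
cancellation). The reported `z0` is the intersection of the two fitted
lines when it falls within ±2.5 samples of the changepoint, else the
midpoint of the straddling samples; on noise-free curves this recovers
the programmed contact exactly.

Two guards:

* the scan runs only on the portion of the curve before the first
  detected force drop, so the post-failure branch cannot masquerade as
  the "contact line" of the two-piece model;
* "no contact" is declared when the best changepoint fails to reduce the
  SSE below 0.8× the single-line fit, or the post-changepoint slope does
  not rise. Pure-noise and tilt-only curves fail these tests.

Baseline removal subtracts the fitted pre-contact line, but the tilt term
only when it is statistically significant (|slope| > 3 SE of the baseline
fit). Subtracting a noise-fitted tilt from an untilted curve injects a
random slope error that the series inversion amplifies; the significance
gate removes this at zero cost when a real tilt is present.

## Spring-constant fit

The elastic window is the band between 10% and 90% of the pre-break peak
force (skipping contact nonlinearity at the bottom and near-failure
softening at the top). Two estimator choices matter at realistic noise:

* **Regress force on z, not on δ.** The indentation contains `−F/S`, so
  the same force noise enters both axes of a force-vs-δ regression; the
  resulting errors-in-variables attenuation is ~5% at the default noise
  level. Force-vs-z regression has a noise-free abscissa; `k` is then
  obtained algebraically, `k = s·S/(S − s)`. Both routes agree exactly on
  noise-free curves (tested).
* **Select the window by position, not by noisy force.** Thresholding
  samples on their own force truncates the noise distribution at both
  window edges and biases the slope. A first pass (on smoothed force)
  seeds the fit; the second pass selects samples by the z-interval the
  fitted line assigns to the force band, which is independent of each
  sample's own noise.

Degenerate cases: a fitted slope within 5% of the calibration slope
(`max_slope_ratio = 0.95`) or an implied indentation span below 1 nm is
rejected as glass-like — the tip is not measurably indenting the sample
and the inversion is ill-conditioned. Non-positive slopes are flagged and
no `k` is reported.

Fit quality is judged by reduced χ² against a robust per-curve noise
estimate (`MAD(diff(F))/(0.6745·√2)`, noise-dominated because the
piecewise-linear signal contributes only ~slope·dz per step): residual
variance above 2× the noise variance flags `poor_fit`, meaning the linear
model does not describe the window (typically an undetected small break
inside the fit range). r² is kept as a weak backstop (default 0.5) — a
fixed high r² bar would misgrade low-force curves where pure noise caps
r² far below 1. Flagged curves are excluded from group aggregation.

## Break detection

The smoothed force (moving average, halfwidth 4) is scanned for the first
sample that falls below the maximum of the preceding 12 smoothed samples
by at least `max(0.2 × running peak, 2.5 σ̂)`, with σ̂ the robust noise
estimate (at the default 0.05 nN noise the floor is 0.125 nN). The peak
sample just before the drop is located on the raw force, and `F_break` is
read off a local line fit to the last ≤40 pre-break samples evaluated
there — robust to single-sample noise, unbiased to within ~1% over the
studied force range. The earliest qualifying drop defines failure (the
breaking force is the maximum force withstood *before* failure); absence
of a drop is a flagged outcome (`no_break`), not an error. At the default
configuration the detector reaches 100% detection of ≥5σ drops with zero
false positives over hundreds of no-break curves.

## Thin-shell inversion

`E = k·R/(α·h²)`, `α = 1` by default (kept as a field). Which radius to
use is a genuine modeling choice for walls that are not vanishingly thin;
the geometry type carries an explicit `radius_convention`
(outer/midwall/inner, default midwall). Registry defaults: HSV-1 outer
diameter 125 nm, wall 15 nm; λ procapsid 55 nm diameter, 4 nm wall; λ
expanded capsid 63 nm diameter, 1.8 nm wall. The two λ wall thicknesses
are structural measurements; radii and the HSV-1 wall value are
literature-level defaults, and every report row cites the registry entry
used. Published λ Young's moduli are matched to within ~10–15% under the
default convention (the procapsid value is matched almost exactly under
the inner-radius convention), which is the expected fidelity given that
the radii behind the published values are not stated.

## Ensemble statistics

The primary group estimate is the exact Gaussian MLE — sample mean and
unbiased sd, SE = sd/√n — because least-squares fitting of binned
histogram counts is unstable at n ≈ 15–20. The binned Gaussian fit
(Sturges bins by default) is attached as a secondary output for fidelity
to how such data are displayed; at n = 1000 the two agree to a fraction
of the sd. Groups below 3 particles are refused, below 15 warned. No
outlier rejection. Comparisons report `100·(a−b)/a` (positive = decrease)
and the fold ratio `b/a`, with first-order error propagation (relative
SEs in quadrature) — informational, since percent changes in this kind of
study are customarily quoted without uncertainties.

## Synthetic data: what it emulates, and what it does not

The generator produces the curve anatomy the analysis assumes: flat
(optionally tilted) baseline, series-spring elastic loading, an
instantaneous drop of a configurable fraction (default 60%) of the peak
at the programmed breaking force, reloading at a residual stiffness
(default 0.3·k), additive white Gaussian force noise, and a sample that
records exactly the peak force at failure. Ensembles draw `k` and
`F_break` from truncated normals; per-particle spreads are reconstructed
from published standard errors as `sd = SE·√20`. Thermal traces are an
AR(1) Gaussian process with equipartition variance (knee 5 kHz at 100 kHz
sampling, φ ≈ 0.73 — chosen so the variance estimator at 10⁵ samples has
~1% sampling error); the full SHO spectrum is not simulated, which is
sufficient because calibration uses only the stationary variance.

Deliberate idealizations: no 1/f drift or adhesion dips, no multiple
partial failures, no tip-shape contact mechanics, single approach segment
only, and exactly linear elastic loading. Passing tests therefore
demonstrate correctness of the estimators under the stated noise model,
not robustness to every artifact of real instrument data — the
changepoint, noise-floor and χ² machinery is designed to extend to those
cases, but is validated here against this generator.

Force noise scales with cantilever stiffness (deflection noise
0.8333 nm × `k_c`): 0.05 nN on the 0.06 N/m HSV-1 lever and 0.025 nN on
the 0.03 N/m λ lever. Protocol defaults — ramp 0→200 nm, 1600 samples,
contact offset 30 nm — are package choices; sampling density and ramp
length are not experimental constants of the study and are declared in
`IndentationProtocol`.

## Benchmarks and their scales

* Round-trip recovery: 100 particles spanning k ∈ [0.05, 0.4] N/m,
  F_break ∈ [0.4, 6] nN at 0.05 nN noise; median recovery error ~1% for
  both quantities (the 3% bar is met with margin). A stiff particle with
  a tiny breaking force yields almost no elastic signal and is honestly
  rejected rather than estimated.
* Parameter recovery: 200 replicate ensembles of 20 particles at each of
  the nine capsid-group operating points; the recovered Gaussian mean is
  compared against the realized ensemble ground truth (the mean of the
  true spring constants of the successfully analyzed curves) within 2 SE.
  Comparing against the population mean instead would test the central
  limit theorem (whose pass rate is ~95.4% by construction), not the
  pipeline.
* Determinism: identical seeds give bit-identical curves and byte-
  identical summary CSVs; every run log records a configuration hash.

## Known limitations

* The series inversion is ill-conditioned when `k ≫ k_c`; per-curve λ
  spring constants carry ~10–20% scatter at the default noise even though
  group means are accurate. This is physics, not implementation: the
  measured slope saturates at `k_c`.
* `F_break` from the local line fit is biased low by roughly half a
  sample step (~0.3% at HSV-1 scales).
* The histogram Gaussian fit can fail to converge at small n; it is then
  simply omitted (the moment fit always exists).
* Young's moduli inherit the full uncertainty of the geometry registry;
  they are reported with the geometry citation for that reason.
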