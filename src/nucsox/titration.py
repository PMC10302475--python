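"""Footprinting-titration quantification and apparent-Kd extraction.

Band intensities from a titration gel are normalized against internal
standard bands and the zero-concentration lane, then fitted by nonlinear
least squares to the biexponential decay

    f1(x) = a * exp(b * x) + c * exp(d * x)

with concentration x in nM.  The apparent dissociation constant Kd^app is
the concentration at the half-level of the signal-intensity change.  A
biexponential with d > 0 has no finite asymptote, so the "change" is
bounded by the assayed range: Kd^app solves
f1(x) = (f1(0) + f1(x_max)) / 2 on [0, x_max].  Kd^app is an operational
quantity and must not be read as the true thermodynamic Kd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import (
    ArgumentError,
    ExtractionError,
    FitError,
    NormalizationError,
)


@dataclass
class TitrationSeries:
    """Concentration (nM, strictly ascending, first lane may be 0) vs
    normalized band intensity, with optional per-point deviations."""

    concentrations: np.ndarray
    intensities: np.ndarray
    site: str = ""
    sd: np.ndarray | None = None

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.shape != self.intensities.shape:
            raise ArgumentError("concentrations and intensities must align")
        if self.concentrations.size < 5:
            raise ArgumentError("a titration series needs >= 5 points")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ArgumentError("concentrations must be strictly increasing")
        if self.concentrations[0] < 0:
            raise ArgumentError("concentrations must be non-negative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.concentrations.shape:
                raise ArgumentError("sd must align with concentrations")

    @property
    def max_concentration(self) -> float:
        return float(self.concentrations[-1])

    def scaled(self, factor: float) -> "TitrationSeries":
        return TitrationSeries(self.concentrations, self.intensities * factor,
                               site=self.site,
                               sd=None if self.sd is None else self.sd * factor)


def biexponential(x, a, b, c, d):
    """f1(x) = a exp(bx) + c exp(dx)."""
    x = np.asarray(x, dtype=float)
    return a * np.exp(b * x) + c * np.exp(d * x)


@dataclass
class BiexpFit:
    a: float
    b: float
    c: float
    d: float
    r_squared: float            # NaN when the series has zero variance
    rmse: float
    seed: int
    degenerate_variance: bool = False
    kd_app: float | None = None

    def __call__(self, x):
        return biexponential(x, self.a, self.b, self.c, self.d)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def normalize_intensities(concentrations, raw, internal_standards,
                          baseline_lane: int | None = None,
                          site: str = "") -> TitrationSeries:
    """Normalize per-lane band intensities.

    intensity(lane) = (band / standard)(lane) / (band / standard)(baseline),
    where the baseline is the zero-concentration lane (auto-detected as the
    lane with concentration 0 when ``baseline_lane`` is None).  The baseline
    lane maps to exactly 1.0 and the result is invariant to per-gel exposure
    scaling.
    """
    conc = np.asarray(concentrations, dtype=float)
    raw = np.asarray(raw, dtype=float)
    std = np.asarray(internal_standards, dtype=float)
    if not (conc.shape == raw.shape == std.shape):
        raise ArgumentError("lanes must be aligned across inputs")
    if baseline_lane is None:
        zeros = np.nonzero(conc == 0)[0]
        if zeros.size == 0:
            raise ArgumentError("no zero-concentration baseline lane present")
        baseline_lane = int(zeros[0])
    if np.any(std == 0):
        raise NormalizationError("zero internal-standard intensity")
    ratio = raw / std
    if ratio[baseline_lane] == 0:
        raise NormalizationError("zero baseline band intensity")
    return TitrationSeries(conc, ratio / ratio[baseline_lane], site=site)


def _fit_starts(y0: float, seed: int, n_rates: int = 4):
    """Multi-start grid: log-spaced |b|, |d| in [1e-5, 1e-1], a = f(0),
    c small; deterministic 1% jitter from the recorded seed."""
    rng = np.random.default_rng(seed)
    rates = np.logspace(-5, -1, n_rates)
    starts = []
    for bb in rates:
        for dd in rates:
            jitter = 1.0 + 0.01 * rng.standard_normal(4)
            starts.append(np.array([y0 * 0.99, -bb, 0.01 * max(abs(y0), 1e-3), dd]) * jitter)
    return starts


def fit_biexponential(series: TitrationSeries, init_strategy: str = "multistart",
                      seed: int = 0) -> BiexpFit:
    """Best-of-starts nonlinear least squares for the biexponential decay.

    Residuals are weighted by 1/sd when per-point deviations are present.
    R^2 = 1 - SSres/SStot; RMSE = sqrt(SSres / n).  A constant series has
    undefined R^2 (flagged, fit still returned).
    """
    if init_strategy != "multistart":
        raise ArgumentError(f"unknown init strategy {init_strategy!r}")
    x, y = series.concentrations, series.intensities
    w = np.ones_like(y)
    if series.sd is not None and np.all(series.sd > 0):
        w = 1.0 / series.sd

    def resid(p):
        return (biexponential(x, *p) - y) * w

    best, diagnostics = None, []
    for p0 in _fit_starts(float(y[0]), seed):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = least_squares(resid, p0, method="lm", max_nfev=5000)
        except Exception as e:     # singular Jacobian etc.
            diagnostics.append(str(e))
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(np.sum((biexponential(x, *res.x) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        raise FitError("no start converged", diagnostics)
    sse, p = best
    # f1 is symmetric under exchanging its two terms; canonicalize with the
    # dominant-amplitude term first so reported parameters are stable
    if abs(p[2]) > abs(p[0]):
        p = np.array([p[2], p[3], p[0], p[1]])
    sst = float(np.sum((y - y.mean()) ** 2))
    degenerate = sst == 0.0
    r2 = float("nan") if degenerate else 1.0 - sse / sst
    rmse = float(np.sqrt(sse / len(y)))
    return BiexpFit(a=float(p[0]), b=float(p[1]), c=float(p[2]), d=float(p[3]),
                    r_squared=r2, rmse=rmse, seed=seed,
                    degenerate_variance=degenerate)


def kd_app(fit: BiexpFit, x_max: float, tolerance_nM: float = 0.1) -> float:
    """Concentration at the half-level of the signal change over [0, x_max].

    Solves f1(x*) = (f1(0) + f1(x_max)) / 2 by bracketed root finding.  The
    fitted curve must show a decreasing trend over the assayed range; an
    increasing curve raises ExtractionError, non-monotone dips only warn.
    """
    if x_max <= 0:
        raise ArgumentError("x_max must be positive")
    grid = np.linspace(0.0, x_max, 512)
    vals = fit(grid)
    f0, fmax = float(vals[0]), float(vals[-1])
    if fmax >= f0:
        raise ExtractionError("curve does not decrease over the assayed range")
    if np.any(np.diff(vals) > 1e-9 * max(abs(f0), 1.0)):
        warnings.warn("fitted curve is not monotone over [0, x_max]; "
                      "Kd^app is the first half-change crossing", stacklevel=2)
    mid = 0.5 * (f0 + fmax)

    def g(x):
        return fit(x) - mid

    # first bracketing interval on the grid, so the first crossing is taken
    sign0 = np.sign(g(0.0))
    for lo, hi in zip(grid[:-1], grid[1:]):
        if np.sign(g(hi)) != sign0:
            return float(brentq(g, lo, hi, xtol=min(tolerance_nM, 0.1) / 10))
    raise ExtractionError("no half-change crossing in [0, x_max]")


def fit_titration(series: TitrationSeries, seed: int = 0,
                  x_max: float | None = None) -> BiexpFit:
    """Fit and attach Kd^app at the series' maximal concentration."""
    fit = fit_biexponential(series, seed=seed)
    fit.kd_app = kd_app(fit, x_max if x_max is not None else series.max_concentration)
    return fit


def make_dilution_series(max_conc: float, step: float = 1.5, n_points: int = 12,
                         include_zero: bool = False) -> np.ndarray:
    """Ascending geometric dilution series ending at ``max_conc``.

    ``step`` is the serial dilution factor (1.5 in the footprinting
    protocol); ``include_zero`` prepends the no-protein lane.
    """
    if step <= 1:
        raise ArgumentError("dilution step must exceed 1")
    if n_points < 2:
        raise ArgumentError("need at least 2 points")
    if max_conc <= 0:
        raise ArgumentError("max_conc must be positive")
    conc = max_conc / step ** np.arange(n_points)[::-1]
    if include_zero:
        conc = np.concatenate([[0.0], conc])
    return conc
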