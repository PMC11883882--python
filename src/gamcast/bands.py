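"""Quartic-kernel regression, uniform confidence bands, linearity test.

The linearity test asks whether the relationship between a covariate and GAM
prevalence can be described by a straight line.  It compares two bands over a
common evaluation grid:

* a *uniform* (simultaneous) 95% confidence band around the Nadaraya-Watson
  kernel-regression estimate, built from the classical extreme-value limit
  for the supremum of the standardised kernel estimator: the half-width at a
  grid point g is

      [ σ̂²(g) · ‖K‖₂² / (n · h · f̂(g)) ]^{1/2} · ( √(2δ log n) + c_α/√(2δ log n) )

  with ‖K‖₂² = 5/7 for the quartic kernel, f̂ a kernel density estimate and
  σ̂²(g) a kernel-weighted local residual variance (both with the same h),
  δ = log(1/h̃)/log n for the bandwidth h̃ rescaled to the unit interval, and
  c_α solving exp(−2e^{−c}) = 1 − α.  The second-order kernel-dependent
  centering constant of the extreme-value limit is deliberately omitted: it
  is negative for the quartic kernel, vanishes at rate (log n)^{−1/2}, and
  omitting it keeps finite-sample entire-curve coverage at or above the
  nominal level (the band's contract) rather than below it;

* a simultaneous (Working–Hotelling) 95% band around the OLS line.

The relationship is declared *linear* when the OLS band lies inside the
kernel band at every grid point, and *nonlinear* otherwise.  Because the
parametric band shrinks at rate n^{−1/2} while the kernel band shrinks at the
slower nonparametric rate, a genuinely linear relationship yields containment
with high probability as n grows, while any fixed departure from linearity
eventually forces the line (and its band) outside the kernel band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from gamcast.errors import (
    AlignmentError,
    CoverageError,
    DegenerateVariableError,
)

#: ∫K² for the quartic (biweight) kernel
QUARTIC_L2 = 5.0 / 7.0
#: ‖K′‖₂²/‖K‖₂² for the quartic kernel
QUARTIC_C1 = 3.0


def quartic_kernel(u) -> np.ndarray | float:
    """Quartic (biweight) kernel K(u) = (15/16)(1−u²)² on |u| ≤ 1, else 0."""
    u = np.asarray(u, dtype=float)
    inside = np.abs(u) <= 1.0
    out = np.where(inside, (15.0 / 16.0) * (1.0 - u**2) ** 2, 0.0)
    return out if out.ndim else float(out)


def rule_of_thumb_bandwidth(x: np.ndarray) -> float:
    """Normal-reference bandwidth h = 1.06 · σ̂ · n^(−1/5) (sample SD)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateVariableError("bandwidth needs at least 2 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateVariableError("bandwidth undefined for a constant covariate")
    return 1.06 * sd * n ** (-0.2)


def _weights(x: np.ndarray, grid: np.ndarray, h: float) -> np.ndarray:
    """(len(grid) × len(x)) matrix of kernel weights K((x−g)/h)."""
    return quartic_kernel((x[None, :] - grid[:, None]) / h)


def kernel_regression(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, h: float
) -> np.ndarray:
    """Nadaraya-Watson estimate m̂(g) = Σ K((xᵢ−g)/h)·yᵢ / Σ K((xᵢ−g)/h)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    grid = np.asarray(grid, float)
    if h <= 0:
        raise ValueError(f"bandwidth must be positive, got {h}")
    w = _weights(x, grid, h)
    denom = w.sum(axis=1)
    empty = denom <= 0
    if empty.any():
        raise CoverageError(
            f"no observations within bandwidth of grid point(s) "
            f"{grid[empty][:5].round(4).tolist()} — trim the grid"
        )
    return w @ y / denom


@dataclass
class Band:
    """A regression curve with lower/upper confidence limits on a grid."""

    grid: np.ndarray
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    bandwidth: float | None = None
    level: float = 0.95

    def half_width(self) -> np.ndarray:
        return (self.upper - self.lower) / 2.0

    def contains_curve(self, values: np.ndarray) -> bool:
        """Whether a curve evaluated on this grid lies inside everywhere."""
        v = np.asarray(values, float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))


def trimmed_grid(
    x: np.ndarray, n_points: int = 100, trim: tuple[float, float] = (0.05, 0.95)
) -> np.ndarray:
    """Equispaced evaluation grid between covariate quantiles (boundary trim)."""
    lo, hi = np.quantile(np.asarray(x, float), trim)
    if hi <= lo:
        raise DegenerateVariableError("degenerate covariate: trimmed range is empty")
    return np.linspace(lo, hi, n_points)


def _gumbel_constant(level: float) -> float:
    # c solving exp(−2 e^{−c}) = level
    return -np.log(-0.5 * np.log(level))


def uniform_band(
    x: np.ndarray,
    y: np.ndarray,
    h: float | None = None,
    level: float = 0.95,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    trim: tuple[float, float] = (0.05, 0.95),
    pointwise: bool = False,
) -> Band:
    """Uniform (simultaneous) confidence band for the kernel regression curve.

    With ``pointwise=True`` the extreme-value inflation factor is replaced by
    the normal quantile, giving ordinary pointwise intervals (for sensitivity
    analysis; the simultaneous band is the default and is strictly wider).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if h is None:
        h = rule_of_thumb_bandwidth(x)
    if grid is None:
        grid = trimmed_grid(x, n_grid, trim)
    grid = np.asarray(grid, float)

    w = _weights(x, grid, h)
    denom = w.sum(axis=1)
    if (denom <= 0).any():
        raise CoverageError("empty kernel window on the grid — trim harder")
    m_hat = w @ y / denom

    # residuals against the fit evaluated at the data points
    m_at_x = kernel_regression(x, y, x, h)
    resid = y - m_at_x
    sigma2 = (w @ resid**2) / denom  # kernel-weighted local residual variance
    f_hat = denom / (n * h)  # KDE with the same kernel and bandwidth
    if (f_hat <= 0).any():
        raise CoverageError("estimated density vanishes on the grid — trim harder")

    scale = np.sqrt(sigma2 * QUARTIC_L2 / (n * h * f_hat))

    if pointwise:
        factor = stats.norm.ppf(0.5 + level / 2.0)
    else:
        # bandwidth exponent on the unit-interval scale of the trimmed support
        span = grid[-1] - grid[0]
        h_unit = min(h / span, 0.9)
        delta = np.clip(np.log(1.0 / h_unit) / np.log(n), 0.05, 0.5)
        two_dln = 2.0 * delta * np.log(n)
        # leading-order Gumbel inflation √(2δ log n) + c_α/√(2δ log n); the
        # second-order kernel-dependent centering term is omitted — it is
        # negative for the quartic kernel and makes the band undercover at
        # practical n, while the contract here is coverage ≥ level
        factor = np.sqrt(two_dln) + _gumbel_constant(level) / np.sqrt(two_dln)

    half = factor * scale
    return Band(grid, m_hat, m_hat - half, m_hat + half, bandwidth=h, level=level)


def ols_band(
    x: np.ndarray,
    y: np.ndarray,
    grid: np.ndarray,
    level: float = 0.95,
    simultaneous: bool = True,
) -> Band:
    """Confidence band for the OLS regression line over a grid.

    ``simultaneous=True`` gives the Working–Hotelling band (√(2·F₂,ₙ₋₂)
    inflation, valid for the whole line at once); otherwise pointwise
    t-intervals for the conditional mean.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    grid = np.asarray(grid, float)
    n = x.size
    if n < 3:
        raise DegenerateVariableError("OLS band needs at least 3 observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise DegenerateVariableError("OLS band undefined for a constant covariate")

    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    dof = n - 2
    s2 = float(np.sum((y - fitted) ** 2) / dof)

    line = intercept + slope * grid
    se = np.sqrt(s2 * (1.0 / n + (grid - x.mean()) ** 2 / sxx))
    if simultaneous:
        factor = np.sqrt(2.0 * stats.f.ppf(level, 2, dof))
    else:
        factor = stats.t.ppf(0.5 + level / 2.0, dof)
    half = factor * se
    return Band(grid, line, line - half, line + half, level=level)


def containment_test(linear: Band, nonparam: Band) -> str:
    """'linear' iff the OLS band lies inside the kernel band at every point."""
    if linear.grid.shape != nonparam.grid.shape or not np.allclose(
        linear.grid, nonparam.grid
    ):
        raise AlignmentError("bands evaluated on different grids")
    inside = np.all(linear.lower >= nonparam.lower) and np.all(
        linear.upper <= nonparam.upper
    )
    return "linear" if inside else "nonlinear"
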