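"""Allometric power-law fits and scaling-exponent maps.

Trait growth against size is modeled as Y = b·x^α; after a log
transformation the fit is ordinary least squares of log₁₀Y on log₁₀x,
giving the scaling exponent α (slope) and initial growth index b
(10^intercept).  Exponents below 1 mean the trait grows more slowly than
the size measure.

Fits come in two flavours that must not be conflated: one *global* fit
per variable across individuals (eye-wide means), and *local* fits per
world-grid cell restricted to cells seen by at least ``min_n``
individuals (default 4), which yield scaling-exponent maps over the
visual field with a "fringe" marking cells seen by 1-3 individuals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .projection import WorldGrid


@dataclasses.dataclass
class AllometryFit:
    """Result of one power-law fit Y = b·x^α (log-log OLS)."""

    alpha: float          # scaling exponent (slope on log-log axes)
    b: float              # initial growth index (10^intercept)
    r: float              # Pearson correlation of the log-log regression
    p_value: float        # two-sided; NaN when n == 2
    n: int

    @property
    def significant(self) -> bool:
        """Drives dashed-vs-solid plotting of the fitted curve."""
        return bool(np.isfinite(self.p_value) and self.p_value < 0.05)

    def predict(self, x):
        return self.b * np.asarray(x, dtype=np.float64) ** self.alpha

    def summary(self) -> str:
        sig = "significant" if self.significant else "not significant"
        return (f"Y = {self.b:.4g}·x^{self.alpha:.4g}  "
                f"(r = {self.r:.3f}, p = {self.p_value:.3g}, n = {self.n}; "
                f"{sig})")


def fit_power_law(x, y) -> AllometryFit:
    """Fit Y = b·x^α by OLS on log₁₀-transformed data."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need at least two (x, y) pairs of equal length")
    bad = ~((x > 0) & (y > 0))
    if bad.any():
        raise ValueError(
            f"nonpositive values at records {np.flatnonzero(bad).tolist()}; "
            "power-law fits require positive x and y")
    lx, ly = np.log10(x), np.log10(y)
    if len(x) == 2:
        slope = (ly[1] - ly[0]) / (lx[1] - lx[0])
        intercept = ly[0] - slope * lx[0]
        return AllometryFit(alpha=float(slope), b=float(10 ** intercept),
                            r=1.0, p_value=np.nan, n=2)
    if np.allclose(ly, ly[0]):
        # constant trait: slope 0; correlation undefined
        return AllometryFit(alpha=0.0, b=float(10 ** ly[0]), r=np.nan,
                            p_value=np.nan, n=len(x))
    res = stats.linregress(lx, ly)
    return AllometryFit(alpha=float(res.slope),
                        b=float(10 ** res.intercept),
                        r=float(res.rvalue), p_value=float(res.pvalue),
                        n=len(x))


def size_measures(record) -> dict[str, float]:
    """Canonical size measures of one individual: cube-root eye volume
    (μm), square-root eye area (μm), and intertegular width (mm)."""
    out = {}
    if record.ev_um3 is not None:
        if record.ev_um3 <= 0:
            raise ValueError("eye volume must be positive")
        out["ev_cbrt"] = float(record.ev_um3) ** (1.0 / 3.0)
    if record.area_um2 is not None:
        if record.area_um2 <= 0:
            raise ValueError("eye area must be positive")
        out["sqrt_area"] = float(record.area_um2) ** 0.5
    if record.itw_mm is not None:
        if record.itw_mm <= 0:
            raise ValueError("ITW must be positive")
        out["itw"] = float(record.itw_mm)
    return out


@dataclasses.dataclass
class ExponentMap:
    """Per-cell scaling exponents over the visual field."""

    grid: WorldGrid
    alpha: np.ndarray        # α̂ per cell; NaN where n < min_n
    n: np.ndarray            # individuals contributing per cell
    min_n: int = 4

    @property
    def mask(self) -> np.ndarray:
        """Cells with enough individuals for a fit (n ≥ min_n)."""
        return self.n >= self.min_n

    @property
    def fringe(self) -> np.ndarray:
        """Cells seen by some but too few individuals (1 ≤ n < min_n)."""
        return (self.n >= 1) & (self.n < self.min_n)


def exponent_map(sizes, layers, grid: WorldGrid,
                 min_n: int = 4) -> ExponentMap:
    """Map the local scaling exponent of a projected variable.

    Parameters
    ----------
    sizes : per-individual size measures (positive), length n_eyes.
    layers : list of per-individual grid layers of the variable; a cell
        contributes an (size, value) pair for an eye when its value
        there is finite (i.e. the cell is inside that eye's CP).
    min_n : cells seen by fewer individuals are masked (default 4).

    The per-cell fit is the same log₁₀-OLS as :func:`fit_power_law`,
    vectorized over cells.
    """
    sizes = np.asarray(sizes, dtype=np.float64)
    if len(layers) != len(sizes):
        raise ValueError("one layer per size measure required")
    if np.any(sizes <= 0):
        raise ValueError("size measures must be positive")
    for lay in layers:
        if lay.shape != grid.shape:
            raise ValueError("layer shape does not match grid")
    stack = np.stack(layers)                      # (n_eyes, nel, naz)
    ok = np.isfinite(stack) & (stack > 0)
    n = ok.sum(axis=0)

    lx = np.log10(sizes)[:, None, None] * np.ones_like(stack)
    with np.errstate(invalid="ignore", divide="ignore"):
        ly = np.where(ok, np.log10(np.where(ok, stack, 1.0)), np.nan)
    lx = np.where(ok, lx, np.nan)

    cnt = np.maximum(n, 1)
    mx = np.nansum(lx, axis=0) / cnt
    my = np.nansum(ly, axis=0) / cnt
    sxx = np.nansum((lx - mx) ** 2, axis=0)
    sxy = np.nansum((lx - mx) * (ly - my), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = sxy / sxx
    alpha[(n < min_n) | (sxx == 0)] = np.nan
    return ExponentMap(grid=grid, alpha=alpha, n=n, min_n=min_n)
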