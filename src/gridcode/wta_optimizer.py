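"""Winner-take-all (WTA) grid optimization.

Under a WTA decoder, each module localizes the animal within the field of
its most active cell.  Unambiguous decoding requires the field width at one
scale not to exceed the period of the next, which ties the per-module cell
count to the scale ratio: for coverage factor d the total cell count in n
dimensions is N = d · Σ r_i^n, minimized at fixed resolution R = Π r_i^n.
The optimum has all ratios equal, with r* = e^(1/n); the normalized cost
curve is (x / ln x) / e with x = r^n, independent of both R and d.

The general constrained formulation (range L, accuracy A, accuracy
constant c1, ambiguity constant c2) is solved in closed form via the KKT
conditions: all constraints bind, giving λ_1 = L, λ_{i+1} = c2·l_i, a
common ratio r, and m = ln(c1·L/A)/ln r modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "GridSystem",
    "ResolutionConstraint",
    "CostCurve",
    "wta_neuron_count",
    "wta_optimal_scale",
    "wta_relative_cost",
    "wta_tolerance_interval",
    "wta_general_grid",
    "wta_integer_optimum",
]


class InvalidGridError(ValueError):
    """Raised when a grid system would be ambiguous or ill-formed."""


@dataclass(frozen=True)
class GridSystem:
    """A hierarchical grid system: ordered module periods and field widths.

    Parameters
    ----------
    dimension : int
        Spatial dimension (1, 2, or 3).
    periods : tuple of float
        Module periods λ_1 > λ_2 > ... > λ_m > 0, length units.
    field_widths : tuple of float
        Grid-field widths l_i > 0, same length and units as ``periods``.
    coverage : float
        Coverage factor d — number of cells responding at any location.
    geometry : LatticeGeometry, optional
        Response-lattice geometry (2D only).
    """

    dimension: int
    periods: tuple
    field_widths: tuple
    coverage: float = 1.0
    geometry: Optional[object] = None

    def __post_init__(self):
        if self.dimension not in (1, 2, 3):
            raise InvalidGridError(f"dimension must be 1, 2 or 3, got {self.dimension}")
        lam = np.asarray(self.periods, dtype=float)
        wid = np.asarray(self.field_widths, dtype=float)
        if lam.size == 0:
            raise InvalidGridError("grid system needs at least one module")
        if lam.size != wid.size:
            raise InvalidGridError("periods and field_widths must have equal length")
        if np.any(lam <= 0) or np.any(wid <= 0):
            raise InvalidGridError("periods and field widths must be positive")
        if np.any(np.diff(lam) >= 0):
            raise InvalidGridError("periods must be strictly decreasing")
        if np.any(wid > lam * (1 + 1e-12)):
            raise InvalidGridError("field width may not exceed the module period")
        if self.coverage <= 0:
            raise InvalidGridError("coverage factor must be positive")
        object.__setattr__(self, "periods", tuple(lam))
        object.__setattr__(self, "field_widths", tuple(wid))

    @property
    def n_modules(self) -> int:
        return len(self.periods)

    @property
    def scale_factors(self) -> np.ndarray:
        """Adjacent-period ratios r_i = λ_i/λ_{i+1} (length m-1)."""
        lam = np.asarray(self.periods)
        return lam[:-1] / lam[1:]

    def neuron_count(self) -> float:
        """Total cell count d·Σ (λ_i/l_i)^dimension."""
        lam = np.asarray(self.periods)
        wid = np.asarray(self.field_widths)
        return float(self.coverage * np.sum((lam / wid) ** self.dimension))


@dataclass(frozen=True)
class ResolutionConstraint:
    """Behavioral constraints on a grid code.

    L is the range to represent, A the required positional accuracy,
    c1 the accuracy constant (positional accuracy = c1·l_m), and c2 the
    ambiguity constant (decoding requires λ_{i+1} ≥ c2·l_i; c2 absorbs
    tuning-curve shape and coverage dependence).  The implied resolution
    is R = c1·L/A.
    """

    L: float
    A: float
    c1: float = 1.0
    c2: float = 1.0
    R: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.L <= 0 or self.A <= 0 or self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("L, A, c1, c2 must all be positive")
        if self.L <= self.A:
            raise ValueError("range L must exceed accuracy A")
        if self.R is None:
            object.__setattr__(self, "R", self.c1 * self.L / self.A)


@dataclass
class CostCurve:
    """Normalized cost curve N_r/N_min as a function of the scale ratio."""

    ratios: np.ndarray
    relative_cost: np.ndarray
    dimension: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r": self.ratios, "relative_cost": self.relative_cost})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def wta_neuron_count(ratios: Sequence[float], d: float = 1.0) -> float:
    """Total WTA cell count N = d·Σ r_i for given per-module scale factors.

    With the no-ambiguity constraint saturated (λ_i/l_i = r_i) the
    per-module phase count is d·r_i, so the population sums to d·Σ r_i.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise InvalidGridError("at least one scale factor is required")
    if np.any(r <= 1):
        raise InvalidGridError("scale factors must exceed 1 (ambiguous code otherwise)")
    if d <= 0:
        raise ValueError("coverage d must be positive")
    return float(d * r.sum())


def wta_optimal_scale(dimension: int = 1) -> float:
    """Optimal adjacent-scale ratio e^(1/n) for the WTA decoder in n dimensions.

    The cost r^n/ln(r^n) is minimized where ln(r^n) = 1, i.e. r = e^(1/n):
    e ≈ 2.72 in 1D, √e ≈ 1.65 in 2D.
    """
    if not isinstance(dimension, (int, np.integer)) or dimension < 1:
        raise ValueError("dimension must be a positive integer")
    return math.e ** (1.0 / dimension)


def wta_relative_cost(r, dimension: int = 1):
    """Normalized WTA cost N_r/N_min = (x/ln x)/e with x = r^dimension.

    Independent of the resolution R and coverage d, which both cancel in
    the ratio.  Accepts scalars or arrays; r must exceed 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 1):
        raise ValueError("scale factor must exceed 1")
    x = r**dimension
    out = (x / np.log(x)) / math.e
    return float(out) if out.ndim == 0 else out


def wta_tolerance_interval(excess_fraction: float, dimension: int = 1) -> tuple:
    """Scale-factor interval within which the WTA cost exceeds its minimum
    by at most ``excess_fraction``.

    Solves (x/ln x)/e = 1 + excess on both branches of the unimodal cost
    by bisection (absolute tolerance 1e-6).  At 5% excess this gives
    (2.05, 3.85) in 1D and (1.43, 1.96) in 2D.
    """
    if excess_fraction < 0:
        raise ValueError("excess_fraction must be nonnegative")
    r_star = wta_optimal_scale(dimension)
    if excess_fraction == 0:
        return (r_star, r_star)
    target = 1.0 + excess_fraction

    def f(r):
        return wta_relative_cost(r, dimension) - target

    lo_bracket = 1.0 + 1e-6
    hi_bracket = 50.0
    while f(hi_bracket) < 0:  # extremely large excess
        hi_bracket *= 2
    r_lo = brentq(f, lo_bracket, r_star, xtol=1e-6)
    r_hi = brentq(f, r_star, hi_bracket, xtol=1e-6)
    return (float(r_lo), float(r_hi))


def wta_general_grid(constraint: ResolutionConstraint, d: float = 1.0) -> GridSystem:
    """Solve the general constrained WTA problem (1D) in closed form.

    All KKT constraints bind: λ_1 = L, λ_{i+1} = c2·l_i, c1·l_m = A, and
    the scale factor is common across modules.  The module count is the
    integer (floor or ceiling of ln(c1·L/A)) minimizing the total count
    N = d·c2·m·r with r = (c1·L/A)^(1/m); ties prefer fewer modules.
    """
    if d <= 0:
        raise ValueError("coverage d must be positive")
    z = constraint.c1 * constraint.L / constraint.A
    if z <= 1:
        raise InvalidGridError("resolution c1*L/A must exceed 1")
    lnz = math.log(z)

    def total(m):
        return d * constraint.c2 * m * z ** (1.0 / m)

    m_lo = max(1, math.floor(lnz))
    candidates = sorted({m_lo, m_lo + 1})
    m = min(candidates, key=lambda mm: (total(mm), mm))
    r = z ** (1.0 / m)

    periods = tuple(constraint.L * r ** (-i) for i in range(m))
    # λ_{i+1} = c2·l_i for i < m; the last width closes with c1·l_m = A
    widths = [periods[i + 1] / constraint.c2 for i in range(m - 1)]
    widths.append(constraint.A / constraint.c1)
    return GridSystem(
        dimension=1,
        periods=periods,
        field_widths=tuple(widths),
        coverage=d,
    )


def wta_integer_optimum(R: float, d: float = 1.0) -> tuple:
    """Integer-module WTA optimum: (m, r, N) minimizing N = d·m·R^(1/m).

    m·R^(1/m) is unimodal in m with continuous minimum at m = ln R, so the
    integer optimum is floor(ln R) or floor(ln R)+1 (tie → smaller m).
    As R → ∞ the resulting ratio r = R^(1/m) tends to e.
    """
    if R <= 1:
        raise ValueError("resolution R must exceed 1")
    if d <= 0:
        raise ValueError("coverage d must be positive")
    z = max(1, math.floor(math.log(R)))

    def total(m):
        return d * m * R ** (1.0 / m)

    m = min((z, z + 1), key=lambda mm: (total(mm), mm))
    r = R ** (1.0 / m)
    return (m, float(r), float(total(m)))


def wta_cost_curve(
    dimension: int = 1, r_min: float = 1.05, r_max: float = 5.0, n: int = 200
) -> CostCurve:
    """Tabulate the normalized WTA cost curve over [r_min, r_max]."""
    ratios = np.linspace(r_min, r_max, n)
    return CostCurve(ratios=ratios, relative_cost=wta_relative_cost(ratios, dimension), dimension=dimension)


def _numeric_optimal_scale(dimension: int) -> float:
    """Numeric cross-check of the closed-form optimum (used in tests/CLI)."""
    res = minimize_scalar(
        lambda r: wta_relative_cost(r, dimension),
        bounds=(1.0 + 1e-9, 50.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
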