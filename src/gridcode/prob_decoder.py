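"""Probabilistic (Bayesian) decoder model of a hierarchical grid code.

Each module i contributes a likelihood over position that is a periodic
sum of Gaussians of width σ_i spaced at the period λ_i.  Combining it with
the Gaussian posterior of width δ_{i-1} carried by all coarser modules
yields a Gaussian mixture whose weights, centers and common width have
closed forms; its standard deviation defines the per-module sharpening
factor ρ = δ_{i-1}/δ_i, a function of the two dimensionless ratios λ/σ
and σ/δ only.  At the symmetric optimum ρ equals the adjacent-scale
ratio, so optimizing the neuron-count objective

    N ∝ (λ/σ) / ln ρ_max(λ/σ)          (1D)
    N ∝ v_perp (λ/σ)^2 / ln ρ_max      (2D, unit-cell area factor)

predicts the optimal scale factor: ρ* ≈ 2.3 in one dimension and ≈ 1.44
in two dimensions, where the optimal response lattice is triangular.

All quantities are expressed in units of the likelihood peak width σ, in
which the model is fully specified by λ/σ and σ/δ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

__all__ = [
    "LatticeGeometry",
    "MixtureParams",
    "OptimizationResult",
    "mixture_posterior",
    "rho_1d",
    "rho_2d",
    "rho_max",
    "optimize_prob",
    "prob_relative_cost",
    "prob_tolerance_interval",
    "geometry_scan",
    "delta_oracle",
]

#: default lattice-sum truncation (1D index range [-K, K])
DEFAULT_K_1D = 500
#: default 2D truncation: |n|, |m| <= 60, with a boundary tail-mass check
DEFAULT_K_2D = 60

# boundary mixture weight must not exceed 1e-12 of the central weight
_LOG_TAIL = 2.0 * math.log(1e12)
_S_MIN, _S_MAX = 1e-3, 10.0


@dataclass(frozen=True)
class LatticeGeometry:
    """2D response-lattice geometry (v_par, v_perp).

    The lattice is generated by a unit vector u and a second vector v with
    components v_par along u and v_perp orthogonal to it.  Lattice symmetry
    reduces the canonical domain to v_par in [0, 1/2]; the triangular
    lattice is (1/2, sqrt(3)/2) and the square lattice (0, 1).
    """

    v_par: float
    v_perp: float

    def __post_init__(self):
        if self.v_perp <= 0:
            raise ValueError("v_perp must be positive (degenerate lattice otherwise)")

    @classmethod
    def triangular(cls) -> "LatticeGeometry":
        return cls(0.5, math.sqrt(3.0) / 2.0)

    @classmethod
    def square(cls) -> "LatticeGeometry":
        return cls(0.0, 1.0)

    def canonical(self) -> "LatticeGeometry":
        """Reduce v_par into [0, 1/2] using lattice relabeling symmetry."""
        vp = self.v_par % 1.0
        if vp > 0.5:
            vp = 1.0 - vp
        return LatticeGeometry(vp, abs(self.v_perp))

    def unit_cell_area(self) -> float:
        return abs(self.v_perp)


@dataclass(frozen=True)
class MixtureParams:
    """Gaussian-mixture posterior at one scale, in units of σ.

    weights[k] is π_n for n = k - K (so the central weight is weights[K]);
    centers are the peak locations μ_n = (Σ/σ)²·(λ/σ)·n and ``width`` the
    common peak width Σ/σ = (1 + (σ/δ)²)^(-1/2).  ``truncation_ok`` is
    False when the truncated tail carries non-negligible mass, flagging
    the result as truncation-suspect.
    """

    weights: np.ndarray
    centers: np.ndarray
    width: float
    K: int
    truncation_ok: bool

    @property
    def indices(self) -> np.ndarray:
        return np.arange(-self.K, self.K + 1)

    @property
    def second_moment_n(self) -> float:
        """Σ n² π_n, the ambiguity term of the variance recursion."""
        return float(np.sum(self.indices**2 * self.weights))


class RhoMaxResult(NamedTuple):
    rho: float
    sigma_over_delta: float
    at_boundary: bool


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of the nested scale-ratio optimization."""

    dimension: int
    r_opt: float
    lam_over_sigma: float
    sigma_over_delta: float
    geometry: Optional[LatticeGeometry] = None
    cost_curve: Optional[object] = None
    neurons_per_module_constant: float = 1.0


def _check_ratios(lam_over_sigma: float, sigma_over_delta: float) -> None:
    if lam_over_sigma <= 0 or sigma_over_delta <= 0:
        raise ValueError("lam_over_sigma and sigma_over_delta must be positive")


def mixture_posterior(
    lam_over_sigma: float, sigma_over_delta: float, K: int = DEFAULT_K_1D
) -> MixtureParams:
    """Mixture parameters of the combined posterior at one scale (1D).

    π_n ∝ exp(-n²λ²/(2(σ²+δ²))) over n in [-K, K], μ_n = (Σ/σ)²·λ·n and
    Σ² = (σ⁻² + δ⁻²)⁻¹, all in units of σ.
    """
    _check_ratios(lam_over_sigma, sigma_over_delta)
    if K < 1:
        raise ValueError("K must be at least 1")
    a, s = lam_over_sigma, sigma_over_delta
    n = np.arange(-K, K + 1)
    # σ² + δ² = σ²(1 + 1/s²) in units of σ
    log_w = -(n.astype(float) ** 2) * a**2 / (2.0 * (1.0 + 1.0 / s**2))
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    width_sq = 1.0 / (1.0 + s**2)  # (Σ/σ)²
    centers = width_sq * a * n
    trunc_ok = log_w[0] - log_w[K] < math.log(1e-12)
    return MixtureParams(
        weights=w, centers=centers, width=math.sqrt(width_sq), K=int(K), truncation_ok=bool(trunc_ok)
    )


def rho_1d(
    lam_over_sigma: float, sigma_over_delta: float, K: int = DEFAULT_K_1D
) -> float:
    """Posterior sharpening factor ρ = δ_{i-1}/δ_i for the 1D mixture.

    ρ = (1 + δ²/σ²)^(1/2) · (1 + (1+σ²/δ²)⁻¹ (λ/σ)² Σ n²π_n)^(-1/2);
    the first factor is the precision gain from the central peak, the
    second the penalty from side-lobe ambiguity.
    """
    mix = mixture_posterior(lam_over_sigma, sigma_over_delta, K)
    s = sigma_over_delta
    num = math.sqrt(1.0 + 1.0 / s**2)
    den = math.sqrt(1.0 + lam_over_sigma**2 * mix.second_moment_n / (1.0 + s**2))
    return num / den


@lru_cache(maxsize=64)
def _lattice_sq(v_par: float, v_perp: float, K: int):
    """Squared lengths |n·u + m·v|² of the truncated lattice, plus the
    smallest squared length on the truncation boundary (for tail checks)."""
    n, m = np.meshgrid(np.arange(-K, K + 1), np.arange(-K, K + 1), indexing="ij")
    q2 = (n + m * v_par) ** 2 + (m * v_perp) ** 2
    boundary = (np.abs(n) == K) | (np.abs(m) == K)
    return q2.ravel(), float(q2[boundary].min())


def _rho2_from_q2(a: float, s: float, q2: np.ndarray) -> float:
    log_w = -q2 * a**2 / (2.0 * (1.0 + 1.0 / s**2))
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    second = float(np.sum(q2 * w))
    num = math.sqrt(1.0 + 1.0 / s**2)
    den = math.sqrt(1.0 + 0.5 * a**2 * second / (1.0 + s**2))
    return num / den


def rho_2d(
    lam_over_sigma: float,
    sigma_over_delta: float,
    geometry: LatticeGeometry,
    K: int = DEFAULT_K_2D,
) -> float:
    """2D sharpening factor ρ₂ for a lattice-periodic likelihood.

    Weights π_{n,m} ∝ exp(-|n·u + m·v|²λ²/(2(σ²+δ²))); the variance is
    defined per spatial axis (δ² = ½⟨|x|²⟩), which puts a factor ½ on the
    lattice second moment.  Reduces to the single-peak closed form when
    all off-center weights vanish.
    """
    _check_ratios(lam_over_sigma, sigma_over_delta)
    geometry = geometry.canonical()
    q2, _ = _lattice_sq(geometry.v_par, geometry.v_perp, int(K))
    return _rho2_from_q2(lam_over_sigma, sigma_over_delta, q2)


def _s_floor(a: float, boundary_q2: float) -> float:
    """Smallest σ/δ for which the truncated lattice sum is trustworthy.

    Requires the boundary weight to be at most 1e-12 of the central one:
    exp(-q2_bdry·a²/(2(1+1/s²))) <= 1e-12.  Below this floor the truncated
    second moment saturates and ρ is spuriously inflated.
    """
    v = boundary_q2 * a**2 / _LOG_TAIL - 1.0
    if v <= 0:
        return math.inf
    return max(_S_MIN, 1.0 / math.sqrt(v))


def rho_max(
    lam_over_sigma: float,
    dimension: int = 1,
    geometry: Optional[LatticeGeometry] = None,
    K: Optional[int] = None,
) -> RhoMaxResult:
    """Maximize ρ over σ/δ at fixed λ/σ.

    Coarse log-spaced scan over the truncation-valid range of σ/δ followed
    by bounded scalar refinement (tolerance 1e-9 in log σ/δ).  The
    ``at_boundary`` flag marks optima pinned to the search bounds (e.g.
    the flat-objective λ/σ → ∞ limit, where σ/δ runs to its lower bound).
    """
    if lam_over_sigma <= 0:
        raise ValueError("lam_over_sigma must be positive")
    if dimension == 1:
        K = DEFAULT_K_1D if K is None else int(K)
        bq2 = float(K) ** 2

        def f(s):
            return rho_1d(lam_over_sigma, s, K)

    elif dimension == 2:
        K = DEFAULT_K_2D if K is None else int(K)
        geometry = (geometry or LatticeGeometry.triangular()).canonical()
        q2, bq2 = _lattice_sq(geometry.v_par, geometry.v_perp, K)

        def f(s):
            return _rho2_from_q2(lam_over_sigma, s, q2)

    else:
        raise ValueError("dimension must be 1 or 2")

    s_lo = _s_floor(lam_over_sigma, bq2)
    if not (s_lo < _S_MAX):
        raise ValueError(
            "truncated lattice sum cannot represent this lam_over_sigma; "
            "increase K or lam_over_sigma"
        )
    log_lo, log_hi = math.log(s_lo), math.log(_S_MAX)
    grid = np.linspace(log_lo, log_hi, 60)
    vals = np.array([f(math.exp(g)) for g in grid])
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda ls: -f(math.exp(ls)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    s_star = math.exp(res.x)
    at_boundary = k in (0, len(grid) - 1)
    return RhoMaxResult(rho=float(-res.fun), sigma_over_delta=float(s_star), at_boundary=at_boundary)


def _cost_1d(a: float, K: int) -> float:
    rm = rho_max(a, dimension=1, K=K)
    return a / math.log(rm.rho)


def _cost_2d_at_geometry(a: float, q2: np.ndarray, bq2: float, v_perp: float) -> float:
    s_lo = _s_floor(a, bq2)
    if not (s_lo < _S_MAX):
        return math.inf
    grid = np.linspace(math.log(s_lo), math.log(_S_MAX), 60)
    vals = [_rho2_from_q2(a, math.exp(g), q2) for g in grid]
    k = int(np.argmax(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda ls: -_rho2_from_q2(a, math.exp(ls), q2),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    rho = -res.fun
    if rho <= 1.0:
        return math.inf
    return v_perp * a**2 / math.log(rho)


def _min_cost_at_geometry(geometry: LatticeGeometry, K: int, xatol: float = 1e-6):
    """Minimize v_perp·(λ/σ)²/ln ρ_max over λ/σ at fixed geometry."""
    geometry = geometry.canonical()
    q2, bq2 = _lattice_sq(geometry.v_par, geometry.v_perp, K)
    res = minimize_scalar(
        lambda a: _cost_2d_at_geometry(a, q2, bq2, geometry.v_perp),
        bounds=(2.5, 20.0),
        method="bounded",
        options={"xatol": xatol},
    )
    return float(res.x), float(res.fun)


def optimize_prob(
    dimension: int = 1,
    geometry_mode: str = "free",
    K: Optional[int] = None,
    with_cost_curve: bool = False,
) -> OptimizationResult:
    """Nested optimization of the probabilistic-decoder neuron count.

    1D: minimizes (λ/σ)/ln ρ_max(λ/σ) over λ/σ in [2, 30]; the optimal
    scale ratio is ρ at the optimum (≈ 2.3, with λ* ≈ 9σ).

    2D: minimizes v_perp·(λ/σ)²/ln ρ₂,max over λ/σ and, when
    ``geometry_mode='free'``, the lattice geometry (coarse geometry scan
    then Nelder-Mead refinement); the optimum is the triangular lattice
    with r ≈ 1.44 and λ* ≈ 5.2σ.  ``geometry_mode`` may also be
    'triangular' or 'square' to fix the lattice.
    """
    if dimension == 1:
        K = DEFAULT_K_1D if K is None else int(K)
        res = minimize_scalar(
            lambda a: _cost_1d(a, K),
            bounds=(2.0, 30.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        a_star = float(res.x)
        rm = rho_max(a_star, dimension=1, K=K)
        curve = prob_cost_curve(1, K=K) if with_cost_curve else None
        return OptimizationResult(
            dimension=1,
            r_opt=rm.rho,
            lam_over_sigma=a_star,
            sigma_over_delta=rm.sigma_over_delta,
            cost_curve=curve,
        )

    if dimension != 2:
        raise ValueError("dimension must be 1 or 2")
    K = DEFAULT_K_2D if K is None else int(K)

    if geometry_mode in ("triangular", "fixed"):
        geom = LatticeGeometry.triangular()
    elif geometry_mode == "square":
        geom = LatticeGeometry.square()
    elif geometry_mode == "free":
        geom = None
    else:
        raise ValueError(f"unknown geometry_mode {geometry_mode!r}")

    if geom is not None:
        a_star, _ = _min_cost_at_geometry(geom, K)
        rm = rho_max(a_star, dimension=2, geometry=geom, K=K)
        curve = prob_cost_curve(2, K=K, geometry=geom) if with_cost_curve else None
        return OptimizationResult(
            dimension=2,
            r_opt=rm.rho,
            lam_over_sigma=a_star,
            sigma_over_delta=rm.sigma_over_delta,
            geometry=geom,
            cost_curve=curve,
        )

    # free geometry: coarse scan over the canonical domain, then refine
    best = None
    for vpar in (0.0, 0.25, 0.5):
        for vperp in (0.7, math.sqrt(3.0) / 2.0, 1.0):
            g = LatticeGeometry(vpar, vperp)
            a, c = _min_cost_at_geometry(g, K, xatol=1e-3)
            if best is None or c < best[0]:
                best = (c, a, g)

    _, a0, g0 = best

    def objective(p):
        a, vpar, vperp = p
        if not (2.5 <= a <= 25.0) or not (0.3 <= vperp <= 3.0):
            return math.inf
        g = LatticeGeometry(vpar, vperp).canonical()
        q2, bq2 = _lattice_sq(g.v_par, g.v_perp, K)
        return _cost_2d_at_geometry(a, q2, bq2, g.v_perp)

    res = minimize(
        objective,
        x0=[a0, g0.v_par, g0.v_perp],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
    )
    if not res.success and res.status != 2:  # status 2: maxiter, still usable
        raise RuntimeError(f"2D geometry optimization failed: {res.message}")
    a_star = float(res.x[0])
    geom = LatticeGeometry(float(res.x[1]), float(res.x[2])).canonical()
    rm = rho_max(a_star, dimension=2, geometry=geom, K=K)
    curve = prob_cost_curve(2, K=K, geometry=geom) if with_cost_curve else None
    return OptimizationResult(
        dimension=2,
        r_opt=rm.rho,
        lam_over_sigma=a_star,
        sigma_over_delta=rm.sigma_over_delta,
        geometry=geom,
        cost_curve=curve,
    )


@lru_cache(maxsize=16)
def _cost_model(dimension: int, K: Optional[int], geom_key: Optional[tuple]):
    """Precompute the pieces needed to evaluate the normalized cost curve."""
    geometry = LatticeGeometry(*geom_key) if geom_key else None
    if dimension == 1:
        Kv = DEFAULT_K_1D if K is None else int(K)
        opt = optimize_prob(1, K=Kv)

        def numerator(a):
            return a

        def rho_of_a(a):
            return rho_max(a, dimension=1, K=Kv).rho

        a_lo, a_hi = 2.0, 60.0
    elif dimension == 2:
        Kv = DEFAULT_K_2D if K is None else int(K)
        geometry = geometry or LatticeGeometry.triangular()
        opt = optimize_prob(2, geometry_mode="fixed", K=Kv) if geom_key is None else None
        if opt is None:
            a_star, _ = _min_cost_at_geometry(geometry, Kv)
            rm = rho_max(a_star, dimension=2, geometry=geometry, K=Kv)
            opt = OptimizationResult(
                dimension=2,
                r_opt=rm.rho,
                lam_over_sigma=a_star,
                sigma_over_delta=rm.sigma_over_delta,
                geometry=geometry,
            )

        def numerator(a):
            return geometry.v_perp * a**2

        def rho_of_a(a):
            return rho_max(a, dimension=2, geometry=geometry, K=Kv).rho

        a_lo, a_hi = 1.8, 60.0
    else:
        raise ValueError("dimension must be 1 or 2")

    c_min = numerator(opt.lam_over_sigma) / math.log(opt.r_opt)
    return opt, numerator, rho_of_a, a_lo, a_hi, c_min


def _geom_key(geometry: Optional[LatticeGeometry]):
    if geometry is None:
        return None
    g = geometry.canonical()
    return (round(g.v_par, 12), round(g.v_perp, 12))


def prob_relative_cost(
    r: float,
    dimension: int = 1,
    K: Optional[int] = None,
    geometry: Optional[LatticeGeometry] = None,
) -> float:
    """Normalized neuron count N_r/N_min at scale ratio r (probabilistic).

    Inverts the monotone map λ/σ → ρ_max (at the optimal geometry in 2D,
    unless one is given) to find the smallest λ/σ achieving ρ = r, then
    evaluates the cost normalized by its minimum.  Independent of the
    resolution R, which cancels in the ratio.
    """
    opt, numerator, rho_of_a, a_lo, a_hi, c_min = _cost_model(
        dimension, K, _geom_key(geometry)
    )
    if r <= 1.0:
        raise ValueError("scale ratio must exceed 1")
    r_min_reach = rho_of_a(a_lo)
    r_max_reach = rho_of_a(a_hi)
    if not (r_min_reach < r < r_max_reach):
        raise ValueError(
            f"scale ratio {r} outside the achievable range "
            f"({r_min_reach:.4f}, {r_max_reach:.4f})"
        )
    a = brentq(lambda aa: rho_of_a(aa) - r, a_lo, a_hi, xtol=1e-10)
    return (numerator(a) / math.log(r)) / c_min


def prob_tolerance_interval(
    excess_fraction: float,
    dimension: int = 2,
    K: Optional[int] = None,
    geometry: Optional[LatticeGeometry] = None,
) -> tuple:
    """Scale-ratio interval where the probabilistic cost is within
    ``excess_fraction`` of its minimum (e.g. (1.28, 1.66) at 5% in 2D)."""
    if excess_fraction < 0:
        raise ValueError("excess_fraction must be nonnegative")
    opt, numerator, rho_of_a, a_lo, a_hi, c_min = _cost_model(
        dimension, K, _geom_key(geometry)
    )
    r_star = opt.r_opt
    if excess_fraction == 0:
        return (r_star, r_star)
    target = 1.0 + excess_fraction

    def f(r):
        return prob_relative_cost(r, dimension, K, geometry) - target

    lo_lim = rho_of_a(a_lo) * (1 + 1e-9) + 1e-12
    hi_lim = rho_of_a(a_hi) * (1 - 1e-9)
    r_lo = brentq(f, max(lo_lim, 1.0 + 1e-9), r_star, xtol=1e-9)
    r_hi = brentq(f, r_star, hi_lim, xtol=1e-9)
    return (float(r_lo), float(r_hi))


def prob_cost_curve(
    dimension: int = 1,
    r_values=None,
    K: Optional[int] = None,
    geometry: Optional[LatticeGeometry] = None,
):
    """Tabulate the normalized probabilistic cost curve."""
    from gridcode.wta_optimizer import CostCurve

    opt, *_ = _cost_model(dimension, K, _geom_key(geometry))
    if r_values is None:
        r_values = np.linspace(opt.r_opt * 0.75, opt.r_opt * 1.5, 40)
    costs = np.array(
        [prob_relative_cost(float(r), dimension, K, geometry) for r in r_values]
    )
    return CostCurve(ratios=np.asarray(r_values, float), relative_cost=costs, dimension=dimension)


def geometry_scan(v_par_grid, v_perp_grid, K: int = DEFAULT_K_2D):
    """Normalized neuron count over lattice geometries, minimized over λ/σ.

    Returns a DataFrame with columns (v_par, v_perp, relative_cost), where
    cost is min_a v_perp·a²/ln ρ₂,max normalized by the grid minimum.  The
    global minimum sits at the triangular lattice (1/2, √3/2).
    """
    import pandas as pd

    rows = []
    for vpar in np.asarray(v_par_grid, float):
        for vperp in np.asarray(v_perp_grid, float):
            _, c = _min_cost_at_geometry(LatticeGeometry(float(vpar), float(vperp)), K, xatol=1e-4)
            rows.append((float(vpar), float(vperp), c))
    df = pd.DataFrame(rows, columns=["v_par", "v_perp", "relative_cost"])
    df["relative_cost"] /= df["relative_cost"].min()
    return df


def delta_oracle(
    lam: float,
    sigma: float,
    delta_prev: float,
    grid_halfwidth: Optional[float] = None,
    grid_step: Optional[float] = None,
) -> float:
    """Posterior width by direct quadrature (independent of the ρ formulas).

    Multiplies the periodic sum-of-Gaussians likelihood (peaks at nλ,
    width σ) by a Gaussian prior of width delta_prev centered at the true
    position (0), normalizes numerically, and returns the standard
    deviation of the product density.  Raises if the grid leaves
    non-negligible tail mass (> 1e-10) outside its support.
    """
    if lam <= 0 or sigma <= 0 or delta_prev <= 0:
        raise ValueError("lam, sigma, delta_prev must be positive")
    if grid_halfwidth is None:
        grid_halfwidth = 10.0 * delta_prev
    if grid_step is None:
        grid_step = sigma / 30.0
    if grid_step > sigma / 20.0:
        raise ValueError("grid_step must be at most sigma/20 to resolve the peaks")
    x = np.arange(-grid_halfwidth, grid_halfwidth + grid_step / 2, grid_step)
    n_max = int(math.ceil(grid_halfwidth / lam)) + 2
    n = np.arange(-n_max, n_max + 1)
    # likelihood: periodic Gaussian bumps; prior: Gaussian at 0
    like = np.exp(-((x[:, None] - n[None, :] * lam) ** 2) / (2 * sigma**2)).sum(axis=1)
    prior = np.exp(-(x**2) / (2 * delta_prev**2))
    q = like * prior
    total = np.trapezoid(q, x)
    if total <= 0:
        raise ValueError("degenerate density on the grid")
    edge_mass = (q[0] + q[-1]) * grid_step / total
    if edge_mass > 1e-10:
        raise ValueError("grid too narrow: tail mass exceeds 1e-10")
    q = q / total
    mean = np.trapezoid(x * q, x)
    var = np.trapezoid((x - mean) ** 2 * q, x)
    return float(math.sqrt(var))
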