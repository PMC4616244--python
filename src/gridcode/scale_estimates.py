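"""Order-of-magnitude estimates for the rodent grid system.

Given a behavioral resolution R (range² / accuracy² in 2D) and a scale
ratio r, the module count follows from R = (r^n)^m, and the total neuron
count from N = m·c·(λ/σ)² with c inversely proportional to the expected
spike count per sampling window.  For R₂ = 10⁴, r = √e and K ≈ 1/5 spikes
these give m ≈ 10 modules and N ≈ 1400 grid cells.
"""

from __future__ import annotations

import math

from scipy.optimize import minimize_scalar

__all__ = [
    "module_count_estimate",
    "neuron_count_estimate",
    "base_complexity",
    "optimal_base",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def module_count_estimate(R: float, r: float, dimension: int = 2) -> tuple:
    """Modules needed for resolution R at scale ratio r: m = ln R / ln r^n.

    Returns (real value, ceiling).  R = 10⁴ with r = √e in 2D gives 9.21,
    i.e. on the order of 10 modules.
    """
    if R <= 1:
        raise ValueError("resolution R must exceed 1")
    if r <= 1:
        raise ValueError("scale ratio r must exceed 1")
    if dimension < 1:
        raise ValueError("dimension must be a positive integer")
    m = math.log(R) / math.log(r**dimension)
    return (m, math.ceil(m))


def neuron_count_estimate(m: float, K_spikes: float, lam_over_sigma: float) -> float:
    """Total neuron count N = m·(1/K)·(λ/σ)² for independent Poisson cells.

    K_spikes is the expected spike count per sampling window; the
    per-module constant c = 1/K_spikes reflects that single-cell
    positional information scales with the number of emitted spikes.
    """
    if m <= 0 or lam_over_sigma <= 0:
        raise ValueError("m and lam_over_sigma must be positive")
    if K_spikes <= 0:
        raise ValueError("K_spikes must be positive")
    return m * (1.0 / K_spikes) * lam_over_sigma**2


def base_complexity(b: float, R: float) -> float:
    """Cost C = b·ln R/ln b of a base-b positional representation.

    A base-b code for R distinguishable values needs log_b R digits with
    b states each; the neuron count is proportional to their product.
    """
    if b <= 1:
        raise ValueError("base must exceed 1")
    if R <= 1:
        raise ValueError("range R must exceed 1")
    return b * math.log(R) / math.log(b)


def optimal_base() -> float:
    """The base minimizing b·ln R/ln b, which is e for every R.

    Cross-checked by numeric minimization of b/ln b; raises if the numeric
    argmin strays from e by more than 1e-6.
    """
    res = minimize_scalar(
        lambda b: b / math.log(b), bounds=(1.0 + 1e-9, 20.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if abs(res.x - math.e) > 1e-6:
        raise RuntimeError(f"numeric argmin {res.x} disagrees with e")
    return math.e
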