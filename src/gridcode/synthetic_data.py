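"""Synthetic grid-cell data with the statistical structure the theory assumes.

Two generators:

* noisy geometric period tables (per-animal module periods with
  multiplicative lognormal noise and missing modules), exercising the
  reanalysis pipeline with a known ground-truth ratio;

* multi-module populations of Poisson-spiking grid cells with periodic
  Gaussian tuning and uniformly tiled phases on a 1D circular track,
  for Monte-Carlo validation of the probabilistic decoder — simulated
  spike counts, per-module likelihoods and fitted peak widths, and
  end-to-end decode error versus the analytic δ-recursion.

Positions live on a circle of circumference λ_1 (no edge effects).  So
that every module is exactly periodic on the circle, periods are snapped
to λ_1/k with integer k nearest the requested geometric progression; the
realized periods are recorded on the model and used in all comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gridcode.prob_decoder import rho_1d

__all__ = [
    "Module",
    "PopulationModel",
    "ModulePosterior",
    "generate_period_table",
    "build_population",
    "simulate_spike_counts",
    "module_posterior",
    "monte_carlo_resolution",
    "predicted_sigma",
    "predicted_posterior_sd",
]

FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # field width in tuning-sd units


def generate_period_table(
    n_animals: int,
    m: int = 4,
    r: float = 1.65,
    noise_cv: float = 0.05,
    missing_prob: float = 0.0,
    lam1: float = 100.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-animal grid periods: geometric progression with noise and dropout.

    Animal a gets periods λ_1·r^(-i)·ε_i (i = 0..m-1, ε lognormal with
    log-sd ``noise_cv``), each module independently missing with
    probability ``missing_prob``.  Columns: animal_id, period_cm.
    Deterministic under a fixed seed.
    """
    if r <= 1:
        raise ValueError("ratio r must exceed 1")
    if not 0 <= noise_cv < 0.2:
        raise ValueError("noise_cv must lie in [0, 0.2)")
    if not 0 <= missing_prob < 1:
        raise ValueError("missing_prob must lie in [0, 1)")
    if n_animals < 1 or m < 1:
        raise ValueError("n_animals and m must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        for i in range(m):
            if rng.random() < missing_prob:
                continue
            eps = math.exp(rng.normal(0.0, noise_cv)) if noise_cv > 0 else 1.0
            rows.append((f"animal{a:03d}", lam1 * r ** (-i) * eps))
    return pd.DataFrame(rows, columns=["animal_id", "period_cm"])


@dataclass(frozen=True)
class Module:
    """One grid module: period, tuning width, and cell phases in [0, λ)."""

    period: float
    tuning_sd: float
    phases: np.ndarray
    n_fields: int  # fields per cell on the circle (= circumference/period)

    @property
    def field_width(self) -> float:
        """Full width at half maximum of a tuning bump."""
        return FWHM * self.tuning_sd


@dataclass(frozen=True)
class PopulationModel:
    """Multi-module population of Poisson grid cells on a circular track."""

    modules: tuple
    peak_rate: float
    T_sample: float
    circumference: float
    dimension: int = 1
    phase_mode: str = "even"
    seed: Optional[int] = None

    @property
    def n_cells(self) -> int:
        return sum(len(mod.phases) for mod in self.modules)

    @property
    def periods(self) -> np.ndarray:
        return np.array([mod.period for mod in self.modules])

    @property
    def expected_spikes_at_peak(self) -> float:
        """Expected spike count of a cell at its field center in one sample."""
        return self.peak_rate * self.T_sample

    def module_rates(self, module_index: int, x) -> np.ndarray:
        """Firing rates (cells × positions) of one module at positions x."""
        mod = self.modules[module_index]
        x = np.atleast_1d(np.asarray(x, dtype=float))
        # circular distance from each phase-shifted field center
        centers = (
            mod.phases[:, None, None]
            + mod.period * np.arange(mod.n_fields)[None, :, None]
        )
        d = (x[None, None, :] - centers) % self.circumference
        d = np.where(d > self.circumference / 2, d - self.circumference, d)
        return self.peak_rate * np.exp(-(d**2) / (2 * mod.tuning_sd**2)).sum(axis=1)

    def realized_coverage(self, module_index: int, n_eval: int = 8192) -> float:
        """Mean number of cells whose nearest field center lies within half
        a field width (FWHM/2) of a point; compare with the analytic
        n_phases·FWHM·sd/λ."""
        mod = self.modules[module_index]
        x = np.linspace(0, self.circumference, n_eval, endpoint=False)
        centers = (
            mod.phases[:, None, None]
            + mod.period * np.arange(mod.n_fields)[None, :, None]
        )
        d = (x[None, None, :] - centers) % self.circumference
        d = np.where(d > self.circumference / 2, d - self.circumference, d)
        near = (np.abs(d).min(axis=1) <= mod.field_width / 2).sum(axis=0)
        return float(near.mean())


def build_population(
    m: int,
    r: float,
    lam1: float = 100.0,
    n_phases_per_module: int = 32,
    tuning_sd_frac: float = 0.08,
    peak_rate: float = 10.0,
    T_sample: float = 0.1,
    dimension: int = 1,
    seed: Optional[int] = None,
    phase_mode: str = "even",
) -> PopulationModel:
    """Construct a multi-module population with geometric periods.

    Module i targets period λ_1·r^(1-i); periods are snapped to an integer
    number of fields on the circle of circumference λ_1 (exact
    periodicity).  Phases tile the period evenly ('even') or uniformly at
    random ('random', seeded).  tuning_sd = tuning_sd_frac·period.
    """
    if dimension != 1:
        raise NotImplementedError(
            "spiking simulation is implemented on a 1D circular track"
        )
    if m < 1 or r <= 1 or lam1 <= 0:
        raise ValueError("m >= 1, r > 1 and lam1 > 0 required")
    if n_phases_per_module < 8:
        raise ValueError("need at least 8 phases per module for coverage")
    if not 0 < tuning_sd_frac < 0.3:
        raise ValueError("tuning_sd_frac must lie in (0, 0.3)")
    rng = np.random.default_rng(seed)
    modules = []
    prev_k = 0
    for i in range(m):
        target = lam1 * r ** (-i)
        k = max(prev_k + 1, int(round(lam1 / target)))
        prev_k = k
        period = lam1 / k
        sd = tuning_sd_frac * period
        if phase_mode == "even":
            phases = (np.arange(n_phases_per_module) + 0.5) * period / n_phases_per_module
        elif phase_mode == "random":
            phases = rng.uniform(0, period, n_phases_per_module)
        else:
            raise ValueError(f"unknown phase_mode {phase_mode!r}")
        modules.append(Module(period=period, tuning_sd=sd, phases=phases, n_fields=k))
    return PopulationModel(
        modules=tuple(modules),
        peak_rate=peak_rate,
        T_sample=T_sample,
        circumference=lam1,
        dimension=dimension,
        phase_mode=phase_mode,
        seed=seed,
    )


def simulate_spike_counts(
    population: PopulationModel, x_true: float, seed=None
) -> list:
    """Poisson spike counts per cell at position x_true, one list per module.

    ``seed`` may be an int or a numpy Generator (for streaming trials).
    """
    if not 0 <= x_true < population.circumference:
        raise ValueError("x_true must lie in [0, circumference)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = []
    for i in range(len(population.modules)):
        rates = population.module_rates(i, x_true)[:, 0]
        counts.append(rng.poisson(rates * population.T_sample))
    return counts


@dataclass(frozen=True)
class ModulePosterior:
    """Normalized single-module likelihood over the position grid."""

    x_grid: np.ndarray
    density: np.ndarray
    log_likelihood: np.ndarray
    sigma_hat: Optional[float]
    flat: bool


def _circular_moments(x: np.ndarray, p: np.ndarray, C: float):
    theta = 2 * math.pi * x / C
    z = np.sum(p * np.exp(1j * theta))
    mean = (np.angle(z) % (2 * math.pi)) * C / (2 * math.pi)
    d = (x - mean) % C
    d = np.where(d > C / 2, d - C, d)
    sd = math.sqrt(float(np.sum(p * d**2)))
    return mean, sd


def module_posterior(
    counts: Sequence[int],
    population: PopulationModel,
    module_index: int,
    x_grid: Optional[np.ndarray] = None,
) -> ModulePosterior:
    """Exact Poisson likelihood of position from one module's spike counts.

    The density over the circular grid is periodic with the module period;
    sigma_hat is the circular standard deviation of the central peak
    (mass within half a period of the argmax), verifying the
    Gaussian-bump approximation of the likelihood.
    """
    mod = population.modules[module_index]
    if x_grid is None:
        step = mod.tuning_sd / 10.0
        x_grid = np.arange(0, population.circumference, step)
    counts = np.asarray(counts[module_index] if isinstance(counts, list) else counts)
    rates = population.module_rates(module_index, x_grid)
    with np.errstate(divide="ignore"):
        log_rates = np.log(np.maximum(rates, 1e-300))
    loglik = counts @ log_rates - population.T_sample * rates.sum(axis=0)
    if counts.sum() == 0:
        dens = np.full_like(x_grid, 1.0 / len(x_grid))
        return ModulePosterior(x_grid, dens, loglik, None, True)
    dens = np.exp(loglik - loglik.max())
    dens /= dens.sum()
    # isolate the central peak: mass within half a period of the argmax
    x_peak = x_grid[np.argmax(dens)]
    d = (x_grid - x_peak) % population.circumference
    d = np.where(d > population.circumference / 2, d - population.circumference, d)
    win = np.abs(d) <= mod.period / 2
    p = dens[win] / dens[win].sum()
    _, sd = _circular_moments(x_grid[win], p, population.circumference)
    return ModulePosterior(x_grid, dens, loglik, float(sd), False)


def predicted_sigma(population: PopulationModel, module_index: int) -> float:
    """Analytic likelihood peak width from Fisher information.

    For independent Poisson cells with Gaussian bumps of width w and peak
    rate R0 at phase density n_phases/λ, the Fisher information at any
    position is I = T·(n_phases/λ)·R0·√(2π)/w, so σ = I^(-1/2).  Only
    nearby fields are informative, hence the density rather than the
    total cell count enters.
    """
    mod = population.modules[module_index]
    density = len(mod.phases) / mod.period
    info = (
        population.T_sample
        * density
        * population.peak_rate
        * math.sqrt(2 * math.pi)
        / mod.tuning_sd
    )
    return 1.0 / math.sqrt(info)


def predicted_posterior_sd(population: PopulationModel) -> float:
    """Analytic combined-posterior width via the δ-recursion.

    Starts from the uniform prior on the circle (δ_0 = C/√12) and applies
    δ_i = δ_{i-1}/ρ(λ_i/σ_i, σ_i/δ_{i-1}) with the analytic per-module σ.
    """
    delta = population.circumference / math.sqrt(12.0)
    for i, mod in enumerate(population.modules):
        sigma = predicted_sigma(population, i)
        delta = delta / rho_1d(mod.period / sigma, sigma / delta)
    return delta


def monte_carlo_resolution(
    population: PopulationModel,
    n_trials: int = 500,
    seed: Optional[int] = None,
    grid_step: Optional[float] = None,
) -> dict:
    """End-to-end Monte-Carlo decode: empirical posterior sd and RMSE.

    Draws positions uniformly on the circle, simulates Poisson spike
    counts, forms the full-population posterior (product of module
    likelihoods with a uniform prior), and decodes by circular posterior
    mean.  Returns empirical posterior sd, decode RMSE (circular), their
    Monte-Carlo standard errors, and the per-trial errors.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    finest = population.modules[-1]
    if grid_step is None:
        grid_step = finest.tuning_sd / 8.0
    x_grid = np.arange(0, population.circumference, grid_step)
    log_rates, rate_sums = [], []
    for i in range(len(population.modules)):
        rates = population.module_rates(i, x_grid)
        with np.errstate(divide="ignore"):
            log_rates.append(np.log(np.maximum(rates, 1e-300)))
        rate_sums.append(rates.sum(axis=0))
    errors = np.empty(n_trials)
    post_sds = np.empty(n_trials)
    for t in range(n_trials):
        x_true = rng.uniform(0, population.circumference)
        counts = simulate_spike_counts(population, x_true, rng)
        loglik = np.zeros_like(x_grid)
        for i in range(len(population.modules)):
            loglik += counts[i] @ log_rates[i] - population.T_sample * rate_sums[i]
        dens = np.exp(loglik - loglik.max())
        dens /= dens.sum()
        x_hat, sd = _circular_moments(x_grid, dens, population.circumference)
        d = (x_hat - x_true) % population.circumference
        if d > population.circumference / 2:
            d -= population.circumference
        errors[t] = d
        post_sds[t] = sd
    rmse = float(np.sqrt(np.mean(errors**2)))
    return {
        "posterior_sd": float(post_sds.mean()),
        "posterior_sd_se": float(post_sds.std(ddof=1) / math.sqrt(n_trials)),
        "rmse": rmse,
        "rmse_se": float(np.std(errors**2, ddof=1) / (2 * rmse * math.sqrt(n_trials))),
        "errors": errors,
        "n_trials": n_trials,
        "seed": seed,
        "predicted_posterior_sd": predicted_posterior_sd(population),
    }
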