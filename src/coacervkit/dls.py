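"""DLS forward simulation and CONTIN-style regularized inversion.

Forward model: for an intensity-weighted distribution w over hydrodynamic
radii R_H, the field autocorrelation is the Laplace-like sum
g1(tau) = sum_i w_i exp(-D_i q^2 tau) with D_i from Stokes-Einstein, and
the measured intensity autocorrelation follows the Siegert relation
g2 - 1 = beta g1^2.

Inversion: recovering w from g1 is a classically ill-posed inverse Laplace
problem.  We solve non-negative least squares with a second-difference
(curvature) Tikhonov penalty,

    min_{w >= 0} ||A w - g1||^2 + alpha^2 ||L w||^2,

on a log-spaced R_H grid — the same constrained-regularization strategy as
CONTIN.  alpha defaults to an L-curve corner pick over a log grid, with
manual override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .constants import (
    BOLTZMANN,
    ROOM_TEMPERATURE,
    WATER_REFRACTIVE_INDEX,
    WATER_VISCOSITY,
)


@dataclass(frozen=True)
class DLSInstrument:
    """Scattering geometry and solvent conditions."""

    wavelength_nm: float = 632.8  # vacuum wavelength
    scattering_angle_deg: float = 90.0
    refractive_index: float = WATER_REFRACTIVE_INDEX
    temperature: float = ROOM_TEMPERATURE  # K
    viscosity: float = WATER_VISCOSITY  # Pa s

    def __post_init__(self) -> None:
        if not (0.0 < self.scattering_angle_deg < 180.0):
            raise ValueError("scattering angle must be in (0, 180) degrees")
        for name in ("wavelength_nm", "refractive_index", "temperature", "viscosity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Correlogram:
    """Intensity autocorrelation trace g2(tau) - 1."""

    lag_times: np.ndarray  # s, strictly increasing
    g2_minus_1: np.ndarray
    beta: float = 1.0  # coherence factor

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.g2_minus_1 = np.asarray(self.g2_minus_1, dtype=float)
        if self.lag_times.shape != self.g2_minus_1.shape:
            raise ValueError("lag_times and g2_minus_1 must have equal length")
        if np.any(self.lag_times <= 0) or np.any(np.diff(self.lag_times) <= 0):
            raise ValueError("lag times must be positive and strictly increasing")
        if self.beta <= 0:
            raise ValueError("coherence factor beta must be positive")


@dataclass
class SizeDistribution:
    """Intensity-weighted distribution over a hydrodynamic-radius grid (nm)."""

    rh_nm: np.ndarray  # log-spaced grid
    weights: np.ndarray  # non-negative, sum 1

    def __post_init__(self) -> None:
        self.rh_nm = np.asarray(self.rh_nm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.rh_nm.shape != self.weights.shape:
            raise ValueError("grid and weights must have equal length")
        if np.any(self.rh_nm <= 0):
            raise ValueError("R_H grid must be positive")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        total = float(self.weights.sum())
        if total <= 0:
            raise ValueError("weights must have positive sum")
        if abs(total - 1.0) > 1e-9:
            self.weights = self.weights / total

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"Rh_nm": self.rh_nm, "weight": self.weights}).to_csv(
            path, index=False
        )


def default_rh_grid(rh_min_nm: float = 1.0, rh_max_nm: float = 1e4, n: int = 60) -> np.ndarray:
    """Log-spaced hydrodynamic-radius grid in nm (default 1 nm - 10 um)."""
    return np.logspace(math.log10(rh_min_nm), math.log10(rh_max_nm), n)


def scattering_vector(inst: DLSInstrument) -> float:
    """Magnitude of the scattering vector q = 4 pi n sin(theta/2) / lambda, 1/m."""
    theta = math.radians(inst.scattering_angle_deg)
    return (
        4.0
        * math.pi
        * inst.refractive_index
        * math.sin(theta / 2.0)
        / (inst.wavelength_nm * 1e-9)
    )


def diffusion_coefficient(
    rh_m: float, temperature: float = ROOM_TEMPERATURE, viscosity: float = WATER_VISCOSITY
):
    """Stokes-Einstein translational diffusion coefficient, m^2/s."""
    rh_m = np.asarray(rh_m, dtype=float)
    if np.any(rh_m <= 0):
        raise ValueError("hydrodynamic radius must be positive")
    d = BOLTZMANN * temperature / (6.0 * math.pi * viscosity * rh_m)
    return float(d) if d.ndim == 0 else d


def _kernel(tau: np.ndarray, rh_nm: np.ndarray, inst: DLSInstrument) -> np.ndarray:
    q = scattering_vector(inst)
    d = diffusion_coefficient(rh_nm * 1e-9, inst.temperature, inst.viscosity)
    return np.exp(-np.outer(tau, d * q**2))


def simulate_g2(
    dist: SizeDistribution,
    inst: DLSInstrument | None = None,
    beta: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    lag_times: np.ndarray | None = None,
) -> Correlogram:
    """Simulate g2 - 1 for a size distribution via the Siegert relation.

    Additive Gaussian noise of standard deviation noise_sd, seeded.
    """
    if dist.rh_nm.size == 0:
        raise ValueError("distribution is empty")
    inst = inst or DLSInstrument()
    if lag_times is None:
        lag_times = np.logspace(-7, 1, 200)
    g1 = _kernel(lag_times, dist.rh_nm, inst) @ dist.weights
    g2m1 = beta * g1**2
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        g2m1 = g2m1 + rng.normal(0.0, noise_sd, size=g2m1.shape)
    return Correlogram(lag_times=lag_times, g2_minus_1=g2m1, beta=beta)


def _second_difference(n: int) -> np.ndarray:
    l = np.zeros((n - 2, n))
    for i in range(n - 2):
        l[i, i : i + 3] = (1.0, -2.0, 1.0)
    return l


#: Weight floor: baseline points (g1 ~ 0) keep a small but non-zero weight.
_WEIGHT_FLOOR = 0.05
#: Auto-alpha: largest alpha whose weighted residual is within this relative
#: margin of the best achievable residual (discrepancy-style rule).
_AUTO_ALPHA_TOL = 0.002
_AUTO_ALPHA_GRID = np.logspace(-4, 1, 21)


def _solve_regularized(
    a: np.ndarray, g1: np.ndarray, alpha: float, weights: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Weighted NNLS with second-difference penalty; returns (w, residual)."""
    n = a.shape[1]
    wt = np.ones_like(g1) if weights is None else weights
    aw = a * wt[:, None]
    bw = g1 * wt
    if alpha > 0:
        l = _second_difference(n)
        a_aug = np.vstack([aw, alpha * l])
        b_aug = np.concatenate([bw, np.zeros(l.shape[0])])
    else:
        a_aug, b_aug = aw, bw
    w, _ = nnls(a_aug, b_aug)
    return w, float(np.linalg.norm(aw @ w - bw))


def _auto_alpha(a: np.ndarray, g1: np.ndarray, weights: np.ndarray) -> float:
    """Largest alpha on a log grid whose residual stays within a small
    relative margin of the minimum achievable (smoothest solution the data
    permit).  The residual-vs-alpha curve here is flat until regularization
    starts to bite, so this corner-free rule is robust."""
    rhos = np.array(
        [_solve_regularized(a, g1, al, weights)[1] for al in _AUTO_ALPHA_GRID]
    )
    ok = np.where(rhos <= (1.0 + _AUTO_ALPHA_TOL) * rhos.min())[0]
    return float(_AUTO_ALPHA_GRID[ok.max()])


def invert_g2(
    c: Correlogram,
    inst: DLSInstrument | None = None,
    rh_grid_nm: np.ndarray | None = None,
    alpha: float | str = "auto",
) -> SizeDistribution:
    """Regularized non-negative inversion of a correlogram.

    Returns the normalized intensity-weighted distribution on the grid.
    Residuals are precision-weighted: additive noise on g2 - 1 propagates
    to g1 with standard deviation proportional to 1/|g1|, so each lag is
    weighted by |g1| (floored), which keeps the noise-only baseline from
    feeding spurious slow modes.  alpha='auto' picks the largest
    regularization weight whose residual matches the minimum achievable
    within a small margin; a numeric alpha (>= 0) is used as given.
    Deterministic.
    """
    inst = inst or DLSInstrument()
    if rh_grid_nm is None:
        rh_grid_nm = default_rh_grid()
    rh_grid_nm = np.asarray(rh_grid_nm, dtype=float)
    # signed sqrt keeps baseline noise zero-mean instead of rectifying it
    # into a spurious slow tail
    scaled = c.g2_minus_1 / c.beta
    g1 = np.sign(scaled) * np.sqrt(np.abs(scaled))
    weights = np.maximum(np.abs(g1), _WEIGHT_FLOOR)
    a = _kernel(c.lag_times, rh_grid_nm, inst)
    if isinstance(alpha, str):
        if alpha != "auto":
            raise ValueError("alpha must be a number or 'auto'")
        alpha_val = _auto_alpha(a, g1, weights)
    else:
        alpha_val = float(alpha)
        if alpha_val < 0:
            raise ValueError("alpha must be non-negative")
    w, _ = _solve_regularized(a, g1, alpha_val, weights)
    if w.sum() <= 0:
        raise RuntimeError("inversion produced an empty distribution")
    return SizeDistribution(rh_nm=rh_grid_nm, weights=w / w.sum())


def intensity_weighted_mean_diameter(dist: SizeDistribution) -> float:
    """Intensity-weighted mean diameter in nm: 2 sum_i w_i R_H,i."""
    return float(2.0 * np.sum(dist.weights * dist.rh_nm))


def read_correlogram(path: str | Path, beta: float = 1.0) -> Correlogram:
    """Read a 2-column ASCII correlogram (tau s, g2 - 1); '#' comments."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: fewer than 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    arr = arr[np.argsort(arr[:, 0])]
    return Correlogram(lag_times=arr[:, 0], g2_minus_1=arr[:, 1], beta=beta)


def write_correlogram(c: Correlogram, path: str | Path) -> None:
    np.savetxt(
        path,
        np.column_stack([c.lag_times, c.g2_minus_1]),
        header=f"tau_s g2_minus_1 (beta={c.beta})",
    )
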