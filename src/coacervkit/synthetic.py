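"""Seeded synthetic-data generators with known ground truth.

Every generator returns a (data, truth) pair in the same in-memory types
the analysis stages consume, so the whole pipeline is testable without
instrument data.  All randomness flows from a single integer seed.

Default scenario parameters are pinned to the study conditions the
toolkit targets: coacervate SAXS curves with Rg = 9.23 Angstrom (the
tetrapeptide fit) or 18.95 Angstrom (the hexapeptide fit) and Porod
exponent 4 at 2 % relative noise; DLS droplet ensembles with an
intensity-weighted mean diameter of 1.3 um; titrations of an
arginine-tryptophan peptide with NaOH; and sigmoidal turbidity surfaces
over a (concentration, pH) phase boundary.

Noise structure: multiplicative (relative) Gaussian noise for SAXS,
additive Gaussian noise for DLS correlograms — matching the error
structure typical of the respective instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dls import (
    Correlogram,
    DLSInstrument,
    SizeDistribution,
    default_rh_grid,
    intensity_weighted_mean_diameter,
    simulate_g2,
)
from .formulation import TurbidityPoint
from .saxs import SAXSCurve, SAXSModelParams, composite_intensity
from .seq_props import PeptideSpec, parse_peptide, solve_ph

SCENARIOS = (
    "saxs_coacervate",
    "saxs_monomer",
    "dls_ensemble",
    "titration",
    "turbidity_grid",
)

#: Ground-truth composite-model parameters for the default coacervate
#: scenarios (tetrapeptide W2R2 and hexapeptide W3R3 fits).
W2R2_COACERVATE_TRUTH = SAXSModelParams(
    coil_scale=1.0,
    rg=9.23,
    nu=0.4,
    porod_amplitude=1e-8,
    porod_exponent=4.0,
    background=0.01,
)
W3R3_COACERVATE_TRUTH = SAXSModelParams(
    coil_scale=1.0,
    rg=18.95,
    nu=0.4,
    porod_amplitude=1e-8,
    porod_exponent=4.0,
    background=0.01,
)
MONOMER_TRUTH = SAXSModelParams(
    coil_scale=1.0,
    rg=9.23,
    nu=0.4,
    background=0.01,
    peak_amplitude=0.5,
    peak_position=0.1,
    peak_width=50.0,
    peak_shape=2.0,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Scenario selector + seed + scenario-specific parameter overrides."""

    seed: int
    scenario: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; one of {SCENARIOS}")


def gen_saxs(
    seed: int,
    truth: SAXSModelParams | None = None,
    variant: str = "coacervate",
    q_min: float = 0.004,
    q_max: float = 0.4,
    n_points: int = 200,
    noise: float = 0.02,
) -> tuple[SAXSCurve, SAXSModelParams]:
    """Synthetic SAXS curve: composite model on a log-spaced q grid with
    multiplicative Gaussian noise; returns (curve, truth params)."""
    if truth is None:
        truth = W2R2_COACERVATE_TRUTH if variant == "coacervate" else MONOMER_TRUTH
    q = np.logspace(np.log10(q_min), np.log10(q_max), n_points)
    ideal = composite_intensity(q, truth, variant)
    rng = np.random.default_rng(seed)
    if noise > 0:
        intensity = ideal * (1.0 + rng.normal(0.0, noise, size=q.shape))
        sigma = noise * ideal
    else:
        intensity, sigma = ideal.copy(), None
    return SAXSCurve(q=q, intensity=intensity, sigma=sigma), truth


def lognormal_size_distribution(
    mean_diameter_nm: float = 1300.0,
    sigma_g: float = 1.1,
    rh_grid_nm: np.ndarray | None = None,
) -> SizeDistribution:
    """Log-normal intensity-weighted R_H ensemble with the requested
    intensity-weighted mean diameter (geometric sd sigma_g)."""
    if mean_diameter_nm <= 0 or sigma_g <= 1.0:
        raise ValueError("mean diameter must be > 0 and sigma_g > 1")
    grid = default_rh_grid() if rh_grid_nm is None else np.asarray(rh_grid_nm, float)
    s = np.log(sigma_g)

    def weights_for(median_radius: float) -> np.ndarray:
        logw = -0.5 * ((np.log(grid) - np.log(median_radius)) / s) ** 2
        w = np.exp(logw - logw.max())  # stable for arbitrarily narrow sigma_g
        return w / w.sum()

    mu = mean_diameter_nm / 2.0 / np.exp(s**2 / 2.0)  # median radius
    dist = SizeDistribution(rh_nm=grid, weights=weights_for(mu))
    # one multiplicative correction of the median absorbs discretization bias
    achieved = intensity_weighted_mean_diameter(dist)
    return SizeDistribution(
        rh_nm=grid, weights=weights_for(mu * mean_diameter_nm / achieved)
    )


def gen_dls(
    seed: int,
    mean_diameter_nm: float = 1300.0,
    sigma_g: float = 1.1,
    beta: float = 0.9,
    noise: float = 1e-3,
    inst: DLSInstrument | None = None,
    lag_times: np.ndarray | None = None,
    rh_grid_nm: np.ndarray | None = None,
) -> tuple[Correlogram, SizeDistribution]:
    """Synthetic DLS correlogram for a log-normal droplet ensemble."""
    dist = lognormal_size_distribution(mean_diameter_nm, sigma_g, rh_grid_nm)
    corr = simulate_g2(
        dist, inst=inst, beta=beta, noise_sd=noise, seed=seed, lag_times=lag_times
    )
    return corr, dist


def gen_titration(
    seed: int,
    peptide: PeptideSpec | str = "WWRR",
    peptide_conc: float = 0.01,
    base_max: float = 0.05,
    n_points: int = 50,
    ph_noise: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Synthetic NaOH titration curve (base added vs pH) for a peptide
    TFA salt; returns the table and the ground-truth pKa set."""
    p = parse_peptide(peptide) if isinstance(peptide, str) else peptide
    base = np.linspace(0.0, base_max, n_points)
    ph = np.array([solve_ph(p, peptide_conc, b) for b in base])
    if ph_noise > 0:
        rng = np.random.default_rng(seed)
        ph = ph + rng.normal(0.0, ph_noise, size=ph.shape)
    table = pd.DataFrame({"base_mol_per_L": base, "pH": ph})
    truth = {g.label: g.pka for g in p.groups}
    return table, truth


def gen_turbidity_grid(
    seed: int,
    conc_range: tuple[float, float] = (0.5, 5.0),
    ph_range: tuple[float, float] = (9.0, 13.0),
    n_conc: int = 10,
    n_ph: int = 17,
    boundary_ph0: float = 12.5,
    boundary_slope: float = 0.2,  # pH units per wt %: pH*(c) = ph0 - slope*c
    sigmoid_width: float = 0.15,  # pH units
    t_max: float = 2.0,  # cm^-1
    noise: float = 0.0,  # sd as fraction of t_max
    path_cm: float = 1.0,
) -> tuple[list[tuple[float, float, TurbidityPoint]], dict[str, float]]:
    """Sigmoidal turbidity surface across a linear (conc, pH) phase boundary.

    LLPS onset pH decreases with concentration: pH*(c) = ph0 - slope*c.
    Turbidity rises sigmoidally from 0 to t_max across the boundary.
    Returns (points, truth) with the boundary parameters echoed.
    """
    rng = np.random.default_rng(seed)
    concs = np.linspace(*conc_range, n_conc)
    phs = np.linspace(*ph_range, n_ph)
    points = []
    for c in concs:
        ph_star = boundary_ph0 - boundary_slope * c
        for ph in phs:
            t = t_max / (1.0 + np.exp(-(ph - ph_star) / sigmoid_width))
            if noise > 0:
                t = max(0.0, t + rng.normal(0.0, noise * t_max))
            a = t * path_cm / np.log(10.0)
            points.append((float(c), float(ph), TurbidityPoint(float(a), path_cm)))
    truth = {
        "boundary_ph0": boundary_ph0,
        "boundary_slope": boundary_slope,
        "sigmoid_width": sigmoid_width,
        "t_max": t_max,
    }
    return points, truth


def generate(config: GeneratorConfig):
    """Dispatch a GeneratorConfig to the matching generator."""
    fns = {
        "saxs_coacervate": lambda: gen_saxs(config.seed, variant="coacervate", **config.params),
        "saxs_monomer": lambda: gen_saxs(config.seed, variant="monomer", **config.params),
        "dls_ensemble": lambda: gen_dls(config.seed, **config.params),
        "titration": lambda: gen_titration(config.seed, **config.params),
        "turbidity_grid": lambda: gen_turbidity_grid(config.seed, **config.params),
    }
    return fns[config.scenario]()
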