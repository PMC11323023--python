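"""Composite SAXS model and weighted least-squares fitting.

Two model variants describe 1-D scattering curves from peptide solutions:

* ``coacervate`` — Porod power law + generalized Gaussian coil + flat
  background.  The power law (exponent n, default 4) captures the low-q
  forward scattering from droplet interfaces; the coil term captures the
  monomer plateau and high-q decay.
* ``monomer`` — generalized Gaussian coil multiplied by an empirical
  correlation-peak structure factor, + background, for concentrated
  non-phase-separated solutions.

The generalized Gaussian coil is the excluded-volume chain form factor
parameterized by the radius of gyration Rg and the Flory exponent nu
(nu = 0.5 reduces to the Debye function):

    U = (2 nu + 1)(2 nu + 2) q^2 Rg^2 / 6
    P(q) = gamma_inc(1/(2 nu), U) / (nu U^(1/(2 nu)))
         - gamma_inc(1/nu, U) / (nu U^(1/nu))

with gamma_inc the lower incomplete gamma function; P(0) = 1 and the
high-q decay exponent is 1/nu.

Fitting uses lmfit least squares, weighted by 1/sigma^2 when an
uncertainty column is present, with bounds enforcing parameter validity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from lmfit import Parameters, minimize
from scipy.special import gamma as _gamma_fn
from scipy.special import gammainc as _reg_lower_gamma


@dataclass
class SAXSCurve:
    """1-D scattering curve: q (1/Angstrom, ascending), I, optional sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if self.q.size < 10:
            raise ValueError("curve must have at least 10 points")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass(frozen=True)
class SAXSModelParams:
    """Parameter set for the composite model (q in 1/Angstrom, Rg in Angstrom)."""

    coil_scale: float = 1.0
    rg: float = 10.0
    nu: float = 0.5
    porod_amplitude: float = 0.0
    porod_exponent: float = 4.0
    background: float = 0.0
    # optional correlation-peak structure factor
    peak_amplitude: float = 0.0
    peak_position: float = 0.1  # 1/Angstrom
    peak_width: float = 50.0  # Angstrom (correlation length xi)
    peak_shape: float = 2.0

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("Rg must be positive")
        if not (0.2 <= self.nu <= 1.0):
            raise ValueError("nu must lie in [0.2, 1]")
        if self.porod_exponent <= 0:
            raise ValueError("Porod exponent must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


@dataclass
class FitResult:
    params: SAXSModelParams
    stderr: dict[str, float]
    redchi: float
    success: bool
    nfev: int = 0


def read_saxs_ascii(path: str | Path) -> SAXSCurve:
    """Read a 2- or 3-column ASCII curve (q, I[, sigma]).

    Whitespace- or comma-separated; lines starting with '#' are comments.
    Rows are sorted by q.  Malformed or non-positive-q rows raise a format
    error naming the offending line.
    """
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
                vals = [float(x) for x in parts[:3]]
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric value") from None
            if vals[0] <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive q {vals[0]}")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    arr = arr[np.argsort(arr[:, 0])]
    sigma = arr[:, 2] if ncol >= 3 else None
    return SAXSCurve(q=arr[:, 0], intensity=arr[:, 1], sigma=sigma)


def write_saxs_ascii(curve: SAXSCurve, path: str | Path, header: str = "q I sigma") -> None:
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), header=header)


def gg_coil_intensity(
    q: np.ndarray,
    rg: float,
    nu: float,
    scale: float = 1.0,
    background: float = 0.0,
) -> np.ndarray:
    """Generalized Gaussian coil (excluded-volume chain) intensity.

    I(q) = scale * P(q) + background with P(0) = 1; high-q slope -> -1/nu.
    """
    q = np.asarray(q, dtype=float)
    u = (2.0 * nu + 1.0) * (2.0 * nu + 2.0) * q**2 * rg**2 / 6.0
    a, b = 1.0 / (2.0 * nu), 1.0 / nu
    safe = np.where(u > 0, u, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = _gamma_fn(a) * _reg_lower_gamma(a, safe) / (nu * safe**a)
        term2 = _gamma_fn(b) * _reg_lower_gamma(b, safe) / (nu * safe**b)
        p = term1 - term2
    p = np.where(u < 1e-12, 1.0, p)
    return scale * p + background


def porod_term(q: np.ndarray, amplitude: float, exponent: float) -> np.ndarray:
    """Power-law term I_s q^-n (n = 4: Porod scattering from sharp interfaces)."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    return amplitude * q ** (-exponent)


def peak_structure_factor(
    q: np.ndarray,
    amplitude: float,
    position: float,
    width: float,
    shape: float = 2.0,
) -> np.ndarray:
    """Empirical correlation-peak factor S(q) = 1 + c / (1 + (|q-q0| xi)^m).

    S is maximal (1 + c) at q0 and decays to 1 far from the peak.
    """
    if width <= 0:
        raise ValueError("peak width must be positive")
    q = np.asarray(q, dtype=float)
    return 1.0 + amplitude / (1.0 + (np.abs(q - position) * width) ** shape)


def composite_intensity(
    q: np.ndarray, params: SAXSModelParams, variant: str = "coacervate"
) -> np.ndarray:
    """Evaluate the composite model for either variant."""
    q = np.asarray(q, dtype=float)
    coil = gg_coil_intensity(q, params.rg, params.nu, params.coil_scale, 0.0)
    if variant == "coacervate":
        return (
            porod_term(q, params.porod_amplitude, params.porod_exponent)
            + coil
            + params.background
        )
    if variant == "monomer":
        s = peak_structure_factor(
            q,
            params.peak_amplitude,
            params.peak_position,
            params.peak_width,
            params.peak_shape,
        )
        return coil * s + params.background
    raise ValueError(f"unknown variant {variant!r}")


_FIT_NAMES = [
    "coil_scale",
    "rg",
    "nu",
    "porod_amplitude",
    "porod_exponent",
    "background",
    "peak_amplitude",
    "peak_position",
    "peak_width",
    "peak_shape",
]


def _to_lmfit_params(init: SAXSModelParams, variant: str, fixed: set[str]) -> Parameters:
    p = Parameters()
    p.add("coil_scale", value=init.coil_scale, min=0.0)
    p.add("rg", value=init.rg, min=1e-3)
    p.add("nu", value=init.nu, min=0.2, max=1.0)
    p.add("porod_amplitude", value=init.porod_amplitude, min=0.0)
    p.add("porod_exponent", value=init.porod_exponent, min=0.5, max=8.0)
    p.add("background", value=init.background, min=0.0)
    p.add("peak_amplitude", value=init.peak_amplitude, min=0.0)
    p.add("peak_position", value=init.peak_position, min=1e-4)
    p.add("peak_width", value=init.peak_width, min=1e-3)
    p.add("peak_shape", value=init.peak_shape, min=0.5, max=8.0)
    if variant == "coacervate":
        for name in ("peak_amplitude", "peak_position", "peak_width", "peak_shape"):
            p[name].vary = False
    else:
        for name in ("porod_amplitude", "porod_exponent"):
            p[name].vary = False
    for name in fixed:
        if name not in p:
            raise ValueError(f"unknown parameter {name!r}")
        p[name].vary = False
    return p


def fit_saxs(
    curve: SAXSCurve,
    variant: str = "coacervate",
    init: SAXSModelParams | None = None,
    fixed: set[str] | frozenset[str] = frozenset(),
) -> FitResult:
    """Weighted nonlinear least-squares fit of the composite model.

    Residuals are (model - I)/sigma when the curve carries uncertainties,
    otherwise unweighted.  Non-convergence is reported on the result, not
    raised.  Deterministic given the initial values.
    """
    if init is None:
        init = SAXSModelParams(
            coil_scale=float(np.median(curve.intensity)),
            rg=2.0 / float(np.median(curve.q)),
        )
    lmp = _to_lmfit_params(init, variant, set(fixed))

    def residual(pars):
        mp = SAXSModelParams(**{n: pars[n].value for n in _FIT_NAMES})
        model = composite_intensity(curve.q, mp, variant)
        res = model - curve.intensity
        if curve.sigma is not None:
            res = res / np.where(curve.sigma > 0, curve.sigma, 1.0)
        return res

    out = minimize(residual, lmp, method="leastsq")
    fitted = SAXSModelParams(**{n: out.params[n].value for n in _FIT_NAMES})
    stderr = {
        n: (out.params[n].stderr if out.params[n].stderr is not None else float("nan"))
        for n in _FIT_NAMES
        if out.params[n].vary
    }
    return FitResult(
        params=fitted,
        stderr=stderr,
        redchi=float(out.redchi),
        success=bool(out.success),
        nfev=int(out.nfev),
    )
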