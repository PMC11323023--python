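"""Charged-droplet electrostatics: Debye screening, Grahame equation, and
the Rayleigh stability limit.

The chain implemented here converts two routine measurements on coacervate
droplets — the zeta potential (used directly as the surface potential
psi_0) and the mean droplet diameter d — into an estimate of the
interfacial tension gamma:

1. Grahame (linearized, valid at low surface charge):
       sigma = eps * eps0 * kappa * psi_0,
   with kappa the inverse Debye length.  The full 1:1-electrolyte form
       sigma = (2 eps eps0 kappa kB T / e) * sinh(e psi_0 / (2 kB T))
   is available and agrees to first order as psi_0 -> 0.

2. Rayleigh stability limit.  A droplet of diameter d and interfacial
   tension gamma can hold at most
       q = pi * sqrt(8 eps0 gamma d^3)
   of charge before Coulomb repulsion overcomes surface tension.  Writing
   q = sigma * pi * d^2 at the limit gives the equivalent forms
       d = 8 eps0 gamma / sigma^2   and   gamma = d sigma^2 / (8 eps0).

Assuming observed droplets sit at their stability limit, the measured
(sigma, d) pair therefore yields gamma.  All quantities are SI internally;
convenience constructors accept the units measurements are reported in
(mV, nm, um).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    ROOM_TEMPERATURE,
    VACUUM_PERMITTIVITY,
    WATER_RELATIVE_PERMITTIVITY,
)


def debye_length(
    ionic_strength: float,
    temperature: float = ROOM_TEMPERATURE,
    relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY,
) -> float:
    """Debye length in nm for a given ionic strength (mol/L).

    kappa^-1 = sqrt(eps eps0 kB T / (2 NA e^2 * 1000 * I)).
    """
    if ionic_strength <= 0:
        raise ValueError("ionic strength must be positive")
    num = relative_permittivity * VACUUM_PERMITTIVITY * BOLTZMANN * temperature
    den = 2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * 1000.0 * ionic_strength
    return math.sqrt(num / den) * 1e9


def ionic_strength_from_debye(
    debye_length_nm: float,
    temperature: float = ROOM_TEMPERATURE,
    relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY,
) -> float:
    """Inverse of :func:`debye_length`: ionic strength (mol/L) from nm."""
    if debye_length_nm <= 0:
        raise ValueError("Debye length must be positive")
    lam = debye_length_nm * 1e-9
    num = relative_permittivity * VACUUM_PERMITTIVITY * BOLTZMANN * temperature
    den = 2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * 1000.0 * lam**2
    return num / den


@dataclass(frozen=True)
class ElectrolyteEnvironment:
    """Solvent/electrolyte context for the Grahame conversion."""

    temperature: float = ROOM_TEMPERATURE  # K
    relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY
    debye_length_nm: float | None = None
    ionic_strength: float | None = None  # mol/L, optional

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.relative_permittivity <= 1:
            raise ValueError("relative permittivity must exceed 1")
        if self.debye_length_nm is None and self.ionic_strength is None:
            raise ValueError("provide debye_length_nm or ionic_strength")
        if self.debye_length_nm is None:
            object.__setattr__(
                self,
                "debye_length_nm",
                debye_length(
                    self.ionic_strength, self.temperature, self.relative_permittivity
                ),
            )
        elif self.ionic_strength is not None:
            implied = debye_length(
                self.ionic_strength, self.temperature, self.relative_permittivity
            )
            if abs(implied - self.debye_length_nm) > 1e-6 * self.debye_length_nm:
                raise ValueError(
                    f"debye_length_nm={self.debye_length_nm} inconsistent with "
                    f"ionic_strength={self.ionic_strength} (implies {implied:.6g} nm)"
                )
        if self.debye_length_nm <= 0:
            raise ValueError("Debye length must be positive")

    @property
    def kappa(self) -> float:
        """Inverse Debye length in 1/m."""
        return 1.0 / (self.debye_length_nm * 1e-9)


@dataclass(frozen=True)
class DropletMeasurement:
    """Measured droplet diameter (m) and zeta potential (V)."""

    diameter: float  # m
    zeta_potential: float  # V

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @classmethod
    def from_common_units(cls, diameter_um: float, zeta_mv: float) -> "DropletMeasurement":
        return cls(diameter=diameter_um * 1e-6, zeta_potential=zeta_mv * 1e-3)


@dataclass(frozen=True)
class DropletResult:
    """Output of the measurement -> tension chain, with inputs echoed."""

    surface_charge_density: float  # C/m^2
    limit_charge: float  # C
    interfacial_tension: float  # N/m
    measurement: DropletMeasurement = None
    environment: ElectrolyteEnvironment = None
    grahame_mode: str = "linear"

    def as_dict(self) -> dict:
        d = {
            "surface_charge_density_C_per_m2": self.surface_charge_density,
            "surface_charge_density_mC_per_m2": self.surface_charge_density * 1e3,
            "limit_charge_C": self.limit_charge,
            "interfacial_tension_N_per_m": self.interfacial_tension,
            "interfacial_tension_mN_per_m": self.interfacial_tension * 1e3,
            "grahame_mode": self.grahame_mode,
        }
        if self.measurement is not None:
            d["diameter_um"] = self.measurement.diameter * 1e6
            d["zeta_mV"] = self.measurement.zeta_potential * 1e3
        if self.environment is not None:
            d["debye_length_nm"] = self.environment.debye_length_nm
            d["relative_permittivity"] = self.environment.relative_permittivity
            d["temperature_K"] = self.environment.temperature
        return d


def tension_batch_from_csv(path, grahame_mode: str = "linear"):
    """Run the tension chain for one droplet population per CSV row.

    Required columns: diameter_um, zeta_mv, debye_nm; optional: epsilon,
    temperature_k.  Returns a pandas DataFrame of the result records.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("diameter_um", "zeta_mv", "debye_nm"):
        if needed not in cols:
            raise ValueError(f"batch CSV missing column {needed!r}")
    records = []
    for _, row in df.iterrows():
        env = ElectrolyteEnvironment(
            temperature=float(row[cols["temperature_k"]])
            if "temperature_k" in cols
            else ROOM_TEMPERATURE,
            relative_permittivity=float(row[cols["epsilon"]])
            if "epsilon" in cols
            else WATER_RELATIVE_PERMITTIVITY,
            debye_length_nm=float(row[cols["debye_nm"]]),
        )
        m = DropletMeasurement.from_common_units(
            float(row[cols["diameter_um"]]), float(row[cols["zeta_mv"]])
        )
        records.append(tension_from_measurements(m, env, grahame_mode).as_dict())
    return pd.DataFrame(records)


def grahame_surface_charge(
    zeta_potential: float,
    env: ElectrolyteEnvironment,
    mode: str = "linear",
) -> float:
    """Surface charge density (C/m^2) from the surface potential (V).

    mode='linear': sigma = eps eps0 kappa psi0 (low-potential limit).
    mode='full_1to1': sinh form for a symmetric 1:1 electrolyte.
    """
    eps = env.relative_permittivity * VACUUM_PERMITTIVITY
    if mode == "linear":
        return eps * env.kappa * zeta_potential
    if mode == "full_1to1":
        kt = BOLTZMANN * env.temperature
        x = ELEMENTARY_CHARGE * zeta_potential / (2.0 * kt)
        return 2.0 * eps * env.kappa * kt / ELEMENTARY_CHARGE * math.sinh(x)
    raise ValueError(f"unknown Grahame mode {mode!r}")


def rayleigh_limit_charge(diameter: float, interfacial_tension: float) -> float:
    """Maximum (Rayleigh) charge in C for a droplet of diameter d (m) and
    interfacial tension gamma (N/m): q = pi sqrt(8 eps0 gamma d^3)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    if interfacial_tension < 0:
        raise ValueError("interfacial tension must be non-negative")
    return math.pi * math.sqrt(
        8.0 * VACUUM_PERMITTIVITY * interfacial_tension * diameter**3
    )


def critical_diameter(surface_charge_density: float, interfacial_tension: float) -> float:
    """Droplet diameter (m) at the stability limit: d = 8 eps0 gamma / sigma^2."""
    if surface_charge_density == 0:
        raise ValueError("surface charge density must be non-zero (d unbounded)")
    if interfacial_tension < 0:
        raise ValueError("interfacial tension must be non-negative")
    return 8.0 * VACUUM_PERMITTIVITY * interfacial_tension / surface_charge_density**2


def interfacial_tension(diameter: float, surface_charge_density: float) -> float:
    """Interfacial tension (N/m) from droplet diameter (m) and surface
    charge density (C/m^2): gamma = d sigma^2 / (8 eps0)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return diameter * surface_charge_density**2 / (8.0 * VACUUM_PERMITTIVITY)


def tension_from_measurements(
    m: DropletMeasurement,
    env: ElectrolyteEnvironment,
    grahame_mode: str = "linear",
) -> DropletResult:
    """Full chain: zeta -> sigma (Grahame) -> gamma (Rayleigh) -> limit charge."""
    sigma = grahame_surface_charge(m.zeta_potential, env, mode=grahame_mode)
    gamma = interfacial_tension(m.diameter, sigma)
    q = math.copysign(rayleigh_limit_charge(m.diameter, gamma), sigma)
    return DropletResult(
        surface_charge_density=sigma,
        limit_charge=q,
        interfacial_tension=gamma,
        measurement=m,
        environment=env,
        grahame_mode=grahame_mode,
    )
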