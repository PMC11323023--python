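"""Coacervate formulation arithmetic and turbidity phase maps.

Compositions follow the charge-matching convention used for peptide:ATP
complex coacervates: the partner (e.g. ATP, assumed charge -2) is dosed so
that its charge equivalents are a stated fraction (the charge ratio) of the
peptide's charge equivalents.  wt % means g solute per 100 mL assuming a
solution density of 1 g/mL, so molarity = 10 * wt% / M.
"""

from __future__ import annotations

import decimal

from dataclasses import dataclass


import pandas as pd

from .constants import LN10


@dataclass(frozen=True)
class MixtureSpec:
    """Peptide + oppositely charged partner at a target charge ratio.

    charge_ratio is the partner:peptide charge-equivalent factor
    (1.0 for 1:1, 0.5 for 1:0.5).
    """

    peptide_molar_mass: float  # Da
    peptide_charge: int  # assumed integer charge, > 0
    partner_molar_mass: float  # Da
    partner_charge: int  # assumed integer charge, < 0
    peptide_wt_pct: float
    charge_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.peptide_molar_mass <= 0 or self.partner_molar_mass <= 0:
            raise ValueError("molar masses must be positive")
        if self.peptide_charge <= 0:
            raise ValueError("peptide charge must be positive")
        if self.partner_charge >= 0:
            raise ValueError("partner charge must be negative")
        if not (0.0 < self.peptide_wt_pct < 100.0):
            raise ValueError("peptide wt % must be in (0, 100)")
        if self.charge_ratio <= 0:
            raise ValueError("charge ratio must be positive")


@dataclass(frozen=True)
class TurbidityPoint:
    """One turbidity measurement: absorbance at 500 nm over a known path."""

    absorbance_500nm: float
    path_length_cm: float

    def __post_init__(self) -> None:
        if self.absorbance_500nm < 0:
            raise ValueError("absorbance must be non-negative")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")

    @property
    def turbidity(self) -> float:
        return turbidity_from_absorbance(self.absorbance_500nm, self.path_length_cm)


@dataclass(frozen=True)
class PhaseMap:
    """Grid of turbidity values with a boolean LLPS flag per point."""

    table: pd.DataFrame  # columns: concentration, pH, turbidity, llps
    threshold: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _round_half_up(x: float, ndigits: int) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def molarity_from_wt_pct(wt_pct: float, molar_mass: float) -> float:
    """mol/L from wt %, assuming 1 g/mL solution density."""
    if wt_pct <= 0 or molar_mass <= 0:
        raise ValueError("wt % and molar mass must be positive")
    return 10.0 * wt_pct / molar_mass


def wt_pct_from_molarity(molarity: float, molar_mass: float) -> float:
    if molarity < 0 or molar_mass <= 0:
        raise ValueError("molarity must be >= 0 and molar mass > 0")
    return molarity * molar_mass / 10.0


def partner_wt_pct_for_charge_ratio(m: MixtureSpec, rounded: bool = True) -> float:
    """Partner wt % that matches the target charge ratio.

    partner molarity = peptide molarity * peptide charge * ratio / |partner
    charge|, converted back to wt %.  Rounded half-up to 1 decimal (the
    convention of composition labels) unless rounded=False.
    """
    c_pep = molarity_from_wt_pct(m.peptide_wt_pct, m.peptide_molar_mass)
    c_partner = c_pep * m.peptide_charge * m.charge_ratio / abs(m.partner_charge)
    wt = wt_pct_from_molarity(c_partner, m.partner_molar_mass)
    return _round_half_up(wt, 1) if rounded else wt


def turbidity_from_absorbance(absorbance: float, path_length_cm: float) -> float:
    """Turbidity T = ln(10) * A / L in cm^-1 from decadic absorbance."""
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    if path_length_cm <= 0:
        raise ValueError("path length must be positive")
    return LN10 * absorbance / path_length_cm


def assemble_phase_map(points, threshold: float) -> PhaseMap:
    """Organize (concentration, pH, TurbidityPoint) triples into a PhaseMap.

    The LLPS flag is turbidity >= threshold (inclusive).  Duplicate
    (concentration, pH) coordinates are rejected.
    """
    points = list(points)
    if not points:
        raise ValueError("points must be non-empty")
    rows = []
    seen = set()
    for conc, ph, tp in points:
        key = (float(conc), float(ph))
        if key in seen:
            raise ValueError(f"duplicate grid coordinate {key}")
        seen.add(key)
        t = tp.turbidity if isinstance(tp, TurbidityPoint) else float(tp)
        rows.append(
            {
                "concentration": float(conc),
                "pH": float(ph),
                "turbidity": t,
                "llps": bool(t >= threshold),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["concentration", "pH"])
        .reset_index(drop=True)
    )
    return PhaseMap(table=table, threshold=float(threshold))


def read_turbidity_csv(path) -> list[tuple[float, float, TurbidityPoint]]:
    """Read turbidity measurements from CSV.

    Expected columns: concentration, pH, A500, path_cm (a leading sample
    column is allowed and ignored).
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    needed = ["concentration", "ph", "a500", "path_cm"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ValueError(f"turbidity CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            (
                float(row[cols["concentration"]]),
                float(row[cols["ph"]]),
                TurbidityPoint(float(row[cols["a500"]]), float(row[cols["path_cm"]])),
            )
        )
    return out
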