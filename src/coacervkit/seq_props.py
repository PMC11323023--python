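"""Peptide sequence properties: mass, multi-site ionization, speciation, pI.

Charge arithmetic treats every ionizable site as an independent
Henderson-Hasselbalch two-state equilibrium.  A *base* (N-terminus, Arg,
Lys, His) carries +1 when protonated and 0 when deprotonated; an *acid*
(C-terminus, Asp, Glu, Cys, Tyr) carries 0 when protonated and -1 when
deprotonated.  The net charge is the sum of per-site expected charges and
the integer charge-state distribution is the convolution of the per-site
Bernoulli charge variables — exactly what a Boltzmann enumeration over all
2^N protonation microstates gives when sites do not interact.

Masses are computed with :mod:`pyteomics.mass` (monoisotopic and IUPAC
average atomic weights) and reported rounded half-up to two decimals.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy.optimize import brentq

from .constants import KW

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Three-letter labels for ionizable side chains
_SIDECHAIN_NAME = {
    "D": "Asp", "E": "Glu", "C": "Cys", "Y": "Tyr",
    "H": "His", "K": "Lys", "R": "Arg",
}

#: Default pKa table.  Values are a conventional textbook set for model
#: peptides in water; the table is a named, swappable input because measured
#: pKas for a given peptide can differ from free-amino-acid values.
#: charge_when_protonated is +1 for bases and 0 for acids.
DEFAULT_PKA_TABLE: dict[str, tuple[float, int]] = {
    "N-term": (9.0, 1),
    "C-term": (3.2, 0),
    "D": (3.9, 0),
    "E": (4.1, 0),
    "C": (8.3, 0),
    "Y": (10.5, 0),
    "H": (6.0, 1),
    "K": (10.5, 1),
    "R": (12.5, 1),
}


@dataclass(frozen=True)
class IonizableGroup:
    """One titratable site with its pKa and protonated-state charge."""

    label: str
    pka: float
    charge_when_protonated: int  # +1 for bases, 0 for acids

    def __post_init__(self) -> None:
        if not (0.0 < self.pka < 14.0):
            raise ValueError(f"pKa out of range (0, 14): {self.pka}")
        if self.charge_when_protonated not in (0, 1):
            raise ValueError("charge_when_protonated must be 0 or +1")

    @property
    def is_base(self) -> bool:
        return self.charge_when_protonated == 1

    def protonated_fraction(self, ph: float) -> float:
        """Henderson-Hasselbalch fraction protonated at the given pH."""
        return 1.0 / (1.0 + 10.0 ** (ph - self.pka))

    def expected_charge(self, ph: float) -> float:
        f = self.protonated_fraction(ph)
        # base: +1 with prob f; acid: -1 with prob (1 - f)
        return f if self.is_base else -(1.0 - f)


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence together with its ionizable groups."""

    sequence: str
    groups: tuple[IonizableGroup, ...]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_AA:
                raise ValueError(
                    f"unknown residue {aa!r} at position {i} in {self.sequence!r}"
                )
        labels = [g.label for g in self.groups]
        if labels.count("N-term") != 1 or labels.count("C-term") != 1:
            raise ValueError("groups must contain exactly one N-term and one C-term")

    @property
    def n_basic(self) -> int:
        return sum(1 for g in self.groups if g.is_base)


@dataclass(frozen=True)
class SpeciationProfile:
    """Distribution over integer net-charge states at one pH."""

    ph: float
    fractions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(not (0.0 <= f <= 1.0 + 1e-12) for f in self.fractions.values()):
            raise ValueError("fractions must lie in [0, 1]")

    def mean_charge(self) -> float:
        return sum(z * f for z, f in self.fractions.items())


def load_pka_table(path: str | Path) -> dict[str, tuple[float, int]]:
    """Read a pKa table from CSV with columns group,pKa,charge_when_protonated."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    out = {}
    for _, row in df.iterrows():
        out[str(row["group"]).strip()] = (
            float(row["pka"]),
            int(row["charge_when_protonated"]),
        )
    return out


def sequence_from_fasta(text_or_path: str | Path) -> str:
    """Extract the sequence from a plain string or a single-record FASTA.

    A leading ``>`` header line is discarded; whitespace is stripped.
    """
    p = Path(str(text_or_path))
    try:
        is_file = p.is_file()
    except OSError:
        is_file = False
    text = p.read_text() if is_file else str(text_or_path)
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    return "".join(lines)


def parse_peptide(
    sequence: str,
    pka_set: dict[str, tuple[float, int]] | None = None,
) -> PeptideSpec:
    """Build a :class:`PeptideSpec` from a one-letter sequence and a pKa table.

    Groups are the N-terminus, the C-terminus, and one entry per ionizable
    side chain present both in the sequence and in the pKa table.
    """
    pka_set = DEFAULT_PKA_TABLE if pka_set is None else pka_set
    sequence = sequence_from_fasta(sequence).upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, aa in enumerate(sequence, start=1):
        if aa not in STANDARD_AA:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    groups = [
        IonizableGroup("N-term", *pka_set["N-term"]),
        IonizableGroup("C-term", *pka_set["C-term"]),
    ]
    for i, aa in enumerate(sequence, start=1):
        if aa in _SIDECHAIN_NAME and aa in pka_set:
            pka, cwp = pka_set[aa]
            groups.append(IonizableGroup(f"{_SIDECHAIN_NAME[aa]}-{i}", pka, cwp))
    return PeptideSpec(sequence=sequence, groups=tuple(groups))


def _round_half_up(x: float, ndigits: int = 2) -> float:
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def monoisotopic_mass(p: PeptideSpec) -> float:
    """Monoisotopic neutral mass in Da, rounded half-up to 2 decimals."""
    return _round_half_up(_pmass.calculate_mass(sequence=p.sequence), 2)


def average_mass(p: PeptideSpec) -> float:
    """Average (IUPAC atomic weights) neutral mass in Da, 2 decimals."""
    return _round_half_up(_pmass.calculate_mass(sequence=p.sequence, average=True), 2)


def net_charge(p: PeptideSpec, ph: float) -> float:
    """Expected (fractional) net charge at the given pH.

    Strictly decreasing in pH: every site's expected charge is a decreasing
    logistic in pH.
    """
    return sum(g.expected_charge(ph) for g in p.groups)


def speciation(p: PeptideSpec, ph: float) -> SpeciationProfile:
    """Distribution over integer net-charge states at one pH.

    Convolution of the independent per-site Bernoulli charge variables;
    equals the 2^N microstate Boltzmann enumeration exactly for
    non-interacting sites.
    """
    dist: dict[int, float] = {0: 1.0}
    for g in p.groups:
        f = g.protonated_fraction(ph)
        if g.is_base:
            site = {1: f, 0: 1.0 - f}
        else:
            site = {0: f, -1: 1.0 - f}
        new: dict[int, float] = {}
        for z, pz in dist.items():
            for dz, pdz in site.items():
                new[z + dz] = new.get(z + dz, 0.0) + pz * pdz
        dist = new
    total = sum(dist.values())
    dist = {z: f / total for z, f in dist.items()}
    return SpeciationProfile(ph=ph, fractions=dist)


def speciation_table(p: PeptideSpec, ph_values) -> pd.DataFrame:
    """Long-format table (pH, charge, fraction) over a pH grid."""
    rows = []
    for ph in ph_values:
        prof = speciation(p, float(ph))
        for z in sorted(prof.fractions):
            rows.append({"pH": float(ph), "charge": z, "fraction": prof.fractions[z]})
    return pd.DataFrame(rows)


def isoelectric_point(p: PeptideSpec) -> float:
    """pH at which the expected net charge is zero.

    Unique because net_charge is strictly decreasing in pH.  Requires at
    least one acidic and one basic group so a sign change exists on [0, 14].
    """
    has_acid = any(not g.is_base for g in p.groups)
    has_base = any(g.is_base for g in p.groups)
    if not (has_acid and has_base):
        raise ValueError("isoelectric point requires at least one acid and one base")
    f = lambda ph: net_charge(p, ph)
    lo, hi = 0.0, 14.0
    if f(lo) * f(hi) > 0:
        raise ValueError("net charge does not change sign on [0, 14]")
    pi = brentq(f, lo, hi, xtol=1e-10)
    if abs(f(pi)) > 1e-6:
        raise RuntimeError("bisection failed to reach |charge| < 1e-6")
    return float(pi)


def solve_ph(
    p: PeptideSpec | None,
    peptide_conc: float,
    base_conc: float,
    counterions_per_peptide: float | None = None,
) -> float:
    """Forward solve: pH of peptide (TFA salt) + strong base at the given
    concentrations, from the charge-balance equation.

    Electroneutrality: [Na+] + [H+] + C_p * z(pH) = [OH-] + [TFA-], with
    [TFA-] = counterions_per_peptide * C_p (default: one TFA- per cationic
    group, i.e. the salt is neutral as supplied).
    """
    if peptide_conc < 0 or base_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if counterions_per_peptide is None:
        counterions_per_peptide = float(p.n_basic) if p is not None else 0.0
    c_tfa = counterions_per_peptide * peptide_conc

    def balance(ph: float) -> float:
        h = 10.0 ** (-ph)
        oh = KW / h
        z = net_charge(p, ph) if (p is not None and peptide_conc > 0) else 0.0
        return base_conc + h + peptide_conc * z - oh - c_tfa

    # balance is strictly decreasing in pH -> unique root
    return float(brentq(balance, 0.0, 14.0, xtol=1e-10))


def base_to_reach_ph(
    p: PeptideSpec | None,
    peptide_conc: float,
    target_ph: float,
    counterions_per_peptide: float | None = None,
) -> float:
    """Strong-base (NaOH) concentration in mol/L required to reach target_ph.

    Closed-form from the same charge balance used by :func:`solve_ph`;
    raises if the target pH sits below the un-titrated pH (a base-only
    titrant cannot lower pH).
    """
    if peptide_conc < 0:
        raise ValueError("peptide_conc must be non-negative")
    if counterions_per_peptide is None:
        counterions_per_peptide = float(p.n_basic) if p is not None else 0.0
    h = 10.0 ** (-target_ph)
    oh = KW / h
    z = net_charge(p, target_ph) if (p is not None and peptide_conc > 0) else 0.0
    c_base = oh + counterions_per_peptide * peptide_conc - h - peptide_conc * z
    if c_base < 0:
        raise ValueError(
            f"target pH {target_ph} is below the un-titrated pH; "
            "unreachable with a strong base"
        )
    return float(c_base)
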