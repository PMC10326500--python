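"""Fixed numeric tables underlying every property computation.

The tables live in a packaged TOML file (``data/constants.toml``) rather
than in code so that alternates (or deliberately broken copies, in tests)
can be loaded through the same machinery.  All tables are exposed as frozen
dataclasses wrapping read-only mappings.

Contents
--------
* average isotopic residue masses plus the mass of one water (chain mass =
  sum of residue masses + water),
* per-residue C/H/N/O/S atom counts (residue = amino acid minus one water),
* pK values of the nine ionizable groups used by the charge model,
* the Kyte-Doolittle hydropathy scale,
* the aliphatic-index side-chain volume coefficients a (Val) and b (Leu/Ile).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

#: The 20 canonical residues, in the display order used throughout (the
#: alphabetical order of the three-letter codes: Ala, Arg, Asn, ... Val).
CANONICAL_ORDER: str = "ARNDCQEGHILKMFPSTWYV"

#: Three-letter names for every accepted code, canonical and ambiguous.
THREE_LETTER: Mapping[str, str] = MappingProxyType({
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "B": "Asx", "X": "Xaa", "Z": "Glx",
})

ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class MassTable:
    """Average isotopic residue masses (Da) and the mass of one water."""

    residue_mass: Mapping[str, float]
    water_mass: float


@dataclass(frozen=True)
class AtomTable:
    """Per-residue element counts (amino acid minus one water)."""

    residue_atoms: Mapping[str, Mapping[str, int]]


@dataclass(frozen=True)
class PKSet:
    """pK values of the ionizable groups and their acid/base character.

    Groups are keyed ``Nterm``, ``Cterm`` and the one-letter codes of the
    seven ionizable side chains (D, E, C, Y, H, K, R).  A single N-terminal
    pK is used for every residue type.
    """

    pk: Mapping[str, float]
    sign: Mapping[str, str]

    @property
    def acidic(self) -> tuple[str, ...]:
        return tuple(g for g, s in self.sign.items() if s == "acidic")

    @property
    def basic(self) -> tuple[str, ...]:
        return tuple(g for g, s in self.sign.items() if s == "basic")


@dataclass(frozen=True)
class HydropathyScale:
    """Kyte-Doolittle hydropathy values, one per canonical residue."""

    kd: Mapping[str, float]

    @property
    def min_value(self) -> float:
        return min(self.kd.values())

    @property
    def max_value(self) -> float:
        return max(self.kd.values())


@dataclass(frozen=True)
class AliphaticCoefficients:
    """Relative side-chain volumes against Ala: a for Val, b for Leu/Ile."""

    a: float
    b: float


@dataclass(frozen=True)
class ConstantTables:
    """Bundle of every fixed table, as loaded from one constants file."""

    masses: MassTable
    atoms: AtomTable
    pks: PKSet
    hydropathy: HydropathyScale
    aliphatic: AliphaticCoefficients
    atomic_weights: Mapping[str, float] = field(default_factory=dict)


def _frozen(d: dict) -> Mapping:
    return MappingProxyType(dict(d))


def load_tables(source: str | Path | None = None) -> ConstantTables:
    """Load constant tables from a TOML file (packaged default if None)."""
    if source is None:
        text = (resources.files("protprops") / "data" / "constants.toml").read_text()
    else:
        text = Path(source).read_text()
    raw = tomllib.loads(text)
    return ConstantTables(
        masses=MassTable(
            residue_mass=_frozen(raw["masses"]["residues"]),
            water_mass=float(raw["masses"]["water"]),
        ),
        atoms=AtomTable(
            residue_atoms=_frozen(
                {r: _frozen(counts) for r, counts in raw["atoms"]["residues"].items()}
            ),
        ),
        pks=PKSet(pk=_frozen(raw["pk"]), sign=_frozen(raw["pk_sign"])),
        hydropathy=HydropathyScale(kd=_frozen(raw["hydropathy"])),
        aliphatic=AliphaticCoefficients(
            a=float(raw["aliphatic"]["a"]), b=float(raw["aliphatic"]["b"])
        ),
        atomic_weights=_frozen(raw["atomic_weights"]),
    )


DEFAULT_TABLES: ConstantTables = load_tables()


def elemental_mass(atoms: Mapping[str, int],
                   weights: Mapping[str, float] | None = None) -> float:
    """Mass of an atom-count vector from standard atomic weights (Da)."""
    if weights is None:
        weights = DEFAULT_TABLES.atomic_weights
    return sum(count * weights[el] for el, count in atoms.items())


def validate_tables(tables: ConstantTables | None = None) -> list[str]:
    """Check every internal-consistency invariant; return the violations.

    An empty list means the tables are consistent.  Checks: 20 canonical
    entries per table, positive masses, water mass near 18.015 Da, N >= 1
    and C >= 2 per residue, sulfur only in Cys/Met, the nine pK groups with
    their acid/base split, hydropathy extremes at Ile and Arg, the exact
    aliphatic coefficients, and the cross-table constraint that
    residue_mass + water agrees with the elemental mass of the free amino
    acid to within 0.01 Da.
    """
    t = tables if tables is not None else DEFAULT_TABLES
    problems: list[str] = []
    canonical = set(CANONICAL_ORDER)

    got = set(t.masses.residue_mass)
    if got != canonical:
        problems.append(f"MassTable residues {sorted(got ^ canonical)} mismatch canonical set")
    for r, m in t.masses.residue_mass.items():
        if not m > 0:
            problems.append(f"MassTable: non-positive mass for {r} ({m})")
    if not 18.0 < t.masses.water_mass < 18.1:
        problems.append(f"MassTable: water mass {t.masses.water_mass} outside (18.0, 18.1)")

    got = set(t.atoms.residue_atoms)
    if got != canonical:
        problems.append(f"AtomTable residues {sorted(got ^ canonical)} mismatch canonical set")
    for r, counts in t.atoms.residue_atoms.items():
        if any(c < 0 for c in counts.values()):
            problems.append(f"AtomTable: negative count for {r}")
        if counts.get("N", 0) < 1 or counts.get("C", 0) < 2:
            problems.append(f"AtomTable: {r} must have N >= 1 and C >= 2")
        if counts.get("S", 0) > 0 and r not in ("C", "M"):
            problems.append(f"AtomTable: sulfur in {r} (only Cys/Met carry S)")

    groups = {"Nterm", "Cterm", "D", "E", "C", "Y", "H", "K", "R"}
    if set(t.pks.pk) != groups:
        problems.append(f"PKSet groups {sorted(set(t.pks.pk) ^ groups)} mismatch required set")
    for g, v in t.pks.pk.items():
        if not 0 < v < 14:
            problems.append(f"PKSet: pK of {g} ({v}) outside (0, 14)")
    if set(t.pks.acidic) != {"Cterm", "D", "E", "C", "Y"}:
        problems.append("PKSet: acidic groups must be {Cterm, Asp, Glu, Cys, Tyr}")
    if set(t.pks.basic) != {"Nterm", "H", "K", "R"}:
        problems.append("PKSet: basic groups must be {Nterm, His, Lys, Arg}")

    got = set(t.hydropathy.kd)
    if got != canonical:
        problems.append(f"HydropathyScale residues {sorted(got ^ canonical)} mismatch")
    else:
        if max(t.hydropathy.kd, key=t.hydropathy.kd.get) != "I":
            problems.append("HydropathyScale: maximum must be Ile")
        if min(t.hydropathy.kd, key=t.hydropathy.kd.get) != "R":
            problems.append("HydropathyScale: minimum must be Arg")
    for r, v in t.hydropathy.kd.items():
        if not -4.5 <= v <= 4.5:
            problems.append(f"HydropathyScale: {r} value {v} outside [-4.5, 4.5]")

    if t.aliphatic.a != 2.9:
        problems.append(f"AliphaticCoefficients: a = {t.aliphatic.a}, expected 2.9")
    if t.aliphatic.b != 3.9:
        problems.append(f"AliphaticCoefficients: b = {t.aliphatic.b}, expected 3.9")

    # Cross-table: residue mass + water vs elemental mass of the free
    # amino acid (residue atoms + H2O) from standard atomic weights.
    if t.atomic_weights:
        for r in sorted(canonical & set(t.masses.residue_mass) & set(t.atoms.residue_atoms)):
            free = dict(t.atoms.residue_atoms[r])
            free["H"] = free.get("H", 0) + 2
            free["O"] = free.get("O", 0) + 1
            expected = elemental_mass(free, t.atomic_weights)
            actual = t.masses.residue_mass[r] + t.masses.water_mass
            if abs(actual - expected) >= 0.01:
                problems.append(
                    f"cross-table: {r} mass {actual:.4f} vs elemental {expected:.4f} "
                    f"(|diff| >= 0.01 Da)"
                )
    return problems
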