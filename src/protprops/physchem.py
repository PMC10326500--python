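"""Physicochemical property computations for protein sequences.

Implements the classic ProtParam-style parameter set: residue composition
(counts and mole percents), average molecular weight, Henderson-Hasselbalch
net charge and theoretical pI by bisection, C/H/N/O/S atomic composition
with molecular formula, charged-residue counts, the Ikai aliphatic index

    AI = X(Ala) + a * X(Val) + b * (X(Ile) + X(Leu)),    a = 2.9, b = 3.9,

with X(.) in mole percent, and GRAVY (the mean Kyte-Doolittle hydropathy).

Ambiguity policy: B and Z contribute the mean of their two candidate
masses to molecular weight (flagged approximate); X makes the mass
undefined; any of B/X/Z makes atomic composition and GRAVY unavailable.
:func:`compute_report` converts these errors into explicit "unavailable"
fields rather than failing the whole report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .constants import (
    CANONICAL_ORDER,
    ELEMENTS,
    AliphaticCoefficients,
    AtomTable,
    ConstantTables,
    DEFAULT_TABLES,
    HydropathyScale,
    MassTable,
    PKSet,
)
from .sequence import AMBIGUOUS, ProteinSequence

#: Candidate residues behind each two-way ambiguity code.
_AMBIGUITY_CANDIDATES = {"B": ("N", "D"), "Z": ("Q", "E")}


class AmbiguityError(ValueError):
    """A property is undefined because ambiguous residues are present."""

    def __init__(self, quantity: str, codes: set[str]):
        self.quantity = quantity
        self.codes = codes
        super().__init__(
            f"{quantity} undefined: ambiguous residue(s) {''.join(sorted(codes))} present"
        )


class MassUndefinedError(AmbiguityError):
    """Molecular weight is undefined (unspecified residue X present)."""

    def __init__(self) -> None:
        super().__init__("molecular weight", {"X"})


@dataclass(frozen=True)
class CompositionProfile:
    """Residue counts and mole percents (100 x mole fraction) of a sequence.

    Every canonical residue has an entry (zero when absent); ambiguity
    codes appear only when present in the sequence.
    """

    counts: Mapping[str, int]
    length: int
    mole_percent: Mapping[str, float]

    def residues_present(self) -> tuple[str, ...]:
        """Residues with nonzero count, canonical order then B/X/Z."""
        order = CANONICAL_ORDER + AMBIGUOUS
        return tuple(r for r in order if self.counts.get(r, 0) > 0)


@dataclass(frozen=True)
class AtomicComposition:
    """C/H/N/O/S atom counts, molecular formula and total atom count."""

    atoms: Mapping[str, int]
    formula: str
    total_atoms: int


@dataclass(frozen=True)
class PhysChemReport:
    """The full property bundle for one sequence.

    Properties that are undefined for an ambiguous sequence are ``None``
    with a human-readable reason in :attr:`unavailable`.
    """

    sequence: ProteinSequence
    n_residues: int
    composition: CompositionProfile
    n_negative: int
    n_positive: int
    theoretical_pi: float
    aliphatic_index: float
    molecular_weight: float | None
    atomic: AtomicComposition | None
    gravy: float | None
    ambiguous: bool
    mass_approximate: bool = False
    unavailable: Mapping[str, str] = field(default_factory=dict)


def residue_composition(seq: ProteinSequence) -> CompositionProfile:
    """Count each residue and convert to mole percent of chain length."""
    counts = Counter(seq.residues)
    n = len(seq)
    full = {r: counts.get(r, 0) for r in CANONICAL_ORDER}
    for code in AMBIGUOUS:
        if counts.get(code, 0):
            full[code] = counts[code]
    percent = {r: 100.0 * c / n for r, c in full.items()}
    return CompositionProfile(
        counts=MappingProxyType(full),
        length=n,
        mole_percent=MappingProxyType(percent),
    )


def molecular_weight(seq: ProteinSequence, masses: MassTable | None = None) -> float:
    """Average molecular weight: sum of residue masses plus one water (Da).

    B and Z use the arithmetic mean of their candidate residue masses;
    X raises :class:`MassUndefinedError`.
    """
    if masses is None:
        masses = DEFAULT_TABLES.masses
    if seq.has_unspecified:
        raise MassUndefinedError()
    total = 0.0
    for ch in seq.residues:
        if ch in _AMBIGUITY_CANDIDATES:
            a, b = _AMBIGUITY_CANDIDATES[ch]
            total += (masses.residue_mass[a] + masses.residue_mass[b]) / 2.0
        else:
            total += masses.residue_mass[ch]
    return total + masses.water_mass


def net_charge(seq: ProteinSequence, pH: float, pks: PKSet | None = None) -> float:
    """Modeled net charge (elementary charges) at a given pH.

    Henderson-Hasselbalch partial charges: each basic group g contributes
    ``+n_g / (1 + 10**(pH - pK_g))`` and each acidic group
    ``-n_g / (1 + 10**(pK_g - pH))``; both termini count once.  Strictly
    decreasing in pH.  Ambiguity codes carry no ionizable side chain.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be within [0, 14], got {pH}")
    if pks is None:
        pks = DEFAULT_TABLES.pks
    counts = Counter(seq.residues)
    charge = 0.0
    for group in pks.pk:
        n = 1 if group in ("Nterm", "Cterm") else counts.get(group, 0)
        if n == 0:
            continue
        pk = pks.pk[group]
        if pks.sign[group] == "basic":
            charge += n / (1.0 + 10.0 ** (pH - pk))
        else:
            charge -= n / (1.0 + 10.0 ** (pk - pH))
    return charge


def theoretical_pi(
    seq: ProteinSequence,
    pks: PKSet | None = None,
    tolerance: float = 1e-4,
) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14].

    The charge is continuous and strictly decreasing in pH and, with both
    termini always present, spans zero, so bisection always converges.
    Terminates when |charge| <= tolerance or the bracket is narrower than
    ``tolerance``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(seq, mid, pks)
        if abs(q) <= tolerance or (hi - lo) <= tolerance:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def _render_formula(atoms: Mapping[str, int]) -> str:
    """Formula in C, H, N, O, S order, count suffix omitted when 1."""
    parts = []
    for el in ELEMENTS:
        c = atoms.get(el, 0)
        if c == 0:
            continue
        parts.append(el if c == 1 else f"{el}{c}")
    return "".join(parts)


def atomic_composition(
    seq: ProteinSequence, atoms: AtomTable | None = None
) -> AtomicComposition:
    """Per-element atom counts of the chain plus one water (H2, O1).

    Undefined for sequences containing B, X or Z (their elemental makeup
    cannot be resolved), in which case :class:`AmbiguityError` is raised.
    """
    if atoms is None:
        atoms = DEFAULT_TABLES.atoms
    if seq.has_ambiguous:
        codes = {c for c in seq.residues if c in AMBIGUOUS}
        raise AmbiguityError("atomic composition", codes)
    totals = {el: 0 for el in ELEMENTS}
    for ch in seq.residues:
        for el, c in atoms.residue_atoms[ch].items():
            totals[el] += c
    totals["H"] += 2
    totals["O"] += 1
    return AtomicComposition(
        atoms=MappingProxyType(totals),
        formula=_render_formula(totals),
        total_atoms=sum(totals.values()),
    )


def charged_residue_counts(seq: ProteinSequence) -> tuple[int, int]:
    """(negative, positive) residue counts: Asp+Glu and Arg+Lys.

    Histidine is deliberately excluded from the positive count.
    """
    counts = Counter(seq.residues)
    n_negative = counts.get("D", 0) + counts.get("E", 0)
    n_positive = counts.get("R", 0) + counts.get("K", 0)
    return n_negative, n_positive


def aliphatic_index(
    profile: CompositionProfile,
    coeffs: AliphaticCoefficients | None = None,
) -> float:
    """Ikai aliphatic index from mole percents; range [0, 390]."""
    if coeffs is None:
        coeffs = DEFAULT_TABLES.aliphatic
    x = profile.mole_percent
    return (
        x.get("A", 0.0)
        + coeffs.a * x.get("V", 0.0)
        + coeffs.b * (x.get("I", 0.0) + x.get("L", 0.0))
    )


def gravy(seq: ProteinSequence, scale: HydropathyScale | None = None) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value.

    Undefined when B, X or Z are present (no hydropathy value exists and
    silently dropping residues would change the denominator).
    """
    if scale is None:
        scale = DEFAULT_TABLES.hydropathy
    if seq.has_ambiguous:
        codes = {c for c in seq.residues if c in AMBIGUOUS}
        raise AmbiguityError("GRAVY", codes)
    return sum(scale.kd[ch] for ch in seq.residues) / len(seq)


def compute_report(
    seq: ProteinSequence, tables: ConstantTables | None = None
) -> PhysChemReport:
    """Assemble every property into a report with partial-result semantics.

    Length, composition, charged counts, pI and aliphatic index are always
    computed.  Molecular weight (when X present), atomic composition and
    GRAVY (when any of B/X/Z present) are recorded as unavailable with a
    reason instead of failing the report.
    """
    t = tables if tables is not None else DEFAULT_TABLES
    profile = residue_composition(seq)
    n_neg, n_pos = charged_residue_counts(seq)
    unavailable: dict[str, str] = {}

    mw: float | None = None
    mass_approx = False
    try:
        mw = molecular_weight(seq, t.masses)
        mass_approx = any(c in "BZ" for c in seq.residues)
    except MassUndefinedError as e:
        unavailable["molecular_weight"] = str(e)

    atomic: AtomicComposition | None = None
    try:
        atomic = atomic_composition(seq, t.atoms)
    except AmbiguityError as e:
        unavailable["atomic"] = str(e)

    gravy_value: float | None = None
    try:
        gravy_value = gravy(seq, t.hydropathy)
    except AmbiguityError as e:
        unavailable["gravy"] = str(e)

    return PhysChemReport(
        sequence=seq,
        n_residues=len(seq),
        composition=profile,
        n_negative=n_neg,
        n_positive=n_pos,
        theoretical_pi=theoretical_pi(seq, t.pks),
        aliphatic_index=aliphatic_index(profile, t.aliphatic),
        molecular_weight=mw,
        atomic=atomic,
        gravy=gravy_value,
        ambiguous=seq.has_ambiguous,
        mass_approximate=mass_approx,
        unavailable=MappingProxyType(unavailable),
    )
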