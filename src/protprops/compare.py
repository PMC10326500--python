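"""Two-protein comparison: thermostability and hydrophobicity verdicts.

Thermostability is ordered by aliphatic index, hydrophobicity by GRAVY.
Each verdict is rendered as a relational symbol ('>', '<' or '=' on a
tie), matching the head-to-head comparison panel of the original tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .constants import CANONICAL_ORDER
from .physchem import CompositionProfile, PhysChemReport

Verdict = Literal["first", "second", "tie"]

_SYMBOL = {"first": ">", "second": "<", "tie": "="}


class IncomparableError(ValueError):
    """A required quantity is missing from one of the reports."""

    def __init__(self, which: str, quantity: str):
        super().__init__(
            f"cannot compare: {quantity} unavailable for {which} protein "
            f"(ambiguous sequence)"
        )


@dataclass(frozen=True)
class ComparisonResult:
    """Two reports plus thermostability and hydrophobicity verdicts."""

    report_1: PhysChemReport
    report_2: PhysChemReport
    thermostability_verdict: Verdict
    hydrophobicity_verdict: Verdict
    symbols: tuple[str, str]


def _verdict(v1: float, v2: float, tolerance: float) -> Verdict:
    if abs(v1 - v2) <= tolerance:
        return "tie"
    return "first" if v1 > v2 else "second"


def compare_reports(
    r1: PhysChemReport,
    r2: PhysChemReport,
    tolerance: float = 1e-9,
) -> ComparisonResult:
    """Decide which protein is more thermostable and more hydrophobic.

    Raises :class:`IncomparableError` when either report lacks GRAVY
    (ambiguous sequence); differences within ``tolerance`` are ties.
    """
    for which, r in (("first", r1), ("second", r2)):
        if r.gravy is None:
            raise IncomparableError(which, "GRAVY")
    thermo = _verdict(r1.aliphatic_index, r2.aliphatic_index, tolerance)
    hydro = _verdict(r1.gravy, r2.gravy, tolerance)
    return ComparisonResult(
        report_1=r1,
        report_2=r2,
        thermostability_verdict=thermo,
        hydrophobicity_verdict=hydro,
        symbols=(_SYMBOL[thermo], _SYMBOL[hydro]),
    )


def composition_delta(
    p1: CompositionProfile, p2: CompositionProfile
) -> list[tuple[str, float, float, float]]:
    """Per-residue mole-percent differences over the canonical 20 residues.

    Returns (residue, percent_1, percent_2, percent_1 - percent_2) in the
    alphabetical three-letter-code order (Ala ... Val).  Residue percent
    sums are both 100, so the deltas sum to zero.
    """
    out = []
    for r in CANONICAL_ORDER:
        a = p1.mole_percent.get(r, 0.0)
        b = p2.mole_percent.get(r, 0.0)
        out.append((r, a, b, a - b))
    return out
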