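"""Plain-text and TSV rendering of computed property reports.

Numeric conventions: molecular weight, pI and aliphatic index to 2
decimals, GRAVY to 3, composition percents to 1 (full precision is kept
internally; rounding happens only here).  Unavailable quantities are
rendered explicitly ("unavailable: <reason>" in text, "NA" in TSV) —
never silently omitted.  Rendering is deterministic: identical inputs
produce byte-identical documents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .compare import ComparisonResult
from .constants import CANONICAL_ORDER, ELEMENTS, THREE_LETTER
from .physchem import PhysChemReport
from .sequence import AMBIGUOUS, chunk_sequence

_ELEMENT_NAMES = {
    "C": "Carbon", "H": "Hydrogen", "N": "Nitrogen",
    "O": "Oxygen", "S": "Sulfur",
}

TSV_COLUMNS = (
    "id", "n_residues", "mw", "pi", "n_negative", "n_positive",
    "aliphatic_index", "gravy", "formula", "total_atoms", "ambiguous",
)


@dataclass(frozen=True)
class ReportDocument:
    """A rendered text report with its ordered section names."""

    text: str
    sections: tuple[str, ...]


def _composition_rows(report: PhysChemReport) -> list[str]:
    rows = []
    order = CANONICAL_ORDER + AMBIGUOUS
    for r in order:
        count = report.composition.counts.get(r)
        if count is None:
            continue  # ambiguity codes absent from the sequence
        pct = report.composition.mole_percent[r]
        rows.append(f"{THREE_LETTER[r]:<4} {count:>6} {pct:>7.1f}")
    return rows


def _protein_section(report: PhysChemReport, label: str) -> list[str]:
    lines: list[str] = []
    name = report.sequence.seq_id or "(unnamed)"
    lines.append(f"{label}: {name}")
    lines.append("")
    lines.append("Sequence (blocks of 10):")
    view = chunk_sequence(report.sequence, 10)
    for i in range(0, len(view.blocks), 6):
        offset = i * view.block_width + 1
        lines.append(f"  {offset:>6}  " + " ".join(view.blocks[i:i + 6]))
    lines.append("")
    lines.append(f"Number of amino acids: {report.n_residues}")
    if report.molecular_weight is not None:
        approx = " (approximate: B/Z averaged)" if report.mass_approximate else ""
        lines.append(f"Molecular weight: {report.molecular_weight:.2f} Da{approx}")
    else:
        lines.append(
            f"Molecular weight: unavailable: {report.unavailable['molecular_weight']}"
        )
    lines.append(f"Theoretical pI: {report.theoretical_pi:.2f}")
    lines.append("")
    lines.append("Amino acid composition (residue, count, mole percent):")
    lines.extend("  " + row for row in _composition_rows(report))
    lines.append("")
    lines.append(
        f"Total number of negatively charged residues (Asp + Glu): {report.n_negative}"
    )
    lines.append(
        f"Total number of positively charged residues (Arg + Lys): {report.n_positive}"
    )
    lines.append("")
    if report.atomic is not None:
        lines.append("Atomic composition (atom, symbol, count):")
        for el in ELEMENTS:
            lines.append(
                f"  {_ELEMENT_NAMES[el]:<9} {el:>2} {report.atomic.atoms[el]:>8}"
            )
        lines.append(f"Formula: {report.atomic.formula}")
        lines.append(f"Total number of atoms: {report.atomic.total_atoms}")
    else:
        lines.append(f"Atomic composition: unavailable: {report.unavailable['atomic']}")
        lines.append("Formula: unavailable: ambiguous residues")
        lines.append("Total number of atoms: unavailable: ambiguous residues")
    lines.append("")
    lines.append(f"Aliphatic index: {report.aliphatic_index:.2f}")
    if report.gravy is not None:
        lines.append(f"GRAVY: {report.gravy:.3f}")
    else:
        lines.append(f"GRAVY: unavailable: {report.unavailable['gravy']}")
    return lines


def _comparison_section(cmp: ComparisonResult) -> list[str]:
    s_thermo, s_hydro = cmp.symbols
    return [
        "Comparison:",
        f"  Thermostability (aliphatic index): Protein-1 {s_thermo} Protein-2",
        f"  Hydrophobicity (GRAVY):            Protein-1 {s_hydro} Protein-2",
    ]


def render_text_report(
    reports: Sequence[PhysChemReport],
    comparison: ComparisonResult | None = None,
) -> ReportDocument:
    """Render one or two reports (plus an optional comparison) as text."""
    if not 1 <= len(reports) <= 2:
        raise ValueError("render_text_report takes one or two reports")
    if comparison is not None and len(reports) != 2:
        raise ValueError("a comparison requires exactly two reports")

    sections: list[str] = []
    lines: list[str] = []
    for i, rep in enumerate(reports, start=1):
        label = f"Protein-{i}" if len(reports) == 2 else "Protein"
        lines.extend(_protein_section(rep, label))
        lines.append("")
        sections.append(label)
    if comparison is not None:
        lines.extend(_comparison_section(comparison))
        lines.append("")
        sections.append("Comparison")
    return ReportDocument(text="\n".join(lines), sections=tuple(sections))


def _tsv_row(report: PhysChemReport, index: int) -> list[str]:
    def na(value: str | None) -> str:
        return value if value is not None else "NA"

    return [
        report.sequence.seq_id or f"seq{index}",
        str(report.n_residues),
        na(f"{report.molecular_weight:.2f}" if report.molecular_weight is not None else None),
        f"{report.theoretical_pi:.2f}",
        str(report.n_negative),
        str(report.n_positive),
        f"{report.aliphatic_index:.2f}",
        na(f"{report.gravy:.3f}" if report.gravy is not None else None),
        na(report.atomic.formula if report.atomic is not None else None),
        na(str(report.atomic.total_atoms) if report.atomic is not None else None),
        "yes" if report.ambiguous else "no",
    ]


def render_tsv(reports: Sequence[PhysChemReport]) -> str:
    """Render reports as tab-separated text, one row per sequence."""
    if not reports:
        raise ValueError("no reports to render")
    lines = ["\t".join(TSV_COLUMNS)]
    for i, rep in enumerate(reports, start=1):
        lines.append("\t".join(_tsv_row(rep, i)))
    return "\n".join(lines) + "\n"
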