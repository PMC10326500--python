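"""Chart rendering: composition bar chart, atomic pie chart, two-protein
overlay line plot and the '>'/'<' verdict panel, all written as PNG files.

Every plotting operation returns the computed plot data (bar heights,
wedge percentages, series values) alongside writing the image, so tests
assert on numbers rather than pixels.  With fixed raster parameters the
rendering is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .compare import ComparisonResult
from .constants import CANONICAL_ORDER, ELEMENTS, THREE_LETTER
from .physchem import AtomicComposition, CompositionProfile
from .sequence import AMBIGUOUS


class PlotUnavailableError(ValueError):
    """The requested chart is undefined for this input."""


@dataclass(frozen=True)
class ChartSpec:
    """Raster parameters and destination for one chart."""

    kind: str
    output_path: str | Path
    title: str = ""
    dpi: int = 100
    figsize: tuple[float, float] = (8.0, 5.0)

    def __post_init__(self) -> None:
        if not str(self.output_path).endswith(".png"):
            raise ValueError("output_path must end in .png")


@dataclass(frozen=True)
class PlotData:
    """The numbers behind a rendered chart."""

    kind: str
    labels: tuple[str, ...]
    series: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    text: tuple[str, ...] = ()


def _save(fig, spec: ChartSpec) -> None:
    fig.savefig(spec.output_path, dpi=spec.dpi)
    plt.close(fig)


def plot_aa_composition(profile: CompositionProfile, spec: ChartSpec) -> PlotData:
    """Bar chart of residue counts over the canonical 20-residue axis.

    Ambiguity codes present in the sequence are appended after the
    canonical residues.
    """
    order = [r for r in CANONICAL_ORDER] + [
        r for r in AMBIGUOUS if profile.counts.get(r, 0) > 0
    ]
    labels = tuple(THREE_LETTER[r] for r in order)
    heights = tuple(float(profile.counts.get(r, 0)) for r in order)

    fig, ax = plt.subplots(figsize=spec.figsize)
    ax.bar(range(len(order)), heights, color="steelblue")
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(labels, rotation=90, fontsize=8)
    ax.set_ylabel("Number of residues")
    ax.set_title(spec.title or "AMINO ACID COMPOSITION")
    fig.tight_layout()
    _save(fig, spec)
    return PlotData(kind="aa_bar", labels=labels, series={"counts": heights})


def plot_atomic_composition(atomic: AtomicComposition | None, spec: ChartSpec) -> PlotData:
    """Pie chart of C/H/N/O/S percentages with 1-decimal labels.

    Zero-count elements are omitted from the pie (a zero-area wedge with a
    label is unreadable) but listed in the legend with 0.0%.  Passing
    ``None`` (the ambiguous-sequence case) raises
    :class:`PlotUnavailableError`.
    """
    if atomic is None:
        raise PlotUnavailableError(
            "atomic composition plot unavailable: ambiguous residues present"
        )
    total = atomic.total_atoms
    percentages = tuple(100.0 * atomic.atoms[el] / total for el in ELEMENTS)
    nonzero = [(el, p) for el, p in zip(ELEMENTS, percentages) if p > 0]

    fig, ax = plt.subplots(figsize=spec.figsize)
    ax.pie(
        [p for _, p in nonzero],
        labels=[el for el, _ in nonzero],
        autopct="%0.1f%%",
        startangle=90,
        counterclock=False,
    )
    legend_labels = [f"{el}: {p:.1f}%" for el, p in zip(ELEMENTS, percentages)]
    ax.legend(legend_labels, loc="center left", bbox_to_anchor=(1.0, 0.5))
    ax.set_title(spec.title or "ATOMIC COMPOSITION")
    fig.tight_layout()
    _save(fig, spec)
    return PlotData(
        kind="atomic_pie",
        labels=ELEMENTS,
        series={"percent": percentages},
        text=tuple(f"{p:.1f}" for p in percentages),
    )


def plot_composition_overlay(
    delta: Sequence[tuple[str, float, float, float]], spec: ChartSpec
) -> PlotData:
    """Overlaid line plot of two composition profiles (mole percent)."""
    labels = tuple(THREE_LETTER[r] for r, *_ in delta)
    series1 = tuple(p1 for _, p1, _, _ in delta)
    series2 = tuple(p2 for _, _, p2, _ in delta)

    fig, ax = plt.subplots(figsize=spec.figsize)
    x = range(len(labels))
    ax.plot(x, series1, marker="o", label="Protein-1", color="tab:blue")
    ax.plot(x, series2, marker="s", linestyle="--", label="Protein-2",
            color="tab:orange")
    ax.set_xticks(list(x))
    ax.set_xticklabels(labels, rotation=90, fontsize=8)
    ax.set_ylabel("Mole percent")
    ax.set_title(spec.title or "AMINO ACID COMPOSITION COMPARISON")
    ax.legend()
    fig.tight_layout()
    _save(fig, spec)
    return PlotData(
        kind="overlay_line",
        labels=labels,
        series={"protein_1": series1, "protein_2": series2},
    )


def render_verdict_panel(cmp: ComparisonResult, spec: ChartSpec) -> PlotData:
    """Panel showing the thermostability and hydrophobicity verdicts.

    Two rows, each reading ``Protein-1 <symbol> Protein-2`` with the
    symbol drawn from {>, <, =}; drawn programmatically rather than by
    editing a template image.
    """
    s_thermo, s_hydro = cmp.symbols
    rows = (
        f"Thermostability (aliphatic index):  Protein-1  {s_thermo}  Protein-2",
        f"Hydrophobicity (GRAVY):  Protein-1  {s_hydro}  Protein-2",
    )
    fig, ax = plt.subplots(figsize=spec.figsize)
    ax.axis("off")
    ax.set_title(spec.title or "COMPARISON", fontsize=14)
    for i, row in enumerate(rows):
        ax.text(0.5, 0.65 - 0.3 * i, row, ha="center", va="center", fontsize=12)
    _save(fig, spec)
    return PlotData(kind="verdict_panel", labels=("thermostability", "hydrophobicity"),
                    text=(s_thermo, s_hydro))
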