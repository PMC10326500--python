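"""Seeded synthetic sequence generation for tests and demonstrations.

A single explicit pseudo-random source (numpy PCG64) per generator call;
no global random state.  Defaults sample uniformly over the 20 canonical
residues with no ambiguity codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import CANONICAL_ORDER
from .sequence import AMBIGUOUS, ProteinSequence


@dataclass(frozen=True)
class SequenceGeneratorConfig:
    """Parameters of the synthetic sequence sampler.

    ``length`` is either an exact residue count or an inclusive
    (low, high) range; ``weights`` are per-residue sampling weights over
    the canonical alphabet (uniform when omitted); ``ambiguous_rate`` is
    the per-position probability of replacement by a random B/X/Z.
    """

    length: int | tuple[int, int] = 100
    weights: Mapping[str, float] | None = None
    ambiguous_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ambiguous_rate <= 1.0:
            raise ValueError("ambiguous_rate must be within [0, 1]")
        if self.weights is not None:
            vals = [self.weights.get(r, 0.0) for r in CANONICAL_ORDER]
            if any(v < 0 for v in vals) or sum(vals) <= 0:
                raise ValueError("weights must be non-negative and not all zero")


def random_sequence(config: SequenceGeneratorConfig, seq_id: str = "") -> ProteinSequence:
    """Draw one sequence per the config; identical config => identical output."""
    rng = np.random.default_rng(config.seed)
    if isinstance(config.length, tuple):
        lo, hi = config.length
        if lo < 1:
            raise ValueError("length must be >= 1")
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(config.length)
        if n < 1:
            raise ValueError("length must be >= 1")

    letters = list(CANONICAL_ORDER)
    if config.weights is None:
        p = None
    else:
        raw = np.array([config.weights.get(r, 0.0) for r in letters], dtype=float)
        p = raw / raw.sum()
    chars = rng.choice(letters, size=n, p=p)
    if config.ambiguous_rate > 0:
        mask = rng.random(n) < config.ambiguous_rate
        codes = rng.choice(list(AMBIGUOUS), size=n)
        chars = np.where(mask, codes, chars)
    return ProteinSequence(seq_id=seq_id, residues="".join(chars))


def random_record_set(n: int, seed: int,
                      length: tuple[int, int] = (1, 500)) -> list[ProteinSequence]:
    """n independent unambiguous sequences with unique ids, one shared seed."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        cfg = SequenceGeneratorConfig(length=length, seed=sub)
        out.append(random_sequence(cfg, seq_id=f"rand{i:03d}"))
    return out


#: (id, residues) pairs for the small worked examples used throughout the
#: documentation and tests: homopolymers with closed-form aliphatic index
#: and GRAVY, charged 10-mers with known pI behaviour, the full canonical
#: alphabet, and one ambiguous sequence.
_WORKED_EXAMPLES: tuple[tuple[str, str], ...] = (
    ("gly1", "G"),
    ("aag", "AAG"),
    ("tetra_ala", "AAAA"),
    ("tetra_val", "VVVV"),
    ("avil", "AVIL"),
    ("tetra_ile", "IIII"),
    ("tetra_arg", "RRRR"),
    ("ile_arg", "IR"),
    ("dekr", "DEKR"),
    ("ambiguous_axa", "AXA"),
    ("all20", "ACDEFGHIKLMNPQRSTVWY"),
    ("deca_lys", "KKKKKKKKKK"),
    ("deca_asp", "DDDDDDDDDD"),
)


def worked_example_set() -> list[ProteinSequence]:
    """The fixed example sequences, with stable unique ids."""
    return [ProteinSequence(seq_id=i, residues=s) for i, s in _WORKED_EXAMPLES]


def worked_example(name: str) -> ProteinSequence:
    """Look up one worked example by id."""
    for rec in worked_example_set():
        if rec.seq_id == name:
            return rec
    raise KeyError(name)
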