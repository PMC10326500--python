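# Methods

## Scope and model

`protprops` computes sequence-derived physicochemical properties of
proteins from the primary sequence alone. Everything is a function of the
residue multiset (plus the two chain termini): no structure, no
post-translational modification, no disulfide state. Cysteines are
treated as reduced free thiols for the charge model; masses are average
isotopic, not monoisotopic.

### Constants

All numeric tables live in `src/protprops/data/constants.toml` and are
loaded read-only; `validate_tables()` checks every internal invariant and
is itself under test, so a swapped-in alternative table set is vetted by
the same machinery.

- **Residue masses** (Da, average isotopic): the standard table used by
  the ExPASy-family calculators (Gly 57.0519 … Trp 186.2132; water
  18.01524). Chain mass = Σ residue masses + one water.
- **Atom counts**: per-residue C/H/N/O/S of the amino acid minus one
  water; the chain total adds back H₂O.
- **pK values** (Bjellqvist-style, from polypeptide migration in
  immobilized pH gradients): C-terminus 3.55, Asp 4.05, Glu 4.45,
  His 5.98, N-terminus 7.50, Cys 9.00, Tyr 10.00, Lys 10.00, Arg 12.00.
  A single N-terminal pK is used for every residue type; residue-specific
  N-terminal pKs (as in some ExPASy implementations) are a documented
  alternative that would shift pI by at most a few hundredths for typical
  sequences.
- **Hydropathy**: the Kyte–Doolittle 1982 scale (Ile +4.5 … Arg −4.5).
- **Aliphatic coefficients**: a = 2.9 (Val), b = 3.9 (Leu/Ile), relative
  side-chain volumes against Ala.

The mass and atom tables are cross-validated against each other: for all
20 residues, residue mass + water must equal the free amino acid's
elemental mass from standard atomic weights (C 12.011, H 1.008, N 14.007,
O 15.999, S 32.06) within 0.01 Da.

### Charge model and pI

Net charge at a given pH is the sum of Henderson–Hasselbalch partial
charges over the nine ionizable group types; each basic group contributes
`+n/(1+10^(pH−pK))`, each acidic group `−n/(1+10^(pK−pH))`, with both
termini counting once. The function is continuous and strictly
decreasing in pH and, because the termini are always present, changes
sign on [0, 14]; the theoretical pI is found by bisection, terminating at
|charge| ≤ 1e−4 or bracket width ≤ 1e−4. Bisection was chosen over faster
root finders because convergence on a monotone function is unconditional
and the solver must never fail on adversarial compositions (e.g. 100%
His). For a sequence with no ionizable side chains the closed form is
pI = (pK_Nterm + pK_Cterm)/2 = 5.525, which the solver reproduces within
the bisection tolerance.

### Ambiguity policy

B (Asn/Asp), X (unspecified) and Z (Gln/Glu) are accepted on input.

- Molecular weight: B/Z use the arithmetic mean of the two candidate
  residue masses and the result is flagged approximate; X makes the mass
  undefined (an error at the function level, an explicit "unavailable"
  field at the report level).
- Atomic composition and GRAVY: undefined whenever any of B/X/Z is
  present. GRAVY errors rather than skipping the residues, because a
  silently changed denominator would be invisible to the caller.
- Charge/pI: ambiguity codes carry no ionizable side chain, so pI is
  always computed; for B/Z-rich sequences it should be read as the value
  for the uncharged-candidate interpretation (Asn/Gln).
- Composition and aliphatic index: always defined (ambiguity codes get
  their own composition entries and contribute to the denominator).

### Comparison

Thermostability is ordered by aliphatic index, hydrophobicity by GRAVY.
Differences within a tolerance (default 1e−9) are ties rendered as `=`;
otherwise `>`/`<`. Exact ties must exist (a protein compared with itself)
even though strict orderings are the common case. Comparison requires
GRAVY on both sides; an ambiguous sequence makes the pair incomparable
and the CLI degrades gracefully (per-protein artifacts and the
composition overlay are still produced, only the verdicts are skipped,
with a warning on stderr).

## Rendering conventions

Text reports print the sequence in 10-residue blocks, the composition
table as three-letter name / count / mole percent to 1 decimal
(alphabetical by three-letter code: Ala … Val), MW, pI and aliphatic
index to 2 decimals and GRAVY to 3; full precision is kept internally and
rounded only at this layer. Note that a column of 20 percentages each
rounded to 1 decimal can sum as far as ±0.05 per row from 100.0; tests
bound the drift by that per-row figure rather than a fixed constant.
Unavailable quantities render as `unavailable: <reason>` in text and `NA`
in the TSV. The TSV has a fixed 11-column header
(id … total_atoms, ambiguous).

Charts expose their computed data (bar heights, wedge percentages, series
values, verdict symbols) to callers; the PNG is a pure rendering of that
data, and tests assert on the numbers, not pixels. Pie wedges with zero
atoms (e.g. S in a Cys/Met-free protein) are omitted from the pie but
listed in the legend at 0.0%, since a zero-area labelled wedge is
unreadable. With fixed raster parameters rendering is deterministic
(byte-identical on rerun), which the end-to-end tests rely on.

## Synthetic data

The generator (`protprops.fixtures`) draws i.i.d. residues from a
configurable weight vector over the 20 canonical residues (uniform by
default), with an optional per-position ambiguity rate, from an
explicitly seeded numpy PCG64 stream; there is no global random state.
It emulates nothing about real proteomes — no organism-specific residue
frequencies, no length distribution, no local composition structure — so
passing tests demonstrate the correctness of the arithmetic and the
contracts on arbitrary sequences, not biological realism of any derived
statistic. Test batches use 100–1000 sequences of length 1–500, sizes at
which every property check runs in seconds.

## Numerical choices

- pI bisection tolerance 1e−4 on both the charge and the bracket; ≤ 200
  iterations (47 suffice for the width criterion).
- The aliphatic index is computed from mole percents as defined; an
  independent oracle computed from raw counts agrees only to the last few
  ulps (floating-point summation order), so oracle tests compare AI at
  relative 1e−12 while MW, atom counts and GRAVY — where the accumulation
  order is identical — are compared for exact equality.
- Formula rendering: C, H, N, O, S order, suffix omitted for count 1
  (`C2H5NO2`).
- Degenerate inputs: empty sequences are rejected at parse time with a
  positioned error; validation is strict by design even though permissive
  pasting (whitespace, digits, lowercase) is cleaned silently.

## Known limitations

- No instability index, extinction coefficient or half-life estimate; no
  hydropathy sliding-window profiles; single fixed hydropathy scale.
- The charge model ignores electrostatic interactions between groups,
  temperature, and ionic strength; theoretical pI routinely deviates from
  measured pI by a few tenths of a pH unit for real proteins.
- Comparison is defined for exactly two proteins; the TSV writer accepts
  lists, but no n-way ranking is offered.
- FASTA headers are taken verbatim as identifiers; no accession parsing
  or database lookup.
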