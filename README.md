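# protprops

Physicochemical property calculation and two-protein comparison for
amino-acid sequences, as a Python library and a command-line tool.

Given a protein's primary sequence in one-letter code (pasted text or a
FASTA file), `protprops` computes the classic parameter set used to
characterize proteins before any structural work:

- **Length and amino-acid composition** — per-residue counts and mole
  percents X(r) = 100 · n(r)/N.
- **Average molecular weight** — Σ residue masses + one water (average
  isotopic masses).
- **Theoretical pI** — the pH at which the modeled net charge is zero.
  Each ionizable group g (both termini plus the Asp, Glu, Cys, Tyr, His,
  Lys, Arg side chains) carries a Henderson–Hasselbalch partial charge,

      Q(pH) = Σ_basic n_g / (1 + 10^(pH − pK_g)) − Σ_acidic n_g / (1 + 10^(pK_g − pH)),

  which is strictly decreasing in pH; the root is found by bisection on
  [0, 14].
- **Atomic composition** — C/H/N/O/S counts, molecular formula and total
  atom count.
- **Charged-residue counts** — Asp+Glu (negative) and Arg+Lys (positive).
- **Aliphatic index** (Ikai) — a thermostability correlate of globular
  proteins,

      AI = X(Ala) + a·X(Val) + b·[X(Ile) + X(Leu)],  a = 2.9, b = 3.9.

- **GRAVY** — grand average of hydropathicity, the mean Kyte–Doolittle
  hydropathy over all residues (positive = hydrophobic).

Two sequences can be compared head to head: the tool decides which is
more thermostable (higher aliphatic index) and more hydrophobic (higher
GRAVY), renders the verdicts as `>`/`<`/`=`, and plots a composition
bar chart and atomic pie chart per protein plus an overlaid composition
line plot for the pair.

The 20 canonical residues plus the ambiguity codes B (Asn/Asp), X
(unspecified) and Z (Gln/Glu) are accepted. Ambiguous residues make
atomic composition and GRAVY undefined (reported explicitly as
unavailable, never silently skipped); B/Z molecular weights use the mean
of the two candidate masses and are flagged approximate; X makes the
mass undefined.

## Worked example

```sh
protprops compute AVILKDE --literal --id demo
```

prints (abridged):

```
Protein: demo

Number of amino acids: 7
Molecular weight: 786.92 Da
Theoretical pI: 4.37
...
Total number of negatively charged residues (Asp + Glu): 2
Total number of positively charged residues (Arg + Lys): 1
Formula: C35H62N8O12
Total number of atoms: 117
Aliphatic index: 167.14
GRAVY: 0.486
```

The pI of 4.37 reflects the excess of acidic side chains (2 Asp/Glu vs
1 Lys); the aliphatic index of 167.14 is 100·(1 + 2.9 + 3.9·2)/7, and the
GRAVY of 0.486 is the mean of the seven Kyte–Doolittle values — a mildly
hydrophobic peptide.

To compare two proteins and write every artifact (text report, TSV table,
six PNG charts):

```sh
protprops compare protein1.fasta protein2.fasta --out results/ --formats txt,tsv,png
```

Library use mirrors the CLI:

```python
from protprops import parse_sequence, compute_report, compare_reports

r1 = compute_report(parse_sequence("IIIIKKDDWW"))
r2 = compute_report(parse_sequence("GGGGSSTTYY"))
print(r1.theoretical_pi, r1.aliphatic_index, r1.gravy)
print(compare_reports(r1, r2).symbols)   # ('>', '>')
```

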