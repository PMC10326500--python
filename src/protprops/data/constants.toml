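# Numeric tables used by every property computation.
#
# Masses are average isotopic *residue* masses in daltons (free amino acid
# minus one water); chain mass = sum of residue masses + one water.
# Atom counts are per residue (amino acid minus one water).
# pK values are the Bjellqvist-style set derived from polypeptide migration
# in immobilized pH gradients; hydropathy is the Kyte-Doolittle 1982 scale.
# Aliphatic coefficients are the relative side-chain volumes of Val (a) and
# Leu/Ile (b) against Ala.
#
# Stored as data, not code, so tests can load deliberately mutated copies.

[masses]
water = 18.01524

[masses.residues]
A = 71.0788
R = 156.1875
N = 114.1038
D = 115.0886
C = 103.1388
E = 129.1155
Q = 128.1307
G = 57.0519
H = 137.1411
I = 113.1594
L = 113.1594
K = 128.1741
M = 131.1926
F = 147.1766
P = 97.1167
S = 87.0782
T = 101.1051
W = 186.2132
Y = 163.1760
V = 99.1326

[atoms.residues]
A = { C = 3, H = 5, N = 1, O = 1, S = 0 }
R = { C = 6, H = 12, N = 4, O = 1, S = 0 }
N = { C = 4, H = 6, N = 2, O = 2, S = 0 }
D = { C = 4, H = 5, N = 1, O = 3, S = 0 }
C = { C = 3, H = 5, N = 1, O = 1, S = 1 }
E = { C = 5, H = 7, N = 1, O = 3, S = 0 }
Q = { C = 5, H = 8, N = 2, O = 2, S = 0 }
G = { C = 2, H = 3, N = 1, O = 1, S = 0 }
H = { C = 6, H = 7, N = 3, O = 1, S = 0 }
I = { C = 6, H = 11, N = 1, O = 1, S = 0 }
L = { C = 6, H = 11, N = 1, O = 1, S = 0 }
K = { C = 6, H = 12, N = 2, O = 1, S = 0 }
M = { C = 5, H = 9, N = 1, O = 1, S = 1 }
F = { C = 9, H = 9, N = 1, O = 1, S = 0 }
P = { C = 5, H = 7, N = 1, O = 1, S = 0 }
S = { C = 3, H = 5, N = 1, O = 2, S = 0 }
T = { C = 4, H = 7, N = 1, O = 2, S = 0 }
W = { C = 11, H = 10, N = 2, O = 1, S = 0 }
Y = { C = 9, H = 9, N = 1, O = 2, S = 0 }
V = { C = 5, H = 9, N = 1, O = 1, S = 0 }

[pk]
Nterm = 7.50
Cterm = 3.55
D = 4.05
E = 4.45
C = 9.00
Y = 10.00
H = 5.98
K = 10.00
R = 12.00

[pk_sign]
Nterm = "basic"
Cterm = "acidic"
D = "acidic"
E = "acidic"
C = "acidic"
Y = "acidic"
H = "basic"
K = "basic"
R = "basic"

[hydropathy]
A = 1.8
R = -4.5
N = -3.5
D = -3.5
C = 2.5
Q = -3.5
E = -3.5
G = -0.4
H = -3.2
I = 4.5
L = 3.8
K = -3.9
M = 1.9
F = 2.8
P = -1.6
S = -0.8
T = -0.7
W = -0.9
Y = -1.3
V = 4.2

[aliphatic]
a = 2.9
b = 3.9

# Standard atomic weights (IUPAC conventional values), used only for the
# cross-table consistency check between masses and atom counts.
[atomic_weights]
C = 12.011
H = 1.008
N = 14.007
O = 15.999
S = 32.06
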