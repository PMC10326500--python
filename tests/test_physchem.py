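"""Property computations against closed forms and independent oracles."""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings, strategies as st

from protprops.constants import CANONICAL_ORDER, DEFAULT_TABLES, elemental_mass
from protprops.fixtures import SequenceGeneratorConfig, random_sequence
from protprops.physchem import (
    AmbiguityError,
    MassUndefinedError,
    aliphatic_index,
    atomic_composition,
    charged_residue_counts,
    compute_report,
    gravy,
    molecular_weight,
    net_charge,
    residue_composition,
    theoretical_pi,
)
from protprops.sequence import ProteinSequence

canonical_seqs = st.text(alphabet=list(CANONICAL_ORDER), min_size=1, max_size=120)


def _seq(s: str) -> ProteinSequence:
    return ProteinSequence("t", s)


# --- independent naive oracle: straight per-character accumulation ---------

def oracle_mw(s: str) -> float:
    t = DEFAULT_TABLES
    return sum(t.masses.residue_mass[c] for c in s) + t.masses.water_mass


def oracle_atoms(s: str) -> dict:
    t = DEFAULT_TABLES
    out = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}
    for c in s:
        for el, n in t.atoms.residue_atoms[c].items():
            out[el] += n
    return out


def oracle_ai(s: str) -> float:
    n = len(s)
    return 100.0 * (
        s.count("A") + 2.9 * s.count("V") + 3.9 * (s.count("I") + s.count("L"))
    ) / n


def oracle_gravy(s: str) -> float:
    kd = DEFAULT_TABLES.hydropathy.kd
    return sum(kd[c] for c in s) / len(s)


class TestComposition:
    def test_counts_and_percents(self):
        p = residue_composition(_seq("AAG"))
        assert p.counts["A"] == 2 and p.counts["G"] == 1
        assert p.mole_percent["A"] == pytest.approx(200 / 3)
        assert p.mole_percent["G"] == pytest.approx(100 / 3)
        assert p.counts["W"] == 0

    def test_uniform_canonical_sequence(self):
        p = residue_composition(_seq("ACDEFGHIKLMNPQRSTVWY"))
        assert all(p.counts[r] == 1 for r in CANONICAL_ORDER)
        assert all(p.mole_percent[r] == pytest.approx(5.0) for r in CANONICAL_ORDER)

    @given(canonical_seqs)
    @settings(max_examples=100, derandomize=True)
    def test_normalization_identity(self, s):
        p = residue_composition(_seq(s))
        assert sum(p.counts.values()) == p.length == len(s)
        assert sum(p.mole_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_ambiguous_codes_get_entries(self):
        p = residue_composition(_seq("AXA"))
        assert p.counts["X"] == 1
        assert p.mole_percent["X"] == pytest.approx(100 / 3)


class TestMolecularWeight:
    def test_glycine_matches_elemental_oracle(self, tables):
        expected = elemental_mass({"C": 2, "H": 5, "N": 1, "O": 2}, tables.atomic_weights)
        assert molecular_weight(_seq("G")) == pytest.approx(expected, abs=0.01)

    def test_peptide_bond_additivity(self):
        w = DEFAULT_TABLES.masses.water_mass
        assert molecular_weight(_seq("GG")) == pytest.approx(
            2 * molecular_weight(_seq("G")) - w, abs=1e-9
        )

    def test_x_makes_mass_undefined(self):
        with pytest.raises(MassUndefinedError):
            molecular_weight(_seq("AXA"))

    @pytest.mark.parametrize("code,pair", [("B", "ND"), ("Z", "QE")])
    def test_two_way_codes_use_mean_candidate_mass(self, code, pair):
        w = DEFAULT_TABLES.masses.water_mass
        mean = (molecular_weight(_seq(pair[0])) + molecular_weight(_seq(pair[1]))) / 2 - w
        assert molecular_weight(_seq(code)) == pytest.approx(mean + w, abs=1e-9)

    @given(canonical_seqs)
    @settings(max_examples=50, derandomize=True)
    def test_matches_biopython_average_mass(self, s):
        ours = molecular_weight(_seq(s))
        ref = ProteinAnalysis(s).molecular_weight()
        assert ours == pytest.approx(ref, abs=0.01 * len(s) + 0.05)


class TestCharge:
    def test_single_group_half_charged_at_its_pk(self, tables):
        # At pH = pK the Henderson-Hasselbalch contribution is exactly 0.5;
        # subtract the terminal contributions measured on a glycine carrier.
        pk_his = tables.pks.pk["H"]
        carrier = net_charge(_seq("GG"), pk_his)
        with_his = net_charge(_seq("GH"), pk_his)
        assert with_his - carrier == pytest.approx(0.5, abs=1e-12)

    def test_limit_behaviour(self):
        assert net_charge(_seq("AAAA"), 0.0) == pytest.approx(1.0, abs=1e-3)
        assert net_charge(_seq("DDDD"), 14.0) == pytest.approx(-5.0, abs=1e-3)

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            net_charge(_seq("AA"), -0.1)
        with pytest.raises(ValueError):
            net_charge(_seq("AA"), 14.01)

    @given(canonical_seqs)
    @settings(max_examples=30, derandomize=True)
    def test_strictly_decreasing_in_ph(self, s):
        seq = _seq(s)
        grid = np.arange(0.0, 14.0 + 1e-12, 0.01)
        values = np.array([net_charge(seq, ph) for ph in grid])
        assert np.all(np.diff(values) < 0)


class TestIsoelectricPoint:
    def test_no_side_chain_closed_form(self, tables):
        expected = (tables.pks.pk["Nterm"] + tables.pks.pk["Cterm"]) / 2
        assert theoretical_pi(_seq("AAAA")) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "s,lo,hi", [("KKKKKKKKKK", 9.5, 14.0), ("DDDDDDDDDD", 0.0, 4.5)]
    )
    def test_extreme_sequences_match_brute_force_scan(self, s, lo, hi):
        seq = _seq(s)
        pi = theoretical_pi(seq)
        assert lo < pi < hi
        # brute-force: the sign change of the charge on a 0.001 pH grid
        grid = np.arange(0.0, 14.0, 0.001)
        values = np.array([net_charge(seq, ph) for ph in grid])
        crossing = grid[np.argmax(values < 0)]
        assert pi == pytest.approx(crossing, abs=0.002)

    @given(canonical_seqs)
    @settings(max_examples=50, derandomize=True)
    def test_solver_contract(self, s):
        seq = _seq(s)
        assert abs(net_charge(seq, theoretical_pi(seq))) <= 1e-4


class TestAtomicComposition:
    def test_glycine(self):
        a = atomic_composition(_seq("G"))
        assert dict(a.atoms) == {"C": 2, "H": 5, "N": 1, "O": 2, "S": 0}
        assert a.formula == "C2H5NO2"
        assert a.total_atoms == 10

    def test_cysteine_has_sulfur(self):
        a = atomic_composition(_seq("C"))
        assert a.atoms["S"] == 1
        assert a.formula == "C3H7NO2S"

    @pytest.mark.parametrize("s", ["AZA", "AXA", "BB"])
    def test_ambiguous_sequences_rejected(self, s):
        with pytest.raises(AmbiguityError):
            atomic_composition(_seq(s))

    @given(canonical_seqs, canonical_seqs)
    @settings(max_examples=50, derandomize=True)
    def test_additivity_minus_one_water(self, s1, s2):
        joined = atomic_composition(_seq(s1 + s2)).atoms
        a1 = atomic_composition(_seq(s1)).atoms
        a2 = atomic_composition(_seq(s2)).atoms
        water = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}
        for el in joined:
            assert joined[el] == a1[el] + a2[el] - water[el]


class TestChargedCountsAndIndices:
    @pytest.mark.parametrize(
        "s,expected",
        [("DEKR", (2, 2)), ("HHHH", (0, 0)), ("AAAA", (0, 0)), ("DDRK", (2, 2))],
    )
    def test_charged_residue_counts(self, s, expected):
        assert charged_residue_counts(_seq(s)) == expected

    @pytest.mark.parametrize(
        "s,expected",
        [("AAAA", 100.0), ("VVVV", 290.0), ("IIII", 390.0), ("LLLL", 390.0),
         ("GGGG", 0.0), ("AVIL", 292.5)],
    )
    def test_aliphatic_index_closed_forms(self, s, expected):
        assert aliphatic_index(residue_composition(_seq(s))) == pytest.approx(expected)

    @pytest.mark.parametrize("s,expected", [("IIII", 4.5), ("RRRR", -4.5), ("IR", 0.0)])
    def test_gravy_closed_forms(self, s, expected):
        assert gravy(_seq(s)) == pytest.approx(expected)

    def test_gravy_ambiguous_rejected(self, axa):
        with pytest.raises(AmbiguityError):
            gravy(axa)

    @given(canonical_seqs)
    @settings(max_examples=50, derandomize=True)
    def test_gravy_matches_biopython(self, s):
        assert gravy(_seq(s)) == pytest.approx(ProteinAnalysis(s).gravy(), abs=1e-9)


class TestInvariantsAndOracle:
    @given(canonical_seqs, st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_permutation_invariance(self, s, seed):
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(s)))
        a, b = _seq(s), _seq(shuffled)
        assert molecular_weight(a) == pytest.approx(molecular_weight(b), abs=1e-9)
        assert gravy(a) == pytest.approx(gravy(b), abs=1e-12)
        assert theoretical_pi(a) == theoretical_pi(b)
        assert dict(atomic_composition(a).atoms) == dict(atomic_composition(b).atoms)

    def test_oracle_equivalence_on_200_random_sequences(self):
        """MW, atoms, AI and GRAVY equal a naive per-character accumulation."""
        rng = np.random.default_rng(1234)
        for _ in range(200):
            seed = int(rng.integers(0, 2**31 - 1))
            seq = random_sequence(SequenceGeneratorConfig(length=(1, 500), seed=seed))
            s = seq.residues
            assert molecular_weight(seq) == oracle_mw(s)
            assert dict(atomic_composition(seq).atoms) == oracle_atoms(s)
            profile = residue_composition(seq)
            # AI goes through mole percents, the oracle through raw counts;
            # the two arrangements agree to the last few ulps.
            assert aliphatic_index(profile) == pytest.approx(oracle_ai(s), rel=1e-12)
            assert gravy(seq) == oracle_gravy(s)

    def test_mass_additivity_on_random_pairs(self):
        w = DEFAULT_TABLES.masses.water_mass
        rng = np.random.default_rng(99)
        for _ in range(100):
            s1 = random_sequence(
                SequenceGeneratorConfig(length=(1, 100), seed=int(rng.integers(2**31)))
            )
            s2 = random_sequence(
                SequenceGeneratorConfig(length=(1, 100), seed=int(rng.integers(2**31)))
            )
            joined = _seq(s1.residues + s2.residues)
            assert abs(
                molecular_weight(joined) - molecular_weight(s1) - molecular_weight(s2) + w
            ) < 1e-9


class TestReportAssembly:
    def test_complete_report_for_canonical_sequence(self):
        rep = compute_report(_seq("ACDEFGHIKLMNPQRSTVWY"))
        assert not rep.ambiguous
        assert rep.n_residues == 20 == rep.composition.length
        assert rep.molecular_weight is not None
        assert rep.atomic is not None
        assert rep.gravy is not None
        assert 0 < rep.theoretical_pi < 14
        assert -4.5 <= rep.gravy <= 4.5
        assert not rep.unavailable

    def test_partial_report_for_ambiguous_sequence(self, axa):
        rep = compute_report(axa)
        assert rep.ambiguous
        assert rep.n_residues == 3
        assert rep.molecular_weight is None
        assert rep.atomic is None
        assert rep.gravy is None
        assert set(rep.unavailable) == {"molecular_weight", "atomic", "gravy"}
        # composition, charge counts, pI and AI are still present
        assert rep.composition.counts["X"] == 1
        assert 0 < rep.theoretical_pi < 14

    def test_bz_mass_is_approximate_not_missing(self):
        rep = compute_report(_seq("AZA"))
        assert rep.molecular_weight is not None
        assert rep.mass_approximate
        assert rep.atomic is None and rep.gravy is None
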