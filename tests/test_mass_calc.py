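"""Mass arithmetic against an independent elemental-composition oracle."""

from collections import Counter

import pytest
from pyteomics import mass as pt_mass

from conftest import random_modified_sequence
from silnas.digestion import ModifiedRnaSequence, NucleolyticFragment, digest
from silnas.mass_calc import (
    CU_13C9,
    D2_U,
    G_13C10,
    H2O,
    PROTON,
    D_MINUS_H,
    LabelingScheme,
    fragment_neutral_mass,
    msms_ion_series,
    mz_from_neutral,
    psi_mass_shift_d2,
    sequence_neutral_mass,
    signature_ion_mz,
)

# Elemental compositions: internal nucleotide residues (NMP - H2O) and
# modification increments.  The oracle assembles formulas and prices them
# with the pyteomics NIST atomic-mass table, independently of the
# residue-mass constants used by the implementation.
RESIDUE_FORMULA = {
    "A": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1},
    "C": {"C": 9, "H": 12, "N": 3, "O": 7, "P": 1},
    "G": {"C": 10, "H": 12, "N": 5, "O": 7, "P": 1},
    "U": {"C": 9, "H": 11, "N": 2, "O": 8, "P": 1},
}
MOD_FORMULA = {
    "Ψ": {},
    "Am": {"C": 1, "H": 2}, "Cm": {"C": 1, "H": 2}, "Gm": {"C": 1, "H": 2},
    "Um": {"C": 1, "H": 2}, "Ψm": {"C": 1, "H": 2},
    "m1A": {"C": 1, "H": 2}, "m6A": {"C": 1, "H": 2}, "m5C": {"C": 1, "H": 2},
    "m7G": {"C": 1, "H": 2}, "m3U": {"C": 1, "H": 2},
    "m62A": {"C": 2, "H": 4},
    "ac4C": {"C": 2, "H": 2, "O": 1},
    "m1acp3Ψ": {"C": 5, "H": 9, "N": 1, "O": 2},
}


def _atomic(element, isotope=0):
    return pt_mass.nist_mass[element][isotope][0]


def oracle_mass(fragment: NucleolyticFragment, labeling: LabelingScheme | None = None) -> float:
    comp: Counter = Counter({"H": 2, "O": 1})  # the terminal water
    c13 = 0.0
    lm = fragment.local_mods
    for i, base in enumerate(fragment.residues, start=1):
        comp.update(RESIDUE_FORMULA[base])
        comp.update(MOD_FORMULA.get(lm.get(i), {}))
        if labeling is not None:
            # oracle re-derives label increments from isotope mass tables
            if labeling is G_13C10 and base == "G":
                c13 += 10 * (_atomic("C", 13) - _atomic("C", 12))
            elif labeling is CU_13C9 and base in "CU":
                c13 += 9 * (_atomic("C", 13) - _atomic("C", 12))
            elif labeling is D2_U and base in "CU":
                nd = 1 if (lm.get(i) is not None and "Ψ" in lm[i]) else 2
                c13 += nd * (_atomic("H", 2) - _atomic("H", 1))
    if fragment.five_prime_terminus == "phosphate":
        comp.update({"H": 1, "P": 1, "O": 3})
    if fragment.three_prime_terminus == "OH":
        comp.subtract({"H": 1, "P": 1, "O": 3})
    elif fragment.three_prime_terminus == "cyclic-phosphate":
        comp.subtract({"H": 2, "O": 1})
    return sum(n * _atomic(el) for el, n in comp.items()) + c13


def frag(residues, mods=None, five="OH", three="linear-phosphate"):
    return NucleolyticFragment("t", 1, len(residues), residues, mods or {}, five, three, 0, "T1")


class TestNeutralMass:
    def test_single_g_is_gmp(self):
        assert fragment_neutral_mass(frag("G")) == pytest.approx(363.0580, abs=1e-4)

    def test_g13c10_increment(self):
        delta = fragment_neutral_mass(frag("G"), G_13C10) - fragment_neutral_mass(frag("G"))
        assert delta == pytest.approx(10.03355, abs=1e-5)

    def test_pseudouridine_isobaric_with_uridine(self):
        assert fragment_neutral_mass(frag("U", {1: "Ψ"})) == fragment_neutral_mass(frag("U"))

    @pytest.mark.parametrize("labeling", [None, G_13C10, CU_13C9, D2_U])
    def test_oracle_agreement_random_fragments(self, labeling, rng):
        for i in range(25):
            seq = random_modified_sequence(rng, length=60, seq_id=f"m{i}")
            for f in digest(seq, "T1", 0):
                assert fragment_neutral_mass(f, labeling) == pytest.approx(
                    oracle_mass(f, labeling), abs=1e-4
                )

    @pytest.mark.parametrize("five", ["OH", "phosphate"])
    @pytest.mark.parametrize("three", ["linear-phosphate", "cyclic-phosphate", "OH"])
    def test_oracle_agreement_termini(self, five, three):
        f = frag("ACGU", {2: "Cm"}, five, three)
        assert fragment_neutral_mass(f) == pytest.approx(oracle_mass(f), abs=1e-4)

    def test_cyclic_phosphate_option(self):
        assert fragment_neutral_mass(frag("AG"), cyclic_phosphate=True) == pytest.approx(
            fragment_neutral_mass(frag("AG")) - H2O, abs=1e-9
        )

    def test_additivity_of_condensation(self):
        f1, f2, cat = frag("ACG"), frag("UUG"), frag("ACGUUG")
        assert fragment_neutral_mass(cat) == pytest.approx(
            fragment_neutral_mass(f1) + fragment_neutral_mass(f2) - H2O, abs=1e-9
        )

    def test_label_linearity(self):
        f = frag("GAGG")
        inc = G_13C10.increments["G"]
        assert fragment_neutral_mass(f, G_13C10) - fragment_neutral_mass(f) == pytest.approx(
            3 * inc, abs=1e-9
        )

    def test_whole_sequence_mass_matches_fragment_view(self):
        seq = ModifiedRnaSequence("w", "GACUG", {2: "Am"}, "phosphate", "OH")
        f = NucleolyticFragment("w", 1, 5, "GACUG", {2: "Am"}, "phosphate", "OH", 0, "T1")
        assert sequence_neutral_mass(seq) == pytest.approx(fragment_neutral_mass(f), abs=1e-9)


class TestPsiShift:
    def test_one_uridine(self):
        assert psi_mass_shift_d2(1, 0) == pytest.approx(2.0126, abs=1e-4)

    def test_one_pseudouridine(self):
        assert psi_mass_shift_d2(0, 1) == pytest.approx(1.0063, abs=1e-4)

    def test_net_conversion_shift_rounds_to_minus_one(self):
        shift = psi_mass_shift_d2(0, 1) - psi_mass_shift_d2(1, 0)
        assert shift == pytest.approx(-1.0063, abs=1e-4)
        assert round(shift) == -1


class TestIonSeries:
    def test_c1_of_dinucleotide(self):
        ions = {(i.series, i.index): i for i in msms_ion_series(frag("AU"))}
        assert ions[("c", 1)].neutral_mass == pytest.approx(347.0631, abs=1e-4)

    def test_complementarity_on_random_fragments(self, rng):
        for i in range(20):
            seq = random_modified_sequence(rng, length=40, seq_id=f"c{i}")
            for f in digest(seq, "T1", 0):
                if len(f) < 2:
                    continue
                M = fragment_neutral_mass(f)
                ions = {(x.series, x.index): x.neutral_mass for x in msms_ion_series(f)}
                n = len(f)
                for j in range(1, n):
                    assert ions[("c", j)] + ions[("y", n - j)] == pytest.approx(M + H2O, abs=1e-6)
                    assert ions[("a", j)] + ions[("w", n - j)] == pytest.approx(M, abs=1e-6)

    def test_charge_two_mz(self):
        M = 1000.0
        assert mz_from_neutral(M, 2) == pytest.approx((M - 2 * PROTON) / 2)

    def test_too_short_fragment_rejected(self):
        with pytest.raises(ValueError):
            msms_ion_series(frag("G"))


class TestSignatureIon:
    def test_natural(self):
        assert round(signature_ion_mz(False), 3) == 207.041

    def test_six_d_labeled(self):
        assert round(signature_ion_mz(True), 3) == 208.047

    def test_difference_is_deuterium_substitution(self):
        assert signature_ion_mz(True) - signature_ion_mz(False) == pytest.approx(
            D_MINUS_H, abs=1e-9
        )
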