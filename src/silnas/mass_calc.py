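"""Monoisotopic masses and m/z for modified, isotope-labeled RNA fragments.

A linear oligonucleotide is priced as a sum of nucleotide residue masses
(nucleoside monophosphate minus water) plus one water, plus terminus
adjustments: the baseline termini are 5'-OH / 3'-linear-phosphate, the
form RNase T1/A products take after complete digestion.  Modification
deltas and stable-isotope label increments add on top.  All ions are
negative mode: m/z = (M - z * m_proton) / z.

MS/MS backbone series follow the standard nucleic-acid nomenclature:
a/c ions retain the 5' terminus, w/y the 3' terminus.  c cleaves the
P-O5' bond (5' piece keeps the phosphate), y is its 3' complement;
a cleaves the 3'C-O bond, w its complement.  With the conventions here,
c_i + y_{n-i} = M + H2O and a_i + w_{n-i} = M, asserted in the tests.

The pseudouridine diagnostics implement metabolic 5,6-dideuterouridine
labeling: uridine in such RNA carries both deuteriums (+2 * (D - H)),
whereas pseudouridylation exchanges the C5 deuterium with solvent, so Ψ
retains only the 6-D — a net -1.0063 Da shift per Ψ relative to U that
makes the mass-silent isomer countable.  Ψ additionally yields a
characteristic MS/MS signature ion (deprotonated C9H8N2O4) at m/z
207.041, or 208.047 for the 6-D form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .digestion import ModifiedRnaSequence, NucleolyticFragment
from .ptm_catalog import MODIFICATION_ALPHABET, METHYL as METHYL_MASS, resolve_code

__all__ = [
    "PROTON",
    "H2O",
    "HPO3",
    "RESIDUE_MASSES",
    "LabelingScheme",
    "G_13C10",
    "CU_13C9",
    "D2_U",
    "TheoreticalIon",
    "fragment_neutral_mass",
    "sequence_neutral_mass",
    "psi_mass_shift_d2",
    "msms_ion_series",
    "signature_ion_mz",
    "mz_from_neutral",
    "neutral_from_mz",
]

# IUPAC/CODATA monoisotopic atomic masses (Da).
MASS_H = 1.007825
MASS_D = 2.014102
MASS_C = 12.0
MASS_C13 = 13.003355
MASS_N = 14.003074
MASS_O = 15.994915
MASS_P = 30.973762

PROTON = 1.007276  # mass of H+ (negative-mode charge carrier)
H2O = 2 * MASS_H + MASS_O  # 18.010565
HPO3 = MASS_H + MASS_P + 3 * MASS_O  # 79.966331
H3PO4 = H2O + HPO3

#: Internal-residue masses (nucleoside monophosphate - H2O), Da.
RESIDUE_MASSES: dict[str, float] = {
    "A": 329.052520,  # C10H12N5O6P
    "C": 305.041290,  # C9H12N3O7P
    "G": 345.047440,  # C10H12N5O7P
    "U": 306.025300,  # C9H11N2O8P
}

_FIVE_ADJ = {"OH": 0.0, "phosphate": HPO3}
_THREE_ADJ = {"linear-phosphate": 0.0, "cyclic-phosphate": -H2O, "OH": -HPO3}

D_MINUS_H = MASS_D - MASS_H  # 1.006277


@dataclass(frozen=True)
class LabelingScheme:
    """A stable-isotope labeling pattern of in-vivo or in-vitro RNA.

    ``increments`` maps the parent base to the per-residue mass increment
    (Da) of the fully labeled form; unlisted bases are unlabeled.
    ``psi_increment`` overrides the U increment for pseudouridine
    residues (used by 5,6-D2-U labeling, where Ψ keeps only the 6-D).
    ``impurity_fraction`` is the probability that a nominally labeled
    residue lacks the label entirely (commercial rNTPs, ~2%); it affects
    intensity bookkeeping, never theoretical masses.
    """

    name: str
    increments: Mapping[str, float]
    psi_increment: float | None = None
    impurity_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.impurity_fraction < 1):
            raise ValueError("impurity_fraction must be in [0, 1)")
        for base, inc in self.increments.items():
            if inc <= 0:
                raise ValueError(f"label increment for {base} must be > 0")

    def residue_increment(self, base: str, mod_code: str | None) -> float:
        if mod_code is not None and "Ψ" in mod_code and self.psi_increment is not None:
            return self.psi_increment
        return self.increments.get(base, 0.0)

    def n_labeled(self, fragment: NucleolyticFragment) -> int:
        return sum(1 for b in fragment.residues if b in self.increments)


#: Guanosine-13C10 transcript labeling (RNase T1 reference RNA).
G_13C10 = LabelingScheme("G-13C10", {"G": 10 * (MASS_C13 - MASS_C)})
#: Cytidine- and uridine-13C9 labeling (RNase A reference RNA).
CU_13C9 = LabelingScheme("CU-13C9", {"C": 9 * (MASS_C13 - MASS_C), "U": 9 * (MASS_C13 - MASS_C)})
#: Metabolic 5,6-D2-uridine labeling; Ψ retains only the 6-D.
D2_U = LabelingScheme("5,6-D2-U", {"U": 2 * D_MINUS_H, "C": 2 * D_MINUS_H}, psi_increment=D_MINUS_H)


@dataclass(frozen=True)
class TheoreticalIon:
    series: Literal["a", "c", "w", "y", "precursor", "signature"]
    index: int
    charge: int
    neutral_mass: float
    mz: float


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """Negative-mode m/z of a neutral mass at charge magnitude ``charge``."""
    if charge < 1:
        raise ValueError("charge magnitude must be >= 1")
    return (neutral_mass - charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    return mz * charge + charge * PROTON


def _residue_mass(base: str, mod_code: str | None, labeling: LabelingScheme | None) -> float:
    m = RESIDUE_MASSES[base]
    if mod_code is not None:
        m += MODIFICATION_ALPHABET[resolve_code(mod_code)].mass_delta
    if labeling is not None:
        m += labeling.residue_increment(base, mod_code)
    return m


def fragment_neutral_mass(
    fragment: NucleolyticFragment,
    labeling: LabelingScheme | None = None,
    cyclic_phosphate: bool = False,
) -> float:
    """Neutral monoisotopic mass of a digestion product.

    ``cyclic_phosphate=True`` prices a 2',3'-cyclic phosphate 3' end
    (-18.0106 Da versus the default linear phosphate)."""
    lm = fragment.local_mods
    mass = H2O + _FIVE_ADJ[fragment.five_prime_terminus]
    three = fragment.three_prime_terminus
    if cyclic_phosphate and three == "linear-phosphate":
        three = "cyclic-phosphate"
    mass += _THREE_ADJ[three]
    for i, base in enumerate(fragment.residues, start=1):
        mass += _residue_mass(base, lm.get(i), labeling)
    return mass


def sequence_neutral_mass(
    seq: ModifiedRnaSequence, labeling: LabelingScheme | None = None
) -> float:
    """Neutral mass of a whole (modified, labeled) RNA molecule."""
    mass = H2O + _FIVE_ADJ[seq.five_prime_terminus] + _THREE_ADJ[seq.three_prime_terminus]
    for i, base in enumerate(seq.residues, start=1):
        mass += _residue_mass(base, seq.mods.get(i), labeling)
    return mass


def psi_mass_shift_d2(u_count: int, psi_count: int) -> float:
    """Mass shift of a fragment under 5,6-D2-U labeling versus unlabeled.

    Each uridine contributes +2(D-H); each pseudouridine, having
    exchanged the 5-D with solvent protium, contributes only +(D-H), so
    every U→Ψ conversion shifts the fragment by -1.0063 Da.
    """
    if u_count < 0 or psi_count < 0:
        raise ValueError("counts must be >= 0")
    return u_count * 2 * D_MINUS_H + psi_count * D_MINUS_H


def msms_ion_series(
    fragment: NucleolyticFragment,
    max_charge: int = 1,
    labeling: LabelingScheme | None = None,
    series: Iterable[str] = ("a", "c", "w", "y"),
) -> list[TheoreticalIon]:
    """Theoretical a/c/w/y backbone ions of a fragment at charges 1..max.

    Neutral-fragment conventions (5' piece of length i, 3' piece of
    length k, precursor M):

    ==  ===========================  ======================
    c   prefix + H2O + 5'-terminus   keeps 3'-phosphate
    a   c - H3PO4                    dehydrated, no phosphate
    y   suffix + H2O + 3'-terminus   5'-OH
    w   y + HPO3                     keeps 5'-phosphate
    ==  ===========================  ======================
    """
    n = len(fragment)
    if n < 2:
        raise ValueError("MS/MS series require fragment length >= 2")
    lm = fragment.local_mods
    res = [
        _residue_mass(b, lm.get(i), labeling) for i, b in enumerate(fragment.residues, start=1)
    ]
    prefix = list(itertools.accumulate(res))
    total = prefix[-1]
    adj5 = _FIVE_ADJ[fragment.five_prime_terminus]
    adj3 = _THREE_ADJ[fragment.three_prime_terminus]
    ions = []
    want = set(series)
    for i in range(1, n):  # cleavage after residue i
        c_mass = prefix[i - 1] + H2O + adj5
        y_mass = (total - prefix[i - 1]) + H2O + adj3
        masses = {
            "a": c_mass - H3PO4,
            "c": c_mass,
            "w": y_mass + HPO3,
            "y": y_mass,
        }
        for s in ("a", "c", "w", "y"):
            if s not in want:
                continue
            idx = i if s in "ac" else n - i
            for z in range(1, max_charge + 1):
                ions.append(TheoreticalIon(s, idx, z, masses[s], mz_from_neutral(masses[s], z)))
    return ions


# Elemental composition of the Ψ signature fragment (neutral), chosen as the
# unique small CHNO composition matching the observed m/z within 5 ppm.
_SIGNATURE_NEUTRAL = 9 * MASS_C + 8 * MASS_H + 2 * MASS_N + 4 * MASS_O  # C9H8N2O4


def signature_ion_mz(labeled: bool = False) -> float:
    """m/z of the pseudouridine signature ion (deprotonated C9H8N2O4).

    ``labeled=True`` gives the 6-D form seen in 5,6-D2-U-labeled RNA
    (one protium replaced by deuterium, +1.0063).
    """
    neutral = _SIGNATURE_NEUTRAL + (D_MINUS_H if labeled else 0.0)
    return mz_from_neutral(neutral, 1)
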