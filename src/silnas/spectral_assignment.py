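"""MS/MS fragment assignment and pseudouridine calling.

A desk-scale database search over the digestion products of a known
sequence: candidate variants carry 0–2 variable methyl groups (any
residue), precursors are filtered at ±5 ppm, and candidates are scored
by the number of matched theoretical a/c/w/y backbone ions at ±20 ppm,
ties broken by the lower mean |ppm| error.

Pseudouridine is mass-silent in natural RNA, so Ψ calls rest on the
metabolic 5,6-D2-uridine labeling chemistry: pseudouridylation exchanges
the 5-D with solvent, shifting each converted residue by -1.0063 Da.
Comparing the observed D2-labeled digest masses with the all-uridine
expectation counts the Ψ per fragment; single-U fragments localize the
call directly, multi-U fragments need MS/MS localization via the shifted
c/y (or a/w) ions.  When MS/MS is available the Ψ-characteristic
signature ion (m/z 207.041 natural / 208.047 in the 6-D channel) must
corroborate the mass shift; a shift without the signature ion is
reported as ambiguous rather than called.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import ModifiedRnaSequence, NucleolyticFragment, digest
from .mass_calc import (
    D_MINUS_H,
    METHYL_MASS,
    LabelingScheme,
    D2_U,
    fragment_neutral_mass,
    msms_ion_series,
    neutral_from_mz,
    signature_ion_mz,
)

__all__ = [
    "MsmsSpectrum",
    "SpectrumMatch",
    "CandidateVariant",
    "generate_candidates",
    "search_spectrum",
    "PsiCall",
    "call_pseudouridine",
]


@dataclass
class MsmsSpectrum:
    """A centroided MS/MS spectrum (peaks sorted by m/z)."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(i <= 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be > 0")
        self.peaks = sorted(self.peaks)

    @property
    def precursor_neutral_mass(self) -> float:
        return neutral_from_mz(self.precursor_mz, self.precursor_charge)

    def mz_array(self) -> np.ndarray:
        return np.array([mz for mz, _ in self.peaks]) if self.peaks else np.empty(0)

    def base_peak_intensity(self) -> float:
        return max((i for _, i in self.peaks), default=0.0)

    def has_peak(self, mz: float, ppm_tol: float, min_relative: float = 0.0) -> bool:
        floor = min_relative * self.base_peak_intensity()
        return any(
            abs(p - mz) / mz * 1e6 <= ppm_tol and inten >= floor for p, inten in self.peaks
        )


@dataclass(frozen=True)
class CandidateVariant:
    """A fragment plus a variable-methyl placement (fragment-local positions)."""

    fragment: NucleolyticFragment
    methyl_positions: tuple[int, ...]  # multiset; a residue may carry two

    @property
    def neutral_mass_shift(self) -> float:
        return len(self.methyl_positions) * METHYL_MASS

    def as_fragment(self) -> NucleolyticFragment:
        """The variant as a fragment whose mods reflect the methyl placement.

        Variable methyls are represented as generic ribose methyls of the
        local parent base; mass-wise every methyl is +14.0157 regardless.
        """
        by_base = {"A": "Am", "C": "Cm", "G": "Gm", "U": "Um"}
        mods = dict(self.fragment.mods)
        doubled = {p for p in self.methyl_positions if self.methyl_positions.count(p) > 1}
        if doubled:
            # two methyls on one residue: dimethyladenosine is the only
            # alphabet representative; fall back to mass bookkeeping
            raise ValueError("doubly methylated residues are matched by mass only")
        for local in self.methyl_positions:
            parent_pos = self.fragment.start + local - 1
            mods[parent_pos] = by_base[self.fragment.residues[local - 1]]
        return NucleolyticFragment(
            self.fragment.parent_id, self.fragment.start, self.fragment.end,
            self.fragment.residues, mods, self.fragment.five_prime_terminus,
            self.fragment.three_prime_terminus, self.fragment.missed_cleavages,
            self.fragment.enzyme,
        )


@dataclass
class SpectrumMatch:
    spectrum_id: str
    candidate: CandidateVariant
    matched_ions: int
    total_ions: int
    matched_ppm: list[float]
    score: float

    @property
    def mean_abs_ppm(self) -> float:
        return float(np.mean(np.abs(self.matched_ppm))) if self.matched_ppm else math.inf


def generate_candidates(
    fragments: Sequence[NucleolyticFragment], max_methylations: int = 2
) -> list[CandidateVariant]:
    """Enumerate 0..max variable methyl placements on every fragment.

    Placements are position multisets (a residue may take two methyls),
    deduplicated; a 3-mer at the default limit yields 1 + 3 + 6 = 10
    variants.
    """
    if max_methylations < 0:
        raise ValueError("max_methylations must be >= 0")
    out = []
    for frag in fragments:
        positions = range(1, len(frag) + 1)
        seen = set()
        for k in range(max_methylations + 1):
            for combo in itertools.combinations_with_replacement(positions, k):
                if combo not in seen:
                    seen.add(combo)
                    out.append(CandidateVariant(frag, combo))
    return out


def _variant_neutral_mass(
    candidate: CandidateVariant, labeling: LabelingScheme | None
) -> float:
    return fragment_neutral_mass(candidate.fragment, labeling) + candidate.neutral_mass_shift


def search_spectrum(
    spectrum: MsmsSpectrum,
    candidates: Sequence[CandidateVariant],
    precursor_tol_ppm: float = 5.0,
    fragment_tol_ppm: float = 20.0,
    labeling: LabelingScheme | None = None,
    max_charge: int | None = None,
) -> SpectrumMatch | None:
    """Best candidate for one spectrum, or None.

    Candidates outside the precursor tolerance are discarded; the rest
    are scored by matched a/c/w/y ion count at the fragment tolerance
    (ties: lower mean |ppm| of the matched ions).
    """
    if not candidates:
        raise ValueError("no candidates supplied")
    if not spectrum.peaks:
        raise ValueError("spectrum has no peaks")
    obs = spectrum.mz_array()
    target = spectrum.precursor_neutral_mass
    zmax = max_charge or spectrum.precursor_charge
    best: SpectrumMatch | None = None
    for cand in candidates:
        mass = _variant_neutral_mass(cand, labeling)
        if abs(mass - target) / target * 1e6 > precursor_tol_ppm:
            continue
        if len(cand.fragment) < 2:
            continue
        # variable methyls shift only the prefix/suffix sums they sit in;
        # price them by attaching mass to the residue via a mods overlay
        try:
            frag = cand.as_fragment() if cand.methyl_positions else cand.fragment
        except ValueError:
            continue  # doubly methylated residue: skip ion-level scoring
        ions = msms_ion_series(frag, max_charge=zmax, labeling=labeling)
        ppms = []
        for ion in ions:
            if obs.size == 0:
                break
            d = np.abs(obs - ion.mz) / ion.mz * 1e6
            k = int(np.argmin(d))
            if d[k] <= fragment_tol_ppm:
                ppms.append(float((obs[k] - ion.mz) / ion.mz * 1e6))
        match = SpectrumMatch(
            spectrum.spectrum_id, cand, len(ppms), len(ions), ppms, score=float(len(ppms))
        )
        if (
            best is None
            or match.matched_ions > best.matched_ions
            or (match.matched_ions == best.matched_ions and match.mean_abs_ppm < best.mean_abs_ppm)
        ):
            best = match
    return best


@dataclass
class PsiCall:
    """A per-position pseudouridine call."""

    parent_id: str
    position: int  # 1-based on the parent
    status: str  # "called", "ambiguous"
    evidence: str
    fragment_span: tuple[int, int]


def _match_mass(observed: np.ndarray, expected: float, ppm_tol: float) -> bool:
    if observed.size == 0:
        return False
    return bool(np.min(np.abs(observed - expected)) <= expected * ppm_tol * 1e-6)


def call_pseudouridine(
    sequence: ModifiedRnaSequence,
    d2_masses: Iterable[float],
    spectra: Mapping[tuple[int, int], MsmsSpectrum] | None = None,
    enzyme: str = "T1",
    ppm_tol: float = 5.0,
    fragment_tol_ppm: float = 20.0,
    signature_min_relative: float = 0.01,
) -> list[PsiCall]:
    """Call Ψ positions from a 5,6-D2-U-labeled digest of ``sequence``.

    ``sequence`` is the plain (or reference-annotated) chain; its
    ``enzyme`` digest defines the fragments.  ``d2_masses`` are the
    observed neutral masses of the labeled digest.  For each U-containing
    fragment the all-U expectation is compared with expectation - k * 1.0063
    for k = 0..#U; the best-supported k gives the Ψ count.  Single-U
    fragments yield site-resolved calls; multi-U fragments are localized
    with the spectrum supplied for their (start, end) span, scoring every
    k-subset of U positions by matched shifted c/y/a/w ions.  When a
    spectrum is present, the 6-D signature ion (m/z 208.047) must also be
    present above ``signature_min_relative`` of the base peak; a mass
    shift without it downgrades the call to ambiguous.
    """
    observed = np.sort(np.fromiter(d2_masses, dtype=float))
    frags = digest(sequence, enzyme, 0)
    sig_mz = signature_ion_mz(labeled=True)
    calls: list[PsiCall] = []
    for frag in frags:
        lm = frag.local_mods
        u_local = [
            i
            for i, b in enumerate(frag.residues, start=1)
            if b == "U" and lm.get(i) in (None, "Ψ")
        ]
        if not u_local:
            continue
        # all-U expectation: strip any reference Ψ annotations
        bare = NucleolyticFragment(
            frag.parent_id, frag.start, frag.end, frag.residues,
            {p: c for p, c in frag.mods.items() if "Ψ" not in c},
            frag.five_prime_terminus, frag.three_prime_terminus,
            frag.missed_cleavages, frag.enzyme,
        )
        all_u = fragment_neutral_mass(bare, D2_U)
        # a redundant sequence can contribute an unshifted copy from another
        # locus, so the call rests on the largest supported Ψ count
        k_found = None
        for k in range(len(u_local), -1, -1):
            if _match_mass(observed, all_u - k * D_MINUS_H, ppm_tol):
                k_found = k
                break
        if not k_found:
            continue  # no shift (or fragment unobserved): no call
        spectrum = (spectra or {}).get((frag.start, frag.end))
        signature_ok = spectrum is None or spectrum.has_peak(
            sig_mz, fragment_tol_ppm, signature_min_relative
        )
        span = (frag.start, frag.end)
        if len(u_local) == 1:
            pos = frag.start + u_local[0] - 1
            status = "called" if signature_ok else "ambiguous"
            ev = "mass-shift" + ("+signature" if spectrum is not None and signature_ok else "")
            if not signature_ok:
                ev = "mass-shift-without-signature"
            calls.append(PsiCall(frag.parent_id, pos, status, ev, span))
            continue
        if spectrum is None:
            for i in u_local:
                calls.append(
                    PsiCall(frag.parent_id, frag.start + i - 1, "ambiguous",
                            f"{k_found}Ψ in multi-U fragment, no MS/MS", span)
                )
            continue
        best_subset, best_score = None, -1
        for subset in itertools.combinations(u_local, k_found):
            mods = {p: c for p, c in bare.mods.items()}
            for i in subset:
                mods[frag.start + i - 1] = "Ψ"
            variant = NucleolyticFragment(
                frag.parent_id, frag.start, frag.end, frag.residues, mods,
                frag.five_prime_terminus, frag.three_prime_terminus,
                frag.missed_cleavages, frag.enzyme,
            )
            ions = msms_ion_series(variant, max_charge=spectrum.precursor_charge, labeling=D2_U)
            obs = spectrum.mz_array()
            score = sum(
                1
                for ion in ions
                if obs.size and np.min(np.abs(obs - ion.mz)) / ion.mz * 1e6 <= fragment_tol_ppm
            )
            if score > best_score:
                best_subset, best_score = subset, score
        status = "called" if signature_ok else "ambiguous"
        for i in best_subset or ():
            calls.append(
                PsiCall(
                    frag.parent_id, frag.start + i - 1, status,
                    "mass-shift+msms-localization" + ("" if signature_ok else "-without-signature"),
                    span,
                )
            )
    return calls
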