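"""In-silico nucleolytic digestion of modified RNA.

RNase T1 cleaves 3' of guanosine and RNase A 3' of pyrimidines; both
require the 2'-hydroxyl, so any 2'-O-methylated residue (Gm, Cm, Um, Ψm)
resists cleavage.  Base modifications that leave the ribose untouched
(m5C, m3U, m6A, ...) do not alter specificity, and pseudouridine is a
cleavable pyrimidine for RNase A.  Sequence-directed RNase H cleavage
(RNA:DNA hybrid directed by a complementary oligo) cuts wherever the
experimenter points it; here a plan is just the ordered list of
after-residue cut positions.

Enzyme products carry 5'-OH / 3'-linear-phosphate termini (the end state
after complete digestion; cyclic-phosphate masses are an option in
:mod:`silnas.mass_calc`), while RNase H junctions carry 5'-phosphate /
3'-OH.  The parent molecule's own termini are inherited at its ends.

The redundancy-driven cut planner addresses the central bookkeeping
problem of fragment-based quantitation: a digestion product whose
sequence occurs at several positions of the parent pools signal from all
copies, so the per-site stoichiometry read from it is only a lower bound.
Cutting the parent into sub-molecules before digestion restores
uniqueness; ``plan_rnase_h_cuts`` searches greedily for such cuts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .ptm_catalog import MODIFICATION_ALPHABET, resolve_code

__all__ = [
    "ModifiedRnaSequence",
    "NucleolyticFragment",
    "CleavagePlan",
    "digest",
    "digest_rnase_t1",
    "digest_rnase_a",
    "digest_rnase_h",
    "plan_rnase_h_cuts",
    "fragment_redundancy",
]

FivePrime = Literal["OH", "phosphate"]
ThreePrime = Literal["linear-phosphate", "cyclic-phosphate", "OH"]


@dataclass
class ModifiedRnaSequence:
    """An RNA chain with per-position (1-based) modification codes."""

    id: str
    residues: str
    mods: dict[int, str] = field(default_factory=dict)
    five_prime_terminus: FivePrime = "phosphate"
    three_prime_terminus: ThreePrime = "OH"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper().replace("T", "U")
        bad = set(self.residues) - set("ACGU")
        if bad:
            raise ValueError(f"{self.id}: non-RNA residues {sorted(bad)}")
        canon = {}
        for pos, code in self.mods.items():
            if not (1 <= pos <= len(self.residues)):
                raise ValueError(f"{self.id}: modification position {pos} outside sequence")
            code = resolve_code(code)
            parent = MODIFICATION_ALPHABET[code].parent_base
            if self.residues[pos - 1] != parent:
                raise ValueError(
                    f"{self.id}: {code} at position {pos} requires {parent}, "
                    f"sequence has {self.residues[pos - 1]}"
                )
            canon[pos] = code
        self.mods = canon

    def __len__(self) -> int:
        return len(self.residues)

    def mod_at(self, pos: int) -> str | None:
        return self.mods.get(pos)

    def annotated(self) -> str:
        """Human-readable string, e.g. ``"AU[Gm]CG"``."""
        out = []
        for i, base in enumerate(self.residues, start=1):
            code = self.mods.get(i)
            out.append(f"[{code}]" if code else base)
        return "".join(out)


@dataclass
class NucleolyticFragment:
    """A digestion product, coordinates 1-based inclusive on the parent."""

    parent_id: str
    start: int
    end: int
    residues: str
    mods: dict[int, str]  # positions are parent coordinates
    five_prime_terminus: FivePrime
    three_prime_terminus: ThreePrime
    missed_cleavages: int
    enzyme: Literal["T1", "A", "H"]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def local_mods(self) -> dict[int, str]:
        """Modification map re-indexed to fragment-local 1-based positions."""
        return {p - self.start + 1: c for p, c in self.mods.items()}

    def key(self) -> str:
        """Sequence-plus-modification identity string (redundancy grouping)."""
        lm = self.local_mods
        return "".join(
            f"[{lm[i]}]" if i in lm else b for i, b in enumerate(self.residues, start=1)
        )

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class CleavagePlan:
    """Ordered after-residue cut positions for RNase H cleavage."""

    parent_id: str
    cuts: list[int] = field(default_factory=list)
    guide_windows: list[tuple[int, int]] = field(default_factory=list)
    residual_redundancy: int = 0

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cuts must be strictly increasing")


def _is_blocked(seq: ModifiedRnaSequence, pos: int) -> bool:
    code = seq.mods.get(pos)
    return bool(code) and MODIFICATION_ALPHABET[code].blocks_2prime_cleavage


def cleavage_sites(seq: ModifiedRnaSequence, enzyme: str) -> list[int]:
    """After-residue positions cleaved by T1 (3' of G) or A (3' of pyrimidine).

    A site is suppressed when the residue carries a 2'-O-methyl.  The
    final residue is never a site (there is nothing 3' of it to release).
    """
    targets = {"T1": "G", "A": "CU"}[enzyme]
    return [
        i
        for i in range(1, len(seq))
        if seq.residues[i - 1] in targets and not _is_blocked(seq, i)
    ]


def _build_fragments(
    seq: ModifiedRnaSequence,
    boundaries: Sequence[int],
    missed_cleavages: int,
    enzyme: str,
    junction_five: FivePrime,
    junction_three: ThreePrime,
) -> list[NucleolyticFragment]:
    edges = [0, *boundaries, len(seq)]
    frags = []
    npieces = len(edges) - 1
    for i in range(npieces):
        for j in range(i, min(i + missed_cleavages + 1, npieces)):
            start, end = edges[i] + 1, edges[j + 1]
            frags.append(
                NucleolyticFragment(
                    parent_id=seq.id,
                    start=start,
                    end=end,
                    residues=seq.residues[start - 1 : end],
                    mods={p: c for p, c in seq.mods.items() if start <= p <= end},
                    five_prime_terminus=seq.five_prime_terminus if start == 1 else junction_five,
                    three_prime_terminus=seq.three_prime_terminus if end == len(seq) else junction_three,
                    missed_cleavages=j - i,
                    enzyme=enzyme,  # type: ignore[arg-type]
                )
            )
    return frags


def digest(seq: ModifiedRnaSequence, enzyme: str, missed_cleavages: int = 0) -> list[NucleolyticFragment]:
    """Digest with RNase ``"T1"`` or ``"A"``, emitting all products with up
    to ``missed_cleavages`` internal uncleaved sites."""
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    sites = cleavage_sites(seq, enzyme)
    return _build_fragments(seq, sites, missed_cleavages, enzyme, "OH", "linear-phosphate")


def digest_rnase_t1(seq: ModifiedRnaSequence, missed_cleavages: int = 0) -> list[NucleolyticFragment]:
    return digest(seq, "T1", missed_cleavages)


def digest_rnase_a(seq: ModifiedRnaSequence, missed_cleavages: int = 0) -> list[NucleolyticFragment]:
    return digest(seq, "A", missed_cleavages)


def digest_rnase_h(seq: ModifiedRnaSequence, plan: CleavagePlan) -> list[NucleolyticFragment]:
    """Cut at the planned positions; junctions are 5'-phosphate / 3'-OH."""
    for cut in plan.cuts:
        if not (1 <= cut < len(seq)):
            raise ValueError(f"cut {cut} outside sequence of length {len(seq)}")
    return _build_fragments(seq, list(plan.cuts), 0, "H", "phosphate", "OH")


def subsequences(seq: ModifiedRnaSequence, plan: CleavagePlan) -> list[ModifiedRnaSequence]:
    """RNase H products as standalone molecules (for further digestion)."""
    out = []
    for f in digest_rnase_h(seq, plan):
        out.append(
            ModifiedRnaSequence(
                id=f"{seq.id}:{f.start}-{f.end}",
                residues=f.residues,
                mods=f.local_mods,
                five_prime_terminus=f.five_prime_terminus,
                three_prime_terminus=f.three_prime_terminus,
            )
        )
    return out


def fragment_redundancy(fragments: Iterable[NucleolyticFragment]) -> dict[str, int]:
    """Count identical sequence+modification strings within one digest."""
    return dict(Counter(f.key() for f in fragments))


def _redundant_mod_fragments(seq: ModifiedRnaSequence, enzyme: str, plan_cuts: Sequence[int]) -> int:
    """Number of modification-bearing enzyme fragments whose sequence string
    is non-unique within its RNase H product's digest."""
    total = 0
    for sub in subsequences(seq, CleavagePlan(seq.id, list(plan_cuts))):
        frags = digest(sub, enzyme, 0)
        counts = Counter(f.key() for f in frags)
        total += sum(1 for f in frags if f.mods and counts[f.key()] > 1)
    return total


def plan_rnase_h_cuts(
    seq: ModifiedRnaSequence,
    enzyme: str = "T1",
    max_cuts: int = 10,
    guide_length: int = 12,
) -> CleavagePlan:
    """Greedily choose RNase H cuts so that every modification-bearing
    enzyme fragment becomes sequence-unique within its product's digest.

    Each greedy step evaluates all candidate cut positions and keeps the
    one that removes the most redundant modification-bearing fragments,
    breaking ties by the leftmost position.  Stops when redundancy reaches
    zero or ``max_cuts`` is exhausted; the residual is reported on the
    returned plan.  ``guide_windows`` records, for each cut, the window a
    complementary DNA oligo of ``guide_length`` nt would cover.
    """
    cuts: list[int] = []
    current = _redundant_mod_fragments(seq, enzyme, cuts)
    while current > 0 and len(cuts) < max_cuts:
        best_pos, best_score = None, current
        for pos in range(1, len(seq)):
            if pos in cuts:
                continue
            score = _redundant_mod_fragments(seq, enzyme, sorted([*cuts, pos]))
            if score < best_score:
                best_pos, best_score = pos, score
        if best_pos is None:  # no single cut improves matters
            break
        cuts = sorted([*cuts, best_pos])
        current = best_score
    half = guide_length // 2
    windows = [(max(1, c - half + 1), min(len(seq), c + half)) for c in cuts]
    return CleavagePlan(seq.id, cuts, windows, residual_redundancy=current)
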