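"""Modification alphabet and per-site modification atlases of ribosomal RNA.

The human 80S ribosome carries 14 distinct chemical modification types at
228 internal rRNA sites.  This module packages that map (one row per
modified nucleotide: molecule, 1-based position, modification code and
percent stoichiometry) together with the modification alphabet itself —
each code's parent base, monoisotopic mass increment, and whether it
carries a ribose 2'-O-methyl group, which is what blocks cleavage by the
2'-OH-dependent ribonucleases T1 and A.

Positions are 1-based throughout, matching the conventional rRNA residue
numbering; the BED export converts explicitly to 0-based half-open.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ModificationType",
    "PtmSiteRecord",
    "PtmAtlas",
    "MODIFICATION_ALPHABET",
    "MOLECULE_LENGTHS",
    "resolve_code",
    "load_atlas",
    "write_atlas",
    "summarize_atlas",
    "annotate_sequence",
    "atlas_to_bed",
]

#: Monoisotopic mass of one methyl substitution (CH2), Da.
METHYL = 14.015650
#: Monoisotopic mass of one acetyl substitution (C2H2O), Da.
ACETYL = 42.010565
#: 3-amino-3-carboxypropyl group (C4H7NO2), Da.
ACP = 101.047679

#: Mature human rRNA chain lengths (nt).
MOLECULE_LENGTHS: dict[str, int] = {"5S": 120, "5.8S": 157, "18S": 1869, "28S": 5064}

_MOLECULE_ORDER = {"5S": 0, "5.8S": 1, "18S": 2, "28S": 3}


@dataclass(frozen=True)
class ModificationType:
    """One entry of the modification alphabet.

    Parameters
    ----------
    code : str
        Short code, e.g. ``"Ψ"``, ``"Am"``, ``"m1acp3Ψ"``.
    parent_base : str
        Unmodified residue the code applies to (A/C/G/U).
    mass_delta : float
        Monoisotopic mass increment relative to the unmodified residue, Da.
        Pseudouridine is an isomer of uridine and has delta exactly 0.
    blocks_2prime_cleavage : bool
        True for every 2'-O-methylated ribose (Nm, Ψm); such residues are
        resistant to RNase T1 / RNase A cleavage at their 3' side.
    mod_class : str
        One of ``ribose-methyl``, ``base-methyl``, ``isomerization``,
        ``acetylation``, ``composite``.
    """

    code: str
    parent_base: str
    mass_delta: float
    blocks_2prime_cleavage: bool
    mod_class: str


def _mt(code, base, delta, blocks, cls):
    return ModificationType(code, base, delta, blocks, cls)


#: The 14-code alphabet of modifications observed in human rRNA.
MODIFICATION_ALPHABET: dict[str, ModificationType] = {
    m.code: m
    for m in [
        _mt("Ψ", "U", 0.0, False, "isomerization"),
        _mt("Am", "A", METHYL, True, "ribose-methyl"),
        _mt("Cm", "C", METHYL, True, "ribose-methyl"),
        _mt("Gm", "G", METHYL, True, "ribose-methyl"),
        _mt("Um", "U", METHYL, True, "ribose-methyl"),
        # 2'-O-methylpseudouridine: isomerization plus a ribose methyl.
        _mt("Ψm", "U", METHYL, True, "composite"),
        _mt("m1A", "A", METHYL, False, "base-methyl"),
        _mt("m6A", "A", METHYL, False, "base-methyl"),
        _mt("m62A", "A", 2 * METHYL, False, "base-methyl"),
        _mt("m5C", "C", METHYL, False, "base-methyl"),
        _mt("m7G", "G", METHYL, False, "base-methyl"),
        _mt("m3U", "U", METHYL, False, "base-methyl"),
        _mt("ac4C", "C", ACETYL, False, "acetylation"),
        # 1-methyl-3-(3-amino-3-carboxypropyl)pseudouridine.
        _mt("m1acp3Ψ", "U", METHYL + ACP, False, "composite"),
    ]
}

# ASCII aliases accepted on input (Ψ → Y) for file portability.
_ALIASES = {"Y": "Ψ", "Ym": "Ψm", "m1acp3Y": "m1acp3Ψ", "psi": "Ψ"}


def resolve_code(code: str) -> str:
    """Return the canonical modification code, accepting ASCII aliases.

    Raises ``KeyError`` naming the code if it is not in the alphabet.
    """
    code = code.strip()
    code = _ALIASES.get(code, code)
    if code not in MODIFICATION_ALPHABET:
        raise KeyError(f"unknown modification code: {code!r}")
    return code


@dataclass(frozen=True)
class PtmSiteRecord:
    """One modified nucleotide of an atlas."""

    molecule: str
    position: int  # 1-based
    mod_code: str
    percent: float
    newly_identified: bool = False
    redundancy_count: int = 1

    @property
    def over_100(self) -> bool:
        """Stoichiometries above 100% are retained verbatim but flagged."""
        return self.percent > 100

    @property
    def modification(self) -> ModificationType:
        return MODIFICATION_ALPHABET[self.mod_code]


@dataclass
class PtmAtlas:
    """A per-site modification map for one species' rRNAs."""

    species: str
    records: list[PtmSiteRecord] = field(default_factory=list)
    molecule_lengths: Mapping[str, int] = field(default_factory=lambda: dict(MOLECULE_LENGTHS))

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for i, rec in enumerate(self.records):
            if rec.mod_code not in MODIFICATION_ALPHABET:
                raise ValueError(f"record {i}: unknown modification code {rec.mod_code!r}")
            length = self.molecule_lengths.get(rec.molecule)
            if length is not None and not (1 <= rec.position <= length):
                raise ValueError(
                    f"record {i}: position {rec.position} outside {rec.molecule} "
                    f"(length {length})"
                )
            if rec.percent < 0:
                raise ValueError(f"record {i}: negative percent {rec.percent}")
            if rec.redundancy_count < 1:
                raise ValueError(f"record {i}: redundancy_count must be >= 1")
            key = (rec.molecule, rec.position)
            if key in seen:
                raise ValueError(f"duplicate site {key}")
            seen.add(key)
        self.records.sort(key=lambda r: (_MOLECULE_ORDER.get(r.molecule, 99), r.molecule, r.position))

    def __len__(self) -> int:
        return len(self.records)

    def sites(self, molecule: str) -> list[PtmSiteRecord]:
        return [r for r in self.records if r.molecule == molecule]

    def get(self, molecule: str, position: int) -> PtmSiteRecord | None:
        for r in self.records:
            if r.molecule == molecule and r.position == position:
                return r
        return None


_COLUMNS = ["molecule", "position", "mod_code", "percent", "newly_identified", "redundancy_count"]


def _parse_percent(text: str) -> float:
    v = float(text)
    return v


def load_atlas(source: str | Path = "human", species: str | None = None) -> PtmAtlas:
    """Load a modification atlas from the packaged table or a TSV path.

    ``source="human"`` loads the packaged human rRNA atlas (228 sites).
    Any other value is treated as a path to a TSV with columns
    ``molecule, position, mod_code, percent`` and optional
    ``newly_identified, redundancy_count``.  Parse errors name the
    offending row and column.
    """
    if source == "human":
        text = resources.files("silnas.data").joinpath("human_rrna_ptm.tsv").read_text("utf-8")
        species = species or "Homo sapiens"
    else:
        text = Path(source).read_text("utf-8")
        species = species or Path(source).stem
    reader = csv.DictReader(_io.StringIO(text), delimiter="\t")
    missing = [c for c in _COLUMNS[:4] if c not in (reader.fieldnames or [])]
    if missing:
        raise ValueError(f"atlas table missing column(s): {', '.join(missing)}")
    records = []
    for lineno, row in enumerate(reader, start=2):
        try:
            code = resolve_code(row["mod_code"])
        except KeyError as exc:
            raise ValueError(f"row {lineno}, column mod_code: {exc.args[0]}") from None
        try:
            position = int(row["position"])
        except ValueError:
            raise ValueError(f"row {lineno}, column position: not an integer: {row['position']!r}") from None
        try:
            percent = _parse_percent(row["percent"])
        except ValueError:
            raise ValueError(f"row {lineno}, column percent: not a number: {row['percent']!r}") from None
        records.append(
            PtmSiteRecord(
                molecule=row["molecule"],
                position=position,
                mod_code=code,
                percent=percent,
                newly_identified=(row.get("newly_identified", "no").strip().lower() in {"yes", "true", "1"}),
                redundancy_count=int(row.get("redundancy_count") or 1),
            )
        )
    return PtmAtlas(species=species, records=records)


def write_atlas(atlas: PtmAtlas, path: str | Path | None = None) -> str:
    """Serialize an atlas to TSV; round-trips the packaged table byte-identically."""
    buf = ["\t".join(_COLUMNS)]
    for r in atlas.records:
        pct = f"{int(r.percent)}" if float(r.percent).is_integer() else f"{r.percent:g}"
        buf.append(
            f"{r.molecule}\t{r.position}\t{r.mod_code}\t{pct}\t"
            f"{'yes' if r.newly_identified else 'no'}\t{r.redundancy_count}"
        )
    text = "\n".join(buf) + "\n"
    if path is not None:
        Path(path).write_text(text, "utf-8")
    return text


def summarize_atlas(atlas: PtmAtlas, percent_threshold: float = 85.0) -> dict:
    """Summary counts of an atlas.

    Returns total sites, per-molecule counts (every molecule with a known
    length appears, possibly with 0), distinct modification type count,
    sites at/above ``percent_threshold``, and newly-identified counts
    broken down by modification class.
    """
    per_molecule = {m: 0 for m in atlas.molecule_lengths}
    for r in atlas.records:
        per_molecule[r.molecule] = per_molecule.get(r.molecule, 0) + 1
    per_type: dict[str, int] = {}
    for r in atlas.records:
        per_type[r.mod_code] = per_type.get(r.mod_code, 0) + 1
    new = [r for r in atlas.records if r.newly_identified]
    new_ribose = sum(1 for r in new if r.modification.blocks_2prime_cleavage)
    new_psi = sum(1 for r in new if r.mod_code == "Ψ")
    return {
        "total_sites": len(atlas),
        "per_molecule": per_molecule,
        "per_type": per_type,
        "distinct_types": len(per_type),
        "at_or_above_threshold": sum(1 for r in atlas.records if r.percent >= percent_threshold),
        "percent_threshold": percent_threshold,
        "newly_identified": len(new),
        "newly_identified_ribose_methyl": new_ribose,
        "newly_identified_pseudouridine": new_psi,
    }


def annotate_sequence(sequence: str, atlas: PtmAtlas, molecule: str):
    """Attach the atlas' modification codes for ``molecule`` to a plain sequence.

    Each record's parent base must match the residue at its position;
    mismatches are reported with the position.  Returns a
    :class:`silnas.digestion.ModifiedRnaSequence`.
    """
    from .digestion import ModifiedRnaSequence

    seq = sequence.upper().replace("T", "U")
    mods: dict[int, str] = {}
    for rec in atlas.sites(molecule):
        if rec.position > len(seq):
            raise ValueError(f"{molecule} position {rec.position} beyond sequence length {len(seq)}")
        base = seq[rec.position - 1]
        expected = rec.modification.parent_base
        if base != expected:
            raise ValueError(
                f"base mismatch at {molecule}:{rec.position}: {rec.mod_code} requires "
                f"{expected}, sequence has {base}"
            )
        mods[rec.position] = rec.mod_code
    return ModifiedRnaSequence(id=molecule, residues=seq, mods=mods)


def atlas_to_bed(atlas: PtmAtlas, molecule: str | None = None) -> str:
    """Export modified positions as BED lines (0-based, half-open)."""
    lines = []
    for r in atlas.records:
        if molecule is not None and r.molecule != molecule:
            continue
        lines.append(f"{r.molecule}\t{r.position - 1}\t{r.position}\t{r.mod_code}\t{r.percent:g}")
    return "\n".join(lines) + ("\n" if lines else "")
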