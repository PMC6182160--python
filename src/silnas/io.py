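"""File formats: FASTA sequences, modification TSVs, MS1 feature tables,
fragment tables, and MGF-like MS/MS peak lists.

MS1 feature lists use a simple CSV/TSV dialect with a header row and
columns ``mz, charge, rt, intensity`` (delimiter inferred from the file
extension: ``.tsv`` → tab, otherwise comma).  Fragment tables are TSV
with columns ``parent, start, end, sequence, mods, five_prime,
three_prime, missed_cleavages, enzyme``; ``mods`` is a semicolon list of
``position:code`` entries in parent coordinates.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .digestion import ModifiedRnaSequence, NucleolyticFragment
from .silnas_quant import Ms1Feature
from .spectral_assignment import MsmsSpectrum

__all__ = [
    "read_fasta",
    "read_modification_tsv",
    "read_features",
    "write_features",
    "write_fragments",
    "read_fragments",
    "read_mgf",
    "write_mgf",
]


def read_fasta(path: str | Path) -> list[ModifiedRnaSequence]:
    """Read RNA sequences (T coerced to U) as unmodified molecules."""
    return [
        ModifiedRnaSequence(id=rec.id, residues=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_modification_tsv(path: str | Path) -> dict[str, dict[int, str]]:
    """Per-molecule modification maps from a TSV with columns
    ``molecule, position, mod_code``."""
    out: dict[str, dict[int, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["molecule"], {})[int(row["position"])] = row["mod_code"]
    return out


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_features(path: str | Path) -> list[Ms1Feature]:
    path = Path(path)
    feats = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path))
        required = {"mz", "charge", "rt", "intensity"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for row in reader:
            feats.append(
                Ms1Feature(
                    mz=float(row["mz"]),
                    charge=int(row["charge"]),
                    rt=float(row["rt"]),
                    intensity=float(row["intensity"]),
                )
            )
    return feats


def write_features(features: Iterable[Ms1Feature], path: str | Path) -> None:
    path = Path(path)
    delim = _delimiter(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delim)
        w.writerow(["mz", "charge", "rt", "intensity"])
        for f in features:
            w.writerow([f"{f.mz:.6f}", f.charge, f"{f.rt:.2f}", f"{f.intensity:.4f}"])


def _mods_str(frag: NucleolyticFragment) -> str:
    return ";".join(f"{p}:{c}" for p, c in sorted(frag.mods.items()))


def write_fragments(fragments: Iterable[NucleolyticFragment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["parent", "start", "end", "sequence", "mods", "five_prime", "three_prime",
             "missed_cleavages", "enzyme"]
        )
        for f in fragments:
            w.writerow(
                [f.parent_id, f.start, f.end, f.residues, _mods_str(f),
                 f.five_prime_terminus, f.three_prime_terminus, f.missed_cleavages, f.enzyme]
            )


def read_fragments(path: str | Path) -> list[NucleolyticFragment]:
    frags = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            mods = {}
            if row["mods"]:
                for item in row["mods"].split(";"):
                    pos, code = item.split(":")
                    mods[int(pos)] = code
            frags.append(
                NucleolyticFragment(
                    parent_id=row["parent"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    residues=row["sequence"],
                    mods=mods,
                    five_prime_terminus=row["five_prime"],  # type: ignore[arg-type]
                    three_prime_terminus=row["three_prime"],  # type: ignore[arg-type]
                    missed_cleavages=int(row["missed_cleavages"]),
                    enzyme=row["enzyme"],  # type: ignore[arg-type]
                )
            )
    return frags


def read_mgf(path: str | Path) -> list[MsmsSpectrum]:
    """Minimal MGF-like reader (BEGIN IONS / END IONS blocks with TITLE,
    PEPMASS as precursor m/z, CHARGE as magnitude)."""
    spectra = []
    title, pepmass, charge, peaks = None, None, 1, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                title, pepmass, charge, peaks = None, None, 1, []
            elif line == "END IONS":
                if pepmass is None:
                    raise ValueError(f"{path}: spectrum without PEPMASS")
                spectra.append(
                    MsmsSpectrum(title or f"spectrum{len(spectra) + 1}", pepmass, charge, peaks)
                )
            elif line.startswith("TITLE="):
                title = line[6:]
            elif line.startswith("PEPMASS="):
                pepmass = float(line[8:].split()[0])
            elif line.startswith("CHARGE="):
                charge = abs(int(line[7:].rstrip("+-")))
            elif line[0].isdigit():
                mz, inten = line.split()[:2]
                peaks.append((float(mz), float(inten)))
    return spectra


def write_mgf(spectra: Iterable[MsmsSpectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}-\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz:.6f} {inten:.4f}\n")
            fh.write("END IONS\n")
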