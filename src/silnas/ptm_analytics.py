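"""Downstream analytics over modification atlases.

Three analyses: (i) 1D modification-density profiles along an rRNA chain
with cluster calls — modification sites accumulate in discrete regions
of the large-subunit rRNA rather than uniformly; (ii) cross-species
site-count comparison (human vs budding yeast vs E. coli), reflecting the
expansion of snoRNA-guided modification during eukaryotic evolution; and
(iii) per-site case/control comparison of modification stoichiometry
with a one-tailed two-sample Student's t-test (pooled variance, testing
for *reduction* in cases), the analysis used to detect hypomodified
pseudouridines in dyskeratosis congenita patient ribosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ptm_catalog import MODIFICATION_ALPHABET, PtmAtlas

__all__ = [
    "DensityProfile",
    "ClusterInterval",
    "modification_density",
    "SPECIES_SITE_COUNTS",
    "compare_species_counts",
    "GroupComparison",
    "compare_groups",
]


@dataclass(frozen=True)
class ClusterInterval:
    start: int
    end: int
    site_count: int

    def overlaps(self, lo: int, hi: int) -> bool:
        return self.start <= hi and self.end >= lo


@dataclass
class DensityProfile:
    """Sliding-window modification density along one molecule."""

    molecule: str
    window: int
    min_sites: int
    length: int
    density: np.ndarray  # per-position count in the centered window
    clusters: list[ClusterInterval] = field(default_factory=list)

    def largest_clusters(self, k: int) -> list[ClusterInterval]:
        return sorted(self.clusters, key=lambda c: -c.site_count)[:k]


def modification_density(
    atlas: PtmAtlas, molecule: str, window: int = 200, min_sites: int = 8
) -> DensityProfile:
    """Per-position site count in a centered ``window`` and cluster calls.

    density[p] counts the modified sites within [p - window/2,
    p + window/2); clusters are the maximal coordinate runs where the
    density reaches ``min_sites``, reported as the span of the sites
    inside each run together with their count.  Results are independent
    of atlas row order (positions are a set).
    """
    if molecule not in atlas.molecule_lengths:
        raise ValueError(f"unknown molecule {molecule!r}")
    length = atlas.molecule_lengths[molecule]
    positions = sorted({r.position for r in atlas.sites(molecule)})
    hits = np.zeros(length + 1)
    for p in positions:
        hits[p] = 1
    half = window // 2
    csum = np.concatenate([[0], np.cumsum(hits)])
    density = np.empty(length + 1)
    for p in range(length + 1):
        lo = max(p - half, 0)
        hi = min(p + half, length + 1)
        density[p] = csum[hi] - csum[lo]
    density[0] = 0
    clusters = []
    in_run, run_start = False, 0
    for p in range(1, length + 2):
        dense = p <= length and density[p] >= min_sites
        if dense and not in_run:
            in_run, run_start = True, p
        elif not dense and in_run:
            in_run = False
            lo, hi = max(run_start - half, 1), min(p - 1 + half, length)
            inside = [q for q in positions if lo <= q <= hi]
            if inside:
                clusters.append(ClusterInterval(min(inside), max(inside), len(inside)))
    # adjacent dense runs can claim overlapping site spans; merge them
    merged: list[ClusterInterval] = []
    for c in clusters:
        if merged and c.start <= merged[-1].end:
            prev = merged[-1]
            sites = [q for q in positions if prev.start <= q <= max(prev.end, c.end)]
            merged[-1] = ClusterInterval(prev.start, max(prev.end, c.end), len(sites))
        else:
            merged.append(c)
    return DensityProfile(molecule, window, min_sites, length, density[1:], merged)


#: Published whole-ribosome internal modification site counts.
SPECIES_SITE_COUNTS: dict[str, int] = {
    "Homo sapiens": 228,
    "Saccharomyces cerevisiae": 112,
    # E. coli: 11 sites in 16S plus 25 in 23S
    "Escherichia coli": 36,
}


def _human_class_breakdown(atlas: PtmAtlas) -> dict[str, int]:
    counts = {"pseudouridine": 0, "ribose-methyl": 0, "base-modified": 0}
    for r in atlas.records:
        mod = MODIFICATION_ALPHABET[r.mod_code]
        if r.mod_code == "Ψ":
            counts["pseudouridine"] += 1
        elif mod.blocks_2prime_cleavage:  # any 2'-O-methyl, incl. Ψm
            counts["ribose-methyl"] += 1
        else:
            counts["base-modified"] += 1
    return counts


def compare_species_counts(human_atlas: PtmAtlas | None = None) -> dict:
    """Site-count table across species with the human per-class breakdown.

    The human count is derived from the atlas (packaged if not given);
    yeast and E. coli whole-ribosome counts are packaged literals.
    """
    if human_atlas is None:
        from .ptm_catalog import load_atlas

        human_atlas = load_atlas("human")
    counts = dict(SPECIES_SITE_COUNTS)
    counts["Homo sapiens"] = len(human_atlas)
    return {
        "site_counts": counts,
        "human_class_breakdown": _human_class_breakdown(human_atlas),
        "e_coli_by_molecule": {"16S": 11, "23S": 25},
    }


@dataclass
class GroupComparison:
    """One-tailed t-test of case vs control stoichiometry at one site."""

    molecule: str
    position: int
    mod_code: str
    case_values: list[float]
    control_values: list[float]
    mean_difference: float  # case - control, percentage points
    t_statistic: float
    p_value: float
    flagged: bool
    flagged_strict: bool


def compare_groups(
    case_atlases: Sequence[PtmAtlas],
    control_atlases: Sequence[PtmAtlas],
    alpha: float = 0.005,
    alpha_strict: float = 0.0005,
    bonferroni: bool = False,
) -> list[GroupComparison]:
    """Per-site one-tailed Student's t-test for reduced modification in cases.

    Equal-variance pooled t on percent values over sites shared by every
    atlas of both groups; alternative hypothesis: case mean < control
    mean.  Sites missing from any atlas are skipped.  ``bonferroni``
    divides both alpha levels by the number of shared sites (off by
    default; the conventional analysis reports per-site significance).
    """
    if len(case_atlases) < 2 or len(control_atlases) < 2:
        raise ValueError("need >= 2 atlases per group")
    keys = None
    for atlas in [*case_atlases, *control_atlases]:
        ks = {(r.molecule, r.position, r.mod_code) for r in atlas.records}
        keys = ks if keys is None else keys & ks
    keys = sorted(keys or set())
    m = len(keys)
    a1 = alpha / m if (bonferroni and m) else alpha
    a2 = alpha_strict / m if (bonferroni and m) else alpha_strict
    out = []
    for molecule, position, code in keys:
        case = [a.get(molecule, position).percent for a in case_atlases]
        ctrl = [a.get(molecule, position).percent for a in control_atlases]
        with warnings.catch_warnings():
            # near-identical groups trip scipy's precision-loss warning; the
            # degenerate case is handled explicitly below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(case, ctrl, equal_var=True, alternative="less")
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):  # zero pooled variance, equal means: t taken as 0
            t, p = 0.0, 0.5
        out.append(
            GroupComparison(
                molecule, position, code, list(case), list(ctrl),
                mean_difference=float(np.mean(case) - np.mean(ctrl)),
                t_statistic=t, p_value=p,
                flagged=p < a1, flagged_strict=p < a2,
            )
        )
    return out
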