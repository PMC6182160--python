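"""SILNAS quantitation: light/heavy MS1 pairing and stoichiometry estimation.

The measurement design: natural (sample) RNA is mixed 1:1 with an
in-vitro-transcribed, stable-isotope-labeled, unmodified reference of
identical sequence, and the mixture is digested.  For every digestion
product the reference contributes a "heavy" MS1 feature whose intensity
reflects *all* molecules, while the sample's feature at the unmodified
fragment mass ("light") reflects only the molecules NOT modified on that
fragment — any mass-shifting modification moves them elsewhere.  The
stoichiometry of modification is therefore

    percent = 100 * (I_H - c * I_L) / I_H

with a global mixing-correction factor ``c`` fitted on pairs from
modification-free fragments.  Two corrections refine the raw ratio:

* mixing: the nominal 1:1 mix (by A260) is imperfect; ``c`` is the
  median heavy/light ratio over unmodified pairs (robust to the odd
  contaminated pair), conventionally fitted on ~10 such pairs.
* label impurity: a nominally labeled residue lacks its label with
  probability ~2% (commercial rNTPs), so a fragment with n labeled
  residues shows only (1-p)^n of the reference at the heavy mass while
  p^n of it lands exactly on the light (fully unlabeled) mass.  The
  estimator rescales the heavy intensity by (1-p)^-n and subtracts the
  p^n leakage from the light intensity before taking the ratio.

Estimates from sequence-redundant fragments pool signal across all copies
of the sequence and are reported as lower bounds carrying the redundancy
count; unique-fragment estimates take precedence at aggregation.
"""

from __future__ import annotations

import math
import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import NucleolyticFragment
from .mass_calc import LabelingScheme, fragment_neutral_mass, mz_from_neutral
from .ptm_catalog import PtmAtlas, PtmSiteRecord

__all__ = [
    "Ms1Feature",
    "PairMeasurement",
    "CorrectionModel",
    "SiteEstimate",
    "match_pairs",
    "fit_correction",
    "estimate_stoichiometry",
    "aggregate_sites",
]


@dataclass(frozen=True)
class Ms1Feature:
    """One deconvoluted MS1 feature (negative mode; charge is magnitude)."""

    mz: float
    charge: int
    rt: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.intensity <= 0 or self.charge < 1:
            raise ValueError("invalid MS1 feature")


@dataclass
class PairMeasurement:
    """A matched light/heavy feature pair for one fragment.

    ``light_intensity`` is 0 when no light feature fell inside tolerance
    (the fully-modified case).  Intensities are summed over charge states.
    """

    fragment: NucleolyticFragment
    light_intensity: float
    heavy_intensity: float
    n_labeled_residues: int
    rt_delta: float = 0.0
    ppm_error_light: float = math.nan
    ppm_error_heavy: float = math.nan
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.heavy_intensity <= 0:
            raise ValueError("a usable pair needs heavy intensity > 0")
        if self.n_labeled_residues < 1:
            raise ValueError("pair requires >= 1 labeled residue (channels must differ in mass)")


@dataclass
class CorrectionModel:
    """Global mixing factor plus the label-impurity fraction."""

    mixing_factor: float = 1.0
    impurity_fraction: float = 0.02
    pairs_used: int = 0

    def __post_init__(self) -> None:
        if self.mixing_factor <= 0:
            raise ValueError("mixing factor must be > 0")
        if not (0 <= self.impurity_fraction < 1):
            raise ValueError("impurity fraction must be in [0, 1)")

    def corrected_intensities(self, pair: PairMeasurement) -> tuple[float, float]:
        """(light*, heavy*) after undoing label-impurity leakage."""
        p = self.impurity_fraction
        n = pair.n_labeled_residues
        heavy_total = pair.heavy_intensity / (1 - p) ** n
        light = max(pair.light_intensity - heavy_total * p**n, 0.0)
        return light, heavy_total


def _match_channel(
    mass: float,
    features_by_charge: Mapping[int, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ppm_tol: float,
    rt_window: tuple[float, float] | None,
    charges: Sequence[int],
):
    """Best feature per charge within ppm tolerance; returns (intensity sum,
    best ppm error, rt of the strongest match, ambiguity flag)."""
    total, best_ppm, best_rt, best_int = 0.0, math.nan, math.nan, 0.0
    ambiguous = False
    for z in charges:
        if z not in features_by_charge:
            continue
        mzs, rts, ints = features_by_charge[z]
        target = mz_from_neutral(mass, z)
        ppm = (mzs - target) / target * 1e6
        ok = np.abs(ppm) <= ppm_tol
        if rt_window is not None:
            ok &= (rts >= rt_window[0]) & (rts <= rt_window[1])
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            continue
        order = idx[np.argsort(np.abs(ppm[idx]), kind="stable")]
        pick = order[0]
        if order.size > 1 and math.isclose(
            abs(ppm[order[0]]), abs(ppm[order[1]]), abs_tol=1e-9
        ):
            ambiguous = True
        total += float(ints[pick])
        if float(ints[pick]) > best_int:
            best_int = float(ints[pick])
            best_ppm = float(ppm[pick])
            best_rt = float(rts[pick])
    return total, best_ppm, best_rt, ambiguous


def _index_features(features: Iterable[Ms1Feature]):
    by_charge: dict[int, list[Ms1Feature]] = {}
    for f in features:
        by_charge.setdefault(f.charge, []).append(f)
    out = {}
    for z, fs in by_charge.items():
        fs.sort(key=lambda f: f.mz)
        out[z] = (
            np.array([f.mz for f in fs]),
            np.array([f.rt for f in fs]),
            np.array([f.intensity for f in fs]),
        )
    return out


def match_pairs(
    fragments: Sequence[NucleolyticFragment],
    light_features: Iterable[Ms1Feature],
    heavy_features: Iterable[Ms1Feature],
    heavy_labeling: LabelingScheme,
    light_labeling: LabelingScheme | None = None,
    ppm_tol: float = 5.0,
    rt_tol: float | None = 60.0,
    charges: Sequence[int] = (1, 2, 3),
) -> list[PairMeasurement]:
    """Match each fragment's light and heavy MS1 features.

    The light channel is searched at the fragment's *unmodified* mass
    under ``light_labeling`` (None = natural isotopes) and the heavy
    channel at its unmodified mass under ``heavy_labeling``; per channel
    and charge the closest-ppm feature inside ``ppm_tol`` wins and charge
    states are summed.  The pair must co-elute within ``rt_tol`` seconds
    (None disables the check).  Fragments without a heavy match, or with
    no labeled residue (light and heavy masses coincide), are skipped;
    an exact ppm tie between two heavy candidates flags the pair
    ambiguous, which excludes it from correction fitting.
    """
    light_idx = _index_features(light_features)
    heavy_idx = _index_features(heavy_features)
    pairs = []
    for frag in fragments:
        n_lab = heavy_labeling.n_labeled(frag)
        if n_lab < 1:
            continue
        bare = NucleolyticFragment(
            frag.parent_id, frag.start, frag.end, frag.residues, {},
            frag.five_prime_terminus, frag.three_prime_terminus,
            frag.missed_cleavages, frag.enzyme,
        )
        heavy_mass = fragment_neutral_mass(bare, heavy_labeling)
        light_mass = fragment_neutral_mass(bare, light_labeling)
        h_int, h_ppm, h_rt, h_amb = _match_channel(heavy_mass, heavy_idx, ppm_tol, None, charges)
        if h_int <= 0:
            continue
        window = None if rt_tol is None or math.isnan(h_rt) else (h_rt - rt_tol, h_rt + rt_tol)
        l_int, l_ppm, l_rt, _ = _match_channel(light_mass, light_idx, ppm_tol, window, charges)
        pairs.append(
            PairMeasurement(
                fragment=frag,
                light_intensity=l_int,
                heavy_intensity=h_int,
                n_labeled_residues=n_lab,
                rt_delta=(l_rt - h_rt) if not math.isnan(l_rt) and not math.isnan(h_rt) else 0.0,
                ppm_error_light=l_ppm,
                ppm_error_heavy=h_ppm,
                ambiguous=h_amb,
            )
        )
    return pairs


def fit_correction(
    unmodified_pairs: Sequence[PairMeasurement],
    impurity_fraction: float = 0.02,
) -> CorrectionModel:
    """Fit the mixing factor from pairs of modification-free fragments.

    c = median of heavy*/light* over the supplied pairs (impurity-
    corrected intensities), so that a perfectly mixed run gives c = 1.
    Warns below 10 pairs (the conventional count) and refuses below 3.
    """
    usable = [
        p for p in unmodified_pairs if not p.ambiguous and p.light_intensity > 0
    ]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 unambiguous unmodified pairs to fit the mixing factor, got {len(usable)}; "
            "supply CorrectionModel(mixing_factor=1.0) explicitly to skip fitting"
        )
    if len(usable) < 10:
        warnings.warn(
            f"mixing factor fitted on only {len(usable)} unmodified pairs (< 10)",
            stacklevel=2,
        )
    probe = CorrectionModel(1.0, impurity_fraction, 0)
    ratios = []
    for p in usable:
        light, heavy = probe.corrected_intensities(p)
        if light > 0:
            ratios.append(heavy / light)
    return CorrectionModel(
        mixing_factor=statistics.median(ratios),
        impurity_fraction=impurity_fraction,
        pairs_used=len(ratios),
    )


def estimate_stoichiometry(pair: PairMeasurement, correction: CorrectionModel) -> float:
    """Percent modification of the fragment covered by a light/heavy pair.

    percent = 100 * (H* - c * L*) / H* with impurity-corrected
    intensities; clipped at 0 below, reported verbatim above 100.
    """
    light, heavy = correction.corrected_intensities(pair)
    percent = 100.0 * (heavy - correction.mixing_factor * light) / heavy
    return max(percent, 0.0)


@dataclass
class SiteEstimate:
    """Aggregated stoichiometry estimate for one modified site."""

    molecule: str
    position: int
    mod_code: str
    percent: float | None
    sd: float | None
    n_fragments: int
    redundancy_count: int
    lower_bound: bool
    quantified: bool


def aggregate_sites(
    pairs: Sequence[PairMeasurement],
    site_map: Mapping[tuple[int, int], Sequence[tuple[str, int, str]]],
    correction: CorrectionModel,
) -> list[SiteEstimate]:
    """Combine per-fragment estimates into per-site records.

    ``site_map`` maps fragment (start, end) coordinates to the modified
    sites [(molecule, position, mod_code), ...] the fragment covers;
    only fragments covering exactly one site give site-resolved
    estimates.  Sequence-unique fragments give point estimates; if a
    site is covered only by redundant fragments the (diluted) estimate
    is kept as a lower bound with its redundancy count.  Multiple
    unique-fragment estimates for one site are averaged with their SD.
    Sites in ``site_map`` with no usable pair are reported unquantified.
    """
    # redundancy here is plain-sequence identity: the unmodified-mass pair
    # pools signal from every copy, whichever copy carries the modification
    from collections import Counter

    counts = Counter(p.fragment.residues for p in pairs)
    unique_est: dict[tuple[str, int, str], list[float]] = {}
    redundant_est: dict[tuple[str, int, str], list[tuple[float, int]]] = {}
    all_sites: set[tuple[str, int, str]] = set()
    for sites in site_map.values():
        all_sites.update(tuple(s) for s in sites)
    for pair in pairs:
        frag = pair.fragment
        sites = site_map.get((frag.start, frag.end), ())
        if len(sites) != 1:
            continue
        site = tuple(sites[0])
        est = estimate_stoichiometry(pair, correction)
        k = counts.get(frag.residues, 1)
        if k == 1:
            unique_est.setdefault(site, []).append(est)
        else:
            redundant_est.setdefault(site, []).append((est, k))
    out = []
    for site in sorted(all_sites, key=lambda s: (s[0], s[1])):
        molecule, position, code = site
        if site in unique_est:
            vals = unique_est[site]
            out.append(
                SiteEstimate(
                    molecule, position, code,
                    percent=float(np.mean(vals)),
                    sd=float(np.std(vals)) if len(vals) > 1 else None,
                    n_fragments=len(vals),
                    redundancy_count=1,
                    lower_bound=False,
                    quantified=True,
                )
            )
        elif site in redundant_est:
            vals = redundant_est[site]
            k = max(r for _, r in vals)
            out.append(
                SiteEstimate(
                    molecule, position, code,
                    percent=float(np.mean([v for v, _ in vals])),
                    sd=float(np.std([v for v, _ in vals])) if len(vals) > 1 else None,
                    n_fragments=len(vals),
                    redundancy_count=k,
                    lower_bound=True,
                    quantified=True,
                )
            )
        else:
            out.append(
                SiteEstimate(
                    molecule, position, code,
                    percent=None, sd=None, n_fragments=0,
                    redundancy_count=1, lower_bound=False, quantified=False,
                )
            )
    return out


def site_estimates_to_atlas(
    estimates: Sequence[SiteEstimate], species: str = "synthetic"
) -> PtmAtlas:
    """Quantified site estimates as a PtmAtlas (schema of the packaged table)."""
    records = [
        PtmSiteRecord(
            molecule=e.molecule,
            position=e.position,
            mod_code=e.mod_code,
            percent=round(e.percent, 4),
            redundancy_count=e.redundancy_count,
        )
        for e in estimates
        if e.quantified and e.percent is not None
    ]
    return PtmAtlas(species=species, records=records, molecule_lengths={})
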