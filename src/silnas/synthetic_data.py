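"""Ground-truth simulation of SILNAS experiments.

Emulates the 1:1 mixture of a natural (modified) RNA digest with an
in-vitro-transcribed, isotope-labeled, unmodified reference digest, at
the MS1 feature level (deconvoluted m/z, charge, retention time,
intensity).  The generative model per digestion fragment:

* the reference ("heavy") channel carries every fragment of the
  unmodified sequence at its labeled mass;
* the sample ("light") channel carries, for a fragment whose single
  covered site is modified with stoichiometry s, the unmodified-mass
  feature at relative abundance (1 - s) and the modified-mass feature at
  s (modified molecules of a cleavage-blocking 2'-O-methyl produce the
  fused read-through fragment instead);
* intensities are multiplicative-noise draws:
  a per-fragment ionization/abundance factor exp(N(0, sigma_fragment))
  SHARED by the co-eluting light and heavy features of a pair (the
  design's premise — the pair is chemically identical up to isotopes, so
  ionization and elution cancel in the ratio), an independent
  per-channel residual exp(N(0, sigma_channel)), and one global mixing
  factor exp(N(0, sigma_mixing)) applied to the heavy channel;
* label impurity: a labeled residue lacks its label with probability p,
  so a heavy fragment with n labeled residues keeps (1-p)^n at the fully
  labeled mass and sheds a binomial tail of lighter satellites, the
  k = n term landing exactly on the light unmodified mass.

Defaults (sigma_fragment 0.5, sigma_channel 0.014, sigma_mixing 0.02,
impurity 0.02) are calibrated so the per-site stoichiometry SD is about
2 percentage points, the reproducibility this quantitation method
reports; see docs/methods.md.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .digestion import (
    ModifiedRnaSequence,
    NucleolyticFragment,
    digest,
    fragment_redundancy,
)
from .mass_calc import (
    CU_13C9,
    D2_U,
    G_13C10,
    LabelingScheme,
    fragment_neutral_mass,
    msms_ion_series,
    mz_from_neutral,
    signature_ion_mz,
)
from .silnas_quant import Ms1Feature
from .spectral_assignment import MsmsSpectrum

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_molecule",
    "simulate_channels",
    "simulate_msms",
    "simulate_d2_digest_masses",
]

#: Modification codes the default simulation plants (all mass-shifting,
#: hence quantifiable against a 13C reference under natural light isotopes).
DEFAULT_MOD_POOL: tuple[str, ...] = ("Am", "Cm", "Gm", "Um", "m5C", "m6A", "m3U", "ac4C")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated SILNAS run."""

    seed: int
    length: int = 4000
    gc_content: float = 0.5
    n_sites: int = 50
    mod_pool: Sequence[str] = DEFAULT_MOD_POOL
    #: planted stoichiometries are drawn from this grid (percent)
    stoichiometry_grid: Sequence[float] = tuple(range(5, 101, 5))
    enzyme: Literal["T1", "A"] = "T1"
    heavy_labeling: LabelingScheme = G_13C10
    light_labeling: LabelingScheme | None = None
    sigma_fragment: float = 0.5
    sigma_channel: float = 0.014
    sigma_mixing: float = 0.02
    impurity_fraction: float = 0.02
    mz_ppm_sd: float = 1.0
    rt_sd: float = 2.0
    msms_drop_rate: float = 0.1
    base_intensity: float = 1e6
    #: planted sites must sit on unique-sequence fragments of at least
    #: this length, with no second planted site on the same fragment
    min_fragment_length: int = 4

    def __post_init__(self) -> None:
        for name in ("gc_content", "impurity_fraction", "msms_drop_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """A simulated molecule with its planted truth."""

    sequence: ModifiedRnaSequence  # reference (mods annotated at planted sites)
    stoichiometry: dict[int, float]  # position -> percent
    config: SimulationConfig
    #: fragment (start, end) -> [(molecule, position, mod_code)] site map
    site_map: dict[tuple[int, int], list[tuple[str, int, str]]] = field(default_factory=dict)
    #: fragments eligible for mixing-factor fitting (no planted site nearby)
    unmodified_spans: set[tuple[int, int]] = field(default_factory=set)

    @property
    def fragments(self) -> list[NucleolyticFragment]:
        return digest(self.sequence, self.config.enzyme, 0)


def _rt_fraction(key: str) -> float:
    """Deterministic pseudo-elution fraction in [0, 1) for a fragment species."""
    import hashlib

    h = hashlib.sha1(key.encode()).digest()
    return int.from_bytes(h[:6], "big") / 2**48


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=length, p=probs))


def simulate_molecule(config: SimulationConfig) -> GroundTruth:
    """Random sequence with planted modifications and stoichiometries.

    Site placement honors parent-base rules and, to keep every planted
    site independently quantifiable (the situation the real workflow
    engineers via RNase H), requires the covering fragment of the
    configured digest to be sequence-unique, at least
    ``min_fragment_length`` nt, and free of other planted sites.
    """
    from .ptm_catalog import MODIFICATION_ALPHABET

    rng = np.random.default_rng(config.seed)
    plain = ModifiedRnaSequence("sim", _random_sequence(rng, config.length, config.gc_content))
    frags = digest(plain, config.enzyme, 0)
    counts = fragment_redundancy(frags)
    # composition-unique fragments have a unique mass in the digest, so
    # their MS1 features cannot be confused with an isomer's
    comp_counts = Counter("".join(sorted(f.key())) for f in frags)
    eligible = [
        f
        for f in frags
        if len(f) >= config.min_fragment_length
        and counts[f.key()] == 1
        and comp_counts["".join(sorted(f.key()))] == 1
        and config.heavy_labeling.n_labeled(f) >= 1
    ]
    rng.shuffle(eligible)
    mods: dict[int, str] = {}
    stoich: dict[int, float] = {}
    site_map: dict[tuple[int, int], list[tuple[str, int, str]]] = {}
    pool = list(config.mod_pool)
    for frag in eligible:
        if len(stoich) >= config.n_sites:
            break
        # pick a residue of the fragment a pooled mod can sit on; avoid the
        # cleavage-determining final residue so planting never changes the
        # light digest pattern for unmodified molecules
        choices = []
        for i, base in enumerate(frag.residues[:-1], start=1):
            codes = [c for c in pool if MODIFICATION_ALPHABET[c].parent_base == base]
            if codes:
                choices.append((frag.start + i - 1, codes))
        if not choices:
            continue
        pos, codes = choices[rng.integers(len(choices))]
        code = codes[rng.integers(len(codes))]
        mods[pos] = code
        stoich[pos] = float(rng.choice(config.stoichiometry_grid))
        site_map[(frag.start, frag.end)] = [("sim", pos, code)]
    seq = ModifiedRnaSequence("sim", plain.residues, mods)
    modified_spans = set(site_map)
    unmodified = set()
    for f in frags:
        if (f.start, f.end) in modified_spans:
            continue
        # exclude immediate neighbors of planted fragments: a blocked
        # cleavage next door would leak modification signal into them
        if any(s - 1 <= f.end and f.start <= e + 1 for (s, e) in modified_spans):
            continue
        if (
            config.heavy_labeling.n_labeled(f) >= 1
            and counts[f.key()] == 1
            and comp_counts["".join(sorted(f.key()))] == 1
        ):
            unmodified.add((f.start, f.end))
    return GroundTruth(seq, stoich, config, site_map, unmodified)


def _emit(
    features: list[Ms1Feature],
    rng: np.random.Generator,
    mass: float,
    rt: float,
    intensity: float,
    config: SimulationConfig,
    charges=(1, 2),
    charge_split=(0.65, 0.35),
) -> None:
    if intensity <= 0:
        return
    for z, fr in zip(charges, charge_split):
        mz = mz_from_neutral(mass, z)
        mz *= 1 + rng.normal(0, config.mz_ppm_sd) * 1e-6
        features.append(Ms1Feature(mz=mz, charge=z, rt=rt, intensity=intensity * fr))


def _modified_form_fragment(
    truth: GroundTruth, pos: int
) -> NucleolyticFragment:
    """The fragment covering ``pos`` in molecules modified (only) at ``pos``."""
    variant = ModifiedRnaSequence(
        truth.sequence.id, truth.sequence.residues, {pos: truth.sequence.mods[pos]}
    )
    for f in digest(variant, truth.config.enzyme, 0):
        if f.covers(pos):
            return f
    raise AssertionError("unreachable: every position is covered")


def simulate_channels(truth: GroundTruth) -> tuple[list[Ms1Feature], list[Ms1Feature]]:
    """Simulate (light, heavy) MS1 feature lists for one run.

    Duplicate-sequence fragments co-add into single features per channel,
    reproducing the redundancy dilution the planner exists to remove.
    """
    config = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    mixing = math.exp(rng.normal(0, config.sigma_mixing))
    p = config.impurity_fraction
    light: list[Ms1Feature] = []
    heavy: list[Ms1Feature] = []
    # accumulate intensity per (channel, neutral mass string) so identical
    # sequences pool; rt shared within a pool
    light_acc: dict[str, list] = {}
    heavy_acc: dict[str, list] = {}

    def add(acc, key, mass, rt, amount):
        slot = acc.setdefault(key, [mass, rt, 0.0])
        slot[2] += amount

    for frag in truth.fragments:
        span = (frag.start, frag.end)
        key = frag.key()
        # sequence-determined elution time spreads isomers apart, as the
        # chromatography does; jitter is per-run
        rt = 60.0 + 3400.0 * _rt_fraction(key) + rng.normal(0, config.rt_sd)
        abundance = config.base_intensity * math.exp(rng.normal(0, config.sigma_fragment))
        bare = NucleolyticFragment(
            frag.parent_id, frag.start, frag.end, frag.residues, {},
            frag.five_prime_terminus, frag.three_prime_terminus,
            frag.missed_cleavages, frag.enzyme,
        )
        light_mass = fragment_neutral_mass(bare, config.light_labeling)
        n_lab = config.heavy_labeling.n_labeled(frag)
        heavy_mass = fragment_neutral_mass(bare, config.heavy_labeling)
        # heavy channel: labeled reference, all fragments unmodified; label
        # impurity spreads a binomial ladder of satellites below the fully
        # labeled mass, the all-unlabeled term landing on the light mass
        increments = sorted(
            {config.heavy_labeling.increments[b] for b in frag.residues if b in config.heavy_labeling.increments}
        )
        inc = increments[0] if increments else 0.0
        for k in range(n_lab + 1):
            amount = abundance * mixing * math.comb(n_lab, k) * p**k * (1 - p) ** (n_lab - k)
            if amount <= 0:
                continue
            if k == 0:
                add(heavy_acc, key, heavy_mass, rt, amount)
            elif k == n_lab and config.light_labeling is None:
                add(light_acc, key, light_mass, rt, amount)
            else:
                add(heavy_acc, f"sat{k}:{key}", heavy_mass - k * inc, rt, amount)
        # light channel: sample molecules
        sites = truth.site_map.get(span, [])
        s = truth.stoichiometry.get(sites[0][1], 0.0) / 100.0 if sites else 0.0
        if s < 1.0:
            add(light_acc, key, light_mass, rt, abundance * (1 - s))
        if sites and s > 0:
            mod_frag = _modified_form_fragment(truth, sites[0][1])
            mod_mass = fragment_neutral_mass(mod_frag, config.light_labeling)
            add(light_acc, "mod:" + mod_frag.key(), mod_mass, rt, abundance * s)

    for acc, out in ((light_acc, light), (heavy_acc, heavy)):
        for mass, rt, amount in acc.values():
            amount *= math.exp(rng.normal(0, config.sigma_channel))
            _emit(out, rng, mass, rt, amount, config)
    return light, heavy


def simulate_msms(
    fragment: NucleolyticFragment,
    config: SimulationConfig,
    labeling: LabelingScheme | None = None,
    max_charge: int = 2,
) -> MsmsSpectrum:
    """Noise-free-mass MS/MS spectrum of one fragment variant.

    Emits the full a/c/w/y series at charges 1..max_charge, dropping
    each peak with ``msms_drop_rate``; Ψ-containing fragments emit the
    signature ion (6-D form under D2-U labeling).  Deterministic given
    the config seed and the fragment coordinates.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, fragment.start, fragment.end])
    )
    mass = fragment_neutral_mass(fragment, labeling)
    charge = min(max_charge, max(1, len(fragment) // 2))
    peaks: list[tuple[float, float]] = []
    for ion in msms_ion_series(fragment, max_charge=max_charge, labeling=labeling):
        if rng.random() < config.msms_drop_rate:
            continue
        mz = ion.mz * (1 + rng.normal(0, config.mz_ppm_sd) * 1e-6)
        peaks.append((mz, float(rng.lognormal(10, 0.5))))
    if any("Ψ" in c for c in fragment.mods.values()):
        labeled = labeling is not None and labeling.psi_increment is not None
        peaks.append((signature_ion_mz(labeled=labeled), float(rng.lognormal(10, 0.5))))
    return MsmsSpectrum(
        spectrum_id=f"{fragment.parent_id}:{fragment.start}-{fragment.end}",
        precursor_mz=mz_from_neutral(mass, charge),
        precursor_charge=charge,
        peaks=peaks,
    )


def simulate_d2_digest_masses(
    seq: ModifiedRnaSequence, config: SimulationConfig
) -> list[float]:
    """Observed neutral masses of a 5,6-D2-U-labeled digest of ``seq``.

    Each fragment contributes its D2-labeled mass (Ψ residues at the
    exchanged, -1.0063 Da form) with a small ppm-scale mass error.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    masses = []
    for frag in digest(seq, config.enzyme, 0):
        m = fragment_neutral_mass(frag, D2_U)
        masses.append(m * (1 + rng.normal(0, config.mz_ppm_sd) * 1e-6))
    return masses
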