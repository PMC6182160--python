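"""silnas: quantitative mapping of RNA chemical modifications.

Implements a stable-isotope internal-standard (SILNAS) workflow for
LC-MS analysis of RNA: in-silico RNase T1/A/H digestion, monoisotopic
mass and a/c/w/y ion calculation, light/heavy MS1 pair matching,
per-site modification stoichiometry estimation with mixing and label-
impurity corrections, pseudouridine calling from 5,6-D2-uridine
labeling, a packaged human rRNA modification atlas, and downstream
atlas analytics (density clusters, species comparisons, case/control
stoichiometry tests).
"""

from __future__ import annotations

from typing import Sequence

from . import (
    digestion,
    mass_calc,
    ptm_analytics,
    ptm_catalog,
    silnas_quant,
    spectral_assignment,
    synthetic_data,
)
from .ptm_catalog import load_atlas, summarize_atlas
from .silnas_quant import (
    CorrectionModel,
    Ms1Feature,
    SiteEstimate,
    aggregate_sites,
    estimate_stoichiometry,
    fit_correction,
    match_pairs,
)

__version__ = "0.1.0"

__all__ = [
    "digestion",
    "mass_calc",
    "ptm_catalog",
    "ptm_analytics",
    "silnas_quant",
    "spectral_assignment",
    "synthetic_data",
    "load_atlas",
    "summarize_atlas",
    "quantify_run",
    "__version__",
]


def quantify_run(
    truth: "synthetic_data.GroundTruth",
    light_features: Sequence[Ms1Feature],
    heavy_features: Sequence[Ms1Feature],
    ppm_tol: float = 5.0,
    rt_tol: float | None = 60.0,
) -> list[SiteEstimate]:
    """Full SILNAS quantitation of one (simulated or real) run.

    Matches light/heavy pairs for the ground truth's digest, fits the
    mixing factor on the truth's modification-free fragments, and
    aggregates per-fragment estimates into per-site records.
    """
    config = truth.config
    pairs = match_pairs(
        truth.fragments,
        light_features,
        heavy_features,
        heavy_labeling=config.heavy_labeling,
        light_labeling=config.light_labeling,
        ppm_tol=ppm_tol,
        rt_tol=rt_tol,
    )
    unmod = [p for p in pairs if (p.fragment.start, p.fragment.end) in truth.unmodified_spans]
    correction = fit_correction(unmod, impurity_fraction=config.impurity_fraction)
    return aggregate_sites(pairs, truth.site_map, correction)
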