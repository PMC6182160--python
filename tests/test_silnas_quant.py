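"""Estimator identities, corrections, matching, and site aggregation."""

import math

import numpy as np
import pytest

from silnas.digestion import ModifiedRnaSequence, NucleolyticFragment, digest_rnase_t1
from silnas.mass_calc import G_13C10, fragment_neutral_mass, mz_from_neutral
from silnas.silnas_quant import (
    CorrectionModel,
    Ms1Feature,
    PairMeasurement,
    aggregate_sites,
    estimate_stoichiometry,
    fit_correction,
    match_pairs,
)


def make_frag(residues="AUCG", start=1, mods=None):
    return NucleolyticFragment(
        "p", start, start + len(residues) - 1, residues, mods or {},
        "OH", "linear-phosphate", 0, "T1",
    )


def make_pair(light, heavy, n_labeled=1, frag=None, ambiguous=False):
    return PairMeasurement(
        fragment=frag or make_frag(),
        light_intensity=light,
        heavy_intensity=heavy,
        n_labeled_residues=n_labeled,
        ambiguous=ambiguous,
    )


IDENTITY = CorrectionModel(mixing_factor=1.0, impurity_fraction=0.0)


class TestEstimatorIdentities:
    def test_equal_intensities_give_zero(self):
        assert estimate_stoichiometry(make_pair(5.0, 5.0), IDENTITY) == 0.0

    def test_absent_light_gives_hundred(self):
        assert estimate_stoichiometry(make_pair(0.0, 5.0), IDENTITY) == 100.0

    def test_sixty_percent(self):
        assert estimate_stoichiometry(make_pair(0.4, 1.0), IDENTITY) == pytest.approx(60.0)

    @pytest.mark.parametrize("k", [1e-3, 1.0, 7.3, 1e6])
    def test_scale_invariance(self, k):
        base = estimate_stoichiometry(make_pair(0.3, 1.2), IDENTITY)
        assert estimate_stoichiometry(make_pair(0.3 * k, 1.2 * k), IDENTITY) == pytest.approx(base)

    def test_simple_form_when_no_corrections(self):
        for il, ih in [(0.1, 1.0), (0.9, 1.1), (0.5, 2.0)]:
            assert estimate_stoichiometry(make_pair(il, ih), IDENTITY) == pytest.approx(
                100 * (1 - il / ih)
            )

    def test_negative_estimates_clipped_to_zero(self):
        assert estimate_stoichiometry(make_pair(2.0, 1.0), IDENTITY) == 0.0

    def test_light_excess_clipped_at_zero(self):
        c = CorrectionModel(mixing_factor=1.2, impurity_fraction=0.0)
        assert estimate_stoichiometry(make_pair(1.0, 1.0), c) == 0.0


class TestImpurityCorrection:
    def test_exact_recovery_with_leakage(self):
        # ground truth: heavy total H, light true L; observed heavy
        # (1-p)^n H, observed light L + p^n H
        p, n, H, s = 0.02, 3, 1000.0, 0.35
        L = (1 - s) * H
        pair = make_pair(L + p**n * H, (1 - p) ** n * H, n_labeled=n)
        c = CorrectionModel(mixing_factor=1.0, impurity_fraction=p)
        assert estimate_stoichiometry(pair, c) == pytest.approx(100 * s, abs=1e-9)

    def test_single_labeled_residue_bias_without_correction(self):
        p, H, s = 0.02, 1000.0, 0.5
        pair = make_pair((1 - s) * H + p * H, (1 - p) * H, n_labeled=1)
        naive = estimate_stoichiometry(pair, IDENTITY)
        corrected = estimate_stoichiometry(pair, CorrectionModel(1.0, p))
        assert corrected == pytest.approx(100 * s, abs=1e-9)
        assert naive < corrected  # uncorrected estimate is biased low


class TestFitCorrection:
    def test_balanced_pairs_give_unity(self):
        pairs = [make_pair(1.0, 1.0) for _ in range(10)]
        model = fit_correction(pairs, impurity_fraction=0.0)
        assert model.mixing_factor == pytest.approx(1.0)
        assert model.pairs_used == 10

    def test_ten_percent_excess_heavy(self):
        pairs = [make_pair(1.0, 1.1) for _ in range(10)]
        assert fit_correction(pairs, 0.0).mixing_factor == pytest.approx(1.1)

    def test_median_robust_to_outlier(self):
        pairs = [make_pair(1.0, 1.0) for _ in range(9)] + [make_pair(1.0, 5.0)]
        assert fit_correction(pairs, 0.0).mixing_factor == pytest.approx(1.0)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_correction([make_pair(1.0, 1.0)] * 2)

    def test_warns_below_ten(self):
        with pytest.warns(UserWarning, match="< 10"):
            fit_correction([make_pair(1.0, 1.0)] * 5, 0.0)

    def test_ambiguous_pairs_excluded(self):
        good = [make_pair(1.0, 1.0) for _ in range(10)]
        bad = [make_pair(1.0, 9.9, ambiguous=True) for _ in range(5)]
        assert fit_correction(good + bad, 0.0).mixing_factor == pytest.approx(1.0)


class TestMatchPairs:
    def _features_for(self, frag, labeling, intensity, rt=100.0, ppm_off=0.0):
        mass = fragment_neutral_mass(frag, labeling)
        mz = mz_from_neutral(mass, 1) * (1 + ppm_off * 1e-6)
        return [Ms1Feature(mz=mz, charge=1, rt=rt, intensity=intensity)]

    def test_exact_features_both_channels(self):
        frag = make_frag("AUCG")
        light = self._features_for(frag, None, 40.0)
        heavy = self._features_for(frag, G_13C10, 100.0)
        pairs = match_pairs([frag], light, heavy, G_13C10)
        assert len(pairs) == 1
        assert pairs[0].light_intensity == pytest.approx(40.0)
        assert pairs[0].heavy_intensity == pytest.approx(100.0)
        assert pairs[0].n_labeled_residues == 1

    def test_missing_light_gives_zero(self):
        frag = make_frag("AUCG")
        heavy = self._features_for(frag, G_13C10, 100.0)
        pairs = match_pairs([frag], [], heavy, G_13C10)
        assert pairs[0].light_intensity == 0.0

    def test_out_of_tolerance_light_ignored(self):
        frag = make_frag("AUCG")
        light = self._features_for(frag, None, 40.0, ppm_off=12.0)
        heavy = self._features_for(frag, G_13C10, 100.0)
        pairs = match_pairs([frag], light, heavy, G_13C10, ppm_tol=5.0)
        assert pairs[0].light_intensity == 0.0

    def test_equal_ppm_tie_flags_ambiguous(self):
        frag = make_frag("AUCG")
        mass = fragment_neutral_mass(frag, G_13C10)
        mz = mz_from_neutral(mass, 1)
        heavy = [
            Ms1Feature(mz=mz * (1 + 2e-6), charge=1, rt=100.0, intensity=10.0),
            Ms1Feature(mz=mz * (1 - 2e-6), charge=1, rt=100.0, intensity=20.0),
        ]
        pairs = match_pairs([frag], [], heavy, G_13C10)
        assert pairs[0].ambiguous

    def test_unlabeled_fragment_skipped(self):
        frag = make_frag("AUCU")  # no G: invisible to a G-labeled reference
        pairs = match_pairs([frag], [], self._features_for(frag, G_13C10, 5.0), G_13C10)
        assert pairs == []

    def test_charge_states_summed(self):
        frag = make_frag("AUCG")
        mass_h = fragment_neutral_mass(frag, G_13C10)
        heavy = [
            Ms1Feature(mz=mz_from_neutral(mass_h, z), charge=z, rt=100.0, intensity=v)
            for z, v in [(1, 60.0), (2, 40.0)]
        ]
        pairs = match_pairs([frag], [], heavy, G_13C10)
        assert pairs[0].heavy_intensity == pytest.approx(100.0)


class TestAggregateSites:
    def test_unique_fragment_point_estimate(self):
        frag = make_frag("AUCG", mods={2: "Um"})
        pairs = [make_pair(0.07, 1.0, frag=frag)]
        est = aggregate_sites(pairs, {(1, 4): [("p", 2, "Um")]}, IDENTITY)
        assert len(est) == 1
        assert est[0].percent == pytest.approx(93.0)
        assert not est[0].lower_bound and est[0].redundancy_count == 1

    def test_redundant_fragment_is_lower_bound(self):
        f1 = make_frag("AUCG", start=1, mods={2: "Um"})
        copies = [make_frag("AUCG", start=s) for s in (11, 21, 31)]
        pairs = [make_pair(0.8, 1.0, frag=f1)] + [make_pair(1.0, 1.0, frag=c) for c in copies]
        est = aggregate_sites(pairs, {(1, 4): [("p", 2, "Um")]}, IDENTITY)
        assert est[0].lower_bound
        assert est[0].redundancy_count == 4
        assert est[0].percent == pytest.approx(20.0)

    def test_unique_beats_redundant(self):
        unique = make_frag("AUUCG", start=1, mods={2: "Um"})
        red = make_frag("AUCG", start=6, mods={7: "Um"})
        red_copy = make_frag("AUCG", start=16)
        pairs = [
            make_pair(0.1, 1.0, frag=unique),
            make_pair(0.6, 1.0, frag=red),
            make_pair(1.0, 1.0, frag=red_copy),
        ]
        site_map = {(1, 5): [("p", 2, "Um")], (6, 9): [("p", 2, "Um")]}
        est = aggregate_sites(pairs, site_map, IDENTITY)
        assert len(est) == 1
        assert est[0].percent == pytest.approx(90.0)
        assert not est[0].lower_bound

    def test_two_unique_fragments_mean_and_sd(self):
        f1 = make_frag("AUUCG", start=1, mods={2: "Um"})
        f2 = make_frag("CAUG", start=20, mods={22: "Um"})
        pairs = [make_pair(0.10, 1.0, frag=f1), make_pair(0.06, 1.0, frag=f2)]
        # both fragments are mapped to the same site key
        site_map = {(1, 5): [("p", 2, "Um")], (20, 23): [("p", 2, "Um")]}
        est = aggregate_sites(pairs, site_map, IDENTITY)
        assert est[0].percent == pytest.approx(92.0)
        assert est[0].sd == pytest.approx(2.0)

    def test_uncovered_site_reported_unquantified(self):
        est = aggregate_sites([], {(1, 4): [("p", 2, "Um")]}, IDENTITY)
        assert len(est) == 1
        assert not est[0].quantified and est[0].percent is None

    def test_multi_site_fragment_not_site_resolved(self):
        frag = make_frag("AUCCG", mods={2: "Um", 3: "Cm"})
        pairs = [make_pair(0.5, 1.0, frag=frag)]
        est = aggregate_sites(pairs, {(1, 5): [("p", 2, "Um"), ("p", 3, "Cm")]}, IDENTITY)
        assert all(not e.quantified for e in est)


def test_invalid_inputs_rejected():
    with pytest.raises(ValueError):
        Ms1Feature(mz=-1.0, charge=1, rt=0.0, intensity=1.0)
    with pytest.raises(ValueError):
        make_pair(1.0, 0.0)
    with pytest.raises(ValueError):
        CorrectionModel(mixing_factor=0.0)
    with pytest.raises(ValueError):
        estimate_stoichiometry(make_pair(1.0, 1.0, n_labeled=0), IDENTITY)
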