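# Methods

## The measurement model

SILNAS quantitation treats each nucleolytic fragment as its own internal
standard experiment.  Let a fragment carry one candidate modification site
with stoichiometry *s*.  In a 1:1 mixture of sample and isotope-labeled
unmodified reference, the reference contributes intensity *H* at the
labeled fragment mass and the sample contributes (1 − *s*)·*A* at the
unlabeled, unmodified fragment mass (modified molecules appear elsewhere:
+14.0157 Da per methyl, +42.0106 per acetyl, or as a read-through fragment
when the modification blocks the cleavage).  Because the light and heavy
species are chemically identical up to isotopes, they co-elute and ionize
identically, and the intensity ratio is insensitive to the large
fragment-to-fragment differences in ionization efficiency.  The estimator
is

  percent = 100 · (H* − c·L*) / H*

where the starred intensities are impurity-corrected (below) and *c* is a
global mixing factor absorbing the error of mixing by UV absorbance.

**Mixing factor.** *c* = median of H*/L* over pairs from modification-free
fragments.  The median is used for robustness to occasional contaminated
pairs; the fitter warns below 10 pairs (the conventional count) and
refuses below 3.  Ambiguously matched pairs are excluded.

**Label impurity.**  Commercial labeled rNTPs are ~98 atom% pure.  The
model treats each nominally labeled residue as entirely unlabeled with
probability *p* (default 0.02), so a reference fragment with *n* labeled
residues retains (1−p)ⁿ at the fully labeled mass and sheds a binomial
ladder of satellites; the all-unlabeled term (fraction pⁿ) lands exactly
on the light feature.  The correction rescales H by (1−p)⁻ⁿ and subtracts
H*·pⁿ from L before ratio-taking.  With G-¹³C₁₀ labeling of RNase T1
fragments n = 1 for every pair (each fragment ends in its only G), so the
uncorrected bias would be a full 2 points.  The exact algebra of the
original instrument software is unpublished; this explicit binomial model
reproduces the stated ~2% magnitude and makes the correction testable —
with it, recovery on noise-free simulated data is exact to float
precision, at any mixture of n across fragments.

**Charge states** are summed per fragment per channel before the ratio is
taken (intensity-conserving; how the original software combined them is
unstated).  **Missed cleavages** default to 0 in quantitation and up to 1
in spectrum search, matching the conventional search settings.

**Redundancy.**  A fragment whose plain nucleotide sequence occurs k > 1
times in the molecule pools light-channel signal from all copies, diluting
the estimate by ~1/k; such estimates are reported as lower bounds carrying
the redundancy count, and unique-fragment estimates take precedence when
both exist.  Redundancy for this purpose is *plain-sequence* identity
(the unmodified-mass pair cannot tell copies apart), whereas the
`fragment_redundancy` digest report keys on sequence+modification strings.
The RNase H planner greedily picks hybrid-directed cuts that minimize the
number of modification-bearing, sequence-redundant fragments per product
(ties broken leftmost), reporting residual redundancy when the cut budget
is exhausted.  Any unique-ifying plan is acceptable; greedy is not claimed
optimal beyond the single-cut cases the tests verify by brute force.

## Masses and ions

Fragment masses are sums of hard-coded monoisotopic residue masses
(A 329.05252, C 305.04129, G 345.04744, U 306.02530 — nucleoside
monophosphate minus water) plus one water, terminus adjustments
(default termini 5′-OH / 3′-linear-phosphate for T1/A products, the end
state of complete digestion; 2′,3′-cyclic phosphate available as a
−18.0106 option; RNase H junctions 5′-phosphate / 3′-OH), modification
deltas, and label increments.  The unit tests re-derive every mass from
elemental compositions with an independent atomic-mass table and require
agreement to 1e-4 Da.

MS/MS series use the standard nucleic-acid nomenclature with neutral
masses c = prefix + H₂O + 5′-adjustment (retains 3′-phosphate),
a = c − H₃PO₄, y = suffix + H₂O + 3′-adjustment (5′-OH), w = y + HPO₃.
These conventions give the exact complementarity identities
cᵢ + yₙ₋ᵢ = M + H₂O and aᵢ + wₙ₋ᵢ = M, which the tests assert on random
fragments.  Negative-mode m/z = (M − z·1.007276)/z.

The Ψ signature ion is priced as the deprotonated anion of C₉H₈N₂O₄ —
the unique small CHNO composition matching the observed m/z within 5 ppm;
only the m/z values (207.041 natural, 208.047 with 6-D) are authoritative,
the composition is a derivation.  5,6-D₂-uridine labeling adds 2·(D−H)
per U; Ψ, having exchanged the 5-D with solvent, retains +1·(D−H), making
the isomer mass-visible at −1.0063 Da per converted residue.

## Pseudouridine calling

Ψ is isobaric with U under natural isotopes, so a ¹³C-only SILNAS pair
cannot see it; calls use the D₂-U-labeled digest.  For each U-containing
fragment the caller tests the all-U mass expectation minus k·1.0063 for
k = #U … 0 and keeps the largest supported k — largest, because a
sequence-redundant fragment may contribute an unshifted copy from another
locus.  Single-U fragments localize directly; multi-U fragments are
localized by scoring every k-subset of U positions against the supplied
MS/MS spectrum (D₂-priced a/c/w/y ions).  When a spectrum is available the
6-D signature ion must be present above 1% of the base peak (no threshold
is conventional; 1% is this package's choice); a mass shift without it is
reported as ambiguous, never silently called.  Adding MS/MS evidence can
therefore only confirm or localize, never remove, a mass-supported call.

## Spectrum search

The search is deliberately desk-scale: candidates are the digest fragments
of the *given* sequence with 0–2 variable methyl placements (position
multisets, so a 3-mer yields 1+3+6 = 10 variants), precursor filtering at
±5 ppm, fragment matching at ±20 ppm, score = matched a/c/w/y ion count
with mean |ppm| as tie-break.  The original search engine's scoring
function and FDR machinery are not published; this is the simplest
deterministic score that exercises the printed tolerances.  Genome-scale
search spaces and decoy FDR are out of scope.

## The synthetic-data generator

The generator emulates the paired-channel experiment end to end: a random
sequence (default 4000 nt, GC 0.5 — comparable to a large-subunit rRNA),
50 planted modification sites drawn from the mass-shifting alphabet
(Nm, base-methyls, ac4C) with stoichiometries on a 5–100% grid in 5-point
steps, digestion (default RNase T1, G-¹³C₁₀ reference), and MS1 features
at charges 1–2 with ppm-scale m/z error.  Planted sites are placed only on
fragments that are sequence- and composition-unique, at least 4 nt long,
and free of other planted sites — the situation the real workflow
engineers deliberately via RNase H cleavage and fragment alignment across
two enzymes.  Ψ recovery is simulated separately through the D₂-U channel
(`simulate_d2_digest_masses`, `simulate_msms`), mirroring the fact that
¹³C SILNAS alone cannot quantify an isobaric isomer.

The intensity noise model is decomposed according to what the paired
design does and does not cancel:

* a per-fragment ionization/abundance factor, log-normal σ = 0.5, shared
  by the light and heavy features of a pair (cancels in the ratio — the
  premise of the method);
* an independent per-channel residual, log-normal σ = 0.014, so the pair
  ratio has σ ≈ 2% and the per-site stoichiometry SD is ≈ 2 percentage
  points — the reproducibility this quantitation method reports.  A naive
  independent per-feature noise of several percent would contradict that
  reproducibility, which is why the shared/residual decomposition is used;
* one global mixing factor per run, log-normal σ = 0.02, removed by the
  fitted correction factor;
* binomial label-impurity satellites at p = 0.02 as described above.

Retention time is a deterministic per-species pseudo-elution coordinate
with σ = 2 s jitter, so sequence isomers (equal mass) separate
chromatographically as they do on a real column.

What the generator does **not** model: chromatographic peak shapes and
detector saturation, co-isolation chimeras, fragment-dependent ionization
bias correlated with composition, sequence variants, partial digestion
kinetics, and isotope fine structure beyond the residue-level impurity
model.  Passing recovery tests therefore demonstrate the correctness of
the estimator and its corrections under the stated noise structure, not
performance on raw instrument data.

With these defaults the pipeline recovers planted stoichiometries with
MAE < 1 point, rank correlation > 0.99, and > 95% detection of sites at
≥ 5% stoichiometry (detection = estimate minus its SD, or the global
2-point SD when a site has a single fragment, excludes zero).  At zero
noise recovery is exact; that identity is a regression test.

## Atlas and analytics choices

* The packaged human atlas stores the printed per-site percent values
  verbatim; the two values above 100 (109, 120) are retained and flagged,
  not clamped, and count as ≥ 85 in threshold summaries.  Per-site
  uncertainties are not stored: the ~2% SD is a global expectation, not a
  per-site measurement.  `redundancy_count` defaults to 1 in the packaged
  table (per-site redundancy is supplementary material not shipped here).
* Positions are 1-based (standard rRNA numbering); molecule lengths are
  fixed to 5S 120, 5.8S 157, 18S 1869, 28S 5064.  BED export converts to
  0-based half-open explicitly.
* Ψm counts as one distinct type code in type counts, but chemically as
  both a ribose methyl (blocks T1/A cleavage) and an isomerization.
* Density clusters: sliding centered window of 200 nt, cluster = maximal
  run with ≥ 8 sites in the window, overlapping runs merged; the window
  and threshold are an operationalization of qualitative cluster
  descriptions and are config-exposed.  On the packaged 28S records this
  yields three large clusters (spanning ≈1509–1868, 3606–4032, 4166–4659)
  and two small ones near 2400 and 2900.
* Case/control comparison: one-tailed two-sample Student's t with pooled
  (equal) variance, alternative "reduced in cases" — the direction of a
  pseudouridine-synthase loss of function.  Whether the original analysis
  pooled variances is unstated; pooled is the textbook default for small
  equal-variance groups.  Zero-variance ties are reported as t = 0,
  p = 0.5.  No multiple-testing correction by default, matching per-site
  reporting conventions; a Bonferroni switch exists.

## Numerical and degenerate-input conventions

Atomic masses are hard-coded at 6 decimals; bit-exact self-consistency
across modules matters more than the table revision.  Matching uses
closest-|ppm| per charge with an exact-tie ambiguity flag; ambiguous pairs
never enter correction fitting.  Estimates are clipped at 0 below and
reported verbatim above 100 (flagged).  Empty atlases summarize to zero
counts; an empty cut plan is the identity digestion; fragments shorter
than 2 nt have no MS/MS series and raise.

## Known limitations

Site-level estimates require fragments covering exactly one candidate
site; composite fragments (several modified sites, common inside dense
clusters) are reported unquantified rather than attributed — resolving
them needs the RNase H planner plus multi-enzyme alignment, which the
pipeline supports but the default simulation avoids by construction.
Feature detection from raw profile spectra is upstream and out of scope;
the pipeline starts from deconvoluted feature lists.
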