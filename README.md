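# silnas

Quantitative mapping of RNA chemical modifications by stable-isotope
internal-standard mass spectrometry (SILNAS), with a packaged atlas of the
228 modified sites of human ribosomal RNA.

## The problem and the method

Ribosomal RNA carries dozens to hundreds of post-transcriptional
modifications (PTMs) — pseudouridine (Ψ), 2′-O-methylribose (Nm), base
methylations, N4-acetylcytidine — that shape ribosome structure and
function, and whose dysregulation appears in cancer and in inherited
disorders such as dyskeratosis congenita.  SILNAS measures the fraction of
molecules modified at each site (the *stoichiometry*): the natural RNA is
mixed 1:1 with an in-vitro-transcribed, fully ¹³C-labeled, unmodified
reference of identical sequence, the mixture is digested with a
base-specific ribonuclease (RNase T1 cuts 3′ of G, RNase A 3′ of
pyrimidines; 2′-O-methyls block both), and each digestion product yields a
light/heavy MS1 feature pair.  The heavy feature reports all molecules;
the light feature at the *unmodified* fragment mass reports only molecules
not modified there, so

```
stoichiometry [%] = 100 · (I_H − c · I_L) / I_H
```

with a mixing factor `c` fitted as the median heavy/light ratio over ~10
modification-free fragment pairs, and a binomial correction for the ~2%
isotopic impurity of commercial rNTPs.  Mass-silent Ψ is handled by
metabolic 5,6-D₂-uridine labeling: pseudouridylation exchanges the 5-D
with solvent, shifting each converted residue by −1.0063 Da, corroborated
by the Ψ-characteristic MS/MS signature ion (m/z 207.041 natural, 208.047
in the 6-D channel).  Fragments whose sequence recurs in the molecule pool
signal across copies, so their estimates are lower bounds; a greedy RNase H
cut planner chooses hybrid-directed cleavages that restore uniqueness.

The package implements the full desk-side workflow: in-silico digestion
(T1/A/H, missed cleavages, the cut planner), monoisotopic masses and
a/c/w/y MS/MS ion series for modified, isotope-labeled fragments, MS1 pair
matching and stoichiometry estimation with both corrections, simplified
database search and Ψ calling, atlas analytics (density clusters along the
chain, cross-species counts, case/control t-tests), and a synthetic-data
generator that emulates the whole experiment for testing.

## Worked example

```python
from silnas import quantify_run, load_atlas, summarize_atlas
from silnas.synthetic_data import SimulationConfig, simulate_molecule, simulate_channels

# the packaged human rRNA atlas
s = summarize_atlas(load_atlas("human"))
print(s["total_sites"], s["per_molecule"], s["distinct_types"])
# 228 {'5S': 0, '5.8S': 4, '18S': 91, '28S': 133} 14

# a simulated SILNAS run: 4-kb molecule, 50 planted sites, default noise
truth = simulate_molecule(SimulationConfig(seed=1))
estimates = quantify_run(truth, *simulate_channels(truth))
e = estimates[0]
print(e.position, e.mod_code, truth.stoichiometry[e.position], round(e.percent, 1))
# 22 m5C 60.0 61.5
```

The first block prints the atlas totals: 228 modified sites across the
four rRNAs (none in 5S) and 14 distinct modification types.  The second
simulates light/heavy MS1 channels for a random modified molecule and runs
the full matching → correction → estimation pipeline; the planted site at
position 22 (5-methylcytidine, true stoichiometry 60%) is recovered at
61.5%.  Mean absolute recovery error over the 50 planted sites of this run
is 0.86 percentage points.

The same workflow is scriptable from the shell:

```sh
silnas simulate --seed 3 --outdir run/
silnas quantify --fragments run/fragments.tsv --light run/light.csv --heavy run/heavy.csv
silnas summarize            # atlas totals
silnas map --molecule 28S   # modification-density clusters
```

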