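# polyqmod

Analytics for cell-based screens of polyglutamine (polyQ) toxicity
modifiers, built around the computational workflow used to characterise
human modifiers of pathogenic ataxin-1 (ATXN1) toxicity and aggregation.

Expanded polyQ tracts in proteins such as ataxin-1 drive spinocerebellar
ataxia type 1; co-expression screens identify human proteins that enhance
or suppress the toxicity and aggregation of a pathogenic ATXN1 fragment.
`polyqmod` implements the full analysis layer of such a screen for anyone
who needs to classify screen hits, scan hit sequences for glutamine-rich
and coiled-coil features, call protein interactions from LUMIER co-IPs,
analyse far-UV CD spectra, and test set-level enrichment — all from
plain-text inputs (FASTA, CSV, TSV).

## What it computes

* **Glutamine scans** (`polyqmod.seqscan`): a 50-residue window records the
  glutamine fraction and the fraction of residues in uninterrupted polyQ
  runs (>5 Qs). A protein is *Q-rich* if some stretch of ≥ 10 residues is
  more than 50% glutamine, and a *polyQ protein* if it carries more than
  10 consecutive Qs. Gap-aware profiles over a multiple alignment compare
  orthologues on a common column coordinate.
* **Coiled-coil prediction** (`polyqmod.coiledcoil`): sliding-window
  heptad-propensity scoring. For window w and register f, the score is the
  (optionally a/d-weighted) geometric mean of residue propensities
  s = (∏ᵢ P[aaᵢ, posᵢ]^wᵢ)^(1/Σwᵢ); each residue keeps the best score of
  any covering window/register, converted to
  P(cc|s) = G(s;m_cc,σ)/(G(s;m_cc,σ) + 30·G(s;m_g,σ)). Default window 28,
  segments called at probability ≥ 0.8.
* **Screen classification** (`polyqmod.screen`): caspase-3/7 fluorescence
  normalised to cell counts; a modifier is a toxicity enhancer/suppressor
  when its relative effect vs the plate control is ≥ ±20% in *each of
  three* independent experiments, with hits excluded when the modifier
  alone perturbs the readout; aggregation effects called from
  filter-retardation densitometry (control = 100%) by Student's t-test at
  α = 0.05 with consistent direction; combined calls cross-tabulated on a
  3 × 3 grid.
* **LUMIER interactions** (`polyqmod.interaction`):
  R_op = FL(A)/FL(B), R_ob = FL(A)/FL(C); both strictly > 1.5 calls an
  interaction.
* **CD spectra** (`polyqmod.cdspec`): mean residue ellipticity
  [θ] = θ_mdeg/(10·l·c·n), smoothing, per-mole tag subtraction, and the
  coiled-coil criterion [θ]222/[θ]208 > 1.0.
* **Enrichment** (`polyqmod.enrichment`): chi-square of coiled-coil
  prevalence against the human Swiss-Prot background (73,427 proteins,
  20.3% coiled-coil) and one-sided Fisher's exact category enrichment
  with Bonferroni correction.
* **Synthetic data** (`polyqmod.synthetic`): seeded generators for every
  input — sequences with planted polyQ/Q-rich/heptad features, screen
  plates with planted fold effects, LUMIER triplets with planted binding
  ratios, CD spectra from secondary-structure basis spectra — each with a
  truth table.

## Worked example

Generate the packaged 21-modifier synthetic screen and run the full
pipeline:

```sh
polyqmod simulate sequences --seed 1 --out demo
polyqmod simulate plate --seed 1 --cv 0.0 --out demo
polyqmod scan-cc demo/sequences.fasta --out demo/cc
polyqmod enrich cc --k 6 --n 12
```

The sequence scan writes `demo/cc/cc_calls.tsv`, in which 6 of the 21
modifiers carry a predicted coiled coil (probability ≥ 0.8, window 28).
The enrichment command prints:

```
{"chi2": 6.539910723540557, "p": 0.01054806423869281}
```

i.e. finding 6 coiled-coil proteins among the 12 toxicity enhancers is a
significant excess over the 20.3% proteome background (χ² = 6.54,
p ≈ 0.011, df = 1). The same run through the Python API:

```python
from polyqmod import pipeline
cfg = pipeline.RunConfig(out_dir="demo/run",
                         fasta="demo/sequences.fasta",
                         plate_csv="demo/plate.csv")
report = pipeline.run_pipeline(cfg)
print(report["cross_table"]["enhancer"]["enhancer"])  # 9
```

classifies 12 toxicity enhancers and 9 suppressors, 15 modifiers with
aggregation effects, and places 9 modifiers in the enhancer/enhancer
quadrant of the toxicity × aggregation cross-table.

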