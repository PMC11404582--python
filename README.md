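# gutseg

Segmental patterning of the gut microbiome and immune system: a tested
analysis pipeline for two-factor mouse colonization studies.

## The problem

Along the intestine (duodenum → jejunum → ileum → cecum → colon), both the
microbial community and the gut-associated immune compartment change
dramatically. Comparing germ-free (GF) mice with conventionally colonized
(CONV) mice makes it possible to ask, per immune cell population, *what
drives its regional abundance*: the microbiota, the anatomical segment,
both independently, or a genuine interaction in which the microbiota
reshapes the spatial pattern itself.

`gutseg` implements the full desk-side analysis for this design:

* **Microbiome**: read-depth and prevalence/abundance QC (no rarefaction),
  blank-contaminant flagging, Shannon alpha diversity, Bray–Curtis beta
  diversity with PCoA, binary presence/absence overlap across segments
  (core taxa and Euler regions), genus-level differential abundance
  (Mann–Whitney + Benjamini–Hochberg), and absolute 16S quantification
  from qPCR standard curves.
* **Immune patterning**: z-score PCA, within-group dispersion, per-segment
  CONV-vs-GF testing, and the central classifier — per-population OLS
  against colonization, segment, and their interaction.
* **Association**: GF-median normalization of immune abundances and
  Spearman correlation with microbial species across all segments.
* **Synthetic cohorts**: seeded generators that emulate the study design
  (5 segments × 2 colonization states × 6 mice) with known ground truth,
  so every stage of the pipeline is testable end to end.

## The model

Each immune population's relative abundance *y* is fit by ordinary least
squares against the two experimental factors,

```
y ~ colonization + segment + colonization:segment
```

with colonization binary (CONV = 0, GF = 1) and segment a 5-level factor.
The interaction is tested by a partial *F* (full vs additive model); the
main effects by Type-II *F* tests within the additive model. After BH FDR
control (α = 0.05, per term family across populations), populations are
categorized by rule precedence:

| q-values | category |
|---|---|
| q_interaction < α | **interaction** |
| else q_colonization < α and q_segment < α | **main effects** |
| else q_colonization < α | **microbiome only** |
| else q_segment < α | **segment only** |
| else | none |

Estimated marginal means (model-predicted cell means ± SE per segment ×
colonization) accompany every non-degenerate fit; for the balanced design
they coincide with arithmetic cell means.

## Worked example

Run the numbered analysis scripts from the repository root (seed 0):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_microbiome_qc_diversity.py
python analysis/03_core_taxa_overlap.py
python analysis/05_dependence_classification.py
```

`01` builds the study-shaped cohort: 82 immune populations × 60 samples
with true dependence categories split 36/25/17/4 (interaction /
microbiome-only / main-effects / segment-only), and 292 microbial species
× 30 samples with richness rising oral→aboral around a 72-species core.

`02`/`03` then report:

```
depth filter: discarded 6 of 30 samples (< 500 reads)
blank overlap: flagged ['jejunum_s3'] -- excluded from downstream analysis
rare-feature filter: kept 194 species (98 discarded)
species detected per segment: {'duodenum': 78, 'jejunum': 100, 'ileum': 123,
                               'cecum': 150, 'colon': 190}
core species (present in all segments): 72; 72 of 72 true core recovered after QC
```

i.e. the QC reproduces the intended sample losses, detected richness
increases along the gut, and the presence/absence core recovers the
ground-truth core exactly. `05` fits the dependence model for all 82
populations and prints the recovery against the simulation's truth:

```
assigned categories: {'interaction': 39, 'microbiome_only': 20,
                      'main_effects': 19, 'segment_only': 4}
ground-truth recovery: 93.9% of 82 populations
```

(the handful of misclassified populations are microbiome-only features
whose noise mimics a weak interaction or segment signal — the expected
behavior at this signal-to-noise ratio).

The same end-to-end run is available as one command:

```bash
gutseg pipeline demo --seed 0 --out results/demo
```

which writes every stage output plus a manifest with per-file checksums;
rerunning with the same seed reproduces all files bitwise.

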