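# musclemap

From the skeletal-muscle proteome of a genetically diverse mouse population to
a causal "fingerprint" of insulin resistance — and from that fingerprint to a
ranked list of candidate reversal compounds.

## The problem

Insulin resistance precedes type 2 diabetes, and skeletal muscle is the main
site of insulin-stimulated glucose disposal. In an outbred mouse population
(eight founder strains, high genetic and metabolic heterogeneity), protein
abundances that track whole-body insulin sensitivity may be *causes* of
insulin resistance or mere *consequences* of it. `musclemap` implements a
genetics-first pipeline that enriches for causality and then converts the
candidate set into actionable pharmacology:

1. **Phenotype.** Whole-body insulin sensitivity per mouse from glucose
   tolerance test (GTT) curves via the Matsuda Index

   `M = 10,000 / sqrt(G0 * I0 * G_mean * I_mean)`

   with fasting glucose/insulin `G0`, `I0` and means over the sampled GTT
   timepoints. Adiposity (% fat mass) comes from body composition.
2. **Association.** Per protein, ordinary least squares of log2 M on log2
   abundance with adiposity as a covariate; Storey q-values for multiplicity.
   Negative effects mean "more protein, less insulin sensitive".
3. **pQTL mapping.** A kinship-aware linear mixed model scan per protein
   (one spectral decomposition of the relatedness matrix K, REML variance
   ratio, per-marker GLS; `LOD = (n/2) log10(RSS0/RSS1)`), latent-factor
   residualisation beforehand, genome-wide significance by permutation
   (1000 by default; p<0.1 for cis, p<0.05 for trans, cis window ±2 Mbp).
4. **Fingerprint.** Proteins that are negatively associated *and* carry a
   cis-pQTL: when local genotype explains abundance, reverse causation from
   the phenotype is implausible, so these are candidate drivers that are "up
   in insulin resistance".
5. **Connectivity.** The fingerprint, exported as a GMT gene set, is scored
   against a compound × cell-line signature database with a weighted
   Kolmogorov–Smirnov running statistic; strongly negative enrichment means a
   compound down-regulates the fingerprint ("reversal"). Scores are averaged
   across cell lines.
6. **Screen + integration.** Hits in three GLUT4-translocation assay modes
   (basal agonist / insulin sensitiser / resistance reverser; each at strict
   50%-of-control thresholds), then compound ranking by

   `overall = (z_bas + z_sens + z_rev)/3 + z_cmap`

   where each column is z-scored over the consensus compound set and raw
   connectivity is sign-flipped so reversal scores positively.

Because the real datasets behind such a study (proteomics repository
deposits, the L1000 signature service, a physical compound screen) are
external, the package ships a first-class **synthetic-data generator** with
known ground truth — founder-mosaic genotypes with kinship and local LD,
cis/trans protein architectures, GTT curves that invert the Matsuda formula
exactly, signature databases with planted reversers, and screen plates with
planted actives — so every stage is testable end to end.

## Worked example

```sh
musclemap run-all --outdir demo --seed 1
```

runs simulate → phenotype → associate → mapqtl → fingerprint → connect →
screen → integrate on the default synthetic design (215 mice, 2×100 proteins,
8 planted causal proteins, 5 planted reverser compounds of which one is also
a planted screen active). With 200 permutations per scan the pipeline prints
its artifacts into `demo/`; at seed 1:

- `fingerprint.tsv` — 6 proteins, all with negative effect sizes
  (−0.50 … −0.33 log2-Matsuda per SD) and cis-pQTL, every one a planted
  causal protein (Jaccard to truth 0.75; the two misses drew the weakest
  planted effects);
- `pqtl.tsv` — 99 cis, 23 trans, 78 unclassified peaks across 200 proteins;
- `hits_*.tsv` — 5 basal agonists, 4 sensitisers, 6 reversers (5+4+5 planted,
  plus the dual-active);
- `score_matrix.tsv` — the planted dual-active reverser `cpd002` ranks 1 with
  `z_rev = 3.03`, `z_cmap = 2.52`, `overall = 3.49`; the other four planted
  signature reversers fill most of the next ranks on connectivity alone.

Rows, columns and thresholds of every artifact are documented in
`docs/methods.md`; each file's header comment records the tool version,
config hash and seed that produced it. Re-running the same command skips
completed stages; `--force` recomputes.

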