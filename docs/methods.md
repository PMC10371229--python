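# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `musclemap`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself recompute.

## Phenotypes

**Matsuda Index.** `M = 10,000 / sqrt(G0 · I0 · G_mean · I_mean)`, with the
GTT means taken over *all* sampled timepoints including t = 0; including the
baseline is the convention of the original composite-index derivation, and a
`exclude_baseline_from_mean` flag gives the post-bolus-only variant. Insulin
is measured at 0 and 15 min only, so `I_mean` is the mean of those two
values; no interpolation is attempted. The index is scale-equivariant, not
unit-free — doubling all glucose values halves it — so units need only be
consistent across mice (the simulator uses mM-scale glucose and arbitrary
consistent insulin units). Downstream modelling uses log2 M, which is
closer to normal for a strictly positive, right-skewed index.

**Adiposity** is 100 · fat mass / body mass from body-composition records.

**Proteome summaries.** Presence filtering keeps proteins observed in ≥ 50%
of mice (inclusive boundary). Median normalisation shifts each mouse's
(log2) median to the grand median; on raw intensities a log2 transform comes
first and non-positive intensities are a hard error. The coefficient of
variation is computed on the *linear* intensity scale (CV of log values is
not scale-free) with sample (n−1) SD, and proteins are ranked by descending
CV for enrichment use.

## Trait association

Per protein: OLS of log2 Matsuda on log2 abundance plus covariates
(adiposity by default), complete cases only, two-sided Wald t-test on the
protein coefficient with n−k−1 df. Constant-protein designs are flagged and
excluded from multiplicity adjustment. Negative effect sizes mean higher
abundance in less insulin-sensitive mice; the fingerprint selects these.

**q-values.** Storey's method: pi0 estimated on the lambda grid
0.05…0.95 (step 0.05) by a cubic polynomial in lambda evaluated at the grid
maximum, clipped to [1/m, 1]; with fewer than 20 p-values pi0 is set to 1
(the conservative limit — the tail cannot be estimated). q_i = pi0 ·
min_{p_j ≥ p_i} (m p_j / rank_j), computed as p/(rank/m) so that pi0 = 1
reproduces the standard Benjamini–Hochberg implementation bit for bit. Ties
in p receive equal q (stable sort + tail cummin). q-values are computed
within each proteome fraction separately; pooling is a caller choice.

## pQTL mapping

**Kinship.** K = A·Aᵀ/m on column-standardised dosages, monomorphic markers
dropped. Overall kinship (not leave-one-chromosome-out) is the default;
LOCO would require per-chromosome null models and is left to future work.

**Hidden structure.** Proteins are z-scored and the top-10 latent factors of
the matrix (truncated SVD, missing values mean-imputed for estimation only)
are regressed out. This is a deliberate stand-in for probabilistic factor
models: at a few hundred proteins the truncated decomposition captures the
same shared variation, and the step is pluggable. Note the factor count is
calibrated to proteome widths of ~100+ columns; on very narrow matrices
(tens of proteins) 10 factors will eat real signal.

**Scan.** For each protein, the null model y = Xb + g + e with
g ~ N(0, σ²g K) is fitted once by REML: K is eigendecomposed, the heritability
ratio h = σ²g/(σ²g+σ²e) profiled on a 100-point grid over [0, 0.99] (the
restricted likelihood in h is cheap and smooth at these sizes; a grid avoids
optimizer edge cases), and the fitted h reused across markers. After
rotation and whitening, each marker's LOD is (n/2)·log10(RSS0/RSS1) obtained
from the squared partial correlation of the projected marker with the
projected phenotype. Markers whose adjusted dosage is numerically constant
get LOD 0 with a logged warning. LOD is invariant to affine transforms of
the phenotype. With `use_kinship=False` the scan reduces exactly to OLS.

**Permutations.** Whitened null-model residuals are permuted, covariates
re-projected, and the max-LOD over markers recorded per permutation. This
preserves the fitted covariate/kinship structure under the null and differs
deliberately from naive phenotype shuffling, which breaks exchangeability
under relatedness. Genome-wide p of the observed peak is
(1 + #{perm max ≥ observed})/(n_perm + 1) — the +1 correction means p is
never zero and never below 1/(n_perm+1). Thresholds at level α are empirical
(1−α) quantiles (conservative "higher" interpolation). Fewer than 20
permutations is refused.

**cis/trans calls.** Peak = global max-LOD marker (ties to the lowest
chromosome/position via map order). A peak is *cis* if it lies on the
protein's chromosome within ±2,000,000 bp (inclusive both ends, 1-based
physical coordinates) of the gene position and genome-wide p < 0.1;
otherwise *trans* if p < 0.05; otherwise unclassified. The two-tier alpha
means a local peak with 0.05 ≤ p < 0.1 is still cis, reflecting the stronger
prior on local regulation.

The dosage-based single-marker scan is a declared simplification of
founder-haplotype-probability regression; with simulated dosage data the two
coincide up to the haplotype-reconstruction step, which is out of scope.

## Fingerprint

Intersection of {effect < 0, q < threshold (default 0.05)} with
{classification == cis}, ordered by effect size ascending. Gene-symbol
collisions across fractions collapse to the more significant entry. The
query set is single-directional ("up in insulin resistance"): reversal is
*negative* enrichment of this one set. This is flagged prominently because
connectivity services conventionally take paired up/down sets. Export is
one standard GMT line; symbols containing whitespace are rejected.
Tightening the q-threshold can only shrink the fingerprint (asserted as a
property test), and fingerprint ⊆ (negative-significant ∩ cis) is asserted
on every pipeline run.

## Enrichment core

One weighted-KS implementation serves GSEA-by-effect-size, GSEA-by-CV and
connectivity. Walking the ranked list, a hit adds |metric|^w / (total hit
weight) and a miss subtracts 1/(N − n_set); ES is the running-sum value of
largest magnitude, in [−1, 1]. Weight w defaults to 1 for GSEA (metric-
weighted, the common default) and 0 for connectivity (the fingerprint is an
unordered set). Ranking ties break by gene id. When the running extremum is
exactly tied in magnitude between a positive and a negative excursion the
earlier one wins; at w = 0 the identity ES(reversed ranking) = −ES holds
whenever the extremum is untied. A contiguous set at the exact bottom of a
ranking gives ES = −1 exactly (the analytic extreme), which anchors the
simulator's maximal-strength reversers. Gene-permutation p-values are
two-sided with the +1 correction; FDR across sets uses the q-value machinery
with pi0 = 1.

Connectivity: per compound × cell line ES of the query, arithmetic mean
across cell lines ("raw" scores, no percentile/tau machinery — that would
require a reference touchstone database), output ascending so the strongest
reversers come first. Signatures covering < 90% of the query are scored on
the intersection with a logged coverage warning.

## Screen scoring

Thresholds per mode (control values are replicate means; calls use strict
`>`): basal agonist — basal + 0.5·(ins100 − basal); sensitiser — ins1 +
0.5·(ins100 − ins1); reverser — palmitate + 0.5·(ins100 − palmitate). The
agonist rule reads "50% of control" as 50% of the insulin *response* above
basal, parallel to the two difference rules; the literal absolute reading
(0.5 · ins100) is available as `basal_rule="absolute"`. A mode whose
ins100 control does not exceed its reference control has no assay window
and is a hard error.

Integration z-scores each assay's mean responses and the connectivity score
over the consensus compounds (present in both the screen and the signature
database), with sample SD. Raw connectivity is negated before z-scoring so
that stronger reversal contributes positively to
`overall = (z_bas + z_sens + z_rev)/3 + z_cmap`; without the flip, reversers
could never top a ranking that the formula otherwise rewards, and the raw
convention remains available (`cmap_sign="raw"`). Compounds missing one
assay take z = 0 there (population-neutral) and are flagged. z-scores are
always recomputed on the scored subset, never reused across subsets. Final
ranking is descending by overall with deterministic tie-breaks
(z_cmap, then compound id).

## Synthetic-data generator

The generator emulates the study conditions the pipeline is designed for;
its defaults are the package's reference design and are not tuned per run.

* **Genotypes.** 215 mice; 5 chromosomes × 60 markers × 100 Mbp; each
  haplotype a founder mosaic with Poisson(15) breakpoints per chromosome.
  Fifteen expected switch points reflects *accumulated* recombination in a
  population outbred for ~30 generations (haplotype blocks of ~6–7 Mb), not
  a single meiosis; this is what makes the ±2 Mbp cis window meaningful
  while keeping long-range LD realistic. Founder allele states are
  Bernoulli(1/2); dosage = sum of the two founder alleles, in [0, 2].
  Kinship arises from finite founder sharing.
* **Proteome.** 100 proteins per fraction (mito / post-mitochondrial). Half
  the proteins carry a local (cis) driver at h² = 0.30, 10% a distal
  (trans) driver of equal strength; variance shares: 15% shared latent
  factors (5 of them), 10% polygenic (kinship-structured), remainder
  independent noise. Missingness is MCAR at 10% — the study it emulates
  does not describe its missingness mechanism, so the simplest one is used.
* **Trait.** log2 M = b0 + Σ β_j·(protein_j) + γ·adiposity + ε with 8 causal
  proteins drawn from the cis set, all β negative (magnitude
  0.5·U(0.7, 1.3) — every planted driver is meant to be detectable at
  n = 215; a forward power calculation gives per-protein partial R² ≈ 0.11,
  q<0.05 power ≈ 0.9), γ = −0.5 per SD of the adiposity latent, ε with SD
  0.3. Crucially the causal drive goes through the *biological* protein
  signal (cis + polygenic + residual + confounder), excluding the latent
  factors: physiology does not see batch structure in the measurement —
  that is the premise of factor adjustment. Trait heterogeneity under these
  defaults spans two to three orders of magnitude across mice, the scale of
  heterogeneity outbred populations show. Eight additional null proteins mix
  in the adiposity latent (strength 0.6), so the with/without-covariate
  contrast is reproducible in silico.
* **GTT curves.** Fixed post-bolus glucose shape (peak ≈ 2.2× fasting at
  15 min) around a noisy fasting level; insulin at 15 min is a noisy 2–3×
  multiple of fasting insulin, whose level is solved in closed form so the
  Matsuda formula reproduces the drawn target exactly (round-trip tested to
  1e-9 relative).
* **Signatures.** 100 compounds × 3 cell lines ranking a gene universe; each
  gene scores U(0,1), and the 5 planted reversers subtract 0.7 from the
  target genes' scores — strength ≥ 1 would force an exact bottom block
  (ES = −1). Neutral compounds are uniform rankings.
* **Screen.** Control means (%GLUT4 at PM): basal 5, 1 nM insulin 10,
  100 nM insulin 25, insulin+palmitate 12; well noise SD 1.5, 4 replicates.
  Planted actives sit at threshold + 0.25·window in expectation; one planted
  signature reverser is also planted as a reverser-mode active (the
  "dual-active" the integration stage should rank first).

Determinism: every stage draws from `default_rng([seed, stage_tag])`, so
identical config + seed give byte-identical artifacts and stages can be
re-run independently.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic 8-founder haplotype structure and array
genotyping error; non-random (abundance-dependent) missingness; shared
peptide/protein quantification error; mRNA–protein discordance between
fingerprint and signature space; plate/edge effects and dose–response in
the screen; meiotic drive and diet arms.

## Validation studies and problem sizes

`musclemap.studies` packages the calibration/recovery experiments used by
both the test suite and the acceptance script; sizes are chosen so each
study resolves its statistic in seconds to a few minutes on one core:
q-value null calibration (100 seeds × 10,000 p-values), permutation
calibration (100 mice × 500 markers, 200 permutations × 200 seeds, exact
binomial check at α = 0.05), cis/trans recovery (default proteome, n = 215,
200 permutations), connectivity and integration recovery (50 seeds),
end-to-end fingerprint recovery (default design, 200 permutations), and a
byte-determinism check (two full runs). Permutation counts below the 1000
default trade threshold resolution for runtime; 200 still resolves the
α = 0.1 and 0.05 tails used in classification.

## Known limitations

* The grid REML profile is single-protein; a shared-variance-component
  approximation across proteins would be faster at scale.
* pi0 estimation on ~100 p-values is noisy; within-fraction q-values at
  desk scale inherit that noise (conservative fallback pi0 = 1 below 20
  tests).
* The fingerprint's "causality" is enrichment, not proof: a cis-driven
  protein correlated with a causal neighbour through LD can still enter.
* Connectivity raw means across 3 simulated cell lines ignore cell-line
  weighting and signature reliability.
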