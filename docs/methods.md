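# Methods

## The model

Divergent selection on one trait should leave localized regions where the
two lines carry different haplotypes at frequencies too extreme for drift.
The scan works on haplotype-*cluster* frequencies rather than phased
haplotypes:

1. **Kinship.**  Per-population alternate-allele frequencies (F0
   individuals only) give pairwise Reynolds distances
   D = Σ(pᵢ−pⱼ)² / Σ(1 − pᵢpⱼ − (1−pᵢ)(1−pⱼ)), approximately linear in
   drift time.  For two populations the drift matrix is F = diag(D/2, D/2)
   (midpoint rooting — with no outgroup the symmetric split is the only
   principled choice; the split is configurable).  For more populations a
   neighbor-joining tree is midpoint-rooted and F read off its branches.
   Kinship uses a 1% subsample of the MAF-filtered SNPs; it needs few.

2. **Haplotype-cluster HMM.**  The Scheet–Stephens-style model: each
   chromosome is a mosaic of K latent clusters; between adjacent SNPs the
   cluster path jumps with probability r_s and redraws from local weights
   α·s; alleles are Bernoulli(θ_ks).  Genotypes are handled *unphased*:
   the hidden state is the unordered cluster pair, giving exact
   marginalization with no phasing step.  Forward–backward runs in scaled
   probability space (numba kernels); Baum–Welch updates θ, α and r (r
   from expected jump counts).  K defaults to 6 — the number of ancestral
   lines in the founder mix.  F1 individuals are included in the fit
   (they enlarge the haplotype sample) but excluded from cluster
   frequencies and kinship.

3. **hapFLK.**  Per-cluster ancestral frequencies p̂₀ by the GLS
   estimator (1ᵀF⁻¹p)/(1ᵀF⁻¹1), clipped and renormalized to the simplex;
   B₀ = diag(p̂₀) − p̂₀p̂₀ᵀ; the statistic is the drift-standardized
   quadratic form with the Moore–Penrose pseudo-inverse of F ⊗ B₀
   (singular values < 10⁻¹⁰ × max treated as zero — this absorbs the
   simplex constraint).  Because EM is multi-modal and cluster labels
   arbitrary, the label-invariant statistic is averaged over n_fits = 10
   independent EM fits (25 iterations each); no label alignment is needed.

4. **Calibration.**  The neutral distribution is modeled as a·χ²_d and
   fitted to the genome-wide values by median/MAD matching (solve for d by
   1-D root finding, then scale).  Median and MAD ignore the upper tail,
   so selected outliers are automatically down-weighted; a trimmed-ML
   variant is available (`null_method="trimmed_ml"`).  p-values are upper
   tails of the fitted null, q-values follow Storey's procedure
   (λ = 0.5), and sweeps are runs of ≥ 2 significant SNPs (q < 0.1) merged
   across gaps ≤ 50 kb — half the expected sweep size; there is no
   published merging rule.

## Tunable parameters that matter

| parameter | default | meaning |
|---|---|---|
| `maf_min` | 0.10 | SNPs with MAF strictly below are removed (boundary kept) |
| `kinship_fraction`, `scan_fraction` | 0.01, 0.30 | SNP subsamples for kinship / scan |
| `K` | 6 | haplotype clusters = ancestral founder lines |
| `n_fits`, `em_iterations` | 10, 25 | EM ensemble size and depth |
| `q_threshold` | 0.1 | FDR call level |
| `merge_gap` | 50 kb | sweep-region merging distance |

The published phrase "10 expectation maximization iterations" is ambiguous
(fits vs iterations); it is read here as 10 independent fits averaged —
standard multi-start practice — with 25 iterations each, both configurable.

## The synthetic world

`simulate_design` runs the breeding scheme forward: 23 + 68 founders drawn
from a mix of 6 ancestral lines (Balding–Nichols F = 0.2 line divergence
around shared ancestral frequencies), 7 generations of within-sex
truncation selection on an additive trait (heritability 0.5, top fraction
0.25) splitting a common candidate pool into an up- and a down-selected
line, 28 maintenance generations with 20 sires and 60 dams (dam count is
an assumption; only the sire count is published), Poisson crossovers at
3×10⁻⁸ /bp/generation, SNPs at 2.6/kb, and sampling of 4 + 7 F0 and 9 F1
birds.  Only SNPs segregating in the sample are emitted (sequencing
discovers variants in the sample).

Founder LD comes from emitting each founder haplotype as a mosaic of
**line-specific prototype haplotypes** (3 per line, within-line prototype
switches at 5×10⁻⁶/bp, rare between-line switches at 10⁻⁶/bp, 1% allele
noise).  This matches the cluster-model assumption (few ancestral
haplotypes locally) and gives selection a haplotype to sweep.  Each QTN
allele is planted on exactly one prototype of one line — a mutation that
arose once — because a favourable allele spread over many founder
backgrounds sweeps softly and leaves no haplotype signature.

What the generator does **not** emulate: coalescent-exact ancestral
variation, mutation during the experiment, sequencing error/depth,
structural variation, the two-trait selection index, or inbreeding-managed
matings.  A green simulation test therefore establishes internal
consistency of the method under this stylized world, not field performance.

The default genome is 5 × 10 Mb; tests and the acceptance script run 1
chromosome of 3–4 Mb with reduced EM settings purely for runtime, with
replicate counts and thresholds unchanged.

## Numerical choices

- Forward–backward in scaled (not log) space; per-SNP normalizers give the
  exact log-likelihood.  EM log-likelihood is non-decreasing to 10⁻⁸
  relative (θ flooring at 10⁻³ and an α pseudo-count of 10⁻⁶ bound the
  deviation).
- SNPs whose estimated p̂₀ hits {0, 1} are non-informative for FLK and
  return NaN (excluded, counted) rather than 0.
- Degenerate inputs raise: identically-fixed frequency vectors (Reynolds
  denominator 0), constant genome-wide statistics (MAD 0), empty QTL sets,
  zero-variance correlations.
- ΔCt analyses: fold change = mean(2^−ΔCt) ratio; two identical
  zero-variance groups give p = 1 by convention.  The published
  "Mann–Whitney against the expected ratio of 1" is degenerate as a
  two-sample test and is realized as a one-sample Wilcoxon signed-rank of
  log-ratios against 0 (exact for n ≤ 25); a genuine two-sample mode
  (cDNA vs gDNA odds) is provided.  Pyrosequencing duplicates are averaged
  per individual before testing (configurable).
- Allelic ratios are odds ratios, odds(cDNA)/odds(gDNA), invariant to
  common multiplicative assay skew.

## Known limitations

- **Localization power under extreme drift.**  With ~60 parents per line
  for 35 generations, drift alone fixes alternative haplotypes in many
  regions; apparent complete differentiation saturates the
  kinship-standardized statistic (a ceiling set by F), so a true sweep
  cannot exceed the strongest drift peaks by much.  On the scaled-down
  single-chromosome world the top averaged hapFLK lands within 250 kb of
  a strong single-origin QTN in ~65–70% of replicates, and drift-calibrated
  q-values rarely fall below 0.1 anywhere — consistent with the method's
  deliberately conservative control of drift false positives, but short of
  the 80% localization mark at this scale.  More EM fits measurably help
  (label-noise averaging); the ensemble size is kept at the documented 10.
- The consequence classifier covers SNPs only (no indels), collapses the
  VEP ontology to the reported categories, and defines the splice region
  as the ±2 intronic bases; a published "regulatory region" class has no
  stated definition and is not reproduced.
- Reynolds-based kinship assumes drift-only divergence; migration or
  admixture after the split would bias F.
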