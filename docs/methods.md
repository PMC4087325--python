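# Methods

## The synthetic F2 intercross

The generator emulates a resource population built by crossing two lines
divergently selected for fatness: an obese-prone line A and a lean line B.
Defaults: 12 founders per line, 78 F1 from A×B matings, 454 F2 from F1×F1
matings; 10 chromosomes of 100 cM carrying 500 evenly spaced SNPs each
(1 cM ≈ 1 Mb, so bp = cM·10⁶ in the map).

**Recombination.** Meiosis places crossovers by a homogeneous Poisson
process at rate 1 per Morgan (Haldane, no interference); chromosomes
assort independently. This gives closed forms used throughout the tests:
the recombination fraction over d cM is c = (1 − e^(−2d/100))/2, and the
F2 dosage correlation between loci fixed for alternative alleles in the
founder lines is exactly 1 − 2c. The Haldane choice is deliberate: chi²
interference models fit real data slightly better but destroy the
closed-form oracle.

**Founder genetics.** Neutral loci get a shared base frequency
~ U(0.1, 0.9) shifted ±divergence/2 per line (default divergence 0.3,
clipped to [0.02, 0.98]); haplotype alleles are drawn independently, so
background LD in the F2 is admixture LD from the line frequency contrast,
not founder haplotype structure. Planted clusters are different: every
founder chromosome carries the cluster's full all-1 haplotype with a
per-line frequency (1/0 = fixed divergent), so cluster markers segregate
as a coherent haplotype and show strong within-cluster LD — the structure
the network stages are meant to detect. The 0.3 divergence default makes
roughly a quarter to a third of all markers nominally associated
(p < 0.05) with the index through genome-wide admixture LD, the same
order as the emulated study's 9,485/40,910; it is a parameter, not a
claim of fidelity.

**Traits.** Seventeen traits on a standardized scale (phenotypic variance
1): the nine index traits plus eight further obesity-related traits, with
published heritabilities for this kind of population (0.08–0.78).
Correlation structure comes from a single latent "adiposity/size" factor
(phenotypic loadings 0.5–0.65, meat percentage −0.45; genetic loadings
1.15× phenotypic, capped at 0.9), which guarantees positive definite P, G
and P − G. Per animal, the multi-trait breeding value is the sum of
centered QTL contributions and a polygenic deviate ~ N(0, G − Cov_qtl);
the phenotype adds an environmental deviate ~ N(0, P − G). A
configuration whose P − G is not PSD is rejected with the offending
eigenvalue. Estimated breeding values are the true ones by default
(REML estimation is outside this package's scope); an accuracy r < 1
blurs them as r·BV + √(1−r²)·noise.

**Planted signals.** Two clusters are planted by default:

* `oi_qtl` — 60 markers (chromosome 1, from 20 cM), fixed divergent, 12
  causal markers carrying a haplotype effect of b′e ≈ 0.95 index units
  (≈ 25% of the index genetic variance). Major QTL of this size are what
  divergent intercrosses are designed to segregate.
* `dw_qtl` — 20 markers (chromosome 3, from 40 cM), haplotype frequency
  0.3 in line A and 0 in line B (F2 allele frequency ≈ 0.15), 10 causal
  markers with a haplotype effect ≈ 2.85 index units. The effect was sized
  analytically so that carriers are excluded from the lean-50 tail with
  probability ≈ 0.97 per cohort: the block is then monomorphic among lean
  extremes (connectivity 0) while remaining polymorphic and tightly
  correlated among obese extremes — the differential-wiring signature,
  including the k_diff ≈ −1 extreme that max-normalized connectivity
  permits.

Both effect vectors point along the index-efficient trait direction
(DXA %fat, omental fat, DXA fat, daily gain, weight — the traits with
large index coefficients under the default P, G, v). The `dw_qtl` effect
deliberately exceeds the per-trait polygenic budget G − Cov_qtl on those
traits; the residual polygenic covariance is clipped to the nearest PSD
matrix, so realized genetic variance on the affected traits exceeds the
nominal G in the default world. Consequences: the index sd is ≈ 1.5
rather than √(b′Gb) ≈ 1.2, and the index distribution is right-skewed by
the rare haplotype (a cluster-free configuration reproduces G element-wise
and a normal index, and that is the configuration under which those
contracts are tested).

**What a green test does not establish.** The generator has no selection
or drift across generations, no genotyping error beyond uniform missing
calls (default rate 0.01), no X-chromosome model, no crossover
interference, and founder lines without internal haplotype structure
outside the planted clusters. Module recovery on this world says the
algorithm chain works, not that real chip data will produce comparably
clean modules.

## Quality control

Fixed order: sample call rate (> 5% missing removed) → pairwise IBS
(mean over shared markers of 1 − |d_i − d_j|/2; from each pair ≥ 0.95 the
member with more missingness is removed, ties by larger id) → marker call
rate → MAF (inclusive boundary: MAF ≤ 0.05 removed; monomorphic markers
fall out here with MAF 0) → exact HWE (p < 10⁻⁵ removed). The HWE test is
the exact conditional test (Wigginton-style, no mid-p), matching
GenABEL-era defaults and admitting an enumeration oracle; a chi-square
option exists. IBS and HWE are computed on the full cohort even though an
F2 design inflates both — fidelity to the emulated analysis over
statistical purity.

## Selection index

b solves P b = G v by a symmetric solve (never an explicit inverse), with
a condition-number guard that reports the smallest eigenvalue of P. G is
only required symmetric; indefinite G (common in estimated genetic
covariances) warns rather than errors. The index is reported in natural
units (no z-scaling by default). "Intermediate" animals in the 25/25/25
network selection are those nearest the cohort median after the tails are
taken, with ties broken by animal id so selection is order-invariant.

## GWAS

OLS per marker with intercept, pairwise missing-data deletion, two-sided p
on n − 2 df. Zero-variance markers and markers with fewer than 3
informative animals are NA with a reason code; perfect fits report p = 0
flagged `perfect_fit`. No structure covariates by default — the index is
already a genetic value estimated net of systematic effects, and
re-correcting would double-correct; a covariate hook exists. Bonferroni
thresholds are α/M over the markers actually scanned, α ∈ {0.05, 0.001}.

## WISH network

* **Pre-selection** ranks by normalized connectivity k_i = Σ|r_ij|/(m−1)
  at γ = 1: the ranking precedes the soft-threshold choice, so it cannot
  depend on γ. Ties at the top-N cut keep the lower marker index. The
  0.12 audit threshold is recorded alongside the realized cut value.
* **Adjacency** is unsigned, |r|^γ: with an odd power a signed version
  would leave [0, 1]. Correlations are pairwise-complete over non-missing
  animals; zero-variance SNPs get zero rows (flagged).
* **Soft threshold**: the scale-free fit bins connectivity into 10
  equal-width bins and fits log₁₀(frequency) on log₁₀(mean k); the fit
  index counts only negative slopes. Chosen γ is the smallest reaching
  R² ≥ 0.85, else the argmax; γ = 5 is the shipped default when fitting is
  off. (Equal-count binning would make the per-bin frequency constant by
  construction; equal-width is the field convention and what an exact
  power law reproduces with R² = 1.)
* **Modules**: average-linkage clustering of 1 − TOM, cut statically at
  the 0.99 quantile of merge heights; branches under 50 SNPs merge into
  the nearest retained branch when their mean dissimilarity stays below
  the cut, else label 0; labels ordered by decreasing size. This is the
  simple "tree" variant of dynamic tree cutting — deterministic and
  sufficient for well-separated genotype blocks; the variant name is in
  the output metadata. A degenerate all-equal dissimilarity yields a
  single module with a logged note, never a crash.
* **eigenSNPs**: missing dosages mean-imputed within SNP, columns
  standardized, first singular vector over animals, sign aligned with the
  module's mean standardized dosage; variance explained = λ₁/Σλ.
* **GMAT**: MTR = cor(eigenSNP, trait), p = Student asymptotic two-sided
  on n − 2 df. Selection: p(OI) < 0.001 and |MTR| > 0.4 with ≥ 1 other
  trait — absolute value, because an eigenSNP's sign is arbitrary.

## Differential wiring

k is the sum of absolute correlations (signed sums could cancel),
max-normalized within each subgroup so k ∈ [0, 1] and k_diff ∈ [−1, 1] —
the normalization that makes extreme values ±1 attainable when a SNP is
monomorphic in one subgroup (its correlations are defined as 0 there,
flagged). The full post-QC marker set is the default SNP universe, with an
option to restrict to the WISH pre-selection; correlations are computed in
float32 blocks for memory. No permutation significance: the fixed 0.6
cutoff is the method's rule.

## Annotation and enrichment

Internal coordinates are 0-based half-open (BED); map bp is 1-based and
converted on entry, so a SNP at 1-based bp b maps to gene [start, end)
with flank f iff start − f ≤ b − 1 < end + f. The default flank is 20 kb
(promoter coverage). Enrichment is the two-sided Fisher exact test per
gene set over a background of all genes mappable from post-QC SNPs
(overridable), Bonferroni-corrected over the sets actually tested. Gene
sets come from local GMT files; no external services are queried.

## Numerical and testing choices

* Seeds: one master seed spawns independent per-stage streams
  (`numpy` SeedSequence); identical config + seed gives byte-identical
  outputs.
* TOM denominators below 10⁻¹² yield 0; adjacency/TOM are clipped to
  [0, 1] against float drift.
* LD-law tests compare dosage correlations to 1 − 2c within bootstrap
  standard errors over animals: dosages are discrete, and the Gaussian
  (Fisher) SE understates their sampling variance by nearly a factor of
  two at high ρ.
* p-values are written in scientific notation with 6 significant figures;
  all thresholds used at every stage are logged in the run manifest.
* The end-to-end suites run the default desk-scale cohort (454 F2, 5,000
  markers — the emulated study's 60K chip scaled down ~8×) across 10
  seeds in a few minutes on one CPU.

## Known limitations

Single-factor trait covariance is a crude stand-in for a real multi-trait
genetic architecture; the tree-cut is the static variant, so modules with
nested substructure split differently than WGCNA's hybrid cut; GMAT
p-values are not corrected for the number of modules × traits (the
selection rule's 0.001 is the method's own control); enrichment treats
genes as exchangeable and ignores gene length and LD clumping of SNPs to
genes.
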