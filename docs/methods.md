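# Methods

This note documents the statistical model behind each pipeline stage,
the synthetic-data generator's assumptions, the numerical choices, and
the limitations a user should know before trusting results on real
data.

## Two-stage design

The scan treats pleiotropy detection as a screening problem: stage one
(discovery) trades specificity for sensitivity by using a false
discovery rate of 5 % instead of a Bonferroni-style bound; stage two
(replication) restores specificity by demanding genome-wide significance
(p < 5×10⁻⁸) in an independent, individual-level cohort. A variant is
reported as pleiotropic only if it is (a) established genome-wide
significant for a non-bone phenotype, (b) FDR-significant for at least
one of the two BMD traits, (c) independent of other reported variants
(r² < 0.2), (d) not a perfect proxy of an already-known BMD locus, and
(e) replicated at genome-wide significance in the cohort.

## Catalog curation

Rules are applied in a fixed order with first-match attribution, so the
report partitions the input exactly (a property test enforces
`retained + Σ removed = input` on arbitrary inputs): sub-threshold p,
interaction entries, haplotype entries, missing rsIDs, bone-related
traits, known BMD SNPs, pleiotropy-rule traits, duplicates. Two of the
steps are judgment calls in any real analysis and are therefore
declarative and overridable here:

* *bone-relatedness* is decided by case-insensitive keyword match on the
  trait and trait-category labels (defaults: bone mineral density, BMD,
  osteoporosis, fracture, calcium, bone, heel ultrasound) rather than an
  ontology, keeping the step auditable without an external dependency;
* the *pleiotropy criteria* (the scanned phenotype must not be a
  pathophysiological counterpart, subset, derived measure, close
  correlate, or known causal factor of the bone phenotype) are encoded
  as a keyword list (defaults include vitamin D, parathyroid, phosphate
  levels, lean body mass) that a user extends per study.

Duplicate resolution keeps the first occurrence in file order —
deterministic and order-preserving. Rows with missing rsIDs are dropped
with a warning; no attempt is made to rescue them from other columns.

## LD: r², proxies, pruning

r² is the squared Pearson correlation of allele-dosage vectors over
pairwise-complete samples (composite LD). This is phase-free, symmetric,
invariant to allele relabeling (g ↦ 2−g), and exact on the synthetic
panel; no haplotype-phase EM is attempted. Monomorphic variants have
undefined LD: the proxy search skips them, pruning treats them as r² = 0.

* Proxy search returns all same-chromosome variants within a window
  (default 500 kb each side — common proxy-server practice, bounds
  compute) whose r² reaches the query threshold; r² = 1 comparisons use
  an absolute tolerance of 1e−9 because exact duplicate columns reach
  correlation 1 only up to float rounding. Query SNPs absent from the
  panel are reported as unresolvable, never silently dropped.
* Pruning is greedy best-first clumping: candidates visited in ascending
  p (ties: chromosome, position, rsid), kept iff r² with every kept
  same-chromosome variant is below the threshold (default 0.2). The
  output is maximal under that order (tested exhaustively on small
  panels). Candidates absent from the panel are kept and flagged, since
  their LD cannot be assessed.

## Discovery: Simes/BH step-up

The per-trait procedure sorts the m intersected p-values, finds
k = max{i : p₍ᵢ₎ ≤ (i/m)·q}, and declares every p ≤ p₍ₖ₎ significant —
exact step-up semantics, so p-values below a passing rank are carried
even if they miss their own bound. "Simes" here denotes this
Benjamini–Hochberg step-up at level q, not the global Simes test, which
yields no per-SNP threshold; the reported per-trait threshold is the
bound (k/m)·q, displayed at two significant figures but used at full
precision internally.

Design choices worth stating:

* the two traits are combined by **union** — a SNP significant for
  either femoral-neck or lumbar-spine BMD is carried forward; each
  trait's BH run controls its own FDR at q.
* per-trait m is the size of the intersected, deduplicated test set
  (candidates plus proxies, restricted to SNPs present in that trait's
  statistics), not the full catalog.
* independence pruning is applied once to the union, with each SNP
  entering at its minimum p across the two traits. The alternative
  (pruning per trait, then merging) is not uniquely defined when the
  two orderings disagree; the single-prune interpretation is simpler
  and reproducible.

Calibration: under a fully null simulation the mean false-discovery
proportion of the stage equals the nominal level in expectation (for a
full null the FDP is 1 exactly when anything is rejected, and the BH
guarantee makes that probability q under independence). The acceptance
script recomputes this with 500 replicates of m = 2 000 null statistics.

## Replication

**QC.** Per-sex exclusion bounds on SOS (m·s⁻¹), BUA (dB·MHz⁻¹) and BMD
(g·cm⁻²) are applied with *boundary values excluded* — the bounds are
stated as "≤ lower / ≥ upper", and an exhaustive 12-case boundary suite
pins that semantics. With `use_ebmd` the BMD bound is applied to
0.002592·(BUA+SOS) − 3.687 instead of the device value (sensitivity
analysis).

**Kinship.** The KING-robust between-family estimator
φ̂ = (N_het,het − 2·N_opposite-hom) / (N_het(i) + N_het(j)) is used, as
appropriate for a structured cohort; it is validated by class-recovery
properties (duplicates ≈ 0.5, parent–offspring/full sibs ≈ 0.25, second
degree ≈ 0.125, third degree ≈ 0.0625) rather than against a printed
formula. Pairs with φ̂ ≥ 2^(−9/2) (degree 3 or closer) are related. The
all-pairs scan is computed with blocked float32 matrix products of
heterozygosity/homozygosity indicator matrices, so biobank-scale sample
counts remain tractable on one core; a per-pair scalar implementation
serves as its oracle in the tests.

A moment estimator from m markers has standard error ≈ 0.9/√m for
unrelated pairs. At a few thousand markers this noise floor sits close
enough to the degree-3 cutoff that, across hundreds of millions of
pairs, a visible fraction of unrelated pairs would be falsely flagged;
real pipelines avoid this by running the kinship screen on dense array
genotypes. The simulator therefore carries independent "background
array markers" (`n_background_markers`) alongside the LD blocks; the
demo scenario uses 12 000, placing the cutoff >6 SEs from zero so false
pairs are rare. This is a property of moment-based kinship estimation,
not of this implementation.

**Unrelated-set selection.** "Keep one member of each pair" is made
deterministic: repeatedly remove the sample with the most related
partners, breaking ties by removing the lexicographically larger sample
ID, until no pair at or above the cutoff remains. Reproducibility is
preferred over fidelity to an unstated arbitrary choice.

**Phenotype.** Within each sex, BMD is residualized by OLS on intercept,
age, age², weight; the residual divided by its standard deviation
(ddof = 1) gives a Z with per-sex mean 0 and SD 1; |Z| > 4 is excluded
afterwards. The stage order is fixed and logged: QC → kinship pruning →
Z-score → |Z| bound → association.

**Association.** OLS of Z on intercept, dosage and 15 ancestry PCs,
pooled across sexes (sex is absorbed by the per-sex standardization).
The dosage coefficient's two-sided p uses the t distribution with
n − 17 degrees of freedom — exact at small fixture sizes, numerically
identical to the normal at cohort sizes. Missing dosages are
mean-imputed per SNP by default (standard GWAS practice); a strict
complete-case mode exists. Constant dosages raise a monomorphic error.

**Concordance.** Replication betas are harmonized to the discovery
effect allele, including strand-complement matches; palindromic (A/T,
C/G) SNPs with MAF > 0.4 are strand-ambiguous and leave the
denominator, as do allele mismatches.

## Synthetic-data generator

The generator's goal is statistical structure sufficient to exercise
every decision the pipeline makes, not demographic realism.

* **LD blocks** use a haplotype-copy scheme: each block has an anchor
  SNP; one designated partner is an exact copy (even blocks) or exact
  allele-flipped copy (odd blocks) — guaranteeing one perfect-proxy
  pair per block and exercising the g ↦ 2−g invariance; remaining
  members copy the anchor haplotype with probability √(within-block r²),
  giving anchor–member r² at the target level in expectation. A
  coalescent simulator would add realism the LD logic does not need.
* **Summary statistics**: SE = 1/√(2·EAF·(1−EAF)·N); the true marginal
  effect of each variant is the block anchor's planted standardized beta
  attenuated by the realized signed dosage correlation r with the
  anchor. Sampling noise is drawn *jointly per block* with the panel's
  realized correlation as its covariance — independent noise per SNP
  would be unfaithful exactly where it matters most, at r² = 1 proxies,
  which in real data carry bit-identical statistics. Exact copies are
  assigned sign-harmonized identical estimates, which also makes
  pruning tie-breaks deterministic.
* **Cohort**: latent eBMD = baseline + per-allele genetic effects
  (standardized beta × residual SD, in g·cm⁻²) + covariate effects +
  Gaussian noise (default residual SD 0.09 g·cm⁻², in line with the
  unit-SD Z-scale of heel BMD after covariate adjustment). Age is
  uniform on [40, 69] (the recruitment window), weight normal (78, 15²)
  truncated at 30 kg, sex balanced; default covariate coefficients give
  BMD the expected mild decline with age and increase with weight. SOS
  is drawn from N(1550, 30²) truncated so that both SOS and the implied
  BUA = (eBMD + 3.687)/0.002592 − SOS stay strictly inside the QC
  bounds; the printed formula therefore inverts to the latent eBMD
  exactly (tested to 1e−12). A configurable fraction of records is
  placed on or strictly outside the bounds (cycling through measure ×
  side, including exact-boundary cases) with the reason recorded;
  ground-truth exclusion flags are re-derived from the final values so
  accidental tail outliers are also captured.
* **Relatedness**: derived samples share haplotypes
  identical-by-descent with their base sample per relationship class —
  duplicates share both haplotype slots everywhere; parent–offspring
  one (randomly chosen) parental haplotype per block; full sibs each
  parental slot independently with probability ½ per block; second/
  third degree one slot with probability ½/¼. These reproduce the
  expected kinship coefficients (0.5, 0.25, 0.25, 0.125, 0.0625) and
  their KING intervals.
* **Decoys** (`n_planted_decoy`) carry an effect in the summary
  statistics but not in the cohort — the false-positive mode the
  replication stage exists to catch.
* Principal components are pure noise: the generator does not model
  population structure, so passing tests show covariate plumbing works,
  not that PC adjustment removes real stratification. Other real-data
  features deliberately absent: genotyping error and missingness
  patterns, imputation uncertainty, realistic human LD maps,
  X-chromosome inheritance, sample overlap between stages.

All randomness flows from one seed through named per-stage substreams,
so identical configurations reproduce byte-identical artifacts and any
stage can be regenerated independently.

## Problem sizes in the shipped scenarios

The end-to-end demonstration plants 3 pleiotropic SNPs and 2 decoys
among 2 000 null candidate blocks, with 20 000 cohort participants, 40
related pairs, and 12 000 background kinship markers. The planted
standardized effect (0.12 per allele) and the demo's common-variant MAF
range (0.2–0.5) put per-SNP replication power above 99.9 % at 5×10⁻⁸
even after QC and kinship attrition, so the replicated set equals the
planted set deterministically under the fixed seed. The calibration
study uses 500 replicates of 2 000 null statistics. Smaller seeded
variants of the same scenario back the per-module tests.

## Known limitations

* The five pleiotropy criteria and the bone-trait vocabulary are
  keyword heuristics; on real catalog exports they need curation.
* The FDR guarantee is per trait under independence/PRDS; with heavy LD
  between test SNPs the procedure remains valid but conservative
  interpretation of the union set is the user's responsibility.
* r² is panel-dependent; proxies and pruning inherit the ancestry of
  whatever panel is supplied, and the panel's identity is only logged,
  not checked.
* Kinship estimation needs enough markers (see above); with only a few
  hundred variants, third-degree detection is unreliable by
  construction.
* The eBMD formula is treated as exact; device-specific calibration
  differences are out of scope.
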