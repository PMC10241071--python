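# Methods

This note documents the models, parameter choices and numerical decisions
behind `pgxcohort`, and what the synthetic-data validation does and does not
establish about real cohorts.

## The synthetic founder cohort

The generator is the package's substitute for restricted human data, and its
defaults *are* the study conditions everything else is validated under: 459
diploid samples, a star-allele frequency map taken from the bundled 19-gene
definition table (CYP3A5\*3 0.94, CYP2C9\*3 0.42, CYP2D6\*5 0.24,
CYP2B6\*6 0.39, CYP2C19\*2 0.25 / \*3 0.12, CYP4F2\*3 0.36 / \*4 0.40,
NUDT15\*3 0.05, SLCO1B1\*20 0.11, the VKORC1/ABCG2/IFNL3 target and
transporter variants at 0.10/0.03/0.11, and rare alleles for DPYD, CYP2C8
and G6PD), and an inbreeding coefficient F = 0.05.

* **Diplotype draws.** For each gene the first haplotype is drawn from the
  frequency map; with probability F the second is identical by descent,
  otherwise independent. This yields exactly the inbreeding-adjusted
  Hardy–Weinberg proportions P(hom i) = pᵢ² + F·pᵢ(1−pᵢ) and
  P(het i,j) = 2pᵢpⱼ(1−F). Genes are independent; within a gene the defining
  variants of a haplotype are fully linked. F = 0.05 is a deliberately
  modest default for a founder population — it is a free parameter of the
  simulator, not an estimate for any real population.
* **Whole-gene deletions** (CYP2D6\*5) are bookkept as copy number 2 − #
  deletion haplotypes in a per-sample sidecar TSV; the VCF stays a plain
  biallelic SNP/indel file. Real pipelines infer such CNVs from read depth,
  which is out of scope here.
* **Background SNPs.** Kinship, HWE calibration and PCA need many
  independent autosomal sites that the ~30 pharmacogene defining variants
  cannot provide, so the generator also emits neutral background SNPs
  (default 1000; tests use up to 50 000 for kinship and 3000 for structure
  recovery) with allele frequencies uniform on [0.05, 0.5], placed on a
  chromosome not used by the definition table.
* **Depth/quality model.** DP is negative binomial with mean 30 and shape
  20 (≈30× WGS with mild overdispersion); GQ = clip(5 + 3·DP + N(0, 6²),
  0, 99). This masks ≈0.15% of calls, exercising both sides of the DP ≥ 10
  / GQ ≥ 20 thresholds while keeping per-variant missingness realistic for
  PCR-free short-read data. Any of these can be overridden per run.
* **Planted structure.** Duplicate pairs copy all haplotypes (DP/GQ noise is
  redrawn); parent–offspring targets inherit one parental haplotype per
  independent locus. Admixed outliers draw each background haplotype from a
  second population (AFs shifted by U(−0.5, 0.5), a continental-scale
  divergence) with 50% admixture proportion; their pharmacogene haplotypes
  follow founder frequencies so they perturb structure, not star-allele
  truth.
* **VIP annotation tables** plant four categories whose AF ranges are
  validated up front against the triage thresholds (e.g. known-enriched
  cohort AF is drawn above 0.12 with all panel AFs below 0.05), so that
  truth recovery is exact by construction; a spec that cannot satisfy its
  category's filters is rejected. Default composition: 14 known-enriched,
  55 deleterious-enriched, 31 novel, 900 benign (benign rows are built to
  robustly fail at least one filter: no deleterious evidence, or common in
  every panel, or annotated but rare in the cohort).

What passing on this cohort does **not** show: robustness to LD between
genes, depth-correlated masking, batch effects, hybrid/fusion alleles,
sub-allele suffixes, sex-chromosome dosage (G6PD is simulated diploid), or
annotation noise in real ANNOVAR/ClinVar exports.

## QC chain

Fixed, auditable order: normalize → mask → variant filters → sample filters
→ (structure profile: MAF + LD pruning → kinship → PCA → outlier flagging).
Every removed variant and sample appears exactly once in an exclusion
report with its first failing rule.

* **Normalization** trims shared allele bases and left-aligns indels (the
  classic parsimony/left-shift loop), splits multiallelic records, removes
  exact duplicates and rejects records whose REF disagrees with the
  reference; it is tested against both exhaustive shift enumeration and
  `bcftools norm`.
* **HWE exact test**: conditional on allele counts, plain (not mid-)
  p-value, strict < 10⁻⁶ removal boundary. For ≤1000 samples the
  heterozygote-count distribution is computed with exact integer weights so
  tie handling is bit-reproducible against enumeration oracles; larger
  counts use the standard mode-outward recurrence in floats.
* **Kinship** uses the KING-robust between-family estimator
  φ = (N_het,het − 2·N_opposite-hom)/(N_het(i) + N_het(j)) over jointly
  non-missing sites — the estimator conventionally paired with the 0.354
  duplicate/monozygotic-twin cutoff (2^−1.5, the midpoint between duplicate
  and first-degree expectation on the log scale). Pairs with no
  heterozygote in either member are reported unevaluable rather than
  assigned φ. From each flagged pair the higher-missingness member is
  removed (tie: lexicographically later id).
* **LD pruning** is greedy over 50-variant windows sliding by 5: within a
  window each pair with r² > 0.2 (pairwise-complete correlation) loses its
  lower-MAF member (tie: later position). The scan repeats to a fixed
  point, which makes the operation idempotent even though removals can
  bring previously separated variants into one window.
* **PCA** mean-imputes missing dosages per variant (missingness is already
  capped at 1% in this profile), standardizes by 2p̂ and √(2p̂(1−p̂)), and
  takes the SVD; component signs are fixed by making the largest-magnitude
  sample coordinate positive. The default outlier rule — robust z
  (median/1.4826·MAD) > 6 on PC1 or PC2 — is a configurable stand-in for
  threshold-based outlier picking; at the simulator's admixture divergence
  it recovers planted outliers exactly, but the threshold deserves
  re-tuning on any real dataset.

## Star alleles, phenotypes, actionability

Matching is exact-combinatorial: all unordered pairs of defined haplotypes
(or haplotype + deletion under copy number 1, deletion/deletion under 0)
whose summed per-site dosages reproduce the observed non-missing dosages.
No partial or novel-haplotype inference is attempted — the matcher is a
reproducible stand-in for external ensemble callers, whose outputs the
consensus operation consumes generically (agreement of ≥2 callers on the
unordered pair; single-caller pass-through for ABCG2, RYR1, CACNA1S;
everything else queued unresolved for manual review). Tie-break among
consistent pairs: fewest total defining variants, then highest product of
bundled population frequencies, then lexicographic — and all alternatives
are always reported in the ambiguity set. Missing dosages act as wildcards
but are counted, and a pair supported only by wildcards is never reported
as confident.

Phenotypes: CYP2D6 uses activity-score bins (0 → PM, (0,1] → IM,
(1,2.25] → NM, >2.25 → UM; configurable, since published definitions bin
scores without a single canonical table); other enzymes use function-pair
rules ({No,No} → PM, {Normal,No} → IM, {Increased,Normal} → RM, …); drug
targets and transporters (VKORC1, ABCG2, SLCO1B1, IFNL3, CYP4F2) use
explicit diplotype→label maps. Any allele of unknown function (CYP2D6\*131,
CYP4F2\*4) forces Indeterminate, which is excluded from prevalence
denominators and never counted actionable.

"Actionable" defaults to every gene–phenotype pair with a non-default
prescribing recommendation in the bundled rule table (impaired and
ultrarapid metabolizer classes plus decreased/poor/increased-function and
unfavorable-response labels). CYP3A5 is the deliberate exception: poor
metabolizers receive the standard tacrolimus starting dose and default to
non-actionable, with a switch (`cyp3a5_pm_actionable`) because guideline
readings differ. The cohort-level ≥1/≥3 fractions are sensitive to this
definition; the bundled table is a defensible default, not the only one.

## Enrichment statistics

2×2 tables compare allele counts (2n per diploid sample) — the conventional
reading of "AF comparison" — between cohort and a declared reference
population; reference AFs are converted to counts using the declared panel
size, with a gnomAD-scale default of 70 000 samples when none is given.
Fisher's exact test is two-sided (point probabilities ≤ the observed one;
exact integer weights for tables up to n = 10 000, hypergeometric floats
with a 10⁻¹² tie tolerance beyond); the odds ratio is ad/bc with ∞/0/NaN
conventions for empty cells. BH adjustment is one family per invocation —
the full screened set, or the full annotated VIP table for triage.
Boundaries are strict everywhere: AF > 10%, < 6%, > 1%, CADD > 20, ≥2
votes.

Triage order matters and is fixed: star-defining and high-evidence variants
are excluded first (they belong to the other analysis arms); annotated
(ClinVar ∨ HGMD) variants can only become known-enriched; remaining
variants need in-silico deleterious evidence, with novelty (absence from
all three panels *and* all three databases, read conjunctively) taking
precedence over common-enrichment. The gnomAD rare-AF cap applies to
gnomAD_All only in the unknown branch; the known branch additionally caps
UKB, and its significance test is against gnomAD_All with UKB serving only
as an AF cap. Every non-retained variant carries a reasons trail that
re-evaluates to the same failure.

## Problem sizes and determinism

Validation runs use 459–500 samples, 19 genes, 1000–3000 background SNPs
(50 000 for pairwise kinship checks) and 1000-row VIP tables; exact-test
oracles are exhaustive over all tables with margins ≤ 30. All randomness
flows from a single integer seed through `numpy.random.default_rng`;
identical spec + seed reproduces VCFs and truth files byte for byte, and
the pipeline manifest records a SHA-256 checksum for every artifact.

## Known limitations

Phasing is never attempted (unphased dosage-sum matching only); genuinely
phase-ambiguous diplotypes (e.g. \*1/\*6 vs \*4/\*9 patterns in CYP2B6-like
definitions) surface as ambiguity sets rather than resolved calls. The
consensus operation does not adjudicate two-vs-two caller splits. The
simulator's missingness is independent across calls, which understates the
clustered missingness of real data. Reference-panel AFs in the bundled
synthetic screen inputs are perturbed truths, so screen hit counts on
synthetic runs are illustrative, not calibrated.
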