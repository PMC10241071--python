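# pgxcohort

Population pharmacogenomics for cohort VCFs: quality control, star-allele
diplotype calling, CPIC-style phenotype translation, enrichment screening
and triage of potentially actionable variants — with a synthetic
founder-cohort generator that makes the entire pipeline testable end to end.

## The problem

Isolated founder populations carry pharmacogene allele frequencies that can
differ several-fold from the continental reference panels on which most
prescribing guidance is based; characterizing a cohort's *pharmacogenomic
landscape* means asking, for each of a panel of pharmacogenes, which star
alleles (named haplotypes such as CYP3A5\*3 or the CYP2D6\*5 whole-gene
deletion) segregate in the cohort, at what frequencies, what metabolizer
phenotypes they imply, and which additional variants — known pathogenic,
predicted deleterious, or entirely novel — are enriched relative to global
populations. Cohorts like this are typically a few hundred whole genomes
with restricted access, so the package ships a first-class simulator whose
defaults emulate a homogeneous founder cohort of 459 diploid samples and
whose planted ground truth (diplotypes, relative pairs, admixed outliers,
variant categories) lets every stage be validated exactly.

`pgxcohort` is aimed at statistical-genetics and PGx researchers who want a
reproducible, library-first implementation of this analysis: each stage is
an importable function, the `examples/` scripts are the guided tour, and a
thin `pgx` CLI wraps the same functions for shell use.

## What's inside

| stage | core method |
| --- | --- |
| `sim` | inbreeding-adjusted Hardy–Weinberg draws: P(hom *i*) = *p*ᵢ² + *F·p*ᵢ(1−*p*ᵢ), P(het *i,j*) = 2*p*ᵢ*p*ⱼ(1−*F*); VCF v4.2 + copy-number sidecar emission; planted duplicates/parent–offspring pairs, admixed outliers, annotated VIP tables |
| `qc` | genotype masking (DP < 10 or GQ < 20 → missing); variant filters (missingness > 10%, HWE exact *p* < 10⁻⁶, MAF < 1% for the structure profile); sample filters (missingness, het rate beyond ±3 SD); KING-robust kinship φ = (N_het,het − 2N_opp-hom)/(N_het(i) + N_het(j)) with the 0.354 duplicate cutoff; sliding-window LD pruning (50 variants, step 5, r² > 0.2); dosage PCA with robust-z outlier flagging |
| `star` | exact combinatorial diplotype matching of unphased dosage sums against allele definitions, deletion alleles via copy number, ambiguity sets, ≥2-tool ensemble consensus |
| `phenotype` | CYP2D6 activity-score bins (0 → PM, ≤1 → IM, ≤2.25 → NM, >2.25 → UM), function-pair rules, explicit maps for drug targets/transporters, per-sample actionable-genotype counts |
| `stats` | allele frequency from genotype classes (hom + het/2), exact two-sided Fisher tests on allele counts, Benjamini–Hochberg FDR, the high-evidence (level 1A/1B) screen |
| `triage` | cascade for VIP-gene variants: known (ClinVar/HGMD) enrichment branch (cohort AF > 10%, panels < 6%, adj *p* < 0.05), in-silico deleteriousness vote (≥2 of 8 tools or CADD > 20), novel (absent from gnomAD/1KGP/UKB and dbSNP/HGMD/ClinVar) vs commonly enriched (AF > 1%, >2-fold) |

## Worked example

```bash
python examples/03_star_alleles_and_phenotypes.py
```

```
consensus CYP2C9 for S0001: *1/*3 (two callers agree)
cohort CYP3A5*3 allele frequency: 0.93
impaired CYP2D6 metabolism (IM+PM): 40.7% of the cohort
actionable genotypes per person: mean 3.13; >=1 in 98.9%, >=3 in 68.4% of the cohort
```

Reading the numbers: on a simulated 459-sample founder cohort the no-function
CYP3A5\*3 allele is near fixation (AF 0.93 against a simulated truth of
0.94), about 41% of individuals are intermediate or poor CYP2D6 metabolizers
(driven by the \*5 whole-gene deletion at AF 0.24, called through the
copy-number sidecar), and nearly everyone carries at least one gene–phenotype
pair with a non-default prescribing recommendation. The other examples cover
simulation (`01`), QC with planted duplicates and admixed outliers (`02`),
the high-evidence screen (`04`) and VIP triage (`05`). The same stages are
available from the shell:

```bash
pgx simulate --out-dir run --seed 1
pgx call --vcf run/cohort.vcf --copy-number run/copy_number.tsv --out run/calls.tsv
pgx run --out-dir full_run --seed 1     # whole pipeline + manifest + report
```

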