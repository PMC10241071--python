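"""Run the QC chain on a cohort with planted duplicates and admixed samples.

Masks low-quality calls (DP < 10 or GQ < 20), applies variant and sample
filters, removes duplicate samples at KING kinship > 0.354 and flags
population-structure outliers on the leading principal components.
"""

import tempfile

import numpy as np

import pgxcohort as pgx

spec = pgx.SimulationSpec(
    n_samples=459, n_background_snps=3000, n_admixed=10, seed=1,
    relative_pairs=(pgx.RelativePairSpec("duplicate", 3),),
)
truth = pgx.simulate_diplotypes(spec)
truth = pgx.plant_relatives(truth, spec.relative_pairs, spec)
out = tempfile.mkdtemp(prefix="pgx_qc_")
paths = pgx.emit_cohort_vcf(truth, spec, out)

cfg = pgx.QcConfig()
cm = pgx.CohortMatrix.from_vcf(paths["vcf"])
cm = pgx.mask_low_quality_calls(cm, cfg)
print(f"masked calls: {100 * np.isnan(cm.dosage).mean():.2f}% (DP<10 or GQ<20)")

cm, var_report = pgx.filter_variants(cm, cfg, profile="basic")
cm, sample_report = pgx.filter_samples(cm, cfg)
print(f"variant exclusions: {len(var_report)}; sample exclusions: {len(sample_report)}")

bg = cm.subset_variants(np.flatnonzero(cm.variants["id"].str.startswith("20:")))
bg, _ = pgx.filter_variants(bg, cfg, profile="pca")
bg = bg.subset_variants(pgx.ld_prune(bg, cfg))
bg, kin_table, removed = pgx.kinship_filter(bg, cfg)
print(f"kinship > {cfg.kinship_cutoff}: removed {removed}")
print("-> one member of each planted duplicate pair, as the cutoff intends.")

projection = pgx.pca_project(bg, cfg.pca_components)
flagged = pgx.flag_pca_outliers(projection)
print(f"PCA structure outliers (robust z > {cfg.outlier_z} on PC1/PC2): {flagged}")
print(f"planted admixed samples:                                       "
      f"{sorted(truth.outlier_samples)}")
print("-> admixed individuals separate from the homogeneous founder cluster")
print("   and are excluded before allele frequencies are estimated.")
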