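"""Synthetic founder-cohort generator: HWE structure, determinism, round trips."""

import filecmp

import numpy as np
import pytest

import pgxcohort as pgx


def _one_gene_spec(freqs, inbreeding, n, seed=1, **kw):
    return pgx.SimulationSpec(
        n_samples=n,
        gene_frequencies={"CYP3A5": freqs},
        inbreeding=inbreeding,
        n_background_snps=kw.pop("n_background_snps", 0),
        seed=seed,
        **kw,
    )


# ---------------------------------------------------------------------------
# genotype-class structure
# ---------------------------------------------------------------------------

def test_homozygote_fraction_matches_hwe_closed_form():
    """freqs {*3: 0.94}, F=0: fraction *3/*3 ~ p^2 within 3 binomial SD."""
    n = 100_000
    spec = _one_gene_spec({"*1": 0.06, "*3": 0.94}, inbreeding=0.0, n=n)
    truth = pgx.simulate_diplotypes(spec)
    haps = truth.star_haplotypes["CYP3A5"]
    star3 = truth.allele_names["CYP3A5"].index("*3")
    hom = np.mean((haps[:, 0] == star3) & (haps[:, 1] == star3))
    p2 = 0.94**2
    sd = np.sqrt(p2 * (1 - p2) / n)
    assert abs(hom - p2) < 3 * sd


def test_full_inbreeding_forbids_heterozygotes():
    spec = _one_gene_spec({"*1": 0.5, "*3": 0.5}, inbreeding=1.0, n=2000)
    truth = pgx.simulate_diplotypes(spec)
    haps = truth.star_haplotypes["CYP3A5"]
    assert np.all(haps[:, 0] == haps[:, 1])


def test_inbreeding_adjusted_heterozygosity():
    """F=0.3 halves heterozygosity accordingly: 2pq(1-F)."""
    n = 50_000
    spec = _one_gene_spec({"*1": 0.5, "*3": 0.5}, inbreeding=0.3, n=n, seed=2)
    truth = pgx.simulate_diplotypes(spec)
    haps = truth.star_haplotypes["CYP3A5"]
    het = np.mean(haps[:, 0] != haps[:, 1])
    expected = 2 * 0.5 * 0.5 * (1 - 0.3)
    assert het == pytest.approx(expected, abs=4 * np.sqrt(expected / n))


def test_spec_validation_rejects_bad_inputs():
    with pytest.raises(ValueError, match="reference allele"):
        pgx.SimulationSpec(gene_frequencies={"G": {"*2": 1.0}})
    with pytest.raises(ValueError, match="sum"):
        pgx.SimulationSpec(gene_frequencies={"G": {"*1": 0.6, "*2": 0.3}})
    with pytest.raises(ValueError, match="inbreeding"):
        pgx.SimulationSpec(inbreeding=1.5)


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------

def test_reference_diplotype_emits_zero_dosages(tmp_path, definitions):
    spec = _one_gene_spec({"*1": 1.0}, inbreeding=0.0, n=5)
    truth = pgx.simulate_diplotypes(spec, definitions)
    paths = pgx.emit_cohort_vcf(truth, spec, str(tmp_path), definitions)
    cm = pgx.CohortMatrix.from_vcf(paths["vcf"])
    assert np.all(cm.dosage == 0.0)


def test_vcf_round_trip_reproduces_truth_dosages(small_cohort_run, definitions):
    """Re-parsed VCF dosages equal truth haplotype sums for 100% of calls."""
    truth, cm = small_cohort_run["truth"], small_cohort_run["cm"]
    key_index = {k: j for j, k in enumerate(cm.variant_keys())}
    checked = 0
    for gene in truth.genes:
        defs = {a.name: a for a in definitions.for_gene(gene)}
        names = truth.allele_names[gene]
        haps = truth.star_haplotypes[gene]
        for key in sorted(definitions.defining_variant_keys(gene)):
            j = key_index[key]
            carrier = np.array([key in defs[a].variants for a in names])
            expected = carrier[haps[:, 0]].astype(int) + carrier[haps[:, 1]]
            assert np.array_equal(cm.dosage[:, j], expected.astype(float))
            checked += 1
    assert checked > 10
    # background SNPs too
    bg = truth.background
    for jj, pos in enumerate(bg.positions):
        j = key_index[(bg.chrom, int(pos), "A", "G")]
        assert np.array_equal(
            cm.dosage[:, j], bg.haplotypes[:, jj].sum(axis=1).astype(float)
        )


def test_deletion_allele_goes_to_sidecar(tmp_path, definitions):
    spec = pgx.SimulationSpec(
        n_samples=400,
        gene_frequencies={"CYP2D6": {"*1": 0.5, "*5": 0.5}},
        inbreeding=0.0, n_background_snps=0, seed=3,
    )
    truth = pgx.simulate_diplotypes(spec, definitions)
    paths = pgx.emit_cohort_vcf(truth, spec, str(tmp_path), definitions)
    cn = pgx.sim.load_copy_number_sidecar(paths["copy_number"])
    frame = truth.diplotype_frame()
    hemi = frame[(frame.allele1 == "*1") & (frame.allele2 == "*5")]
    assert len(hemi) > 0
    for rec in hemi.itertuples(index=False):
        assert cn[(rec.sample, "CYP2D6")] == 1
    null = frame[(frame.allele1 == "*5") & (frame.allele2 == "*5")]
    for rec in null.itertuples(index=False):
        assert cn[(rec.sample, "CYP2D6")] == 0
    # the VCF itself carries no trace of the deletion (defining set empty)
    cm = pgx.CohortMatrix.from_vcf(paths["vcf"])
    assert cm.n_variants == len(definitions.defining_variant_keys("CYP2D6"))


def test_identical_spec_and_seed_give_identical_bytes(tmp_path, definitions):
    spec = pgx.SimulationSpec(n_samples=30, n_background_snps=40, seed=11)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        truth = pgx.simulate_diplotypes(spec, definitions)
        pgx.emit_cohort_vcf(truth, spec, str(d), definitions)
    for name in ("cohort.vcf", "copy_number.tsv", "truth_diplotypes.tsv"):
        assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name


def test_emission_rejects_undefined_alleles(tmp_path, definitions):
    spec = pgx.SimulationSpec(
        n_samples=5,
        gene_frequencies={"CYP2C9": {"*1": 0.5, "*99": 0.5}},
        n_background_snps=0, seed=1,
    )
    truth = pgx.simulate_diplotypes(spec, definitions)
    with pytest.raises(ValueError, match="lacks a definition"):
        pgx.emit_cohort_vcf(truth, spec, str(tmp_path), definitions)


# ---------------------------------------------------------------------------
# relative planting
# ---------------------------------------------------------------------------

def test_zero_pairs_leaves_cohort_unchanged(definitions):
    spec = pgx.SimulationSpec(n_samples=20, n_background_snps=30, seed=5)
    truth = pgx.simulate_diplotypes(spec, definitions)
    same = pgx.plant_relatives(truth, [], spec)
    assert same is truth


def test_planted_duplicates_have_kinship_half(definitions):
    spec = pgx.SimulationSpec(
        n_samples=60, n_background_snps=500, seed=6,
        relative_pairs=(pgx.RelativePairSpec("duplicate", 3),),
    )
    truth = pgx.simulate_diplotypes(spec, definitions)
    truth = pgx.plant_relatives(truth, spec.relative_pairs, spec)
    assert len(truth.planted_pairs) == 3
    g = truth.background.haplotypes.sum(axis=2).astype(float)
    for s1, s2, kind in truth.planted_pairs:
        i, j = truth.samples.index(s1), truth.samples.index(s2)
        assert pgx.king_phi(g[i], g[j]).phi == 0.5


def test_parent_offspring_kinship_near_quarter(definitions):
    spec = pgx.SimulationSpec(
        n_samples=10, n_background_snps=50_000, inbreeding=0.0, seed=8,
        relative_pairs=(pgx.RelativePairSpec("parent_offspring", 2),),
    )
    truth = pgx.simulate_diplotypes(spec, definitions)
    truth = pgx.plant_relatives(truth, spec.relative_pairs, spec)
    g = truth.background.haplotypes.sum(axis=2).astype(float)
    for s1, s2, kind in truth.planted_pairs:
        i, j = truth.samples.index(s1), truth.samples.index(s2)
        assert pgx.king_phi(g[i], g[j]).phi == pytest.approx(0.25, abs=0.02)


def test_too_many_pairs_rejected(definitions):
    spec = pgx.SimulationSpec(n_samples=5, n_background_snps=10, seed=1)
    truth = pgx.simulate_diplotypes(spec, definitions)
    with pytest.raises(ValueError, match="pairs"):
        pgx.plant_relatives(truth, [pgx.RelativePairSpec("duplicate", 3)], spec)


def test_hwe_calibration_on_outbred_cohort():
    """With F = 0 and n = 10^4 samples, the HWE exact test at p < 1e-6
    rejects essentially no simulated site (expected fraction <= 1e-4)."""
    spec = _one_gene_spec(
        {"*1": 0.5, "*3": 0.5}, inbreeding=0.0, n=10_000, seed=4,
        n_background_snps=2000,
    )
    truth = pgx.simulate_diplotypes(spec)
    dosage = truth.background.haplotypes.sum(axis=2)
    rejected = 0
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        counts = np.bincount(col, minlength=3)
        if pgx.hwe_exact_p(int(counts[0]), int(counts[1]), int(counts[2])) < 1e-6:
            rejected += 1
    assert rejected <= 2  # 2000 sites at a 1e-4 expected fraction


# ---------------------------------------------------------------------------
# allele-frequency recovery (generator-level)
# ---------------------------------------------------------------------------

def test_truth_allele_frequencies_within_binomial_interval(definitions):
    from scipy.stats import binom

    spec = pgx.SimulationSpec(n_samples=459, n_background_snps=0, seed=13)
    truth = pgx.simulate_diplotypes(spec, definitions)
    n_alleles = 2 * spec.n_samples
    for gene, freqs in spec.gene_frequencies.items():
        names = truth.allele_names[gene]
        haps = truth.star_haplotypes[gene]
        counts = np.bincount(haps.ravel(), minlength=len(names))
        for idx, name in enumerate(names):
            p = freqs[name]
            lo, hi = binom.interval(0.95, n_alleles, p)
            assert lo <= counts[idx] <= hi, (gene, name, counts[idx], p)
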