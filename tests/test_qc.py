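"""QC chain: normalization, masking, HWE, filters, kinship, LD pruning, PCA."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import pgxcohort as pgx
from pgxcohort.qc import _normalize_one

from oracles import (
    apply_variant,
    fisher_exact_oracle,
    hwe_exact_oracle,
    leftmost_parsimonious,
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

SEQ = "GGGGGGGGGAATTTGGCACACAGT"  # TTT run at 12-14, CACACA at 17-22


@pytest.mark.parametrize(
    "pos,ref,alt",
    [
        (12, "TT", "T"),      # deletion inside a homopolymer run
        (13, "T", "TT"),      # insertion inside the run
        (11, "ATT", "AT"),    # non-parsimonious right-anchored deletion
        (19, "CACA", "CA"),   # dinucleotide-repeat contraction
        (18, "A", "ACA"),     # repeat expansion
        (16, "G", "C"),       # plain SNP: unchanged
    ],
)
def test_normalize_matches_enumeration_oracle(pos, ref, alt):
    """Left-aligned parsimonious form equals the exhaustive-enumeration result."""
    expected = leftmost_parsimonious(SEQ, pos, ref, alt)
    got = _normalize_one("1", pos, ref, alt, SEQ)
    assert got == expected
    # and the normalized variant is still equivalent to the input
    assert apply_variant(SEQ, *got) == apply_variant(SEQ, pos, ref, alt)


def test_normalize_matches_bcftools(tmp_path):
    """Cross-check left alignment against bcftools norm on the same records."""
    fasta = tmp_path / "ref.fa"
    fasta.write_text(f">1\n{SEQ}\n")
    records = [(12, "TT", "T"), (19, "CACA", "CA"), (13, "T", "TT"), (16, "G", "C")]
    vcf = tmp_path / "in.vcf"
    body = "\n".join(f"1\t{p}\t.\t{r}\t{a}\t.\t.\t." for p, r, a in records)
    vcf.write_text(textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##contig=<ID=1>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        """) + body + "\n")
    subprocess.run(["samtools", "faidx", str(fasta)], check=True)
    out = subprocess.run(
        ["bcftools", "norm", "-f", str(fasta), str(vcf)],
        check=True, capture_output=True, text=True,
    ).stdout
    expected = []
    for line in out.splitlines():
        if line.startswith("#"):
            continue
        f = line.split("\t")
        expected.append(("1", int(f[1]), f[3], f[4]))
    frame = pd.DataFrame(
        [("1", p, r, a) for p, r, a in records],
        columns=["chrom", "pos", "ref", "alt"],
    )
    normalized, rejected = pgx.normalize_variants(frame, {"1": SEQ})
    assert rejected.empty
    got = sorted(zip(normalized.chrom, normalized.pos, normalized.ref, normalized.alt))
    assert got == sorted(expected)


def test_normalize_dedups_and_rejects_ref_mismatch():
    frame = pd.DataFrame(
        [
            ("1", 16, "G", "C"),
            ("1", 16, "G", "C"),          # exact duplicate
            ("1", 16, "T", "C"),          # REF disagrees with the reference
            ("1", 10, "A", "G,T"),        # multiallelic: split
        ],
        columns=["chrom", "pos", "ref", "alt"],
    )
    normalized, rejected = pgx.normalize_variants(frame, {"1": SEQ})
    assert list(rejected["reason"]) == ["REF mismatch with reference"]
    keys = set(zip(normalized.pos, normalized.ref, normalized.alt))
    assert keys == {(16, "G", "C"), (10, "A", "G"), (10, "A", "T")}
    assert normalized["id"].is_unique


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def test_mask_thresholds_are_strict(matrix_factory):
    dosage = [[1.0, 1.0, 1.0, 1.0]]
    dp = np.array([[9.0, 10.0, 30.0, np.nan]])
    gq = np.array([[30.0, 20.0, 19.0, 50.0]])
    cm = matrix_factory(dosage, dp=30.0, gq=60.0)
    cm.dp, cm.gq = dp, gq
    out = pgx.mask_low_quality_calls(cm, pgx.QcConfig())
    # DP 9 masked; DP 10 & GQ 20 boundary retained; GQ 19 masked; absent DP masked
    assert np.isnan(out.dosage[0, 0])
    assert out.dosage[0, 1] == 1.0
    assert np.isnan(out.dosage[0, 2])
    assert np.isnan(out.dosage[0, 3])


def test_mask_fraction_matches_full_scan(matrix_factory):
    rng = np.random.default_rng(11)
    n, m = 40, 60
    cm = matrix_factory(rng.integers(0, 3, size=(n, m)).astype(float))
    cm.dp = rng.uniform(0, 40, size=(n, m))
    cm.gq = rng.uniform(0, 80, size=(n, m))
    cfg = pgx.QcConfig()
    out = pgx.mask_low_quality_calls(cm, cfg)
    expected = sum(
        1
        for i in range(n)
        for j in range(m)
        if cm.dp[i, j] < cfg.dp_min or cm.gq[i, j] < cfg.gq_min
    )
    assert int(np.isnan(out.dosage).sum()) == expected
    # retained dosages are untouched
    kept = ~np.isnan(out.dosage)
    assert np.array_equal(out.dosage[kept], cm.dosage[kept])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def test_hwe_examples():
    assert pgx.hwe_exact_p(17, 0, 0) == 1.0            # monomorphic
    assert pgx.hwe_exact_p(0, 100, 0) < 1e-6           # all-het excess
    assert pgx.hwe_exact_p(25, 50, 25) == 1.0          # observed het is modal
    with pytest.raises(ValueError):
        pgx.hwe_exact_p(-1, 0, 1)


def test_hwe_agrees_with_enumeration_oracle():
    """Exact agreement (1e-12) with rational-arithmetic enumeration, n <= 50."""
    for n in range(1, 51):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                c = n - a - b
                got = pgx.hwe_exact_p(a, b, c)
                want = hwe_exact_oracle(a, b, c)
                assert got == pytest.approx(want, abs=1e-12), (a, b, c)


# ---------------------------------------------------------------------------
# variant / sample filters
# ---------------------------------------------------------------------------

def test_variant_filters_missingness_hwe_maf(matrix_factory):
    n = 459
    rng = np.random.default_rng(5)
    base = rng.binomial(2, 0.4, size=(n, 4)).astype(float)
    base[:, 1] = 1.0                    # all-het variant: extreme HWE failure
    base[:51, 2] = np.nan               # 51/459 = 11.1% missing
    base[:, 3] = 0.0                    # monomorphic
    cm = matrix_factory(base)
    out, report = pgx.filter_variants(cm, pgx.QcConfig(), profile="basic")
    reasons = dict(zip(report["id"], report["reason"]))
    ids = list(cm.variants["id"])
    assert reasons[ids[1]] == "hwe"
    assert reasons[ids[2]] == "missingness"
    assert ids[3] in list(out.variants["id"])  # monomorphic passes basic profile
    # each removed variant accounted for exactly once
    assert not report["id"].duplicated().any()
    out_pca, report_pca = pgx.filter_variants(cm, pgx.QcConfig(), profile="pca")
    assert dict(zip(report_pca["id"], report_pca["reason"]))[ids[3]] == "maf"


def test_sample_filters_missingness_and_heterozygosity(matrix_factory):
    rng = np.random.default_rng(9)
    n, m = 200, 400
    dosage = rng.binomial(2, 0.3, size=(n, m)).astype(float)
    dosage[0, : int(0.15 * m)] = np.nan  # 15% missing
    dosage[1, :] = 1.0                   # heterozygous everywhere
    cm = matrix_factory(dosage)
    out, report = pgx.filter_samples(cm, pgx.QcConfig())
    removed = dict(zip(report["sample"], report["reason"]))
    assert removed[cm.samples[0]] == "missingness"
    assert removed[cm.samples[1]] == "heterozygosity"
    assert cm.samples[0] not in out.samples and cm.samples[1] not in out.samples


def test_sample_filter_skips_het_rule_below_three_samples(matrix_factory):
    cm = matrix_factory([[1.0, 0.0], [1.0, 2.0]])
    with pytest.warns(UserWarning):
        out, report = pgx.filter_samples(cm, pgx.QcConfig())
    assert out.n_samples == 2 and report.empty


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def test_king_phi_identical_vectors_is_half():
    g = np.array([0, 1, 2, 1, 0, 1, 2, 2, 1])
    pair = pgx.king_phi(g, g)
    assert pair.phi == 0.5
    assert pair.n_opposite_hom == 0


def test_king_phi_symmetric_and_unevaluable():
    gi = np.array([0, 0, 0, 0])
    gj = np.array([2, 2, 2, 2])
    assert np.isnan(pgx.king_phi(gi, gj).phi)  # zero denominator
    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, 50).astype(float)
    b = rng.integers(0, 3, 50).astype(float)
    assert pgx.king_phi(a, b).phi == pgx.king_phi(b, a).phi


def test_king_phi_unrelated_near_zero_at_50k_sites():
    rng = np.random.default_rng(12)
    m = 50_000
    p = rng.uniform(0.05, 0.5, m)
    a = rng.binomial(1, p) + rng.binomial(1, p)
    b = rng.binomial(1, p) + rng.binomial(1, p)
    assert abs(pgx.king_phi(a, b).phi) < 0.02


def test_kinship_table_matches_pairwise_calls(matrix_factory):
    rng = np.random.default_rng(8)
    dosage = rng.integers(0, 3, size=(6, 200)).astype(float)
    dosage[rng.random(dosage.shape) < 0.05] = np.nan
    cm = matrix_factory(dosage)
    table = pgx.kinship_table(cm)
    for rec in table.itertuples(index=False):
        i = cm.samples.index(rec.sample_i)
        j = cm.samples.index(rec.sample_j)
        direct = pgx.king_phi(cm.dosage[i], cm.dosage[j])
        if np.isnan(direct.phi):
            assert np.isnan(rec.phi)
        else:
            assert rec.phi == pytest.approx(direct.phi, abs=1e-12)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_ld_prune_removes_one_of_duplicated_column(matrix_factory):
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.3, size=(100, 10)).astype(float)
    g[:, 5] = g[:, 4]  # perfect LD pair
    cm = matrix_factory(g)
    kept = pgx.ld_prune(cm, pgx.QcConfig())
    assert (4 in kept) != (5 in kept)


def test_ld_prune_is_idempotent_and_keeps_independent_variants(matrix_factory):
    rng = np.random.default_rng(21)
    n, m = 800, 120
    p = rng.uniform(0.1, 0.5, m)
    g = rng.binomial(2, p, size=(n, m)).astype(float)
    cm = matrix_factory(g)
    cfg = pgx.QcConfig()
    kept = pgx.ld_prune(cm, cfg)
    assert len(kept) >= 0.99 * m  # independent variants: <1% false removals
    pruned = cm.subset_variants(kept)
    assert pgx.ld_prune(pruned, cfg) == list(range(len(kept)))


# ---------------------------------------------------------------------------
# PCA + outliers
# ---------------------------------------------------------------------------

def test_pca_separates_two_subpopulations(matrix_factory):
    rng = np.random.default_rng(4)
    m, div = 1000, 0.3
    p1 = rng.uniform(0.2, 0.8, m)
    p2 = np.clip(p1 + rng.uniform(-div, div, m), 0.02, 0.98)
    g1 = rng.binomial(2, p1, size=(60, m)).astype(float)
    g2 = rng.binomial(2, p2, size=(60, m)).astype(float)
    cm = matrix_factory(np.vstack([g1, g2]))
    proj = pgx.pca_project(cm, 4)
    pc1_a, pc1_b = proj.coords[:60, 0], proj.coords[60:, 0]
    assert max(pc1_a.min(), pc1_b.min()) > min(pc1_a.max(), pc1_b.max()) or \
        max(pc1_b.min(), pc1_a.min()) > min(pc1_b.max(), pc1_a.max())
    assert np.all(np.diff(proj.eigenvalues) <= 1e-9)
    assert proj.variance_fraction.sum() <= 1.0 + 1e-9


def test_pca_duplicate_samples_get_identical_coordinates(matrix_factory):
    rng = np.random.default_rng(6)
    g = rng.binomial(2, 0.4, size=(30, 200)).astype(float)
    g[7] = g[3]
    proj = pgx.pca_project(matrix_factory(g), 3)
    assert np.allclose(proj.coords[3], proj.coords[7], atol=1e-9)


def test_outlier_rule_edge_cases(matrix_factory):
    rng = np.random.default_rng(10)
    g = rng.binomial(2, 0.4, size=(80, 300)).astype(float)
    proj = pgx.pca_project(matrix_factory(g), 2)
    assert pgx.flag_pca_outliers(proj, pgx.OutlierRule(z_max=float("inf"))) == []
    assert pgx.flag_pca_outliers(proj) == []  # homogeneous cohort, default rule


# ---------------------------------------------------------------------------
# Fisher sanity vs the same oracle (cross-module consistency)
# ---------------------------------------------------------------------------

def test_fisher_spot_checks_against_oracle():
    for table in [(10, 10, 10, 10), (0, 20, 20, 0), (3, 7, 12, 2), (0, 0, 5, 9)]:
        _, p = pgx.fisher_exact_2x2(*table)
        assert p == pytest.approx(fisher_exact_oracle(*table), abs=1e-12)
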