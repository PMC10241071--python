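"""Synthetic founder-cohort generator.

Emulates the statistical structure of a homogeneous founder population so
that every downstream stage — QC, star-allele calling, phenotyping,
enrichment screening and VIP triage — can be exercised and validated
without access-restricted human data. The generator emits a multi-sample
VCF (v4.2), a gene copy-number sidecar, truth tables (true diplotypes,
planted relative pairs, planted admixed outliers) and an annotated VIP
variant table with planted category labels.

Defaults follow the founder-cohort study conditions this package targets:
459 diploid samples, star-allele frequencies from the bundled definition
table (e.g. CYP3A5*3 at 0.94, CYP2C9*3 at 0.42, CYP2D6*5 whole-gene
deletion at 0.24), ~30x depth, and a modest inbreeding coefficient.
Genotype classes follow inbreeding-adjusted Hardy-Weinberg proportions:
P(hom i) = p_i^2 + F p_i (1 - p_i), P(het i,j) = 2 p_i p_j (1 - F).
"""

from __future__ import annotations

import copy as _copy
import hashlib
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import variant_id
from .star import AlleleDefinitionSet, default_definitions
from .triage import PREDICTION_COLUMNS, TOOL_DELETERIOUS_CODES, TriageThresholds

#: PharmGKB-style Very Important Pharmacogene panel (67 genes; the
#: mitochondrial VIP is excluded as the simulator is autosomal/diploid).
VIP_GENES = (
    "ABCB1", "ABCG2", "ACE", "ADH1A", "ADH1B", "ADRB1", "ADRB2", "AHR",
    "ALDH1A1", "ALOX5", "BRCA1", "CACNA1S", "CBR3", "CFTR", "COMT", "CRHR1",
    "CYP1A1", "CYP1A2", "CYP1B1", "CYP2A6", "CYP2B6", "CYP2C19", "CYP2C8",
    "CYP2C9", "CYP2D6", "CYP2E1", "CYP2J2", "CYP3A4", "CYP3A5", "CYP4F2",
    "DBH", "DPYD", "DRD2", "EGFR", "ERCC1", "F2", "F5", "G6PD", "GSTP1",
    "GSTT1", "HLA-A", "HLA-B", "HMGCR", "KCNH2", "KCNJ11", "MTHFR", "NAT2",
    "NQO1", "NR1I2", "NUDT15", "P2RY1", "P2RY12", "PTGIS", "PTGS2",
    "RUNDC3B", "RYR1", "SCN5A", "SLC19A1", "SLC22A1", "SLCO1B1", "SULT1A1",
    "TPMT", "TYMS", "UGT1A1", "VDR", "VKORC1", "XDH",
)

_BENIGN_CODES = {
    "sift": "T", "polyphen2": "B", "lrt": "N", "mutationtaster": "P",
    "mutationassessor": "L", "fathmm": "T", "metasvm": "T", "metalr": "T",
}


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------

@dataclass
class RelativePairSpec:
    kind: str  # "duplicate" | "parent_offspring"
    count: int

    def __post_init__(self) -> None:
        if self.kind not in ("duplicate", "parent_offspring"):
            raise ValueError(f"unknown relative-pair kind {self.kind!r}")
        if self.count < 0:
            raise ValueError("pair count must be non-negative")


@dataclass
class VipSpec:
    """Planted VIP annotation-table composition.

    Default counts mirror the scale of a founder-cohort VIP screen: 14
    known-enriched, 55 deleterious-enriched, 31 novel and 900 benign rows.
    AF ranges must be consistent with the triage filter definitions; an
    unsatisfiable range is rejected up front.
    """

    n_known: int = 14
    n_deleterious: int = 55
    n_novel: int = 31
    n_benign: int = 900
    known_cohort_af: tuple[float, float] = (0.12, 0.30)
    known_ref_af: tuple[float, float] = (0.0, 0.05)
    deleterious_cohort_af: tuple[float, float] = (0.05, 0.20)
    deleterious_ref_af: tuple[float, float] = (0.001, 0.02)
    novel_cohort_af: tuple[float, float] = (0.002, 0.08)

    def validate(self, thresholds: TriageThresholds | None = None) -> None:
        t = thresholds or TriageThresholds()
        for n in (self.n_known, self.n_deleterious, self.n_novel, self.n_benign):
            if n < 0:
                raise ValueError("category counts must be non-negative")
        if self.known_cohort_af[0] <= t.known_cohort_af:
            raise ValueError(
                "known-enriched cohort AF range must exceed the "
                f"known-branch threshold {t.known_cohort_af}"
            )
        if self.known_ref_af[1] >= t.panel_rare_af:
            raise ValueError("known-enriched reference AFs must stay below "
                             f"the rare cap {t.panel_rare_af}")
        if self.deleterious_cohort_af[0] <= t.common_af:
            raise ValueError("deleterious-enriched cohort AF range must exceed "
                             f"the common-variant floor {t.common_af}")
        if self.deleterious_ref_af[1] >= t.panel_rare_af:
            raise ValueError("deleterious-enriched reference AFs must stay "
                             f"below the rare cap {t.panel_rare_af}")
        if self.deleterious_cohort_af[0] <= t.fold * self.deleterious_ref_af[1]:
            raise ValueError("deleterious-enriched ranges do not guarantee "
                             f">{t.fold}-fold enrichment")
        if self.novel_cohort_af[0] <= 0:
            raise ValueError("novel variants must be present in the cohort")

    @property
    def total(self) -> int:
        return self.n_known + self.n_deleterious + self.n_novel + self.n_benign


@dataclass
class SimulationSpec:
    """Everything the generator needs, with founder-cohort defaults."""

    n_samples: int = 459
    gene_frequencies: dict[str, dict[str, float]] = field(default_factory=dict)
    inbreeding: float = 0.05
    depth_mean: float = 30.0
    depth_shape: float = 20.0  # negative-binomial dispersion (larger = tighter)
    gq_intercept: float = 5.0
    gq_slope: float = 3.0
    gq_sd: float = 6.0
    relative_pairs: tuple[RelativePairSpec, ...] = ()
    n_admixed: int = 0
    admixture_fraction: float = 0.5
    admixture_divergence: float = 0.5
    n_background_snps: int = 1000
    background_maf_range: tuple[float, float] = (0.05, 0.5)
    vip: VipSpec = field(default_factory=VipSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gene_frequencies:
            self.gene_frequencies = default_definitions().frequency_map()
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0 <= self.inbreeding <= 1:
            raise ValueError("inbreeding coefficient F must lie in [0, 1]")
        if self.n_admixed < 0 or self.n_background_snps < 0:
            raise ValueError("counts must be non-negative")
        for gene, freqs in self.gene_frequencies.items():
            if "*1" not in freqs:
                raise ValueError(f"{gene}: frequency map missing the reference allele *1")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{gene}: allele frequencies sum to {total}, not 1")
            if any(not 0 <= f <= 1 for f in freqs.values()):
                raise ValueError(f"{gene}: frequencies must lie in [0, 1]")
        self.vip.validate()


# ---------------------------------------------------------------------------
# truth container
# ---------------------------------------------------------------------------

@dataclass
class BackgroundGenotypes:
    chrom: str
    positions: np.ndarray     # (m,)
    afs: np.ndarray           # founder-population AFs
    haplotypes: np.ndarray    # (n_samples, m, 2) uint8


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the simulator."""

    samples: list[str]
    genes: list[str]
    allele_names: dict[str, list[str]]
    star_haplotypes: dict[str, np.ndarray]  # gene -> (n, 2) allele indices
    copy_number: dict[tuple[str, str], int]
    background: BackgroundGenotypes
    planted_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    outlier_samples: list[str] = field(default_factory=list)

    def diplotype(self, sample: str, gene: str) -> tuple[str, str]:
        i = self.samples.index(sample)
        names = self.allele_names[gene]
        h = self.star_haplotypes[gene][i]
        return tuple(sorted((names[h[0]], names[h[1]])))

    def diplotype_frame(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            names = self.allele_names[gene]
            haps = self.star_haplotypes[gene]
            for i, s in enumerate(self.samples):
                a, b = sorted((names[haps[i, 0]], names[haps[i, 1]]))
                rows.append((s, gene, a, b, self.copy_number[(s, gene)]))
        return pd.DataFrame(
            rows, columns=["sample", "gene", "allele1", "allele2", "copy_number"]
        )

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        dip = os.path.join(out_dir, "truth_diplotypes.tsv")
        self.diplotype_frame().to_csv(dip, sep="\t", index=False)
        paths["diplotypes"] = dip
        pairs = os.path.join(out_dir, "truth_pairs.tsv")
        pd.DataFrame(
            self.planted_pairs, columns=["sample_i", "sample_j", "kind"]
        ).to_csv(pairs, sep="\t", index=False)
        paths["pairs"] = pairs
        outl = os.path.join(out_dir, "truth_outliers.tsv")
        pd.DataFrame({"sample": self.outlier_samples}).to_csv(
            outl, sep="\t", index=False
        )
        paths["outliers"] = outl
        return paths


# ---------------------------------------------------------------------------
# diplotype simulation
# ---------------------------------------------------------------------------

def _draw_haplotypes(
    rng: np.random.Generator, probs: np.ndarray, n: int, inbreeding: float
) -> np.ndarray:
    """Two haplotypes per sample with inbreeding-adjusted HW proportions.

    With probability F the second haplotype is identical by descent to the
    first, which yields exactly P(hom i) = p_i^2 + F p_i (1-p_i) and
    P(het i,j) = 2 p_i p_j (1-F).
    """
    k = len(probs)
    h1 = rng.choice(k, size=n, p=probs)
    h2 = rng.choice(k, size=n, p=probs)
    ibd = rng.random(n) < inbreeding
    h2[ibd] = h1[ibd]
    return np.stack([h1, h2], axis=1).astype(np.int64)


def simulate_diplotypes(
    spec: SimulationSpec, definitions: AlleleDefinitionSet | None = None
) -> SyntheticTruth:
    """Draw the full cohort truth: star diplotypes, copy numbers, background
    SNP haplotypes, and (optionally) admixed structure outliers."""
    spec.validate()
    definitions = definitions or default_definitions()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_samples + spec.n_admixed
    samples = [f"S{i:04d}" for i in range(1, n_total + 1)]
    outliers = samples[spec.n_samples:]

    genes = sorted(spec.gene_frequencies)
    allele_names: dict[str, list[str]] = {}
    star_haps: dict[str, np.ndarray] = {}
    copy_number: dict[tuple[str, str], int] = {}
    for gene in genes:
        freqs = spec.gene_frequencies[gene]
        names = sorted(freqs)
        probs = np.array([freqs[a] for a in names], dtype=float)
        probs = probs / probs.sum()
        haps = _draw_haplotypes(rng, probs, n_total, spec.inbreeding)
        allele_names[gene] = names
        star_haps[gene] = haps
        deletion_idx = {
            j for j, a in enumerate(names)
            if gene in definitions.genes
            and any(d.name == a and d.is_deletion for d in definitions.for_gene(gene))
        }
        for i, s in enumerate(samples):
            n_del = sum(1 for h in haps[i] if h in deletion_idx)
            copy_number[(s, gene)] = 2 - n_del

    # background autosomal SNPs (for kinship, PCA, HWE exercises)
    m = spec.n_background_snps
    lo, hi = spec.background_maf_range
    afs = rng.uniform(lo, hi, size=m)
    h = np.empty((n_total, m, 2), dtype=np.uint8)
    p = afs[None, :]
    h1 = (rng.random((n_total, m)) < p).astype(np.uint8)
    h2 = (rng.random((n_total, m)) < p).astype(np.uint8)
    ibd = rng.random((n_total, m)) < spec.inbreeding
    h2[ibd] = h1[ibd]
    h[:, :, 0], h[:, :, 1] = h1, h2
    if spec.n_admixed:
        q = np.clip(
            afs + rng.uniform(-spec.admixture_divergence,
                              spec.admixture_divergence, size=m),
            0.01, 0.99,
        )
        for i in range(spec.n_samples, n_total):
            for hap in (0, 1):
                src2 = rng.random(m) < spec.admixture_fraction
                draw_q = (rng.random(m) < q).astype(np.uint8)
                h[i, :, hap] = np.where(src2, draw_q, h[i, :, hap])
    background = BackgroundGenotypes(
        chrom="20",
        positions=1_000_000 + 1_500 * np.arange(m, dtype=np.int64),
        afs=afs,
        haplotypes=h,
    )
    return SyntheticTruth(
        samples=samples,
        genes=genes,
        allele_names=allele_names,
        star_haplotypes=star_haps,
        copy_number=copy_number,
        background=background,
        outlier_samples=list(outliers),
    )


def plant_relatives(
    truth: SyntheticTruth,
    pairs: Sequence[RelativePairSpec],
    spec: SimulationSpec,
    seed: int | None = None,
) -> SyntheticTruth:
    """Overwrite selected samples to create duplicate / parent-offspring pairs.

    Duplicates become genotype-identical to their source (DP/GQ noise is
    redrawn independently at VCF emission); a parent-offspring target
    inherits one parental haplotype per independent locus (per gene, and per
    background SNP) with the other haplotype drawn fresh from the population.
    """
    total = sum(p.count for p in pairs)
    if total == 0:
        return truth
    n_founder = len(truth.samples) - len(truth.outlier_samples)
    if 2 * total > n_founder:
        raise ValueError(
            f"{total} pairs need {2 * total} samples; only {n_founder} available"
        )
    rng = np.random.default_rng(spec.seed + 101 if seed is None else seed)
    out = _copy.deepcopy(truth)
    eligible = [s for s in out.samples if s not in out.outlier_samples]
    chosen = rng.choice(len(eligible), size=2 * total, replace=False)
    chosen_samples = [eligible[int(i)] for i in chosen]
    cursor = 0
    for pspec in pairs:
        for _ in range(pspec.count):
            src, dst = chosen_samples[cursor], chosen_samples[cursor + 1]
            cursor += 2
            i = out.samples.index(src)
            j = out.samples.index(dst)
            if pspec.kind == "duplicate":
                for gene in out.genes:
                    out.star_haplotypes[gene][j] = out.star_haplotypes[gene][i]
                    out.copy_number[(dst, gene)] = out.copy_number[(src, gene)]
                out.background.haplotypes[j] = out.background.haplotypes[i]
            else:  # parent_offspring
                for gene in out.genes:
                    freqs = spec.gene_frequencies[gene]
                    names = out.allele_names[gene]
                    probs = np.array([freqs[a] for a in names], dtype=float)
                    probs = probs / probs.sum()
                    inherited = out.star_haplotypes[gene][i, rng.integers(2)]
                    fresh = rng.choice(len(names), p=probs)
                    out.star_haplotypes[gene][j] = (inherited, fresh)
                    definitions = default_definitions()
                    deletion = {
                        k for k, a in enumerate(names)
                        if gene in definitions.genes
                        and any(d.name == a and d.is_deletion
                                for d in definitions.for_gene(gene))
                    }
                    n_del = sum(1 for hh in out.star_haplotypes[gene][j] if hh in deletion)
                    out.copy_number[(dst, gene)] = 2 - n_del
                m = out.background.haplotypes.shape[1]
                pick = rng.integers(2, size=m)
                inherited_bg = out.background.haplotypes[i, np.arange(m), pick]
                fresh_bg = (rng.random(m) < out.background.afs).astype(np.uint8)
                out.background.haplotypes[j, :, 0] = inherited_bg
                out.background.haplotypes[j, :, 1] = fresh_bg
            out.planted_pairs.append((src, dst, pspec.kind))
    return out


# ---------------------------------------------------------------------------
# VCF + sidecar emission
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def emit_cohort_vcf(
    truth: SyntheticTruth,
    spec: SimulationSpec,
    out_dir: str,
    definitions: AlleleDefinitionSet | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write the multi-sample VCF, the copy-number sidecar and truth TSVs.

    Genotype dosage at every defining site is the sum over the sample's two
    haplotypes of that variant's haplotype dosage; haplotypes carrying a
    whole-gene deletion contribute nothing (the deletion itself lives in the
    sidecar, keeping the VCF a plain biallelic SNP/indel file). DP is drawn
    negative-binomially around the depth model mean and GQ as a clipped
    linear function of DP plus noise. Same truth + seed => identical bytes.
    """
    definitions = definitions or default_definitions()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 7 if seed is None else seed)
    n = len(truth.samples)

    # validate: every non-reference allele in truth must be defined
    for gene in truth.genes:
        if gene not in definitions.genes:
            raise ValueError(f"gene {gene} in truth has no definitions")
        defined = {a.name for a in definitions.for_gene(gene)}
        for name in truth.allele_names[gene]:
            if name not in defined:
                raise ValueError(f"{gene} allele {name} lacks a definition")

    rows = []  # (chrom, pos, ref, alt, gene, dosage vector)
    for gene in truth.genes:
        defs = {a.name: a for a in definitions.for_gene(gene)}
        names = truth.allele_names[gene]
        haps = truth.star_haplotypes[gene]
        keys = sorted(definitions.defining_variant_keys(gene))
        for key in keys:
            carrier = np.array(
                [1 if key in defs[a].variants else 0 for a in names], dtype=np.int8
            )
            dosage = carrier[haps[:, 0]] + carrier[haps[:, 1]]
            rows.append((*key, gene, dosage))
    bg = truth.background
    bg_dosage = bg.haplotypes.sum(axis=2)
    for j in range(len(bg.positions)):
        rows.append(
            (bg.chrom, int(bg.positions[j]), "A", "G", "", bg_dosage[:, j])
        )
    rows.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1], r[2], r[3]))

    seen = set()
    for r in rows:
        k = r[:4]
        if k in seen:
            raise ValueError(f"duplicate variant in emission: {k}")
        seen.add(k)

    p_nb = spec.depth_shape / (spec.depth_shape + spec.depth_mean)
    dp = rng.negative_binomial(spec.depth_shape, p_nb, size=(len(rows), n))
    gq = np.clip(
        np.rint(spec.gq_intercept + spec.gq_slope * dp
                + rng.normal(0.0, spec.gq_sd, size=dp.shape)),
        0, 99,
    ).astype(int)

    contigs = []
    for chrom in sorted({r[0] for r in rows}, key=_chrom_sort_key):
        contigs.append(chrom)
    vcf_path = os.path.join(out_dir, "cohort.vcf")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgxcohort-simulator\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description='
                 '"Pharmacogene owning this defining variant">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description='
                 '"Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(truth.samples) + "\n")
        for r_idx, (chrom, pos, ref, alt, gene, dosage) in enumerate(rows):
            info = f"GENE={gene}" if gene else "."
            vid = variant_id(chrom, pos, ref, alt)
            cells = [
                f"{gt_map[int(dosage[i])]}:{dp[r_idx, i]}:{gq[r_idx, i]}"
                for i in range(n)
            ]
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DP:GQ\t"
                + "\t".join(cells) + "\n"
            )

    cn_path = os.path.join(out_dir, "copy_number.tsv")
    with open(cn_path, "w") as fh:
        fh.write("sample\tgene\tcopy_number\n")
        for s in truth.samples:
            for gene in truth.genes:
                fh.write(f"{s}\t{gene}\t{truth.copy_number[(s, gene)]}\n")

    paths = {"vcf": vcf_path, "copy_number": cn_path}
    paths.update(truth.write(out_dir))
    return paths


def load_copy_number_sidecar(path: str) -> dict[tuple[str, str], int]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r.sample, r.gene): int(r.copy_number) for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# VIP annotation table
# ---------------------------------------------------------------------------

def _deleterious_predictions(rng: np.random.Generator, n_votes: int) -> dict[str, str]:
    tools = list(TOOL_DELETERIOUS_CODES)
    codes = dict(_BENIGN_CODES)
    for tool in rng.choice(tools, size=n_votes, replace=False):
        codes[tool] = sorted(TOOL_DELETERIOUS_CODES[tool])[0]
    return codes


def simulate_vip_table(
    vip: VipSpec,
    seed: int = 0,
    thresholds: TriageThresholds | None = None,
    genes: Sequence[str] = VIP_GENES,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build an annotated VIP variant table with planted category truth.

    Returns ``(table, truth_labels)`` where labels are drawn from
    {known_enriched, deleterious_enriched, novel, benign}. Planted rows are
    constructed to satisfy (or robustly fail) the triage cascade filters,
    so that triage truth-recovery is exact by design.
    """
    t = thresholds or TriageThresholds()
    vip.validate(t)
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    pos_counter = 5_000_000

    def base_row(gene: str) -> dict:
        nonlocal pos_counter
        pos_counter += 997
        refalt = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        return {
            "chrom": "15",
            "pos": pos_counter,
            "ref": refalt[0],
            "alt": refalt[1],
            "gene": gene,
            "exonic_function": "nonsynonymous SNV",
            "clinvar": False,
            "hgmd": False,
            "annotation": "",
            "cadd": float(rng.uniform(0, 15)),
            "in_dbsnp": True,
            **_BENIGN_CODES,
        }

    def uniform(rng_range):
        return float(rng.uniform(*rng_range))

    for _ in range(vip.n_known):
        r = base_row(str(rng.choice(genes)))
        which = rng.random()
        r["clinvar"] = which < 0.7
        r["hgmd"] = not r["clinvar"] or rng.random() < 0.3
        r["annotation"] = "pathogenic/drug-response"
        r["cohort_af"] = uniform(vip.known_cohort_af)
        r["af_gnomad_all"] = uniform(vip.known_ref_af)
        r["af_1kgp"] = uniform(vip.known_ref_af)
        r["af_ukb"] = uniform(vip.known_ref_af)
        rows.append(r)
        labels.append("known_enriched")

    for _ in range(vip.n_deleterious):
        r = base_row(str(rng.choice(genes)))
        if rng.random() < 0.5:
            r.update(_deleterious_predictions(rng, int(rng.integers(2, 5))))
        else:
            r["cadd"] = float(rng.uniform(20.5, 40))
        gnom = uniform(vip.deleterious_ref_af)
        r["cohort_af"] = max(uniform(vip.deleterious_cohort_af), t.fold * gnom * 1.05)
        r["af_gnomad_all"] = gnom
        r["af_1kgp"] = gnom * float(rng.uniform(0.5, 1.5))
        r["af_ukb"] = gnom * float(rng.uniform(0.5, 1.5))
        rows.append(r)
        labels.append("deleterious_enriched")

    for _ in range(vip.n_novel):
        r = base_row(str(rng.choice(genes)))
        if rng.random() < 0.5:
            r.update(_deleterious_predictions(rng, int(rng.integers(2, 5))))
        else:
            r["cadd"] = float(rng.uniform(20.5, 40))
        if rng.random() < 0.1:
            r["exonic_function"] = "stopgain"
        r["cohort_af"] = uniform(vip.novel_cohort_af)
        r["af_gnomad_all"] = np.nan
        r["af_1kgp"] = np.nan
        r["af_ukb"] = np.nan
        r["in_dbsnp"] = False
        rows.append(r)
        labels.append("novel")

    for _ in range(vip.n_benign):
        r = base_row(str(rng.choice(genes)))
        sub = rng.random()
        if sub < 0.6:
            # no deleterious evidence at all (votes <= 1, CADD < 20)
            if rng.random() < 0.3:
                r.update(_deleterious_predictions(rng, 1))
            r["cohort_af"] = float(rng.uniform(0.0, 0.4))
            g = float(rng.uniform(0.0, 0.4))
            r["af_gnomad_all"] = g
            r["af_1kgp"] = g * float(rng.uniform(0.5, 1.5))
            r["af_ukb"] = g * float(rng.uniform(0.5, 1.5))
        elif sub < 0.85:
            # deleterious but common in every panel (fails the rare caps)
            if rng.random() < 0.5:
                r.update(_deleterious_predictions(rng, int(rng.integers(2, 5))))
            else:
                r["cadd"] = float(rng.uniform(20.5, 40))
            g = float(rng.uniform(0.10, 0.5))
            r["af_gnomad_all"] = g
            r["af_1kgp"] = min(g * float(rng.uniform(0.8, 1.2)), 0.99)
            r["af_ukb"] = min(g * float(rng.uniform(0.8, 1.2)), 0.99)
            r["cohort_af"] = min(g * float(rng.uniform(0.8, 1.2)), 0.99)
        else:
            # known annotation but too rare in the cohort to be enriched
            r["clinvar"] = True
            r["annotation"] = "pathogenic"
            r["cohort_af"] = float(rng.uniform(0.0, 0.08))
            g = float(rng.uniform(0.0, 0.05))
            r["af_gnomad_all"] = g
            r["af_1kgp"] = g
            r["af_ukb"] = g
        rows.append(r)
        labels.append("benign")

    df = pd.DataFrame(rows)
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    truth = pd.Series(np.array(labels)[order], name="true_category")
    return df, truth


# ---------------------------------------------------------------------------
# synthetic high-evidence list and reference panel
# ---------------------------------------------------------------------------

def synthetic_high_evidence(
    definitions: AlleleDefinitionSet | None = None,
    n_snps: int = 118,
    n_haplotypes: int = 147,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic stand-in for a level-1A/1B clinical-annotation list.

    Entries that resolve inside the bundled definition table come first
    (defining SNPs and star alleles); the remainder are filler entries on
    genes outside the simulated panel, present so that the screen's
    unresolvable-entry path is exercised at realistic scale.
    """
    definitions = definitions or default_definitions()
    rng = np.random.default_rng(seed)
    rows = []
    rs = 1_000_000
    for gene in definitions.genes:
        for key in sorted(definitions.defining_variant_keys(gene)):
            if len(rows) >= n_snps:
                break
            rs += int(rng.integers(1, 5000))
            rows.append({
                "identifier": f"rs{rs}", "kind": "SNP",
                "level": "1A" if rng.random() < 0.6 else "1B", "gene": gene,
                "chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
                "allele": "",
            })
    while len(rows) < n_snps:
        rs += int(rng.integers(1, 5000))
        rows.append({
            "identifier": f"rs{rs}", "kind": "SNP",
            "level": "1B", "gene": "NAT2",
            "chrom": "8", "pos": 18_400_000 + len(rows), "ref": "G", "alt": "A",
            "allele": "",
        })
    n_hap = 0
    for gene in definitions.genes:
        for a in definitions.for_gene(gene):
            if a.name == "*1" or n_hap >= n_haplotypes:
                continue
            rows.append({
                "identifier": f"{gene}{a.name}", "kind": "haplotype",
                "level": "1A" if rng.random() < 0.5 else "1B", "gene": gene,
                "chrom": "", "pos": np.nan, "ref": "", "alt": "",
                "allele": a.name,
            })
            n_hap += 1
    filler = 0
    while n_hap < n_haplotypes:
        filler += 1
        rows.append({
            "identifier": f"NAT2*F{filler}", "kind": "haplotype",
            "level": "1B", "gene": "NAT2",
            "chrom": "", "pos": np.nan, "ref": "", "alt": "",
            "allele": f"*F{filler}",
        })
        n_hap += 1
    return pd.DataFrame(rows)


def synthetic_reference_af(
    evidence: pd.DataFrame,
    truth: SyntheticTruth,
    definitions: AlleleDefinitionSet | None = None,
    populations: Sequence[str] = ("gnomAD_All", "1KGP", "UKB"),
    population_n: Mapping[str, int] | None = None,
    divergence: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference-panel AFs for the evidence entries (synthetic stand-in).

    Each entry's reference AF is the founder-cohort truth frequency shrunk
    toward 0.5*divergence-perturbed global value, so entries enriched in the
    founder cohort exist by construction without being hard-coded.
    """
    definitions = definitions or default_definitions()
    rng = np.random.default_rng(seed)
    ns = dict(population_n or {"gnomAD_All": 70_000, "1KGP": 2_504, "UKB": 200_000})
    freq_map = definitions.frequency_map()
    rows = []
    for rec in evidence.itertuples(index=False):
        # truth frequency when resolvable, else a random global AF
        base = None
        if rec.kind == "haplotype" and rec.gene in freq_map:
            base = freq_map[rec.gene].get(rec.allele)
        elif rec.kind == "SNP" and rec.gene in freq_map:
            key = None
            if isinstance(rec.chrom, str) and rec.chrom and not pd.isna(rec.pos):
                key = (str(rec.chrom), int(rec.pos), str(rec.ref), str(rec.alt))
            if key is not None and rec.gene in definitions.genes:
                for a in definitions.for_gene(rec.gene):
                    if key in a.variants:
                        base = freq_map[rec.gene].get(a.name)
                        break
        if base is None:
            base = float(rng.uniform(0.01, 0.5))
        for pop in populations:
            shift = float(rng.uniform(-divergence, divergence))
            af = float(np.clip(base * (1 + shift) * 0.5, 0.0, 0.95))
            rows.append({
                "identifier": rec.identifier, "population": pop,
                "af": af, "n": ns.get(pop, np.nan),
            })
    return pd.DataFrame(rows)


def file_sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
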