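"""Cohort VCF quality control.

Implements the standard WGS-cohort QC chain for downstream pharmacogenomic
analysis, in a fixed, auditable order:

normalize -> mask low-quality calls -> variant filters (missingness, HWE)
-> sample filters (missingness, heterozygosity) -> and, for the population
structure profile: MAF filter + LD pruning -> kinship-based deduplication
-> PCA -> structure-outlier flagging.

Numerical cores (Hardy-Weinberg exact test, KING-robust kinship, sliding
window LD pruning, dosage PCA) are implemented here directly; each is small,
exactly specified, and covered by enumeration or simulation oracles in the
test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortMatrix, VARIANT_COLUMNS, variant_id


@dataclass
class QcConfig:
    """Thresholds for the QC chain.

    Defaults are the conventional WGS-cohort values: genotypes with DP < 10
    or GQ < 20 are masked; variants with > 10% missingness or an HWE exact
    p < 1e-6 are removed; samples with > 10% missingness or a heterozygosity
    rate more than 3 SD from the cohort mean are removed. The population
    structure profile additionally applies a 1% missingness cap, a 1% MAF
    floor and LD pruning with a 50-variant window, step 5 and r^2 > 0.2,
    and duplicates/monozygotic twins are removed at kinship phi > 0.354
    (midpoint between first-degree and duplicate expectation, 2^-1.5).
    """

    dp_min: float = 10.0
    gq_min: float = 20.0
    variant_missingness_max: float = 0.10
    sample_missingness_max: float = 0.10
    het_sd: float = 3.0
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    pca_variant_missingness_max: float = 0.01
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    kinship_cutoff: float = 0.354
    pca_components: int = 10
    outlier_z: float = 6.0

    def __post_init__(self) -> None:
        if not 0 <= self.variant_missingness_max <= 1:
            raise ValueError("variant_missingness_max must be in [0,1]")
        if not 0 <= self.sample_missingness_max <= 1:
            raise ValueError("sample_missingness_max must be in [0,1]")
        if not 0 < self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in (0,1]")
        if self.ld_window < 2 or self.ld_step < 1:
            raise ValueError("ld_window >= 2 and ld_step >= 1 required")


# ---------------------------------------------------------------------------
# variant normalization
# ---------------------------------------------------------------------------

def _normalize_one(
    chrom: str, pos: int, ref: str, alt: str, seq: str
) -> tuple[int, str, str]:
    """Left-align and make parsimonious one biallelic allele pair.

    ``seq`` is the full reference sequence of ``chrom`` (1-based positions).
    The classic normalization loop: truncate shared trailing bases (extending
    to the left from the reference when an allele would become empty), then
    truncate shared leading bases.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1) and pos > 1:
            prev = seq[pos - 2].upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variants(
    records: pd.DataFrame, reference: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize raw variant records against a reference sequence.

    Splits multiallelic records (comma-separated ALT) into biallelic rows,
    left-aligns and trims indels, removes exact duplicates and assigns stable
    ``chrom:pos:ref:alt`` ids. Records whose REF disagrees with the reference
    are rejected and reported, not silently dropped.

    Returns ``(normalized, rejected)`` data frames.
    """
    out_rows, rejected = [], []
    for rec in records.itertuples(index=False):
        chrom, pos, ref = str(rec.chrom), int(rec.pos), str(rec.ref)
        seq = reference.get(chrom)
        if seq is None or pos < 1 or pos + len(ref) - 1 > len(seq):
            rejected.append((chrom, pos, ref, str(rec.alt), "position outside reference"))
            continue
        if seq[pos - 1 : pos - 1 + len(ref)].upper() != ref.upper():
            rejected.append((chrom, pos, ref, str(rec.alt), "REF mismatch with reference"))
            continue
        for alt in str(rec.alt).split(","):
            npos, nref, nalt = _normalize_one(chrom, pos, ref, alt, seq)
            out_rows.append((chrom, npos, nref, nalt))
    normalized = pd.DataFrame(out_rows, columns=VARIANT_COLUMNS)
    normalized = normalized.drop_duplicates().reset_index(drop=True)
    normalized["id"] = [
        variant_id(c, p, r, a)
        for c, p, r, a in normalized.itertuples(index=False, name=None)
    ]
    report = pd.DataFrame(
        rejected, columns=VARIANT_COLUMNS + ["reason"]
    )
    return normalized, report


# ---------------------------------------------------------------------------
# genotype masking
# ---------------------------------------------------------------------------

def mask_low_quality_calls(cm: CohortMatrix, config: QcConfig) -> CohortMatrix:
    """Set genotypes with DP < dp_min or GQ < gq_min to missing.

    Absent DP/GQ values are treated as failing. Thresholds are strict: a call
    at exactly DP = dp_min and GQ = gq_min is retained.
    """
    out = cm.copy()
    with np.errstate(invalid="ignore"):
        bad = ~(out.dp >= config.dp_min) | ~(out.gq >= config.gq_min)
    out.dosage[bad] = np.nan
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg p-value conditional on the allele counts.

    Plain (not mid-) p: the summed conditional probability of every
    heterozygote count whose probability is <= that of the observed count
    (with a 1e-12 relative tie tolerance). Monomorphic sites return 1.0.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0
    if n <= 1000:
        # exact integer weights: ties are resolved exactly, so the p-value is
        # reproducible to full precision against enumeration oracles
        import math as _math

        n_a = 2 * n_hom_ref + n_het
        weights: dict[int, int] = {}
        for h in range(rare % 2, rare + 1, 2):
            hom_a = (n_a - h) // 2
            hom_b = n - h - hom_a
            if hom_a < 0 or hom_b < 0:
                continue
            weights[h] = (
                2**h * _math.comb(n, hom_a) * _math.comb(n - hom_a, h)
            )
        total = sum(weights.values())
        obs_w = weights[n_het]
        return float(min(sum(w for w in weights.values() if w <= obs_w) / total, 1.0))
    # Unnormalized conditional distribution over heterozygote counts of the
    # same parity as `rare`, built by the standard two-sided recurrence from
    # the mode outward.
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    hets = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(len(hets))
    idx = {h: i for i, h in enumerate(hets)}
    probs[idx[mid]] = 1.0
    # going down from the mode: P(h-2) = P(h) * h*(h-1) / (4*(r+1)*(c+1))
    h = mid
    while h >= 2:
        r = (rare - h) // 2          # rare-allele homozygotes at h
        c = n - h - r                # common-allele homozygotes at h
        probs[idx[h - 2]] = probs[idx[h]] * h * (h - 1) / (4.0 * (r + 1) * (c + 1))
        h -= 2
    # going up: P(h+2) = P(h) * 4*r*c / ((h+2)*(h+1))
    h = mid
    while h + 2 <= rare:
        r = (rare - h) // 2
        c = n - h - r
        probs[idx[h + 2]] = probs[idx[h]] * 4.0 * r * c / ((h + 2) * (h + 1))
        h += 2
    probs /= probs.sum()
    obs = probs[idx[n_het]]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# variant and sample filters
# ---------------------------------------------------------------------------

def filter_variants(
    cm: CohortMatrix, config: QcConfig, profile: str = "basic"
) -> tuple[CohortMatrix, pd.DataFrame]:
    """Remove variants failing missingness, HWE and (PCA profile) MAF.

    ``profile`` is ``"basic"`` (missingness > 10%, HWE p < 1e-6) or ``"pca"``
    (missingness > 1%, HWE, MAF < 1%). Each removed variant appears exactly
    once in the report with the first rule it failed, in the order
    missingness -> HWE -> MAF.
    """
    if profile not in ("basic", "pca"):
        raise ValueError(f"unknown profile {profile!r}")
    miss_max = (
        config.variant_missingness_max
        if profile == "basic"
        else config.pca_variant_missingness_max
    )
    miss = cm.variant_missingness()
    counts = cm.genotype_counts()
    reasons: list[tuple[str, str]] = []
    keep = np.ones(cm.n_variants, dtype=bool)
    for j in range(cm.n_variants):
        vid = cm.variants["id"].iloc[j]
        if miss[j] > miss_max:
            keep[j] = False
            reasons.append((vid, "missingness"))
            continue
        if hwe_exact_p(*counts[j]) < config.hwe_p_min:
            keep[j] = False
            reasons.append((vid, "hwe"))
            continue
        if profile == "pca":
            total = counts[j].sum()
            af = (counts[j, 1] + 2 * counts[j, 2]) / (2 * total) if total else 0.0
            if min(af, 1 - af) < config.maf_min:
                keep[j] = False
                reasons.append((vid, "maf"))
    report = pd.DataFrame(reasons, columns=["id", "reason"])
    out = cm.subset_variants(np.flatnonzero(keep))
    if out.n_variants == 0:
        raise ValueError("no variants remain after filtering")
    return out, report


def heterozygosity_rate(cm: CohortMatrix) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among non-missing calls."""
    het = np.nansum(cm.dosage == 1, axis=1).astype(float)
    nonmiss = np.sum(~np.isnan(cm.dosage), axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(nonmiss > 0, het / np.maximum(nonmiss, 1), np.nan)


def filter_samples(
    cm: CohortMatrix, config: QcConfig
) -> tuple[CohortMatrix, pd.DataFrame]:
    """Remove samples with excess missingness or extreme heterozygosity.

    Heterozygosity outliers are samples whose het rate lies outside
    mean +/- het_sd * SD across the cohort; the rule is skipped (with a
    warning) when fewer than 3 samples are available.
    """
    miss = cm.sample_missingness()
    reasons: list[tuple[str, str]] = []
    keep = np.ones(cm.n_samples, dtype=bool)
    for i, s in enumerate(cm.samples):
        if miss[i] > config.sample_missingness_max:
            keep[i] = False
            reasons.append((s, "missingness"))
    if keep.sum() >= 3:
        het = heterozygosity_rate(cm)
        ok = keep & ~np.isnan(het)
        mean, sd = het[ok].mean(), het[ok].std(ddof=1)
        if sd > 0:
            for i, s in enumerate(cm.samples):
                if keep[i] and ok[i] and abs(het[i] - mean) > config.het_sd * sd:
                    keep[i] = False
                    reasons.append((s, "heterozygosity"))
    else:
        warnings.warn("fewer than 3 samples: heterozygosity filter skipped")
    report = pd.DataFrame(reasons, columns=["sample", "reason"])
    out = cm.subset_samples([s for i, s in enumerate(cm.samples) if keep[i]])
    return out, report


# ---------------------------------------------------------------------------
# kinship (KING-robust between-family estimator)
# ---------------------------------------------------------------------------

@dataclass
class KinshipPair:
    sample_i: str
    sample_j: str
    phi: float  # nan when unevaluable
    n_both_het: int
    n_opposite_hom: int
    n_het_i: int
    n_het_j: int


def king_phi(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    sample_i: str = "i",
    sample_j: str = "j",
) -> KinshipPair:
    """KING-robust kinship for one pair of dosage vectors.

    phi = (N_het,het - 2 N_opposite-hom) / (N_het(i) + N_het(j)), computed
    over jointly non-missing sites. A zero denominator (no heterozygote in
    either sample) leaves the pair unevaluable (phi = nan).
    """
    gi = np.asarray(genotypes_i, dtype=float)
    gj = np.asarray(genotypes_j, dtype=float)
    both = ~np.isnan(gi) & ~np.isnan(gj)
    gi, gj = gi[both], gj[both]
    n_hh = int(np.sum((gi == 1) & (gj == 1)))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    n_het_i = int(np.sum(gi == 1))
    n_het_j = int(np.sum(gj == 1))
    denom = n_het_i + n_het_j
    phi = (n_hh - 2.0 * n_opp) / denom if denom > 0 else float("nan")
    return KinshipPair(sample_i, sample_j, phi, n_hh, n_opp, n_het_i, n_het_j)


def kinship_table(cm: CohortMatrix) -> pd.DataFrame:
    """All-pairs KING-robust kinship, vectorized over the cohort."""
    g = cm.dosage
    m = ~np.isnan(g)
    het = (g == 1) & m
    hom_ref = (g == 0) & m
    hom_alt = (g == 2) & m
    H = het.astype(np.float64)
    n_hh = H @ H.T
    n_opp = hom_ref.astype(np.float64) @ hom_alt.T.astype(np.float64)
    n_opp = n_opp + n_opp.T
    M = m.astype(np.float64)
    het_i = H @ M.T  # het in i over sites non-missing in both
    rows = []
    n = cm.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            denom = het_i[i, j] + het_i[j, i]
            phi = (n_hh[i, j] - 2.0 * n_opp[i, j]) / denom if denom > 0 else np.nan
            rows.append(
                (
                    cm.samples[i],
                    cm.samples[j],
                    phi,
                    int(n_hh[i, j]),
                    int(n_opp[i, j]),
                    int(het_i[i, j]),
                    int(het_i[j, i]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_i",
            "sample_j",
            "phi",
            "n_both_het",
            "n_opposite_hom",
            "n_het_i",
            "n_het_j",
        ],
    )


def kinship_filter(
    cm: CohortMatrix, config: QcConfig
) -> tuple[CohortMatrix, pd.DataFrame, list[str]]:
    """Flag pairs with phi > cutoff and drop one member of each.

    From each flagged pair the member with the higher missingness is removed
    (tie: the lexicographically later sample id). Returns the reduced cohort,
    the full kinship table (with a ``flagged`` column) and the removed ids.
    """
    table = kinship_table(cm)
    table["flagged"] = table["phi"] > config.kinship_cutoff
    miss = dict(zip(cm.samples, cm.sample_missingness()))
    removed: list[str] = []
    flagged = table[table["flagged"]].sort_values(["sample_i", "sample_j"])
    for rec in flagged.itertuples(index=False):
        i, j = rec.sample_i, rec.sample_j
        if i in removed or j in removed:
            continue
        if miss[i] > miss[j]:
            removed.append(i)
        elif miss[j] > miss[i]:
            removed.append(j)
        else:
            removed.append(max(i, j))
    out = cm.subset_samples([s for s in cm.samples if s not in removed])
    return out, table, removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _window_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared Pearson correlation of dosage columns."""
    ma = np.ma.masked_invalid(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = np.ma.corrcoef(ma, rowvar=False)
    r2 = np.asarray(r.filled(0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(cm: CohortMatrix, config: QcConfig) -> list[int]:
    """Greedy sliding-window LD pruning; returns retained variant indices.

    Windows of ``ld_window`` variants slide by ``ld_step`` over the retained
    list; within a window, for each pair with r^2 > ``ld_r2_max`` the
    lower-MAF member is removed (tie: the later position). Scanning repeats
    until no removal occurs, so the operation is idempotent on its output.
    """
    maf = cm.maf()
    pos = cm.variants["pos"].to_numpy()
    keep = np.ones(cm.n_variants, dtype=bool)
    changed = True
    while changed:
        changed = False
        kept = np.flatnonzero(keep)
        for start in range(0, max(len(kept), 1), config.ld_step):
            window = [k for k in kept[start : start + config.ld_window] if keep[k]]
            if len(window) < 2:
                continue
            r2 = _window_r2(cm.dosage[:, window])
            for a in range(len(window)):
                if not keep[window[a]]:
                    continue
                for b in range(a + 1, len(window)):
                    if not keep[window[b]]:
                        continue
                    if r2[a, b] > config.ld_r2_max:
                        va, vb = window[a], window[b]
                        if maf[va] < maf[vb]:
                            drop = va
                        elif maf[vb] < maf[va]:
                            drop = vb
                        else:
                            drop = va if pos[va] > pos[vb] else vb
                        keep[drop] = False
                        changed = True
                        if drop == va:
                            break
            if len(kept) <= config.ld_window:
                break
    return list(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# PCA and outlier flagging
# ---------------------------------------------------------------------------

@dataclass
class PcaProjection:
    samples: list[str]
    coords: np.ndarray        # (n_samples, k)
    eigenvalues: np.ndarray   # non-increasing
    variance_fraction: np.ndarray
    dropped_variants: list[int] = field(default_factory=list)


def pca_project(cm: CohortMatrix, k: int = 10) -> PcaProjection:
    """Dosage PCA with the standard allele-frequency scaling.

    Missing dosages are mean-imputed per variant; each variant is centred at
    2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)). Monomorphic variants are
    dropped with a warning. Component signs are fixed by making the
    largest-magnitude sample coordinate positive.
    """
    g = cm.dosage.copy()
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    dropped = list(np.flatnonzero(~poly))
    if dropped:
        warnings.warn(f"{len(dropped)} zero-variance variants dropped before PCA")
    g = g[:, poly]
    p = p[poly]
    x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    k = min(k, min(x.shape))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    coords = u[:, :k] * s[:k]
    for j in range(k):
        top = np.argmax(np.abs(coords[:, j]))
        if coords[top, j] < 0:
            coords[:, j] = -coords[:, j]
    return PcaProjection(
        list(cm.samples),
        coords,
        eigenvalues[:k],
        eigenvalues[:k] / total if total > 0 else np.zeros(k),
        dropped,
    )


@dataclass
class OutlierRule:
    """Robust-z rule on the leading principal components."""

    z_max: float = 6.0
    n_components: int = 2


def flag_pca_outliers(
    projection: PcaProjection, rule: OutlierRule | None = None
) -> list[str]:
    """Samples whose robust z (median/MAD) exceeds z_max on PC1 or PC2."""
    rule = rule or OutlierRule()
    if projection.coords.shape[1] < rule.n_components:
        raise ValueError("projection has fewer components than the rule requires")
    if not np.isfinite(rule.z_max):
        return []
    flagged: set[str] = set()
    for j in range(rule.n_components):
        x = projection.coords[:, j]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        scale = 1.4826 * mad if mad > 0 else np.std(x)
        if scale == 0:
            continue
        z = np.abs(x - med) / scale
        flagged.update(
            s for s, zi in zip(projection.samples, z) if zi > rule.z_max
        )
    return sorted(flagged)
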