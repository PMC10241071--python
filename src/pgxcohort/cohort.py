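"""Cohort genotype container and VCF ingestion.

The central in-memory object is :class:`CohortMatrix`: a samples x variants
matrix of biallelic genotype dosages (0/1/2, ``nan`` = missing) with the
per-call sequencing depth (DP) and genotype quality (GQ) needed for
genotype-level masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: (chrom, pos, ref, alt) with a 1-based position.
VariantKey = tuple[str, int, str, str]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class CohortMatrix:
    """Samples x biallelic variants with dosage, DP and GQ per call.

    ``dosage`` is float so that missing calls can be ``nan``; retained values
    are exactly 0, 1 or 2. ``dp``/``gq`` are ``nan`` where the caller emitted
    no value (treated as failing any quality threshold).
    """

    samples: list[str]
    variants: pd.DataFrame  # columns chrom, pos, ref, alt, id
    dosage: np.ndarray  # (n_samples, n_variants) float
    dp: np.ndarray
    gq: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.variants)
        for name in ("dosage", "dp", "gq"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {(n, m)}"
                )
        if "id" not in self.variants.columns:
            self.variants = self.variants.assign(
                id=[
                    variant_id(c, p, r, a)
                    for c, p, r, a in zip(
                        self.variants["chrom"],
                        self.variants["pos"],
                        self.variants["ref"],
                        self.variants["alt"],
                    )
                ]
            )
        if self.variants["id"].duplicated().any():
            dups = self.variants.loc[self.variants["id"].duplicated(), "id"]
            raise ValueError(f"duplicate variant keys: {list(dups)[:5]}")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[VariantKey]:
        v = self.variants
        return list(zip(v["chrom"], v["pos"].astype(int), v["ref"], v["alt"]))

    def copy(self) -> "CohortMatrix":
        return CohortMatrix(
            list(self.samples),
            self.variants.copy(),
            self.dosage.copy(),
            self.dp.copy(),
            self.gq.copy(),
            dict(self.meta),
        )

    # -- summaries --------------------------------------------------------
    def variant_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=1)

    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def genotype_counts(self) -> np.ndarray:
        """(n_variants, 3) counts of hom-ref, het, hom-alt (missing ignored)."""
        out = np.zeros((self.n_variants, 3), dtype=int)
        for g in (0, 1, 2):
            out[:, g] = np.nansum(self.dosage == g, axis=0)
        return out

    # -- subsetting (pure removal: retained values never change) ----------
    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "CohortMatrix":
        index = np.asarray(index)
        return CohortMatrix(
            list(self.samples),
            self.variants.iloc[index].reset_index(drop=True),
            self.dosage[:, index],
            self.dp[:, index],
            self.gq[:, index],
            dict(self.meta),
        )

    def subset_samples(self, keep: Iterable[str]) -> "CohortMatrix":
        keep = list(keep)
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([pos[s] for s in keep], dtype=int)
        return CohortMatrix(
            keep,
            self.variants.copy(),
            self.dosage[idx],
            self.dp[idx],
            self.gq[idx],
            dict(self.meta),
        )

    def dosages_at(self, sample: str, keys: Iterable[VariantKey]) -> dict[VariantKey, float]:
        """Per-call dosages for one sample at the requested variant keys."""
        row = self.dosage[self.samples.index(sample)]
        lookup = {k: j for j, k in enumerate(self.variant_keys())}
        out = {}
        for key in keys:
            if key in lookup:
                out[key] = row[lookup[key]]
        return out

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_vcf(cls, path: str) -> "CohortMatrix":
        """Load a multi-sample VCF (FORMAT GT, DP, GQ) via cyvcf2.

        Records must be biallelic; run :func:`pgxcohort.qc.normalize_variants`
        upstream if they are not.
        """
        from cyvcf2 import VCF

        vcf = VCF(path, gts012=True)
        samples = list(vcf.samples)
        rows, dosages, dps, gqs = [], [], [], []
        for v in vcf:
            if len(v.ALT) != 1:
                raise ValueError(
                    f"multiallelic record at {v.CHROM}:{v.POS}; normalize first"
                )
            rows.append((v.CHROM, int(v.POS), v.REF, v.ALT[0]))
            g = v.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
            g[g == 3] = np.nan
            dosages.append(g)
            dp = v.format("DP")
            gq = v.format("GQ")
            dps.append(
                np.full(len(samples), np.nan)
                if dp is None
                else np.where(dp[:, 0] < 0, np.nan, dp[:, 0]).astype(float)
            )
            gqs.append(
                np.full(len(samples), np.nan)
                if gq is None
                else np.where(gq[:, 0] < 0, np.nan, gq[:, 0]).astype(float)
            )
        variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
        return cls(
            samples,
            variants,
            np.array(dosages).T if dosages else np.empty((len(samples), 0)),
            np.array(dps).T if dps else np.empty((len(samples), 0)),
            np.array(gqs).T if gqs else np.empty((len(samples), 0)),
        )
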