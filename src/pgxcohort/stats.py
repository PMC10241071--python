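"""Allele-frequency statistics and the high-evidence variant screen.

Fisher's exact test is implemented here (two-sided, summing hypergeometric
point probabilities no larger than the observed one, with a 1e-12 relative
tie tolerance) so that its tie handling is exactly reproducible against an
enumeration oracle; Benjamini-Hochberg adjustment delegates to statsmodels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cohort import CohortMatrix
from .star import Diplotype, diplotypes_to_frame


def af_from_genotype_classes(
    hom_variant_fraction: float, het_fraction: float, decimals: int | None = None
) -> float:
    """Allele frequency from genotype-class prevalences: hom + het/2.

    This is the aggregation used to recover printed allele frequencies from
    published genotype prevalences (e.g. 2% hom + 14.2% het -> 0.091 -> 0.1).
    """
    if not (0 <= hom_variant_fraction <= 1 and 0 <= het_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if hom_variant_fraction + het_fraction > 1 + 1e-12:
        raise ValueError("genotype-class fractions sum to more than 1")
    af = hom_variant_fraction + het_fraction / 2.0
    return round(af, decimals) if decimals is not None else af


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    Returns (odds ratio, p). OR = ad/bc with infinity for a zero denominator
    (nan when 0/0). The p-value sums the hypergeometric probabilities of all
    tables with the observed margins whose point probability is <= the
    observed one, with a 1e-12 relative tie tolerance.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    row1, col1 = a + b, a + c
    row2 = c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    if n <= 10_000:
        # exact integer weights: tie handling is exact, matching enumeration
        # oracles to full precision on small tables
        import math as _math

        weights = [
            _math.comb(row1, x) * _math.comb(row2, col1 - x)
            for x in range(lo, hi + 1)
        ]
        total = sum(weights)
        w_obs = weights[a - lo]
        p = sum(w for w in weights if w <= w_obs) / total
        return odds, float(min(p, 1.0))
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return odds, min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# high-evidence variant screen
# ---------------------------------------------------------------------------

_RSID = re.compile(r"^rs\d+$")


def load_evidence_table(source) -> pd.DataFrame:
    """Load/validate a high-evidence variant list (level 1A/1B entries).

    Columns: identifier, kind (SNP|haplotype), level (1A|1B), gene, and the
    resolution columns chrom/pos/ref/alt (SNPs) or allele (haplotypes).
    Identifier form must match the kind (rsID for SNPs).
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(
        source, sep="\t", comment="#", dtype={"chrom": str})
    required = {"identifier", "kind", "level", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    if df["identifier"].duplicated().any():
        raise ValueError("evidence identifiers must be unique")
    bad_kind = ~df["kind"].isin(["SNP", "haplotype"])
    if bad_kind.any():
        raise ValueError(f"unknown kind values: {df.loc[bad_kind, 'kind'].unique()}")
    snp_bad = df[(df["kind"] == "SNP") & ~df["identifier"].str.match(_RSID)]
    hap_bad = df[(df["kind"] == "haplotype") & df["identifier"].str.match(_RSID)]
    if len(snp_bad) or len(hap_bad):
        raise ValueError("identifier form inconsistent with kind")
    if not df["level"].isin(["1A", "1B"]).all():
        raise ValueError("evidence level must be 1A or 1B")
    return df.reset_index(drop=True)


def evidence_partition(df: pd.DataFrame) -> dict[str, int]:
    return {
        "total": len(df),
        "snps": int((df["kind"] == "SNP").sum()),
        "haplotypes": int((df["kind"] == "haplotype").sum()),
    }


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    common_af: float = 0.10
    fold: float = 2.0
    ref_population: str = "gnomAD_All"
    default_ref_n: int = 70_000  # gnomAD-scale sample count when none declared


def screen_high_evidence(
    cm: CohortMatrix,
    diplotypes: Iterable[Diplotype] | pd.DataFrame,
    evidence: pd.DataFrame,
    reference_af: pd.DataFrame,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Screen high-evidence entries for presence and enrichment in the cohort.

    Cohort AFs come from genotypes (SNP entries) or star-allele calls
    (haplotype entries); each entry is compared with the declared reference
    population by Fisher's exact test on allele counts, BH-adjusted across
    the screened set. Entries that cannot be resolved to a variant or allele
    call are reported with ``screened = False``, never silently dropped.
    """
    config = config or ScreenConfig()
    frame = (
        diplotypes
        if isinstance(diplotypes, pd.DataFrame)
        else diplotypes_to_frame(diplotypes)
    )
    assigned = frame.dropna(subset=["allele1", "allele2"])
    key_index = {k: j for j, k in enumerate(cm.variant_keys())}
    ref = reference_af[reference_af["population"] == config.ref_population]
    ref_af = dict(zip(ref["identifier"], ref["af"]))
    ref_n = dict(zip(ref["identifier"], ref["n"]))

    rows = []
    for rec in evidence.itertuples(index=False):
        ident = rec.identifier
        cohort_alt = cohort_ref = None
        if rec.kind == "SNP":
            key = None
            if isinstance(rec.chrom, str) and not pd.isna(rec.pos):
                key = (str(rec.chrom), int(rec.pos), str(rec.ref), str(rec.alt))
            if key in key_index:
                col = cm.dosage[:, key_index[key]]
                nonmiss = int(np.sum(~np.isnan(col)))
                cohort_alt = int(np.nansum(col))
                cohort_ref = 2 * nonmiss - cohort_alt
        else:
            allele = getattr(rec, "allele", None)
            grp = assigned[assigned["gene"] == rec.gene]
            if allele and len(grp):
                n = len(grp)
                cohort_alt = int(
                    (grp["allele1"] == allele).sum() + (grp["allele2"] == allele).sum()
                )
                cohort_ref = 2 * n - cohort_alt
        if cohort_alt is None:
            rows.append((ident, rec.kind, rec.gene, np.nan, np.nan, np.nan,
                         np.nan, False, "unresolvable"))
            continue
        total = cohort_alt + cohort_ref
        af = cohort_alt / total if total else np.nan
        r_af = ref_af.get(ident, np.nan)
        if np.isnan(r_af):
            rows.append((ident, rec.kind, rec.gene, af, np.nan, np.nan,
                         np.nan, False, "no reference AF"))
            continue
        n_ref = ref_n.get(ident)
        n_ref = config.default_ref_n if (n_ref is None or pd.isna(n_ref)) else int(n_ref)
        ref_alt = int(round(r_af * 2 * n_ref))
        odds, p = fisher_exact_2x2(cohort_alt, cohort_ref,
                                   ref_alt, 2 * n_ref - ref_alt)
        rows.append((ident, rec.kind, rec.gene, af, float(r_af), odds, p,
                     True, ""))
    out = pd.DataFrame(
        rows,
        columns=["identifier", "kind", "gene", "cohort_af", "ref_af",
                 "odds_ratio", "p", "screened", "reason"],
    )
    out["p_adj"] = np.nan
    mask = out["screened"]
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["identified"] = mask & (out["cohort_af"] > 0)
    out["significant"] = mask & (out["p_adj"] < config.alpha)
    out["common"] = out["identified"] & (out["cohort_af"] > config.common_af)
    out["fold_enriched"] = out["identified"] & (
        out["cohort_af"] >= config.fold * out["ref_af"]
    )
    return out
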