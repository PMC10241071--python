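"""VIP-gene variant triage cascade.

Partitions annotated variants in Very Important Pharmacogenes into
mutually exclusive categories:

* ``excluded`` — star-allele-defining or high-evidence variants (handled by
  the other two analysis arms);
* ``known_enriched`` — ClinVar/HGMD-annotated variants enriched in the
  cohort (cohort AF > 10%, gnomAD_All and UKB AF < 6%, BH-adjusted Fisher
  p < 0.05 vs gnomAD_All);
* ``novel_actionable`` — in-silico deleterious variants absent from every
  reference panel (gnomAD, 1KGP, UKB) and every database (dbSNP, HGMD,
  ClinVar);
* ``deleterious_enriched`` — in-silico deleterious variants that are common
  (AF > 1%) and more than 2-fold enriched over a rare gnomAD_All AF (< 6%),
  or absent from all panels, with adjusted p < 0.05;
* ``not_retained`` — everything else, with a non-empty reasons trail.

In-silico deleteriousness is a vote over eight prediction tools (deleterious
codes: SIFT D; PolyPhen2 D/P; LRT D; MutationTaster D/A; MutationAssessor
H/M; FATHMM D; MetaSVM D; MetaLR D): at least two votes, or CADD phred > 20,
qualifies. All AF boundaries are strict as printed in the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_2x2

TOOL_DELETERIOUS_CODES: dict[str, frozenset[str]] = {
    "sift": frozenset({"D"}),
    "polyphen2": frozenset({"D", "P"}),
    "lrt": frozenset({"D"}),
    "mutationtaster": frozenset({"D", "A"}),
    "mutationassessor": frozenset({"H", "M"}),
    "fathmm": frozenset({"D"}),
    "metasvm": frozenset({"D"}),
    "metalr": frozenset({"D"}),
}

PREDICTION_COLUMNS = list(TOOL_DELETERIOUS_CODES)

REQUIRED_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "exonic_function",
    "clinvar", "hgmd", "cadd", "cohort_af",
    "af_gnomad_all", "af_1kgp", "af_ukb", "in_dbsnp",
] + PREDICTION_COLUMNS

CATEGORIES = (
    "known_enriched",
    "deleterious_enriched",
    "novel_actionable",
    "excluded",
    "not_retained",
)


@dataclass
class TriageThresholds:
    """Cascade thresholds; AF boundaries are strict comparisons."""

    known_cohort_af: float = 0.10     # known branch: cohort AF must exceed
    panel_rare_af: float = 0.06       # "rare" cap for gnomAD_All (and UKB, known branch)
    common_af: float = 0.01           # unknown branch: commonly-enriched floor
    fold: float = 2.0
    cadd_min: float = 20.0
    min_votes: int = 2
    alpha: float = 0.05
    cohort_n: int = 459               # diploid samples behind cohort_af
    ref_n: int = 70_000               # gnomAD_All-scale sample count


def is_insilico_deleterious(
    predictions: Mapping[str, str | None],
    cadd: float | None,
    thresholds: TriageThresholds | None = None,
) -> tuple[bool, int]:
    """Vote-based deleteriousness call; returns (verdict, vote count).

    Absent predictions contribute no vote; the verdict is true when at least
    ``min_votes`` tools vote deleterious or CADD phred exceeds ``cadd_min``
    (strictly).
    """
    t = thresholds or TriageThresholds()
    votes = 0
    for tool, codes in TOOL_DELETERIOUS_CODES.items():
        code = predictions.get(tool)
        if isinstance(code, str) and code in codes:
            votes += 1
    cadd_hit = cadd is not None and not pd.isna(cadd) and cadd > t.cadd_min
    return votes >= t.min_votes or cadd_hit, votes


def classify_known(clinvar: bool, hgmd: bool) -> bool:
    """Known pathogenic / drug-response: annotated in ClinVar OR HGMD."""
    return bool(clinvar) or bool(hgmd)


def _absent(af) -> bool:
    return pd.isna(af) or af == 0


def enrichment_flags(
    row: Mapping, adjusted_p: float, thresholds: TriageThresholds | None = None
) -> dict[str, bool]:
    """Evaluate the enrichment rules for one annotated variant.

    ``known_enriched``: cohort AF > 10%, gnomAD_All and UKB AF < 6%, adj p < 0.05.
    ``common_enriched``: cohort AF > 1% and (gnomAD_All-rare with > 2-fold
    enrichment, or absent from all panels), adj p < 0.05.
    ``absent_everywhere``: AF absent-or-zero in gnomAD_All, 1KGP and UKB.
    """
    t = thresholds or TriageThresholds()
    cohort = row["cohort_af"]
    gnomad = row["af_gnomad_all"]
    ukb = row["af_ukb"]
    absent_everywhere = (
        _absent(gnomad) and _absent(row["af_1kgp"]) and _absent(ukb)
    )
    sig = not pd.isna(adjusted_p) and adjusted_p < t.alpha
    known = (
        cohort > t.known_cohort_af
        and (_absent(gnomad) or gnomad < t.panel_rare_af)
        and (_absent(ukb) or ukb < t.panel_rare_af)
        and sig
    )
    fold_ok = (
        not _absent(gnomad)
        and cohort > t.fold * gnomad
        and gnomad < t.panel_rare_af
    )
    common = cohort > t.common_af and (fold_ok or absent_everywhere) and sig
    return {
        "known_enriched": bool(known),
        "common_enriched": bool(common),
        "absent_everywhere": bool(absent_everywhere),
    }


@dataclass
class TriageResult:
    frame: pd.DataFrame  # input + category, reasons, votes, p, p_adj
    counts: dict[str, int] = field(default_factory=dict)

    def per_gene_counts(self) -> pd.DataFrame:
        return (
            self.frame.groupby(["gene", "category"]).size().rename("n").reset_index()
        )


def run_triage(
    annotated: pd.DataFrame,
    star_variant_ids: set[str] | None = None,
    high_evidence_ids: set[str] | None = None,
    thresholds: TriageThresholds | None = None,
) -> TriageResult:
    """Run the full cascade over an annotated VIP variant table.

    Fisher p-values (cohort vs gnomAD_All allele counts) and the BH
    adjustment are computed over the entire input table — one family per
    run — before any flag is evaluated. Evaluation order per variant:
    exclusion, known branch, in-silico deleterious branch (novel before
    common-enrichment), else not retained with reasons.
    """
    t = thresholds or TriageThresholds()
    star_variant_ids = star_variant_ids or set()
    high_evidence_ids = high_evidence_ids or set()
    missing = [c for c in REQUIRED_COLUMNS if c not in annotated.columns]
    if missing:
        raise ValueError(f"annotation table missing required column(s): {missing}")
    df = annotated.copy().reset_index(drop=True)
    if df.empty:
        empty = df.assign(category=pd.Series(dtype=str),
                          reasons=pd.Series(dtype=str))
        return TriageResult(empty, {c: 0 for c in CATEGORIES})

    # Fisher + BH over the full family first
    ps = np.empty(len(df))
    for i, rec in enumerate(df.itertuples(index=False)):
        alt = int(round(float(rec.cohort_af) * 2 * t.cohort_n))
        gaf = 0.0 if _absent(rec.af_gnomad_all) else float(rec.af_gnomad_all)
        ref_alt = int(round(gaf * 2 * t.ref_n))
        _, ps[i] = fisher_exact_2x2(
            alt, 2 * t.cohort_n - alt, ref_alt, 2 * t.ref_n - ref_alt
        )
    p_adj = bh_adjust(ps)

    categories, reasons_col, votes_col = [], [], []
    for i, rec in enumerate(df.itertuples(index=False)):
        vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alt}"
        reasons: list[str] = []
        row = {
            "cohort_af": float(rec.cohort_af),
            "af_gnomad_all": rec.af_gnomad_all,
            "af_1kgp": rec.af_1kgp,
            "af_ukb": rec.af_ukb,
        }
        predictions = {tool: getattr(rec, tool) for tool in PREDICTION_COLUMNS}
        deleterious, votes = is_insilico_deleterious(predictions, rec.cadd, t)
        votes_col.append(votes)

        category = None
        if vid in star_variant_ids:
            category = "excluded"
            reasons.append("star-allele-defining variant")
        elif hasattr(rec, "identifier") and rec.identifier in high_evidence_ids:
            category = "excluded"
            reasons.append("high-evidence variant")
        elif vid in high_evidence_ids:
            category = "excluded"
            reasons.append("high-evidence variant")
        elif classify_known(rec.clinvar, rec.hgmd):
            flags = enrichment_flags(row, p_adj[i], t)
            if flags["known_enriched"]:
                category = "known_enriched"
            else:
                category = "not_retained"
                reasons.append("known annotation but not cohort-enriched "
                               "(known_enriched rule failed)")
        elif deleterious:
            flags = enrichment_flags(row, p_adj[i], t)
            if flags["absent_everywhere"] and not bool(rec.in_dbsnp):
                category = "novel_actionable"
            elif flags["common_enriched"]:
                category = "deleterious_enriched"
            else:
                category = "not_retained"
                reasons.append("deleterious but neither novel nor "
                               "commonly enriched")
        else:
            category = "not_retained"
            reasons.append(f"not deleterious ({votes} votes, CADD "
                           f"{'NA' if pd.isna(rec.cadd) else rec.cadd})")
        categories.append(category)
        reasons_col.append("; ".join(reasons))

    out = df.assign(category=categories, reasons=reasons_col,
                    votes=votes_col, p=ps, p_adj=p_adj)
    counts = {c: int((out["category"] == c).sum()) for c in CATEGORIES}
    return TriageResult(out, counts)
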