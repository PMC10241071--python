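"""Diplotype -> phenotype translation, activity scores and cohort summaries.

Metabolizer phenotypes (NM/IM/PM/RM/UM) follow CPIC-style rules: CYP2D6 uses
activity-score bins (sum of per-allele activity values), most enzymes use
generic function-pair rules, and drug target/transporter genes (VKORC1,
ABCG2, SLCO1B1, IFNL3, CYP4F2) use explicit diplotype -> function-label maps.
Any allele of unknown function makes the call Indeterminate. Actionability
is a flat per-gene-phenotype rule table; the bundled defaults flag every
pair with a non-default prescribing recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .star import AlleleDefinitionSet, Diplotype

INDETERMINATE = "Indeterminate"

#: Genes binned on the summed activity score.
SCORE_GENES = frozenset({"CYP2D6"})

#: Default activity-score bins: (lower, upper, phenotype], lower-exclusive.
DEFAULT_SCORE_BINS: tuple[tuple[float, float, str], ...] = (
    (-0.001, 0.0, "PM"),
    (0.0, 1.0, "IM"),
    (1.0, 2.25, "NM"),
    (2.25, float("inf"), "UM"),
)

_EFFECTIVE = {"Possible decreased": "Decreased"}

#: Generic function-pair rules (keys sorted alphabetically).
FUNCTION_PAIR_PHENOTYPE: dict[tuple[str, str], str] = {
    ("Normal", "Normal"): "NM",
    ("Decreased", "Normal"): "IM",
    ("No", "Normal"): "IM",
    ("Decreased", "Decreased"): "PM",
    ("Decreased", "No"): "PM",
    ("No", "No"): "PM",
    ("Increased", "Normal"): "RM",
    ("Increased", "Increased"): "UM",
    ("Decreased", "Increased"): "IM",
    ("Increased", "No"): "IM",
}


@dataclass
class PhenotypeCall:
    gene: str
    sample: str
    phenotype: str | None  # None when the diplotype was unresolved
    activity_score: float | None = None


def _load_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("pgxcohort.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


class PhenotypeMapper:
    """Maps (gene, allele pair) to a phenotype label.

    ``explicit`` rows (gene, allele1, allele2, phenotype) take precedence;
    score genes are binned on the activity score; everything else falls back
    to the generic function-pair rules.
    """

    def __init__(
        self,
        definitions: AlleleDefinitionSet,
        explicit: pd.DataFrame | None = None,
        score_bins: Mapping[str, Sequence[tuple[float, float, str]]] | None = None,
    ):
        self.definitions = definitions
        explicit = explicit if explicit is not None else _load_tsv("diplotype_phenotypes.tsv")
        self._explicit: dict[tuple[str, str, str], str] = {}
        for rec in explicit.itertuples(index=False):
            key = (rec.gene, *sorted((str(rec.allele1), str(rec.allele2))))
            self._explicit[key] = str(rec.phenotype)
        self._explicit_genes = {g for g, _, _ in self._explicit}
        self._score_bins = dict(score_bins or {})

    def bins_for(self, gene: str) -> Sequence[tuple[float, float, str]]:
        return self._score_bins.get(gene, DEFAULT_SCORE_BINS)

    def assign(self, gene: str, alleles: tuple[str, str]) -> tuple[str, float | None]:
        """Return (phenotype, activity score or None) for one diplotype."""
        if gene not in self.definitions.genes:
            raise KeyError(f"gene {gene!r} absent from the definition table")
        a, b = sorted(alleles)
        if gene in self._explicit_genes:
            try:
                return self._explicit[(gene, a, b)], None
            except KeyError:
                return INDETERMINATE, None
        da, db = self.definitions.get(gene, a), self.definitions.get(gene, b)
        if gene in SCORE_GENES:
            score = activity_score((a, b), self.definitions, gene)
            if score is None:
                return INDETERMINATE, None
            return score_to_phenotype(score, self.bins_for(gene)), score
        if "Unknown" in (da.function, db.function):
            return INDETERMINATE, None
        fa = _EFFECTIVE.get(da.function, da.function)
        fb = _EFFECTIVE.get(db.function, db.function)
        key = tuple(sorted((fa, fb)))
        try:
            return FUNCTION_PAIR_PHENOTYPE[key], None
        except KeyError:
            return INDETERMINATE, None


def activity_score(
    alleles: tuple[str, str], definitions: AlleleDefinitionSet, gene: str
) -> float | None:
    """Sum of the two per-allele activity values; None if either is unknown."""
    vals = [definitions.get(gene, a).activity for a in alleles]
    if any(v is None for v in vals):
        return None
    return float(sum(vals))


def score_to_phenotype(
    score: float, bins: Sequence[tuple[float, float, str]] = DEFAULT_SCORE_BINS
) -> str:
    """Bin an activity score: default 0 -> PM, (0,1] -> IM, (1,2.25] -> NM, >2.25 -> UM."""
    for lo, hi, label in bins:
        if lo < score <= hi:
            return label
    return INDETERMINATE


def assign_phenotype(
    gene: str,
    alleles: tuple[str, str],
    definitions: AlleleDefinitionSet,
    mapper: PhenotypeMapper | None = None,
    sample: str = "",
) -> PhenotypeCall:
    mapper = mapper or PhenotypeMapper(definitions)
    phenotype, score = mapper.assign(gene, alleles)
    return PhenotypeCall(gene, sample, phenotype, score)


def phenotype_cohort(
    calls: Iterable[Diplotype],
    definitions: AlleleDefinitionSet,
    mapper: PhenotypeMapper | None = None,
) -> pd.DataFrame:
    """Phenotype every resolved diplotype; unresolved calls get a null phenotype."""
    mapper = mapper or PhenotypeMapper(definitions)
    rows = []
    for d in calls:
        if d.alleles is None:
            rows.append((d.sample, d.gene, None, np.nan))
            continue
        phenotype, score = mapper.assign(d.gene, d.alleles)
        rows.append((d.sample, d.gene, phenotype,
                     np.nan if score is None else score))
    return pd.DataFrame(rows, columns=["sample", "gene", "phenotype", "activity_score"])


# ---------------------------------------------------------------------------
# actionability
# ---------------------------------------------------------------------------

def load_actionability(source=None) -> pd.DataFrame:
    """Rule table: gene, phenotype, actionable (0/1), tag."""
    df = (
        _load_tsv("actionability.tsv")
        if source is None
        else pd.read_csv(source, sep="\t", comment="#")
    )
    if df.duplicated(["gene", "phenotype"]).any():
        raise ValueError("actionability table has duplicate gene-phenotype rules")
    return df


def count_actionable(
    phenotypes: pd.DataFrame,
    rules: pd.DataFrame | None = None,
    cyp3a5_pm_actionable: bool = False,
) -> tuple[pd.Series, dict[str, float]]:
    """Actionable-genotype count per sample plus cohort >=1 / >=3 fractions.

    Indeterminate and unresolved phenotypes are never counted. The
    ``cyp3a5_pm_actionable`` switch flips the one rule (standard-dose CYP3A5
    poor metabolizers) on which guideline readings differ.
    """
    rules = rules if rules is not None else load_actionability()
    actionable = {
        (r.gene, r.phenotype)
        for r in rules.itertuples(index=False)
        if bool(int(r.actionable))
    }
    if cyp3a5_pm_actionable:
        actionable.add(("CYP3A5", "PM"))
    ok = phenotypes.dropna(subset=["phenotype"])
    ok = ok[ok["phenotype"] != INDETERMINATE]
    flags = [
        (rec.sample, (rec.gene, rec.phenotype) in actionable)
        for rec in ok.itertuples(index=False)
    ]
    per_sample = (
        pd.DataFrame(flags, columns=["sample", "hit"])
        .groupby("sample")["hit"]
        .sum()
        .astype(int)
    )
    # samples with no actionable phenotype at all still count in denominators
    all_samples = phenotypes["sample"].unique()
    per_sample = per_sample.reindex(all_samples, fill_value=0).sort_index()
    n = len(per_sample)
    summary = {
        "frac_ge1": float((per_sample >= 1).mean()) if n else 0.0,
        "frac_ge3": float((per_sample >= 3).mean()) if n else 0.0,
        "mean": float(per_sample.mean()) if n else 0.0,
    }
    return per_sample, summary


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(
    diplotypes: Iterable[Diplotype] | pd.DataFrame,
    phenotypes: pd.DataFrame,
    decimals: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Star-allele frequency and phenotype prevalence tables.

    Allele frequency = allele count over 2 x evaluable samples per gene,
    deletion alleles included as ordinary alleles. Phenotype prevalence is
    reported in percent over determinate calls (Indeterminate excluded from
    the denominator). ``decimals`` optionally rounds the frequency column to
    the display precision; full precision is retained otherwise.
    """
    if isinstance(diplotypes, pd.DataFrame):
        frame = diplotypes
    else:
        from .star import diplotypes_to_frame

        frame = diplotypes_to_frame(diplotypes)
    assigned = frame.dropna(subset=["allele1", "allele2"])
    af_rows = []
    for gene, grp in assigned.groupby("gene", sort=True):
        n = len(grp)
        if n == 0:
            continue
        counts = (
            pd.concat([grp["allele1"], grp["allele2"]])
            .value_counts()
            .sort_index()
        )
        for allele, c in counts.items():
            freq = c / (2.0 * n)
            af_rows.append(
                (gene, allele, int(c), 2 * n,
                 round(freq, decimals) if decimals is not None else freq)
            )
    af = pd.DataFrame(
        af_rows, columns=["gene", "allele", "count", "n_alleles", "frequency"]
    )
    determinate = phenotypes.dropna(subset=["phenotype"])
    determinate = determinate[determinate["phenotype"] != INDETERMINATE]
    prev_rows = []
    for gene, grp in determinate.groupby("gene", sort=True):
        n = len(grp)
        for phen, c in grp["phenotype"].value_counts().sort_index().items():
            prev_rows.append((gene, phen, int(c), n, 100.0 * c / n))
    prevalence = pd.DataFrame(
        prev_rows, columns=["gene", "phenotype", "count", "n", "prevalence_pct"]
    )
    return af, prevalence
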