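"""Star-allele diplotype calling and ensemble consensus.

A star allele is a named pharmacogene haplotype defined by a fixed set of
variants inherited together; ``*1`` denotes the reference haplotype and
whole-gene deletion alleles (e.g. CYP2D6 *5) are represented through a
per-sample copy-number sidecar rather than VCF records. Diplotypes are
called by exact combinatorial matching of unphased dosage sums against all
unordered pairs of defined haplotypes; every consistent alternative pair is
reported in an ambiguity set, never silently discarded.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortMatrix, VariantKey

FUNCTION_LABELS = {
    "Normal",
    "Decreased",
    "No",
    "Increased",
    "Unknown",
    "Possible decreased",
}

#: Genes called by a single tool in the ensemble (pass-through consensus).
SINGLE_CALLER_GENES = frozenset({"ABCG2", "RYR1", "CACNA1S"})


@dataclass(frozen=True)
class AlleleDefinition:
    """One star allele: its defining variants, function and activity value."""

    gene: str
    name: str
    variants: tuple[VariantKey, ...]  # haplotype carries dosage 1 at each
    function: str
    activity: float | None
    is_deletion: bool = False
    frequency: float | None = None

    def __post_init__(self) -> None:
        if self.function not in FUNCTION_LABELS:
            raise ValueError(
                f"{self.gene} {self.name}: unknown function label {self.function!r}"
            )
        if self.name == "*1" and (self.variants or self.is_deletion):
            raise ValueError("*1 must be the reference haplotype (no variants)")
        if self.is_deletion and self.variants:
            raise ValueError(
                f"{self.gene} {self.name}: deletion alleles carry no defining variants"
            )


class AlleleDefinitionSet:
    """Validated star-allele definitions for one or more genes."""

    def __init__(self, alleles: Iterable[AlleleDefinition]):
        self._by_gene: dict[str, list[AlleleDefinition]] = {}
        for a in alleles:
            self._by_gene.setdefault(a.gene, []).append(a)
        for gene, defs in self._by_gene.items():
            seen: dict[tuple, str] = {}
            for a in defs:
                key = (frozenset(a.variants), a.is_deletion)
                if key in seen:
                    raise ValueError(
                        f"{gene}: alleles {seen[key]} and {a.name} share an "
                        "identical defining-variant set (ambiguous definitions)"
                    )
                seen[key] = a.name

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def for_gene(self, gene: str) -> list[AlleleDefinition]:
        return list(self._by_gene[gene])

    def get(self, gene: str, name: str) -> AlleleDefinition:
        for a in self._by_gene[gene]:
            if a.name == name:
                return a
        raise KeyError(f"{gene} {name}")

    def defining_variant_keys(self, gene: str | None = None) -> set[VariantKey]:
        genes = [gene] if gene else self.genes
        keys: set[VariantKey] = set()
        for g in genes:
            for a in self._by_gene[g]:
                keys.update(a.variants)
        return keys

    def frequency_map(self) -> dict[str, dict[str, float]]:
        """gene -> allele -> bundled population frequency (simulator defaults)."""
        out: dict[str, dict[str, float]] = {}
        for g, defs in self._by_gene.items():
            out[g] = {a.name: float(a.frequency or 0.0) for a in defs}
        return out

    def __iter__(self):
        for defs in self._by_gene.values():
            yield from defs


def load_allele_definitions(source) -> AlleleDefinitionSet:
    """Load an allele-definition TSV (one row per defining variant).

    Columns: gene, allele, chrom, pos, ref, alt, function, activity,
    is_deletion, frequency. Reference and deletion alleles use a single row
    with empty variant columns.
    """
    df = pd.read_csv(
        source, sep="\t", comment="#", dtype={"chrom": str}, keep_default_na=True
    )
    required = {"gene", "allele", "chrom", "pos", "ref", "alt", "function",
                "activity", "is_deletion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele definition table missing columns: {sorted(missing)}")
    alleles = []
    for (gene, name), grp in df.groupby(["gene", "allele"], sort=True):
        variants = []
        for rec in grp.itertuples(index=False):
            if isinstance(rec.chrom, str) and rec.chrom and not pd.isna(rec.pos):
                variants.append((str(rec.chrom), int(rec.pos), str(rec.ref), str(rec.alt)))
        first = grp.iloc[0]
        activity = None if pd.isna(first["activity"]) else float(first["activity"])
        freq = None
        if "frequency" in grp.columns and not pd.isna(first["frequency"]):
            freq = float(first["frequency"])
        alleles.append(
            AlleleDefinition(
                gene=str(gene),
                name=str(name),
                variants=tuple(sorted(variants)),
                function=str(first["function"]),
                activity=activity,
                is_deletion=bool(int(first["is_deletion"])),
                frequency=freq,
            )
        )
    return AlleleDefinitionSet(alleles)


def default_definitions() -> AlleleDefinitionSet:
    """The bundled 19-gene definition table."""
    ref = resources.files("pgxcohort.data").joinpath("allele_definitions.tsv")
    with resources.as_file(ref) as path:
        return load_allele_definitions(path)


# ---------------------------------------------------------------------------
# diplotype matching
# ---------------------------------------------------------------------------

@dataclass
class Diplotype:
    """An unordered star-allele pair for one sample at one gene.

    ``alleles`` is None for unassigned/unresolved calls; every alternative
    pair consistent with the observed dosages appears in ``ambiguity``.
    """

    gene: str
    sample: str
    alleles: tuple[str, str] | None
    ambiguity: tuple[tuple[str, str], ...] = ()
    source: str = "pgxcohort"
    note: str = ""
    wildcard_sites: int = 0

    @property
    def is_assigned(self) -> bool:
        return self.alleles is not None

    def pair_key(self) -> tuple[str, str] | None:
        return tuple(sorted(self.alleles)) if self.alleles else None


def _pair_sort_key(pair: tuple[AlleleDefinition, AlleleDefinition]):
    a, b = pair
    n_var = len(a.variants) + len(b.variants)
    freq = (a.frequency or 0.0) * (b.frequency or 0.0)
    return (n_var, -freq, tuple(sorted((a.name, b.name))))


def match_diplotype(
    dosages: Mapping[VariantKey, float],
    copy_number: int,
    definitions: Sequence[AlleleDefinition],
    gene: str | None = None,
    sample: str = "",
) -> Diplotype:
    """Call the diplotype consistent with unphased dosages and copy number.

    Enumerates every unordered pair of defined haplotypes (copy number 2),
    haplotype + deletion (copy number 1) or deletion/deletion (copy number
    0) and keeps the pairs whose summed per-site dosages reproduce every
    non-missing observed dosage exactly. Missing dosages act as wildcards
    but are counted; a pair supported only by wildcards is reported with its
    alternatives as ambiguous. The reported pair is chosen by: fewest total
    defining variants, then highest product of bundled population
    frequencies, then lexicographic order.
    """
    definitions = list(definitions)
    if not definitions:
        raise ValueError("no allele definitions supplied")
    gene = gene or definitions[0].gene
    if copy_number not in (0, 1, 2):
        raise ValueError("copy number must be 0, 1 or 2")

    covered = set()
    for a in definitions:
        covered.update(a.variants)
    off = [
        k for k, d in dosages.items()
        if k not in covered and not (isinstance(d, float) and math.isnan(d)) and d > 0
    ]
    if off:
        return Diplotype(
            gene, sample, None,
            note=f"off-definition variant dosage at {sorted(off)[:3]}",
        )

    deletions = [a for a in definitions if a.is_deletion]
    normals = [a for a in definitions if not a.is_deletion]
    if copy_number < 2 and not deletions:
        return Diplotype(
            gene, sample, None,
            note=f"copy number {copy_number} but no deletion allele defined",
        )
    if copy_number == 2:
        candidates = list(itertools.combinations_with_replacement(
            sorted(normals, key=lambda a: a.name), 2))
    elif copy_number == 1:
        candidates = [(a, deletions[0]) for a in sorted(normals, key=lambda a: a.name)]
    else:
        candidates = [(deletions[0], deletions[0])]

    sites = list(dosages)
    consistent: list[tuple[AlleleDefinition, AlleleDefinition]] = []
    wildcards: dict[tuple[str, str], int] = {}
    for pair in candidates:
        expected = {k: 0 for k in sites}
        for hap in pair:
            for k in hap.variants:
                if k in expected:
                    expected[k] += 1
        ok, used_wild = True, 0
        for k in sites:
            obs = dosages[k]
            if isinstance(obs, float) and math.isnan(obs):
                if expected[k] > 0 or any(k in h.variants for h in (pair[0], pair[1])):
                    used_wild += 1
                continue
            if expected[k] != int(obs):
                ok = False
                break
        if ok:
            consistent.append(pair)
            wildcards[tuple(sorted((pair[0].name, pair[1].name)))] = used_wild
    if not consistent:
        return Diplotype(gene, sample, None, note="no consistent pair")

    consistent.sort(key=_pair_sort_key)
    best = consistent[0]
    best_names = tuple(sorted((best[0].name, best[1].name)))
    alternatives = tuple(
        tuple(sorted((a.name, b.name))) for a, b in consistent[1:]
    )
    n_wild = wildcards[best_names]
    note = ""
    n_def_sites = len(set(best[0].variants) | set(best[1].variants))
    if n_wild > 0 and n_def_sites > 0 and n_wild >= n_def_sites:
        note = "supported only by missing-call wildcards"
        if not alternatives:
            alternatives = ()
    return Diplotype(
        gene, sample, best_names, ambiguity=alternatives,
        note=note, wildcard_sites=n_wild,
    )


def call_diplotypes(
    cm: CohortMatrix,
    definitions: AlleleDefinitionSet,
    copy_numbers: Mapping[tuple[str, str], int] | None = None,
    source: str = "pgxcohort",
) -> list[Diplotype]:
    """Call diplotypes for every sample at every gene in the definition set."""
    copy_numbers = copy_numbers or {}
    key_index = {k: j for j, k in enumerate(cm.variant_keys())}
    calls = []
    for gene in definitions.genes:
        defs = definitions.for_gene(gene)
        keys = sorted(definitions.defining_variant_keys(gene))
        cols = [key_index[k] for k in keys if k in key_index]
        present = [k for k in keys if k in key_index]
        for i, sample in enumerate(cm.samples):
            dosages = {k: float(cm.dosage[i, j]) for k, j in zip(present, cols)}
            # defining sites absent from the (filtered) VCF: treated as dosage 0
            for k in keys:
                if k not in dosages:
                    dosages[k] = 0.0
            cn = copy_numbers.get((sample, gene), 2)
            d = match_diplotype(dosages, cn, defs, gene=gene, sample=sample)
            d.source = source
            calls.append(d)
    return calls


def diplotypes_to_frame(calls: Iterable[Diplotype]) -> pd.DataFrame:
    rows = []
    for d in calls:
        a1, a2 = (d.alleles if d.alleles else (None, None))
        rows.append(
            (
                d.sample, d.gene, a1, a2,
                ";".join("/".join(p) for p in d.ambiguity),
                d.source, d.note, d.wildcard_sites,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["sample", "gene", "allele1", "allele2",
                 "ambiguity", "source", "note", "wildcard_sites"],
    )


# ---------------------------------------------------------------------------
# ensemble consensus
# ---------------------------------------------------------------------------

def consensus_diplotype(
    calls: Sequence[Diplotype],
    min_agree: int = 2,
    single_caller_genes: frozenset[str] = SINGLE_CALLER_GENES,
) -> Diplotype:
    """Consensus across caller outputs for one sample/gene.

    A pair reported identically (unordered) by at least ``min_agree`` callers
    becomes the consensus; genes configured as single-caller pass the lone
    call through. Anything else is emitted unresolved for manual review.
    """
    if not calls:
        raise ValueError("at least one caller output required")
    gene = calls[0].gene
    sample = calls[0].sample
    if any(c.gene != gene or c.sample != sample for c in calls):
        raise ValueError("consensus inputs must share one sample and gene")
    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        key = c.pair_key()
        if key is not None:
            counts[key] = counts.get(key, 0) + 1
    if gene in single_caller_genes and len(calls) == 1:
        best = calls[0].pair_key()
        if best is None:
            return Diplotype(gene, sample, None, source="consensus",
                             note="single-caller gene, unassigned call")
        return Diplotype(gene, sample, best, source="consensus",
                         note="single-caller gene pass-through")
    winners = [k for k, v in counts.items() if v >= min_agree]
    if len(winners) == 1:
        return Diplotype(gene, sample, winners[0], source="consensus")
    note = (
        "no pair reached agreement"
        if not winners
        else "multiple pairs reached agreement"
    )
    detail = ", ".join(f"{'/'.join(k)}x{v}" for k, v in sorted(counts.items()))
    return Diplotype(
        gene, sample, None, source="consensus",
        note=f"unresolved for manual review: {note} ({detail})",
    )


def consensus_from_tables(
    tables: Sequence[pd.DataFrame], min_agree: int = 2,
    single_caller_genes: frozenset[str] = SINGLE_CALLER_GENES,
) -> list[Diplotype]:
    """Consensus over per-caller call tables (sample, gene, allele1, allele2, caller)."""
    merged = pd.concat(tables, ignore_index=True)
    out = []
    for (sample, gene), grp in merged.groupby(["sample", "gene"], sort=True):
        calls = []
        for rec in grp.itertuples(index=False):
            alleles = None
            if isinstance(rec.allele1, str) and isinstance(rec.allele2, str):
                alleles = tuple(sorted((rec.allele1, rec.allele2)))
            calls.append(
                Diplotype(gene, sample, alleles,
                          source=str(getattr(rec, "caller", "caller")))
            )
        out.append(consensus_diplotype(calls, min_agree, single_caller_genes))
    return out
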