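"""Star-allele definition loading, diplotype matching and ensemble consensus."""

import io
import math

import numpy as np
import pytest

import pgxcohort as pgx
from oracles import enumerate_diplotype_matches


def _defs_tuple(definitions, gene):
    return [
        (a.name, set(a.variants), a.is_deletion)
        for a in definitions.for_gene(gene)
    ]


# ---------------------------------------------------------------------------
# loader
# ---------------------------------------------------------------------------

def test_bundled_table_covers_nineteen_genes(definitions):
    assert len(definitions.genes) == 19
    for gene in ("CYP2D6", "CYP2C9", "CYP2C19", "CYP2B6", "CYP3A5", "CYP4F2",
                 "VKORC1", "NUDT15", "UGT1A1", "ABCG2", "SLCO1B1", "IFNL3",
                 "CFTR", "RYR1", "CACNA1S", "DPYD", "TPMT", "G6PD", "CYP2C8"):
        assert gene in definitions.genes
    star5 = definitions.get("CYP2D6", "*5")
    assert star5.is_deletion and star5.variants == ()


def test_loader_accepts_minimal_table_and_rejects_ambiguity():
    tsv = io.StringIO(
        "gene\tallele\tchrom\tpos\tref\talt\tfunction\tactivity\tis_deletion\tfrequency\n"
        "CYP2C9\t*1\t\t\t\t\tNormal\t1.0\t0\t0.5\n"
        "CYP2C9\t*3\t10\t94981296\tA\tC\tNo\t0.0\t0\t0.5\n"
    )
    defs = pgx.load_allele_definitions(tsv)
    assert {a.name for a in defs.for_gene("CYP2C9")} == {"*1", "*3"}
    dup = io.StringIO(
        "gene\tallele\tchrom\tpos\tref\talt\tfunction\tactivity\tis_deletion\tfrequency\n"
        "G\t*1\t\t\t\t\tNormal\t1.0\t0\t0.5\n"
        "G\t*2\t1\t100\tA\tG\tNo\t0.0\t0\t0.3\n"
        "G\t*3\t1\t100\tA\tG\tNo\t0.0\t0\t0.2\n"
    )
    with pytest.raises(ValueError, match="identical defining-variant set"):
        pgx.load_allele_definitions(dup)


def test_loader_rejects_unknown_function_label():
    tsv = io.StringIO(
        "gene\tallele\tchrom\tpos\tref\talt\tfunction\tactivity\tis_deletion\tfrequency\n"
        "G\t*1\t\t\t\t\tNormal\t1.0\t0\t1.0\n"
        "G\t*2\t1\t100\tA\tG\tBogus\t0.0\t0\t0.0\n"
    )
    with pytest.raises(ValueError, match="unknown function label"):
        pgx.load_allele_definitions(tsv)


# ---------------------------------------------------------------------------
# diplotype matching
# ---------------------------------------------------------------------------

def test_match_homozygous_and_reference_diplotypes(definitions):
    cyp2c9 = definitions.for_gene("CYP2C9")
    site = definitions.get("CYP2C9", "*3").variants[0]
    assert pgx.match_diplotype({site: 2.0}, 2, cyp2c9).alleles == ("*3", "*3")
    assert pgx.match_diplotype({site: 0.0}, 2, cyp2c9).alleles == ("*1", "*1")


def test_match_deletion_diplotypes(definitions):
    cyp2d6 = definitions.for_gene("CYP2D6")
    sites = sorted(definitions.defining_variant_keys("CYP2D6"))
    zeros = {k: 0.0 for k in sites}
    assert pgx.match_diplotype(zeros, 1, cyp2d6).alleles == ("*1", "*5")
    assert pgx.match_diplotype(zeros, 0, cyp2d6).alleles == ("*5", "*5")


def test_match_reports_ambiguity_with_alternatives(definitions):
    # CYP2B6 *6 = {v1, v2}, *9 = {v1}: dosage v1=2, v2=1 fits *6/*9 only;
    # dosage v1=1, v2=1 fits *1/*6 -- construct a genuinely ambiguous case by
    # adding an allele *X = {v2} so (v1=1, v2=1) fits both *1/*6 and *9/*X.
    base = [a for a in definitions.for_gene("CYP2B6")]
    v1, v2 = definitions.get("CYP2B6", "*6").variants
    extra = pgx.AlleleDefinition("CYP2B6", "*X", (v2,), "Unknown", None)
    defs = base + [extra]
    dosages = {v1: 1.0, v2: 1.0}
    result = pgx.match_diplotype(dosages, 2, defs)
    expected = enumerate_diplotype_matches(
        dosages, 2, [(a.name, set(a.variants), a.is_deletion) for a in defs]
    )
    assert len(expected) > 1
    got = sorted([result.alleles] + list(result.ambiguity))
    assert got == expected


@pytest.mark.parametrize("copy_number", [0, 1, 2])
def test_match_agrees_with_bruteforce_enumeration(definitions, copy_number):
    """Reported + ambiguity pairs equal exhaustive pair enumeration."""
    rng = np.random.default_rng(17)
    gene = "CYP2B6" if copy_number == 2 else "CYP2D6"
    defs = definitions.for_gene(gene)
    sites = sorted(definitions.defining_variant_keys(gene))
    for _ in range(50):
        dosages = {k: float(rng.integers(0, 3)) for k in sites}
        result = pgx.match_diplotype(dosages, copy_number, defs)
        expected = enumerate_diplotype_matches(
            dosages, copy_number, _defs_tuple(definitions, gene)
        )
        if result.alleles is None:
            assert expected == []
        else:
            assert sorted([result.alleles] + list(result.ambiguity)) == expected


def test_match_dosage_conservation(definitions):
    """The reported pair reproduces every observed non-missing dosage exactly."""
    rng = np.random.default_rng(23)
    for gene in ("CYP2B6", "SLCO1B1", "CYP4F2"):
        defs = definitions.for_gene(gene)
        sites = sorted(definitions.defining_variant_keys(gene))
        for _ in range(40):
            dosages = {k: float(rng.integers(0, 3)) for k in sites}
            result = pgx.match_diplotype(dosages, 2, defs)
            if result.alleles is None:
                continue
            a = next(d for d in defs if d.name == result.alleles[0])
            b = next(d for d in defs if d.name == result.alleles[1])
            for k, obs in dosages.items():
                if math.isnan(obs):
                    continue
                assert (k in a.variants) + (k in b.variants) == int(obs)


def test_match_missing_dosages_are_wildcards(definitions):
    cyp2c9 = definitions.for_gene("CYP2C9")
    site = definitions.get("CYP2C9", "*3").variants[0]
    result = pgx.match_diplotype({site: float("nan")}, 2, cyp2c9)
    # every pair is consistent; the call is flagged, not confidently *1/*1
    assert result.alleles is not None
    assert result.wildcard_sites >= 0
    assert result.ambiguity  # alternatives reported


def test_match_off_definition_dosage_is_unassigned(definitions):
    cyp2c9 = definitions.for_gene("CYP2C9")
    site = definitions.get("CYP2C9", "*3").variants[0]
    rogue = ("10", 123, "A", "T")
    result = pgx.match_diplotype({site: 0.0, rogue: 1.0}, 2, cyp2c9)
    assert result.alleles is None
    assert "off-definition" in result.note


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _call(gene, sample, pair, source="c"):
    return pgx.Diplotype(gene, sample, pair, source=source)


def test_consensus_two_tool_agreement():
    calls = [
        _call("CYP2C9", "S1", ("*1", "*3"), "a"),
        _call("CYP2C9", "S1", ("*1", "*3"), "b"),
        _call("CYP2C9", "S1", ("*1", "*1"), "c"),
    ]
    result = pgx.consensus_diplotype(calls)
    assert result.alleles == ("*1", "*3") and result.source == "consensus"


def test_consensus_no_agreement_is_unresolved_for_review():
    calls = [
        _call("CYP2C9", "S1", ("*1", "*2"), "a"),
        _call("CYP2C9", "S1", ("*1", "*3"), "b"),
        _call("CYP2C9", "S1", ("*2", "*3"), "c"),
    ]
    result = pgx.consensus_diplotype(calls)
    assert result.alleles is None and "manual review" in result.note


def test_consensus_single_caller_gene_passthrough():
    result = pgx.consensus_diplotype([_call("ABCG2", "S1", ("*1", "T"), "pypgx")])
    assert result.alleles == ("*1", "T")
    # a non-exempt gene with a single call stays unresolved
    result2 = pgx.consensus_diplotype([_call("CYP2C9", "S1", ("*1", "*3"), "a")])
    assert result2.alleles is None


def test_consensus_is_order_invariant_and_idempotent():
    calls = [
        _call("CYP2C9", "S1", ("*1", "*3"), "a"),
        _call("CYP2C9", "S1", ("*3", "*1"), "b"),
        _call("CYP2C9", "S1", ("*1", "*1"), "c"),
    ]
    forward = pgx.consensus_diplotype(calls)
    backward = pgx.consensus_diplotype(list(reversed(calls)))
    assert forward.alleles == backward.alleles == ("*1", "*3")
    again = pgx.consensus_diplotype([forward, forward])
    assert again.alleles == forward.alleles
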