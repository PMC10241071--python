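"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exact rational arithmetic and full
enumeration, sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Full enumeration of the conditional heterozygote-count distribution."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    weights: dict[int, Fraction] = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        if hom_a < 0 or hom_b < 0:
            continue
        w = Fraction(
            2**h * math.factorial(n),
            math.factorial(hom_a) * math.factorial(h) * math.factorial(hom_b),
        )
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration over margin-consistent tables."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    row2 = c + d
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    weights = {
        x: Fraction(math.comb(row1, x) * math.comb(row2, col1 - x))
        for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    obs = weights[a]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def bh_oracle(p_values):
    """Direct step-up computation of BH adjusted p-values."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Apply one variant (1-based pos) to a reference sequence."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def equivalent_shifts(seq: str, pos: int, ref: str, alt: str):
    """All variant representations equivalent to (pos, ref, alt) on ``seq``.

    Brute force over every position and allele pair (lengths <= 6, non-empty
    VCF-style alleles) whose application yields the same alternate sequence.
    The leftmost-aligned parsimonious representation is the equivalent with
    the smallest position among those of minimal total allele length.
    """
    target = apply_variant(seq, pos, ref, alt)
    found = []
    for p2 in range(1, len(seq) + 1):
        for lr in range(1, 7):
            if p2 - 1 + lr > len(seq):
                continue
            r2 = seq[p2 - 1 : p2 - 1 + lr]
            la = lr + len(target) - len(seq)
            if la < 1:
                continue
            alt2 = target[p2 - 1 : p2 - 1 + la]
            if apply_variant(seq, p2, r2, alt2) == target:
                found.append((p2, r2, alt2))
    return sorted(set(found))


def leftmost_parsimonious(seq: str, pos: int, ref: str, alt: str):
    """The expected normalized representation, by exhaustive enumeration."""
    equivalents = equivalent_shifts(seq, pos, ref, alt)
    min_total = min(len(r) + len(a) for _, r, a in equivalents)
    shortest = [e for e in equivalents if len(e[1]) + len(e[2]) == min_total]
    return min(shortest)


def enumerate_diplotype_matches(dosages, copy_number, definitions):
    """Brute-force pair enumeration for the star-allele matcher.

    ``definitions`` is a list of (name, variant set, is_deletion); returns
    all unordered name pairs whose summed dosage over observed non-missing
    sites matches exactly.
    """
    deletions = [d for d in definitions if d[2]]
    normals = [d for d in definitions if not d[2]]
    if copy_number == 2:
        pairs = list(itertools.combinations_with_replacement(normals, 2))
    elif copy_number == 1:
        pairs = [(n, deletions[0]) for n in normals] if deletions else []
    else:
        pairs = [(deletions[0], deletions[0])] if deletions else []
    matches = []
    for x, y in pairs:
        ok = True
        for key, obs in dosages.items():
            if obs != obs:  # nan -> wildcard
                continue
            expected = (key in x[1]) + (key in y[1])
            if expected != int(obs):
                ok = False
                break
        if ok:
            matches.append(tuple(sorted((x[0], y[0]))))
    return sorted(set(matches))
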