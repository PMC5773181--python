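"""Independent brute-force oracles used to check the optimised paths.

Everything here is deliberately naive: plain loops, full enumeration, no
shared code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from sympy.utilities.iterables import multiset_permutations

from chromoreg.genome import Gene, GenomeAnnotation


def make_annotation(layout: dict[str, list[tuple[str, str]]]) -> GenomeAnnotation:
    """Build an annotation from {chrom: [(gene_id, strand), ...]} with
    1 kb genes and 200 bp gaps, or from explicit (id, strand, start, end,
    feature_type) tuples."""
    chroms: dict[str, list[Gene]] = {}
    for chrom, entries in layout.items():
        genes = []
        pos = 1000
        for entry in entries:
            if len(entry) == 2:
                gid, strand = entry
                start, end, ftype = pos, pos + 1000, "gene"
                pos += 1200
            else:
                gid, strand, start, end, ftype = entry
            genes.append(
                Gene(id=gid, chromosome=chrom, start=start, end=end,
                     strand=strand, feature_type=ftype)
            )
        chroms[chrom] = genes
    return GenomeAnnotation(chromosomes=chroms)


# ---------------------------------------------------------------------------
# window / permutation oracles
# ---------------------------------------------------------------------------

def brute_force_windows(states: list[str], k: int) -> list[tuple[int, int, int]]:
    """(n_U, n_D, n_O) per window by direct counting."""
    out = []
    for i in range(len(states) - k + 1):
        w = states[i : i + k]
        out.append((w.count("U"), w.count("D"), w.count("O")))
    return out


def brute_force_fraction(states: list[str], k: int, m: int) -> float:
    wins = brute_force_windows(states, k)
    q = sum(
        1 for u, d, _ in wins if (u >= m and d == 0) or (d >= m and u == 0)
    )
    return q / len(wins)


def exact_permutation_p(
    states: list[str], k: int, m: int, observed: float, tie_rule: str
) -> float:
    """Exact tail probability over all distinct orderings of the state
    multiset (each equally likely under a uniform shuffle)."""
    total = 0
    exceed = 0
    for perm in multiset_permutations(states):
        total += 1
        frac = brute_force_fraction(perm, k, m)
        if tie_rule == "greater_or_equal":
            exceed += frac >= observed
        else:
            exceed += frac > observed
    return exceed / total


# ---------------------------------------------------------------------------
# Fisher oracle
# ---------------------------------------------------------------------------

def hypergeom_table_prob(a: int, b: int, c: int, d: int) -> float:
    """Null probability of a 2x2 table given its margins."""
    n = a + b + c + d
    return comb(a + b, a) * comb(c + d, c) / comb(n, a + c)


def brute_force_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of tables with the observed
    margins, probability-ordering rule."""
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_table_prob(a, b, c, d)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = hypergeom_table_prob(x, r1 - x, c1 - x, n - r1 - c1 + x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# motif oracle
# ---------------------------------------------------------------------------

def brute_force_motif_scan(
    sequence: str, pattern
) -> list[tuple[int, int, int | None]]:
    """All (start, end, spacer_length) matches on one strand of the given
    text: every start position, every spacer length, position-by-position
    set membership, no early structure sharing."""
    seq = sequence.upper()
    n = len(seq)
    hits = []
    if pattern.spacer is None:
        L = pattern.n_fixed
        for s in range(n - L + 1):
            ok = True
            for i, allowed in enumerate(pattern.positions):
                if seq[s + i] not in allowed:
                    ok = False
                    break
            if ok:
                hits.append((s, s + L, None))
        return hits
    idx, lo, hi = pattern.spacer
    left = pattern.positions[:idx]
    right = pattern.positions[idx:]
    for s in range(n):
        if s + len(left) > n:
            break
        ok = True
        for i, allowed in enumerate(left):
            if seq[s + i] not in allowed:
                ok = False
                break
        if not ok:
            continue
        for gap in range(lo, hi + 1):
            rs = s + len(left) + gap
            if rs + len(right) > n:
                break
            if any(seq[s + len(left) + j] not in "ACGT" for j in range(gap)):
                continue
            ok = True
            for i, allowed in enumerate(right):
                if seq[rs + i] not in allowed:
                    ok = False
                    break
            if ok:
                hits.append((s, rs + len(right), gap))
    return hits
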