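"""Independent brute-force oracles used by the test suite.

These are deliberately written in plain scalar Python, straight from the
textbook formulas, sharing no code with the package implementations.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) estimators
# ---------------------------------------------------------------------------


def wc_locus_components(pop_genotypes: list[list[int]]):
    """Per-locus a, b, c for one biallelic locus.

    ``pop_genotypes[i]`` is the list of genotype codes (0/1/2 = copies of
    the B allele) for population ``i``; missing calls are simply absent.
    Returns (a, b, c) computed for the B allele.
    """
    pops = [g for g in pop_genotypes if len(g) > 0]
    r = len(pops)
    if r < 2:
        raise ValueError("need >= 2 populations with data")
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]

    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni**2 for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2
        - 1.0 / (n_bar - 1) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def wc_theta(loci: list[list[list[int]]]) -> float:
    """Multilocus theta, ratio of sums over loci."""
    num = den = 0.0
    for pop_genotypes in loci:
        a, b, c = wc_locus_components(pop_genotypes)
        num += a
        den += a + b + c
    return num / den


def wc_f_multi(loci: list[list[list[int]]]) -> float:
    """Multilocus within-population f from the multi-population components."""
    c_sum = bc_sum = 0.0
    for pop_genotypes in loci:
        _, b, c = wc_locus_components(pop_genotypes)
        c_sum += c
        bc_sum += b + c
    return 1.0 - c_sum / bc_sum


def wc_f_single(loci: list[list[int]]) -> float:
    """Multilocus f for a single population (r = 1 reduction)."""
    c_sum = bc_sum = 0.0
    for g in loci:
        n = len(g)
        if n < 2:
            continue
        p = sum(g) / (2 * n)
        h = sum(1 for x in g if x == 1) / n
        b = (n / (n - 1)) * (p * (1 - p) - h * (2 * n - 1) / (4 * n))
        c = h / 2.0
        c_sum += c
        bc_sum += b + c
    return 1.0 - c_sum / bc_sum


# ---------------------------------------------------------------------------
# DUST-style low-complexity scoring
# ---------------------------------------------------------------------------


def dust_intervals(seq: str, window: int = 64, threshold: float = 20.0):
    """Brute-force DUST windows: recount triplets for every window start."""
    seq = seq.upper()
    n = len(seq)
    w_tri = min(window - 2, max(n - 2, 0))
    flagged = []
    for start in range(0, n - 2 - w_tri + 1):
        counts: dict[str, int] = {}
        valid = 0
        for i in range(start, start + w_tri):
            tri = seq[i : i + 3]
            if all(b in "ACGT" for b in tri):
                counts[tri] = counts.get(tri, 0) + 1
                valid += 1
        if valid >= 2:
            num = sum(c * (c - 1) // 2 for c in counts.values())
            if 10.0 * num / (valid - 1) >= threshold:
                flagged.append((start, start + w_tri + 2))
    merged = []
    for s, e in flagged:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# k-mer occurrence counting
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def kmer_occurrences(kmer: str, reference: dict[str, str]) -> int:
    """Strand-collapsed occurrence count by naive string scanning."""
    total = 0
    targets = {kmer, revcomp(kmer)}
    for seq in reference.values():
        k = len(kmer)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in targets:
                total += 1
    return total


def probe_max_hits(probe_seqs: list[str], reference: dict[str, str], k: int = 16) -> int:
    """Max naive occurrence count over all k-mers of all probe sequences."""
    best = 0
    for seq in probe_seqs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if all(b in "ACGT" for b in kmer):
                best = max(best, kmer_occurrences(kmer, reference))
    return best
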