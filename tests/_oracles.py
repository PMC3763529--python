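"""Independent brute-force oracles used across the test suite.

These deliberately avoid the code paths they check: translation goes
through Bio.Seq, alignment is a hand-rolled affine Smith-Waterman,
Mann-Whitney is full enumeration of rank assignments, the binomial test
is direct summation over all outcomes.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def synonymous_snvs_bruteforce(cds: str) -> set[tuple[int, str]]:
    """All protein-preserving single substitutions, start/stop excluded,
    by translating both full CDS variants."""
    ref_protein = translate(cds)
    out = set()
    for pos in range(3, len(cds) - 3):
        for alt in "ACGT":
            if alt == cds[pos]:
                continue
            mutated = cds[:pos] + alt + cds[pos + 1:]
            if translate(mutated) == ref_protein:
                out.add((pos, alt))
    return out


def is_synonymous_bruteforce(cds: str, pos: int, alt: str) -> bool:
    mutated = cds[:pos] + alt + cds[pos + 1:]
    return translate(mutated) == translate(cds)


def sw_affine_score(a: str, b: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> float:
    """Optimal local alignment score, affine gaps (first gap position
    costs gap_open, each further position gap_extend), BLOSUM62."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = prev + _BLOSUM62[a[i - 1], b[j - 1]]
            X[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_extend)
            Y[i][j] = max(M[i - 1][j] - gap_open, Y[i - 1][j] - gap_extend)
            best = max(best, M[i][j])
    return best


def mann_whitney_exact(x, y) -> float:
    """Two-sided exact P by enumerating every rank assignment (no ties)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == n + m, "oracle requires no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[v] for v in x) - n * (n + 1) / 2
    dev_obs = abs(u_obs - n * m / 2)
    total = hits = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if abs(u - n * m / 2) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


def binom_minlike_sum(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial P by direct summation."""
    def pmf(j):
        return math.comb(n, j) * p0 ** j * (1 - p0) ** (n - j)
    pk = pmf(k)
    return min(1.0, sum(pmf(j) for j in range(n + 1)
                        if pmf(j) <= pk * (1 + 1e-10)))
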