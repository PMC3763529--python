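"""Per-gene percentile statistic and group-level summaries and tests.

The central quantity is, per gene, the fraction of random synonymous
mutants whose |dMFE| is strictly smaller than that of the observed
mutation; small values mean the observed mutation is unusually
structure-preserving relative to its own null family.  Group-level
machinery compares essential vs nonessential genes: SNP-count and
synonymy contingency tables, the decreased/unchanged/increased MFE sign
summary, percentile quartiles, the Mann-Whitney U test on percentile
distributions and an exact binomial test on synonymous-SNP fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PercentileRecord",
    "percentile_for_gene",
    "mfe_sign_summary",
    "quartile_summary",
    "group_ratio",
    "mann_whitney_u",
    "exact_binomial_test",
    "ecdf_points",
    "snp_count_table",
    "synonymy_table",
]


@dataclass(frozen=True)
class PercentileRecord:
    """Per-gene outcome of the null-family comparison."""

    gene_id: str
    essentiality: str
    observed_abs_delta: float
    signed_delta: float
    family_size: int
    percentile: float

    def __post_init__(self):
        if not 0.0 <= self.percentile <= 1.0:
            raise ValueError("percentile outside [0, 1]")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")


def percentile_for_gene(observed: float, family_deltas,
                        ties: str = "strict") -> float:
    """Fraction of family members with |dMFE| smaller than observed.

    ``ties="strict"`` counts only strictly smaller members (family
    members equal to the observed value count against the gene, a
    conservative choice for unchanged-MFE genes).  ``ties="midrank"``
    credits half of each tied member, which is the unbiased choice when
    the energy model produces many exactly-tied values.
    """
    fam = np.asarray(list(family_deltas), dtype=float)
    if fam.size == 0:
        raise ValueError("empty family")
    less = np.count_nonzero(fam < observed)
    if ties == "strict":
        return less / fam.size
    if ties == "midrank":
        equal = np.count_nonzero(fam == observed)
        return (less + 0.5 * equal) / fam.size
    raise ValueError(f"unknown tie rule {ties!r}")


def mfe_sign_summary(signed_deltas, tol: float = 0.0) -> dict:
    """Counts and percentages of decreased / unchanged / increased MFE.

    ``tol`` is the half-width of the "unchanged" band (default 0: MFE
    values from a single engine are bit-comparable).
    """
    d = np.asarray(list(signed_deltas), dtype=float)
    dec = int(np.count_nonzero(d < -tol))
    inc = int(np.count_nonzero(d > tol))
    unch = d.size - dec - inc
    total = int(d.size)
    pct = (lambda k: round(100.0 * k / total, 1) if total else 0.0)
    return {"decreased": dec, "unchanged": unch, "increased": inc,
            "total": total,
            "decreased_pct": pct(dec), "unchanged_pct": pct(unch),
            "increased_pct": pct(inc)}


def quartile_summary(values) -> tuple[float, float, float]:
    """Lower quartile, median, upper quartile as percentages.

    Quartiles use linear interpolation between order statistics (the
    common spreadsheet/statistics default).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q = np.percentile(v, [25, 50, 75], method="linear")
    return tuple(float(100.0 * x) for x in q)


def group_ratio(count_a: int, count_b: int) -> float:
    """count_a / count_b rounded to 3 decimals."""
    if count_b == 0:
        raise ValueError("zero denominator")
    return round(count_a / count_b, 3)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U statistic (for x) and two-sided P.

    Exact by enumeration when min(n, m) <= 8 and there are no ties,
    otherwise the normal approximation with tie and continuity
    correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:  # degenerate: all values identical
        return x.size * y.size / 2.0, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def exact_binomial_test(k: int, n: int, p0: float,
                        convention: str = "minlike") -> float:
    """Exact two-sided binomial P-value.

    ``minlike`` sums the probabilities of all outcomes no more likely
    than the observed one; ``doubling`` doubles the smaller tail
    (capped at 1).  Both conventions are common in the literature and
    can differ in the second decimal.
    """
    if not (0 <= k <= n):
        raise ValueError("k outside [0, n]")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if convention == "minlike":
        return float(sps.binomtest(k, n, p0).pvalue)
    if convention == "doubling":
        lower = sps.binom.cdf(k, n, p0)
        upper = sps.binom.sf(k - 1, n, p0)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown convention {convention!r}")


def ecdf_points(values) -> list[tuple[float, float]]:
    """Right-continuous empirical CDF as (value, cumulative fraction)."""
    v = np.sort(np.asarray(list(values), dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    uniq, counts = np.unique(v, return_counts=True)
    cum = np.cumsum(counts) / v.size
    return [(float(u), float(c)) for u, c in zip(uniq, cum)]


def snp_count_table(snps_per_gene: dict[str, int],
                    labels: dict[str, str]) -> dict:
    """Genes by number of SNPs (1, 2, 3+) per essentiality class."""
    classes = ("all", "essential", "nonessential")
    table = {c: {"1": 0, "2": 0, "3": 0, "total": 0} for c in classes}
    for gene_id, k in snps_per_gene.items():
        bucket = str(min(k, 3))
        for cls in ("all", labels.get(gene_id, "unknown")):
            if cls in table:
                table[cls][bucket] += 1
                table[cls]["total"] += 1
    return table


def synonymy_table(snp_records, labels: dict[str, str]) -> dict:
    """Synonymous / nonsynonymous SNP counts per essentiality class."""
    classes = ("all", "essential", "nonessential")
    table = {c: {"synonymous": 0, "nonsynonymous": 0} for c in classes}
    for snp in snp_records:
        if snp.synonymy not in ("synonymous", "nonsynonymous"):
            continue
        for cls in ("all", labels.get(snp.gene_id, "unknown")):
            if cls in table:
                table[cls][snp.synonymy] += 1
    return table
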