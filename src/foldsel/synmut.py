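"""Per-gene families of random synonymous single-nucleotide mutants.

The null model of the analysis: for a gene observed to carry k point
mutations, a family of in-silico counterparts is built, each carrying k
synonymous substitutions, so that any MFE change in a family member
cannot be attributed to protein-level selection.  Substitutions are
drawn so that the six strand-symmetric substitution classes occur at
controlled frequencies (uniform by default, i.e. free of
transition/transversion bias).

Start and stop codons are excluded from synonymous candidacy: a change
in the start codon abolishes initiation and stop-to-stop changes affect
termination context, so neither is treated as neutral.  This is
configurable via ``mutable_codon_slice``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "SubstitutionType",
    "SubstitutionSpectrum",
    "MutantFamily",
    "enumerate_synonymous_snvs",
    "substitution_type_of",
    "sample_synonymous_mutant",
    "build_mutant_family",
    "apply_substitutions",
    "ts_tv_ratio",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
START_CODONS = set(_TABLE.start_codons)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


class SubstitutionType(Enum):
    """The six strand-symmetric point-substitution classes.

    Named on the DNA alphabet; e.g. CG_TO_TA covers C→T and G→A
    (the C:G base pair replaced by a T:A pair on either strand).
    """

    CG_TO_AT = "CG->AT"
    AT_TO_CG = "AT->CG"
    AT_TO_TA = "AT->TA"
    CG_TO_GC = "CG->GC"
    CG_TO_TA = "CG->TA"
    AT_TO_GC = "AT->GC"


#: the two transition classes (purine<->purine / pyrimidine<->pyrimidine)
TRANSITIONS = frozenset({SubstitutionType.AT_TO_GC, SubstitutionType.CG_TO_TA})


def substitution_type_of(ref: str, alt: str) -> SubstitutionType:
    """Strand-symmetric class of a ref→alt substitution."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid base in ({ref!r}, {alt!r})")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "GT":  # normalise to the A/C-strand representative
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return {
        ("C", "A"): SubstitutionType.CG_TO_AT,
        ("A", "C"): SubstitutionType.AT_TO_CG,
        ("A", "T"): SubstitutionType.AT_TO_TA,
        ("C", "G"): SubstitutionType.CG_TO_GC,
        ("C", "T"): SubstitutionType.CG_TO_TA,
        ("A", "G"): SubstitutionType.AT_TO_GC,
    }[(ref, alt)]


class SubstitutionSpectrum(dict):
    """Mapping SubstitutionType -> nonnegative weight (count or frequency)."""

    @classmethod
    def uniform(cls) -> "SubstitutionSpectrum":
        return cls({t: 1.0 for t in SubstitutionType})

    @classmethod
    def from_substitutions(cls, subs) -> "SubstitutionSpectrum":
        spectrum = cls({t: 0.0 for t in SubstitutionType})
        for ref, alt in subs:
            spectrum[substitution_type_of(ref, alt)] += 1
        return spectrum

    def normalized(self) -> "SubstitutionSpectrum":
        total = sum(self.values())
        if total <= 0:
            raise ValueError("spectrum has no mass")
        return SubstitutionSpectrum({t: v / total for t, v in self.items()})


def _validate_cds(cds: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0 or len(cds) < 6:
        raise ValueError("CDS length must be a positive multiple of 3 (>=6)")
    if any(c not in _BASES for c in cds):
        raise ValueError("CDS contains non-ACGT characters")
    if cds[:3] not in START_CODONS:
        raise ValueError(f"CDS does not begin with a start codon: {cds[:3]}")
    if CODON_TO_AA[cds[-3:]] != "*":
        raise ValueError("CDS does not end with a stop codon")
    return cds


def enumerate_synonymous_snvs(cds: str) -> list[tuple[int, str]]:
    """All single-nucleotide substitutions leaving the protein unchanged.

    Positions are 0-based on the coding strand.  The start and stop
    codons are excluded from candidacy (no internal position of either
    may mutate, even stop→stop).
    """
    cds = _validate_cds(cds)
    out: list[tuple[int, str]] = []
    for ci in range(1, len(cds) // 3 - 1):  # skip start and stop codons
        codon = cds[3 * ci: 3 * ci + 3]
        aa = CODON_TO_AA[codon]
        for off in range(3):
            for alt in _BASES:
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1:]
                if CODON_TO_AA[mutated] == aa:
                    out.append((3 * ci + off, alt))
    return out


def apply_substitutions(cds: str, subs) -> str:
    """Return cds with each (position, alt) substitution applied."""
    s = list(cds)
    for pos, alt in subs:
        s[pos] = alt
    return "".join(s)


def _group_by_type(cds: str, snvs) -> dict[SubstitutionType, list]:
    groups: dict[SubstitutionType, list] = {t: [] for t in SubstitutionType}
    for pos, alt in snvs:
        groups[substitution_type_of(cds[pos], alt)].append((pos, alt))
    return groups


def sample_synonymous_mutant(cds: str, k: int,
                             target_spectrum: SubstitutionSpectrum | None,
                             rng: np.random.Generator,
                             snvs=None) -> tuple[tuple[int, str], ...]:
    """Draw one mutant: k synonymous substitutions at distinct positions.

    Each substitution is drawn by first sampling a substitution class
    from the target spectrum restricted (and renormalised) to classes
    with at least one available option, then sampling uniformly among
    that class's available (position, alt) pairs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if snvs is None:
        snvs = enumerate_synonymous_snvs(cds)
    spectrum = target_spectrum or SubstitutionSpectrum.uniform()
    n_positions = len({p for p, _ in snvs})
    if n_positions < k:
        raise ValueError(
            f"gene has only {n_positions} synonymous positions, need {k}")
    groups = _group_by_type(cds, snvs)
    chosen: list[tuple[int, str]] = []
    used: set[int] = set()
    for _ in range(k):
        avail = {t: [sv for sv in g if sv[0] not in used]
                 for t, g in groups.items()}
        types = [t for t in SubstitutionType if avail[t] and spectrum.get(t, 0) > 0]
        if not types:
            types = [t for t in SubstitutionType if avail[t]]
        w = np.array([spectrum.get(t, 1.0) for t in types], dtype=float)
        t = types[rng.choice(len(types), p=w / w.sum())]
        opts = avail[t]
        pos, alt = opts[rng.integers(len(opts))]
        chosen.append((pos, alt))
        used.add(pos)
    return tuple(sorted(chosen))


@dataclass
class MutantFamily:
    """The per-gene null family of synonymous k-substitution mutants."""

    gene_id: str
    k: int
    mode: str  # "exhaustive" | "sampled"
    members: list  # tuples of (position, alt), sorted, distinct
    seed: int | None
    achieved_spectrum: SubstitutionSpectrum

    @property
    def size(self) -> int:
        return len(self.members)

    def mutated_sequences(self, cds: str):
        for m in self.members:
            yield apply_substitutions(cds, m)


def _exhaustive_family_size(snvs, k: int) -> int:
    """Number of k-subsets of snvs with pairwise distinct positions.

    Computed by a polynomial product over positions (each position
    contributes 1 + c_p * x, c_p = number of alternates there).
    """
    counts: dict[int, int] = {}
    for pos, _ in snvs:
        counts[pos] = counts.get(pos, 0) + 1
    poly = [1] + [0] * k
    for c in counts.values():
        for d in range(min(k, len(poly) - 1), 0, -1):
            poly[d] += c * poly[d - 1]
    return poly[k]


def build_mutant_family(cds: str, k: int, cap: int = 1000,
                        target_spectrum: SubstitutionSpectrum | None = None,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None,
                        gene_id: str = "",
                        attempt_factor: int = 50) -> MutantFamily:
    """Build the null family for one gene.

    If the exhaustive set of distinct-position k-substitution variants
    has at most ``cap`` members it is enumerated in full; otherwise
    ``cap`` distinct members are sampled under the target spectrum.
    """
    cds = _validate_cds(cds)
    snvs = enumerate_synonymous_snvs(cds)
    if rng is None:
        rng = np.random.default_rng(seed)
    total = _exhaustive_family_size(snvs, k)
    if total == 0:
        raise ValueError(
            f"gene {gene_id or '<anon>'}: no synonymous k={k} variant exists")
    if total <= cap:
        if k == 1:
            members = [(sv,) for sv in snvs]
        else:
            members = [tuple(sorted(c))
                       for c in itertools.combinations(snvs, k)
                       if len({p for p, _ in c}) == k]
        mode = "exhaustive"
    else:
        members_set: set = set()
        budget = attempt_factor * cap
        attempts = 0
        while len(members_set) < cap and attempts < budget:
            members_set.add(
                sample_synonymous_mutant(cds, k, target_spectrum, rng, snvs))
            attempts += 1
        if len(members_set) < cap:
            warnings.warn(
                f"gene {gene_id or '<anon>'}: only {len(members_set)} "
                f"distinct members found within attempt budget")
        members = sorted(members_set)
        mode = "sampled"
    achieved = SubstitutionSpectrum.from_substitutions(
        (cds[pos], alt) for m in members for pos, alt in m)
    return MutantFamily(gene_id=gene_id, k=k, mode=mode, members=members,
                        seed=seed, achieved_spectrum=achieved)


def ts_tv_ratio(substitutions) -> float:
    """Transition/transversion ratio of (ref, alt) pairs; inf if no tv."""
    subs = list(substitutions)
    if not subs:
        raise ValueError("empty substitution collection")
    ts = sum(1 for r, a in subs if substitution_type_of(r, a) in TRANSITIONS)
    tv = len(subs) - ts
    return math.inf if tv == 0 else ts / tv
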