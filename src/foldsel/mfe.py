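"""Minimum free energy of mRNA secondary structure, via pluggable engines.

Two engines are provided:

``reference``
    A deterministic, fully specified nearest-neighbour model: nested
    (pseudoknot-free) structures over the canonical pair set
    {AU, UA, GC, CG, GU, UG}, a minimum hairpin-loop separation, an
    optional prohibition of lonely pairs (helices of length one, the
    ``noLP`` convention), and an energy that is the sum over stacked
    adjacent pairs of ``-(w(p1)+w(p2))/2`` for per-pair-class weights
    ``w``.  The optimum is found by dynamic programming and is verified
    in the test suite against exhaustive structure enumeration.  Values
    are pseudo-kcal/mol: internally consistent, not calibrated against
    any thermodynamic parameter set.

``rnafold``
    An adapter around an external ViennaRNA ``RNAfold`` executable for
    full-fidelity runs (Turner energies, proper loop terms).  The
    lonely-pair prohibition is forwarded as ``--noLP``.  The adapter
    never falls back silently: a missing or failing tool raises.

Ancestor/mutant comparisons must not mix engines; every value carries
its engine tag and :func:`abs_delta_mfe` enforces the match.
"""

from __future__ import annotations

import re
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from numba import njit

__all__ = [
    "FoldingConfig",
    "MfeValue",
    "DeltaMfe",
    "fold_mfe",
    "fold_mfe_reference",
    "fold_mfe_many",
    "fold_mfe_rnafold",
    "enumerate_structures_oracle",
    "abs_delta_mfe",
]

_INF = 1e30

# encoding order for the 4 RNA bases in the DP matrices
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class FoldingConfig:
    """Parameters of the folding model.

    ``stack_weights`` maps an unordered pair class to a positive weight;
    the energy of two stacked pairs is minus the mean of their weights.
    Defaults follow base-pairing strength ordering GC > AU > GU.
    """

    engine: str = "reference"
    no_lonely_pairs: bool = True
    min_hairpin_loop: int = 3
    stack_weights: tuple = (("GC", 3.0), ("AU", 2.0), ("GU", 1.0))
    rnafold_binary: str = "RNAfold"

    def __post_init__(self):
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        for _, w in self.stack_weights:
            if w <= 0:
                raise ValueError("stack weights must be positive")

    def weight_matrix(self) -> np.ndarray:
        """4x4 matrix of pair weights (0 where pairing is disallowed)."""
        m = np.zeros((4, 4))
        for cls, w in self.stack_weights:
            a, b = cls[0], cls[1]
            i, j = _BASE_INDEX[a], _BASE_INDEX[b]
            m[i, j] = w
            m[j, i] = w
        return m


@dataclass(frozen=True)
class MfeValue:
    """A minimum free energy with engine provenance (kcal/mol)."""

    value: float
    engine: str

    def __float__(self) -> float:
        return self.value


class DeltaMfe(NamedTuple):
    """|MFE change| plus the signed change (mutant minus ancestor)."""

    abs: float
    signed: float


def encode_rna(seq: str) -> np.ndarray:
    """Validate and encode a nucleotide sequence; T is mapped to U."""
    s = seq.upper().replace("T", "U")
    if not s:
        raise ValueError("empty sequence")
    try:
        return np.array([_BASE_INDEX[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


@njit(cache=True)
def _fold_dp(enc, wmat, min_hairpin, nolp):  # pragma: no cover - jitted
    n = enc.shape[0]
    W = np.zeros((n, n))
    Wno = np.zeros((n, n))
    Vout = np.full((n, n), _INF)   # (i,j) paired, no support from outside
    Vsup = np.full((n, n), _INF)   # (i,j) paired, stacked on from outside
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            wij = wmat[enc[i], enc[j]]
            pairable = wij > 0.0 and (j - i - 1) >= min_hairpin
            if pairable:
                inner_ok = (
                    j - 1 - (i + 1) - 1 >= min_hairpin
                    and wmat[enc[i + 1], enc[j - 1]] > 0.0
                )
                stack = -(wij + wmat[enc[i + 1], enc[j - 1]]) / 2.0
                # best inside with (i+1,j-1) NOT paired to each other
                if j - 1 >= i + 1:
                    open_inside = Wno[i + 1, j - 1]
                else:
                    open_inside = 0.0
                if nolp:
                    v = open_inside
                    if inner_ok and stack + Vsup[i + 1, j - 1] < v:
                        v = stack + Vsup[i + 1, j - 1]
                    Vsup[i, j] = v
                    if inner_ok:
                        Vout[i, j] = stack + Vsup[i + 1, j - 1]
                else:
                    v = open_inside
                    if inner_ok and stack + Vout[i + 1, j - 1] < v:
                        v = stack + Vout[i + 1, j - 1]
                    Vout[i, j] = v
            best_no = W[i + 1, j]
            if W[i, j - 1] < best_no:
                best_no = W[i, j - 1]
            for k in range(i + 1, j):
                cand = W[i, k] + W[k + 1, j]
                if cand < best_no:
                    best_no = cand
            Wno[i, j] = best_no
            best = best_no
            if Vout[i, j] < best:
                best = Vout[i, j]
            W[i, j] = best
    return W[0, n - 1]


def fold_mfe_reference(seq: str, cfg: FoldingConfig | None = None) -> MfeValue:
    """MFE of ``seq`` under the reference stacking model.

    The empty structure is always admissible, so the result is <= 0.
    """
    cfg = cfg or FoldingConfig()
    enc = encode_rna(seq)
    if enc.shape[0] < 2:
        return MfeValue(0.0, "reference")
    v = _fold_dp(enc, cfg.weight_matrix(), cfg.min_hairpin_loop,
                 cfg.no_lonely_pairs)
    return MfeValue(float(v), "reference")


_RNAFOLD_ENERGY = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\)\s*$")


def fold_mfe_rnafold(seqs: Sequence[str],
                     cfg: FoldingConfig | None = None) -> list[MfeValue]:
    """Fold sequences with an external RNAfold, returning one MFE each.

    Raises ``RuntimeError`` naming the adapter if the tool is missing or
    its output cannot be parsed — there is no silent fallback.
    """
    cfg = cfg or FoldingConfig(engine="rnafold")
    exe = shutil.which(cfg.rnafold_binary)
    if exe is None:
        raise RuntimeError(
            f"rnafold adapter: executable {cfg.rnafold_binary!r} not found")
    fasta = "".join(f">s{i}\n{s.upper().replace('T', 'U')}\n"
                    for i, s in enumerate(seqs))
    args = [exe, "--noPS"]
    if cfg.no_lonely_pairs:
        args.append("--noLP")
    proc = subprocess.run(args, input=fasta, text=True,
                          capture_output=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"rnafold adapter: {cfg.rnafold_binary} exited "
            f"{proc.returncode}: {proc.stderr.strip()[:200]}")
    values = []
    for line in proc.stdout.splitlines():
        m = _RNAFOLD_ENERGY.search(line)
        if m:
            values.append(MfeValue(float(m.group(1)), "rnafold"))
    if len(values) != len(seqs):
        raise RuntimeError(
            f"rnafold adapter: expected {len(seqs)} energies, "
            f"parsed {len(values)}")
    return values


def fold_mfe(seq: str, cfg: FoldingConfig | None = None) -> MfeValue:
    """Fold one sequence with the engine selected in ``cfg``."""
    cfg = cfg or FoldingConfig()
    if cfg.engine == "reference":
        return fold_mfe_reference(seq, cfg)
    if cfg.engine == "rnafold":
        return fold_mfe_rnafold([seq], cfg)[0]
    raise ValueError(f"unknown engine {cfg.engine!r}")


def fold_mfe_many(seqs: Iterable[str],
                  cfg: FoldingConfig | None = None) -> list[MfeValue]:
    """Fold many sequences; batches the external adapter into one call."""
    cfg = cfg or FoldingConfig()
    seqs = list(seqs)
    if cfg.engine == "rnafold":
        return fold_mfe_rnafold(seqs, cfg)
    return [fold_mfe_reference(s, cfg) for s in seqs]


def abs_delta_mfe(ancestor: MfeValue, mutant: MfeValue) -> DeltaMfe:
    """|MFE difference| between ancestor and mutant, same engine required.

    The signed component is mutant minus ancestor, used by the
    decreased/unchanged/increased sign summary.
    """
    if ancestor.engine != mutant.engine:
        raise ValueError(
            f"cannot mix engines: {ancestor.engine!r} vs {mutant.engine!r}")
    signed = mutant.value - ancestor.value
    return DeltaMfe(abs(signed), signed)


# ---------------------------------------------------------------------------
# exhaustive oracle


def _valid_pairings(n: int, pairable) -> list[frozenset]:
    """All nested pairings of positions 0..n-1 (memoised interval recursion)."""
    memo: dict[tuple[int, int], list] = {}

    def gen(i: int, j: int):
        if i >= j:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(gen(i + 1, j))  # i unpaired
        for k in range(i + 1, j + 1):
            if pairable(i, k):
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        memo[key] = out
        return out

    return gen(0, n - 1)


def enumerate_structures_oracle(seq: str,
                                cfg: FoldingConfig | None = None,
                                max_len: int = 22) -> float:
    """Minimum energy by brute force over every admissible structure.

    Intended as an independent correctness oracle for the DP; guarded to
    short sequences because the structure count grows exponentially.
    """
    cfg = cfg or FoldingConfig()
    enc = encode_rna(seq)
    n = enc.shape[0]
    if n > max_len:
        raise ValueError(f"oracle limited to length <= {max_len}")
    wmat = cfg.weight_matrix()
    m = cfg.min_hairpin_loop

    def pairable(i, j):
        return wmat[enc[i], enc[j]] > 0 and (j - i - 1) >= m

    best = 0.0
    for pairs in _valid_pairings(n, pairable):
        if cfg.no_lonely_pairs:
            lonely = any((i + 1, j - 1) not in pairs
                         and (i - 1, j + 1) not in pairs
                         for i, j in pairs)
            if lonely:
                continue
        e = sum(-(wmat[enc[i], enc[j]] + wmat[enc[i + 1], enc[j - 1]]) / 2.0
                for i, j in pairs if (i + 1, j - 1) in pairs)
        if e < best:
            best = e
    return best
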