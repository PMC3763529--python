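"""Essentiality label transfer between gene catalogs via bidirectional best hits.

Essentiality is usually known only for a reference strain; labels are
carried over to the analysed strain through reciprocal best protein
hits.  Alignment is local Smith-Waterman with affine gaps under
BLOSUM62 (open 11, extend 1 by default), a desk-scale equivalent of a
blastp search; an external aligner adapter may populate e-values, in
which case the e-value threshold is enforced in addition to the
aligner-independent identity threshold.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import ESSENTIAL, NONESSENTIAL, UNKNOWN, UNMAPPED, GeneCatalog

log = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "OrthologPair",
    "align_proteins",
    "bidirectional_best_hits",
    "transfer_essentiality",
    "read_essentiality_table",
]


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    score: float
    identity: float          # matches / aligned columns (terminal overhangs excluded)
    evalue: float | None = None  # None = unavailable (built-in aligner)


@dataclass(frozen=True)
class OrthologPair:
    gene_id_a: str
    gene_id_b: str
    identity: float
    evalue: float | None = None


def align_proteins(query: str, subject: str,
                   params: AlignmentParams | None = None,
                   query_id: str = "query",
                   subject_id: str = "subject") -> AlignmentResult:
    """Local alignment of two protein sequences.

    Identity is matches over aligned columns, counting internal gap
    columns but not the unaligned terminal overhangs (which local
    alignment leaves outside the alignment by construction).
    """
    if not query or not subject:
        raise ValueError("empty protein sequence")
    params = params or AlignmentParams()
    aligner = params.make_aligner()
    alns = aligner.align(query, subject)
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    return AlignmentResult(query_id, subject_id, float(aln.score), identity)


def _best_hits(catalog_a: GeneCatalog, catalog_b: GeneCatalog,
               params: AlignmentParams) -> dict[str, str | None]:
    """Unique top-scoring hit in b for every gene of a (None on tie)."""
    aligner = params.make_aligner()
    hits: dict[str, str | None] = {}
    for ga in catalog_a:
        best_score, best_id, tie = float("-inf"), None, False
        for gb in catalog_b:
            score = aligner.score(ga.protein, gb.protein)
            if score > best_score:
                best_score, best_id, tie = score, gb.gene_id, False
            elif score == best_score:
                tie = True
        if tie:
            log.info("gene %s: tie for best hit, left unmapped", ga.gene_id)
            best_id = None
        hits[ga.gene_id] = best_id
    return hits


def bidirectional_best_hits(catalog_a: GeneCatalog, catalog_b: GeneCatalog,
                            identity_min: float = 0.75,
                            evalue_max: float = 1e-25,
                            params: AlignmentParams | None = None
                            ) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs above the identity threshold.

    A pair (a, b) is reported iff b is a's unique top-scoring hit, a is
    b's unique top-scoring hit, and identity > ``identity_min``.  The
    e-value threshold applies only when the aligner supplies e-values
    (the built-in aligner does not).
    """
    params = params or AlignmentParams()
    fwd = _best_hits(catalog_a, catalog_b, params)
    rev = _best_hits(catalog_b, catalog_a, params)
    pairs = []
    for ga in catalog_a:
        b_id = fwd[ga.gene_id]
        if b_id is None or rev.get(b_id) != ga.gene_id:
            continue
        res = align_proteins(ga.protein, catalog_b.get(b_id).protein, params,
                             ga.gene_id, b_id)
        if res.identity <= identity_min:
            continue
        if res.evalue is not None and res.evalue >= evalue_max:
            continue
        pairs.append(OrthologPair(ga.gene_id, b_id, res.identity, res.evalue))
    return pairs


def transfer_essentiality(catalog_a: GeneCatalog, pairs,
                          labels_b: dict[str, str]) -> GeneCatalog:
    """Annotate catalog_a in place with labels mapped through the pairs.

    Mapped genes whose ortholog carries a label become essential /
    nonessential; mapped genes absent from the label table become
    ``unknown``; genes without an ortholog become ``unmapped``.
    """
    mapping = {p.gene_id_a: p.gene_id_b for p in pairs}
    for gene in catalog_a:
        b_id = mapping.get(gene.gene_id)
        if b_id is None:
            gene.essentiality = UNMAPPED
        else:
            label = labels_b.get(b_id)
            if label == "essential":
                gene.essentiality = ESSENTIAL
            elif label == "dispensable":
                gene.essentiality = NONESSENTIAL
            else:
                gene.essentiality = UNKNOWN
    return catalog_a


def read_essentiality_table(path) -> dict[str, str]:
    """Read a TSV of gene_id, label in {essential, dispensable}."""
    labels = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=2):
            label = row["label"].strip()
            if label not in ("essential", "dispensable"):
                raise ValueError(f"{path}:{ln}: bad label {label!r}")
            labels[row["gene_id"]] = label
    return labels
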