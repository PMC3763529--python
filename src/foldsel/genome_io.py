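"""Genomes, gene annotations and SNP tables.

Coordinates are 0-based half-open internally; user-facing files (GenBank,
the SNP TSV) use the 1-based conventions of their formats.  SNPs are
reported on the forward genomic strand, as resequencing pipelines emit
them; complementation into the coding strand is handled here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .synmut import CODON_TO_AA

log = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "SnpRecord",
    "GeneCatalog",
    "read_genome",
    "read_snp_table",
    "classify_snp",
    "classify_snps",
    "filter_snps",
    "apply_snps",
    "translate_cds",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

ESSENTIAL = "essential"
NONESSENTIAL = "nonessential"
UNKNOWN = "unknown"
UNMAPPED = "unmapped"


def translate_cds(cds: str) -> str:
    """Translate a CDS (stop codon dropped from the protein)."""
    aas = [CODON_TO_AA.get(cds[i:i + 3].upper(), "X")
           for i in range(0, len(cds) - len(cds) % 3, 3)]
    if aas and aas[-1] == "*":
        aas = aas[:-1]
    return "".join(aas)


@dataclass
class GeneRecord:
    """One annotated coding gene in coding orientation."""

    gene_id: str
    start: int            # genomic, 0-based half-open, forward strand
    end: int
    strand: str           # "+" or "-"
    cds: str              # coding strand, start codon .. stop codon
    protein: str          # annotated protein (no stop)
    essentiality: str = UNKNOWN

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.end - self.start != len(self.cds):
            raise ValueError(
                f"{self.gene_id}: span {self.end - self.start} != "
                f"CDS length {len(self.cds)}")

    def genomic_to_cds(self, position: int) -> int:
        """Map a forward-strand genomic position into the coding strand."""
        if not self.start <= position < self.end:
            raise ValueError(f"position {position} outside {self.gene_id}")
        if self.strand == "+":
            return position - self.start
        return self.end - 1 - position


@dataclass(frozen=True)
class SnpRecord:
    """One observed point mutation (forward genomic strand)."""

    position: int         # 0-based forward strand
    ref: str
    alt: str
    region_class: str     # cds | intergenic | pseudogene | is_element
    gene_id: str = ""
    synonymy: str = "not_applicable"  # synonymous | nonsynonymous | n.a.

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if (self.region_class == "cds") != bool(self.gene_id):
            raise ValueError("gene_id must be set iff region_class == cds")


@dataclass
class GeneCatalog:
    """An ordered gene set plus the genome it lives on."""

    genes: list[GeneRecord]
    genome: str
    pseudogene_regions: list[tuple[int, int]] = field(default_factory=list)
    is_element_regions: list[tuple[int, int]] = field(default_factory=list)
    source: str = ""
    _tree: IntervalTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids are not unique")
        for g in self.genes:
            if not (0 <= g.start < g.end <= len(self.genome)):
                raise ValueError(f"{g.gene_id} outside genome bounds")

    def __iter__(self):
        return iter(self.genes)

    def __len__(self):
        return len(self.genes)

    def get(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_at(self, position: int) -> list[GeneRecord]:
        if self._tree is None:
            tree = IntervalTree()
            for g in self.genes:
                tree[g.start:g.end] = g
            self._tree = tree
        hits = sorted(self._tree[position], key=lambda iv: iv.begin)
        return [iv.data for iv in hits]


def _check_cds(gene_id: str, cds: str) -> str | None:
    """Return a rejection reason for an untranslatable CDS, else None."""
    if len(cds) % 3 != 0:
        return "length not divisible by 3"
    if any(c not in "ACGT" for c in cds):
        return "ambiguous bases in CDS"
    aa = [CODON_TO_AA[cds[i:i + 3]] for i in range(0, len(cds), 3)]
    if "*" in aa[:-1]:
        return "internal stop codon"
    if aa[-1] != "*":
        return "missing terminal stop codon"
    return None


def read_genome(path, gene_table=None) -> GeneCatalog:
    """Read a genome with CDS annotations into a :class:`GeneCatalog`.

    ``path`` may be a GenBank flat file (CDS features; genes marked
    ``pseudo`` and mobile/IS elements become excluded-region classes) or
    a FASTA file, in which case ``gene_table`` must point to a TSV with
    columns gene_id, start (1-based), end, strand and optional kind.
    Reverse-strand CDSs are reverse-complemented into coding orientation.
    Untranslatable CDSs are excluded with a logged warning.
    """
    path = Path(path)
    if gene_table is None:
        return _read_genbank(path)
    return _read_fasta_table(path, Path(gene_table))


def _read_genbank(path: Path) -> GeneCatalog:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
    genome = str(record.seq).upper()
    genes, pseudo, is_el = [], [], []
    seen = set()
    for feat in record.features:
        start, end = int(feat.location.start), int(feat.location.end)
        if feat.type in ("mobile_element", "repeat_region"):
            is_el.append((start, end))
            continue
        if feat.type in ("gene", "CDS") and "pseudo" in feat.qualifiers:
            if feat.type == "gene":
                pseudo.append((start, end))
            continue
        if feat.type != "CDS":
            continue
        gid = feat.qualifiers.get("locus_tag",
                                  feat.qualifiers.get("gene", ["?"]))[0]
        if gid in seen:
            log.warning("duplicate gene id %s skipped", gid)
            continue
        strand = "+" if feat.location.strand >= 0 else "-"
        span = genome[start:end]
        cds = span if strand == "+" else str(Seq(span).reverse_complement())
        reason = _check_cds(gid, cds)
        if reason is not None:
            log.warning("gene %s excluded: %s", gid, reason)
            continue
        prot = feat.qualifiers.get("translation", [translate_cds(cds)])[0]
        genes.append(GeneRecord(gid, start, end, strand, cds, prot))
        seen.add(gid)
    return GeneCatalog(genes, genome, pseudo, is_el,
                       source=f"{path}#{record.id}")


def _read_fasta_table(fasta: Path, table: Path) -> GeneCatalog:
    record = next(SeqIO.parse(str(fasta), "fasta"))
    genome = str(record.seq).upper()
    genes, pseudo, is_el = [], [], []
    with open(table) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=2):
            try:
                start = int(row["start"]) - 1  # 1-based inclusive in file
                end = int(row["end"])
                kind = row.get("kind", "cds") or "cds"
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{table}:{ln}: bad row ({exc})") from exc
            if kind == "pseudogene":
                pseudo.append((start, end))
                continue
            if kind == "is_element":
                is_el.append((start, end))
                continue
            strand = row["strand"]
            span = genome[start:end]
            cds = span if strand == "+" else str(
                Seq(span).reverse_complement())
            reason = _check_cds(row["gene_id"], cds)
            if reason is not None:
                log.warning("gene %s excluded: %s", row["gene_id"], reason)
                continue
            genes.append(GeneRecord(row["gene_id"], start, end, strand,
                                    cds, translate_cds(cds)))
    return GeneCatalog(genes, genome, pseudo, is_el, source=str(fasta))


def read_snp_table(path) -> list[tuple[int, str, str]]:
    """Read a SNP TSV (position 1-based, ref, alt; header required).

    Returns (position 0-based, ref, alt) tuples.
    """
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "position" not in reader.fieldnames:
            raise ValueError(f"{path}: missing header with 'position' column")
        for ln, row in enumerate(reader, start=2):
            try:
                rows.append((int(row["position"]) - 1,
                             row["ref"].upper(), row["alt"].upper()))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{ln}: bad row ({exc})") from exc
    return rows


def _in_regions(pos: int, regions) -> bool:
    return any(s <= pos < e for s, e in regions)


def classify_snp(position: int, ref: str, alt: str,
                 catalog: GeneCatalog) -> list[SnpRecord]:
    """Classify one SNP against the catalog.

    Returns one record per overlapping CDS (a SNP inside two overlapping
    genes is assigned to both, each gene analysed independently), or a
    single intergenic/pseudogene/is_element record.  A reference-base
    mismatch against the genome raises, naming the 1-based position.
    """
    ref, alt = ref.upper(), alt.upper()
    genome_base = catalog.genome[position]
    if genome_base != ref:
        raise ValueError(
            f"SNP at position {position + 1}: reported ref {ref!r} does not "
            f"match genome base {genome_base!r}")
    genes = catalog.genes_at(position)
    if not genes:
        if _in_regions(position, catalog.pseudogene_regions):
            cls = "pseudogene"
        elif _in_regions(position, catalog.is_element_regions):
            cls = "is_element"
        else:
            cls = "intergenic"
        return [SnpRecord(position, ref, alt, cls)]
    if len(genes) > 1:
        log.info("SNP at %d overlaps %d genes; assigned to each",
                 position + 1, len(genes))
    records = []
    for gene in genes:
        idx = gene.genomic_to_cds(position)
        if gene.strand == "+":
            c_ref, c_alt = ref, alt
        else:
            c_ref, c_alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        assert gene.cds[idx] == c_ref
        ci = idx // 3
        codon = gene.cds[3 * ci:3 * ci + 3]
        mutated = codon[:idx % 3] + c_alt + codon[idx % 3 + 1:]
        syn = ("synonymous" if CODON_TO_AA[mutated] == CODON_TO_AA[codon]
               else "nonsynonymous")
        records.append(SnpRecord(position, ref, alt, "cds",
                                 gene.gene_id, syn))
    return records


def classify_snps(rows, catalog: GeneCatalog):
    """Classify many raw (position, ref, alt) rows.

    Returns (records, mismatches) where mismatches lists the rows whose
    reference base disagreed with the genome (excluded, as in variant
    tables that are inconsistent with the assembly).
    """
    records, mismatches = [], []
    for pos, ref, alt in rows:
        try:
            records.extend(classify_snp(pos, ref, alt, catalog))
        except ValueError:
            mismatches.append((pos, ref, alt))
    return records, mismatches


def filter_snps(snps, catalog: GeneCatalog,
                n_ref_mismatch: int = 0):
    """Apply the coding-SNP retention rules.

    Retains CDS SNPs only; drops intergenic / pseudogene / IS-element
    SNPs; drops every SNP of a gene whose annotated protein disagrees
    with its CDS translation, and of any gene with a SNP in its start
    codon.  Returns (retained, report) where report counts exclusions
    per category plus per-SNP reasons.
    """
    report = {"intergenic": 0, "pseudogene": 0, "is_element": 0,
              "ref_mismatch": n_ref_mismatch, "gene_inconsistent": 0,
              "start_codon_gene": 0, "retained": 0}
    reasons: list[tuple[SnpRecord, str]] = []
    cds_snps: list[SnpRecord] = []
    for snp in snps:
        if snp.region_class != "cds":
            report[snp.region_class] += 1
            reasons.append((snp, snp.region_class))
        else:
            cds_snps.append(snp)

    bad_genes: dict[str, str] = {}
    for snp in cds_snps:
        gene = catalog.get(snp.gene_id)
        if translate_cds(gene.cds) != gene.protein:
            bad_genes.setdefault(gene.gene_id, "gene_inconsistent")
        if gene.genomic_to_cds(snp.position) < 3:
            bad_genes[gene.gene_id] = "start_codon_gene"

    retained = []
    counted: set[str] = set()
    for snp in cds_snps:
        if snp.gene_id in bad_genes:
            reason = bad_genes[snp.gene_id]
            reasons.append((snp, reason))
            if snp.gene_id not in counted:
                report[reason] += 1  # counted per gene, as excluded genes
                counted.add(snp.gene_id)
        else:
            retained.append(snp)
    report["retained"] = len(retained)
    return retained, {"counts": report, "reasons": reasons}


def apply_snps(gene: GeneRecord, snps) -> str:
    """Return the gene's CDS with the given SNPs substituted.

    SNPs are genomic forward-strand records; bases are complemented into
    the coding strand for reverse-strand genes.  Two SNPs at the same
    position raise.
    """
    positions = [s.position for s in snps]
    if len(set(positions)) != len(positions):
        raise ValueError(f"{gene.gene_id}: duplicate SNP positions")
    cds = list(gene.cds)
    for snp in snps:
        idx = gene.genomic_to_cds(snp.position)
        alt = snp.alt if gene.strand == "+" else _COMPLEMENT[snp.alt]
        ref = snp.ref if gene.strand == "+" else _COMPLEMENT[snp.ref]
        if cds[idx] != ref:
            raise ValueError(
                f"{gene.gene_id}: SNP ref {snp.ref} inconsistent at "
                f"position {snp.position + 1}")
        cds[idx] = alt
    return "".join(cds)
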