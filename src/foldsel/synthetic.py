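"""Fully synthetic genomes, SNP tables and essentiality labels.

Generates gene catalogs of random CDSs at a target GC content, then
plants "observed" mutations whose |dMFE| quantile within the gene's own
synonymous null family follows Beta(1, theta): theta = 1 reproduces the
no-constraint null (uniform quantiles), theta > 1 biases observed
mutations toward structure preservation, emulating purifying selection
on mRNA secondary structure.  The Beta(1, theta) law is analytically
invertible (median 1 - 0.5**(1/theta)), giving closed-form recovery
targets for the pipeline.

Family generation uses a per-gene random substream derived from
(seed, crc32(gene_id)); a pipeline run configured with the same seed and
family parameters regenerates the identical families, so recovered
percentiles match planted quantiles up to discreteness and ties
("same-family" mode).  ``fresh_family_seed`` decouples the two for a
noisier, more realistic recovery.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .genome_io import GeneCatalog, GeneRecord, SnpRecord, translate_cds
from .mfe import FoldingConfig, abs_delta_mfe, fold_mfe_many
from .synmut import (CODON_TO_AA, SubstitutionSpectrum, apply_substitutions,
                     build_mutant_family, enumerate_synonymous_snvs)

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "generate_catalog",
    "diverged_copy",
    "plant_observed_mutations",
    "write_fixture",
    "gene_rng",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults echo the analysed E. coli data: essential fraction
    620/3746, SNPs-per-gene distribution (0.92, 0.075, 0.005) over
    {1, 2, 3}, 48 essential and 348 nonessential mutated genes, null
    family cap 1000.
    """

    n_genes: int = 450
    min_codons: int = 50          # gene length ~ log-uniform [min, max]
    max_codons: int = 450
    gc_content: float = 0.5
    essential_fraction: float = 620 / 3746
    snps_per_gene: tuple = (0.92, 0.075, 0.005)
    theta_essential: float = 1.0   # planted selection strength, >= 1
    theta_nonessential: float = 1.0
    n_essential_mutated: int = 48
    n_nonessential_mutated: int = 348
    cap: int = 1000
    n_pseudogenes: int = 0
    n_is_elements: int = 0
    observed_synonymy: str = "synonymous"  # or "nonsynonymous"
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.snps_per_gene) - 1.0) > 1e-9:
            raise ValueError("snps_per_gene probabilities must sum to 1")
        if self.theta_essential < 1 or self.theta_nonessential < 1:
            raise ValueError("planted selection strengths must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    essentiality: str
    theta: float
    planted_quantile: float       # the Beta(1, theta) draw q
    planted_percentile: float     # strict rank fraction of chosen member
    k: int


def gene_rng(seed: int, gene_id: str) -> np.random.Generator:
    """Per-gene substream, stable across runs and worker scheduling."""
    return np.random.default_rng([seed, zlib.crc32(gene_id.encode())])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    codons = []
    while len(codons) < n_codons - 2:
        codon = "".join(rng.choice(bases, size=3, p=p))
        if CODON_TO_AA[codon] != "*":
            codons.append(codon)
    return "ATG" + "".join(codons) + _STOPS[rng.integers(3)]


def generate_catalog(cfg: SyntheticConfig
                     ) -> tuple[GeneCatalog, dict[str, str]]:
    """Random gene catalog plus essentiality labels, deterministic in seed.

    Genes are laid head-to-tail with random intergenic spacers and
    random strands; optional pseudogene and IS-element decoy regions are
    interleaved for SNP-filter testing.
    """
    rng = np.random.default_rng(cfg.seed)
    parts: list[str] = []
    genes: list[GeneRecord] = []
    pseudo: list[tuple[int, int]] = []
    is_el: list[tuple[int, int]] = []
    labels: dict[str, str] = {}
    pos = 0

    def spacer():
        nonlocal pos
        n = int(rng.integers(20, 60))
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        parts.append(s)
        pos += n

    spacer()
    for i in range(cfg.n_genes):
        gid = f"g{i:04d}"
        n_codons = int(round(math.exp(rng.uniform(
            math.log(cfg.min_codons), math.log(cfg.max_codons)))))
        cds = _random_cds(rng, n_codons, cfg.gc_content)
        strand = "+" if rng.random() < 0.5 else "-"
        span = cds if strand == "+" else str(Seq(cds).reverse_complement())
        start = pos
        parts.append(span)
        pos += len(span)
        genes.append(GeneRecord(gid, start, pos, strand, cds,
                                translate_cds(cds)))
        labels[gid] = ("essential" if rng.random() < cfg.essential_fraction
                       else "dispensable")
        spacer()
    for kind, bucket, n in (("pseudo", pseudo, cfg.n_pseudogenes),
                            ("is", is_el, cfg.n_is_elements)):
        for _ in range(n):
            n_nt = int(rng.integers(60, 150))
            s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_nt)])
            bucket.append((pos, pos + n_nt))
            parts.append(s)
            pos += n_nt
            spacer()
    return (GeneCatalog(genes, "".join(parts), pseudo, is_el,
                        source=f"synthetic(seed={cfg.seed})"),
            labels)


def diverged_copy(catalog: GeneCatalog, divergence: float,
                  rng: np.random.Generator,
                  id_prefix: str = "b") -> tuple[GeneCatalog, dict[str, str]]:
    """A second catalog with per-site point divergence, for BBH testing.

    Substitutions that would create an internal stop codon are skipped,
    so every copy remains a translatable CDS.  Returns the copy and the
    true a-id -> b-id mapping.
    """
    genome = list(catalog.genome)
    genes_b: list[GeneRecord] = []
    mapping: dict[str, str] = {}
    for g in catalog.genes:
        cds = list(g.cds)
        n_mut = rng.binomial(len(cds), divergence) if divergence > 0 else 0
        for pos in rng.choice(len(cds), size=n_mut, replace=False) if n_mut else []:
            pos = int(pos)
            alt = "ACGT"[rng.integers(4)]
            if alt == cds[pos]:
                continue
            old = cds[pos]
            cds[pos] = alt
            ci = pos // 3
            codon = "".join(cds[3 * ci:3 * ci + 3])
            if ci == 0 or (CODON_TO_AA[codon] == "*") != (
                    ci == len(cds) // 3 - 1):
                cds[pos] = old  # keep start codon and stop placement intact
        new_cds = "".join(cds)
        span = new_cds if g.strand == "+" else str(
            Seq(new_cds).reverse_complement())
        genome[g.start:g.end] = list(span)
        b_id = id_prefix + g.gene_id
        genes_b.append(GeneRecord(b_id, g.start, g.end, g.strand, new_cds,
                                  translate_cds(new_cds)))
        mapping[g.gene_id] = b_id
    return (GeneCatalog(genes_b, "".join(genome),
                        list(catalog.pseudogene_regions),
                        list(catalog.is_element_regions),
                        source=catalog.source + "+divergence"),
            mapping)


def _to_genomic_snps(gene: GeneRecord, member) -> list[SnpRecord]:
    snps = []
    for pos, alt in member:
        ref = gene.cds[pos]
        if gene.strand == "+":
            gpos, gref, galt = gene.start + pos, ref, alt
        else:
            gpos = gene.end - 1 - pos
            gref, galt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        syn = "synonymous" if _is_synonymous(gene.cds, pos, alt) \
            else "nonsynonymous"
        snps.append(SnpRecord(gpos, gref, galt, "cds", gene.gene_id, syn))
    return snps


def _is_synonymous(cds: str, pos: int, alt: str) -> bool:
    ci = pos // 3
    codon = cds[3 * ci:3 * ci + 3]
    mutated = codon[:pos % 3] + alt + codon[pos % 3 + 1:]
    return CODON_TO_AA[mutated] == CODON_TO_AA[codon]


def _nonsyn_candidates(cds: str, k: int, cap: int,
                       rng: np.random.Generator) -> list[tuple]:
    """Candidate protein-changing k-substitution sets (no stops created)."""
    singles = []
    for ci in range(1, len(cds) // 3 - 1):
        codon = cds[3 * ci:3 * ci + 3]
        for off in range(3):
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                mutated = codon[:off] + alt + codon[off + 1:]
                if CODON_TO_AA[mutated] not in ("*", CODON_TO_AA[codon]):
                    singles.append((3 * ci + off, alt))
    if k == 1:
        if len(singles) <= cap:
            return [(s,) for s in singles]
        idx = rng.choice(len(singles), size=cap, replace=False)
        return [(singles[int(i)],) for i in idx]
    out: set = set()
    budget = 50 * cap
    while len(out) < cap and budget:
        budget -= 1
        idx = rng.choice(len(singles), size=k, replace=False)
        cand = tuple(sorted(singles[int(i)] for i in idx))
        if len({p for p, _ in cand}) == k:
            out.add(cand)
    return sorted(out)


def plant_observed_mutations(catalog: GeneCatalog, labels: dict[str, str],
                             cfg: SyntheticConfig,
                             fold_cfg: FoldingConfig | None = None
                             ) -> tuple[list[SnpRecord], list[TruthRecord]]:
    """Plant one observed mutation set per selected gene.

    For each selected gene: draw k from the SNPs-per-gene distribution,
    build its synonymous null family, fold every member, draw
    q ~ Beta(1, theta_class), and emit the family member at rank
    ceil(q*N) of the |dMFE| ordering as genomic-coordinate SNPs.  Genes
    without enough synonymous sites are skipped and replaced.
    """
    fold_cfg = fold_cfg or FoldingConfig()
    rng = np.random.default_rng([cfg.seed, 1])
    by_class = {"essential": [], "dispensable": []}
    for g in catalog.genes:
        by_class[labels[g.gene_id]].append(g)
    chosen: list[tuple[GeneRecord, str, float]] = []
    for cls, n_want, theta in (
            ("essential", cfg.n_essential_mutated, cfg.theta_essential),
            ("dispensable", cfg.n_nonessential_mutated,
             cfg.theta_nonessential)):
        pool = by_class[cls]
        if len(pool) < n_want:
            raise ValueError(
                f"catalog has only {len(pool)} {cls} genes, need {n_want}")
        idx = rng.choice(len(pool), size=n_want, replace=False)
        chosen.extend((pool[int(i)], cls, theta) for i in idx)

    snps: list[SnpRecord] = []
    truth: list[TruthRecord] = []
    for gene, cls, theta in chosen:
        k = 1 + int(rng.choice(3, p=np.asarray(cfg.snps_per_gene)))
        n_syn_pos = len({p for p, _ in enumerate_synonymous_snvs(gene.cds)})
        k = min(k, max(1, n_syn_pos))
        family = build_mutant_family(
            gene.cds, k, cap=cfg.cap, rng=gene_rng(cfg.seed, gene.gene_id),
            gene_id=gene.gene_id)
        anc = fold_mfe_many([gene.cds], fold_cfg)[0]
        muts = fold_mfe_many(family.mutated_sequences(gene.cds), fold_cfg)
        deltas = np.array([abs_delta_mfe(anc, m).abs for m in muts])
        q = float(rng.beta(1.0, theta))
        if cfg.observed_synonymy == "nonsynonymous":
            cands = _nonsyn_candidates(gene.cds, k, cfg.cap,
                                       gene_rng(cfg.seed + 7, gene.gene_id))
            cmfe = fold_mfe_many(
                (apply_substitutions(gene.cds, c) for c in cands), fold_cfg)
            cdeltas = np.array([abs_delta_mfe(anc, m).abs for m in cmfe])
            order = np.argsort(cdeltas, kind="stable")
            rank = max(1, math.ceil(q * len(cands)))
            member = cands[int(order[rank - 1])]
            observed_delta = float(cdeltas[order[rank - 1]])
        else:
            order = np.argsort(deltas, kind="stable")
            rank = max(1, math.ceil(q * family.size))
            member = family.members[int(order[rank - 1])]
            observed_delta = float(deltas[order[rank - 1]])
        planted_pct = float(np.count_nonzero(deltas < observed_delta)
                            / family.size)
        snps.extend(_to_genomic_snps(gene, member))
        truth.append(TruthRecord(gene.gene_id, cls, theta, q,
                                 planted_pct, k))
    snps.sort(key=lambda s: s.position)
    return snps, truth


def write_fixture(catalog: GeneCatalog, snps, labels: dict[str, str],
                  truth, directory, fmt: str = "genbank") -> dict[str, Path]:
    """Write a complete on-disk fixture; round-trips through genome_io.

    Emits the genome (GenBank or FASTA + gene table), a 1-based SNP TSV,
    an essentiality TSV and a truth TSV; returns the path of each file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "genbank":
        record = SeqRecord(Seq(catalog.genome), id="SYNTH01",
                           name="SYNTH01", description="synthetic genome",
                           annotations={"molecule_type": "DNA"})
        for g in catalog.genes:
            record.features.append(SeqFeature(
                FeatureLocation(g.start, g.end,
                                strand=1 if g.strand == "+" else -1),
                type="CDS",
                qualifiers={"locus_tag": [g.gene_id],
                            "translation": [g.protein]}))
        for s, e in catalog.pseudogene_regions:
            record.features.append(SeqFeature(
                FeatureLocation(s, e, strand=1), type="gene",
                qualifiers={"pseudo": [""]}))
        for s, e in catalog.is_element_regions:
            record.features.append(SeqFeature(
                FeatureLocation(s, e, strand=1), type="mobile_element"))
        paths["genome"] = directory / "genome.gbk"
        SeqIO.write(record, str(paths["genome"]), "genbank")
    elif fmt == "fasta":
        paths["genome"] = directory / "genome.fasta"
        SeqIO.write(SeqRecord(Seq(catalog.genome), id="SYNTH01",
                              description="synthetic genome"),
                    str(paths["genome"]), "fasta")
        paths["gene_table"] = directory / "genes.tsv"
        with open(paths["gene_table"], "w") as fh:
            fh.write("gene_id\tstart\tend\tstrand\tkind\n")
            for g in catalog.genes:
                fh.write(f"{g.gene_id}\t{g.start + 1}\t{g.end}\t"
                         f"{g.strand}\tcds\n")
            for s, e in catalog.pseudogene_regions:
                fh.write(f".\t{s + 1}\t{e}\t+\tpseudogene\n")
            for s, e in catalog.is_element_regions:
                fh.write(f".\t{s + 1}\t{e}\t+\tis_element\n")
    else:
        raise ValueError(f"unknown fixture format {fmt!r}")

    paths["snps"] = directory / "snps.tsv"
    with open(paths["snps"], "w") as fh:
        fh.write("position\tref\talt\tgene_id\n")
        for s in snps:
            fh.write(f"{s.position + 1}\t{s.ref}\t{s.alt}\t{s.gene_id}\n")
    paths["essentiality"] = directory / "essentiality.tsv"
    with open(paths["essentiality"], "w") as fh:
        fh.write("gene_id\tlabel\n")
        for gid, label in labels.items():
            fh.write(f"{gid}\t{label}\n")
    paths["truth"] = directory / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tclass\ttheta\tplanted_quantile\t"
                 "planted_percentile\tk\n")
        for t in truth:
            fh.write(f"{t.gene_id}\t{t.essentiality}\t{t.theta}\t"
                     f"{t.planted_quantile:.6f}\t"
                     f"{t.planted_percentile:.6f}\t{t.k}\n")
    return paths
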