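"""Genome reading, SNP classification/filtering, strand handling."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from _oracles import is_synonymous_bruteforce
from foldsel.genome_io import (GeneCatalog, GeneRecord, SnpRecord, apply_snps,
                               classify_snp, classify_snps, filter_snps,
                               read_genome, read_snp_table, translate_cds)
from foldsel.synthetic import (SyntheticConfig, generate_catalog,
                               plant_observed_mutations, write_fixture)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _toy_catalog():
    """Two forward genes and one reverse gene on a hand-built genome."""
    g1 = "ATGGGCAAATAA"              # fwd at 5
    g2_cds = "ATGTTTCGCTAA"          # rev: genomic span is its revcomp
    g3 = "ATGCCTGATTAA"              # fwd
    genome = ("AAAAA" + g1 + "TTTT"
              + str(Seq(g2_cds).reverse_complement()) + "GGGG" + g3 + "CC")
    s2 = 5 + len(g1) + 4
    s3 = s2 + len(g2_cds) + 4
    genes = [
        GeneRecord("a", 5, 5 + len(g1), "+", g1, translate_cds(g1)),
        GeneRecord("b", s2, s2 + len(g2_cds), "-", g2_cds,
                   translate_cds(g2_cds)),
        GeneRecord("c", s3, s3 + len(g3), "+", g3, translate_cds(g3)),
    ]
    return GeneCatalog(genes, genome)


def test_reverse_gene_coding_orientation_roundtrip(tmp_path):
    cat = _toy_catalog()
    paths = write_fixture(cat, [], {g.gene_id: "dispensable" for g in cat},
                          [], tmp_path, fmt="genbank")
    cat2 = read_genome(paths["genome"])
    assert [g.gene_id for g in cat2] == ["a", "b", "c"]
    for g, g2 in zip(cat, cat2):
        assert (g2.cds, g2.strand, g2.start, g2.end) == \
            (g.cds, g.strand, g.start, g.end)
    b = cat2.get("b")
    span = cat2.genome[b.start:b.end]
    assert b.cds == str(Seq(span).reverse_complement())


def test_empty_annotation_gives_empty_catalog(tmp_path):
    cat = GeneCatalog([], "ACGT" * 30)
    paths = write_fixture(cat, [], {}, [], tmp_path, fmt="genbank")
    cat2 = read_genome(paths["genome"])
    assert len(cat2) == 0


def test_synthetic_fixture_roundtrip(tmp_path, small_catalog):
    catalog, labels, cfg = small_catalog
    for fmt in ("genbank", "fasta"):
        d = tmp_path / fmt
        paths = write_fixture(catalog, [], labels, [], d, fmt=fmt)
        cat2 = read_genome(paths["genome"], paths.get("gene_table"))
        assert cat2.genome == catalog.genome
        assert [(g.gene_id, g.start, g.end, g.strand, g.cds) for g in cat2] \
            == [(g.gene_id, g.start, g.end, g.strand, g.cds) for g in catalog]
        assert cat2.pseudogene_regions == catalog.pseudogene_regions
        assert cat2.is_element_regions == catalog.is_element_regions


def test_classify_forward_third_position_synonymous():
    cat = _toy_catalog()
    # gene a codon 2 is GGC (Gly); third position 5+5: C->T stays Gly
    (rec,) = classify_snp(10, "C", "T", cat)
    assert rec.region_class == "cds" and rec.gene_id == "a"
    assert rec.synonymy == "synonymous"


def test_classify_intergenic():
    cat = _toy_catalog()
    (rec,) = classify_snp(2, "A", "G", cat)
    assert rec.region_class == "intergenic"
    assert rec.synonymy == "not_applicable"
    assert rec.gene_id == ""


def test_classify_reverse_strand_uses_complemented_bases():
    cat = _toy_catalog()
    b = cat.get("b")
    # pick the genomic position of CDS index 4 (codon TTT, middle T)
    gpos = b.end - 1 - 4
    ref = COMP[b.cds[4]]
    for alt in "ACGT":
        if alt == ref:
            continue
        (rec,) = classify_snp(gpos, ref, alt, cat)
        expected = is_synonymous_bruteforce(b.cds, 4, COMP[alt])
        assert (rec.synonymy == "synonymous") == expected


def test_classify_agrees_with_translate_both_oracle_on_planted_snps():
    cfg = SyntheticConfig(n_genes=40, min_codons=20, max_codons=40,
                          n_essential_mutated=5, n_nonessential_mutated=25,
                          cap=30, seed=9)
    catalog, labels = generate_catalog(cfg)
    snps, _ = plant_observed_mutations(catalog, labels, cfg)
    checked = 0
    for snp in snps:
        recs = classify_snp(snp.position, snp.ref, snp.alt, catalog)
        for rec in recs:
            if rec.gene_id != snp.gene_id:
                continue
            gene = catalog.get(rec.gene_id)
            idx = gene.genomic_to_cds(snp.position)
            alt = snp.alt if gene.strand == "+" else COMP[snp.alt]
            expected = is_synonymous_bruteforce(gene.cds, idx, alt)
            assert (rec.synonymy == "synonymous") == expected
            checked += 1
    assert checked == len(snps)


def test_ref_mismatch_raises_with_position():
    cat = _toy_catalog()
    wrong = "G" if cat.genome[2] != "G" else "C"
    with pytest.raises(ValueError, match="position 3"):
        classify_snp(2, wrong, "A", cat)


def _snp_at(cat, pos, alt=None):
    ref = cat.genome[pos]
    if alt is None:
        alt = "A" if ref != "A" else "G"
    return pos, ref, alt


def test_filter_category_counts():
    cfg = SyntheticConfig(n_genes=6, min_codons=20, max_codons=30,
                          n_pseudogenes=1, n_is_elements=1, seed=5)
    catalog, _ = generate_catalog(cfg)
    rows = []
    # 2 intergenic (positions before the first gene)
    first = catalog.genes[0].start
    rows += [_snp_at(catalog, 1), _snp_at(catalog, first - 2)]
    rows.append(_snp_at(catalog, catalog.pseudogene_regions[0][0] + 3))
    rows.append(_snp_at(catalog, catalog.is_element_regions[0][0] + 3))
    for g in catalog.genes:  # 6 mid-gene CDS SNPs, clear of start codons
        rows.append(_snp_at(catalog, g.start + 10))
    records, mismatches = classify_snps(rows, catalog)
    assert not mismatches
    retained, report = filter_snps(records, catalog)
    counts = report["counts"]
    assert (counts["intergenic"], counts["pseudogene"],
            counts["is_element"]) == (2, 1, 1)
    assert len(retained) == 6 and counts["retained"] == 6
    assert all(r.region_class == "cds" for r in retained)
    assert all(any(g.gene_id == r.gene_id for g in catalog)
               for r in retained)


def test_start_codon_snp_excludes_whole_gene():
    cfg = SyntheticConfig(n_genes=4, min_codons=20, max_codons=30, seed=6)
    catalog, _ = generate_catalog(cfg)
    gene = catalog.genes[0]
    start_pos = gene.start if gene.strand == "+" else gene.end - 1
    rows = [_snp_at(catalog, start_pos), _snp_at(catalog, gene.start + 9),
            _snp_at(catalog, catalog.genes[1].start + 9)]
    records, _ = classify_snps(rows, catalog)
    retained, report = filter_snps(records, catalog)
    assert report["counts"]["start_codon_gene"] == 1
    assert {r.gene_id for r in retained} == {catalog.genes[1].gene_id}


def test_filter_empty_input():
    cat = _toy_catalog()
    retained, report = filter_snps([], cat)
    assert retained == []
    assert all(v == 0 for v in report["counts"].values())


def test_inconsistent_annotated_protein_excludes_gene():
    cat = _toy_catalog()
    bad = cat.get("a")
    bad.protein = "M" + "W" * (len(bad.protein) - 1)
    records, _ = classify_snps([_snp_at(cat, bad.start + 4)], cat)
    retained, report = filter_snps(records, cat)
    assert retained == [] and report["counts"]["gene_inconsistent"] == 1


def test_apply_snps_identity_strand_and_order():
    cat = _toy_catalog()
    a, b = cat.get("a"), cat.get("b")
    assert apply_snps(a, []) == a.cds
    # reverse-strand gene: genomic alt is complemented on the coding strand
    gpos = b.end - 1 - 4
    snp = SnpRecord(gpos, COMP[b.cds[4]], "C", "cds", "b")
    mutated = apply_snps(b, [snp])
    assert mutated[4] == "G" and mutated != b.cds
    snps3 = [SnpRecord(a.start + 3, a.cds[3], "C", "cds", "a"),
             SnpRecord(a.start + 4, a.cds[4], "A", "cds", "a"),
             SnpRecord(a.start + 7, a.cds[7], "T", "cds", "a")]
    results = {apply_snps(a, list(p)) for p in itertools.permutations(snps3)}
    assert len(results) == 1
    with pytest.raises(ValueError, match="duplicate"):
        apply_snps(a, [snps3[0], snps3[0]])


def test_read_snp_table(tmp_path):
    p = tmp_path / "snps.tsv"
    p.write_text("position\tref\talt\tgene_id\n10\tA\tG\tx\n")
    assert read_snp_table(p) == [(9, "A", "G")]
    bad = tmp_path / "bad.tsv"
    bad.write_text("pos\tref\talt\n1\tA\tG\n")
    with pytest.raises(ValueError, match="header"):
        read_snp_table(bad)
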