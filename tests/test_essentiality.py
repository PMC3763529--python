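"""Protein alignment, reciprocal best hits and label transfer."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from _oracles import sw_affine_score
from foldsel.essentiality import (AlignmentParams, align_proteins,
                                  bidirectional_best_hits,
                                  transfer_essentiality)
from foldsel.genome_io import GeneCatalog, GeneRecord
from foldsel.synthetic import SyntheticConfig, diverged_copy, generate_catalog

AAS = "ACDEFGHIKLMNPQRSTVWY"


def catalog_from_proteins(proteins: dict[str, str]) -> GeneCatalog:
    """Minimal catalog wrapper so BBH can run on bare protein sets."""
    genes, pos = [], 0
    for gid, prot in proteins.items():
        n = 3 * (len(prot) + 1)
        genes.append(GeneRecord(gid, pos, pos + n, "+", "A" * n, prot))
        pos += n
    return GeneCatalog(genes, "A" * pos)


def test_identical_sequences_score_is_diagonal_sum():
    rng = np.random.default_rng(0)
    prot = "".join(rng.choice(list(AAS), size=50))
    res = align_proteins(prot, prot)
    blosum = substitution_matrices.load("BLOSUM62")
    assert res.score == sum(blosum[a, a] for a in prot)
    assert res.identity == 1.0
    assert res.evalue is None


def test_one_substitution_in_100_gives_identity_099():
    rng = np.random.default_rng(1)
    prot = "".join(rng.choice(list(AAS), size=100))
    other = prot[:50] + ("L" if prot[50] != "L" else "I") + prot[51:]
    res = align_proteins(prot, other)
    assert res.identity == pytest.approx(0.99)


def test_score_matches_bruteforce_dp_on_short_pairs():
    rng = np.random.default_rng(2)
    for _ in range(25):
        a = "".join(rng.choice(list(AAS), size=rng.integers(3, 13)))
        b = "".join(rng.choice(list(AAS), size=rng.integers(3, 13)))
        assert align_proteins(a, b).score == pytest.approx(
            sw_affine_score(a, b))


def test_reverse_sequence_is_not_an_ortholog():
    rng = np.random.default_rng(0)
    prot = "".join(rng.choice(list(AAS), size=50))
    res = align_proteins(prot, prot[::-1])
    assert res.identity < 0.75


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_proteins("", "MKV")


def _random_proteins(rng, n, length=60):
    return ["".join(rng.choice(list(AAS), size=length)) for _ in range(n)]


def test_bbh_identity_mapping_and_symmetry():
    rng = np.random.default_rng(3)
    prots = _random_proteins(rng, 3)
    cat_a = catalog_from_proteins({f"a{i}": p for i, p in enumerate(prots)})
    cat_b = catalog_from_proteins({f"b{i}": p for i, p in enumerate(prots)})
    pairs = bidirectional_best_hits(cat_a, cat_b)
    assert {(p.gene_id_a, p.gene_id_b) for p in pairs} == \
        {("a0", "b0"), ("a1", "b1"), ("a2", "b2")}
    mirrored = bidirectional_best_hits(cat_b, cat_a)
    assert {(p.gene_id_b, p.gene_id_a) for p in mirrored} == \
        {(p.gene_id_a, p.gene_id_b) for p in pairs}
    ids = [p.gene_id_a for p in pairs] + [p.gene_id_b for p in pairs]
    assert len(set(ids)) == len(ids)  # each gene in at most one pair
    # self comparison returns the identity mapping
    self_pairs = bidirectional_best_hits(cat_a, cat_a)
    assert all(p.gene_id_a == p.gene_id_b for p in self_pairs)


def test_duplicated_paralog_tie_leaves_gene_unmapped():
    rng = np.random.default_rng(4)
    p1, p2 = _random_proteins(rng, 2)
    cat_a = catalog_from_proteins({"a1": p1, "a2": p2})
    cat_b = catalog_from_proteins({"b1": p1, "b1dup": p1, "b2": p2})
    pairs = bidirectional_best_hits(cat_a, cat_b)
    assert {(p.gene_id_a, p.gene_id_b) for p in pairs} == {("a2", "b2")}


def test_diverged_ortholog_fails_identity_cutoff():
    rng = np.random.default_rng(5)
    prots = _random_proteins(rng, 6, length=80)
    cat_a = catalog_from_proteins({f"a{i}": p for i, p in enumerate(prots)})
    diverged = list(prots[0])
    # half the residues changed, scattered so no conserved window survives
    for i in rng.choice(80, size=40, replace=False):
        choices = [c for c in AAS if c != diverged[i]]
        diverged[i] = choices[int(rng.integers(len(choices)))]
    b_prots = {"b0": "".join(diverged)}
    b_prots.update({f"b{i}": p for i, p in enumerate(prots) if i > 0})
    cat_b = catalog_from_proteins(b_prots)
    pairs = bidirectional_best_hits(cat_a, cat_b)
    assert len(pairs) == 5
    assert "a0" not in {p.gene_id_a for p in pairs}


def test_transfer_labels_and_unmapped():
    from foldsel.essentiality import OrthologPair
    cat = catalog_from_proteins({"a1": "MKV", "a2": "MLW", "a3": "MHH"})
    pairs = [OrthologPair("a1", "b1", 1.0), OrthologPair("a2", "b2", 1.0),
             OrthologPair("a3", "b3", 1.0)]
    transfer_essentiality(cat, pairs, {"b1": "essential", "b2": "dispensable"})
    assert [g.essentiality for g in cat] == \
        ["essential", "nonessential", "unknown"]
    transfer_essentiality(cat, [], {})
    assert all(g.essentiality == "unmapped" for g in cat)


def test_label_recovery_through_diverged_catalog():
    cfg = SyntheticConfig(n_genes=20, min_codons=30, max_codons=60, seed=8)
    catalog, labels = generate_catalog(cfg)
    rng = np.random.default_rng(8)
    catalog_b, mapping = diverged_copy(catalog, divergence=0.02, rng=rng)
    labels_b = {mapping[gid]: lab for gid, lab in labels.items()}
    pairs = bidirectional_best_hits(catalog, catalog_b)
    assert len(pairs) == 20  # mild divergence: everything still maps
    transfer_essentiality(catalog, pairs, labels_b)
    for g in catalog:
        want = {"essential": "essential",
                "dispensable": "nonessential"}[labels[g.gene_id]]
        assert g.essentiality == want


def test_zero_divergence_maps_everything(small_catalog):
    catalog, labels, _ = small_catalog
    rng = np.random.default_rng(0)
    catalog_b, mapping = diverged_copy(catalog, divergence=0.0, rng=rng)
    pairs = bidirectional_best_hits(catalog, catalog_b)
    assert {(p.gene_id_a, p.gene_id_b) for p in pairs} == set(mapping.items())
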