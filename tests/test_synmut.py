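"""Synonymous mutant enumeration, sampling spectra, ts/tv accounting."""

import itertools
import math

import numpy as np
import pytest

from _oracles import synonymous_snvs_bruteforce, translate
from foldsel.synmut import (SubstitutionSpectrum, SubstitutionType,
                            TRANSITIONS, apply_substitutions,
                            build_mutant_family, enumerate_synonymous_snvs,
                            sample_synonymous_mutant, substitution_type_of,
                            ts_tv_ratio)
from foldsel.synthetic import _random_cds


def test_enumerate_examples():
    assert enumerate_synonymous_snvs("ATGGGGTAA") == [
        (5, "A"), (5, "C"), (5, "T")]
    assert enumerate_synonymous_snvs("ATGTAA") == []
    with pytest.raises(ValueError):
        enumerate_synonymous_snvs("ATGGG")  # not a multiple of 3


@pytest.mark.parametrize("seed", range(5))
def test_enumerate_matches_bruteforce_translation_oracle(seed):
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, 30, gc=0.5)
    assert set(enumerate_synonymous_snvs(cds)) == \
        synonymous_snvs_bruteforce(cds)


def test_substitution_type_strand_symmetry_and_partition():
    assert substitution_type_of("C", "A") is SubstitutionType.CG_TO_AT
    assert substitution_type_of("G", "T") is SubstitutionType.CG_TO_AT
    assert substitution_type_of("A", "G") is SubstitutionType.AT_TO_GC
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = {t: 0 for t in SubstitutionType}
    for ref, alt in itertools.permutations("ACGT", 2):
        t = substitution_type_of(ref, alt)
        assert t is substitution_type_of(comp[ref], comp[alt])
        counts[t] += 1
    assert all(v == 2 for v in counts.values())  # 12 pairs, 6 classes
    with pytest.raises(ValueError):
        substitution_type_of("A", "A")
    with pytest.raises(ValueError):
        substitution_type_of("N", "A")


def test_sampling_two_available_types_long_run_frequency():
    # ATT (Ile) offers exactly ATT->ATC (AT->GC) and ATT->ATA (AT->TA)
    cds = "ATGATTTAA"
    rng = np.random.default_rng(0)
    n = 10_000
    hits = 0
    for _ in range(n):
        (pos, alt), = sample_synonymous_mutant(cds, 1, None, rng)
        assert pos == 5
        if substitution_type_of(cds[pos], alt) is SubstitutionType.AT_TO_GC:
            hits += 1
    sigma = math.sqrt(n * 0.25)
    assert abs(hits - n / 2) < 3 * sigma


def test_sampled_substitutions_have_distinct_positions_and_fixed_seed():
    cds = "ATG" + "GGGCTTAGAACC" * 6 + "TAA"
    rng = np.random.default_rng(7)
    for _ in range(200):
        subs = sample_synonymous_mutant(cds, 2, None, rng)
        assert len({p for p, _ in subs}) == 2
    fam1 = build_mutant_family(cds, 2, cap=40, seed=123, gene_id="g")
    fam2 = build_mutant_family(cds, 2, cap=40, seed=123, gene_id="g")
    assert fam1.members == fam2.members
    with pytest.raises(ValueError, match="synonymous positions"):
        sample_synonymous_mutant("ATGGGGTAA", 2, None, rng)


def test_family_modes_against_enumeration():
    fam = build_mutant_family("ATGGGGTAA", 1)
    assert fam.mode == "exhaustive" and fam.size == 3
    # pair families: exhaustive when the distinct-position pair count <= cap
    cds = "ATG" + "GGGCTT" * 4 + "TAA"
    singles = enumerate_synonymous_snvs(cds)
    pairs = [tuple(sorted(c)) for c in itertools.combinations(singles, 2)
             if len({p for p, _ in c}) == 2]
    fam2 = build_mutant_family(cds, 2, cap=len(pairs))
    assert fam2.mode == "exhaustive"
    assert sorted(fam2.members) == sorted(pairs)
    fam3 = build_mutant_family(cds, 2, cap=len(pairs) - 1, seed=5)
    assert fam3.mode == "sampled" and fam3.size == len(pairs) - 1
    assert len(set(fam3.members)) == fam3.size


@pytest.mark.parametrize("seed", range(3))
def test_every_family_member_preserves_the_protein(seed):
    rng = np.random.default_rng(seed)
    cds = _random_cds(rng, 40, gc=0.55)
    fam = build_mutant_family(cds, 2, cap=60, rng=rng, gene_id="g")
    ref = translate(cds)
    for mutant in fam.mutated_sequences(cds):
        assert translate(mutant) == ref


def test_pooled_achieved_spectrum_tracks_restricted_target():
    """Uniform target: each draw picks uniformly among the gene's
    available classes, so E[count of class t] = sum over draws of
    1/(number of classes available); observed counts stay within 3 sigma."""
    rng = np.random.default_rng(11)
    draws_per_gene = 20
    counts = {t: 0.0 for t in SubstitutionType}
    expected = {t: 0.0 for t in SubstitutionType}
    var = {t: 0.0 for t in SubstitutionType}
    for _ in range(100):
        cds = _random_cds(rng, 25, gc=0.5)
        snvs = enumerate_synonymous_snvs(cds)
        if not snvs:
            continue
        avail = {substitution_type_of(cds[p], a) for p, a in snvs}
        p_class = 1.0 / len(avail)
        for t in avail:
            expected[t] += draws_per_gene * p_class
            var[t] += draws_per_gene * p_class * (1 - p_class)
        for _ in range(draws_per_gene):
            (pos, alt), = sample_synonymous_mutant(cds, 1, None, rng, snvs)
            counts[substitution_type_of(cds[pos], alt)] += 1
    for t in SubstitutionType:
        assert abs(counts[t] - expected[t]) < 3 * math.sqrt(var[t]) + 1e-9


def test_ts_tv_ratio():
    assert ts_tv_ratio([("A", "G"), ("C", "T")]) == math.inf
    assert ts_tv_ratio([("A", "G"), ("A", "C")]) == 1.0
    with pytest.raises(ValueError):
        ts_tv_ratio([])
    # uniform over the 12 ordered pairs: 2 of 6 classes are transitions
    rng = np.random.default_rng(3)
    pairs = list(itertools.permutations("ACGT", 2))
    draws = [pairs[i] for i in rng.integers(0, 12, size=2000)]
    ratio = ts_tv_ratio(draws)
    assert ratio == pytest.approx(0.5, abs=0.08)


def test_tstv_distributions_of_matched_groups_do_not_differ():
    """Two gene groups generated under the same spectrum give a
    Mann-Whitney P that is not systematically small across seeds."""
    from foldsel.stats import mann_whitney_u
    low = 0
    n_seeds = 30
    for seed in range(n_seeds):
        rng = np.random.default_rng(1000 + seed)
        ratios = {0: [], 1: []}
        for grp in (0, 1):
            for _ in range(12):
                cds = _random_cds(rng, 25, gc=0.5)
                snvs = enumerate_synonymous_snvs(cds)
                if len({p for p, _ in snvs}) < 1:
                    continue
                subs = [sample_synonymous_mutant(cds, 1, None, rng, snvs)[0]
                        for _ in range(25)]
                ratios[grp].append(
                    min(ts_tv_ratio([(cds[p], a) for p, a in subs]), 100.0))
        _, p = mann_whitney_u(ratios[0], ratios[1])
        if p < 0.05:
            low += 1
    assert low <= 0.2 * n_seeds
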