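"""Diversity and divergence statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genescape.popgen_stats import (PairwiseDivergence, amova_phi_st,
                                    compute_species_estimates, gene_diversity,
                                    expected_heterozygosity,
                                    normalize_by_species_max,
                                    nucleotide_diversity, pairwise_fst,
                                    sequence_distance_matrix)
from genescape.io_formats import SequenceDataset


# ---------------------------------------------------------------------------
# oracles: independent brute-force enumerations


def oracle_gene_diversity(counts):
    """Fraction of ordered draw-two-without-replacement pairs that differ."""
    copies = [h for h, c in enumerate(counts) for _ in range(c)]
    pairs = [(i, j) for i in range(len(copies)) for j in range(len(copies))
             if i != j]
    return sum(copies[i] != copies[j] for i, j in pairs) / len(pairs)


def oracle_nucleotide_diversity(seqs):
    """Explicit loop over all pairs and sites with pairwise deletion."""
    diffs, lengths = [], []
    for a, b in itertools.combinations(seqs, 2):
        d = L = 0
        for x, y in zip(a, b):
            if x in "-N" or y in "-N":
                continue
            L += 1
            d += x != y
        diffs.append(d)
        lengths.append(L)
    return (sum(diffs) / len(diffs)) / (sum(lengths) / len(lengths))


def oracle_amova(dist, n_a, n_b):
    """Two-group AMOVA variance components from first principles."""
    n = n_a + n_b
    ssd_total = sum(dist[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ssd_a = sum(dist[i][j] for i in range(n_a) for j in range(i + 1, n_a)) / n_a
    ssd_b = sum(dist[i][j] for i in range(n_a, n)
                for j in range(i + 1, n)) / n_b
    ssd_within = ssd_a + ssd_b
    sigma_w = ssd_within / (n - 2)
    n_prime = (n - (n_a ** 2 + n_b ** 2) / n) / 1  # K - 1 = 1
    sigma_a = ((ssd_total - ssd_within) / 1 - sigma_w) / n_prime
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


# ---------------------------------------------------------------------------
# gene diversity


@pytest.mark.parametrize("counts,expected", [
    ([4], 0.0),            # monomorphic
    ([1, 1], 1.0),         # two copies, both unique
    ([2, 1, 1], 0.833333),
])
def test_gene_diversity_known_values(counts, expected):
    assert gene_diversity(counts) == pytest.approx(expected, abs=1e-6)
    assert gene_diversity(counts) == pytest.approx(
        oracle_gene_diversity(counts), abs=1e-12)


def test_gene_diversity_undefined_below_two_copies():
    assert math.isnan(gene_diversity([1]))


def test_gene_diversity_equifrequent_approaches_closed_form():
    """k equifrequent haplotypes: Hd -> 1 - 1/k as n grows."""
    for k in (2, 3, 5):
        n = 10 * k
        hd = gene_diversity([10] * k)
        limit = 1 - 1 / k
        assert abs(hd - limit) <= limit / (n - 1) + 1e-12


@given(st.lists(st.integers(1, 6), min_size=1, max_size=5))
def test_gene_diversity_matches_enumeration(counts):
    if sum(counts) < 2:
        return
    assert gene_diversity(counts) == pytest.approx(
        oracle_gene_diversity(counts), abs=1e-9)


def test_expected_heterozygosity_averages_loci():
    import pandas as pd
    table = pd.DataFrame({
        "individual_id": ["i1", "i1", "i2", "i2"],
        "locus_id": ["L1", "L2", "L1", "L2"],
        "allele_a": [1, 5, 1, 5],
        "allele_b": [2, 5, 1, 5],
    })
    # L1 alleles {1,2,1,1}: H = (4/3)(1 - (9+1)/16) = 0.5 ; L2 monomorphic: 0
    assert expected_heterozygosity(table, ["L1", "L2"]) == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# nucleotide diversity


def test_nucleotide_diversity_examples():
    assert nucleotide_diversity(["ACGT"] * 3) == 0.0
    seqs = ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAATT"]
    assert nucleotide_diversity(seqs) == pytest.approx((0 + 2 + 2) / 3 / 10)
    assert nucleotide_diversity(["AAAA", "TTTT"]) == 1.0


def test_nucleotide_diversity_pairwise_deletion():
    seqs = ["AC-T", "ACGT", "TCGN"]
    assert nucleotide_diversity(seqs) == pytest.approx(
        oracle_nucleotide_diversity(seqs))


def test_nucleotide_diversity_undefined_for_single_sequence():
    assert math.isnan(nucleotide_diversity(["ACGT"]))


# ---------------------------------------------------------------------------
# pairwise AMOVA Phi_ST


def test_fixed_difference_gives_one():
    assert pairwise_fst(["A", "A", "A"], ["T", "T", "T"],
                        "haplotype_identity") == pytest.approx(1.0)
    assert pairwise_fst(["AAA", "AAA"], ["TTT", "TTT"],
                        "molecular_distance") == pytest.approx(1.0)


def test_identical_populations_give_zero_after_clamp():
    raw = pairwise_fst(["AA", "AT", "AT"], ["AA", "AT", "AT"],
                       "haplotype_identity")
    assert max(raw, 0.0) == pytest.approx(0.0, abs=1e-12)


def test_two_population_amova_matches_oracle_example():
    pop_a, pop_b = ["X", "X", "Y"], ["Y", "Y", "Y"]
    d = [[0 if a == b else 1 for b in pop_a + pop_b] for a in pop_a + pop_b]
    expected = oracle_amova(d, 3, 3)
    got = pairwise_fst(pop_a, pop_b, "haplotype_identity")
    assert 0.0 < got < 1.0
    assert got == pytest.approx(expected, abs=1e-12)


def test_amova_random_instances_match_oracle(rng):
    """Random small populations (<=8 copies, <=4 haplotypes), both modes."""
    haplotypes = ["AAAA", "AATA", "TTAA", "TTTT"]
    for _ in range(100):
        n_a, n_b = rng.integers(2, 5, size=2)
        pop_a = [haplotypes[i] for i in rng.integers(0, 4, n_a)]
        pop_b = [haplotypes[i] for i in rng.integers(0, 4, n_b)]
        for mode in ("haplotype_identity", "molecular_distance"):
            d = sequence_distance_matrix(pop_a, pop_b, mode)
            expected = oracle_amova(d.tolist(), len(pop_a), len(pop_b))
            got = pairwise_fst(pop_a, pop_b, mode)
            assert got == pytest.approx(expected, abs=1e-9)


def test_amova_requires_two_copies_each_side():
    with pytest.raises(ValueError):
        amova_phi_st(np.zeros((3, 3)), 1, 2)


# ---------------------------------------------------------------------------
# orchestration and normalization


def test_species_estimates_counts():
    alignment = {f"p{i}": ["ACGT", "ACGA", "TCGT"] for i in range(10)}
    ds = SequenceDataset("sp", "cpDNA", alignment)
    within, pairwise = compute_species_estimates(ds)
    assert len(within) == 10
    n_off_diagonal = np.count_nonzero(~np.eye(10, dtype=bool))
    assert pairwise.matrix.shape == (10, 10) and n_off_diagonal == 90


def test_all_identical_populations_give_all_zero():
    alignment = {f"p{i}": ["ACGT", "ACGT"] for i in range(10)}
    within, pairwise = compute_species_estimates(ds := SequenceDataset("sp", "m", alignment))
    assert all(w.gene_diversity == 0 and w.sequence_diversity == 0 for w in within)
    assert np.allclose(pairwise.matrix, 0.0)


def test_normalize_examples():
    vals = np.array([2.0, 4.0, 8.0])
    from genescape.popgen_stats import _normalize
    assert np.allclose(_normalize(vals), [0.25, 0.5, 1.0])
    assert np.allclose(_normalize(np.zeros(3)), 0.0)
    assert _normalize(vals).max() == 1.0


@given(st.floats(0.1, 100.0))
def test_normalization_scale_invariance(c):
    vals = np.array([0.1, 0.4, 0.7, 0.2])
    from genescape.popgen_stats import _normalize
    assert np.allclose(_normalize(vals * c), _normalize(vals), atol=1e-12)


def test_clamping_preserves_order_of_nonclamped_pairs():
    pops = ["a", "b", "c"]
    raw = np.array([[0.0, 0.3, 0.7], [0.3, 0.0, -0.1], [0.7, -0.1, 0.0]])
    pd_ = PairwiseDivergence("sp", "m", pops, raw, "haplotype_identity")
    assert pd_.matrix[0, 2] > pd_.matrix[0, 1] > pd_.matrix[1, 2] == 0.0
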