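"""Relaxed-Hamming matching and the positional polymorphism matrix."""

from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from censat.kmer_core import (
    SatelliteConsensus,
    consensus_kmer_set,
    count_library,
    reverse_complement,
)
from censat.polymorphism import (
    build_polymorphism_matrix,
    default_h_max,
    hamming,
    match_relaxed,
    motif_report,
    variable_sites,
)
from censat.simulate import ArraySpec, ReadSimSpec, simulate_array, simulate_reads


def test_hamming_examples():
    assert hamming("ACGT", "ACGT") == 0
    assert hamming("AAAA", "TTTT") == 4
    with pytest.raises(ValueError):
        hamming("AC", "ACG")


@settings(derandomize=True, max_examples=200)
@given(a=st.text("ACGT", min_size=1, max_size=31), data=st.data())
def test_hamming_matches_character_oracle(a, data):
    b = data.draw(st.text("ACGT", min_size=len(a), max_size=len(a)))
    assert hamming(a, b) == sum(x != y for x, y in zip(a, b))


def test_default_h_max_anchors():
    assert default_h_max(15) == 2
    assert default_h_max(31) == 5


class TestMatchRelaxed:
    def test_exact_window_single_position(self, consensus):
        cks = consensus_kmer_set(consensus, 15)
        kmer = consensus.sequence[4:19]
        m = match_relaxed(kmer, cks, h_max=2)
        assert m.best_distance == 0
        assert m.positions == [(5, "+")]
        assert m.weight_share == 1.0

    def test_one_substitution_accepted(self, consensus):
        cks = consensus_kmer_set(consensus, 15)
        kmer = list(consensus.sequence[4:19])
        kmer[7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[kmer[7]]
        m = match_relaxed("".join(kmer), cks, h_max=2)
        assert m.best_distance == 1 and (5, "+") in m.positions

    def test_reverse_complement_orientation_recorded(self, consensus):
        cks = consensus_kmer_set(consensus, 15)
        m = match_relaxed(reverse_complement(consensus.sequence[4:19]), cks, h_max=2)
        assert m.best_distance == 0 and m.positions == [(5, "-")]

    def test_distant_kmer_unmatched(self, consensus):
        cks = consensus_kmer_set(consensus, 15)
        assert match_relaxed("A" * 15, cks, h_max=2) is None

    def test_neighborhood_size_991_by_enumeration(self):
        """|{w : hamming(w, x) <= 2}| = sum_i C(15,i) 3^i = 991 for 15-mers."""
        x = "ACGTACGTACGTACG"
        closed_form = sum(
            __import__("math").comb(15, i) * 3**i for i in range(3)
        )
        neighborhood = set()
        for h in range(3):
            for pos in combinations(range(15), h):
                for subs in product("ACGT", repeat=h):
                    w = list(x)
                    ok = True
                    for p, b in zip(pos, subs):
                        if w[p] == b:
                            ok = False
                            break
                        w[p] = b
                    if ok:
                        neighborhood.add("".join(w))
        assert closed_form == 991
        assert len(neighborhood) == 991
        assert all(hamming(w, x) <= 2 for w in neighborhood)


class TestMatrix:
    def test_toy_matrix_matches_bruteforce_oracle(self):
        """Hand-built k-mer frequencies tally exactly as the triple loop does."""
        cons = SatelliteConsensus("toy", "ACGTTGCA", circular=True)
        cks = consensus_kmer_set(cons, 4)
        freqs = {
            "ACGT": 10.0,  # exact at position 1
            "ACGA": 4.0,  # one substitution at offset 3 of position 1
            "TTGC": 6.0,  # exact at position 5
        }
        matrix = build_polymorphism_matrix(freqs, cks, h_max=1)
        L, k = cons.length, 4
        oracle = np.zeros((4, L))
        base_idx = {b: i for i, b in enumerate("ACGT")}
        for kmer, f in freqs.items():
            m = match_relaxed(kmer, cks, h_max=1)
            for start, orient in m.positions:
                aligned = kmer if orient == "+" else reverse_complement(kmer)
                for off in range(k):
                    col = (start - 1 + off) % L
                    oracle[base_idx[aligned[off]], col] += f * m.weight_share
        support = oracle.sum(axis=0)
        expected = np.where(support > 0, oracle / np.where(support > 0, support, 1), 0)
        np.testing.assert_allclose(matrix.probs, expected, atol=1e-12)
        sums = matrix.probs.sum(axis=0)
        assert np.allclose(sums[matrix.supporting_weight > 0], 1.0)

    def test_unmutated_array_has_zero_nonconsensus(self, consensus):
        arr, _ = simulate_array(ArraySpec(consensus=consensus, copies=100, seed=301))
        reads, _ = simulate_reads(arr, ReadSimSpec(depth=10, read_length=100, seed=302))
        lib = count_library(reads, 31)
        cks = consensus_kmer_set(consensus, 31)
        matrix = build_polymorphism_matrix(lib, cks)
        assert matrix.nonconsensus.max() == pytest.approx(0.0, abs=1e-9)
        assert variable_sites(matrix) == []

    def test_planted_biallelic_site_recovered(self, consensus):
        alt = "A" if consensus.sequence[74] != "A" else "C"
        arr, _ = simulate_array(
            ArraySpec(
                consensus=consensus,
                copies=400,
                shared_variants=[(75, alt, 0.5)],
                seed=303,
            )
        )
        reads, _ = simulate_reads(arr, ReadSimSpec(depth=15, read_length=100, seed=304))
        lib = count_library(reads, 31)
        cks = consensus_kmer_set(consensus, 31)
        matrix = build_polymorphism_matrix(lib, cks)
        nonc = matrix.nonconsensus
        assert nonc[74] == pytest.approx(0.50, abs=0.05)
        assert np.delete(nonc, 74).max() < 0.05
        assert variable_sites(matrix) == [75]
        assert variable_sites(matrix, threshold=0.0) == list(range(1, 121))
        # column stochasticity
        sums = matrix.probs.sum(axis=0)
        assert np.allclose(sums[matrix.supporting_weight > 0], 1.0, atol=1e-9)

    def test_empty_match_warns(self, consensus):
        cks = consensus_kmer_set(consensus, 31)
        with pytest.warns(UserWarning, match="matrix is empty"):
            matrix = build_polymorphism_matrix({"A" * 31: 5.0}, cks, h_max=2)
        assert matrix.probs.sum() == 0

    def test_nonconsensus_tracks_cdi_scaled(self, consensus):
        """2 * mean(nonconsensus) * L approximates the CDI on i.i.d. fixtures."""
        from censat.cdi import centromere_diversity_index, map_reads

        p = 0.05
        arr, _ = simulate_array(
            ArraySpec(consensus=consensus, copies=250, substitution_rate=p, seed=305)
        )
        reads, _ = simulate_reads(arr, ReadSimSpec(depth=12, read_length=100, seed=306))
        lib = count_library(reads, 31)
        cks = consensus_kmer_set(consensus, 31)
        matrix = build_polymorphism_matrix(lib, cks)
        alignments, _ = map_reads(reads, consensus)
        cdi = centromere_diversity_index(alignments, consensus, seed=0).cdi
        proxy = 2 * matrix.nonconsensus.mean() * consensus.length
        assert abs(proxy - cdi) / cdi < 0.25


class TestMotifReport:
    def test_window_size_and_flags(self, consensus):
        arr, _ = simulate_array(ArraySpec(consensus=consensus, copies=50, seed=307))
        reads, _ = simulate_reads(arr, ReadSimSpec(depth=8, read_length=100, seed=308))
        lib = count_library(reads, 31)
        matrix = build_polymorphism_matrix(lib, consensus_kmer_set(consensus, 31))
        report = motif_report(matrix)  # default window 62..78
        assert len(report) == 17
        assert report["position"].tolist() == list(range(62, 79))
        assert set(report.loc[report["flagged"], "position"]) == {75, 78}
        assert (report["nonconsensus"] == 0).all()
        with pytest.raises(ValueError):
            motif_report(matrix, 100, 130)

    def test_planted_variant_at_75_is_flagged_with_frequency(self, consensus):
        alt = "A" if consensus.sequence[74] != "A" else "C"
        arr, _ = simulate_array(
            ArraySpec(
                consensus=consensus, copies=300, shared_variants=[(75, alt, 0.45)], seed=309
            )
        )
        reads, _ = simulate_reads(arr, ReadSimSpec(depth=12, read_length=100, seed=310))
        lib = count_library(reads, 31)
        matrix = build_polymorphism_matrix(lib, consensus_kmer_set(consensus, 31))
        report = motif_report(matrix)
        row = report[report["position"] == 75].iloc[0]
        assert row["flagged"]
        assert row["nonconsensus"] == pytest.approx(0.45, abs=0.05)
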