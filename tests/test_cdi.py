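"""Consensus mapping and the Centromere Diversity Index."""

import itertools

import numpy as np
import pytest

from censat.cdi import (
    centromere_diversity_index,
    map_read_to_consensus,
    map_reads,
    mapped_fraction,
    pairwise_difference,
)
from censat.kmer_core import SatelliteConsensus, reverse_complement
from censat.simulate import (
    ArraySpec,
    ReadSimSpec,
    default_consensus,
    random_sequence,
    simulate_array,
    simulate_reads,
)


class TestMapping:
    def test_exact_subread_maps_forward(self, consensus):
        read = consensus.sequence[9:109]  # positions 10..109, 1-based
        aln = map_read_to_consensus(("r", read), consensus)
        assert (aln.strand, aln.start, aln.identity) == ("+", 10, 1.0)
        assert aln.oriented_sequence == read

    def test_reverse_complement_maps_minus_same_start(self, consensus):
        read = consensus.sequence[9:109]
        aln = map_read_to_consensus(("r", reverse_complement(read)), consensus)
        assert (aln.strand, aln.start, aln.identity) == ("-", 10, 1.0)
        assert aln.oriented_sequence == read

    def test_junction_spanning_read_maps_on_circular_consensus(self, consensus):
        read = consensus.sequence[100:] + consensus.sequence[:30]
        aln = map_read_to_consensus(("r", read), consensus)
        assert (aln.start, aln.identity) == (101, 1.0)

    def test_random_reads_do_not_map(self):
        cons = SatelliteConsensus("rand", random_sequence(120, seed=901))
        reads = [("r%d" % i, random_sequence(100, seed=910 + i)) for i in range(100)]
        alignments, total = map_reads(reads, cons)
        assert total == 100 and len(alignments) == 0

    def test_ambiguous_satellite_tie_is_unmapped(self, consensus):
        twin = SatelliteConsensus("twin", consensus.sequence)
        read = consensus.sequence[0:80]
        assert map_read_to_consensus(("r", read), [consensus, twin]) is None

    def test_overlong_read_rejected(self, consensus):
        with pytest.raises(ValueError, match="2L"):
            map_read_to_consensus(("r", "A" * 250), consensus)


class TestPairwiseDifference:
    def _aln(self, seq, start=1, strand="+", name="satA"):
        from censat.cdi import ConsensusAlignment

        return ConsensusAlignment(
            read_id="r", satellite_name=name, strand=strand, start=start,
            identity=1.0, aligned_span=len(seq), oriented_sequence=seq,
        )

    def test_identical_reads_zero(self):
        a = self._aln("ACGT" * 30)
        assert pairwise_difference(a, a, L=120) == 0.0

    def test_full_overlap_counts_raw_mismatches(self):
        x = "A" * 120
        y = "A" * 50 + "C" + "A" * 30 + "C" + "A" * 20 + "C" + "A" * 17
        assert pairwise_difference(self._aln(x), self._aln(y), L=120) == 3.0

    def test_partial_overlap_rescales_to_unit_length(self):
        x = "A" * 60
        y = "C" * 3 + "A" * 57 + "G" * 60  # 3 mismatches in the 60-bp overlap
        d = pairwise_difference(self._aln(x), self._aln(y), L=120)
        assert d == pytest.approx(6.0)  # 3 * 120/60

    def test_short_overlap_skipped_and_preconditions(self):
        assert pairwise_difference(self._aln("A" * 10), self._aln("A" * 10), L=120) is None
        with pytest.raises(ValueError):
            pairwise_difference(self._aln("A" * 60), self._aln("A" * 60, start=2), L=120)


def _array_reads(consensus, copies, rate, seed, depth=15):
    arr, _ = simulate_array(
        ArraySpec(consensus=consensus, copies=copies, substitution_rate=rate, seed=seed)
    )
    reads, _ = simulate_reads(
        arr, ReadSimSpec(depth=depth, read_length=100, seed=seed + 1)
    )
    return reads


class TestCDI:
    def test_zero_heterogeneity_gives_zero_cdi(self, consensus):
        reads = _array_reads(consensus, copies=100, rate=0.0, seed=201, depth=5)
        alignments, _ = map_reads(reads, consensus)
        r = centromere_diversity_index(alignments, consensus, seed=0)
        assert r.cdi == 0.0

    def test_matches_bruteforce_all_pairs(self, consensus):
        """Uncapped CDI equals an independent all-pairs loop on 50 reads."""
        reads = _array_reads(consensus, copies=50, rate=0.05, seed=203, depth=2)[:50]
        alignments, _ = map_reads(reads, consensus)
        r = centromere_diversity_index(
            alignments, consensus, pairs_per_position_cap=None, seed=0
        )
        total, n = 0.0, 0
        for a, b in itertools.combinations(alignments, 2):
            if (a.strand, a.start) != (b.strand, b.start):
                continue
            ov = min(len(a.oriented_sequence), len(b.oriented_sequence))
            if ov < 30:
                continue
            mism = sum(
                x != y
                for x, y in zip(a.oriented_sequence[:ov], b.oriented_sequence[:ov])
            )
            total += mism * consensus.length / ov
            n += 1
        assert n == r.n_pairs
        assert r.cdi == pytest.approx(total / n)

    def test_analytic_expectation_under_iid_substitutions(self, consensus):
        """E[CDI] ~= 2 L p (1-p) for per-copy i.i.d. substitution rate p."""
        p = 0.05
        reads = _array_reads(consensus, copies=250, rate=p, seed=205, depth=12)
        alignments, _ = map_reads(reads, consensus)
        r = centromere_diversity_index(alignments, consensus, seed=0)
        expected = 2 * consensus.length * p * (1 - p)
        assert abs(r.cdi - expected) / expected < 0.15

    def test_invariant_to_global_reverse_complement(self, consensus):
        reads = _array_reads(consensus, copies=60, rate=0.05, seed=207, depth=4)
        rc_reads = [(rid, reverse_complement(s)) for rid, s in reads]
        r1 = centromere_diversity_index(
            map_reads(reads, consensus)[0], consensus, pairs_per_position_cap=None
        )
        r2 = centromere_diversity_index(
            map_reads(rc_reads, consensus)[0], consensus, pairs_per_position_cap=None
        )
        assert r1.cdi == pytest.approx(r2.cdi)
        assert r1.n_pairs == r2.n_pairs

    def test_sequencing_error_inflates_cdi_by_2Le(self, consensus):
        """Adding per-base error e adds ~2 L e(1-e) expected differences."""
        p, e = 0.02, 0.01
        arr, _ = simulate_array(
            ArraySpec(consensus=consensus, copies=250, substitution_rate=p, seed=209)
        )
        cdis = {}
        for err in (0.0, e):
            reads, _ = simulate_reads(
                arr,
                ReadSimSpec(depth=12, read_length=100, per_base_error_rate=err, seed=210),
            )
            alignments, _ = map_reads(reads, consensus)
            cdis[err] = centromere_diversity_index(alignments, consensus, seed=0).cdi
        inflation = cdis[e] - cdis[0.0]
        expected = 2 * consensus.length * e * (1 - e)
        assert abs(inflation - expected) / expected < 0.35

    def test_no_eligible_pairs_is_an_error(self, consensus):
        read = consensus.sequence[0:100]
        alignments, _ = map_reads([("solo", read)], consensus)
        with pytest.raises(ValueError, match="no eligible"):
            centromere_diversity_index(alignments, consensus)

    def test_cdi_bounded_by_unit_length(self, consensus):
        reads = _array_reads(consensus, copies=100, rate=0.15, seed=211, depth=8)
        alignments, _ = map_reads(reads, consensus, min_identity=0.6)
        r = centromere_diversity_index(alignments, consensus, seed=0)
        assert 0 <= r.cdi <= consensus.length


class TestMappedFraction:
    def test_array_only_reads_all_map(self, consensus):
        reads = _array_reads(consensus, copies=80, rate=0.0, seed=213, depth=3)
        frac = mapped_fraction(reads, consensus)
        assert frac[consensus.name] > 0.99

    def test_absent_satellite_maps_nothing(self):
        cons = default_consensus()
        other = SatelliteConsensus("other", random_sequence(120, seed=990))
        reads = _array_reads(cons, copies=50, rate=0.0, seed=215, depth=2)
        frac = mapped_fraction(reads, [other])
        assert frac["other"] == 0.0

    def test_mixture_fraction_tracks_composition(self, consensus):
        sat = _array_reads(consensus, copies=50, rate=0.0, seed=217, depth=4)
        bg = random_sequence(6000, seed=991)
        bg_reads, _ = simulate_reads(bg, ReadSimSpec(depth=4, read_length=100, seed=992))
        n = min(len(sat), len(bg_reads))
        frac = mapped_fraction(sat[:n] + bg_reads[:n], consensus)
        assert frac[consensus.name] == pytest.approx(0.5, abs=0.05)

    def test_zero_reads_error(self, consensus):
        with pytest.raises(ValueError):
            mapped_fraction([], consensus)


def test_wild_like_fixture_has_higher_cdi_and_fewer_copies(scenario_bundles):
    """High-heterogeneity/low-copy vs low-heterogeneity/high-copy contrast."""
    results = {}
    cons = default_consensus()
    for name in ("inbred_like", "wild_like"):
        bundle = scenario_bundles[name]
        # map only array-derived reads for speed: background reads never map
        alignments, _ = map_reads(bundle.reads, cons)
        r = centromere_diversity_index(alignments, cons, seed=1)
        results[name] = (r.cdi, bundle.array_spec.copies)
    assert results["wild_like"][0] > results["inbred_like"][0]
    assert results["wild_like"][1] < results["inbred_like"][1]
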