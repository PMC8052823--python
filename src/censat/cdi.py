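"""Consensus-anchored read mapping and the Centromere Diversity Index (CDI).

The CDI quantifies sequence heterogeneity among copies of a tandem
satellite within one genome: reads are mapped onto the repeat-unit
consensus, partitioned by satellite, strand, and mapped start position
(strand partitioning prevents comparing a sequence to its own reverse
complement), and every pair of reads anchored at the same position is
compared. With d_ij the number of observed differences between reads i and
j (rescaled to the repeat-unit length L), the CDI is the average of d_ij
over all N eligible pairs, summed across strands and positions:

    CDI = sum_strand sum_position sum_ij d_ij / N

so a CDI of 17 on the 120-bp minor satellite means two randomly drawn
repeat copies differ at ~17 of 120 sites (~14% divergence).

Mapping is a deliberately simple ungapped best-identity scan of the read
and its reverse complement against the circularized consensus: the
mismatch-count definition of d_ij has no use for gapped alignment, and
indel contributions are ignored throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from censat.kmer_core import SatelliteConsensus, reverse_complement

DEFAULT_MIN_IDENTITY = 0.8
DEFAULT_MIN_OVERLAP = 30
DEFAULT_PAIRS_PER_POSITION_CAP = 200


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@dataclass
class ConsensusAlignment:
    """Best ungapped placement of one read on a satellite consensus."""

    read_id: str
    satellite_name: str
    strand: str  # '+' or '-'
    start: int  # 1-based position on the consensus (modulo L for circular)
    identity: float
    aligned_span: int
    oriented_sequence: str = field(repr=False, default="")


class _ConsensusIndex:
    """Tiled, encoded consensus for vectorized ungapped scanning."""

    def __init__(self, consensus: SatelliteConsensus):
        self.consensus = consensus
        self.L = consensus.length
        self._tiled_cache: dict[int, np.ndarray] = {}

    def _tiled(self, read_len: int) -> np.ndarray:
        if read_len not in self._tiled_cache:
            if self.consensus.circular:
                reps = read_len // self.L + 2
                seq = self.consensus.sequence * reps
            else:
                seq = self.consensus.sequence
            self._tiled_cache[read_len] = _encode(seq)
        return self._tiled_cache[read_len]

    def scan(self, read: np.ndarray) -> tuple[int, float]:
        """Best (leftmost) 0-based start and identity for an encoded read."""
        m = read.size
        tiled = self._tiled(m)
        if tiled.size < m:
            return 0, 0.0
        windows = np.lib.stride_tricks.sliding_window_view(tiled, m)
        n_starts = min(self.L, windows.shape[0]) if self.consensus.circular else windows.shape[0]
        matches = (windows[:n_starts] == read).sum(axis=1)
        best = int(np.argmax(matches))  # argmax returns the leftmost maximum
        return best, matches[best] / m


def map_read_to_consensus(
    read: str | tuple[str, str],
    consensuses: Sequence[SatelliteConsensus] | SatelliteConsensus,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    *,
    _indexes: dict | None = None,
) -> ConsensusAlignment | None:
    """Ungapped best-hit placement of a read against satellite consensuses.

    The read and its reverse complement are scanned against the
    circularized consensus of each satellite; the best hit by identity
    wins. Hits below ``min_identity`` are unmapped; equal-identity ties
    between satellites are ambiguous and unmapped; position ties resolve
    leftmost; strand ties resolve to '+'. The reported strand is the read's
    orientation relative to the consensus, and ``oriented_sequence`` is the
    read expressed on the consensus strand.
    """
    if isinstance(consensuses, SatelliteConsensus):
        consensuses = [consensuses]
    if isinstance(read, tuple):
        read_id, seq = read
    else:
        read_id, seq = "", read
    seq = seq.upper()
    if any(c not in "ACGT" for c in seq):
        return None
    best: ConsensusAlignment | None = None
    best_identity = -1.0
    tie_between_satellites = False
    fwd = _encode(seq)
    rev = _encode(reverse_complement(seq))
    for cons in consensuses:
        if len(seq) > 2 * cons.length:
            raise ValueError(
                f"read length {len(seq)} exceeds 2L={2 * cons.length}; window long reads"
            )
        if _indexes is not None:
            index = _indexes.setdefault(cons.name, _ConsensusIndex(cons))
        else:
            index = _ConsensusIndex(cons)
        hit = None
        # '+' evaluated first, so a strand tie resolves to '+'
        for strand, arr, oriented in (("+", fwd, seq), ("-", rev, reverse_complement(seq))):
            start0, identity = index.scan(arr)
            if hit is None or identity > hit.identity:
                hit = ConsensusAlignment(
                    read_id=read_id,
                    satellite_name=cons.name,
                    strand=strand,
                    start=start0 + 1,
                    identity=identity,
                    aligned_span=len(seq),
                    oriented_sequence=oriented,
                )
        assert hit is not None
        if hit.identity > best_identity:
            best = hit
            best_identity = hit.identity
            tie_between_satellites = False
        elif hit.identity == best_identity and best is not None and (
            hit.satellite_name != best.satellite_name
        ):
            tie_between_satellites = True
    if best is None or best.identity < min_identity:
        return None
    if tie_between_satellites:
        return None  # ambiguous between satellites
    return best


def map_reads(
    reads: Iterable[tuple[str, str]],
    consensuses: Sequence[SatelliteConsensus] | SatelliteConsensus,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[ConsensusAlignment], int]:
    """Map many reads; returns (alignments, total_read_count)."""
    if isinstance(consensuses, SatelliteConsensus):
        consensuses = [consensuses]
    indexes: dict = {}
    alignments = []
    total = 0
    for read in reads:
        total += 1
        aln = map_read_to_consensus(
            read, consensuses, min_identity, _indexes=indexes
        )
        if aln is not None:
            alignments.append(aln)
    return alignments, total


def mapped_fraction(
    reads: Sequence[tuple[str, str]],
    consensuses: Sequence[SatelliteConsensus] | SatelliteConsensus,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> dict[str, float]:
    """Fraction of reads mapping to each satellite consensus."""
    if isinstance(consensuses, SatelliteConsensus):
        consensuses = [consensuses]
    alignments, total = map_reads(reads, consensuses, min_identity)
    if total == 0:
        raise ValueError("mapped fraction undefined for zero reads")
    out = {c.name: 0 for c in consensuses}
    for aln in alignments:
        out[aln.satellite_name] += 1
    return {name: n / total for name, n in out.items()}


def pairwise_difference(
    a: ConsensusAlignment,
    b: ConsensusAlignment,
    L: int,
    *,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    rescale: bool = True,
) -> float | None:
    """Observed differences d_ij between two co-anchored reads.

    Both reads must share satellite, strand, and start position. Mismatches
    are counted over the overlapping span and, by default, rescaled to the
    repeat-unit length: d_ij = mismatches * L / overlap, making the CDI a
    per-repeat-unit quantity comparable across read lengths. Pairs with
    overlap below ``min_overlap`` are skipped (returns None).
    """
    if (
        a.satellite_name != b.satellite_name
        or a.strand != b.strand
        or a.start != b.start
    ):
        raise ValueError(
            "pairwise difference requires same satellite, strand and start"
        )
    overlap = min(len(a.oriented_sequence), len(b.oriented_sequence))
    if overlap < min_overlap:
        return None
    x = _encode(a.oriented_sequence[:overlap])
    y = _encode(b.oriented_sequence[:overlap])
    mismatches = int((x != y).sum())
    if rescale:
        return mismatches * L / overlap
    return float(mismatches)


@dataclass
class CDIResult:
    """Centromere Diversity Index for one sample x satellite."""

    sample_id: str
    satellite_name: str
    cdi: float  # average pairwise differences per repeat-unit length L
    n_pairs: int
    pairs_per_position_cap: int | None
    per_strand: dict[str, float]  # strand -> mean d_ij on that strand


def centromere_diversity_index(
    alignments: Sequence[ConsensusAlignment],
    satellite: SatelliteConsensus,
    *,
    sample_id: str = "",
    pairs_per_position_cap: int | None = DEFAULT_PAIRS_PER_POSITION_CAP,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    rescale: bool = True,
    seed: int = 0,
) -> CDIResult:
    """Average pairwise differences among co-anchored satellite reads.

    Reads are grouped by (strand, start); within each group all pairs are
    compared, except that groups whose pair count exceeds
    ``pairs_per_position_cap`` are subsampled to the cap (seeded) for
    tractability. The CDI is the grand mean of d_ij over all N eligible
    pairs. Raises if no eligible pairs exist.
    """
    L = satellite.length
    groups: dict[tuple[str, int], list[ConsensusAlignment]] = {}
    for aln in alignments:
        if aln.satellite_name != satellite.name:
            continue
        groups.setdefault((aln.strand, aln.start), []).append(aln)
    rng = np.random.default_rng(seed)
    total = 0.0
    n_pairs = 0
    strand_sum = {"+": 0.0, "-": 0.0}
    strand_n = {"+": 0, "-": 0}
    for (strand, _start), members in sorted(groups.items()):
        m = len(members)
        if m < 2:
            continue
        all_pairs = list(itertools.combinations(range(m), 2))
        if pairs_per_position_cap is not None and len(all_pairs) > pairs_per_position_cap:
            idx = rng.choice(len(all_pairs), size=pairs_per_position_cap, replace=False)
            pairs = [all_pairs[i] for i in sorted(idx)]
        else:
            pairs = all_pairs
        for i, j in pairs:
            d = pairwise_difference(
                members[i], members[j], L, min_overlap=min_overlap, rescale=rescale
            )
            if d is None:
                continue
            total += d
            n_pairs += 1
            strand_sum[strand] += d
            strand_n[strand] += 1
    if n_pairs == 0:
        raise ValueError(
            f"CDI undefined for {satellite.name!r}: no eligible read pairs "
            f"({len(alignments)} alignments, {len(groups)} occupied positions)"
        )
    per_strand = {
        s: (strand_sum[s] / strand_n[s]) if strand_n[s] else float("nan")
        for s in "+-"
    }
    return CDIResult(
        sample_id=sample_id,
        satellite_name=satellite.name,
        cdi=total / n_pairs,
        n_pairs=n_pairs,
        pairs_per_position_cap=pairs_per_position_cap,
        per_strand=per_strand,
    )
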