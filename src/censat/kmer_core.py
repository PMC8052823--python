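"""Canonical k-mer decomposition and per-library count tables.

The abundance of a k-mer in a pool of shotgun reads is proportional to its
copy number in the source genome, which makes k-mer counts an assembly-free
readout for tandem satellites that are collapsed or absent from reference
assemblies. Reads sample both strands, so k-mers are strand-merged by
default: every key is *canonical*, the lexicographic minimum of the word and
its reverse complement.

Supported k is 3..63; satellite work typically uses k = 15 (fast, adequate
specificity) or k = 31 (high specificity).
"""

from __future__ import annotations

import gzip
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

K_MIN = 3
K_MAX = 63

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_INVALID = re.compile(r"[^ACGT]")
_NON_ACGT_SPLIT = re.compile(r"[^ACGT]+")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    m = _INVALID.search(seq)
    if m is not None:
        raise ValueError(
            f"non-ACGT symbol {seq[m.start()]!r} at position {m.start() + 1}"
        )


def canonical(kmer: str) -> str:
    """Strand-merged representative: min(kmer, reverse_complement(kmer)).

    Idempotent, and identical for a k-mer and its reverse complement.
    Raises ``ValueError`` naming the offending position for non-ACGT input.
    """
    _check_alphabet(kmer)
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _check_k(k: int) -> None:
    if not (K_MIN <= k <= K_MAX):
        raise ValueError(f"k must be in [{K_MIN}, {K_MAX}], got {k}")


def decompose_read(
    read_sequence: str, k: int, *, canonicalize: bool = True
) -> tuple[Counter, int]:
    """Decompose a read into its constituent k-mers.

    Every window start yields one k-mer (``len - k + 1`` windows); windows
    containing a non-ACGT character (e.g. N) are skipped. Returns
    ``(counts, n_skipped_windows)``. A read shorter than k yields an empty
    counter.
    """
    _check_k(k)
    seq = read_sequence.upper()
    n = len(seq)
    total_windows = max(n - k + 1, 0)
    counts: Counter = Counter()
    emitted = 0
    # split on non-ACGT runs; only clean segments emit windows
    for segment in _NON_ACGT_SPLIT.split(seq):
        m = len(segment)
        if m < k:
            continue
        if canonicalize:
            rc = reverse_complement(segment)
            for i in range(m - k + 1):
                fwd = segment[i : i + k]
                rev = rc[m - k - i : m - i]
                counts[fwd if fwd <= rev else rev] += 1
        else:
            for i in range(m - k + 1):
                counts[segment[i : i + k]] += 1
        emitted += m - k + 1
    return counts, total_windows - emitted


@dataclass
class KmerTable:
    """Raw counts of (canonical) k-mers observed in one sequencing library."""

    k: int
    counts: dict[str, int] = field(default_factory=dict)
    total_kmers: int = 0
    total_read_bases: int = 0
    library_id: str = ""
    sample_id: str = ""
    n_reads: int = 0
    n_skipped_windows: int = 0
    canonicalized: bool = True

    def __post_init__(self) -> None:
        _check_k(self.k)

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(kmer, default)

    def add_read(self, sequence: str) -> None:
        counts, skipped = decompose_read(
            sequence, self.k, canonicalize=self.canonicalized
        )
        for kmer, c in counts.items():
            self.counts[kmer] = self.counts.get(kmer, 0) + c
        self.total_kmers += sum(counts.values())
        self.n_skipped_windows += skipped
        self.total_read_bases += len(sequence)
        self.n_reads += 1

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write sorted (kmer, count) TSV plus a JSON sidecar of totals."""
        path = Path(path)
        with open(path, "w") as fh:
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")
        meta = {
            "k": self.k,
            "total_kmers": self.total_kmers,
            "total_read_bases": self.total_read_bases,
            "library_id": self.library_id,
            "sample_id": self.sample_id,
            "n_reads": self.n_reads,
            "n_skipped_windows": self.n_skipped_windows,
            "canonicalized": self.canonicalized,
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "KmerTable":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            meta = json.load(fh)
        counts: dict[str, int] = {}
        with open(path) as fh:
            for line in fh:
                kmer, c = line.rstrip("\n").split("\t")
                counts[kmer] = int(c)
        return cls(counts=counts, **meta)


def _open_maybe_gzip(source: Union[str, Path, IO]) -> IO:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(source: Union[str, Path, IO]) -> Iterator[tuple[str, str]]:
    """Yield ``(read_id, sequence)`` from FASTQ, naming the failing record."""
    handle = _open_maybe_gzip(source)
    index = 0
    iterator = FastqGeneralIterator(handle)
    while True:
        try:
            title, seq, _qual = next(iterator)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}")
        yield title.split()[0], seq
        index += 1


def count_library(
    fastq: Union[str, Path, IO, Iterable[tuple[str, str]]],
    k: int,
    *,
    library_id: str = "",
    sample_id: str = "",
    canonicalize: bool = True,
) -> KmerTable:
    """Count all k-mers of one sequencing library.

    ``fastq`` may be a path (optionally .gz), a text handle, or an iterable
    of ``(read_id, sequence)`` pairs. Counting is order-invariant.
    """
    table = KmerTable(
        k=k, library_id=library_id, sample_id=sample_id, canonicalized=canonicalize
    )
    if hasattr(fastq, "read") or isinstance(fastq, (str, Path)):
        reads: Iterable[tuple[str, str]] = iter_fastq(fastq)
    else:
        reads = fastq
    for _rid, seq in reads:
        table.add_read(seq)
    return table


def count_sequence(
    sequence: str, k: int, *, canonicalize: bool = True, sample_id: str = ""
) -> KmerTable:
    """Count k-mers of a single long sequence (e.g. a reference genome)."""
    table = KmerTable(k=k, sample_id=sample_id, canonicalized=canonicalize)
    table.add_read(sequence)
    return table


@dataclass
class SatelliteConsensus:
    """A satellite repeat-unit consensus (e.g. 120-bp minor, 234-bp major).

    ``circular=True`` models the tandem array: windows wrap across the
    junction between adjacent repeat units.
    """

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_fasta(
        cls, path: Union[str, Path], *, circular: bool = True
    ) -> list["SatelliteConsensus"]:
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        out = []
        with _open_maybe_gzip(path) as fh:
            for title, seq in SimpleFastaParser(fh):
                out.append(cls(name=title.split()[0], sequence=seq, circular=circular))
        if not out:
            raise ValueError(f"no FASTA records in {path}")
        return out


@dataclass
class ConsensusKmerSet:
    """Constituent k-mers of a consensus, keyed by 1-based start position."""

    consensus_name: str
    k: int
    L: int
    circular: bool
    # (start_position 1-based, kmer as written on consensus, canonical form)
    entries: list[tuple[int, str, str]]
    duplicate_canonicals: set[str]

    @property
    def distinct_canonical(self) -> set[str]:
        return {canon for _, _, canon in self.entries}


def consensus_kmer_set(consensus: SatelliteConsensus, k: int) -> ConsensusKmerSet:
    """Decompose a satellite consensus into its constituent k-mers.

    Circular consensus yields exactly L entries (one per start, wrapping),
    linear yields L - k + 1. Canonical k-mers occurring at more than one
    start are flagged as duplicates; downstream frequency queries count each
    distinct canonical k-mer once.
    """
    _check_k(k)
    L = consensus.length
    if L <= k:
        raise ValueError(f"consensus length {L} must exceed k={k}")
    seq = consensus.sequence + (consensus.sequence[: k - 1] if consensus.circular else "")
    n_entries = L if consensus.circular else L - k + 1
    entries = []
    seen: Counter = Counter()
    for i in range(n_entries):
        kmer = seq[i : i + k]
        canon = canonical(kmer)
        entries.append((i + 1, kmer, canon))
        seen[canon] += 1
    duplicates = {c for c, n in seen.items() if n > 1}
    return ConsensusKmerSet(
        consensus_name=consensus.name,
        k=k,
        L=L,
        circular=consensus.circular,
        entries=entries,
        duplicate_canonicals=duplicates,
    )


def gc_count(kmer: str) -> int:
    """Number of G/C bases in a k-mer (identical for both strands)."""
    return kmer.count("G") + kmer.count("C")
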