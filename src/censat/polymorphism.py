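"""Positional polymorphism landscape from relaxed-Hamming-distance k-mers.

Exact-match constituent k-mers measure copy number but are blind to the
variant repeat copies within a genome. To profile those, observed k-mers
within a small Hamming distance h of the satellite consensus are assigned
to the consensus positions they cover, and their frequencies are tallied
into a 4 x L matrix of relative nucleotide probabilities per consensus
position. Defaults follow the satellite workflow: h <= 2 for k = 15 and
h <= 5 for k = 31. Distance is substitution-only; indel contributions are
ignored by construction.

Sites with at least 20% non-consensus nucleotide usage are called variable;
the minor-satellite CENP-B box (positions 62-78, with positions 75/78/79 of
particular functional interest) can be inspected with `motif_report`.

Matching scans each distinct observed k-mer against all L consensus windows
(both orientations) in chunked numpy; the Hamming neighborhood of a 31-mer
at h <= 5 is ~41 million words per position and is never enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from censat.gc_normalization import NormalizedProfile, is_missing
from censat.kmer_core import ConsensusKmerSet, KmerTable, reverse_complement

DEFAULT_H_MAX = {15: 2, 31: 5}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

#: CENP-B box window on the 120-bp minor satellite (1-based, inclusive).
CENPB_BOX = (62, 78)
CENPB_FLAGGED_POSITIONS = (75, 78, 79)


def default_h_max(k: int) -> int:
    """Workflow default mismatch allowance: 2 for k=15, 5 for k=31."""
    try:
        return DEFAULT_H_MAX[k]
    except KeyError:
        # scale ~k/6, the same ratio as the anchored defaults
        return max(1, round(k / 6))


def hamming(a: str, b: str) -> int:
    """Substitution-only distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class RelaxedMatch:
    """Best relaxed-Hamming placement(s) of one observed k-mer."""

    kmer: str
    best_distance: int
    # (1-based consensus start, orientation '+'|'-') for every tied placement
    positions: list[tuple[int, str]]

    @property
    def weight_share(self) -> float:
        return 1.0 / len(self.positions)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_arrays(cks: ConsensusKmerSet) -> tuple[np.ndarray, list[int]]:
    """Encoded consensus windows (n_windows x k) and their 1-based starts."""
    windows = np.stack([_encode(kmer) for _, kmer, _ in cks.entries])
    starts = [pos for pos, _, _ in cks.entries]
    return windows, starts


def match_relaxed(
    observed_kmer: str, cks: ConsensusKmerSet, h_max: int | None = None
) -> RelaxedMatch | None:
    """Match one observed k-mer to the consensus within Hamming distance h_max.

    The k-mer and its reverse complement are compared against every
    consensus window; per window the smaller of the two distances is taken
    (forward preferred on a tie) and the orientation recorded. If the
    minimum over windows is <= h_max, all tied positions are returned with
    equal weight shares; otherwise None.
    """
    if len(observed_kmer) != cks.k:
        raise ValueError(f"k-mer length {len(observed_kmer)} != consensus k {cks.k}")
    if h_max is None:
        h_max = default_h_max(cks.k)
    windows, starts = _window_arrays(cks)
    fwd = _encode(observed_kmer)
    rev = _encode(reverse_complement(observed_kmer))
    d_f = (windows != fwd).sum(axis=1)
    d_r = (windows != rev).sum(axis=1)
    d = np.minimum(d_f, d_r)
    best = int(d.min())
    if best > h_max:
        return None
    positions = [
        (starts[i], "+" if d_f[i] <= d_r[i] else "-")
        for i in np.flatnonzero(d == best)
    ]
    return RelaxedMatch(kmer=observed_kmer, best_distance=best, positions=positions)


@dataclass
class PolymorphismMatrix:
    """4 x L relative nucleotide probabilities along a satellite consensus."""

    satellite_name: str
    L: int
    probs: np.ndarray  # shape (4, L), rows A,C,G,T; supported columns sum to 1
    supporting_weight: np.ndarray  # shape (L,), total frequency per column
    consensus: str

    @property
    def nonconsensus(self) -> np.ndarray:
        """Per-position fraction of non-consensus nucleotide usage."""
        out = np.zeros(self.L)
        for i, base in enumerate(self.consensus):
            out[i] = 1.0 - self.probs[_BASE_INDEX[base], i]
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs.T, columns=list(_BASES))
        df.insert(0, "position", np.arange(1, self.L + 1))
        df["consensus_base"] = list(self.consensus)
        df["nonconsensus"] = self.nonconsensus
        df["support"] = self.supporting_weight
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _frequency_map(
    source: Union[KmerTable, NormalizedProfile, Mapping[str, float]],
) -> Mapping[str, float]:
    if isinstance(source, KmerTable):
        return source.counts
    if isinstance(source, NormalizedProfile):
        # normalized values live on the log10 copy scale; weight linearly
        return {
            kmer: 10.0 ** v
            for kmer, v in source.values.items()
            if not is_missing(v)
        }
    return source


def build_polymorphism_matrix(
    source: Union[KmerTable, NormalizedProfile, Mapping[str, float]],
    cks: ConsensusKmerSet,
    h_max: int | None = None,
    *,
    chunk_size: int = 4096,
) -> PolymorphismMatrix:
    """Tally relaxed-match k-mer frequencies into per-position probabilities.

    Every observed k-mer within ``h_max`` of the consensus contributes its
    frequency to the nucleotide it carries at each consensus position it
    covers (start..start+k-1, wrapping when the consensus is circular),
    oriented onto the consensus strand; position ties split the weight
    equally. Columns are then normalized to sum to one. An empty result
    (no matched k-mers) yields an all-zero matrix with a warning.
    """
    import warnings

    freqs = _frequency_map(source)
    if h_max is None:
        h_max = default_h_max(cks.k)
    L, k = cks.L, cks.k
    consensus_seq = "".join(
        dict(sorted((pos, kmer[0]) for pos, kmer, _ in cks.entries)).values()
    ) if cks.circular else None
    windows, starts = _window_arrays(cks)
    n_win = windows.shape[0]
    kmers = sorted(freqs)
    tallies = np.zeros((4, L))
    support = np.zeros(L)
    base_lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        base_lut[ord(b)] = i
    matched_any = False
    for lo in range(0, len(kmers), chunk_size):
        chunk = kmers[lo : lo + chunk_size]
        fwd = np.stack([_encode(s) for s in chunk])  # (n, k)
        rev = np.stack([_encode(reverse_complement(s)) for s in chunk])
        # (n, n_win) mismatch counts for both orientations
        d_f = (fwd[:, None, :] != windows[None, :, :]).sum(axis=2)
        d_r = (rev[:, None, :] != windows[None, :, :]).sum(axis=2)
        d = np.minimum(d_f, d_r)
        best = d.min(axis=1)
        for row in np.flatnonzero(best <= h_max):
            matched_any = True
            freq = freqs[chunk[row]]
            tied = np.flatnonzero(d[row] == best[row])
            w = freq / tied.size
            for col in tied:
                aligned = fwd[row] if d_f[row, col] <= d_r[row, col] else rev[row]
                start0 = starts[col] - 1
                pos = (start0 + np.arange(k)) % L if cks.circular else start0 + np.arange(k)
                rows4 = base_lut[aligned]
                np.add.at(tallies, (rows4, pos), w)
                np.add.at(support, pos, w)
    if not matched_any:
        warnings.warn(
            f"no observed k-mers within h<={h_max} of {cks.consensus_name!r}; "
            "matrix is empty"
        )
    probs = np.zeros_like(tallies)
    nz = support > 0
    probs[:, nz] = tallies[:, nz] / support[nz]
    if consensus_seq is None:
        # linear: reconstruct consensus from first window + tails of the rest
        consensus_seq = cks.entries[0][1] + "".join(
            kmer[-1] for _, kmer, _ in cks.entries[1:]
        )
    return PolymorphismMatrix(
        satellite_name=cks.consensus_name,
        L=L,
        probs=probs,
        supporting_weight=support,
        consensus=consensus_seq,
    )


def variable_sites(matrix: PolymorphismMatrix, threshold: float = 0.20) -> list[int]:
    """1-based positions with non-consensus usage >= threshold (supported only)."""
    nonc = matrix.nonconsensus
    supported = matrix.supporting_weight > 0
    return [int(i) + 1 for i in np.flatnonzero(supported & (nonc >= threshold))]


def motif_report(
    matrix: PolymorphismMatrix,
    start: int = CENPB_BOX[0],
    end: int = CENPB_BOX[1],
) -> pd.DataFrame:
    """Per-position probabilities for a consensus window (1-based inclusive).

    Defaults to the CENP-B box of the minor satellite; positions 75, 78 and
    79 are flagged when inside the window.
    """
    if not (1 <= start <= end <= matrix.L):
        raise ValueError(
            f"window [{start}, {end}] out of range for L={matrix.L}"
        )
    df = matrix.to_frame().iloc[start - 1 : end]
    df = df.copy()
    df["flagged"] = df["position"].isin(CENPB_FLAGGED_POSITIONS)
    return df.reset_index(drop=True)
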