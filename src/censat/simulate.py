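"""Synthetic satellite arrays, genomes, and GC-biased reads with ground truth.

Every estimator in the package is testable offline against genomes whose
satellite copy number, per-position heterogeneity, and sequencing bias are
known exactly. The heterogeneity model applies independent substitutions to
each repeat copy at a per-position rate p, which makes the expected
diversity index analytic: two random copies differ at a site with
probability 2p(1-p), so E[CDI] ~= 2 * L * p * (1 - p). A shared-variant
mode plants population-frequency alleles (e.g. CENP-B-box-like variants) at
chosen positions. Sequencing bias is modeled by thinning: a candidate read
is kept with probability gc_bias(read GC fraction), so expected counts stay
analytic.

The bundled 120-bp repeat-unit consensus is synthetic (a fixed random
sequence, not a biological satellite); real analyses supply their own
consensus FASTA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

from censat.kmer_core import SatelliteConsensus, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def random_sequence(length: int, seed: int, gc: float = 0.5) -> str:
    """Random ACGT sequence with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = _rng(seed).choice(4, size=length, p=p)
    return "".join(_BASE_STR[i] for i in draw)


#: Synthetic 120-bp repeat-unit consensus used by tests and fixtures.
DEFAULT_UNIT_LENGTH = 120
DEFAULT_CONSENSUS_SEED = 20210


def default_consensus(name: str = "satA", L: int = DEFAULT_UNIT_LENGTH) -> SatelliteConsensus:
    """Fixed synthetic repeat-unit consensus (deterministic)."""
    return SatelliteConsensus(
        name=name, sequence=random_sequence(L, DEFAULT_CONSENSUS_SEED), circular=True
    )


@dataclass
class ArraySpec:
    """Specification of one tandem satellite array."""

    consensus: SatelliteConsensus
    copies: int
    substitution_rate: Union[float, Sequence[float]] = 0.0
    # (1-based position, alt base, frequency across copies)
    shared_variants: list[tuple[int, str, float]] = field(default_factory=list)
    seed: int = 0

    def rate_vector(self) -> np.ndarray:
        L = self.consensus.length
        r = np.asarray(self.substitution_rate, dtype=float)
        rates = np.full(L, float(r)) if r.ndim == 0 else r
        if rates.shape != (L,):
            raise ValueError(f"rate vector length {rates.shape} != L={L}")
        if np.any((rates < 0) | (rates >= 1)):
            raise ValueError("substitution rates must lie in [0, 1)")
        return rates


def simulate_array(spec: ArraySpec) -> tuple[str, pd.DataFrame]:
    """Tandem concatenation of mutated repeat copies plus a truth table.

    Shared variants are planted first (each copy carries the alt allele
    with the stated frequency); independent substitutions at the
    per-position rate are applied to the remaining sites. The truth table
    records every substitution as (copy, position, ref, alt). Deterministic
    given the spec seed.
    """
    rng = _rng(spec.seed)
    L = spec.consensus.length
    unit = np.frombuffer(spec.consensus.sequence.encode(), dtype=np.uint8)
    arr = np.tile(unit, (spec.copies, 1)).copy()
    records: list[tuple[int, int, str, str]] = []
    mutated = np.zeros((spec.copies, L), dtype=bool)
    for pos, alt, freq in spec.shared_variants:
        if not (0 < freq < 1):
            raise ValueError(f"shared variant frequency must be in (0,1): {freq}")
        col = pos - 1
        carriers = rng.random(spec.copies) < freq
        ref = spec.consensus.sequence[col]
        if alt == ref:
            raise ValueError(f"alt base equals consensus base at position {pos}")
        arr[carriers, col] = ord(alt)
        mutated[carriers, col] = True
        for c in np.flatnonzero(carriers):
            records.append((int(c), pos, ref, alt))
    rates = spec.rate_vector()
    hits = (rng.random((spec.copies, L)) < rates) & ~mutated
    for c, col in zip(*np.nonzero(hits)):
        ref = chr(arr[c, col])
        alt = _BASE_STR[(_BASE_STR.index(ref) + rng.integers(1, 4)) % 4]
        arr[c, col] = ord(alt)
        records.append((int(c), int(col) + 1, ref, alt))
    sequence = arr.tobytes().decode("ascii")
    truth = pd.DataFrame(records, columns=["copy", "position", "ref", "alt"])
    return sequence, truth


def simulate_genome(
    background_length: int,
    arrays: Sequence[ArraySpec],
    seed: int,
    *,
    gc_target: float = 0.5,
) -> tuple[str, dict]:
    """Random background with satellite arrays appended, plus truth JSON.

    Arrays are placed end-to-end after the background (coordinates
    recorded 1-based in the truth dict); the background is uniform ACGT at
    the requested GC fraction.
    """
    background = random_sequence(background_length, seed, gc=gc_target)
    parts = [background]
    cursor = background_length
    truth: dict = {
        "background_length": background_length,
        "gc_target": gc_target,
        "arrays": [],
        "substitutions": {},
    }
    for i, spec in enumerate(arrays):
        seq, subs = simulate_array(spec)
        parts.append(seq)
        truth["arrays"].append(
            {
                "name": spec.consensus.name,
                "start": cursor + 1,
                "end": cursor + len(seq),
                "copies": spec.copies,
                "unit_length": spec.consensus.length,
            }
        )
        truth["substitutions"][spec.consensus.name] = subs
        cursor += len(seq)
    return "".join(parts), truth


def flat_gc_bias(_gc: float) -> float:
    return 1.0


def linear_gc_bias(low: float = 0.2, high: float = 1.0) -> Callable[[float], float]:
    """Acceptance probability linear in GC fraction, clipped to (0, 1]."""

    def bias(gc: float) -> float:
        return float(np.clip(low + (high - low) * gc, 1e-3, 1.0))

    return bias


@dataclass
class ReadSimSpec:
    """Read-sampling parameters for one simulated library."""

    depth: float
    read_length: int
    per_base_error_rate: float = 0.0
    gc_bias: Callable[[float], float] = flat_gc_bias
    seed: int = 0


def simulate_reads(
    genome: str, spec: ReadSimSpec
) -> tuple[list[tuple[str, str]], dict]:
    """Sample error-prone, GC-thinned reads uniformly from both strands.

    The number of candidate fragments is depth * genome_length /
    read_length; each candidate is kept with probability gc_bias(fragment
    GC fraction), then per-base errors are applied i.i.d. Returns
    ``(reads, truth)`` where truth records candidate and kept counts.
    """
    if spec.depth <= 0 or spec.read_length < 1:
        raise ValueError("depth must be > 0 and read_length >= 1")
    rng = _rng(spec.seed)
    n = len(genome)
    rl = spec.read_length
    if n < rl:
        raise ValueError(f"genome length {n} shorter than read length {rl}")
    n_candidates = int(round(spec.depth * n / rl))
    starts = rng.integers(0, n - rl + 1, size=n_candidates)
    strands = rng.random(n_candidates) < 0.5
    keep_draws = rng.random(n_candidates)
    genome_arr = np.frombuffer(genome.encode(), dtype=np.uint8)
    is_gc = (genome_arr == ord("G")) | (genome_arr == ord("C"))
    gc_cum = np.concatenate([[0], np.cumsum(is_gc)])
    reads: list[tuple[str, str]] = []
    n_errors = 0
    for i in range(n_candidates):
        s = int(starts[i])
        gc_frac = (gc_cum[s + rl] - gc_cum[s]) / rl
        if keep_draws[i] >= spec.gc_bias(gc_frac):
            continue
        frag = genome[s : s + rl]
        if strands[i]:
            frag = reverse_complement(frag)
        if spec.per_base_error_rate > 0:
            errs = np.flatnonzero(rng.random(rl) < spec.per_base_error_rate)
            if errs.size:
                frag_l = list(frag)
                for j in errs:
                    frag_l[j] = _BASE_STR[
                        (_BASE_STR.index(frag_l[j]) + rng.integers(1, 4)) % 4
                    ]
                frag = "".join(frag_l)
                n_errors += errs.size
        reads.append((f"read_{i}", frag))
    truth = {
        "n_candidates": n_candidates,
        "n_kept": len(reads),
        "n_errors": n_errors,
        "read_length": rl,
        "depth_requested": spec.depth,
    }
    return reads, truth


def write_fasta(path: Union[str, Path], records: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_fastq(path: Union[str, Path], reads: Sequence[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def random_tree(n_tips: int, seed: int) -> str:
    """Random pure-birth tree as newick (branch lengths exponential)."""
    import dendropy
    import random as _random

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(1, n_tips + 1)])
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        taxon_namespace=taxa,
        rng=_random.Random(seed),
    )
    return tree.as_string(schema="newick").strip()


def sample_trait_on_tree(
    G: np.ndarray,
    phylo_fraction: float,
    seed: int,
    *,
    mu: float = 0.0,
    total_variance: float = 1.0,
) -> np.ndarray:
    """Trait with a chosen mix of Brownian (tree) and i.i.d. variance.

    ``phylo_fraction`` = 1 gives pure Brownian motion on the tree, 0 gives
    i.i.d. noise; intermediate values mix the two with the stated variance
    fractions (G is normalized to unit mean diagonal first).
    """
    rng = _rng(seed)
    n = G.shape[0]
    Gn = G / np.mean(np.diag(G))
    jitter = 1e-10 * np.eye(n)
    chol = np.linalg.cholesky(Gn + jitter)
    b = chol @ rng.standard_normal(n)
    e = rng.standard_normal(n)
    y = mu + math.sqrt(total_variance) * (
        math.sqrt(phylo_fraction) * b + math.sqrt(1 - phylo_fraction) * e
    )
    return y


@dataclass
class ScenarioFixture:
    """One named simulation bundle with its ground truth."""

    name: str
    genome: str
    truth: dict
    reads: list[tuple[str, str]]
    read_truth: dict
    array_spec: ArraySpec
    read_spec: ReadSimSpec


def scenario_fixtures(seed: int = 1) -> dict:
    """Named simulation bundles contrasting homogeneous and diverse arrays.

    - ``inbred_like``: large homogeneous array (2,000 copies, per-position
      heterogeneity 0.02) — high copy number, low diversity.
    - ``wild_like``: small heterogeneous array (300 copies, rate 0.10) —
      low copy number, high diversity.
    - ``brownian_tree``: a 32-tip tree (newick) with a pure-Brownian trait,
      for heritability checks.

    Byte-identical across calls with the same seed.
    """
    cons = default_consensus()
    bundles: dict = {}
    for name, copies, rate, sub_seed in (
        ("inbred_like", 2000, 0.02, 11),
        ("wild_like", 300, 0.10, 13),
    ):
        aspec = ArraySpec(
            consensus=cons, copies=copies, substitution_rate=rate, seed=seed * 1000 + sub_seed
        )
        genome, truth = simulate_genome(
            50_000, [aspec], seed=seed * 1000 + sub_seed + 1
        )
        rspec = ReadSimSpec(
            depth=20, read_length=100, per_base_error_rate=0.0,
            seed=seed * 1000 + sub_seed + 2,
        )
        reads, read_truth = simulate_reads(genome, rspec)
        bundles[name] = ScenarioFixture(
            name=name, genome=genome, truth=truth, reads=reads,
            read_truth=read_truth, array_spec=aspec, read_spec=rspec,
        )
    newick = random_tree(32, seed=seed * 1000 + 17)
    bundles["brownian_tree"] = {"newick": newick, "n_tips": 32, "seed": seed}
    return bundles
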