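"""End-to-end satellite diversity pipeline and run configuration.

Composes the stages: k-mer counting of each library, GC-bias model fit from
a unique-reference-k-mer panel, satellite copy-number estimation from
constituent k-mer medians, consensus mapping + CDI, the positional
polymorphism matrix, and (when a tree is supplied) phylogenetic
heritability. Every output TSV is accompanied by a JSON run summary
carrying the configuration hash for provenance.

Coordinates on consensus sequences are 1-based inclusive throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from censat import cdi as cdi_mod
from censat import gc_normalization as gcn
from censat import kmer_core, polymorphism, satellite_quant
from censat.kmer_core import SatelliteConsensus

logger = logging.getLogger("censat")


@dataclass
class RunConfig:
    """Pipeline parameters; serialized alongside outputs for provenance."""

    k: int = 31
    h_max: int | None = None  # auto: 2 for k=15, 5 for k=31
    span: float = 0.4
    min_identity: float = cdi_mod.DEFAULT_MIN_IDENTITY
    n_chromosomes: int = satellite_quant.DEFAULT_N_CHROMOSOMES
    panel_size: int = 100_000
    top_n: int = 1000
    n_perm: int = 1000
    pairs_per_position_cap: int = cdi_mod.DEFAULT_PAIRS_PER_POSITION_CAP
    seed: int = 0
    circular_consensus: bool = True

    def resolved_h_max(self) -> int:
        if self.h_max is not None:
            return self.h_max
        return polymorphism.default_h_max(self.k)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Per-sample results of one pipeline run."""

    config: RunConfig
    copy_numbers: dict[str, satellite_quant.CopyNumberEstimate] = field(
        default_factory=dict
    )
    cdi: dict[str, cdi_mod.CDIResult] = field(default_factory=dict)
    matrices: dict[str, polymorphism.PolymorphismMatrix] = field(default_factory=dict)
    heritability: dict[str, object] = field(default_factory=dict)

    def summary(self) -> dict:
        out: dict = {"config_hash": self.config.config_hash()}
        out["copy_number"] = {
            name: {
                "median_normalized": est.median_normalized,
                "copies": est.copies,
                "per_chromosome_kb": est.per_chromosome_bp / 1000,
                "n_missing": est.n_missing,
                "below_detection": est.below_detection,
            }
            for name, est in self.copy_numbers.items()
        }
        out["cdi"] = {
            name: {"cdi": r.cdi, "n_pairs": r.n_pairs}
            for name, r in self.cdi.items()
        }
        out["variable_sites"] = {
            name: polymorphism.variable_sites(m) for name, m in self.matrices.items()
        }
        return out


def run_pipeline(
    reads: Sequence[tuple[str, str]] | str | Path,
    consensuses: Sequence[SatelliteConsensus],
    reference: str | Path | kmer_core.KmerTable,
    config: RunConfig | None = None,
    *,
    sample_id: str = "sample",
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run count -> GC-normalize -> quantify -> CDI -> polymorphism landscape.

    ``reads`` is a FASTQ path or an in-memory list of (id, sequence);
    ``reference`` is a reference FASTA path, raw sequence string, or a
    precomputed reference k-mer table (used only to pick the unique-k-mer
    panel). Deterministic given config.seed.
    """
    config = config or RunConfig()
    k = config.k
    logger.info("stage count: k=%d sample=%s", k, sample_id)
    if isinstance(reads, (str, Path)):
        if not Path(reads).exists():
            raise FileNotFoundError(f"reads file not found: {reads}")
        reads_list = list(kmer_core.iter_fastq(reads))
    else:
        reads_list = list(reads)
    library = kmer_core.count_library(reads_list, k, sample_id=sample_id)

    logger.info("stage gcfit: panel_size=%d span=%.2f", config.panel_size, config.span)
    if isinstance(reference, kmer_core.KmerTable):
        ref_counts = reference
    else:
        # a short string naming an existing file is a path; anything else
        # is treated as raw sequence
        if isinstance(reference, Path) or (
            isinstance(reference, str)
            and len(reference) < 4096
            and Path(reference).exists()
        ):
            refs = SatelliteConsensus.from_fasta(reference, circular=False)
            ref_seq = "".join(r.sequence for r in refs)
        else:
            ref_seq = str(reference)
        ref_counts = kmer_core.count_sequence(ref_seq, k)
    panel = gcn.select_unique_reference_kmers(
        ref_counts, n=config.panel_size, seed=config.seed
    )
    model = gcn.fit_gc_model(library, panel, span=config.span)

    result = PipelineResult(config=config)
    for cons in consensuses:
        logger.info("stage quantify: satellite=%s", cons.name)
        cks = kmer_core.consensus_kmer_set(cons, k)
        profile = gcn.normalize_profile(library, model, cks.distinct_canonical)
        freqs = satellite_quant.satellite_kmer_frequencies(profile, cks)
        result.copy_numbers[cons.name] = satellite_quant.estimate_copy_number(
            freqs,
            cons.length,
            n_chromosomes=config.n_chromosomes,
            sample_id=sample_id,
            satellite_name=cons.name,
            k=k,
        )
        logger.info("stage landscape: satellite=%s", cons.name)
        result.matrices[cons.name] = polymorphism.build_polymorphism_matrix(
            library, cks, h_max=config.resolved_h_max()
        )

    logger.info("stage cdi: mapping %d reads", len(reads_list))
    alignments, _total = cdi_mod.map_reads(
        reads_list, list(consensuses), config.min_identity
    )
    for cons in consensuses:
        try:
            result.cdi[cons.name] = cdi_mod.centromere_diversity_index(
                alignments,
                cons,
                sample_id=sample_id,
                pairs_per_position_cap=config.pairs_per_position_cap,
                seed=config.seed,
            )
        except ValueError as exc:
            logger.warning("cdi undefined for %s: %s", cons.name, exc)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        chash = config.config_hash()
        for name, matrix in result.matrices.items():
            matrix.to_tsv(outdir / f"{sample_id}.{name}.polymorphism.tsv")
        with open(outdir / f"{sample_id}.summary.json", "w") as fh:
            json.dump(result.summary(), fh, indent=2, default=str)
        with open(outdir / f"{sample_id}.copy_number.tsv", "w") as fh:
            fh.write(
                "# config_hash=" + chash + "\n"
                "sample\tsatellite\tmedian_normalized\tcopies\t"
                "per_chromosome_kb\tn_missing\tbelow_detection\n"
            )
            for name, est in result.copy_numbers.items():
                fh.write(
                    f"{sample_id}\t{name}\t{est.median_normalized:.4f}\t"
                    f"{est.copies:.1f}\t{est.per_chromosome_bp / 1000:.3f}\t"
                    f"{est.n_missing}\t{est.below_detection}\n"
                )
        with open(outdir / f"{sample_id}.cdi.tsv", "w") as fh:
            fh.write("# config_hash=" + chash + "\n")
            fh.write("sample\tsatellite\tcdi\tn_pairs\n")
            for name, r in result.cdi.items():
                fh.write(f"{sample_id}\t{name}\t{r.cdi:.4f}\t{r.n_pairs}\n")
    return result
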