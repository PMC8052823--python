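"""Per-library GC-bias baseline and log10 copy-number-scale normalization.

PCR amplification efficiency depends on fragment GC content, so the raw
count of a k-mer confounds genomic copy number with library-specific GC
bias. The baseline is estimated from a random panel of k-mers that occur
exactly once in a reference genome: their observed counts, LOESS-smoothed
as a function of GC content (span 0.4), give the expected count of a
single-copy k-mer at each GC level. A query k-mer's normalized value is

    normalized = log10(observed count / LOESS-predicted count)

which is ~0 for single-copy sequence and ~log10(C) for a C-copy repeat.

GC "bins" are the k + 1 integer GC counts 0..k; the LOESS curve is fitted
on GC fraction and evaluated at the bin centers. Unobserved query k-mers
map to the ``MISSING`` sentinel (NaN), never to -infinity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from censat.kmer_core import KmerTable, gc_count

#: Sentinel for "k-mer unobserved in this library" (count 0).
MISSING = float("nan")

#: Floor for LOESS predictions, guarding undershoot at sparse GC extremes.
PREDICTION_FLOOR = 0.01


def is_missing(value: float) -> bool:
    return isinstance(value, float) and math.isnan(value)


@dataclass
class UniqueKmerPanel:
    """Random panel of k-mers occurring exactly once in the reference."""

    k: int
    kmers: list[str]
    seed: int
    requested_size: int

    @property
    def panel_size(self) -> int:
        return len(self.kmers)


def select_unique_reference_kmers(
    reference_counts: KmerTable, n: int = 100_000, seed: int = 0
) -> UniqueKmerPanel:
    """Sample ``n`` singleton reference k-mers uniformly without replacement.

    Deterministic given ``seed``. If fewer than ``n`` singletons exist, all
    are returned with a warning; zero singletons is an error.
    """
    candidates = sorted(k for k, c in reference_counts.counts.items() if c == 1)
    if not candidates:
        raise ValueError("reference contains no singleton k-mers")
    rng = np.random.default_rng(seed)
    if len(candidates) <= n:
        if len(candidates) < n:
            warnings.warn(
                f"only {len(candidates)} singleton k-mers available "
                f"(requested {n}); using all"
            )
        chosen = candidates
    else:
        idx = rng.choice(len(candidates), size=n, replace=False)
        chosen = [candidates[i] for i in sorted(idx)]
    return UniqueKmerPanel(
        k=reference_counts.k, kmers=chosen, seed=seed, requested_size=n
    )


@dataclass
class GCModel:
    """LOESS-predicted expected count of a single-copy k-mer per GC level."""

    k: int
    predicted: dict[int, float]
    span: float
    n_points: int
    extrapolated_levels: set[int] = field(default_factory=set)

    def predict(self, gc: int) -> float:
        try:
            return self.predicted[gc]
        except KeyError:
            raise KeyError(f"GC level {gc} outside model range 0..{self.k}")

    def to_tsv(self, path: Union[str, Path]) -> None:
        import json

        path = Path(path)
        with open(path, "w") as fh:
            fh.write("gc_count\tpredicted\n")
            for gc in sorted(self.predicted):
                fh.write(f"{gc}\t{self.predicted[gc]:.6g}\n")
        meta = {
            "k": self.k,
            "span": self.span,
            "n_points": self.n_points,
            "extrapolated_levels": sorted(self.extrapolated_levels),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def fit_gc_model(
    library: KmerTable,
    panel: UniqueKmerPanel,
    span: float = 0.4,
    *,
    include_zero_counts: bool = True,
) -> GCModel:
    """Fit the library's GC-bias curve from the unique-k-mer panel.

    Observed counts of panel members (0 where unobserved, unless
    ``include_zero_counts=False``) are LOESS-smoothed against GC fraction
    and evaluated at every integer GC level 0..k. Levels outside the
    panel's observed GC range are filled by the nearest fitted level and
    recorded in ``extrapolated_levels``. Predictions are floored at
    ``PREDICTION_FLOOR``.
    """
    if panel.k != library.k:
        raise ValueError(f"panel k={panel.k} != library k={library.k}")
    k = library.k
    gcs = []
    ys = []
    for kmer in panel.kmers:
        c = library.get(kmer, 0)
        if c == 0 and not include_zero_counts:
            continue
        gcs.append(gc_count(kmer))
        ys.append(c)
    gcs = np.asarray(gcs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    observed_levels = np.unique(gcs)
    if observed_levels.size < 2:
        raise ValueError(
            "GC model undefined: panel spans fewer than 2 distinct GC levels"
        )
    x = gcs / k
    xvals = observed_levels / k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fitted = lowess(ys, x, frac=span, xvals=xvals)
    fitted = np.maximum(np.nan_to_num(fitted, nan=PREDICTION_FLOOR), PREDICTION_FLOOR)
    level_pred = dict(zip(observed_levels.astype(int), fitted))
    predicted: dict[int, float] = {}
    extrapolated: set[int] = set()
    fitted_levels = np.array(sorted(level_pred))
    for gc in range(k + 1):
        if gc in level_pred:
            predicted[gc] = float(level_pred[gc])
        else:
            nearest = int(fitted_levels[np.argmin(np.abs(fitted_levels - gc))])
            predicted[gc] = float(level_pred[nearest])
            extrapolated.add(gc)
    return GCModel(
        k=k,
        predicted=predicted,
        span=span,
        n_points=len(ys),
        extrapolated_levels=extrapolated,
    )


def normalize_count(observed: float, predicted: float) -> float:
    """log10(observed / predicted); 0 observed maps to MISSING, not -inf."""
    if predicted <= 0:
        raise ValueError(f"predicted count must be positive, got {predicted}")
    if observed < 0:
        raise ValueError(f"observed count must be non-negative, got {observed}")
    if observed == 0:
        return MISSING
    return math.log10(observed / predicted)


@dataclass
class NormalizedProfile:
    """GC-normalized (log10 copy-number scale) values for query k-mers."""

    sample_id: str
    k: int
    values: dict[str, float]
    gc_model: GCModel

    def __len__(self) -> int:
        return len(self.values)

    @property
    def missing_fraction(self) -> float:
        if not self.values:
            return 0.0
        n_missing = sum(1 for v in self.values.values() if is_missing(v))
        return n_missing / len(self.values)

    def to_tsv(self, path: Union[str, Path], library: KmerTable | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("kmer\tgc_count\traw\tnormalized\n")
            for kmer in sorted(self.values):
                v = self.values[kmer]
                raw = library.get(kmer, 0) if library is not None else ""
                norm = "NA" if is_missing(v) else f"{v:.6g}"
                fh.write(f"{kmer}\t{gc_count(kmer)}\t{raw}\t{norm}\n")


def normalize_profile(
    library: KmerTable, model: GCModel, query_kmers: Iterable[str]
) -> NormalizedProfile:
    """Normalized value for each query k-mer, keyed by its GC level.

    The model must come from the same library: GC bias is a property of the
    library, not the sample.
    """
    if model.k != library.k:
        raise ValueError(f"model k={model.k} != library k={library.k}")
    values: dict[str, float] = {}
    for kmer in query_kmers:
        if len(kmer) != library.k:
            raise ValueError(
                f"query k-mer {kmer!r} has length {len(kmer)}, expected {library.k}"
            )
        values[kmer] = normalize_count(
            library.get(kmer, 0), model.predict(gc_count(kmer))
        )
    return NormalizedProfile(
        sample_id=library.sample_id, k=library.k, values=values, gc_model=model
    )
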