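"""Satellite copy number, array lengths, variable k-mers, variance components.

The copy number of a satellite consensus in a genome is estimated from the
median GC-normalized frequency of its distinct constituent k-mers: a median
log10 corrected count of m implies 10**m copies. Per-chromosome array
length follows arithmetically as copies * L / n_chromosomes (house mouse
2n = 40 chromosomes by default).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from censat.gc_normalization import NormalizedProfile, is_missing
from censat.kmer_core import ConsensusKmerSet, KmerTable

#: Diploid house mouse chromosome count.
DEFAULT_N_CHROMOSOMES = 40

#: Approximate mouse genome size (bp), default depth standardizer for scans.
MOUSE_GENOME_SIZE = 2.7e9


def satellite_kmer_frequencies(
    profile: NormalizedProfile, cks: ConsensusKmerSet
) -> dict[str, float]:
    """Normalized frequency per *distinct* canonical constituent k-mer.

    Duplicated k-mers within the consensus contribute one value. MISSING
    values (unobserved k-mers) are carried through.
    """
    if profile.k != cks.k:
        raise ValueError(f"profile k={profile.k} != consensus set k={cks.k}")
    out: dict[str, float] = {}
    for canon in sorted(cks.distinct_canonical):
        if canon not in profile.values:
            raise KeyError(
                f"constituent k-mer {canon!r} absent from profile; "
                "normalize with the consensus k-mer set as the query"
            )
        out[canon] = profile.values[canon]
    return out


@dataclass
class CopyNumberEstimate:
    """Median-of-constituent-k-mers satellite copy number for one sample."""

    sample_id: str
    satellite_name: str
    k: int
    median_normalized: float  # log10 scale; NaN when below detection
    n_constituent_kmers: int
    n_missing: int
    unit_length: int
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES
    below_detection: bool = False

    @property
    def copies(self) -> float:
        if self.below_detection and math.isnan(self.median_normalized):
            return float("nan")
        return 10.0 ** self.median_normalized

    @property
    def per_chromosome_bp(self) -> float:
        return self.copies * self.unit_length / self.n_chromosomes


def estimate_copy_number(
    distribution: Mapping[str, float] | Sequence[float],
    L: int,
    *,
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    sample_id: str = "",
    satellite_name: str = "",
    k: int = 0,
) -> CopyNumberEstimate:
    """Estimate satellite copy number from a distribution of normalized values.

    The median is taken over non-missing values (even counts average the
    middle two); copies = 10**median. With more than 50% of constituent
    k-mers missing the estimate is flagged below-detection; with all values
    missing the copy number is undefined (NaN, flagged).
    """
    values = (
        list(distribution.values())
        if isinstance(distribution, Mapping)
        else list(distribution)
    )
    if not values:
        raise ValueError("empty distribution: no constituent k-mer values")
    present = [v for v in values if not is_missing(v)]
    n_missing = len(values) - len(present)
    below = n_missing > 0.5 * len(values)
    median = float(np.median(present)) if present else float("nan")
    return CopyNumberEstimate(
        sample_id=sample_id,
        satellite_name=satellite_name,
        k=k,
        median_normalized=median,
        n_constituent_kmers=len(values),
        n_missing=n_missing,
        unit_length=L,
        n_chromosomes=n_chromosomes,
        below_detection=below or not present,
    )


def fold_range(copy_numbers: Iterable[float]) -> float:
    """max/min ratio across positive copy-number estimates."""
    values = list(copy_numbers)
    if not values:
        raise ValueError("empty copy-number list")
    if any(v <= 0 for v in values):
        raise ValueError("fold range requires strictly positive copy numbers")
    return max(values) / min(values)


@dataclass
class VariableKmerScan:
    """Cross-sample variance of depth-standardized k-mer frequencies."""

    k: int
    samples: list[str]
    variances: pd.Series  # index: k-mer, sorted descending
    top_n: int

    @property
    def top(self) -> pd.Series:
        return self.variances.iloc[: self.top_n]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "kmer": self.variances.index,
                "variance": self.variances.values,
                "rank": np.arange(1, len(self.variances) + 1),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def kmer_variance_scan(
    tables: Sequence[KmerTable],
    top_n: int = 1000,
    *,
    genome_size: float = MOUSE_GENOME_SIZE,
    restrict_to: Iterable[str] | None = None,
) -> VariableKmerScan:
    """Rank k-mers by cross-sample variance of depth-standardized frequency.

    For sample s, F_s = raw count / (total_read_bases_s / genome_size), i.e.
    count per 1x depth; the per-k-mer variance uses the n-1 denominator and
    k-mers absent from a sample contribute F_s = 0. The ranking is invariant
    to any common rescaling of the standardizer.
    """
    if len(tables) < 2:
        raise ValueError("variance scan requires at least 2 samples")
    k = tables[0].k
    if any(t.k != k for t in tables):
        raise ValueError("all tables must share the same k")
    depths = []
    for t in tables:
        if t.total_read_bases <= 0:
            raise ValueError(f"table {t.sample_id!r} has zero read bases")
        depths.append(t.total_read_bases / genome_size)
    if restrict_to is not None:
        universe = sorted(set(restrict_to))
    else:
        universe = sorted(set().union(*(t.counts.keys() for t in tables)))
    F = np.zeros((len(tables), len(universe)))
    index = {kmer: j for j, kmer in enumerate(universe)}
    for i, t in enumerate(tables):
        source = t.counts if restrict_to is None else {
            kk: t.counts[kk] for kk in universe if kk in t.counts
        }
        for kmer, c in source.items():
            F[i, index[kmer]] = c / depths[i]
    variances = pd.Series(F.var(axis=0, ddof=1), index=universe)
    variances = variances.sort_values(ascending=False, kind="stable")
    return VariableKmerScan(
        k=k,
        samples=[t.sample_id for t in tables],
        variances=variances,
        top_n=top_n,
    )


@dataclass
class VariancePartition:
    """Sequential (type-I) ANOVA percent-variance decomposition."""

    response_name: str
    factors: list[str]
    percent_variance: dict[str, float]  # includes "residual"
    F_statistics: dict[str, float]
    p_values: dict[str, float]


def partition_variance(
    response: Sequence[float],
    factors: pd.DataFrame,
    *,
    response_name: str = "response",
) -> VariancePartition:
    """Partition response variance across categorical factors.

    Sequential (type-I) sums of squares in the given column order; percent
    variance per factor = factor SS / total SS * 100, residual reported so
    the percentages sum to 100. Single-level factors contribute 0 with a
    warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    y = np.asarray(response, dtype=float)
    if len(y) != len(factors):
        raise ValueError("response length does not match factor table")
    usable = []
    percent: dict[str, float] = {}
    Fstats: dict[str, float] = {}
    pvals: dict[str, float] = {}
    for col in factors.columns:
        if factors[col].nunique() < 2:
            warnings.warn(f"factor {col!r} has a single level; contributes 0")
            percent[col] = 0.0
            Fstats[col] = float("nan")
            pvals[col] = float("nan")
        else:
            usable.append(col)
    data = factors.copy()
    data["_y"] = y
    formula = "_y ~ " + " + ".join(f"C({c})" for c in usable) if usable else "_y ~ 1"
    model = smf.ols(formula, data=data).fit()
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if usable:
        table = sm.stats.anova_lm(model, typ=1)
        for col in usable:
            row = table.loc[f"C({col})"]
            percent[col] = float(row["sum_sq"]) / total_ss * 100.0
            Fstats[col] = float(row["F"])
            pvals[col] = float(row["PR(>F)"])
        resid_ss = float(table.loc["Residual", "sum_sq"])
    else:
        resid_ss = total_ss
    percent["residual"] = resid_ss / total_ss * 100.0
    return VariancePartition(
        response_name=response_name,
        factors=list(factors.columns),
        percent_variance=percent,
        F_statistics=Fstats,
        p_values=pvals,
    )
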