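# Methods

This note documents the models, estimators, numerical choices, and
simulation conditions behind `censat`, and states what the synthetic tests
do and do not establish about real data.

## k-mer counting

Reads are decomposed into all `len − k + 1` overlapping windows; windows
containing any non-ACGT character are skipped (not corrected) and counted
as skipped, which is unbiased with respect to the surrounding sequence.
Keys are *canonical* — the lexicographic minimum of the word and its
reverse complement — because shotgun reads sample both strands and
canonicalization makes consensus-k-mer queries strand-proof. A
strand-specific mode (`canonicalize=False`) exists for sensitivity
analysis. Supported k is 3–63; the workflow defaults are k = 15 (fast,
adequate specificity) and k = 31 (high specificity). Counting is exact
(hash table); there are no probabilistic sketches, which is appropriate at
the genome sizes a desk analysis handles.

Satellite consensus sequences are decomposed *circularly* by default: a
tandem array makes junction-spanning k-mers physically real, so the
circular decomposition of an L-bp unit yields exactly L constituent k-mers
(linear mode, L − k + 1, is available). Canonical k-mers occurring at more
than one consensus position are flagged and counted once in downstream
frequency queries, so repeated motifs within a unit do not get double
weight.

## GC-bias model

Library preparation amplifies fragments with efficiency that depends on GC
content, confounding raw counts with copy number. The baseline is fitted
per library — bias is a property of the library, never shared across
libraries — from a seeded random panel of k-mers that occur exactly once in
a reference sequence (default panel size 100,000; simulations use
15,000–20,000 against 40–100-kb synthetic references, which leaves
thousands of points per populated GC level). Panel counts (zeros included
by default; an exclusion mode exists) are LOESS-smoothed against GC
fraction with span 0.4 and evaluated at the k + 1 integer GC levels; levels
with no panel support are filled from the nearest fitted level and recorded
as extrapolated. Predictions are floored at 0.01 counts to guard LOESS
undershoot at sparse extremes.

Normalization is `log10(observed / predicted)`. A zero observed count maps
to a MISSING sentinel (NaN), never −∞; medians are taken over non-missing
values and the missing fraction is reported. The flooring and MISSING
conventions only matter at the detection boundary; the self-calibration
property (panel k-mers normalize to a median within ±0.05 of 0) and the
≥5× attenuation of the count–GC correlation are verified on simulated
libraries with a strong linear acceptance bias (0.2 → 1.0 across GC).

## Copy number and array length

Satellite copy number is `10^median` of the normalized values of the
distinct constituent k-mers. The median (even counts average the middle
two) is robust to a minority of k-mers hit by mutations or shared with
other loci. With more than 50% of constituent k-mers missing the estimate
is flagged below-detection. Per-chromosome array length is
`copies × L / n_chromosomes` with n_chromosomes defaulting to 40, the
diploid house mouse karyotype — the divisor that reproduces the published
per-chromosome kilobase conversions exactly (e.g. 1,320 copies × 120 bp /
40 = 3.96 kb).

The estimator reads out *consensus-exact* copies. In an array whose copies
carry independent substitutions at per-position rate p, an exact k-mer
survives in a given copy with probability (1−p)^k, so the expected readout
is C(1−p)^k, not C — at p = 0.02 and k = 31 that is a ~47% deficit. This
is a property of exact-match counting, not an artifact: recovery
simulations therefore plant homogeneous arrays (p = 0, error-free reads) to
isolate estimator accuracy, and recover C ∈ {100, 1,000, 10,000} at 20×
depth within ±10% (measured ≤ ~3%). The heterogeneity-induced deficit is
measured separately by the end-to-end pipeline test against the analytic
C(1−p)^k expectation.

## Variable-k-mer scan and variance partitioning

The cross-sample scan standardizes each sample's raw count by its depth
(total read bases / genome size; 2.7 Gb for mouse data, the true size for
simulations — the ranking is invariant to any common rescaling), computes
the per-k-mer variance with the n−1 denominator, k-mers absent from a
sample contributing 0, and ranks the top 1,000 by default.

Variance partitioning uses sequential (type-I) sums of squares in the
user-given factor order (strain before library; subspecies before
population before individual), reporting percent variance = SS / total SS
× 100 plus the residual so percentages sum to 100. Fitting is delegated to
OLS + ANOVA from statsmodels; single-level factors contribute 0 with a
warning.

## Centromere Diversity Index

The mapper is an internal ungapped best-identity scan of the read and its
reverse complement against the consensus tiled across its junction
(circular), with ties between satellites treated as ambiguous (unmapped),
position ties resolved leftmost, and strand ties resolved to forward. An
ungapped contract is deliberate: the CDI counts substitution differences
and ignores indels, so gapped placement would blur the statistic's
definition. Default minimum identity is 0.8.

Reads are grouped by (satellite, strand, start); strand partitioning
prevents comparing a sequence to its own reverse complement. Each pair's
difference count over the overlapping span is rescaled to the repeat-unit
length, `d_ij = mismatches × L / overlap` (raw-mismatch mode available),
making the CDI a per-unit quantity comparable across read lengths: a CDI
of 17 on L = 120 is ~14% divergence between two random repeat copies.
Pairs overlapping fewer than 30 bp are skipped. Positions with many reads
are subsampled to a seeded cap of 200 pairs per position; below the cap all
pairs are used, and the uncapped statistic equals a brute-force all-pairs
loop exactly.

Under the generator's independent per-copy substitution model the
expectation is analytic — two random copies differ at a site with
probability 2p(1−p), so E[CDI] ≈ 2·L·p(1−p) — and the estimator matches it
within a few percent at p ∈ {0.02, 0.05, 0.10} (250 copies, 12× depth,
100-bp reads). Per-base sequencing error e inflates the CDI by ≈ 2·L·e.

## Polymorphism matrix

Observed k-mers within Hamming distance h of any consensus window (h ≤ 2
for k = 15, h ≤ 5 for k = 31; "edit distance" is substitution-only, in
line with the indel-free treatment above) contribute their frequency to the
nucleotide they carry at each consensus position they cover, oriented per
window onto the consensus strand, with ties across positions splitting
weight equally (winner-take-all available). Columns are normalized to
relative probabilities summing to 1; the per-position non-consensus
fraction is 1 minus the consensus base's probability, and sites at ≥20%
non-consensus usage are called variable.

Matching scans each distinct observed k-mer against all L windows in
chunked vectorized batches — O(#distinct k-mers × L) — rather than
enumerating the Hamming neighborhood (≈41 million words per position at
k = 31, h = 5). No seed prefilter is applied: at h = 5 the pigeonhole
seed length is only ⌊k/(h+1)⌋ = 5 bp, too unselective to prune, and the
vectorized scan is already fast at desk scale. A planted 50/50 biallelic
site reads out at 0.50 ± 0.05 with all other positions < 0.05.

The matrix and the CDI measure related but distinct quantities: mean
non-consensus fraction ≈ divergence of a random copy *from the consensus*
(≈ p under the i.i.d. model), while the CDI is divergence *between two
random copies* (≈ 2p(1−p)); the two agree through that factor-of-two
conversion within ~25% on simulations.

## Phylogenetic heritability

The trait model is `y ~ N(μ1, σ²_phylo·G + σ²_resid·I)` with
G_ij the shared root-to-MRCA path length of tips i and j, computed from
newick input as (d_i + d_j − patristic_ij)/2. Trees may be non-ultrametric
(wild-mouse ML trees are) and are used as-is; G is rescaled internally to
unit mean diagonal, which makes H²_P invariant to global branch-length
rescaling and to affine transforms of the trait.

Fitting is maximum likelihood (not REML; with a single mean parameter the
difference is minor at these n) via a profile over the mixing ratio
λ = σ²_phylo/(σ²_phylo+σ²_resid) ∈ [0, 1]: after one eigendecomposition of
G the likelihood at any λ costs O(n), so a 101-point grid plus bounded
refinement to 1e-6 is cheap; Ĥ²_P = λ̂. The implementation agrees with a
direct 3-parameter Nelder-Mead ML fit to three decimals. On 32-tip
pure-birth trees, pure-Brownian traits recover median Ĥ²_P ≈ 1.0 and
i.i.d. traits ≈ 0.0 over 100 replicates. At intermediate signal the ML
sampling spread is wide at small n (at a 50/50 mixture, n = 64, only
~60% of estimates fall within ±0.2 of 0.5; ~90% at n = 256), a property of
the estimator itself, verified against the oracle fit.

Significance uses a tip-shuffling permutation test with the one-sided,
+1-smoothed p-value `(1 + #{Ĥ²_perm ≥ Ĥ²_obs}) / (n_perm + 1)` (default
n_perm = 1,000, seeded). Because the boundary-constrained estimator has a
point mass at λ = 0 under an exchangeable null (~half of fits), observed
and permuted statistics tie in bulk and the null p-value distribution piles
up near 1: the test is *conservative* — empirical P(p ≤ α) ≤ α holds at
all α — but is not exactly uniform, and no implementation of a
boundary-constrained H²_P can make it so. Uniformity should not be used as
a correctness check for this test; validity (non-anti-conservatism) is the
property the suite asserts.

## Synthetic data

The generator emulates exactly what the estimators consume: a tandem array
of `copies` mutated repeat units (independent per-copy substitutions at a
scalar or per-position rate; optional shared variants planted at chosen
positions with population frequencies, modeling CENP-B-box-like alleles),
embedded after a uniform-ACGT background of configurable GC content, and
reads sampled uniformly from both strands with per-base i.i.d. errors and
GC-dependent *thinning* (acceptance probability as a function of read GC),
chosen over duplication so expected counts stay analytic. All generators
are deterministic given seeds, and truth tables suffice to compute every
estimator's true value in closed form. The bundled 120-bp repeat-unit
consensus is a fixed random synthetic sequence, not a biological satellite.

Default scenario bundles contrast a large homogeneous array (2,000 copies,
rate 0.02, "inbred-like") with a small heterogeneous one (300 copies, rate
0.10, "wild-like"), reproducing qualitatively the negative relationship
between copy number and diversity seen between inbred and wild genomes.

What the simulations do *not* model: real mouse genomic background
(transposons, segmental duplications that share k-mers with satellites),
higher-order repeat structure, indels within repeats, PCR duplicates, or
quality-dependent error profiles. Passing tests therefore establish the
estimators' correctness under their stated models, not the absence of
k-mer homoplasy or alignment artifacts in real genomes.

## Problem sizes

Simulation checks run on desk-scale inputs chosen to keep Monte-Carlo
error well inside the asserted tolerances: 40–100-kb backgrounds,
arrays of 40–10,000 copies, 20× depth, 100-bp reads, panels of
15,000–20,000 unique k-mers, 100 heritability replicates on 32-tip trees,
and ~100-replicate permutation-calibration sweeps at n_perm = 99. The
acceptance script (`scripts/acceptance.py`) re-runs all of them from
scratch in well under a minute on one CPU.
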