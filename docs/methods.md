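# Methods

This note documents the models, estimators and design choices behind each
stage, what the synthetic generators do and do not emulate, and the numerical
conventions that make runs reproducible.

## Synthetic expression model

Bulk expression is simulated on the log2 scale: per-gene baseline drawn once
from Normal(5, 1), plus additive group-specific program effects, plus iid
Normal noise per entry. A *program* is a set of gene indices with a log2 mean
shift per group and its own noise sd. The default study is 2,000 genes × 9
samples (three groups of three: typeI, typeII, dualpos) with three programs:

| program   | genes    | effect (+log2)        | noise sd |
|-----------|----------|-----------------------|----------|
| typeI     | 0–149    | typeI, dualpos        | 0.25     |
| typeII    | 150–299  | typeII, dualpos       | 0.25     |
| embryonic | 300–599  | dualpos only          | 0.25     |

The dual-positive group therefore literally shares planted structure with
both single-positive groups and additionally carries an embryonic program —
the level at which the biological claim ("dual-positive cells share
properties of both type I and type II cells and resemble embryonic
progenitors") is testable on synthetic data. The effect size (+2 log2) and
noise (0.25) were chosen so that a three-vs-three contrast detects a typical
program gene decisively (per-gene fold-change SE ≈ 0.2) without making the
problem trivial at the single-gene level.

Reference panels for signature derivation use the same gene-id space: the
two progenitor panels plant 150-gene programs (+3 log2, the focal type vs a
pooled "other" group, 4 + 4 samples) *inside* the study's embryonic block
(300–449 and 450–599), so signatures derived from them probe the
dual-positive group's embryonic component; the differentiated panel plants
at 600–749, outside every study program, and acts as a negative control.

The oncogene-module cell-line panel is raw-scale and nonnegative: the
1,000-gene module carries a planted rank-3 structure (block-structured W,
near-one-hot H per cell line) plus truncated Normal noise; genes outside the
module are state-independent gamma background. The generator also returns
the planted factors and state labels for parameter-recovery tests, and
`plant_module_activity` overlays a chosen state's factor onto study samples
to simulate populations occupying a known oncogenic state.

Cell tables for gating emulate compensated, log10-transformed flow
intensities as spherical Normals per population: background at 1.0 decades,
stained populations at 5.0, sd 0.5, giving ~4 sd of separation around the
midpoint gate (3.0) so that misgating bias is negligible against binomial
sampling error at n = 100,000. Dual-positive cells are high on both markers.
CT tables are built by inverting the ΔΔCT formula, so the noiseless table
reproduces the requested fold changes exactly.

What the generators do **not** emulate: count-level noise (negative
binomial/overdispersion), library-size and composition effects, correlated
gene–gene noise, batch structure, doublets or spillover in cytometry, or the
distributions of any real GEO series. Passing tests demonstrate that each
stage recovers structure it is designed to detect under a clean, planted
model — not performance on real data.

One global seed drives everything; per-operation child seeds are derived by
fixed offsets (`simulate.SEED_OFFSETS`), keeping stages decoupled but the
whole pipeline reproducible from one integer.

## Differential expression and signatures

Per gene: mean log2 difference, two-sided Welch (unequal-variance) t-test,
BH step-up FDR across genes, and a GSEA-style signal-to-noise ratio
(meanA − meanB)/(sdA + sdB) with each sd floored at max(0.2·|mean|, 0.2).
Welch was preferred over the pooled-variance test because group sizes of
three make the equal-variance assumption both uncheckable and consequential;
the variance floor keeps SNR stable at these sizes. Signatures are the top-N
genes by SNR in a one-vs-rest contrast, upregulated only by default
(signatures act as positive enrichment probes); ranking by |SNR| is
available. Ties break lexicographically by gene id, making derivation
deterministic and column-order invariant.

## ssGSEA

Profiles are rank-normalized per sample (average ties, ranks mapped to
(0, 1] by r/n), making scores invariant to any strictly increasing
per-sample transform. The enrichment score is the running-sum *total* (area
form) of the weighted in-set ECDF minus the out-of-set count ECDF — matching
the ECDF-difference description rather than the max-deviation (KS) form.
Weight exponent defaults to 0.75, the conventional single-sample GSEA
choice; sets overlapping the matrix by fewer than 5 genes are dropped with a
warning. Scores are not renormalized across samples by default; a min-max
normalized view is available (`EnrichmentMatrix.minmax_normalized`).

## Information coefficient

IC(x, y) = sign(ρ)·sqrt(1 − exp(−2·MI)) with MI estimated on standardized
values by a product-Gaussian KDE evaluated on a fixed 25×25 grid padded 3
bandwidths beyond the data range. The per-axis bandwidth is
1.8·n^(−1/6)/(1 + 3|ρ|): a Silverman-type power law whose correlation
shrinkage counters the downward MI bias of isotropic smoothing on elongated
clouds, and whose overall scale keeps the positive finite-sample MI bias
small under independence. Both constants were calibrated once against the
bivariate-Gaussian closed form (MI = −½ln(1−ρ²), hence IC = |ρ|), which the
test suite enforces at ρ ∈ {0.3, 0.6, 0.9} (±0.05 at n = 5,000), together
with near-zero null bias (mean |IC| < 0.1 at n = 1,000) and saturation on
identical vectors. The closed form, not any bandwidth constant, is the
estimator's contract.

Permutation significance shuffles y with a seeded generator;
p = (1 + #{|IC*| ≥ |IC_obs|})/(n_perm + 1), so p is bounded below by
1/(n_perm + 1) and exactly uniform under exchangeability. With nine samples
only 9! distinct label permutations exist; permutations are sampled with
replacement (default 1,000) rather than enumerated. Binary or
low-cardinality phenotypes are jittered by Normal(0, 1e-6) before density
estimation to avoid degenerate KDEs; the jitter is far below any score
scale. Collection-level results are BH-adjusted across sets and sorted by
IC.

## NMF and cluster assignment

Frobenius-norm NMF by Lee–Seung multiplicative updates, which provably never
increase the objective; the recorded objective trace is asserted
non-increasing (1e-9 relative slack for float noise). The best of
`n_restarts` (default 20) seeded uniform random initializations is kept;
convergence when the relative objective drop falls below 1e-6 or at 2,000
iterations. Log-scale matrices are shifted by their global minimum to enter
the nonnegative cone (logged); the shift is recorded on the model. The model
keeps the raw fitted W/H (so V ≈ WH and the trace remain meaningful) and
exposes `sample_weights`, the column-L1-normalized view of H used by cluster
assignment and map projection; column normalization is a per-sample positive
scaling, so argmax cluster assignments are identical between views. Ties in
argmax resolve to the lowest factor index. No consensus/cophenetic machinery
is included — the target analysis presents a single clustering, and rank is
a user input.

Projection of new profiles onto a frozen W runs the H-update only (a convex
subproblem with a unique minimizer when W has full column rank), then
column-normalizes; all-zero profiles stay zero and are flagged.

## Onco-GPS maps

The reference panel is restricted to the module genes (≥ 80% of the module
must be present), decomposed at `k_nodes` (default 9); nodes are placed
equally spaced on the unit circle ordered by factor index — a deterministic
convention replacing force-directed layout, since only relative geometry is
interpreted. States are defined on the reference samples by an in-repo
seeded Lloyd k-means (k-means++ init, 50 restarts, empty clusters reseeded
at the farthest point) on the column-normalized factor weights; its inertia
is oracle-checked against scikit-learn in the tests. Projected samples pull
toward nodes by w^p (pull exponent default 2, sharpening placement toward
the dominant factor) — a convex combination, so every projection lies inside
the node hull — and inherit the state of the nearest reference sample in
factor-weight space (states are defined by the reference, not re-clustered).
State labels on synthetic maps are numeric.

## Quantifications

ΔΔCT: replicate CTs are averaged per condition before dCT (the common
convention; per-replicate normalization is a legitimate alternative the
table layout supports), dCT = CT(target) − CT(housekeeping), ddCT =
dCT(treated) − dCT(control), fold change 2^−ddCT. CT values are validated
into (0, 45) cycles. Gating applies fixed thresholds (inputs, not inferred)
and maps each cell's sign pattern to a population label; rule sets must
partition the pattern space, percentages sum exactly to 100. The 2×2
engraftment comparison reports the two-sided Fisher exact p (scipy) and a
Haldane-corrected odds ratio (0.5 added to every cell when any cell is
zero).

## Pipeline

Stages communicate only through files in the output directory; the manifest
records every artifact with its SHA-256 and stage parameters, and a rerun
with an identical config is byte-identical (fixed seeds, 12-significant-
digit numeric formatting). Config is YAML merged over committed defaults
(`config/default.yaml`) and validated before any compute.

## Problem sizes and known limitations

Default sizes (2,000 genes, 9 samples, 60 cell lines, 100,000 cells,
1,000 permutations) mirror the target study's design at desk scale and keep
a full pipeline run near ten seconds on one core. Limitations: the IC
estimator's constants are tuned to the Gaussian limit and are not guaranteed
minimax for heavy-tailed data; NMF is non-unique, so factors are comparable
only at the objective level across implementations; signature derivation
assumes a pooled "rest" group is a meaningful background; gating assumes
independent spherical marker noise; no count-model differential expression
(no dispersion shrinkage) is provided.
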