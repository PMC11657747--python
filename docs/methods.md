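# Methods

`sparsecnv` infers integer copy-number profiles from sparse single-cell
DNA fragment data and evaluates how well those profiles — and profiles
inferred from expression — agree with a bulk reference. This note
documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic-data generators do and do
not emulate.

## Coordinate frame and counting

All coordinates are 0-based, half-open (fragments-file / BED
convention). A genome is tiled chromosome by chromosome with fixed-width
bins; each chromosome's last bin is truncated at the chromosome length,
so the bin count is Σ ceil(length / bin_size). On the built-in GRCh38
primary assembly (chr1–22, X, Y) the 1 Mb frame has 3102 bins.

A fragment contributes its `support` count to the single bin containing
its **start** coordinate. This keeps counting additive, order-independent
and a partition (no fragment is split or double-counted). The counting
convention of upstream read counters is not standardised; the
start-position rule is this package's documented choice. No
deduplication is performed — the support column is trusted as given.

## Cell calling

Cells are separated from ambient barcodes on the log-log barcode rank
curve. A cubic smoothing spline is fit to (log10 rank, log10 count); the
knee is the point of steepest descent of the fitted curve, the threshold
is the fitted count there, and barcodes strictly above the threshold are
selected. The smoothing factor is chosen by deterministic k-fold
cross-validation (interleaved folds, geometric grid around scipy's
default scale); this is the package's estimator for a data-driven
smoothness — classical GCV requires the smoother's hat matrix, which
scipy does not expose. A slope floor (default −0.5 in log-log units)
guards against calling a knee on featureless curves; below it the caller
is directed to the fixed cutoff method (default 10,000 fragments).

One caveat observed on synthetic data: the extreme tail of any rank
curve is steep in log-rank space because ranks bunch together, so a
pure, ambient-free population can still present a "knee" at its very
tail. That knee is harmless (it selects essentially the whole
population); the guard exists for flat curves, not for tails.

After calling, a quality filter at 1 Mb removes barcodes whose fraction
of non-empty bins is below 0.90 — genuine nuclei at ≥ 0.01× coverage
touch nearly every megabase, ambient aggregates do not. The filter is
defined at 1 Mb only and is idempotent. Coverage uniformity per unit is
summarized by the Lorenz curve of per-bin counts and its Gini
coefficient (trapezoid rule; 0 = uniform, (n−1)/n = fully concentrated).

## Metacelling

Fine-bin copy-number calling needs more reads than one sparse nucleus
provides, so genetically similar cells are pooled under a coverage
constraint:

1. counts at 1 Mb are normalized per cell (counts-per-10k, log1p) and
   embedded by PCA keeping 95% of variance (smallest such k; component
   signs fixed by largest-loading positivity);
2. Leiden preclustering on a kNN graph (k = 15) produces premetacells;
   the resolution starts at 1.0 and doubles (≤ 20 rounds) until every
   cluster's aggregated mean reads per bin is at most the cap (default
   1200) or the offenders are singletons;
3. premetacells are categorized by mean reads per bin: insufficient
   (< 200), sufficient (200–1200), high (> 1200). The 200 floor equals
   0.02× coverage at 100 bp per fragment in a 1 Mb bin;
4. a greedy pass visits pairs in ascending genetic distance and merges a
   pair iff the distance is within a threshold and the pair is
   insufficient+insufficient or insufficient+sufficient. High units
   never merge (pooling them would create outlier depths). Each unit
   merges at most once per pass; categories and distances are
   recomputed between passes; passes repeat until none merges. The unit
   count strictly decreases every merging pass, so termination is
   guaranteed.

Genetic distance is 1 − Pearson correlation of log1p median-of-ratios
normalized aggregated 1 Mb profiles. Correlation distance was chosen
over Euclidean distance in PC space because it is invariant to depth and
directly comparable across passes as units grow; constant profiles are
assigned the maximal distance 2. The merge threshold is selected from
the n = 10 evenly spaced quantiles of the premetacell distances: each
candidate is evaluated by merging to convergence and recording (mean
within-metacell profile variance, number of insufficient units left);
both criteria are min–max normalized and their sum minimized, ties going
to the smaller threshold. Because merging is iterative, the selected
threshold can sit below the within-group distance range and still
produce the same final partition — the tie rule then prefers it.

## Copy-number calling

Each unit's counts are normalized to log2 ratios against the unit's own
mean with a pseudocount of 0.5: r_b = log2((c_b + 0.5) / (mean + 0.5)).
This assumes a mostly diploid genome; heavily aberrant genomes shift the
baseline and with it all state anchors (a known limitation shared by
mean-normalizing CNV callers). Bins with zero counts across all units
are masked.

Segmentation uses a 6-state Gaussian hidden Markov model, states = copy
numbers 0–5, with fixed state means log2(max(cn, 0.5)/2) and one shared
emission SD per unit. The transition matrix starts with stay probability
`e` on the diagonal and (1 − e)/5 off it. EM refits the shared SD and,
under a Dirichlet prior of weight `strength` on the initial transition
rows, the transition matrix; at `strength` ≥ 1e6 the update is
numerically frozen and skipped. The chain is decoded by Viterbi,
independently per chromosome. Free per-state means are deliberately not
fit: they break identifiability on sparse profiles and decouple states
from copy numbers.

Bin-size parameter table: e = 0.995 (strength 1e7, the package default)
at 1 Mb and 500 kb; e = 0.999999999999999 with strength 1e30 at 100 kb,
50 kb and 10 kb, which freezes the transition matrix and heavily
penalizes switching on noisy fine bins.

Numerical choices:

- normalized ratios are clipped to ±3 before decoding. At high depth a
  zero-count bin has ratio ≈ −8; such outliers dominate the shared-SD
  EM update and flatten the segmentation. The deepest anchor is −2, so
  the clip preserves homozygous-loss evidence. (The `normalize_profile`
  contract itself is exact and unclipped.)
- the EM SD is warm-started at each unit's own profile SD (clipped to
  [0.05, 1.5]) and iterated to a relative change < 5e-3, at most 10
  sweeps.
- all forward/backward/Viterbi passes are vectorized across units, which
  is what makes genome-wide decoding of 10,000 cells practical on one
  core (minutes, in ~2000-cell blocks to bound memory).

States are collapsed to loss (< 2), neutral (= 2), gain (> 2);
homozygous and heterozygous deletions are deliberately not
distinguished because sparse data overcalls homozygous losses.

Clone structure is found by clustering units on the integer state
matrix: k-means (k-means++ with 10 restarts) for ordinary designs, or
Leiden at resolution 0.15 on a kNN graph (k = 15) for very large
combinatorial-indexing experiments where the rare population is a tiny
fraction. Cluster labels are contiguous with 0 the largest cluster.
Identity is assigned per unit and per cluster by Pearson correlation of
integer states to each bulk profile over the bins unmasked in both
(correlating states rather than log ratios is a package choice exposed
by the API; ties and zero-variance units are flagged unassigned).

## Concordance analysis

Calls and bulk references are reduced to loss/neutral/gain vectors on a
shared frame. Expression is mapped to bins by gene start coordinate
(mean over genes in a bin; geneless bins masked, never zero-filled) and
classified per cell by bulk-anchored quantiles: with bulk fractions
(f_loss, f_gain), values at or below the cell's own f_loss quantile are
losses, values strictly above the (1 − f_gain) quantile are gains.
Quantiles are type-7 (linear interpolation); a constant vector
degenerates to all-neutral with a warning.

Agreement is macro-F1 over the classes present in truth or prediction
(classes in truth but never predicted score 0; classes absent from both
are excluded). Non-overlapping windows of 5/10/50/100 bins tile the
genome in order; the final partial window is scored rather than dropped
(dropping would systematically discard chromosome ends). Windows where
the bulk is entirely neutral are skipped. Controls: 500 random
permutations of the bulk labels (class counts preserved exactly) and one
all-diploid profile; control scores are reported as separate rows, never
averaged into the assay mean.

## Synthetic data

The generators produce every input the pipeline consumes, as pure
functions of (parameters, seed):

- clone profiles: non-overlapping events on a diploid baseline, sizes
  and copy numbers drawn from configurable laws; optionally clone-private
  (disjoint) events so planted clones are uncorrelated;
- cell counts: counts_cb ~ NB(mean = depth_c · cn_b · bias_b / Σ cn·bias,
  dispersion), dispersion 0 being the Poisson limit; depths lognormal;
  per-bin bias lognormal; clone cell counts by largest-remainder
  rounding so planted fractions are exact (1% of 10,000 is exactly 100);
- bulk: Poisson counts around depth · cn/2 plus the true state vector;
- barcode universe: lognormal cell counts over a capped discrete
  power-law ambient background;
- expression: per-gene dosage baseline · (cn/2)^slope plus Gaussian
  noise, running-mean smoothed along the genome.

The spike-in condition (10,000 cells, 1% minor clone, 6 events of
50–250 Mb-bins per clone) simulates cells at mean 12,000 fragments
(lognormal, σ = 0.2) — the depth regime of a cell population defined by
a 10,000-fragment cutoff, and the minimum regime at which the 90%
non-empty-bin filter is satisfiable at all (at a few hundred fragments a
cell can touch only a few hundred of 3102 bins, and per-cell 1 Mb states
carry no clone signal).

What the generators do **not** emulate: GC/mappability bias structure
(only i.i.d. lognormal bias), doublets, read-level errors, subclonal
heterogeneity within a clone, allele-specific signal, and real ambient
contamination profiles. Passing tests therefore demonstrate the
pipeline's correctness and statistical behavior under its stated noise
model, not robustness to every artifact of real libraries. GC and
mappability correction are out of scope by default; `call_cnv` masks
user-supplied blacklist bins as the hook for externally derived
exclusion lists.

## Problem sizes used in the test suite

The suite runs planted-truth simulations at desk scale: the spike-in
recovery uses the full 10,000-cell, 3102-bin condition; metacelling
properties use 20 replicates of 200 cells × 300 bins; state recovery
uses 10 replicates of 6 units × 1000 bins at 200 reads/bin; the Viterbi
oracle enumerates all 6^n paths up to n = 9 bins and cross-checks 12-bin
instances against an independent reference decoder (full enumeration of
6^12 ≈ 2.2 × 10^9 paths is not tractable; the dynamic program and the
reference decoder agree exactly where enumeration is feasible).

## Known limitations

- The mean-normalization baseline drifts on heavily aberrant genomes
  (> ~30% of bins altered), which can mis-anchor states; a diploid
  baseline of 2 is assumed throughout (no whole-genome doubling
  inference).
- The Gaussian emission model is lighter-tailed than read-count noise;
  the ±3 clip is the pragmatic guard.
- "Genetic distance" between premetacells and the merge-threshold
  trade-off rule are package choices where the procedure is inherently
  underdetermined; both are isolated behind small functions.
- Cell calling assumes a bimodal barcode universe; nested or smeared
  ambient distributions may need the fixed cutoff.
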