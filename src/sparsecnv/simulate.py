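"""Synthetic data with the statistical structure the pipeline assumes.

Generates clonal integer copy-number profiles over a genome bin frame,
per-cell binned fragment counts (Poisson or negative-binomial around
depth x copy-number x per-bin bias), a high-depth bulk profile, an
ambient-barcode background for cell-calling tests, and dosage-coupled
noisy expression for the RNA concordance arm. All generators are pure
functions of their parameters and seed.

Coverage bookkeeping assumes 100 bp per fragment, so 200 fragments per
1 Mb bin corresponds to 0.02x coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cnv import collapse_deletions
from .errors import InvalidArgumentError
from .genome import CellBinMatrix, ChromSizes, GenomeBins


@dataclass(frozen=True)
class CloneSpec:
    """One clone's integer copy-number profile on a bin frame."""

    clone_id: str
    cn: np.ndarray                     # int per bin, 0..5, baseline 2
    events: tuple                      # (start_bin, end_bin, cn) with cn != 2

    def collapsed(self) -> np.ndarray:
        return collapse_deletions(self.cn)


@dataclass(frozen=True)
class SimParams:
    """Noise model for per-cell binned counts.

    counts_cb ~ NB(mean = depth_c * cn_{clone(c),b} * bias_b / sum_b cn*bias,
    dispersion); dispersion 0 is the Poisson limit. Depths are lognormal
    around ``mean_fragments``; per-bin bias is lognormal with sigma
    ``bias_sigma``. Clone cell counts use largest-remainder rounding so the
    planted fractions are exact.
    """

    n_cells: int = 1000
    fractions: tuple = (0.5, 0.5)
    mean_fragments: float = 300.0
    depth_sigma: float = 0.3
    bias_sigma: float = 0.0
    dispersion: float = 0.0
    read_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9 or any(
                not (0 < f <= 1) for f in self.fractions):
            raise InvalidArgumentError("clone fractions must be in (0,1] and sum to 1")
        if self.mean_fragments <= 0 or self.n_cells < 1:
            raise InvalidArgumentError("scale parameters must be positive")


def toy_chrom_sizes(n_chroms: int = 3, length: int = 100_000_000) -> ChromSizes:
    """Small equal-length genome for unit tests and fast simulations."""
    return ChromSizes(tuple((f"chr{i + 1}", length) for i in range(n_chroms)))


def simulate_clone_profiles(bins: GenomeBins, n_clones: int, n_events: int = 6,
                            event_size_bins: tuple[int, int] = (20, 100),
                            seed: int = 0,
                            cn_choices: tuple = (0, 1, 3, 4, 5),
                            cn_weights: tuple = (0.10, 0.35, 0.35, 0.15, 0.05),
                            disjoint_events: bool = False,
                            ) -> list[CloneSpec]:
    """Plant non-overlapping CNV events on a diploid baseline, per clone.

    Events stay within single chromosomes. Clones are pairwise distinct
    (at least one differing bin) by construction check. With
    ``disjoint_events`` no two clones alter the same bin (clone-private
    events), which keeps planted clone profiles uncorrelated.

    Homozygous deletions (CN 0) are kept focal (at most 10 bins): large
    CN-0 events would zero out a visible fraction of the genome, which
    real tumors do not do and which would make whole clones fail
    non-empty-bin QC.
    """
    lo, hi = event_size_bins
    if lo < 1 or hi < lo:
        raise InvalidArgumentError("event sizes must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    chrom_slices = bins.chromosome_slices()
    clones: list[CloneSpec] = []
    shared_occupied = np.zeros(bins.n_bins, dtype=bool)
    for k in range(n_clones):
        cn = np.full(bins.n_bins, 2, dtype=np.int8)
        occupied = shared_occupied if disjoint_events \
            else np.zeros(bins.n_bins, dtype=bool)
        events = []
        for _ in range(n_events):
            placed = False
            for _attempt in range(200):
                state = int(rng.choice(cn_choices, p=cn_weights))
                s_hi = min(hi, 10) if state == 0 else hi  # focal CN-0 only
                s_lo = min(lo, s_hi)
                size = int(rng.integers(s_lo, s_hi + 1))
                eligible = [sl for _, sl in chrom_slices
                            if sl.stop - sl.start >= size]
                if not eligible:
                    break
                sl = eligible[int(rng.integers(len(eligible)))]
                start = int(rng.integers(sl.start, sl.stop - size + 1))
                if occupied[start:start + size].any():
                    continue
                cn[start:start + size] = state
                occupied[start:start + size] = True
                events.append((start, start + size, state))
                placed = True
                break
            if not placed:
                raise InvalidArgumentError(
                    f"genome too small to place {n_events} events of "
                    f"{lo}-{hi} bins")
        clones.append(CloneSpec(f"clone{k}", cn, tuple(sorted(events))))
    for i in range(n_clones):
        for j in range(i + 1, n_clones):
            if np.array_equal(clones[i].cn, clones[j].cn):
                raise InvalidArgumentError(
                    "simulated clones are not pairwise distinct; change the seed")
    return clones


def assign_clone_cells(n_cells: int, fractions: tuple) -> np.ndarray:
    """Largest-remainder apportionment of cells to clones (exact fractions)."""
    quotas = np.asarray(fractions) * n_cells
    counts = np.floor(quotas).astype(int)
    short = n_cells - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:short]] += 1
    return np.repeat(np.arange(len(fractions)), counts)


def simulate_cell_counts(clones: list[CloneSpec], bins: GenomeBins,
                         params: SimParams,
                         ) -> tuple[CellBinMatrix, np.ndarray]:
    """Draw per-cell binned counts; returns (matrix, per-cell clone labels)."""
    if len(clones) != len(params.fractions):
        raise InvalidArgumentError("one fraction per clone required")
    rng = np.random.default_rng(params.seed)
    labels = assign_clone_cells(params.n_cells, params.fractions)
    mu = np.log(params.mean_fragments) - params.depth_sigma ** 2 / 2
    depths = rng.lognormal(mu, params.depth_sigma, size=params.n_cells)
    bias = (rng.lognormal(0.0, params.bias_sigma, size=bins.n_bins)
            if params.bias_sigma > 0 else np.ones(bins.n_bins))
    probs = np.stack([c.cn * bias for c in clones]).astype(float)
    probs /= probs.sum(axis=1, keepdims=True)
    blocks = []
    chunk = 2000
    for lo in range(0, params.n_cells, chunk):
        hi = min(lo + chunk, params.n_cells)
        means = depths[lo:hi, None] * probs[labels[lo:hi]]
        if params.dispersion > 0:
            shape = 1.0 / params.dispersion
            lam = rng.gamma(shape, means / shape)
            counts = rng.poisson(lam)
        else:
            counts = rng.poisson(means)
        blocks.append(sp.csr_matrix(counts.astype(np.int64)))
    matrix = CellBinMatrix([f"cell{i:06d}" for i in range(params.n_cells)],
                           bins, sp.vstack(blocks).tocsr())
    return matrix, labels


def simulate_bulk(clone: CloneSpec, bins: GenomeBins, depth_per_bin: float = 500.0,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """High-depth bulk profile: Poisson counts around depth x cn / 2.

    Returns (per-bin counts, true collapsed states).
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(depth_per_bin * clone.cn.astype(float) / 2.0)
    return counts, clone.collapsed()


def simulate_barcode_universe(n_cells: int = 500, cell_median: float = 20_000.0,
                              cell_sigma: float = 0.4, n_ambient: int = 20_000,
                              ambient_median: float = 50.0,
                              ambient_alpha: float = 1.5,
                              ambient_max: float = 4000.0,
                              seed: int = 0) -> tuple[dict, set]:
    """Fragment counts for a mixed barcode universe.

    Cell barcodes are lognormal around ``cell_median``; ambient barcodes
    follow a discrete power law (Pareto tail, exponent ``ambient_alpha``)
    with the stated median, capped at ``ambient_max`` so the background
    stays below the cell plateau. Returns (barcode -> count, true cell set).
    """
    rng = np.random.default_rng(seed)
    cell_counts = np.maximum(
        1, rng.lognormal(np.log(cell_median), cell_sigma, n_cells).astype(int))
    xm = ambient_median / 2 ** (1.0 / ambient_alpha)
    u = rng.random(n_ambient)
    ambient = np.minimum(np.floor(xm * (1 - u) ** (-1.0 / ambient_alpha)),
                         ambient_max).astype(int)
    ambient = np.maximum(ambient, 1)
    counts = {f"cell{i:06d}": int(c) for i, c in enumerate(cell_counts)}
    counts.update({f"amb{i:06d}": int(c) for i, c in enumerate(ambient)})
    return counts, set(list(counts)[:n_cells])


def simulate_expression(clones: list[CloneSpec], labels: np.ndarray,
                        bins: GenomeBins, n_genes: int = 2000,
                        baseline: float = 1.0, dosage_slope: float = 1.0,
                        noise_sd: float = 0.1, smoothing_span: int = 25,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage-coupled expression mapped to random gene positions.

    Per gene g in the bin with copy number cn, a cell's expression is
    baseline * (cn / 2) ** dosage_slope plus Gaussian noise, then smoothed
    along the genome with a running mean over ``smoothing_span`` genes —
    emulating the window-smoothed expression the concordance arm consumes.
    Returns (gene table with chrom/start/end/gene, cells x genes frame).
    """
    rng = np.random.default_rng(seed)
    gene_bins = np.sort(rng.integers(0, bins.n_bins, size=n_genes))
    names = [f"gene{i:05d}" for i in range(n_genes)]
    gene_table = pd.DataFrame({
        "chrom": [bins.chrom_names[bins.chrom_index[b]] for b in gene_bins],
        "start": bins.starts[gene_bins],
        "end": np.minimum(bins.starts[gene_bins] + 1000, bins.ends[gene_bins]),
        "gene": names,
    })
    cn_per_clone = np.stack([c.cn for c in clones]).astype(float)
    dose = baseline * (cn_per_clone[:, gene_bins] / 2.0) ** dosage_slope
    raw = dose[labels] + rng.normal(0.0, noise_sd, size=(len(labels), n_genes))
    if smoothing_span > 1:
        kernel = np.ones(smoothing_span) / smoothing_span
        pad = smoothing_span // 2
        padded = np.pad(raw, ((0, 0), (pad, pad)), mode="edge")
        smooth = np.apply_along_axis(
            lambda r: np.convolve(r, kernel, mode="valid"), 1, padded)
        smooth = smooth[:, :n_genes]
    else:
        smooth = raw
    expr = pd.DataFrame(smooth, columns=names,
                        index=[f"cell{i:06d}" for i in range(len(labels))])
    return gene_table, expr


def write_fragments(matrix: CellBinMatrix, path: str,
                    extra_counts: dict | None = None,
                    read_length: int = 100, seed: int = 0) -> None:
    """Serialize a count matrix as a fragments TSV (one line per nonzero
    cell/bin entry, the count in the support column; fragment start at the
    bin start). ``extra_counts`` adds background barcodes whose fragments
    are scattered over random bins — used to emulate ambient material for
    cell-calling runs.
    """
    import gzip

    bins = matrix.bins
    opener = gzip.open if path.endswith(".gz") else open
    rng = np.random.default_rng(seed)
    coo = matrix.counts.tocoo()
    with opener(path, "wt") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            chrom = bins.chrom_names[bins.chrom_index[j]]
            start = int(bins.starts[j])
            end = min(start + read_length, int(bins.ends[j]))
            fh.write(f"{chrom}\t{start}\t{end}\t{matrix.barcodes[i]}\t{int(v)}\n")
        if extra_counts:
            for barcode, count in extra_counts.items():
                j = int(rng.integers(bins.n_bins))
                chrom = bins.chrom_names[bins.chrom_index[j]]
                start = int(bins.starts[j])
                end = min(start + read_length, int(bins.ends[j]))
                fh.write(f"{chrom}\t{start}\t{end}\t{barcode}\t{int(count)}\n")


def spikein_params(seed: int = 0) -> SimParams:
    """The rare-clone spike-in condition: 10,000 cells with a 1% minor clone.

    Depths are lognormal around 12,000 fragments per cell, the regime of a
    cell population defined by a 10,000-fragment cutoff (at 1 Mb bins this
    gives ~4 reads per bin, enough for per-cell state calling, and ~98% of
    bins non-empty, consistent with the 90% non-empty-bin QC filter).
    """
    return SimParams(n_cells=10_000, fractions=(0.99, 0.01),
                     mean_fragments=12_000.0, depth_sigma=0.2, seed=seed)
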