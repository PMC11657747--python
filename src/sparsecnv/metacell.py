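"""Coverage-constrained metacelling of sparse single-cell DNA profiles.

Cells too sparse for fine-bin copy-number calling are aggregated into
metacells: (1) counts at 1 Mb are normalized and embedded by PCA keeping
95% of variance; (2) Leiden preclustering on a kNN graph produces
premetacells whose aggregated mean reads per bin must not exceed a cap
(resolution is doubled until the cap holds or offenders are singletons);
(3) premetacells are categorized by mean reads per bin as insufficient
(< 200 by default), sufficient, or high (> 1200); (4) a greedy pass merges
the closest pairs (by correlation distance on normalized aggregate
profiles) within a threshold, but only insufficient+insufficient or
insufficient+sufficient pairs — high-coverage units are never merged;
(5) categorize-and-merge repeats until no pass merges anything. The merge
threshold is picked from distance quantiles by a within-metacell-variance
versus unmerged-cells trade-off.

The 200 reads-per-Mb floor corresponds to 0.02x coverage at 100 bp per
fragment (see :func:`fragments_to_coverage`).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .cnv import leiden_cluster
from .errors import InvalidArgumentError
from .genome import CellBinMatrix

logger = logging.getLogger(__name__)

INSUFFICIENT, SUFFICIENT, HIGH = "insufficient", "sufficient", "high"

DEFAULT_READ_LENGTH = 100


def fragments_to_coverage(n_fragments: float, read_length: int = DEFAULT_READ_LENGTH,
                          bin_size: int = 1_000_000) -> float:
    """Sequence coverage implied by ``n_fragments`` reads of ``read_length`` bp
    in one bin: 200 fragments x 100 bp per 1 Mb bin = 0.02x."""
    return n_fragments * read_length / bin_size


@dataclass(frozen=True)
class MetacellParams:
    """Knobs of the metacelling procedure (defaults are the recommended
    operating point for ~0.02x-coverage single-nucleus DNA data)."""

    var_frac: float = 0.95          # PCA variance retained for preclustering
    max_reads_per_bin: float = 1200  # cap; units above are "high", never merged
    min_reads_per_bin: float = 200   # floor; 0.02x coverage at 100 bp reads
    n_quantiles: int = 10            # candidate merge-distance quantiles
    knn_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.var_frac <= 1):
            raise InvalidArgumentError("var_frac must be in (0, 1]")
        if not (0 <= self.min_reads_per_bin < self.max_reads_per_bin):
            raise InvalidArgumentError("need 0 <= min_reads_per_bin < max_reads_per_bin")
        if self.n_quantiles < 2:
            raise InvalidArgumentError("n_quantiles must be >= 2")


@dataclass
class Premetacell:
    id: str
    members: list[str]
    counts: np.ndarray  # aggregated per-bin counts
    category: str = SUFFICIENT

    @property
    def mean_reads_per_bin(self) -> float:
        return float(self.counts.sum() / len(self.counts))


@dataclass
class MetacellResult:
    assignment: dict            # barcode -> metacell id (a partition)
    metacells: list[Premetacell]
    merge_log: list             # (pass number, (id_a, id_b), distance)
    chosen_distance: float | None
    unmerged_insufficient: list[str]


def normalize_cells(matrix: CellBinMatrix) -> np.ndarray:
    """Depth-free per-cell profiles: counts-per-10k then log1p."""
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    totals = dense.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(dense / totals * 1e4)


def pca_embed(matrix: CellBinMatrix | np.ndarray, var_frac: float = 0.95,
              seed: int = 0) -> np.ndarray:
    """PCA embedding keeping the smallest k components whose cumulative
    explained variance reaches ``var_frac``.

    Input cells are normalized (counts-per-10k, log1p) so depth does not
    dominate the leading components. Deterministic: component signs are
    fixed by making each component's largest-magnitude loading positive.
    """
    X = normalize_cells(matrix) if isinstance(matrix, CellBinMatrix) else np.asarray(matrix, float)
    n = X.shape[0]
    if n < 2:
        raise InvalidArgumentError("PCA embedding needs at least 2 cells")
    if np.allclose(X, X[0]):
        warnings.warn("all cells identical: zero variance, returning one null component",
                      stacklevel=2)
        return np.zeros((n, 1))
    max_rank = min(n - 1, X.shape[1])
    n_comp = min(max_rank, 128)
    while True:
        solver = "full" if n_comp >= max_rank or max(X.shape) < 500 else "randomized"
        pca = PCA(n_components=min(n_comp, max_rank), svd_solver=solver,
                  random_state=seed)
        emb = pca.fit_transform(X)
        cum = np.cumsum(pca.explained_variance_ratio_)
        if cum[-1] >= var_frac or n_comp >= max_rank:
            break
        n_comp = min(n_comp * 2, max_rank)
    k = int(np.searchsorted(cum, var_frac) + 1)
    k = min(k, emb.shape[1])
    emb = emb[:, :k]
    comps = pca.components_[:k]
    signs = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    signs[signs == 0] = 1.0
    return emb * signs[None, :]


def categorize(premetacells: list[Premetacell], min_reads_per_bin: float,
               max_reads_per_bin: float) -> list[Premetacell]:
    """Assign coverage categories in place: < min -> insufficient,
    > max -> high, otherwise sufficient."""
    for pm in premetacells:
        m = pm.mean_reads_per_bin
        pm.category = INSUFFICIENT if m < min_reads_per_bin else (
            HIGH if m > max_reads_per_bin else SUFFICIENT)
    return premetacells


def precluster_leiden(embedding: np.ndarray, matrix: CellBinMatrix,
                      max_reads_per_bin: float, seed: int = 0,
                      knn_k: int = 15, max_rounds: int = 20) -> list[Premetacell]:
    """Leiden-precluster cells so every cluster's aggregated mean reads per
    bin is at most the cap; resolution starts at 1.0 and doubles until the
    cap holds or the offending clusters are singletons (kept as "high")."""
    n = embedding.shape[0]
    if n != matrix.n_cells:
        raise InvalidArgumentError("embedding rows must align with matrix rows")
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    n_bins = matrix.bins.n_bins
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        resolution = 1.0
        for _ in range(max_rounds):
            labels = leiden_cluster(embedding, resolution=resolution, seed=seed, k=knn_k)
            sizes = np.bincount(labels)
            agg_mean = np.array([dense[labels == c].sum() / n_bins
                                 for c in range(labels.max() + 1)])
            offenders = (agg_mean > max_reads_per_bin) & (sizes > 1)
            if not offenders.any():
                break
            resolution *= 2.0
        else:
            logger.warning("precluster_leiden: coverage cap still violated by "
                           "multi-cell clusters after %d rounds", max_rounds)
    out = []
    for c in range(labels.max() + 1):
        members = [matrix.barcodes[i] for i in np.flatnonzero(labels == c)]
        out.append(Premetacell(id=f"pm{c:04d}", members=members,
                               counts=dense[labels == c].sum(axis=0)))
    return out


def _median_of_ratios_profiles(premetacells: list[Premetacell]) -> np.ndarray:
    """log1p median-of-ratios-normalized aggregated profiles (units x bins)."""
    counts = np.stack([pm.counts for pm in premetacells]).astype(float)
    allpos = (counts > 0).all(axis=0)
    if allpos.any():
        logc = np.log(counts[:, allpos])
        ref = logc.mean(axis=0)
        size = np.exp(np.median(logc - ref[None, :], axis=1))
    else:  # fall back to total-count scaling
        totals = counts.sum(axis=1)
        size = totals / max(totals.mean(), 1.0)
        size[size == 0] = 1.0
    return np.log1p(counts / size[:, None])


def pairwise_distance(premetacells: list[Premetacell]) -> np.ndarray:
    """Genetic distance between premetacells: 1 - Pearson correlation of
    log1p median-of-ratios-normalized aggregated profiles. Constant
    (zero-variance) profiles sit at the maximal distance 2.0."""
    if len(premetacells) < 2:
        raise InvalidArgumentError("need at least 2 premetacells")
    prof = _median_of_ratios_profiles(premetacells)
    sd = prof.std(axis=1)
    # tolerance: a constant profile differs from 0 only by rounding
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(prof).max(axis=1))
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} premetacell(s) have constant "
                      "profiles; distances to them set to 2.0", stacklevel=2)
    centered = prof - prof.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(centered, axis=1)
    norm[norm == 0] = 1.0
    corr = (centered / norm[:, None]) @ (centered / norm[:, None]).T
    dist = 1.0 - corr
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    return np.maximum(dist, 0.0)


def greedy_merge_pass(premetacells: list[Premetacell], distances: np.ndarray,
                      threshold: float) -> tuple[list[Premetacell], list]:
    """One greedy pass: visit pairs in ascending distance (ties by id) and
    merge a pair iff distance <= threshold, the categories are
    insufficient+insufficient or insufficient+sufficient, and neither member
    merged earlier in this pass. High-coverage units never merge."""
    order = sorted(
        ((distances[i, j], premetacells[i].id, premetacells[j].id, i, j)
         for i, j in itertools.combinations(range(len(premetacells)), 2)),
        key=lambda t: (t[0], t[1], t[2]))
    used: set[int] = set()
    merges = []
    merged_units: list[Premetacell] = []
    for dist, _, _, i, j in order:
        if dist > threshold:
            break
        if i in used or j in used:
            continue
        cats = {premetacells[i].category, premetacells[j].category}
        ok = cats == {INSUFFICIENT} or cats == {INSUFFICIENT, SUFFICIENT}
        if not ok:
            continue
        a, b = premetacells[i], premetacells[j]
        merged_units.append(Premetacell(
            id=min(a.id, b.id),
            members=a.members + b.members,
            counts=a.counts + b.counts))
        used.update((i, j))
        merges.append((a.id, b.id, float(dist)))
    survivors = [pm for k, pm in enumerate(premetacells) if k not in used]
    return survivors + merged_units, merges


def _merge_to_convergence(premetacells: list[Premetacell], threshold: float,
                          params: MetacellParams) -> tuple[list[Premetacell], list]:
    pms = [Premetacell(pm.id, list(pm.members), pm.counts.copy()) for pm in premetacells]
    log = []
    pass_no = 0
    while len(pms) > 1:
        pass_no += 1
        categorize(pms, params.min_reads_per_bin, params.max_reads_per_bin)
        dist = pairwise_distance(pms)
        pms, merges = greedy_merge_pass(pms, dist, threshold)
        if not merges:
            break
        log.extend((pass_no, (a, b), d) for a, b, d in merges)
    categorize(pms, params.min_reads_per_bin, params.max_reads_per_bin)
    return pms, log


def _within_variance(pms: list[Premetacell], cell_profiles: np.ndarray,
                     row_of: dict) -> float:
    """Mean over metacells of the mean per-bin variance across member cells."""
    vals = []
    for pm in pms:
        rows = [row_of[b] for b in pm.members]
        if len(rows) < 2:
            vals.append(0.0)
        else:
            vals.append(float(cell_profiles[rows].var(axis=0).mean()))
    return float(np.mean(vals)) if vals else 0.0


def select_merge_distance(premetacells: list[Premetacell], params: MetacellParams,
                          cell_profiles: np.ndarray, row_of: dict) -> float:
    """Pick the merge threshold from ``n_quantiles`` evenly spaced quantiles
    of the premetacell distances by minimizing the sum of min-max-normalized
    (within-metacell variance, unmerged-insufficient count); ties prefer the
    smaller threshold."""
    if len(premetacells) < 2:
        raise InvalidArgumentError("need at least 2 premetacells")
    categorize(premetacells, params.min_reads_per_bin, params.max_reads_per_bin)
    dist = pairwise_distance(premetacells)
    upper = dist[np.triu_indices(len(premetacells), k=1)]
    qs = np.quantile(upper, np.arange(1, params.n_quantiles + 1) / params.n_quantiles)
    candidates = np.unique(qs)
    within = np.empty(len(candidates))
    unmerged = np.empty(len(candidates))
    for i, thr in enumerate(candidates):
        pms, _ = _merge_to_convergence(premetacells, float(thr), params)
        within[i] = _within_variance(pms, cell_profiles, row_of)
        unmerged[i] = sum(pm.category == INSUFFICIENT for pm in pms)

    def _minmax(v: np.ndarray) -> np.ndarray:
        rng = v.max() - v.min()
        return np.zeros_like(v) if rng == 0 else (v - v.min()) / rng

    score = _minmax(within) + _minmax(unmerged)
    best = int(np.flatnonzero(score == score.min())[0])  # ties: smaller threshold
    return float(candidates[best])


def run_metacelling(matrix: CellBinMatrix, params: MetacellParams | None = None,
                    ) -> MetacellResult:
    """Full metacelling: embed, precluster, pick a merge distance, and merge
    to convergence. Input should already have passed the non-empty-bin QC
    filter and be binned at 1 Mb."""
    params = params or MetacellParams()
    if matrix.n_cells == 0:
        raise InvalidArgumentError("empty matrix")
    if matrix.n_cells == 1:
        pm = Premetacell("pm0000", list(matrix.barcodes),
                         np.asarray(matrix.counts.todense(), float)[0])
        categorize([pm], params.min_reads_per_bin, params.max_reads_per_bin)
        return MetacellResult({matrix.barcodes[0]: pm.id}, [pm], [], None,
                              [pm.id] if pm.category == INSUFFICIENT else [])
    embedding = pca_embed(matrix, var_frac=params.var_frac, seed=params.seed)
    pms = precluster_leiden(embedding, matrix, params.max_reads_per_bin,
                            seed=params.seed, knn_k=params.knn_k)
    categorize(pms, params.min_reads_per_bin, params.max_reads_per_bin)
    if len(pms) == 1:
        final, log, chosen = pms, [], None
    else:
        cell_profiles = normalize_cells(matrix)
        row_of = {b: i for i, b in enumerate(matrix.barcodes)}
        chosen = select_merge_distance(pms, params, cell_profiles, row_of)
        final, log = _merge_to_convergence(pms, chosen, params)
    assignment = {b: pm.id for pm in final for b in pm.members}
    unmerged = [pm.id for pm in final if pm.category == INSUFFICIENT]
    return MetacellResult(assignment=assignment, metacells=final, merge_log=log,
                          chosen_distance=chosen, unmerged_insufficient=unmerged)
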