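"""Copy-number calling: normalization, HMM segmentation, state collapsing,
clone clustering, and identity assignment against bulk profiles.

Counts are normalized per unit to log2 ratios against the unit's own mean
(pseudocount 0.5), segmented per chromosome into integer states 0..5 with
the segmentation HMM, and collapsed to loss / neutral / gain — homozygous
and heterozygous deletions are deliberately not distinguished, since sparse
data overcalls homozygous losses. Units are clustered on the integer state
matrix (k-means, or Leiden on a kNN graph for very large experiments) and
each cluster is assigned an identity by Pearson correlation to bulk
copy-number profiles over the overlapping bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, InvalidArgumentError, ShapeError
from .genome import GenomeBins
from .hmm import HMMConfig, hmm_segment

LOSS, NEUTRAL, GAIN = -1, 0, 1
COLLAPSED_LABELS = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain"}

# bin size (bp) -> (e, strength). Small bins need a near-1 stay probability
# with a frozen transition matrix to suppress spurious switching.
PARAM_TABLE: dict[int, tuple[float, float]] = {
    1_000_000: (0.995, 1e7),
    500_000: (0.995, 1e7),
    100_000: (0.999999999999999, 1e30),
    50_000: (0.999999999999999, 1e30),
    10_000: (0.999999999999999, 1e30),
}


def normalize_profile(counts: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-bin log2 ratio of counts to the unit's unmasked mean.

    ratio_b = log2((c_b + 0.5) / (mean_unmasked + 0.5)). ``mask`` flags bins
    to exclude (True = masked); masked bins return NaN.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=float))
    squeeze = np.asarray(counts).ndim == 1
    if mask is None:
        mask = np.zeros(c.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise InvalidArgumentError("all bins are masked")
    mean = c[:, ~mask].mean(axis=1, keepdims=True)
    out = np.log2((c + 0.5) / (mean + 0.5))
    out[:, mask] = np.nan
    return out[0] if squeeze else out


def collapse_deletions(states: np.ndarray) -> np.ndarray:
    """Map integer states to collapsed calls: <2 -> loss, 2 -> neutral, >2 -> gain."""
    s = np.asarray(states)
    if s.size and (s.min() < 0 or s.max() > 5):
        raise InvalidArgumentError("states must be integers in [0, 6)")
    out = np.zeros_like(s, dtype=np.int8)
    out[s < 2] = LOSS
    out[s > 2] = GAIN
    return out


@dataclass
class CNVCalls:
    """Per-unit integer copy-number states and collapsed calls on a bin frame."""

    units: list[str]
    states: np.ndarray      # units x bins, int8; masked bins hold -1
    collapsed: np.ndarray   # units x bins, int8 in {LOSS, NEUTRAL, GAIN}
    mask: np.ndarray        # bins excluded from calling (True = masked)
    bins: GenomeBins
    params: dict = field(default_factory=dict)


def call_cnv(counts: np.ndarray | sp.spmatrix, bins: GenomeBins,
             unit_ids: Sequence[str], bin_size: int | None = None,
             hmm_overrides: Mapping | None = None,
             mask: np.ndarray | None = None,
             clip: float = 3.0,
             chunk_size: int = 1000) -> CNVCalls:
    """Normalize, segment, and collapse per-unit binned counts.

    The bin size selects (e, strength) from the parameter table; unknown
    sizes require explicit ``hmm_overrides``. Bins with zero counts across
    all units are masked automatically (on top of any user mask).
    Normalized log2 ratios are clipped to [-clip, clip] before decoding:
    zero-count bins at high depth otherwise produce ratios near -8 whose
    squared residuals dominate the shared Gaussian SD and flatten the
    segmentation (the deepest state anchor sits at -2, so +-3 keeps
    homozygous losses separable). Units are processed in chunks to bound
    memory on large experiments.
    """
    bin_size = bins.bin_size if bin_size is None else bin_size
    if bin_size in PARAM_TABLE:
        e, strength = PARAM_TABLE[bin_size]
        config = HMMConfig(e=e, strength=strength)
    elif hmm_overrides:
        config = HMMConfig()
    else:
        raise ConfigurationError(
            f"no HMM parameters for bin size {bin_size}; supply hmm_overrides")
    if hmm_overrides:
        config = replace(config, **dict(hmm_overrides))

    dense = np.asarray(counts.todense()) if sp.issparse(counts) else np.atleast_2d(np.asarray(counts))
    if dense.shape != (len(unit_ids), bins.n_bins):
        raise ShapeError(f"counts shape {dense.shape} != ({len(unit_ids)}, {bins.n_bins})")
    auto_mask = dense.sum(axis=0) == 0
    full_mask = auto_mask if mask is None else (auto_mask | np.asarray(mask, dtype=bool))
    if full_mask.all():
        raise InvalidArgumentError("every bin is masked (no counts anywhere)")

    keep = ~full_mask
    chrom_index = np.asarray(bins.chrom_index)[keep]
    states = np.full((len(unit_ids), bins.n_bins), -1, dtype=np.int8)
    for lo in range(0, len(unit_ids), chunk_size):
        sl = slice(lo, min(lo + chunk_size, len(unit_ids)))
        profiles = np.clip(normalize_profile(dense[sl][:, keep]), -clip, clip)
        block = states[sl]  # view: writes propagate to `states`
        block[:, keep] = hmm_segment(profiles, chrom_index, config)
    collapsed = np.zeros_like(states)
    collapsed[:, keep] = collapse_deletions(states[:, keep])
    return CNVCalls(units=list(unit_ids), states=states, collapsed=collapsed,
                    mask=full_mask, bins=bins,
                    params={"bin_size": bin_size, "e": config.e,
                            "strength": config.strength})


def correlate_to_bulk(calls: CNVCalls, bulk_profiles: Mapping[str, np.ndarray],
                      bulk_masks: Mapping[str, np.ndarray] | None = None,
                      ) -> tuple[np.ndarray, list[str | None]]:
    """Pearson r of each unit's integer states against each bulk profile.

    Only bins unmasked in both assays are used (the maximal overlapping bin
    set). Returns (units x bulks r matrix, per-unit argmax identity); units
    with zero state variance get NaN and identity None, as do exact ties.
    """
    names = list(bulk_profiles)
    r = np.full((len(calls.units), len(names)), np.nan)
    for j, name in enumerate(names):
        bulk = np.asarray(bulk_profiles[name], dtype=float)
        if bulk.shape[0] != calls.bins.n_bins:
            raise ShapeError(f"bulk {name!r} length {bulk.shape[0]} != {calls.bins.n_bins} bins")
        overlap = ~calls.mask
        if bulk_masks is not None and name in bulk_masks:
            overlap &= ~np.asarray(bulk_masks[name], dtype=bool)
        if not overlap.any():
            raise InvalidArgumentError(f"no overlapping bins with bulk {name!r}")
        b = bulk[overlap]
        X = calls.states[:, overlap].astype(float)
        bv = b - b.mean()
        xv = X - X.mean(axis=1, keepdims=True)
        denom = np.sqrt((xv ** 2).sum(axis=1) * (bv ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r[:, j] = np.where(denom > 0, xv @ bv / denom, np.nan)
    identity: list[str | None] = []
    for row in r:
        if np.all(np.isnan(row)):
            identity.append(None)
            continue
        best = np.nanargmax(row)
        if np.sum(row == row[best]) > 1:
            identity.append(None)  # tied — leave unassigned
        else:
            identity.append(names[best])
    return r, identity


@dataclass(frozen=True)
class CloneAssignment:
    labels: np.ndarray        # unit -> cluster label, contiguous from 0
    method: str               # "kmeans" | "leiden"
    parameters: dict
    bulk_r: np.ndarray | None = None
    identity: tuple | None = None


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters so 0 is the largest (ties: original label order)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in labels], dtype=int)


def knn_graph(X: np.ndarray, k: int = 15) -> igraph.Graph:
    """Undirected kNN graph (Euclidean) over rows of X."""
    n = X.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    return igraph.Graph(n=n, edges=sorted(edges), directed=False)


def leiden_cluster(X: np.ndarray, resolution: float, seed: int, k: int = 15) -> np.ndarray:
    graph = knn_graph(X, k=k)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2)
    return np.asarray(part.membership)


def cluster_units(calls: CNVCalls, method: str = "kmeans", param: float = 2,
                  seed: int = 0) -> CloneAssignment:
    """Cluster units on their integer CNV state matrix.

    ``method='kmeans'`` uses k-means++ with 10 restarts and k = ``param``;
    ``method='leiden'`` builds a kNN graph (k = 15) on the state matrix and
    runs Leiden at resolution ``param`` (default 0.15 for rare-clone
    detection in combinatorial-indexing experiments). Labels are contiguous
    from 0 with cluster 0 the largest.
    """
    if len(calls.units) < 2:
        raise InvalidArgumentError("need at least 2 units to cluster")
    X = calls.states[:, ~calls.mask].astype(float)
    if method == "kmeans":
        k = int(param)
        if k > len(calls.units):
            raise InvalidArgumentError(f"k={k} exceeds unit count {len(calls.units)}")
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    elif method == "leiden":
        labels = leiden_cluster(X, resolution=float(param), seed=seed)
    else:
        raise InvalidArgumentError(f"unknown clustering method {method!r}")
    return CloneAssignment(labels=_relabel_by_size(labels), method=method,
                           parameters={"param": param, "seed": seed})
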