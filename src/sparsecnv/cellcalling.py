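"""Cell calling from the barcode rank plot and coverage QC.

Cells are separated from ambient background either by the knee of a
log-log barcode rank curve (a smoothing spline is fit to
log10(count) vs log10(rank) and the threshold is the fitted count at the
steepest-descent point) or by a fixed fragment-count cutoff. A 1 Mb
non-empty-bin filter removes barcodes with too little genomic footprint,
and Lorenz/Gini summaries quantify coverage uniformity per cell.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.interpolate import UnivariateSpline

from .errors import InvalidArgumentError, KneeNotFoundError
from .genome import CellBinMatrix

logger = logging.getLogger(__name__)

DEFAULT_FIXED_CUTOFF = 10_000
DEFAULT_MIN_NONEMPTY_FRAC = 0.90
DEFAULT_SLOPE_FLOOR = -0.5


@dataclass(frozen=True)
class BarcodeRank:
    """Barcodes ordered by descending fragment count; ties broken by name."""

    barcodes: tuple[str, ...]
    counts: np.ndarray  # aligned, non-increasing
    ranks: np.ndarray   # 1-based

    def __len__(self) -> int:
        return len(self.barcodes)


@dataclass(frozen=True)
class CellCallResult:
    threshold_count: float
    selected_barcodes: frozenset[str]
    method: str  # "gradient" | "fixed"
    diagnostics: dict = field(default_factory=dict)


def rank_barcodes(per_barcode_counts: Mapping[str, int]) -> BarcodeRank:
    """Rank barcodes by descending fragment count (ties: lexicographic)."""
    if not per_barcode_counts:
        raise InvalidArgumentError("no barcodes to rank")
    items = sorted(per_barcode_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    barcodes, counts = zip(*items)
    return BarcodeRank(
        barcodes=barcodes,
        counts=np.asarray(counts, dtype=np.int64),
        ranks=np.arange(1, len(barcodes) + 1, dtype=np.int64),
    )


def _cv_smoothing(x: np.ndarray, y: np.ndarray, n_folds: int = 5) -> float:
    """Pick the spline smoothing factor by deterministic k-fold cross-validation.

    Folds are interleaved by index so the held-out points span the whole
    curve; candidates form a geometric grid around scipy's default scale.
    """
    n = len(x)
    base = n * np.var(y)
    candidates = base * np.geomspace(1e-5, 1.0, 11)
    best_s, best_err = candidates[-1], np.inf
    idx = np.arange(n)
    for s in candidates:
        err = 0.0
        ok = True
        for f in range(n_folds):
            test = idx[f::n_folds]
            train = np.setdiff1d(idx, test)
            if len(train) <= 4:
                ok = False
                break
            try:
                spl = UnivariateSpline(x[train], y[train], k=3,
                                       s=s * len(train) / n)
            except Exception:
                ok = False
                break
            err += float(np.sum((spl(x[test]) - y[test]) ** 2))
        if ok and err < best_err:
            best_err, best_s = err, s
    return float(best_s)


def call_cells_gradient(rank: BarcodeRank, smoothing: float | None = None,
                        slope_floor: float = DEFAULT_SLOPE_FLOOR) -> CellCallResult:
    """Call cells at the knee of the log-log barcode rank curve.

    A cubic smoothing spline is fit to (log10 rank, log10 count); the knee is
    the rank where the spline's derivative is most negative, the threshold is
    the fitted count there, and barcodes with observed count strictly above
    the threshold are selected. If the derivative never drops below
    ``slope_floor`` the curve is considered featureless and a
    :class:`KneeNotFoundError` is raised (use the fixed-cutoff method).
    """
    if len(rank) < 50:
        raise InvalidArgumentError(
            f"gradient cell calling needs >= 50 ranked barcodes, got {len(rank)}")
    x = np.log10(rank.ranks.astype(float))
    y = np.log10(rank.counts.astype(float))
    if smoothing is None:
        smoothing = _cv_smoothing(x, y)
    spl = UnivariateSpline(x, y, k=3, s=smoothing)
    grid = np.linspace(x[0], x[-1], max(2000, 4 * len(x) // 5))
    deriv = spl.derivative()(grid)
    i_min = int(np.argmin(deriv))
    if deriv[i_min] > slope_floor:
        raise KneeNotFoundError(
            f"steepest log-log slope {deriv[i_min]:.3f} is above the floor "
            f"{slope_floor}; no knee detected — consider call_cells_fixed")
    knee_log_rank = grid[i_min]
    threshold = float(10 ** spl(knee_log_rank))
    selected = frozenset(b for b, c in zip(rank.barcodes, rank.counts) if c > threshold)
    if not selected:
        raise KneeNotFoundError("no barcode above the knee threshold")
    return CellCallResult(
        threshold_count=threshold,
        selected_barcodes=selected,
        method="gradient",
        diagnostics={
            "knee_rank": float(10 ** knee_log_rank),
            "knee_slope": float(deriv[i_min]),
            "smoothing": float(smoothing),
        },
    )


def call_cells_fixed(per_barcode_counts: Mapping[str, int],
                     cutoff: int = DEFAULT_FIXED_CUTOFF) -> CellCallResult:
    """Select barcodes with at least ``cutoff`` fragments (default 10,000)."""
    if cutoff < 1:
        raise InvalidArgumentError(f"cutoff must be >= 1, got {cutoff}")
    selected = frozenset(b for b, c in per_barcode_counts.items() if c >= cutoff)
    if not selected:
        warnings.warn("fixed-cutoff cell calling selected no barcodes", stacklevel=2)
    return CellCallResult(threshold_count=float(cutoff), selected_barcodes=selected,
                          method="fixed")


def filter_low_info_cells(matrix: CellBinMatrix,
                          min_nonempty_frac: float = DEFAULT_MIN_NONEMPTY_FRAC,
                          ) -> tuple[CellBinMatrix, list[str]]:
    """Drop cells with too few non-empty 1 Mb bins.

    A cell is kept iff its fraction of bins with count > 0 is at least
    ``min_nonempty_frac`` (default 0.90). Defined at 1 Mb only.
    """
    if matrix.bins.bin_size != 1_000_000:
        raise InvalidArgumentError(
            "the non-empty-bin filter is defined at 1 Mb bin size; "
            f"matrix is binned at {matrix.bins.bin_size} bp")
    nonempty = matrix.counts.getnnz(axis=1)
    frac = nonempty / matrix.bins.n_bins
    keep = frac >= min_nonempty_frac
    kept = CellBinMatrix([b for b, k in zip(matrix.barcodes, keep) if k],
                         matrix.bins, matrix.counts[keep])
    dropped = [b for b, k in zip(matrix.barcodes, keep) if not k]
    return kept, dropped


def lorenz_uniformity(bin_counts: np.ndarray) -> tuple[np.ndarray, float]:
    """Lorenz curve and Gini coefficient of one unit's per-bin coverage.

    Bins are sorted ascending by count; the curve is cumulative count
    fraction vs cumulative bin fraction (prepended with the origin), and the
    Gini is 1 - 2 * area under the curve by the trapezoid rule. 0 means
    perfectly uniform coverage; (n-1)/n means all counts in one bin.
    """
    c = np.asarray(bin_counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise InvalidArgumentError("bin_counts must be a non-empty 1-D array")
    if np.any(c < 0):
        raise InvalidArgumentError("bin_counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise InvalidArgumentError("all-zero coverage has no Lorenz curve")
    srt = np.sort(c)
    xs = np.arange(len(c) + 1) / len(c)
    ys = np.concatenate(([0.0], np.cumsum(srt) / total))
    area = np.trapezoid(ys, xs)
    gini = 1.0 - 2.0 * area
    return np.column_stack([xs, ys]), float(gini)
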