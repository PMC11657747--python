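"""DNA-vs-RNA copy-number concordance at varying genomic resolution.

Copy-number calls are reduced to loss / neutral / gain state vectors on a
shared bin frame. Expression is mapped to bins (mean over genes assigned to
a bin by gene start), classified per cell into states by bulk-anchored
quantiles (if the bulk has 25% losses and 25% gains, the cell's bottom
quartile of bin expression is a loss and its top quartile a gain), and
agreement with the bulk reference is scored by macro-F1 inside
non-overlapping windows tiling the genome; windows where the bulk is
entirely neutral are skipped. Shuffled profiles (same class counts as bulk)
and an all-diploid profile serve as negative controls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from .cnv import GAIN, LOSS, NEUTRAL
from .errors import InvalidArgumentError, ShapeError
from .genome import GenomeBins


def map_expression_to_bins(gene_table: pd.DataFrame, expr: pd.DataFrame,
                           bins: GenomeBins) -> tuple[np.ndarray, np.ndarray]:
    """Average per-gene expression into genome bins.

    ``gene_table`` has columns (chrom, start, end, gene); a gene is assigned
    to the single bin containing its start coordinate. ``expr`` is cells x
    genes. Returns (cells x bins values, mask) where geneless bins are
    masked (True), not zero-filled.
    """
    gene_bin: dict[str, int] = {}
    for row in gene_table.itertuples(index=False):
        if row.chrom not in bins.chrom_names:
            continue
        try:
            gene_bin[row.gene] = bins.bin_of(row.chrom, int(row.start))
        except InvalidArgumentError:
            continue
    genes = [g for g in expr.columns if g in gene_bin]
    if not genes:
        raise InvalidArgumentError("no gene overlaps any bin")
    values = np.zeros((expr.shape[0], bins.n_bins))
    tally = np.zeros(bins.n_bins)
    for g in genes:
        b = gene_bin[g]
        values[:, b] += expr[g].to_numpy(dtype=float)
        tally[b] += 1
    mask = tally == 0
    values[:, ~mask] /= tally[~mask]
    values[:, mask] = np.nan
    return values, mask


def classify_expression(expr_bins: np.ndarray, bulk_fractions: tuple[float, float],
                        mask: np.ndarray | None = None) -> np.ndarray:
    """Classify one cell's binned expression into loss/neutral/gain by
    bulk-anchored quantiles.

    With bulk fractions (frac_loss, frac_gain), values at or below the
    cell's own frac_loss quantile are losses and values strictly above the
    (1 - frac_gain) quantile are gains. Quantiles are type-7 (linear
    interpolation). A constant vector degenerates to all-neutral.
    """
    frac_loss, frac_gain = bulk_fractions
    if frac_loss < 0 or frac_gain < 0 or frac_loss + frac_gain > 1:
        raise InvalidArgumentError("need 0 <= frac_loss + frac_gain <= 1")
    v = np.asarray(expr_bins, dtype=float)
    if mask is None:
        mask = ~np.isfinite(v)
    usable = v[~mask]
    if usable.size == 0:
        raise InvalidArgumentError("no unmasked expression values")
    out = np.full(v.shape, NEUTRAL, dtype=np.int8)
    if usable.max() == usable.min():
        warnings.warn("constant expression vector: degenerate quantiles, "
                      "classifying all bins neutral", stacklevel=2)
        return out
    if frac_loss > 0:
        q_lo = np.quantile(usable, frac_loss)
        out[(~mask) & (v <= q_lo)] = LOSS
    if frac_gain > 0:
        q_hi = np.quantile(usable, 1.0 - frac_gain)
        out[(~mask) & (v > q_hi)] = GAIN
    return out


def state_fractions(states: np.ndarray) -> tuple[float, float]:
    """(fraction loss, fraction gain) of a state vector — the bulk anchor
    for expression classification."""
    s = np.asarray(states)
    return float(np.mean(s == LOSS)), float(np.mean(s == GAIN))


def macro_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """Macro F1 over the loss/neutral/gain classes present in truth or pred.

    Classes present in truth but never predicted score 0; classes absent
    from both are excluded from the average.
    """
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ShapeError(f"pred length {pred.size} != truth length {truth.size}")
    labels = sorted(set(np.unique(pred)) | set(np.unique(truth)))
    return float(f1_score(truth, pred, labels=labels, average="macro",
                          zero_division=0))


def sliding_window_scan(pred_matrix: np.ndarray, truth: np.ndarray,
                        window_bins: int) -> pd.DataFrame:
    """Mean macro-F1 across units in non-overlapping windows along the genome.

    Windows tile the bins in order; the last partial window is scored.
    Windows where the truth is entirely neutral are flagged skipped and get
    no score. Returns a frame with (start_bin, end_bin, skipped, mean_f1).
    """
    if window_bins < 1:
        raise InvalidArgumentError("window_bins must be >= 1")
    P = np.atleast_2d(np.asarray(pred_matrix))
    truth = np.asarray(truth)
    if P.shape[1] != truth.shape[0]:
        raise ShapeError(f"pred bins {P.shape[1]} != truth bins {truth.shape[0]}")
    rows = []
    for lo in range(0, truth.shape[0], window_bins):
        hi = min(lo + window_bins, truth.shape[0])
        t = truth[lo:hi]
        if np.all(t == NEUTRAL):
            rows.append((lo, hi, True, np.nan))
            continue
        scores = [macro_f1(P[u, lo:hi], t) for u in range(P.shape[0])]
        rows.append((lo, hi, False, float(np.mean(scores))))
    return pd.DataFrame(rows, columns=["start_bin", "end_bin", "skipped", "mean_f1"])


def make_random_controls(truth: np.ndarray, n_profiles: int = 500,
                         seed: int = 0) -> np.ndarray:
    """Shuffled control profiles: each is a uniformly random permutation of
    the truth labels, so class counts are preserved exactly."""
    if n_profiles < 1:
        raise InvalidArgumentError("n_profiles must be >= 1")
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth)
    return np.stack([rng.permutation(truth) for _ in range(n_profiles)])


def make_diploid_control(n_bins: int) -> np.ndarray:
    """All-neutral profile on an ``n_bins`` frame."""
    return np.full(n_bins, NEUTRAL, dtype=np.int8)


def correlation_vs_binsize(calls_by_binsize: dict, bulk_by_binsize: dict,
                           ) -> pd.DataFrame:
    """Pearson r between call and bulk state vectors per bin size, over the
    maximal overlapping (finite in both) bin set. Missing sizes are reported
    absent (NaN), not raised."""
    rows = []
    for size in sorted(set(calls_by_binsize) | set(bulk_by_binsize), reverse=True):
        if size not in calls_by_binsize or size not in bulk_by_binsize:
            rows.append((size, np.nan, 0))
            continue
        a = np.asarray(calls_by_binsize[size], dtype=float)
        b = np.asarray(bulk_by_binsize[size], dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
            rows.append((size, np.nan, int(ok.sum())))
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        rows.append((size, r, int(ok.sum())))
    return pd.DataFrame(rows, columns=["bin_size", "pearson_r", "n_bins"])
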