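"""End-to-end orchestration of the three analysis shapes.

``run_dna``: fragments -> cell calling -> 1 Mb binning -> non-empty-bin QC
-> metacelling -> CNV calling (single cells at 1 Mb, metacells at 100 kb)
-> clone clustering -> bulk identity. ``run_spikein``: the DNA arm with
Leiden clustering (resolution 0.15) and minor-cluster prevalence.
``run_concordance``: DNA and expression state vectors scanned against a
bulk reference with shuffled and diploid controls.

Every stage failure is re-raised with the stage name so a long run points
at the step that broke. Reports are plain dicts, JSON-serializable, and
deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import os
from contextlib import contextmanager

import numpy as np

from . import cellcalling, cnv, concordance, metacell as mc
from .errors import SparseCNVError
from .genome import (ChromSizes, bin_fragment_counts, make_bins,
                     parse_fragments, write_cnv_tracks, write_matrix)

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except SparseCNVError as err:
        raise SparseCNVError(f"stage '{name}': {err}") from err
    logger.info("stage %s: done", name)


def load_genome(genome: str) -> ChromSizes:
    """'grch38' or a path to a two-column chrom-sizes TSV."""
    if genome.lower() == "grch38":
        return ChromSizes.grch38()
    return ChromSizes.from_tsv(genome)


def run_dna(fragments_path: str, chrom_sizes: ChromSizes, *,
            cell_method: str = "gradient", cutoff: int = 10_000,
            min_nonempty_frac: float = 0.90,
            metacell_params: mc.MetacellParams | None = None,
            sc_bin_size: int = 1_000_000, metacell_bin_size: int = 100_000,
            cluster_method: str = "kmeans", cluster_param: float = 2,
            bulk_profiles: dict | None = None, seed: int = 0,
            outdir: str | None = None) -> dict:
    """Full DNA arm; returns a JSON-serializable report."""
    with _stage("parse_fragments"):
        records = list(parse_fragments(fragments_path, chrom_sizes))

    with _stage("cell_calling"):
        totals: dict[str, int] = {}
        for r in records:
            totals[r.barcode] = totals.get(r.barcode, 0) + r.support
        if cell_method == "gradient":
            call = cellcalling.call_cells_gradient(cellcalling.rank_barcodes(totals))
        else:
            call = cellcalling.call_cells_fixed(totals, cutoff=cutoff)
        cells = sorted(call.selected_barcodes)

    with _stage("bin_1mb"):
        bins_1mb = make_bins(chrom_sizes, 1_000_000)
        matrix = bin_fragment_counts(records, bins_1mb, barcodes=cells)

    with _stage("nonempty_filter"):
        kept, dropped = cellcalling.filter_low_info_cells(matrix, min_nonempty_frac)

    with _stage("metacelling"):
        params = metacell_params or mc.MetacellParams(seed=seed)
        meta = mc.run_metacelling(kept, params)

    with _stage("cnv_single_cells"):
        sc_bins = make_bins(chrom_sizes, sc_bin_size)
        sc_matrix = (kept if sc_bin_size == 1_000_000
                     else bin_fragment_counts(records, sc_bins, barcodes=kept.barcodes))
        sc_calls = cnv.call_cnv(sc_matrix.counts, sc_matrix.bins, sc_matrix.barcodes)

    with _stage("cnv_metacells"):
        meta_bins = make_bins(chrom_sizes, metacell_bin_size)
        fine = bin_fragment_counts(records, meta_bins, barcodes=kept.barcodes)
        ids = sorted({meta.assignment[b] for b in kept.barcodes})
        agg = np.zeros((len(ids), meta_bins.n_bins))
        row_of = {m: i for i, m in enumerate(ids)}
        dense = np.asarray(fine.counts.todense())
        for i, b in enumerate(kept.barcodes):
            agg[row_of[meta.assignment[b]]] += dense[i]
        meta_calls = cnv.call_cnv(agg, meta_bins, ids)

    with _stage("clustering"):
        assign = cnv.cluster_units(sc_calls, method=cluster_method,
                                   param=cluster_param, seed=seed)

    report = {
        "n_barcodes": len(totals),
        "n_cells_called": len(cells),
        "cell_threshold": call.threshold_count,
        "n_cells_after_filter": kept.n_cells,
        "n_dropped": len(dropped),
        "n_metacells": len(meta.metacells),
        "chosen_merge_distance": meta.chosen_distance,
        "cluster_sizes": np.bincount(assign.labels).tolist(),
        "hmm_params": {"single_cell": sc_calls.params, "metacell": meta_calls.params},
    }

    if bulk_profiles:
        with _stage("bulk_identity"):
            r, identity = cnv.correlate_to_bulk(sc_calls, bulk_profiles)
            per_cluster = {}
            for lab in np.unique(assign.labels):
                members = np.flatnonzero(assign.labels == lab)
                mean_r = np.nanmean(r[members], axis=0)
                best = int(np.nanargmax(mean_r))
                per_cluster[str(int(lab))] = {
                    "identity": list(bulk_profiles)[best],
                    "mean_r": [round(float(v), 6) for v in mean_r],
                }
            report["cluster_identity"] = per_cluster

    if outdir:
        os.makedirs(outdir, exist_ok=True)
        write_matrix(kept, os.path.join(outdir, "matrix_1mb"))
        write_cnv_tracks(sc_calls.states, sc_calls.units, sc_calls.bins,
                         os.path.join(outdir, "tracks_sc"))
        write_cnv_tracks(meta_calls.states, meta_calls.units, meta_calls.bins,
                         os.path.join(outdir, "tracks_metacell"))
        with open(os.path.join(outdir, "metacells.tsv"), "w") as fh:
            for b in kept.barcodes:
                fh.write(f"{b}\t{meta.assignment[b]}\n")
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


def spikein_prevalence(calls: cnv.CNVCalls, bulk_profiles: dict, seed: int = 0,
                       resolution: float = 0.15) -> dict:
    """Leiden-cluster per-cell CNV states and report the minor population.

    Each cluster is assigned a bulk identity by the mean correlation of its
    members' states to the bulk profiles; the prevalence of each bulk is the
    total share of cells in clusters carrying its identity, and the minor
    population is the bulk with the smaller share.
    """
    assign = cnv.cluster_units(calls, method="leiden", param=resolution, seed=seed)
    sizes = np.bincount(assign.labels)
    r, _ = cnv.correlate_to_bulk(calls, bulk_profiles)
    names = list(bulk_profiles)
    identity = {}
    share = {name: 0 for name in names}
    for lab in range(len(sizes)):
        members = np.flatnonzero(assign.labels == lab)
        best = names[int(np.nanargmax(np.nanmean(r[members], axis=0)))]
        identity[str(lab)] = best
        share[best] += int(sizes[lab])
    total = int(sizes.sum())
    prevalence_pct = {name: 100.0 * n / total for name, n in share.items()}
    minor_bulk = min(prevalence_pct, key=lambda k: (prevalence_pct[k], k))
    return {
        "n_clusters": int(len(sizes)),
        "cluster_sizes": sizes.tolist(),
        "minor_bulk": minor_bulk,
        "minor_prevalence_pct": float(prevalence_pct[minor_bulk]),
        "prevalence_pct": prevalence_pct,
        "cluster_identity": identity,
    }


def run_concordance(pred_by_binsize: dict, truth_by_binsize: dict, *,
                    windows: tuple = (5, 10, 50, 100), n_controls: int = 500,
                    seed: int = 0) -> dict:
    """Window macro-F1 scan of predicted state matrices against bulk truth.

    ``pred_by_binsize`` maps bin size -> units x bins collapsed-state
    matrix; ``truth_by_binsize`` maps bin size -> bulk state vector.
    Shuffled (``n_controls``) and diploid controls are scored as separate
    rows per window size.
    """
    out: dict = {"windows": {}, "controls": {}}
    for size, truth in truth_by_binsize.items():
        if size not in pred_by_binsize:
            continue
        pred = np.atleast_2d(pred_by_binsize[size])
        shuffled = concordance.make_random_controls(truth, n_controls, seed=seed)
        diploid = concordance.make_diploid_control(len(truth))
        for w in windows:
            scan = concordance.sliding_window_scan(pred, truth, w)
            ctrl = concordance.sliding_window_scan(shuffled, truth, w)
            dip = concordance.sliding_window_scan(diploid[None, :], truth, w)
            key = f"{size}:{w}"
            out["windows"][key] = scan.to_dict(orient="list")
            out["controls"][key] = {
                "shuffled_mean_f1": float(np.nanmean(ctrl["mean_f1"]))
                if not ctrl["mean_f1"].isna().all() else None,
                "diploid_mean_f1": float(np.nanmean(dip["mean_f1"]))
                if not dip["mean_f1"].isna().all() else None,
                "n_shuffled": n_controls,
            }
    return out
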