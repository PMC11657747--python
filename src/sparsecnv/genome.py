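"""Genome coordinate frame, fragment parsing, binned counting, and standard I/O.

Coordinates are 0-based, half-open everywhere (fragments-file / BED convention).
A fragment contributes its ``support`` count to the single bin containing its
start coordinate; counts are therefore additive and independent of input order.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, InvalidArgumentError, ParseError, ShapeError

logger = logging.getLogger(__name__)

# GRCh38 primary-assembly chromosome lengths (chr1-22, X, Y).
GRCH38_SIZES: tuple[tuple[str, int], ...] = (
    ("chr1", 248956422), ("chr2", 242193529), ("chr3", 198295559),
    ("chr4", 190214555), ("chr5", 181538259), ("chr6", 170805979),
    ("chr7", 159345973), ("chr8", 145138636), ("chr9", 138394717),
    ("chr10", 133797422), ("chr11", 135086622), ("chr12", 133275309),
    ("chr13", 114364328), ("chr14", 107043718), ("chr15", 101991189),
    ("chr16", 90338345), ("chr17", 83257441), ("chr18", 80373285),
    ("chr19", 58617616), ("chr20", 64444167), ("chr21", 46709983),
    ("chr22", 50818468), ("chrX", 156040895), ("chrY", 57227415),
)


@dataclass(frozen=True)
class ChromSizes:
    """Ordered chromosome name/length table.

    Lengths must be strictly positive and names unique; input order is kept.
    """

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if not self.entries:
            raise InvalidArgumentError("ChromSizes must contain at least one chromosome")
        if len(set(names)) != len(names):
            raise InvalidArgumentError("chromosome names must be unique")
        for name, length in self.entries:
            if length <= 0:
                raise InvalidArgumentError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    @classmethod
    def grch38(cls) -> "ChromSizes":
        """Built-in GRCh38 primary assembly (chr1-22, X, Y)."""
        return cls(GRCH38_SIZES)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "ChromSizes":
        """Read a two-column (name, length) chrom-sizes TSV."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1], names=["chrom", "length"])
        return cls(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))))


@dataclass(frozen=True)
class GenomeBins:
    """Ordered fixed-width tiling of chromosomes.

    Within each chromosome bins are contiguous, start at 0, and all but
    possibly the last have width ``bin_size``; the last bin ends at the
    chromosome length.
    """

    bin_size: int
    chroms: tuple[str, ...]
    starts: np.ndarray  # int64, per bin
    ends: np.ndarray
    chrom_index: np.ndarray = field(repr=False)  # int32 index into a chrom list
    chrom_names: tuple[str, ...] = field(repr=False)
    _offsets: dict = field(repr=False, default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [self.chrom_names[i] for i in self.chrom_index],
            "start": self.starts,
            "end": self.ends,
        })

    def bin_of(self, chrom: str, pos: int) -> int:
        """Index of the bin containing ``pos`` on ``chrom``."""
        off, length = self._offsets[chrom]
        if not (0 <= pos < length):
            raise InvalidArgumentError(f"position {pos} outside {chrom} (length {length})")
        return off + pos // self.bin_size

    def chromosome_slices(self) -> list[tuple[str, slice]]:
        """(chrom, slice of bin indices) in genome order."""
        out = []
        idx = np.asarray(self.chrom_index)
        for ci, name in enumerate(self.chrom_names):
            where = np.flatnonzero(idx == ci)
            if where.size:
                out.append((name, slice(int(where[0]), int(where[-1]) + 1)))
        return out


def make_bins(chrom_sizes: ChromSizes, bin_size: int) -> GenomeBins:
    """Tile every chromosome with fixed-width bins (ceiling partition).

    The total bin count is sum over chromosomes of ceil(length / bin_size);
    on the built-in GRCh38 frame at 1 Mb this is 3102 bins.
    """
    if bin_size < 1:
        raise InvalidArgumentError(f"bin_size must be >= 1, got {bin_size}")
    starts, ends, chrom_idx = [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    total = 0
    names = tuple(chrom_sizes.names)
    for ci, (name, length) in enumerate(chrom_sizes.entries):
        n = -(-length // bin_size)  # ceil
        offsets[name] = (total, length)
        s = np.arange(n, dtype=np.int64) * bin_size
        e = np.minimum(s + bin_size, length)
        starts.append(s)
        ends.append(e)
        chrom_idx.append(np.full(n, ci, dtype=np.int32))
        total += n
    return GenomeBins(
        bin_size=bin_size,
        chroms=names,
        starts=np.concatenate(starts),
        ends=np.concatenate(ends),
        chrom_index=np.concatenate(chrom_idx),
        chrom_names=names,
        _offsets=offsets,
    )


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str
    support: int


def parse_fragments(path: str | os.PathLike, chrom_sizes: ChromSizes,
                    ) -> Iterator[FragmentRecord]:
    """Stream validated fragment records from a (optionally gzipped) TSV.

    Columns: chrom, start, end, barcode, support. Lines starting with '#'
    are comments. Records on chromosomes absent from ``chrom_sizes`` are
    skipped; the skip count is logged when the stream is exhausted.
    """
    lengths = chrom_sizes.lengths
    opener = gzip.open if str(path).endswith(".gz") else open
    skipped = 0
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}")
            chrom, s, e, barcode, sup = fields
            try:
                start, end, support = int(s), int(e), int(sup)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinate or support") from None
            if chrom not in lengths:
                skipped += 1
                continue
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            if start < 0 or end > lengths[chrom]:
                raise ParseError(
                    f"line {lineno}: interval [{start},{end}) outside {chrom} "
                    f"(length {lengths[chrom]})")
            if support < 1:
                raise ParseError(f"line {lineno}: support must be a positive integer")
            yield FragmentRecord(chrom, start, end, barcode, support)
    if skipped:
        logger.info("parse_fragments: skipped %d record(s) on chromosomes absent "
                    "from the provided ChromSizes", skipped)


@dataclass
class CellBinMatrix:
    """Barcodes x bins non-negative integer count matrix (CSR sparse)."""

    barcodes: list[str]
    bins: GenomeBins
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), self.bins.n_bins):
            raise ShapeError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.barcodes)}, {self.bins.n_bins})")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise InvalidArgumentError("barcodes must be unique")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def totals(self) -> np.ndarray:
        """Total counted fragments per barcode."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset(self, barcodes: Sequence[str]) -> "CellBinMatrix":
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = [index[b] for b in barcodes]
        return CellBinMatrix(list(barcodes), self.bins, self.counts[rows])


def bin_fragment_counts(fragments: Iterable[FragmentRecord], bins: GenomeBins,
                        barcodes: Sequence[str] | None = None) -> CellBinMatrix:
    """Tally fragments into a barcodes x bins matrix.

    Each fragment adds its ``support`` to the single bin containing its start
    coordinate. If ``barcodes`` is given it acts as a whitelist (row order as
    given); otherwise all observed barcodes become rows in sorted order.
    """
    whitelist = None if barcodes is None else {b: i for i, b in enumerate(barcodes)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    discovered: dict[str, int] = {}
    for frag in fragments:
        if whitelist is not None:
            row = whitelist.get(frag.barcode)
            if row is None:
                continue
        else:
            row = discovered.setdefault(frag.barcode, len(discovered))
        rows.append(row)
        cols.append(bins.bin_of(frag.chrom, frag.start))
        vals.append(frag.support)
    if whitelist is not None:
        names = list(barcodes)
    else:
        names = sorted(discovered)
        order = {name: i for i, name in enumerate(names)}
        remap = np.empty(len(discovered), dtype=np.int64)
        for name, old in discovered.items():
            remap[old] = order[name]
        rows = [int(remap[r]) for r in rows]
    mat = sp.coo_matrix((vals, (rows, cols)),
                        shape=(len(names), bins.n_bins), dtype=np.int64).tocsr()
    mat.sum_duplicates()
    return CellBinMatrix(names, bins, mat)


def write_matrix(matrix: CellBinMatrix, prefix: str | os.PathLike) -> None:
    """Write a matrix as MTX triplet plus barcodes.tsv / bins.tsv sidecars.

    ``prefix`` is a directory; files are counts.mtx, barcodes.tsv, bins.tsv.
    """
    os.makedirs(prefix, exist_ok=True)
    scipy.io.mmwrite(os.path.join(prefix, "counts.mtx"), matrix.counts.tocoo(),
                     field="integer")
    with open(os.path.join(prefix, "barcodes.tsv"), "w") as fh:
        for b in matrix.barcodes:
            fh.write(b + "\n")
    frame = matrix.bins.to_frame()
    frame.insert(0, "bin_size", matrix.bins.bin_size)
    frame[["chrom", "start", "end", "bin_size"]].to_csv(
        os.path.join(prefix, "bins.tsv"), sep="\t", header=False, index=False)


def read_matrix(prefix: str | os.PathLike) -> CellBinMatrix:
    """Inverse of :func:`write_matrix`; round-trip is bit-exact."""
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(prefix, "counts.mtx")),
                           dtype=np.int64)
    with open(os.path.join(prefix, "barcodes.tsv")) as fh:
        barcodes = [line.rstrip("\n") for line in fh if line.strip()]
    bdf = pd.read_csv(os.path.join(prefix, "bins.tsv"), sep="\t", header=None,
                      names=["chrom", "start", "end", "bin_size"])
    if counts.shape[0] != len(barcodes) or counts.shape[1] != len(bdf):
        # mmread collapses a 0-row matrix; rebuild the empty shape explicitly
        if counts.nnz == 0:
            counts = sp.csr_matrix((len(barcodes), len(bdf)), dtype=np.int64)
        else:
            raise FormatError(
                f"matrix shape {counts.shape} disagrees with sidecars "
                f"({len(barcodes)} barcodes, {len(bdf)} bins)")
    if len(bdf):
        bin_size = int(bdf["bin_size"].iloc[0])
        sizes = ChromSizes(tuple(
            (c, int(bdf.loc[bdf["chrom"] == c, "end"].max()))
            for c in bdf["chrom"].unique()))
        bins = make_bins(sizes, bin_size)
        if not (np.array_equal(bins.starts, bdf["start"].to_numpy())
                and np.array_equal(bins.ends, bdf["end"].to_numpy())):
            raise FormatError("bins.tsv is not a valid fixed-width tiling")
    else:
        raise FormatError("bins.tsv is empty")
    return CellBinMatrix(barcodes, bins, counts)


def segments_from_states(states: np.ndarray, bins: GenomeBins) -> pd.DataFrame:
    """Run-length merge per-bin states into (chrom, start, end, state) segments."""
    states = np.asarray(states)
    if states.shape[0] != bins.n_bins:
        raise ShapeError(f"{states.shape[0]} states for {bins.n_bins} bins")
    rows = []
    for chrom, sl in bins.chromosome_slices():
        vals = states[sl]
        starts = bins.starts[sl]
        ends = bins.ends[sl]
        change = np.flatnonzero(np.diff(vals)) + 1
        bounds = np.concatenate(([0], change, [len(vals)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(starts[a]), int(ends[b - 1]), vals[a]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def write_cnv_tracks(states: np.ndarray, unit_ids: Sequence[str], bins: GenomeBins,
                     outdir: str | os.PathLike, merge: bool = False) -> None:
    """Write one bedGraph-style track per unit (chrom, start, end, state).

    With ``merge`` adjacent equal-state bins are collapsed into segments.
    """
    states = np.atleast_2d(np.asarray(states))
    if states.shape != (len(unit_ids), bins.n_bins):
        raise ShapeError(
            f"states shape {states.shape} != ({len(unit_ids)}, {bins.n_bins})")
    os.makedirs(outdir, exist_ok=True)
    frame = bins.to_frame()
    for row, unit in zip(states, unit_ids):
        if merge:
            df = segments_from_states(row, bins)
        else:
            df = frame.assign(state=row)
        df.to_csv(os.path.join(outdir, f"{unit}.bedgraph"),
                  sep="\t", header=False, index=False)
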