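"""Genome binning and interval-to-track conversion.

The genome is tiled with fixed-size, non-overlapping bins (0-based, half-open,
BED convention; the last bin of a chromosome may be partial).  Interval data —
ChIP-seq enriched regions per chromatin factor, or gene spans carrying RNA
counts — are converted into fixed-resolution tracks on those bins:

* factor tracks hold, per bin, the fraction of the bin covered by the union of
  that factor's enriched intervals (a value in [0, 1]);
* transcription scores accumulate, per bin, RNA counts weighted by the
  fraction of the bin the gene occupies, and are thresholded into an
  active / inactive label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBins",
    "FactorTrackSet",
    "TranscriptionTrack",
    "make_bins",
    "read_chrom_sizes",
    "bin_factor_coverage",
    "transcription_classify",
]


@dataclass(frozen=True)
class GenomeBins:
    """Fixed-size tiling of a set of chromosomes.

    Bins are 0-based half-open ``[k*bin_size, (k+1)*bin_size)`` intervals; the
    terminal bin of each chromosome is truncated at the chromosome end.  Flat
    indices run 0..N-1 in the input chromosome order.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    chrom_n_bins: tuple[int, ...] = field(init=False)
    chrom_offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        counts = tuple(
            int(-(-length // self.bin_size)) for length in self.chrom_lengths
        )
        offsets = tuple(int(x) for x in np.concatenate([[0], np.cumsum(counts)[:-1]]))
        object.__setattr__(self, "chrom_n_bins", counts)
        object.__setattr__(self, "chrom_offsets", offsets)

    @property
    def n_bins(self) -> int:
        return sum(self.chrom_n_bins)

    def chrom_index(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def flat_index(self, chrom: str, bin_in_chrom: int) -> int:
        ci = self.chrom_index(chrom)
        if not 0 <= bin_in_chrom < self.chrom_n_bins[ci]:
            raise IndexError(f"bin {bin_in_chrom} out of range for {chrom}")
        return self.chrom_offsets[ci] + bin_in_chrom

    def bin_of_position(self, chrom: str, pos: int) -> int:
        """Flat bin index containing base-pair position ``pos`` (0-based)."""
        ci = self.chrom_index(chrom)
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise IndexError(f"position {pos} outside {chrom}")
        return self.chrom_offsets[ci] + pos // self.bin_size

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Width in bp of every bin of one chromosome (last may be partial)."""
        ci = self.chrom_index(chrom)
        n = self.chrom_n_bins[ci]
        widths = np.full(n, self.bin_size, dtype=np.int64)
        rem = self.chrom_lengths[ci] - (n - 1) * self.bin_size
        widths[-1] = rem
        return widths

    def bin_table(self) -> pd.DataFrame:
        """Per-bin (chrom, start, end) table in flat-index order."""
        rows = []
        for name, length, n in zip(
            self.chrom_names, self.chrom_lengths, self.chrom_n_bins
        ):
            starts = np.arange(n, dtype=np.int64) * self.bin_size
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)


@dataclass
class FactorTrackSet:
    """M x N matrix of fractional factor occupancy per genomic bin."""

    factor_names: list[str]
    values: np.ndarray  # (M, N), entries in [0, 1]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.factor_names):
            raise ValueError("values must be (n_factors, n_bins)")
        if self.values.size and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("factor occupancy fractions must lie in [0, 1]")

    @property
    def n_factors(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


@dataclass
class TranscriptionTrack:
    """Per-bin transcription scores and the active/inactive labels."""

    scores: np.ndarray  # (N,), non-negative
    labels: np.ndarray  # (N,), bool: True = active
    threshold: float = 1.0


def read_chrom_sizes(path) -> pd.DataFrame:
    """Read a two-column chrom.sizes text file (name, length in bp)."""
    table = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "length"], comment="#"
    )
    return table


def make_bins(chrom_sizes: pd.DataFrame, bin_size: int = 10_000) -> GenomeBins:
    """Tile each chromosome with ``bin_size`` bins (last bin may be partial).

    ``chrom_sizes`` is a DataFrame with columns ``chrom`` and ``length`` (bp),
    in the order that defines the flat bin index.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if len(chrom_sizes) == 0:
        raise ValueError("empty chromosome table")
    lengths = chrom_sizes["length"].to_numpy()
    if (lengths <= 0).any():
        bad = chrom_sizes.loc[lengths <= 0, "chrom"].tolist()
        raise ValueError(f"non-positive chromosome length for {bad}")
    return GenomeBins(
        chrom_names=tuple(str(c) for c in chrom_sizes["chrom"]),
        chrom_lengths=tuple(int(x) for x in lengths),
        bin_size=int(bin_size),
    )


def _union_coverage_per_bin(
    intervals: np.ndarray, chrom_len: int, bin_size: int, n_bins: int
) -> np.ndarray:
    """bp of each bin covered by the union of (start, end) intervals."""
    covered = np.zeros(n_bins, dtype=np.int64)
    if len(intervals) == 0:
        return covered
    iv = intervals[np.argsort(intervals[:, 0], kind="stable")]
    # sweep over merged intervals
    cur_s, cur_e = iv[0]
    merged = []
    for s, e in iv[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    merged.append((cur_s, cur_e))
    for s, e in merged:
        s = max(0, int(s))
        e = min(chrom_len, int(e))
        if e <= s:
            continue
        b0, b1 = s // bin_size, (e - 1) // bin_size
        if b0 == b1:
            covered[b0] += e - s
        else:
            covered[b0] += (b0 + 1) * bin_size - s
            covered[b1] += e - b1 * bin_size
            if b1 > b0 + 1:
                covered[b0 + 1 : b1] += bin_size
    return covered


def bin_factor_coverage(
    factor_intervals: dict[str, pd.DataFrame], bins: GenomeBins
) -> FactorTrackSet:
    """Fraction of each bin covered by each factor's enriched regions.

    ``factor_intervals`` maps factor name -> DataFrame with columns
    (chrom, start, end).  Intervals of one factor are unioned before the
    fraction is computed, so overlapping calls never push a bin above 1.
    Intervals on unknown chromosomes are skipped (with a warning); intervals
    extending past chromosome ends are clipped.  Partial terminal bins use
    their true width as denominator.
    """
    names = list(factor_intervals)
    values = np.zeros((len(names), bins.n_bins), dtype=float)
    n_skipped = 0
    for fi, name in enumerate(names):
        table = factor_intervals[name]
        for ci, (chrom, clen, nb, off) in enumerate(
            zip(bins.chrom_names, bins.chrom_lengths, bins.chrom_n_bins, bins.chrom_offsets)
        ):
            sel = table[table["chrom"] == chrom]
            iv = sel[["start", "end"]].to_numpy(dtype=np.int64) if len(sel) else np.empty((0, 2), np.int64)
            covered = _union_coverage_per_bin(iv, clen, bins.bin_size, nb)
            values[fi, off : off + nb] = covered / bins.bin_widths(chrom)
        n_skipped += int((~table["chrom"].isin(bins.chrom_names)).sum())
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} interval(s) on chromosomes absent from the binning",
            stacklevel=2,
        )
    return FactorTrackSet(factor_names=names, values=values)


def transcription_classify(
    gene_table: pd.DataFrame, bins: GenomeBins, threshold: float = 1.0
) -> TranscriptionTrack:
    """Per-bin transcription score and active/inactive label.

    Each gene contributes ``rna_counts * (bp overlap of the bin with the gene)
    / (bin width)`` to every bin it touches; bins whose total score exceeds
    the threshold are labelled active.  Scores exactly at the threshold are
    labelled inactive.
    """
    required = {"chrom", "start", "end", "rna_counts"}
    missing = required - set(gene_table.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    if (gene_table["rna_counts"] < 0).any():
        raise ValueError("rna_counts must be non-negative")
    scores = np.zeros(bins.n_bins, dtype=float)
    for chrom, clen, nb, off in zip(
        bins.chrom_names, bins.chrom_lengths, bins.chrom_n_bins, bins.chrom_offsets
    ):
        widths = bins.bin_widths(chrom)
        sel = gene_table[gene_table["chrom"] == chrom]
        for s, e, counts in sel[["start", "end", "rna_counts"]].itertuples(index=False):
            s = max(0, int(s))
            e = min(clen, int(e))
            if e <= s:
                continue
            b0, b1 = s // bins.bin_size, (e - 1) // bins.bin_size
            for b in range(b0, b1 + 1):
                bs = b * bins.bin_size
                be = bs + widths[b]
                overlap = min(e, be) - max(s, bs)
                scores[off + b] += counts * overlap / widths[b]
    labels = scores > threshold
    return TranscriptionTrack(scores=scores, labels=labels, threshold=threshold)
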