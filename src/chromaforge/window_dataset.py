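"""Sliding-window samples pairing factor tracks with local contact maps.

The forward model predicts the local w x w contact map of an inner genomic
window from an M x 3w input block: the inner w bins plus a w-long flank on
each side.  The target is the flattened upper triangle (diagonal included) of
the inner map, length w(w+1)/2.  Because genome directionality carries no
information about the sequence/structure relationship, every sample has a
left-right inverted twin; mirrored twins are kept in the same train/validation
partition to avoid leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_tracks import FactorTrackSet, GenomeBins
from .hic_maps import NormalizedContactMap

__all__ = [
    "WindowSample",
    "DatasetSplit",
    "flatten_upper",
    "unflatten_upper",
    "mirror_permutation",
    "extract_windows",
    "mirror_augment",
    "make_splits",
]


@dataclass
class WindowSample:
    chrom: str
    start_bin: int  # first bin of the inner region, chromosome-local
    orientation: str  # "forward" | "inverted"
    input_block: np.ndarray  # (M, 3w): left flank, inner, right flank
    target: np.ndarray  # (w(w+1)/2,)

    @property
    def w(self) -> int:
        return self.input_block.shape[1] // 3


@dataclass
class DatasetSplit:
    train: list[WindowSample]
    validation: list[WindowSample]
    test: list[WindowSample]
    split_seed: int
    train_regions: list[tuple[str, int, int]]
    test_regions: list[tuple[str, int, int]]


def flatten_upper(map_w: np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal included) of a symmetric matrix."""
    map_w = np.asarray(map_w)
    if map_w.ndim != 2 or map_w.shape[0] != map_w.shape[1]:
        raise ValueError("input must be a square matrix")
    iu, ju = np.triu_indices(map_w.shape[0])
    return map_w[iu, ju]


def unflatten_upper(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_upper`: rebuild the symmetric w x w matrix."""
    vec = np.asarray(vec)
    w = int(round((np.sqrt(8 * vec.shape[-1] + 1) - 1) / 2))
    if w * (w + 1) // 2 != vec.shape[-1]:
        raise ValueError(f"length {vec.shape[-1]} is not triangular")
    out = np.zeros(vec.shape[:-1] + (w, w), dtype=vec.dtype)
    iu, ju = np.triu_indices(w)
    out[..., iu, ju] = vec
    out[..., ju, iu] = vec
    return out


def mirror_permutation(w: int) -> np.ndarray:
    """Index permutation sending upper-triangle element (i,j) to (w-1-j, w-1-i).

    Applying it to a flattened target yields the target of the left-right
    inverted window; it is an involution.
    """
    iu, ju = np.triu_indices(w)
    flat = np.full((w, w), -1, dtype=np.int64)
    flat[iu, ju] = np.arange(len(iu))
    return flat[w - 1 - ju, w - 1 - iu]


def extract_windows(
    tracks: FactorTrackSet,
    norm_map: NormalizedContactMap,
    bins: GenomeBins,
    w: int = 80,
    stride: int = 1,
) -> list[WindowSample]:
    """Cut aligned (tracks, map) data into forward-orientation window samples.

    Inner regions start at chromosome-local bin w + k*stride; only windows
    whose full 3w block fits inside one chromosome are emitted, so a
    chromosome of L bins yields floor((L - 3w)/stride) + 1 windows (0 if
    L < 3w, with a warning).
    """
    if w < 1 or stride < 1:
        raise ValueError("w and stride must be >= 1")
    samples: list[WindowSample] = []
    for chrom, n, off in zip(bins.chrom_names, bins.chrom_n_bins, bins.chrom_offsets):
        if chrom not in norm_map.matrices:
            continue
        if n < 3 * w:
            warnings.warn(f"{chrom}: {n} bins < 3w={3 * w}, no windows", stacklevel=2)
            continue
        mat = norm_map.matrices[chrom]
        for start in range(w, n - 2 * w + 1, stride):
            block = tracks.values[:, off + start - w : off + start + 2 * w]
            target = flatten_upper(mat[start : start + w, start : start + w])
            samples.append(
                WindowSample(
                    chrom=chrom,
                    start_bin=start,
                    orientation="forward",
                    input_block=block.copy(),
                    target=target.copy(),
                )
            )
    return samples


def mirror_augment(samples: list[WindowSample]) -> list[WindowSample]:
    """Append the left-right inverted twin of every forward sample."""
    if not samples:
        return []
    perm_cache: dict[int, np.ndarray] = {}
    out = list(samples)
    for s in samples:
        w = s.w
        if w not in perm_cache:
            perm_cache[w] = mirror_permutation(w)
        out.append(
            WindowSample(
                chrom=s.chrom,
                start_bin=s.start_bin,
                orientation="inverted",
                input_block=s.input_block[:, ::-1].copy(),
                target=s.target[perm_cache[w]].copy(),
            )
        )
    return out


def _in_region(
    sample: WindowSample, regions: list[tuple[str, int, int]], bin_size: int
) -> bool:
    span_start = sample.start_bin * bin_size
    span_end = (sample.start_bin + sample.w) * bin_size
    return any(
        chrom == sample.chrom and start <= span_start and span_end <= end
        for chrom, start, end in regions
    )


def make_splits(
    samples: list[WindowSample],
    train_regions: list[tuple[str, int, int]],
    test_regions: list[tuple[str, int, int]],
    bin_size: int,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Assign samples to train/validation/test by genomic region.

    A sample belongs to a region when its inner span lies fully inside it.
    The train-region pool is split 1-val_fraction / val_fraction by seeded
    subsampling of pool keys (chrom, start_bin), so a forward sample and its
    mirrored twin always land in the same partition.  Train and test regions
    must not overlap.
    """
    for tc, ts, te in train_regions:
        for uc, us, ue in test_regions:
            if tc == uc and ts < ue and us < te:
                raise ValueError(
                    f"train region ({tc},{ts},{te}) overlaps test region ({uc},{us},{ue})"
                )
    pool = [s for s in samples if _in_region(s, train_regions, bin_size)]
    test = [s for s in samples if _in_region(s, test_regions, bin_size)]
    keys = sorted({(s.chrom, s.start_bin) for s in pool})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_val = int(round(val_fraction * len(keys)))
    val_keys = {keys[i] for i in order[:n_val]}
    train = [s for s in pool if (s.chrom, s.start_bin) not in val_keys]
    validation = [s for s in pool if (s.chrom, s.start_bin) in val_keys]
    return DatasetSplit(
        train=train,
        validation=validation,
        test=test,
        split_seed=seed,
        train_regions=list(train_regions),
        test_regions=list(test_regions),
    )
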