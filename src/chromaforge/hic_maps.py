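"""Contact-matrix construction, ICE balancing and distance normalization.

A Hi-C experiment yields pair counts n_ij between genomic bins.  Three steps
turn them into the contact enrichments P(c_ij) the models consume:

1. ``build_contact_matrix`` bins intra-chromosomal read pairs into a symmetric
   count matrix per chromosome, optionally counting each unique pair id once.
2. ``ice_normalize`` iteratively corrects the matrix so every unmasked bin has
   the same marginal (equal visibility), factoring the counts as
   ``n_ij = b_i * b_j * balanced_ij``.
3. ``distance_normalize`` divides the balanced counts by the mean count at
   each genomic separation, removing the polymer distance decay; the result
   has mean 1 along every diagonal and is proportional to contact probability
   once the entropic decay is removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_tracks import GenomeBins

__all__ = [
    "RawContactMap",
    "NormalizedContactMap",
    "build_contact_matrix",
    "ice_normalize",
    "distance_normalize",
]


@dataclass
class RawContactMap:
    """Per-chromosome symmetric count matrices with a valid-bin mask."""

    chrom_names: list[str]
    matrices: dict[str, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            m = np.asarray(self.matrices[name], dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"matrix for {name} is not square")
            if not np.allclose(m, m.T):
                raise ValueError(f"matrix for {name} is not symmetric")
            self.matrices[name] = m
            if name not in self.masks:
                self.masks[name] = np.ones(m.shape[0], dtype=bool)


@dataclass
class NormalizedContactMap:
    """Per-chromosome contact enrichments P(c_ij) with mean 1 per diagonal."""

    chrom_names: list[str]
    matrices: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    expected: np.ndarray | dict[str, np.ndarray] | None = None


def build_contact_matrix(
    pairs, bins: GenomeBins, dedupe: bool = True
) -> RawContactMap:
    """Bin a list of intra-chromosomal contacts into symmetric count matrices.

    ``pairs`` is an iterable of ``(chrom_a, pos_a, chrom_b, pos_b, pair_id)``
    records (or a DataFrame with those columns).  Inter-chromosomal pairs are
    dropped; with ``dedupe`` every distinct ``pair_id`` contributes once.
    Positions outside their chromosome are skipped with a warning count.
    """
    import pandas as pd

    if isinstance(pairs, pd.DataFrame):
        records = pairs[["chrom_a", "pos_a", "chrom_b", "pos_b", "pair_id"]].itertuples(
            index=False
        )
    else:
        records = pairs
    mats = {
        name: np.zeros((n, n), dtype=float)
        for name, n in zip(bins.chrom_names, bins.chrom_n_bins)
    }
    seen: set = set()
    n_skipped = 0
    for chrom_a, pos_a, chrom_b, pos_b, pair_id in records:
        if chrom_a != chrom_b:
            continue
        if chrom_a not in bins.chrom_names:
            n_skipped += 1
            continue
        ci = bins.chrom_index(chrom_a)
        clen = bins.chrom_lengths[ci]
        if not (0 <= pos_a < clen and 0 <= pos_b < clen):
            n_skipped += 1
            continue
        if dedupe:
            if pair_id in seen:
                continue
            seen.add(pair_id)
        i = int(pos_a) // bins.bin_size
        j = int(pos_b) // bins.bin_size
        mats[chrom_a][i, j] += 1
        if i != j:
            mats[chrom_a][j, i] += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} pair(s) outside chromosome bounds", stacklevel=2)
    return RawContactMap(chrom_names=list(bins.chrom_names), matrices=mats)


def _ice_one(
    mat: np.ndarray, mask: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    n = mat.shape[0]
    biases = np.ones(n, dtype=float)
    work = mat.copy()
    work[~mask, :] = 0.0
    work[:, ~mask] = 0.0
    converged = False
    for _ in range(max_iter):
        rowsums = work.sum(axis=1)
        active = rowsums[mask]
        mean = active.mean()
        spread = (active.max() - active.min()) / mean if mean > 0 else 0.0
        if spread < tol:
            converged = True
            break
        delta = np.ones(n)
        delta[mask] = active / mean
        work = work / np.outer(delta, delta)
        work[~mask, :] = 0.0
        work[:, ~mask] = 0.0
        biases *= delta
    return work, biases, converged


def ice_normalize(
    raw: RawContactMap,
    tol: float = 1e-5,
    max_iter: int = 200,
    mask_frac: float = 0.0,
) -> tuple[RawContactMap, dict[str, np.ndarray]]:
    """Iteratively correct each chromosome matrix to equal row sums.

    Bins with a zero raw marginal are masked; ``mask_frac`` additionally masks
    bins whose marginal falls below that quantile of the non-zero marginals.
    Returns the balanced map (``raw_ij = b_i b_j balanced_ij``) and the bias
    vector per chromosome.  Convergence means the relative spread of the row
    sums over unmasked bins drops below ``tol``; hitting ``max_iter`` first
    returns the best iterate with a warning.
    """
    balanced: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    bias_out: dict[str, np.ndarray] = {}
    for name in raw.chrom_names:
        mat = raw.matrices[name]
        if mat.sum() == 0:
            raise ValueError(f"all-zero contact matrix for {name}")
        marg = mat.sum(axis=1)
        mask = raw.masks[name] & (marg > 0)
        if mask_frac > 0:
            cutoff = np.quantile(marg[marg > 0], mask_frac)
            mask &= marg >= cutoff
        work, biases, converged = _ice_one(mat, mask, tol, max_iter)
        if not converged:
            warnings.warn(
                f"ICE did not reach tol={tol} in {max_iter} iterations for {name}",
                stacklevel=2,
            )
        balanced[name] = work
        masks[name] = mask
        bias_out[name] = biases
    out = RawContactMap(
        chrom_names=list(raw.chrom_names), matrices=balanced, masks=masks
    )
    return out, bias_out


def distance_normalize(
    balanced: RawContactMap, expected_mode: str = "pooled"
) -> NormalizedContactMap:
    """Divide contacts by the mean contact at each genomic separation.

    The expected value at separation d is the mean over all unmasked bin
    pairs at that separation — pooled across the supplied chromosomes by
    default, or per chromosome with ``expected_mode='per-chrom'``.  Output
    diagonals have mean exactly 1 over unmasked pairs; separations with zero
    expected value are left at 0.
    """
    if expected_mode not in ("pooled", "per-chrom"):
        raise ValueError(f"unknown expected_mode {expected_mode!r}")

    def _sums(name: str) -> tuple[np.ndarray, np.ndarray]:
        mat, mask = balanced.matrices[name], balanced.masks[name]
        n = mat.shape[0]
        sums = np.zeros(n)
        counts = np.zeros(n)
        mm = np.outer(mask, mask)
        for d in range(n):
            diag = np.diagonal(mat, offset=d)
            dmask = np.diagonal(mm, offset=d)
            sums[d] = diag[dmask].sum()
            counts[d] = dmask.sum()
        return sums, counts

    per_chrom = {name: _sums(name) for name in balanced.chrom_names}
    out_mats: dict[str, np.ndarray] = {}
    expected_store: dict[str, np.ndarray] = {}
    if expected_mode == "pooled":
        max_n = max(m.shape[0] for m in balanced.matrices.values())
        tot_sums = np.zeros(max_n)
        tot_counts = np.zeros(max_n)
        for sums, counts in per_chrom.values():
            tot_sums[: len(sums)] += sums
            tot_counts[: len(counts)] += counts
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled_expected = np.where(tot_counts > 0, tot_sums / tot_counts, 0.0)
    for name in balanced.chrom_names:
        mat, mask = balanced.matrices[name], balanced.masks[name]
        n = mat.shape[0]
        if expected_mode == "pooled":
            expected = pooled_expected[:n]
        else:
            sums, counts = per_chrom[name]
            with np.errstate(invalid="ignore", divide="ignore"):
                expected = np.where(counts > 0, sums / counts, 0.0)
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        exp_mat = expected[dist]
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(exp_mat > 0, mat / exp_mat, 0.0)
        norm[~mask, :] = 0.0
        norm[:, ~mask] = 0.0
        out_mats[name] = norm
        expected_store[name] = expected
    return NormalizedContactMap(
        chrom_names=list(balanced.chrom_names),
        matrices=out_mats,
        masks={k: v.copy() for k, v in balanced.masks.items()},
        expected=expected_store,
    )
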