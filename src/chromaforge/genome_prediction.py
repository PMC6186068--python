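"""Genome-scale assembly and evaluation of window predictions.

Because the dataset consists of overlapping sliding windows, every contact
pair (and every genomic bin) is predicted by many windows.  Averaging those
overlapping outputs — bootstrap-aggregation style "bagging" — yields a single
genome-scale prediction whose accuracy typically exceeds that of individual
windows.  Predicted maps are held as a diagonal band of width w per
chromosome; predicted state sequences as 1D tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from .neural_models import (
    DenseStackParams,
    ForwardModel,
    dense_stack_apply,
)
from .window_dataset import WindowSample, mirror_permutation

__all__ = [
    "AggregatedPrediction",
    "aggregate_windows",
    "band_from_matrix",
    "pearson_eval",
    "per_window_pearson",
    "gaussian_smooth",
    "roundtrip_predict",
]


@dataclass
class AggregatedPrediction:
    """Mean of overlapping window outputs, with per-element coverage.

    For ``kind='map'`` the arrays are (n_bins, w) diagonal bands:
    ``values[i, d]`` is the predicted enrichment for the pair (i, i+d).
    For ``kind='state'`` they are length-n_bins tracks.
    """

    kind: str  # "map" | "state"
    chrom_values: dict[str, np.ndarray]
    chrom_coverage: dict[str, np.ndarray]
    w: int


def aggregate_windows(
    outputs: list[np.ndarray],
    samples: list[WindowSample],
    chrom_n_bins: dict[str, int],
    kind: str = "map",
) -> AggregatedPrediction:
    """Average per-window outputs over the genome elements they cover.

    ``outputs[k]`` is the model output for ``samples[k]``: a flattened
    w(w+1)/2 contact vector (``kind='map'``) or an inner-w state sequence
    (``kind='state'``).  Outputs of inverted-orientation samples are
    un-mirrored before pooling, so a window and its mirrored twin both
    contribute (coverage 2) to the same genomic elements.
    """
    if len(outputs) != len(samples):
        raise ValueError("outputs and samples length mismatch")
    if kind not in ("map", "state"):
        raise ValueError(f"unknown kind {kind!r}")
    ws = {s.w for s in samples}
    if len(ws) > 1:
        raise ValueError(f"conflicting window sizes {sorted(ws)}")
    w = ws.pop() if ws else 0
    perm = mirror_permutation(w) if kind == "map" else None
    if kind == "map":
        sums = {c: np.zeros((n, w)) for c, n in chrom_n_bins.items()}
        cov = {c: np.zeros((n, w)) for c, n in chrom_n_bins.items()}
        iu, ju = np.triu_indices(w)
        dist = ju - iu
    else:
        sums = {c: np.zeros(n) for c, n in chrom_n_bins.items()}
        cov = {c: np.zeros(n) for c, n in chrom_n_bins.items()}
    for out, s in zip(outputs, samples):
        out = np.asarray(out, dtype=float)
        if s.orientation == "inverted":
            out = out[perm] if kind == "map" else out[::-1]
        if kind == "map":
            if out.shape[0] != w * (w + 1) // 2:
                raise ValueError("output length inconsistent with w")
            np.add.at(sums[s.chrom], (s.start_bin + iu, dist), out)
            np.add.at(cov[s.chrom], (s.start_bin + iu, dist), 1.0)
        else:
            if out.shape[0] != w:
                raise ValueError("state output must have length w")
            sums[s.chrom][s.start_bin : s.start_bin + w] += out
            cov[s.chrom][s.start_bin : s.start_bin + w] += 1.0
    values = {}
    for c in sums:
        with np.errstate(invalid="ignore", divide="ignore"):
            values[c] = np.where(cov[c] > 0, sums[c] / cov[c], np.nan)
    return AggregatedPrediction(kind=kind, chrom_values=values, chrom_coverage=cov, w=w)


def band_from_matrix(mat: np.ndarray, w: int) -> np.ndarray:
    """Diagonal band (n, w) view of a symmetric matrix: band[i, d] = mat[i, i+d]."""
    n = mat.shape[0]
    band = np.full((n, w), np.nan)
    for d in range(w):
        band[: n - d, d] = np.diagonal(mat, offset=d)
    return band


def pearson_eval(pred: np.ndarray, obs: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation over unmasked, finite elements of two arrays."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    keep = np.isfinite(pred) & np.isfinite(obs)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).ravel()
    if keep.sum() < 2:
        raise ValueError("need at least 2 unmasked elements")
    p, o = pred[keep], obs[keep]
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(pearsonr(p, o)[0])


def per_window_pearson(outputs: list[np.ndarray], targets: list[np.ndarray]) -> float:
    """Mean of per-window Pearson correlations (windows with zero variance skipped)."""
    vals = []
    for p, o in zip(outputs, targets):
        p = np.asarray(p, dtype=float).ravel()
        o = np.asarray(o, dtype=float).ravel()
        if np.ptp(p) == 0 or np.ptp(o) == 0:
            continue
        vals.append(pearsonr(p, o)[0])
    if not vals:
        raise ValueError("no windows with defined correlation")
    return float(np.mean(vals))


def gaussian_smooth(track: np.ndarray, sigma_bins: float, boundary: str = "reflect") -> np.ndarray:
    """Gaussian smoothing of a 1D state track.

    Discrete Gaussian kernel normalized to sum 1, truncated at 4 sigma,
    reflect-padded by default (preserving the mean of constant-extended
    edges).
    """
    if sigma_bins <= 0:
        raise ValueError("sigma_bins must be positive")
    return gaussian_filter1d(
        np.asarray(track, dtype=float), sigma_bins, mode=boundary, truncate=4.0
    )


def roundtrip_predict(
    samples: list[WindowSample],
    backward_stack: DenseStackParams,
    forward_model: ForwardModel,
    backward_states: list[np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Feed backward-model sequences into the forward dense stack.

    The backward model outputs only the inner w states, while the forward
    stack expects 3w; the flanks are taken from the forward model's own
    chromatin states (conv filter on the tracks) with the inner w replaced by
    the backward prediction.  If ``backward_states`` is given it is used
    instead of running the backward stack on each sample's target.
    """
    w = forward_model.w
    out = []
    for k, s in enumerate(samples):
        if backward_states is not None:
            inner = np.asarray(backward_states[k], dtype=float)
        else:
            inner = dense_stack_apply(s.target, backward_stack)
        if inner.shape[0] != w:
            raise ValueError("backward state must be w-long")
        sigma = forward_model.states(s.input_block)
        spliced = sigma.copy()
        spliced[w : 2 * w] = inner
        out.append(dense_stack_apply(spliced, forward_model.stack))
    return out
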