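"""Gradient (sensitivity) analysis of the trained networks.

For the forward model, the gradient of one contact output with respect to the
input chromatin states, dP(c_ij)/d sigma_k, says how the predicted contact
between sites i and j would change were the chromatin at position k made more
active.  For the backward model, d sigma_k / d P(c_ij) says how a change in
one contact would be reflected in the inferred state at position k.  Both are
exact reverse-mode derivatives through the trained stacks.

Genome-scale summaries average these gradients over test windows:
distance-stratified profiles for pairs centred in the window (forward model),
and class-conditional gradient maps for windows whose central state is
inactive or active (backward model).  Mean-squared companions highlight where
gradient magnitude, rather than its sign, is largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .neural_models import (
    DenseStackParams,
    ForwardModel,
    dense_stack_backward,
    dense_stack_forward,
)
from .window_dataset import WindowSample

__all__ = [
    "GradientProfile",
    "GradientContactMap",
    "DistanceProfile",
    "stack_input_gradient",
    "grad_contact_wrt_state",
    "grad_contact_wrt_tracks",
    "grad_state_wrt_contacts",
    "centered_pair",
    "distance_stratified_average",
    "stratified_state_gradients",
]


@dataclass
class GradientProfile:
    """dP(c_ij)/d sigma_k over the 3w input positions, for one probed pair."""

    values: np.ndarray  # (3w,)
    pair: tuple[int, int]


@dataclass
class GradientContactMap:
    """d sigma_k / d P(c_ij) over all i <= j pairs, for one probed position."""

    values: np.ndarray  # (w(w+1)/2,), upper-triangular layout
    position: int


@dataclass
class DistanceProfile:
    """Per-distance mean (and mean-square) gradient profiles with counts."""

    distances: np.ndarray  # (D,)
    mean: np.ndarray  # (D, 3w)
    mean_square: np.ndarray  # (D, 3w)
    counts: np.ndarray  # (D,)


def _flat_index(i: int, j: int, w: int) -> int:
    if not (0 <= i <= j < w):
        raise ValueError(f"pair ({i},{j}) outside window of size {w}")
    return i * w - i * (i - 1) // 2 + (j - i)


def stack_input_gradient(
    stack: DenseStackParams, inputs: np.ndarray, output_index: int
) -> np.ndarray:
    """Exact gradient of one output neuron w.r.t. the stack input.

    ``inputs`` may be a single vector or a batch; the gradient is evaluated
    at those inputs by one forward pass plus reverse-mode back-propagation of
    a one-hot seed at ``output_index``.
    """
    x = np.asarray(inputs, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[None, :]
    out, caches = dense_stack_forward(x, stack)
    if not 0 <= output_index < stack.n_out:
        raise ValueError(f"output index {output_index} out of range")
    seed = np.zeros((x.shape[0], stack.n_out))
    seed[:, output_index] = 1.0
    _, grad_in = dense_stack_backward(stack, caches, seed)
    return grad_in[0] if squeeze else grad_in


def grad_contact_wrt_state(
    forward: ForwardModel, sigma: np.ndarray, pair: tuple[int, int]
) -> GradientProfile:
    """dP(c_ij)/d sigma_k for one pair (i, j) of the inner window.

    ``sigma`` is the 3w-long state sequence at which the gradient is taken
    (the dense-stack input, not the raw tracks); (i, j) are inner-window bin
    indices with i <= j.
    """
    i, j = min(pair), max(pair)
    idx = _flat_index(i, j, forward.w)
    grad = stack_input_gradient(forward.stack, sigma, idx)
    return GradientProfile(values=grad, pair=(i, j))


def grad_contact_wrt_tracks(
    forward: ForwardModel, input_block: np.ndarray, pair: tuple[int, int]
) -> np.ndarray:
    """Gradient of one contact output w.r.t. the raw M x 3w factor block.

    Chains the dense-stack gradient through the filter:
    d/dx_{k,m} = [dP/d sigma_k] * sigma_k (1 - sigma_k) * W0_m.
    """
    sigma = forward.states(input_block)
    prof = grad_contact_wrt_state(forward, sigma, pair)
    return np.outer(forward.filter.W0, prof.values * sigma * (1.0 - sigma))


def grad_state_wrt_contacts(
    backward_stack: DenseStackParams, contact_input: np.ndarray, position: int
) -> GradientContactMap:
    """d sigma_k / d P(c_ij) for one output position of the backward model."""
    w = backward_stack.n_out
    if not 0 <= position < w:
        raise ValueError(f"position {position} out of range for w={w}")
    grad = stack_input_gradient(backward_stack, contact_input, position)
    return GradientContactMap(values=grad, position=position)


def centered_pair(w: int, d: int) -> tuple[int, int]:
    """The pair (i, j) at separation d centred on the inner-window midpoint.

    The midpoint of (i + j)/2 coincides with the window centre w//2; for odd
    d the half-bin offset is rounded left.
    """
    if not 0 <= d < w:
        raise ValueError(f"distance {d} not representable in window of {w}")
    mid = w // 2
    i = mid - (d + 1) // 2
    j = i + d
    if i < 0 or j >= w:
        raise ValueError(f"centred pair at distance {d} falls outside window")
    return i, j


def distance_stratified_average(
    forward: ForwardModel,
    windows: list[WindowSample],
    distances,
) -> DistanceProfile:
    """Genome-average gradient profiles for centred pairs, per distance.

    For each separation d, the probed pair is the one centred in the inner
    window, so every supplied window contributes one gradient profile; the
    per-d mean and mean-square over windows are returned along with counts.
    """
    distances = np.asarray(list(distances), dtype=int)
    if not windows:
        raise ValueError("no windows supplied")
    w = forward.w
    sigma = np.stack([forward.states(s.input_block) for s in windows])
    mean = np.zeros((len(distances), 3 * w))
    mean_sq = np.zeros((len(distances), 3 * w))
    counts = np.zeros(len(distances), dtype=int)
    for di, d in enumerate(distances):
        i, j = centered_pair(w, int(d))
        idx = _flat_index(i, j, w)
        grads = stack_input_gradient(forward.stack, sigma, idx)
        mean[di] = grads.mean(axis=0)
        mean_sq[di] = (grads**2).mean(axis=0)
        counts[di] = len(windows)
    return DistanceProfile(
        distances=distances, mean=mean, mean_square=mean_sq, counts=counts
    )


def stratified_state_gradients(
    backward_stack: DenseStackParams,
    windows: list[WindowSample],
    backward_states: np.ndarray | None = None,
    t_low: float = 0.3,
    t_high: float = 0.7,
) -> dict[str, dict[str, np.ndarray]]:
    """Class-conditional gradient maps for the central output position.

    Windows are grouped by the backward model's central state sigma_{w/2}:
    inactive (< t_low) vs active (> t_high).  For each class the mean and
    mean-square of d sigma_{w/2} / d P(c_ij) over member windows are
    returned, plus the member count; an empty class yields count 0 and NaN
    maps.
    """
    if not windows:
        raise ValueError("no windows supplied")
    w = backward_stack.n_out
    k = w // 2
    inputs = np.stack([s.target for s in windows])
    if backward_states is None:
        backward_states, _ = dense_stack_forward(inputs, backward_stack)
    central = np.asarray(backward_states)[:, k]
    grads = stack_input_gradient(backward_stack, inputs, k)
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, member in (("inactive", central < t_low), ("active", central > t_high)):
        if member.sum() == 0:
            out[name] = {
                "mean": np.full(grads.shape[1], np.nan),
                "mean_square": np.full(grads.shape[1], np.nan),
                "count": np.array(0),
            }
            continue
        sel = grads[member]
        out[name] = {
            "mean": sel.mean(axis=0),
            "mean_square": (sel**2).mean(axis=0),
            "count": np.array(int(member.sum())),
        }
    return out
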