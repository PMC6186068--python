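"""Ground-truthed synthetic chromatin data.

The generator emulates the statistical structure the models assume, with the
truth retained so every pipeline stage can be checked against it:

* a hidden chromatin state sequence s in [0,1]^N organised in alternating
  active/inactive domains (geometric lengths), bimodal with the inactive mode
  near 0.2 and the active mode near 1 — mimicking the bimodal state
  distribution a trained filter produces on real fly chromatin;
* M factor tracks constructed so that a width-1 logistic filter with the true
  mixing weights recovers the state sequence (factors with positive weight
  enriched in active domains, negative weight in inactive ones, plus bounded
  beta noise) — so the filter is identifiable from the tracks;
* a symmetric contact-enrichment map driven by the state sequence through a
  simple folding rule: contacts are promoted by active states at the
  contacting sites themselves and by inactive chromatin in between,

      E(i,j) = exp(alpha (s_i + s_j - 1) - gamma mean(s_i..s_j) + eta_ij),

  with lognormal noise eta, plus Poisson counts with a power-law distance
  decay for count-level testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_tracks import FactorTrackSet, GenomeBins
from .hic_maps import NormalizedContactMap, RawContactMap, distance_normalize

__all__ = [
    "SyntheticTruth",
    "generate_truth",
    "generate_tracks",
    "generate_contact_map",
    "true_enrichment",
]

_LOGIT_CLIP = 0.005  # states are representable through a logistic within [clip, 1-clip]


@dataclass
class SyntheticTruth:
    """Hidden state sequence, mixing weights and contact-rule parameters."""

    states: np.ndarray  # (N,) in [0,1], bimodal
    domain_labels: np.ndarray  # (N,) bool, True = active domain
    mixing_weights: np.ndarray  # (M,), both signs
    intercept: float
    alpha: float = 0.8  # site coefficient: active contacting sites promote contact
    gamma: float = 1.2  # interior coefficient: inactive interiors promote contact
    noise_sd: float = 0.2  # sd of the lognormal enrichment noise
    decay_exponent: float = 1.0  # power-law distance decay of expected counts
    coverage: float = 100.0  # count scale C for the Poisson layer
    track_noise: float = 0.25  # scale of the beta noise added to factor tracks
    seed: int = 0
    track_base: np.ndarray | None = field(default=None, repr=False)
    track_gain: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.states)

    @property
    def n_factors(self) -> int:
        return len(self.mixing_weights)

    def clipped_states(self) -> np.ndarray:
        """States clipped into the logit-representable open interval."""
        return np.clip(self.states, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)


def generate_truth(
    n_bins: int,
    n_factors: int,
    mean_domain_len: float = 10.0,
    seed: int = 0,
    **rule_params,
) -> SyntheticTruth:
    """Draw a hidden state sequence and the mixing weights of the factors.

    Domains alternate active/inactive with geometric lengths of the given
    mean; active states are clipped normal(1.0, 0.05), inactive clipped
    normal(0.2, 0.05).  Mixing weights carry both signs with magnitudes in
    [0.8, 2.0]; the per-factor response geometry (base level and gain) that
    makes the logistic filter exactly invert the construction is precomputed
    here so that ``generate_tracks`` is deterministic given the truth.
    """
    if n_bins < 1 or n_factors < 1:
        raise ValueError("n_bins and n_factors must be >= 1")
    rng = np.random.default_rng(seed)
    p = min(1.0, 1.0 / mean_domain_len)
    labels = np.empty(n_bins, dtype=bool)
    active = bool(rng.integers(2))
    pos = 0
    while pos < n_bins:
        length = rng.geometric(p)
        labels[pos : pos + length] = active
        active = not active
        pos += length
    states = np.where(
        labels,
        rng.normal(1.0, 0.05, n_bins),
        rng.normal(0.2, 0.05, n_bins),
    )
    states = np.clip(states, 0.0, 1.0)
    signs = np.where(rng.random(n_factors) < 0.5, -1.0, 1.0)
    # keep at least one factor of each sign so both chromatin classes exist
    signs[0], signs[1 % n_factors] = 1.0, -1.0
    weights = signs * rng.uniform(0.8, 2.0, n_factors)
    # response geometry: x_{j,i} = base_j + gain_j * u_i with u the unit-scaled
    # logit of the state; choosing gain_j ~ |v_j| makes sum_j v_j x_{j,i} span
    # exactly the logit range, so logistic(v.x + b) = clipped state.
    a = _logit(np.clip(states, _LOGIT_CLIP, 1 - _LOGIT_CLIP))
    a_min, a_max = float(a.min()), float(a.max())
    rho = (a_max - a_min) / np.sum(weights**2)
    gain = rho * np.abs(weights)
    if gain.max() > 0.9:
        # few/weak factors cannot span the logit range with occupancies in
        # [0,1]; scale all weight magnitudes up (signs and ratios preserved)
        weights = weights * (gain.max() / 0.9)
        rho = (a_max - a_min) / np.sum(weights**2)
        gain = rho * np.abs(weights)
    base = rng.uniform(0.0, 1.0 - gain) * 0.5
    const = float(
        np.sum(weights * base) + np.sum(np.where(weights < 0, weights * gain, 0.0))
    )
    intercept = a_min - const
    truth = SyntheticTruth(
        states=states,
        domain_labels=labels,
        mixing_weights=weights,
        intercept=intercept,
        seed=seed,
        track_base=base,
        track_gain=gain,
        **rule_params,
    )
    return truth


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def generate_tracks(truth: SyntheticTruth, noise: float | None = None) -> FactorTrackSet:
    """Factor occupancy tracks consistent with the logistic filter.

    With ``noise=0`` the construction is exact: applying the width-1 logistic
    filter with the true weights and intercept to the tracks returns the
    (logit-clipped) hidden states to machine precision.  Otherwise each entry
    receives independent centred beta noise of the given scale and is clipped
    back into [0, 1].
    """
    if noise is None:
        noise = truth.track_noise
    rng = np.random.default_rng(truth.seed + 1)
    a = _logit(truth.clipped_states())
    u = (a - a.min()) / (a.max() - a.min())  # (N,) in [0,1]
    v = truth.mixing_weights
    resp = np.where(v[:, None] >= 0, u[None, :], 1.0 - u[None, :])
    x = truth.track_base[:, None] + truth.track_gain[:, None] * resp
    if noise > 0:
        x = x + noise * (rng.beta(2.0, 2.0, size=x.shape) - 0.5)
        x = np.clip(x, 0.0, 1.0)
    names = [f"factor_{k:02d}" for k in range(truth.n_factors)]
    return FactorTrackSet(factor_names=names, values=x)


def true_enrichment(truth: SyntheticTruth, noise_sd: float | None = None, rng=None) -> np.ndarray:
    """The contact-enrichment matrix E(i,j) implied by the hidden states.

    ``noise_sd=0`` gives the noiseless rule; otherwise symmetric lognormal
    noise is applied.
    """
    s = truth.states
    n = truth.n_bins
    cs = np.concatenate([[0.0], np.cumsum(s)])
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    interior_mean = (cs[hi + 1] - cs[lo]) / (hi - lo + 1)
    log_e = truth.alpha * (s[lo] + s[hi] - 1.0) - truth.gamma * interior_mean
    if noise_sd is None:
        noise_sd = truth.noise_sd
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(truth.seed + 2)
        eta = rng.normal(0.0, noise_sd, size=(n, n))
        eta = np.triu(eta) + np.triu(eta, 1).T
        log_e = log_e + eta
    return np.exp(log_e)


def generate_contact_map(
    truth: SyntheticTruth, bins: GenomeBins | None = None, chrom: str = "chrS"
) -> tuple[RawContactMap, NormalizedContactMap]:
    """Raw Poisson counts and the distance-normalized enrichment map.

    The normalized map is the noisy enrichment divided by its mean at each
    separation (mean 1 per diagonal); the raw map draws symmetric Poisson
    counts with expectation E(i,j) * C * (|i-j| + 1)^(-decay_exponent).
    """
    n = truth.n_bins
    rng = np.random.default_rng(truth.seed + 3)
    e = true_enrichment(truth, rng=rng)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    decay = (np.abs(i - j) + 1.0) ** (-truth.decay_exponent)
    lam = e * truth.coverage * decay
    counts = rng.poisson(np.triu(lam)).astype(float)
    counts = np.triu(counts) + np.triu(counts, 1).T
    raw = RawContactMap(chrom_names=[chrom], matrices={chrom: counts})
    noisy = RawContactMap(chrom_names=[chrom], matrices={chrom: e})
    norm = distance_normalize(noisy)
    return raw, norm
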