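"""Counterfactual decoding, the factual/counterfactual discriminator, and
the shift-alignment penalty.

A counterfactual query asks: what outcome would the model predict at the
next visit had treatment ã been given instead of the observed a?  The
mean-path answer pushes the current latent state through the transition
with the alternative embedding and decodes it with the same outcome
decoder, ŷ^cf = D_y(f_θ(z, e(ã))).  The expectation version integrates
over posterior and transition noise by Monte Carlo.

The discriminator D_ψ(z, e(a)) scores whether a (latent state, treatment)
pair comes from the factual or the counterfactual stream; its objective
L_disc = E_cf[log(1 − D)] + E_real[log D] is maximized by the
discriminator in the dual-loop training.  Following the composite
objective as specified, the generator carries −λ4·L_disc in its total
loss.  The discriminator conditions on (z, e(a)) only; a config flag
optionally appends the decoded next outcome to its input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, as_tensor, concat, log, sigmoid, tanh
from .cohort import Trajectory
from .model import ModelParams, PosteriorState, encode_posterior

__all__ = [
    "CounterfactualQuery",
    "counterfactual_outcome",
    "counterfactual_expectation",
    "counterfactual_rollout",
    "discriminator_score",
    "discriminator_loss",
    "shift_alignment",
]


@dataclass
class CounterfactualQuery:
    """A what-if query: replace the treatment at visit `s` (one-based) by `a_alt`."""

    patient_id: str
    s: int
    a_alt: str
    n_samples: int = 1
    horizon: int = 1

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("intervention time must be >= 1")
        if self.n_samples < 1 or self.horizon < 1:
            raise ValueError("n_samples and horizon must be >= 1")


# ---------------------------------------------------------------------------
def counterfactual_outcome(z, a_alt: str, params: ModelParams) -> np.ndarray:
    """Mean-path counterfactual ŷ = D_y(f_θ(z, e(ã))) for one latent state."""
    z = as_tensor(np.asarray(z, dtype=np.float64))
    z_next = params.f_theta(z, params.embed(a_alt))
    y_mean, _, _ = params.decode_t(z_next)
    return y_mean.data


def counterfactual_expectation(
    posterior: PosteriorState,
    t: int,
    a_alt: str,
    params: ModelParams,
    n_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo E_{z_t∼q}E_{z_{t+1}∼T(z_t, ã)}[E_y(z_{t+1})].

    `t` is the one-based visit whose posterior is intervened on.
    Deterministic given `seed`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (1 <= t <= posterior.T):
        raise ValueError(f"time {t} outside posterior horizon 1..{posterior.T}")
    rng = np.random.default_rng(seed)
    mu = posterior.mean[t - 1]
    sd = np.sqrt(posterior.var[t - 1])
    d_z = mu.shape[0]
    z_t = mu + sd * rng.normal(size=(n_samples, d_z))
    e = params.embed(a_alt)
    e_b = e.reshape(1, -1) + Tensor(np.zeros((n_samples, 1)))
    mean_next = params.f_theta(as_tensor(z_t), e_b)
    sigma = params.sigma().item()
    z_next = mean_next.data + sigma * rng.normal(size=(n_samples, d_z))
    y_mean, _, _ = params.decode_t(as_tensor(z_next))
    return y_mean.data.mean(axis=0)


def counterfactual_rollout(
    trajectory: Trajectory,
    s: int,
    a_alt: str,
    params: ModelParams,
    horizon: int = 1,
) -> np.ndarray:
    """Mean-path counterfactual outcomes for visits s+1 .. s+horizon.

    Encodes the factual history up to visit `s`, substitutes ã at `s`, then
    chains deterministic transition means (factual treatments after `s`).
    Returns an (horizon, k) array.
    """
    if not (1 <= s <= trajectory.T):
        raise ValueError(f"intervention time {s} outside horizon 1..{trajectory.T}")
    post = encode_posterior(trajectory, params)
    z = as_tensor(post.mean[s - 1])
    out = []
    for h in range(horizon):
        a = a_alt if h == 0 else trajectory.treatments[min(s - 1 + h, trajectory.T - 1)]
        z = params.f_theta(z, params.embed(a))
        y_mean, _, _ = params.decode_t(z)
        out.append(y_mean.data)
    return np.asarray(out)


# ---------------------------------------------------------------------------
def _disc_logit(params: ModelParams, z: Tensor, e: Tensor) -> Tensor:
    inp = concat([z, e], axis=-1)
    if params.config.disc_use_outcome:
        y_next, _, _ = params.decode_t(params.f_theta(z, e))
        inp = concat([inp, y_next], axis=-1)
    hid = tanh(inp @ params.t["disc_W1"].T + params.t["disc_b1"])
    return hid @ params.t["disc_W2"].T + params.t["disc_b2"]


def discriminator_score(z, a: str, params: ModelParams) -> float:
    """D_ψ(z, e(a)) ∈ (0, 1): probability the pair is from the factual stream."""
    z = as_tensor(np.asarray(z, dtype=np.float64))
    logit = _disc_logit(params, z, params.embed(a))
    return float(sigmoid(logit).data.reshape(-1)[0])


def discriminator_loss(real_pairs, cf_pairs, params: ModelParams) -> Tensor:
    """L_disc = mean_cf[log(1 − D(z, ã))] + mean_real[log D(z, a)].

    Each pair is (z, treatment_id) with z a latent vector (array or
    tensor).  Always ≤ 0; the supremum 0 is approached under perfect
    separation.  The discriminator ascends this; the composite generator
    objective carries −λ4·L_disc.
    """
    if not real_pairs or not cf_pairs:
        raise ValueError("real and counterfactual batches must be nonempty")

    def batch_scores(pairs):
        zs = ad.stack([as_tensor(z) for z, _ in pairs], axis=0)
        idx = params.treatment_indices([a for _, a in pairs])
        e = params.embed_indices(idx)
        return sigmoid(_disc_logit(params, zs, e))

    d_real = batch_scores(real_pairs)
    d_cf = batch_scores(cf_pairs)
    eps = 1e-12  # guards log at saturated scores
    return log(1.0 - d_cf + eps).mean() + log(d_real + eps).mean()


def shift_alignment(z, a: str, a_alt: str, params: ModelParams) -> Tensor:
    """‖Δ_real − Δ_cf‖² between factual and counterfactual latent shifts."""
    z = as_tensor(np.asarray(z, dtype=np.float64) if not isinstance(z, Tensor) else z)
    f_real = params.f_theta(z, params.embed(a))
    f_cf = params.f_theta(z, params.embed(a_alt))
    d = f_real - f_cf  # the −z terms cancel
    return (d * d).sum()
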