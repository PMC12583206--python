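"""Knowledge-infusion losses: grounding latent dynamics in clinical priors.

All losses operate on the treatment-induced latent shift
Δ(z, a) = f_θ(z, e(a)) − z or on posterior/decoder outputs:

* consistency: treatments joined by an ontology similarity edge must induce
  similar shifts;
* cumulative influence Γ_T: decay-weighted sum of shifts along a
  trajectory, with geometric weights w_t = ρ^{T−t};
* corridor: squared Euclidean distance from Γ to the convex safe region
  (exact projection: per-coordinate clamp for boxes, radial scaling for
  balls);
* drift: successive shifts should not change direction abruptly;
* anchoring: closed-form KL from the diagonal-Gaussian posterior to a
  diagonal-Gaussian clinical prior, per timestep;
* stage penalty: decoded outcomes track a stage-specific expected curve.

Functions accept autodiff tensors (training) or arrays (analysis); scalar
results are returned as tensors, `.item()` gives the float.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor, log, relu, sqrt
from .cohort import ClinicalPriors, SafeRegion, TreatmentOntology
from .model import ModelParams, PosteriorState

__all__ = [
    "latent_shift",
    "consistency_loss",
    "cumulative_influence",
    "corridor_loss",
    "drift_loss",
    "anchor_kl",
    "stage_penalty",
]


def latent_shift(z, a: str, params: ModelParams) -> Tensor:
    """Δ(z, a) = f_θ(z, e(a)) − z for a latent vector or batch."""
    z = as_tensor(z)
    e = params.embed(a)
    if z.ndim == 2:
        e = ad_broadcast_rows(e, z.shape[0])
    return params.f_theta(z, e) - z


def ad_broadcast_rows(e: Tensor, n: int) -> Tensor:
    """Tile an (m,) tensor to (n, m) keeping the gradient path."""
    return e.reshape(1, -1) + Tensor(np.zeros((n, 1)))


def consistency_loss(z_samples, ontology: TreatmentOntology, params: ModelParams) -> Tensor:
    """Σ over similarity edges of the mean squared shift discrepancy.

    `z_samples` is a batch (n, d_z) of latent states (posterior means or
    samples); an empty edge set yields 0.
    """
    if not ontology.similarity_edges:
        return as_tensor(0.0)
    z = as_tensor(z_samples)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    total = as_tensor(0.0)
    for edge in sorted(ontology.similarity_edges, key=sorted):
        a_i, a_j = sorted(edge)
        d = latent_shift(z, a_i, params) - latent_shift(z, a_j, params)
        total = total + (d * d).sum() * (1.0 / z.shape[0])
    return total


def cumulative_influence(latents, treatments, params: ModelParams, rho: float = 1.0) -> Tensor:
    """Γ_T = Σ_{t=1..T} ρ^{T−t} Δ(z_{t−1}, a_t).

    `latents` holds the pre-administration states z_0..z_{T−1} (one row per
    administration), `treatments` the administered ids a_1..a_T.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError("rho must lie in (0, 1]")
    z = as_tensor(latents)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    T = z.shape[0]
    if len(treatments) != T:
        raise ValueError("need one treatment per latent state")
    total = None
    for t in range(1, T + 1):
        term = latent_shift(z[t - 1], treatments[t - 1], params) * (rho ** (T - t))
        total = term if total is None else total + term
    return total


def corridor_loss(gamma, safe_region: SafeRegion) -> Tensor:
    """Squared distance of Γ to the safe region; 0 inside.

    Differentiable closed forms: for a box, Σ relu(Γ−upper)² + relu(lower−Γ)²;
    for a ball, relu(‖Γ−c‖ − r)².
    """
    g = as_tensor(gamma)
    if safe_region.kind == "box":
        over = relu(g - safe_region.upper)
        under = relu(as_tensor(safe_region.lower) - g)
        return (over * over).sum() + (under * under).sum()
    d = g - safe_region.center
    nrm = sqrt((d * d).sum() + 1e-300)
    excess = relu(nrm - safe_region.radius)
    return excess * excess


def drift_loss(latents, treatments, params: ModelParams) -> Tensor:
    """Σ_{t≥2} ‖Δ(z_{t−1}, a_t) − Δ(z_{t−2}, a_{t−1})‖²; 0 for T < 2."""
    z = as_tensor(latents)
    if z.ndim == 1:
        z = z.reshape(1, -1)
    T = z.shape[0]
    if len(treatments) != T:
        raise ValueError("need one treatment per latent state")
    if T < 2:
        return as_tensor(0.0)
    total = as_tensor(0.0)
    prev = latent_shift(z[0], treatments[0], params)
    for t in range(1, T):
        cur = latent_shift(z[t], treatments[t], params)
        d = cur - prev
        total = total + (d * d).sum()
        prev = cur
    return total


def anchor_kl(posterior: PosteriorState | tuple, prior_mean, prior_var) -> Tensor:
    """Σ_t KL(q_t ‖ π_t) for diagonal Gaussians, in closed form.

    `prior_mean`/`prior_var` are either (d_z,) applied at every timestep or
    (T, d_z) per-timestep.  Non-positive prior variances are rejected.
    """
    if isinstance(posterior, PosteriorState):
        mu_q, var_q = posterior.mean, posterior.var
    else:
        mu_q, var_q = posterior
    mu_q, var_q = as_tensor(mu_q), as_tensor(var_q)
    if mu_q.ndim == 1:
        mu_q, var_q = mu_q.reshape(1, -1), var_q.reshape(1, -1)
    pm = np.atleast_1d(np.asarray(prior_mean, dtype=np.float64))
    pv = np.atleast_1d(np.asarray(prior_var, dtype=np.float64))
    if np.any(pv <= 0):
        raise ValueError("anchor prior variances must be strictly positive")
    if pm.ndim == 1:
        pm = np.broadcast_to(pm, mu_q.shape)
        pv = np.broadcast_to(pv, var_q.shape)
    d = mu_q - pm
    return 0.5 * (
        (np.log(pv) - log(var_q)) + (var_q + d * d) / pv - 1.0
    ).sum()


def stage_penalty(y_hat_path, stage: str, priors: ClinicalPriors) -> Tensor:
    """Σ_t ‖ŷ_t − μ_stage(t)‖² against the stage's expected outcome curve."""
    if stage not in priors.stage_curves:
        raise KeyError(f"no stage curve for stage {stage!r}")
    y_hat = as_tensor(y_hat_path)
    if y_hat.ndim == 1:
        y_hat = y_hat.reshape(1, -1)
    curve = priors.stage_curves[stage]
    T = y_hat.shape[0]
    if curve.shape[0] < T:
        raise ValueError(
            f"stage curve for {stage!r} has length {curve.shape[0]} < trajectory length {T}"
        )
    d = y_hat - curve[:T]
    return (d * d).sum()
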