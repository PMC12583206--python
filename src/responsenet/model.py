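"""Generative and inference core of the latent treatment-response model.

The model is a sequential variational autoencoder over per-patient latent
health states z_t:

* a gated-recurrent (GRU) posterior encoder maps the observed history
  H_t = {(x_s, a_s, y_s, m_s)}_{s<=t} to a diagonal Gaussian q(z_t | H_t)
  (masked outcome entries are zero-imputed and the mask appended, so the
  posterior depends on observed history only);
* a latent transition z_{t+1} = f_θ(z_t, e(a_t)) + ε, ε ~ N(0, σ²I), where
  f_θ is an affine map plus a residual multilayer perceptron on [z; e(a)]
  — the affine part lets the model represent linear-Gaussian dynamics
  exactly, which the Kalman-filter validation exploits;
* a second-order refinement z_{t+1} = z_t + γ(f_θ(z_t, e(a_t)) −
  f_θ(z_{t−1}, e(a_{t−1}))) capturing latent inertia, used as the
  deterministic mean path (and optionally as the transition mean in the
  ELBO);
* heteroscedastic decoders: outcome mean W_y·act(z) + b_y with a softplus
  variance head (floor 1e-4), covariate decoder W_x·act_x(z) + b_x with a
  learnable scalar noise variance;
* a masked Gaussian outcome likelihood so censored entries never enter the
  objective.

The evidence lower bound is estimated by reparameterized Monte Carlo with a
factorized causal posterior; it includes the initial-state prior term and
transition terms for t >= 2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, as_tensor, concat, sigmoid, softplus, tanh, relu
from .cohort import Cohort, Trajectory, TreatmentOntology
from .semantics import EmbeddingTables

__all__ = [
    "ModelConfig",
    "ModelParams",
    "PosteriorState",
    "encode_posterior",
    "transition_mean",
    "transition_second_order",
    "decode",
    "masked_log_likelihood",
    "elbo",
    "temporal_regularizer",
    "smoothness_regularizer",
    "save_checkpoint",
    "load_checkpoint",
    "pad_cohort",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-4
_SIGMA_FLOOR = 1e-6


@dataclass
class ModelConfig:
    """Dimensions and structural switches of the model."""

    d_x: int
    k: int
    d_z: int = 4
    m: int | None = None              # embedding dim; defaults to d_z
    enc_hidden: int = 32
    trans_hidden: int = 32
    disc_hidden: int = 16
    decoder_activation: str = "relu"      # "relu" | "identity"
    covariate_activation: str = "tanh"    # "tanh" | "identity"
    attention_gating: bool = False
    transition_mode: str = "first_order"  # "first_order" | "second_order"
    disc_use_outcome: bool = False        # append decoded next outcome to D_psi input

    def __post_init__(self) -> None:
        if self.m is None:
            self.m = self.d_z
        if self.decoder_activation not in ("relu", "identity"):
            raise ValueError("decoder_activation must be 'relu' or 'identity'")
        if self.covariate_activation not in ("tanh", "identity"):
            raise ValueError("covariate_activation must be 'tanh' or 'identity'")
        if self.transition_mode not in ("first_order", "second_order"):
            raise ValueError("transition_mode must be 'first_order' or 'second_order'")


@dataclass
class PosteriorState:
    """Per-timestep diagonal-Gaussian posterior (μ_t, diag Σ_t)."""

    mean: np.ndarray  # (T, d_z)
    var: np.ndarray   # (T, d_z), strictly positive

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.var = np.atleast_2d(np.asarray(self.var, dtype=np.float64))
        if self.mean.shape != self.var.shape:
            raise ValueError("posterior mean and var shapes differ")
        if np.any(self.var <= 0):
            raise ValueError("posterior variances must be strictly positive")

    @property
    def T(self) -> int:
        return self.mean.shape[0]


class ModelParams:
    """All learnable parameters plus the treatment vocabulary bookkeeping.

    Parameters are float64 autodiff tensors in `self.t`; discriminator
    parameters are the keys with prefix ``disc_``.
    """

    def __init__(self, config: ModelConfig, ontology: TreatmentOntology, seed: int = 0):
        self.config = config
        self.classes = ontology.classes
        self.vocab = ontology.sorted_vocabulary()
        self.class_of = dict(ontology.class_of)
        self._vocab_row = {a: i for i, a in enumerate(self.vocab)}
        self._class_row = {c: i for i, c in enumerate(self.classes)}
        # class row of each vocabulary row
        self.class_idx = np.array([self._class_row[self.class_of[a]] for a in self.vocab])

        rng = np.random.default_rng([seed, 7])
        c = config
        d_in = c.d_x + c.m + 2 * c.k  # x, e(a), masked y, mask
        h, dz, m = c.enc_hidden, c.d_z, c.m

        def W(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
            return Tensor(scale * rng.normal(size=shape), requires_grad=True)

        def zeros(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        self.t: dict[str, Tensor] = {}
        t = self.t
        # GRU encoder (reset r, update u, candidate n)
        for gate in ("r", "u", "n"):
            t[f"enc_Wi{gate}"] = W(h, d_in)
            t[f"enc_Wh{gate}"] = W(h, h)
            t[f"enc_b{gate}"] = zeros(h)
        t["enc_Wmu"] = W(dz, h)
        t["enc_bmu"] = zeros(dz)
        t["enc_Wvar"] = W(dz, h, scale=0.01)
        t["enc_bvar"] = zeros(dz)
        # transition: affine + residual MLP on [z; e]
        t["trans_Wz"] = Tensor(np.eye(dz), requires_grad=True)
        t["trans_We"] = W(dz, m, scale=0.1)
        t["trans_b"] = zeros(dz)
        t["trans_W1"] = W(c.trans_hidden, dz + m)
        t["trans_b1"] = zeros(c.trans_hidden)
        t["trans_W2"] = W(dz, c.trans_hidden, scale=0.01)
        t["trans_b2"] = zeros(dz)
        t["gamma"] = Tensor(np.asarray(0.5), requires_grad=True)
        t["raw_sigma"] = Tensor(np.asarray(0.0), requires_grad=True)       # softplus -> sigma
        t["raw_sigma_x"] = Tensor(np.asarray(0.0), requires_grad=True)     # softplus -> sigma_x
        # initial-state prior
        t["prior_mu0"] = zeros(dz)
        t["prior_rawvar0"] = Tensor(np.zeros(dz), requires_grad=True)      # softplus -> var0
        # decoders
        t["dec_Wy"] = W(c.k, dz)
        t["dec_by"] = zeros(c.k)
        t["dec_Wyvar"] = W(c.k, dz, scale=0.01)
        t["dec_byvar"] = zeros(c.k)
        t["dec_Wx"] = W(c.d_x, dz)
        t["dec_bx"] = zeros(c.d_x)
        # embeddings
        t["emb_sym"] = W(len(self.classes), m, scale=0.1)
        t["emb_spec"] = W(len(self.vocab), m, scale=0.1)
        # attention projection latent -> embedding space
        proj = np.eye(m, dz) if m == dz else 0.1 * rng.normal(size=(m, dz))
        t["att_proj"] = Tensor(proj, requires_grad=True)
        # discriminator (optionally also sees the decoded next outcome)
        d_disc = dz + m + (c.k if c.disc_use_outcome else 0)
        t["disc_W1"] = W(c.disc_hidden, d_disc)
        t["disc_b1"] = zeros(c.disc_hidden)
        t["disc_W2"] = W(1, c.disc_hidden, scale=0.01)
        t["disc_b2"] = zeros(1)

    # -- bookkeeping ---------------------------------------------------
    def vocab_index(self, a: str) -> int:
        try:
            return self._vocab_row[a]
        except KeyError:
            raise KeyError(f"unknown treatment id {a!r}") from None

    def treatment_indices(self, treatments) -> np.ndarray:
        return np.array([self.vocab_index(a) for a in treatments])

    def generator_keys(self) -> list[str]:
        return [k for k in self.t if not k.startswith("disc_")]

    def discriminator_keys(self) -> list[str]:
        return [k for k in self.t if k.startswith("disc_")]

    def zero_grad(self) -> None:
        for v in self.t.values():
            v.grad = None

    # -- derived quantities --------------------------------------------
    def sigma(self) -> Tensor:
        return softplus(self.t["raw_sigma"]) + _SIGMA_FLOOR

    def sigma_x(self) -> Tensor:
        return softplus(self.t["raw_sigma_x"]) + _SIGMA_FLOOR

    def prior_var0(self) -> Tensor:
        return softplus(self.t["prior_rawvar0"]) + _VAR_FLOOR

    def embedding_tables(self, margin: float = 0.1) -> EmbeddingTables:
        return EmbeddingTables(
            classes=list(self.classes),
            vocab=list(self.vocab),
            E_sym=self.t["emb_sym"],
            E_spec=self.t["emb_spec"],
            margin=margin,
        )

    def embed_indices(self, idx: np.ndarray) -> Tensor:
        """Rows e(a) = E_sym[α(a)] + E_spec[a] for integer vocabulary rows."""
        idx = np.asarray(idx)
        return self.t["emb_sym"][self.class_idx[idx]] + self.t["emb_spec"][idx]

    def embed(self, a: str) -> Tensor:
        return self.embed_indices(np.array([self.vocab_index(a)]))[0]

    def copy(self) -> "ModelParams":
        import copy as _copy
        dup = _copy.copy(self)
        dup.t = {k: Tensor(v.data.copy(), requires_grad=v.requires_grad) for k, v in self.t.items()}
        return dup

    # -- network pieces (tensor-level, batched) ------------------------
    def f_theta(self, z: Tensor, e: Tensor) -> Tensor:
        """Transition mean f_θ(z, e): affine part + residual MLP on [z; e]."""
        z, e = as_tensor(z), as_tensor(e)
        pre = concat([z, e], axis=-1)
        hid = tanh(pre @ self.t["trans_W1"].T + self.t["trans_b1"])
        return (
            z @ self.t["trans_Wz"].T
            + e @ self.t["trans_We"].T
            + self.t["trans_b"]
            + hid @ self.t["trans_W2"].T
            + self.t["trans_b2"]
        )

    def decode_t(self, z: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        z = as_tensor(z)
        act_y = relu(z) if self.config.decoder_activation == "relu" else z
        act_x = tanh(z) if self.config.covariate_activation == "tanh" else z
        y_mean = act_y @ self.t["dec_Wy"].T + self.t["dec_by"]
        y_var = softplus(z @ self.t["dec_Wyvar"].T + self.t["dec_byvar"]) + _VAR_FLOOR
        x_hat = act_x @ self.t["dec_Wx"].T + self.t["dec_bx"]
        return y_mean, y_var, x_hat

    def gated_embed_indices(self, idx: np.ndarray, z: Tensor) -> Tensor:
        """Treatment embedding optionally scaled by its class-attention weight.

        The attention over class prototypes is computed from the current
        latent state; the weight of the administered treatment's own class
        multiplies its embedding (a modulation switchable via config).
        """
        e = self.embed_indices(idx)
        if not self.config.attention_gating:
            return e
        zp = z @ self.t["att_proj"].T
        scores = zp @ self.t["emb_sym"].T              # (..., n_classes)
        att = ad.softmax(scores, axis=-1)
        idx = np.asarray(idx)
        gate = att[np.arange(att.shape[0]), self.class_idx[idx]] if att.ndim == 2 else att[self.class_idx[idx]]
        return e * gate.reshape(e.shape[:-1] + (1,))


# ---------------------------------------------------------------------------
# encoder
def _encode_batch(
    params: ModelParams,
    X: np.ndarray,        # (B, T, d_x)
    Aidx: np.ndarray,     # (B, T) int vocabulary rows
    Y: np.ndarray,        # (B, T, k)
    M: np.ndarray,        # (B, T, k) binary
) -> tuple[Tensor, Tensor]:
    """Causal GRU posterior over a padded batch: (mu, var), each (B, T, d_z)."""
    B, T, _ = X.shape
    c = params.config
    t = params.t
    h = Tensor(np.zeros((B, c.enc_hidden)))
    mus, vars_ = [], []
    for step in range(T):
        e = params.embed_indices(Aidx[:, step])
        inp = concat(
            [as_tensor(X[:, step]), e, as_tensor(Y[:, step] * M[:, step]), as_tensor(M[:, step])],
            axis=-1,
        )
        r = sigmoid(inp @ t["enc_Wir"].T + h @ t["enc_Whr"].T + t["enc_br"])
        u = sigmoid(inp @ t["enc_Wiu"].T + h @ t["enc_Whu"].T + t["enc_bu"])
        n = tanh(inp @ t["enc_Win"].T + (r * h) @ t["enc_Whn"].T + t["enc_bn"])
        h = (1.0 - u) * n + u * h
        mus.append(h @ t["enc_Wmu"].T + t["enc_bmu"])
        vars_.append(softplus(h @ t["enc_Wvar"].T + t["enc_bvar"]))
    return ad.stack(mus, axis=1), ad.stack(vars_, axis=1)


def encode_posterior(trajectory: Trajectory, params: ModelParams) -> PosteriorState:
    """Amortized causal posterior q(z_t | H_t) for one trajectory."""
    if trajectory.T < 1:
        raise ValueError("empty trajectory")
    idx = params.treatment_indices(trajectory.treatments)
    mu, var = _encode_batch(
        params,
        trajectory.covariates[None],
        idx[None],
        trajectory.outcomes[None],
        trajectory.outcome_mask[None],
    )
    return PosteriorState(mean=mu.data[0], var=var.data[0])


# ---------------------------------------------------------------------------
# transitions and decoding (public single-vector wrappers)
def transition_mean(z: np.ndarray, a: str, params: ModelParams) -> np.ndarray:
    """f_θ(z, e(a)); the stochastic update adds N(0, σ²I) on top."""
    e = params.embed(a)
    return params.f_theta(as_tensor(np.asarray(z, dtype=np.float64)), e).data


def transition_second_order(
    z_t: np.ndarray,
    z_tm1: np.ndarray,
    a_t: str,
    a_tm1: str,
    params: ModelParams,
) -> np.ndarray:
    """z_t + γ·(f_θ(z_t, e(a_t)) − f_θ(z_{t−1}, e(a_{t−1})))."""
    z_t = np.asarray(z_t, dtype=np.float64)
    f_now = params.f_theta(as_tensor(z_t), params.embed(a_t))
    f_prev = params.f_theta(as_tensor(np.asarray(z_tm1, dtype=np.float64)), params.embed(a_tm1))
    return (as_tensor(z_t) + params.t["gamma"] * (f_now - f_prev)).data


def decode(z: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y_mean, y_var, x_hat) for a latent vector or batch of latents."""
    y_mean, y_var, x_hat = params.decode_t(as_tensor(np.asarray(z, dtype=np.float64)))
    return y_mean.data, y_var.data, x_hat.data


# ---------------------------------------------------------------------------
def gaussian_logpdf(x, mean, var) -> Tensor:
    """Elementwise log N(x; mean, var) on tensors or arrays."""
    x, mean, var = as_tensor(x), as_tensor(mean), as_tensor(var)
    d = x - mean
    return -0.5 * (_LOG2PI + ad.log(var) + d * d / var)


def masked_log_likelihood(y, m, y_mean, y_var) -> Tensor:
    """Σ_j m_j log N(y_j; μ_j, σ_j²): censored entries contribute zero."""
    m_arr = np.asarray(m.data if isinstance(m, Tensor) else m, dtype=np.float64)
    return (gaussian_logpdf(y, y_mean, y_var) * m_arr).sum()


# ---------------------------------------------------------------------------
def _elbo_batch(
    params: ModelParams,
    X: np.ndarray,
    Aidx: np.ndarray,
    Y: np.ndarray,
    M: np.ndarray,
    valid: np.ndarray,          # (B, T) 1 for real timesteps, 0 for padding
    eps: np.ndarray,            # (S, B, T, d_z) standard normal
    transition_mode: str | None = None,
) -> tuple[Tensor, Tensor, Tensor]:
    """Monte-Carlo ELBO, summed over time, averaged over samples and patients.

    Returns (elbo_per_patient_mean, mu_q, var_q); the posterior moments are
    reused by downstream knowledge-infusion losses.
    """
    mode = transition_mode or params.config.transition_mode
    B, T, _ = X.shape
    S = eps.shape[0]
    mu_q, var_q = _encode_batch(params, X, Aidx, Y, M)
    v3 = valid[..., None]                         # (B, T, 1)
    sigma2 = params.sigma() ** 2.0
    var0 = params.prior_var0()
    mu0 = params.t["prior_mu0"]
    total = as_tensor(0.0)
    per_sample: list[Tensor] = []
    for s in range(S):
        z = mu_q + ad.sqrt(var_q) * eps[s]        # (B, T, d_z) reparameterized
        zf = z.reshape(B * T, -1)
        y_mean, y_var, x_hat = params.decode_t(zf)
        y_mean = y_mean.reshape(B, T, -1)
        y_var = y_var.reshape(B, T, -1)
        x_hat = x_hat.reshape(B, T, -1)
        # reconstruction
        ll_x = (gaussian_logpdf(X, x_hat, params.sigma_x() ** 2.0) * v3).sum()
        ll_y = (gaussian_logpdf(Y, y_mean, y_var) * (M * v3)).sum()
        # initial-state prior
        lp0 = (gaussian_logpdf(z[:, 0], mu0, var0)).sum()
        # transitions t >= 2
        z_prev = z[:, :-1].reshape(B * (T - 1), -1) if T > 1 else None
        if T > 1:
            e_prev = params.gated_embed_indices(Aidx[:, :-1].reshape(-1), z_prev)
            f_prev = params.f_theta(z_prev, e_prev).reshape(B, T - 1, -1)
            if mode == "second_order":
                # mean_t = z_{t-1} + γ(f(z_{t-1},a_{t-1}) - f(z_{t-2},a_{t-2})); first-order at t=2
                mean_tr_first = f_prev[:, 0:1]
                if T > 2:
                    diff = f_prev[:, 1:] - f_prev[:, :-1]
                    mean_tr_rest = z[:, 1:-1] + params.t["gamma"] * diff
                    mean_tr = concat([mean_tr_first, mean_tr_rest], axis=1)
                else:
                    mean_tr = mean_tr_first
            else:
                mean_tr = f_prev
            ll_tr = (gaussian_logpdf(z[:, 1:], mean_tr, sigma2) * v3[:, 1:]).sum()
        else:
            ll_tr = as_tensor(0.0)
        # entropy term: -log q at the sampled z
        ll_q = (gaussian_logpdf(z, mu_q, var_q) * v3).sum()
        per_sample.append((ll_x + ll_y + lp0 + ll_tr - ll_q) * (1.0 / B))
        total = total + per_sample[-1]
    return total * (1.0 / S), mu_q, var_q, [p.item() for p in per_sample]


def elbo(
    trajectory: Trajectory,
    params: ModelParams,
    n_samples: int = 1,
    seed: int = 0,
    transition_mode: str | None = None,
    return_samples: bool = False,
):
    """Reparameterized Monte-Carlo estimate of the evidence lower bound.

    Deterministic given `seed`.  With `return_samples=True` also returns the
    per-sample ELBO values (for Monte-Carlo standard errors).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    idx = params.treatment_indices(trajectory.treatments)
    rng = np.random.default_rng(seed)
    X = trajectory.covariates[None]
    A = idx[None]
    Y = trajectory.outcomes[None]
    M = trajectory.outcome_mask[None]
    valid = np.ones((1, trajectory.T))
    eps = rng.normal(size=(n_samples, 1, trajectory.T, params.config.d_z))
    est_t, _, _, per_sample = _elbo_batch(params, X, A, Y, M, valid, eps, transition_mode)
    est = est_t.item()
    if return_samples:
        return est, np.asarray(per_sample)
    return est


# ---------------------------------------------------------------------------
def temporal_regularizer(z_path) -> Tensor:
    """Σ_{t≥2} ||z_t − z_{t−1}||²: penalizes abrupt latent evolution."""
    z = as_tensor(z_path)
    if z.shape[0] < 2:
        return as_tensor(0.0)
    d = z[1:] - z[:-1]
    return (d * d).sum()


def smoothness_regularizer(x_hat_path) -> Tensor:
    """Same squared-difference penalty applied to decoded covariates."""
    return temporal_regularizer(x_hat_path)


# ---------------------------------------------------------------------------
# batching helper
def pad_cohort(cohort: Cohort, params: ModelParams):
    """Pad trajectories to the cohort's maximum length.

    Returns (X, Aidx, Y, M, valid) with shapes (n, Tmax, ·); padded steps
    carry zeros, treatment row 0 and valid = 0, and are excluded from every
    objective term by the validity mask.
    """
    n = len(cohort)
    Tmax = max(tr.T for tr in cohort)
    X = np.zeros((n, Tmax, cohort.d_x))
    Y = np.zeros((n, Tmax, cohort.k))
    M = np.zeros((n, Tmax, cohort.k))
    A = np.zeros((n, Tmax), dtype=int)
    valid = np.zeros((n, Tmax))
    for i, tr in enumerate(cohort):
        T = tr.T
        X[i, :T] = tr.covariates
        Y[i, :T] = tr.outcomes
        M[i, :T] = tr.outcome_mask
        A[i, :T] = params.treatment_indices(tr.treatments)
        valid[i, :T] = 1.0
    return X, A, Y, M, valid


# ---------------------------------------------------------------------------
# checkpoints
def save_checkpoint(params: ModelParams, path: str | Path, extra: dict | None = None) -> None:
    """Serialize all parameter arrays (.npz) with a JSON sidecar of metadata."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **{k: v.data for k, v in params.t.items()})
    sidecar = {
        "config": asdict(params.config),
        "classes": params.classes,
        "vocab": params.vocab,
        "class_of": params.class_of,
        "numpy_version": np.__version__,
    }
    if extra:
        sidecar["extra"] = extra
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> ModelParams:
    """Load a checkpoint; refuses dimension mismatches between arrays and sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar["config"])
    ontology = TreatmentOntology(class_of=sidecar["class_of"])
    params = ModelParams(config, ontology, seed=0)
    with np.load(path.with_suffix(".npz")) as arrs:
        for k, v in params.t.items():
            if k not in arrs:
                raise ValueError(f"checkpoint missing parameter {k!r}")
            if arrs[k].shape != v.data.shape:
                raise ValueError(
                    f"checkpoint dimension mismatch for {k!r}: "
                    f"{arrs[k].shape} vs expected {v.data.shape}"
                )
            v.data = arrs[k].astype(np.float64)
    return params
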