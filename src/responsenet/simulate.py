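"""Synthetic-cohort simulator with known ground truth.

The generator instantiates the partially observed Markov decision process
that the model assumes: a latent health state evolving linearly under
class-structured treatment effects, linear-Gaussian emissions for covariates
and outcomes, missing-completely-at-random outcome masks, and a treatment
policy that is optionally confounded by the current latent state through a
multinomial logit.

A linear-Gaussian ground truth (rather than a neural simulator) is a
deliberate design choice: evidence is computable exactly by a Kalman
filter, counterfactual twins are exact under common random numbers, and
treatment-effect recovery can be scored against known vectors.

Counterfactual twins: each patient's exogenous noise (latent innovations,
emission noise, assignment and masking uniforms) is pre-drawn from a
per-patient stream, so a factual trajectory and its intervened twin share
every random draw and differ only through the intervention's downstream
influence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort import Cohort, Trajectory, TreatmentOntology

__all__ = [
    "SimConfig",
    "SimulationGroundTruth",
    "make_ground_truth",
    "make_ontology",
    "simulate_cohort",
    "simulate_counterfactual_pair",
    "kalman_log_evidence",
]


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a moderately sized oncology-like cohort: 300 patients
    followed for 12 visits, a 4-dimensional latent state, 6 covariates, 2
    outcome channels, 3 therapeutic classes of 3 treatments each, small
    within-class heterogeneity, randomized assignment and 20% outcome
    missingness.
    """

    n_patients: int = 300
    T: int = 12
    d_z: int = 4
    d_x: int = 6
    k: int = 2
    n_classes: int = 3
    treatments_per_class: int = 3
    within_class_spread: float = 0.1
    confounding_strength: float = 0.0
    seed: int = 0
    # ground-truth scales
    effect_scale: float = 1.0
    transition_radius: float = 0.7
    sigma_z: float = 0.1
    sigma_x: float = 0.1
    sigma_y: float = 0.1
    miss_rate: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_patients", "T", "d_z", "d_x", "k", "n_classes", "treatments_per_class"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.within_class_spread < 0:
            raise ValueError("within_class_spread must be >= 0")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must lie in [0, 1)")
        if min(self.sigma_z, self.sigma_x, self.sigma_y) <= 0:
            raise ValueError("noise scales must be > 0")


@dataclass
class SimulationGroundTruth:
    """The simulator's true dynamics, effects and policy."""

    A: np.ndarray                      # (d_z, d_z), spectral radius < 1
    class_effects: dict[str, np.ndarray]
    specific_offsets: dict[str, np.ndarray]
    class_of: dict[str, str]
    C: np.ndarray                      # (d_x, d_z) covariate emission
    D: np.ndarray                      # (k, d_z) outcome emission
    sigma_z: float
    sigma_x: float
    sigma_y: float
    mu0: np.ndarray
    sigma0: np.ndarray                 # diagonal of initial covariance
    policy_weights: dict[str, np.ndarray]
    confounding_strength: float
    miss_rate: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if np.max(np.abs(np.linalg.eigvals(self.A))) >= 1.0:
            raise ValueError("transition matrix must have spectral radius < 1")

    @property
    def vocabulary(self) -> list[str]:
        return sorted(self.class_of)

    def effect(self, a: str) -> np.ndarray:
        """Total latent shift of treatment `a`: class effect + specific offset."""
        return self.class_effects[self.class_of[a]] + self.specific_offsets[a]

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        def arr(x):
            return np.asarray(x).tolist()
        return {
            "A": arr(self.A),
            "class_effects": {c: arr(v) for c, v in self.class_effects.items()},
            "specific_offsets": {a: arr(v) for a, v in self.specific_offsets.items()},
            "class_of": dict(self.class_of),
            "C": arr(self.C), "D": arr(self.D),
            "sigma_z": self.sigma_z, "sigma_x": self.sigma_x, "sigma_y": self.sigma_y,
            "mu0": arr(self.mu0), "sigma0": arr(self.sigma0),
            "policy_weights": {a: arr(v) for a, v in self.policy_weights.items()},
            "confounding_strength": self.confounding_strength,
            "miss_rate": self.miss_rate,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "SimulationGroundTruth":
        return cls(
            A=np.asarray(obj["A"]),
            class_effects={c: np.asarray(v) for c, v in obj["class_effects"].items()},
            specific_offsets={a: np.asarray(v) for a, v in obj["specific_offsets"].items()},
            class_of=dict(obj["class_of"]),
            C=np.asarray(obj["C"]), D=np.asarray(obj["D"]),
            sigma_z=float(obj["sigma_z"]), sigma_x=float(obj["sigma_x"]),
            sigma_y=float(obj["sigma_y"]),
            mu0=np.asarray(obj["mu0"]), sigma0=np.asarray(obj["sigma0"]),
            policy_weights={a: np.asarray(v) for a, v in obj["policy_weights"].items()},
            confounding_strength=float(obj["confounding_strength"]),
            miss_rate=float(obj["miss_rate"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationGroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
def _well_separated_directions(rng: np.random.Generator, n: int, d: int,
                               max_cos: float = 0.6) -> np.ndarray:
    """Unit vectors with pairwise |cosine| bounded away from 1."""
    if n == 1:
        v = rng.normal(size=d)
        return (v / np.linalg.norm(v))[None, :]
    for _ in range(1000):
        vs = rng.normal(size=(n, d))
        vs /= np.linalg.norm(vs, axis=1, keepdims=True)
        cos = vs @ vs.T
        if np.max(np.abs(cos[~np.eye(n, dtype=bool)])) < max_cos:
            return vs
    raise ValueError(f"cannot place {n} well-separated directions in {d} dimensions")


def make_ground_truth(config: SimConfig) -> SimulationGroundTruth:
    """Draw a ground-truth instance; deterministic given ``config.seed``."""
    rng = np.random.default_rng([config.seed, 101])
    d_z = config.d_z
    if config.n_classes > 1 and d_z < 2:
        raise ValueError("d_z must be >= 2 to separate multiple classes")

    # stable transition: scaled random orthogonal matrix
    M = rng.normal(size=(d_z, d_z))
    Q, _ = np.linalg.qr(M)
    A = config.transition_radius * Q

    dirs = _well_separated_directions(rng, config.n_classes, d_z)
    class_labels = [f"class{c}" for c in range(config.n_classes)]
    class_effects = {lab: config.effect_scale * dirs[i] for i, lab in enumerate(class_labels)}
    mean_norm = float(np.mean([np.linalg.norm(v) for v in class_effects.values()]))

    class_of: dict[str, str] = {}
    specific_offsets: dict[str, np.ndarray] = {}
    policy_weights: dict[str, np.ndarray] = {}
    for c, lab in enumerate(class_labels):
        for j in range(config.treatments_per_class):
            a = f"drug{c}_{j}"
            class_of[a] = lab
            off = rng.normal(size=d_z)
            norm = np.linalg.norm(off)
            target = config.within_class_spread * mean_norm
            specific_offsets[a] = off / norm * target if norm > 0 else off
            w = rng.normal(size=d_z)
            policy_weights[a] = w / np.linalg.norm(w)

    C = rng.normal(size=(config.d_x, d_z)) / np.sqrt(d_z)
    D = rng.normal(size=(config.k, d_z)) / np.sqrt(d_z)

    return SimulationGroundTruth(
        A=A,
        class_effects=class_effects,
        specific_offsets=specific_offsets,
        class_of=class_of,
        C=C,
        D=D,
        sigma_z=config.sigma_z,
        sigma_x=config.sigma_x,
        sigma_y=config.sigma_y,
        mu0=np.zeros(d_z),
        sigma0=np.ones(d_z),
        policy_weights=policy_weights,
        confounding_strength=config.confounding_strength,
        miss_rate=config.miss_rate,
    )


def make_ontology(truth: SimulationGroundTruth) -> TreatmentOntology:
    """Ontology implied by the ground truth: classes plus intra-class edges."""
    edges = []
    classes = sorted(set(truth.class_of.values()))
    for c in classes:
        members = sorted(a for a, cc in truth.class_of.items() if cc == c)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.append((members[i], members[j]))
    return TreatmentOntology(class_of=truth.class_of, similarity_edges=edges)


# ---------------------------------------------------------------------------
@dataclass
class _NoiseBlock:
    """Pre-drawn exogenous randomness for one patient (common random numbers)."""

    z0: np.ndarray          # (d_z,) standard normal
    eps_z: np.ndarray       # (T, d_z)
    eps_x: np.ndarray       # (T, d_x)
    eps_y: np.ndarray       # (T, k)
    u_assign: np.ndarray    # (T,)   uniforms for policy draws
    u_miss: np.ndarray      # (T, k) uniforms for masking


def _draw_noise(truth: SimulationGroundTruth, T: int, rng: np.random.Generator) -> _NoiseBlock:
    d_z = truth.A.shape[0]
    d_x = truth.C.shape[0]
    k = truth.D.shape[0]
    return _NoiseBlock(
        z0=rng.normal(size=d_z),
        eps_z=rng.normal(size=(T, d_z)),
        eps_x=rng.normal(size=(T, d_x)),
        eps_y=rng.normal(size=(T, k)),
        u_assign=rng.uniform(size=T),
        u_miss=rng.uniform(size=(T, k)),
    )


def _policy_draw(truth: SimulationGroundTruth, z: np.ndarray, u: float) -> str:
    """Inverse-CDF multinomial-logit draw; common `u` gives common assignment."""
    vocab = truth.vocabulary
    logits = np.array(
        [truth.confounding_strength * float(truth.policy_weights[a] @ z) for a in vocab]
    )
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    cdf = np.cumsum(p)
    return vocab[int(np.searchsorted(cdf, u, side="right").clip(0, len(vocab) - 1))]


def _roll_trajectory(
    truth: SimulationGroundTruth,
    noise: _NoiseBlock,
    T: int,
    patient_id: str,
    intervention: tuple[int, str] | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Deterministic rollout given a noise block; optional (s, a_tilde) override.

    The intervention time ``s`` is one-based; the treatment at visit s is
    replaced by ``a_tilde`` and everything downstream propagates through the
    dynamics with the same noise.
    """
    z = truth.mu0 + np.sqrt(truth.sigma0) * noise.z0
    lat = np.empty((T, len(z)))
    xs = np.empty((T, truth.C.shape[0]))
    ys = np.empty((T, truth.D.shape[0]))
    ms = np.empty((T, truth.D.shape[0]))
    acts: list[str] = []
    for t in range(T):
        lat[t] = z
        xs[t] = truth.C @ z + truth.sigma_x * noise.eps_x[t]
        ys[t] = truth.D @ z + truth.sigma_y * noise.eps_y[t]
        ms[t] = (noise.u_miss[t] >= truth.miss_rate).astype(np.float64)
        a = _policy_draw(truth, z, noise.u_assign[t])
        if intervention is not None and t == intervention[0] - 1:
            a = intervention[1]
        acts.append(a)
        if t < T - 1:
            z = truth.A @ z + truth.effect(a) + truth.sigma_z * noise.eps_z[t]
    traj = Trajectory(patient_id=patient_id, covariates=xs, treatments=acts,
                      outcomes=ys, outcome_mask=ms)
    return traj, lat


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, 202, index])


def simulate_cohort(
    truth: SimulationGroundTruth,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[Cohort, np.ndarray]:
    """Simulate a cohort; returns (cohort, latent paths (n, T, d_z)).

    Pure function of (truth, config, seed); `seed` defaults to
    ``config.seed``.  Latent paths are ground truth for evaluation only.
    """
    seed = config.seed if seed is None else seed
    trajectories = []
    latents = np.empty((config.n_patients, config.T, config.d_z))
    for i in range(config.n_patients):
        noise = _draw_noise(truth, config.T, _patient_rng(seed, i))
        traj, lat = _roll_trajectory(truth, noise, config.T, patient_id=f"p{i:04d}")
        trajectories.append(traj)
        latents[i] = lat
    cohort = Cohort(trajectories, d_x=config.d_x, k=config.k,
                    metadata={"seed": seed, "simulated": True})
    return cohort, latents


def simulate_counterfactual_pair(
    truth: SimulationGroundTruth,
    config: SimConfig,
    intervention: tuple[int, int, str],
    seed: int | None = None,
) -> tuple[Trajectory, Trajectory]:
    """Factual trajectory and its intervened twin under common random numbers.

    ``intervention = (patient_index, s, a_tilde)`` replaces the treatment at
    one-based visit ``s`` with ``a_tilde``.  The twins share all noise draws
    and are identical before the intervention takes effect.
    """
    i, s, a_alt = intervention
    if not (1 <= s <= config.T):
        raise ValueError(f"intervention time {s} outside horizon 1..{config.T}")
    if a_alt not in truth.class_of:
        raise KeyError(f"unknown treatment id {a_alt!r}")
    seed = config.seed if seed is None else seed
    noise = _draw_noise(truth, config.T, _patient_rng(seed, i))
    factual, _ = _roll_trajectory(truth, noise, config.T, patient_id=f"p{i:04d}")
    counterfactual, _ = _roll_trajectory(
        truth, noise, config.T, patient_id=f"p{i:04d}_cf", intervention=(s, a_alt)
    )
    return factual, counterfactual


# ---------------------------------------------------------------------------
def kalman_log_evidence(truth: SimulationGroundTruth, trajectory: Trajectory) -> float:
    """Exact log-evidence of the observed data under the linear-Gaussian truth.

    Computes log p(x_{1:T}, y^obs_{1:T} | a_{1:T}) by a forward Kalman filter
    with the treatment sequence as a known control input, including only
    masked-in outcome entries in the observation at each step.  Valid as a
    marginal-likelihood oracle when the assignment policy does not depend on
    the latent state (randomized assignment).
    """
    A = truth.A
    d_z = A.shape[0]
    Qn = truth.sigma_z**2 * np.eye(d_z)
    mu = truth.mu0.copy()
    P = np.diag(truth.sigma0)
    total = 0.0
    for t in range(trajectory.T):
        obs_rows = [truth.C]
        obs_vals = [trajectory.covariates[t]]
        noise_diag = [np.full(truth.C.shape[0], truth.sigma_x**2)]
        m = trajectory.outcome_mask[t].astype(bool)
        if m.any():
            obs_rows.append(truth.D[m])
            obs_vals.append(trajectory.outcomes[t][m])
            noise_diag.append(np.full(int(m.sum()), truth.sigma_y**2))
        H = np.vstack(obs_rows)
        o = np.concatenate(obs_vals)
        R = np.diag(np.concatenate(noise_diag))
        # innovation likelihood
        S = H @ P @ H.T + R
        resid = o - H @ mu
        sign, logdet = np.linalg.slogdet(S)
        total += -0.5 * (len(o) * np.log(2 * np.pi) + logdet + resid @ np.linalg.solve(S, resid))
        # measurement update
        K = P @ H.T @ np.linalg.inv(S)
        mu = mu + K @ resid
        P = (np.eye(d_z) - K @ H) @ P
        P = 0.5 * (P + P.T)
        # time update with known control input
        if t < trajectory.T - 1:
            u = truth.effect(trajectory.treatments[t])
            mu = A @ mu + u
            P = A @ P @ A.T + Qn
    return float(total)


# ---------------------------------------------------------------------------
def linear_gaussian_params(
    truth: SimulationGroundTruth,
    ontology: TreatmentOntology | None = None,
    seed: int = 0,
    enc_hidden: int = 16,
):
    """ModelParams whose generative side equals a linear-Gaussian truth.

    Uses identity decoder activations, zeroes the residual MLP, sets the
    affine transition to (A, I) with embeddings equal to the true per-
    treatment latent effects, and matches all noise scales and the initial
    prior.  The encoder remains a randomly initialized GRU: any causal
    posterior keeps the ELBO a valid lower bound on the exact evidence.
    """
    from .model import ModelConfig, ModelParams

    if ontology is None:
        ontology = make_ontology(truth)
    d_z = truth.A.shape[0]
    config = ModelConfig(
        d_x=truth.C.shape[0],
        k=truth.D.shape[0],
        d_z=d_z,
        m=d_z,
        enc_hidden=enc_hidden,
        decoder_activation="identity",
        covariate_activation="identity",
        attention_gating=False,
    )
    params = ModelParams(config, ontology, seed=seed)
    t = params.t

    def inv_softplus(y: float) -> float:
        return float(np.log(np.expm1(max(y, 1e-10))))

    t["trans_Wz"].data = truth.A.copy()
    t["trans_We"].data = np.eye(d_z)
    t["trans_b"].data = np.zeros(d_z)
    t["trans_W2"].data[:] = 0.0
    t["trans_b2"].data[:] = 0.0
    t["raw_sigma"].data = np.asarray(inv_softplus(truth.sigma_z - 1e-6))
    t["raw_sigma_x"].data = np.asarray(inv_softplus(truth.sigma_x - 1e-6))
    t["prior_mu0"].data = truth.mu0.copy()
    t["prior_rawvar0"].data = np.array([inv_softplus(v - 1e-4) for v in truth.sigma0])
    t["dec_Wy"].data = truth.D.copy()
    t["dec_by"].data[:] = 0.0
    t["dec_Wyvar"].data[:] = 0.0
    t["dec_byvar"].data[:] = inv_softplus(truth.sigma_y**2 - 1e-4)
    t["dec_Wx"].data = truth.C.copy()
    t["dec_bx"].data[:] = 0.0
    # class prototypes = class effects, specific rows = per-treatment offsets
    t["emb_sym"].data = np.stack([truth.class_effects[c] for c in params.classes])
    t["emb_spec"].data = np.stack([truth.specific_offsets[a] for a in params.vocab])
    return params
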