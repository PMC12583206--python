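"""scikit-learn style front end to the latent treatment-response model.

`ResponseNetModel` wraps the full pipeline — posterior encoder, latent
dynamics, ontology-informed embeddings, knowledge-infusion losses and
dual-loop adversarial training — behind the familiar fit/predict surface
so it composes with sklearn model-selection tooling.  The lower-level
modules remain usable directly; this class only orchestrates them.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .cohort import ClinicalPriors, Cohort, TreatmentOntology
from .counterfactual import counterfactual_rollout
from .evaluation import evaluate_prediction
from .model import ModelConfig, elbo, encode_posterior
from .training import TrainConfig, train

__all__ = ["ResponseNetModel"]


class ResponseNetModel(BaseEstimator):
    """Variational latent-dynamics model of treatment-response trajectories.

    Parameters
    ----------
    d_z : latent state dimension.
    m : treatment-embedding dimension (defaults to d_z).
    enc_hidden, trans_hidden, disc_hidden : network widths.
    epochs, batch_size, lr, lr_disc, n_critic, mc_samples : optimization.
    transition_mode : "first_order" (stochastic one-step) or "second_order"
        (latent-inertia refinement as the transition mean).
    decoder_activation, covariate_activation : decoder link functions.
    attention_gating : scale treatment inputs by class-attention weights.
    loss_weights : overrides for the composite-objective λ's.
    random_state : seed for initialization, batching and Monte Carlo.

    Attributes
    ----------
    params_ : fitted :class:`ModelParams`.
    history_ : per-epoch loss-term breakdown.
    ontology_ : the treatment ontology used at fit time.
    """

    def __init__(
        self,
        d_z: int = 4,
        m: int | None = None,
        enc_hidden: int = 32,
        trans_hidden: int = 32,
        disc_hidden: int = 16,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-2,
        lr_disc: float = 1e-2,
        n_critic: int = 1,
        mc_samples: int = 1,
        transition_mode: str = "first_order",
        decoder_activation: str = "relu",
        covariate_activation: str = "tanh",
        attention_gating: bool = False,
        loss_weights: dict | None = None,
        random_state: int = 0,
    ):
        self.d_z = d_z
        self.m = m
        self.enc_hidden = enc_hidden
        self.trans_hidden = trans_hidden
        self.disc_hidden = disc_hidden
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_disc = lr_disc
        self.n_critic = n_critic
        self.mc_samples = mc_samples
        self.transition_mode = transition_mode
        self.decoder_activation = decoder_activation
        self.covariate_activation = covariate_activation
        self.attention_gating = attention_gating
        self.loss_weights = loss_weights
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(
        self,
        X: Cohort,
        y=None,
        ontology: TreatmentOntology | None = None,
        priors: ClinicalPriors | None = None,
    ) -> "ResponseNetModel":
        """Fit on a cohort; `y` is ignored (targets live inside the cohort)."""
        if ontology is None:
            # degenerate ontology: every treatment its own class
            ids = sorted(X.treatment_ids())
            ontology = TreatmentOntology(class_of={a: a for a in ids})
        if priors is None:
            priors = ClinicalPriors()
        if self.loss_weights:
            merged = dict(priors.loss_weights)
            merged.update(self.loss_weights)
            priors = ClinicalPriors(
                anchor_mean=priors.anchor_mean,
                anchor_var=priors.anchor_var,
                safe_region=priors.safe_region,
                stage_curves=priors.stage_curves,
                decay_rho=priors.decay_rho,
                loss_weights=merged,
                margin=priors.margin,
            )
        model_config = ModelConfig(
            d_x=X.d_x,
            k=X.k,
            d_z=self.d_z,
            m=self.m,
            enc_hidden=self.enc_hidden,
            trans_hidden=self.trans_hidden,
            disc_hidden=self.disc_hidden,
            decoder_activation=self.decoder_activation,
            covariate_activation=self.covariate_activation,
            attention_gating=self.attention_gating,
            transition_mode=self.transition_mode,
        )
        train_config = TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            lr_disc=self.lr_disc,
            n_critic=self.n_critic,
            mc_samples=self.mc_samples,
            seed=self.random_state,
            transition_mode=self.transition_mode,
        )
        self.params_, self.history_ = train(
            X, ontology, priors, train_config, model_config=model_config
        )
        self.ontology_ = ontology
        self.priors_ = priors
        return self

    # ------------------------------------------------------------------
    def predict(self, X: Cohort) -> list[np.ndarray]:
        """One-step-ahead outcome means: per patient a (T−1, k) array."""
        self._check_fitted()
        out = []
        for tr in X:
            preds = [
                counterfactual_rollout(tr, s, tr.treatments[s - 1], self.params_, horizon=1)[0]
                for s in range(1, tr.T)
            ]
            out.append(np.asarray(preds))
        return out

    def predict_counterfactual(self, trajectory, s: int, a_alt: str,
                               horizon: int = 1) -> np.ndarray:
        """Mean-path counterfactual outcomes under an alternative treatment."""
        self._check_fitted()
        return counterfactual_rollout(trajectory, s, a_alt, self.params_, horizon=horizon)

    def transform(self, X: Cohort) -> list[np.ndarray]:
        """Posterior mean latent paths, one (T, d_z) array per patient."""
        self._check_fitted()
        return [encode_posterior(tr, self.params_).mean for tr in X]

    def score(self, X: Cohort, y=None, n_samples: int = 10) -> float:
        """Mean per-patient ELBO (higher is better)."""
        self._check_fitted()
        return float(np.mean([
            elbo(tr, self.params_, n_samples=n_samples, seed=self.random_state)
            for tr in X
        ]))

    def evaluate(self, X: Cohort, horizon: int = 1, **kw) -> dict:
        self._check_fitted()
        return evaluate_prediction(self.params_, X, horizon=horizon, **kw)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted; call fit() first")
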