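"""Shared fixtures: tiny hand-written cohorts/ontologies and small models."""

import numpy as np
import pytest

from responsenet.cohort import (
    ClinicalPriors,
    Cohort,
    SafeRegion,
    Trajectory,
    TreatmentOntology,
)
from responsenet.model import ModelConfig, ModelParams
from responsenet.simulate import SimConfig, make_ground_truth, make_ontology, simulate_cohort


@pytest.fixture
def tiny_ontology() -> TreatmentOntology:
    """4 drugs in 2 classes with one similarity edge and one explicit kernel entry."""
    return TreatmentOntology(
        class_of={"a1": "chemo", "a2": "chemo", "b1": "hormone", "b2": "hormone"},
        similarity_edges=[("a1", "a2"), ("b1", "b2")],
        kernel={("a1", "b1"): 0.7},
    )


@pytest.fixture
def tiny_trajectory() -> Trajectory:
    return Trajectory(
        patient_id="p0",
        covariates=[[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]],
        treatments=["a1", "b1", "a2"],
        outcomes=[[1.0], [2.0], [3.0]],
        outcome_mask=[[1], [1], [1]],
    )


@pytest.fixture
def tiny_cohort(tiny_trajectory) -> Cohort:
    other = Trajectory(
        patient_id="p1",
        covariates=[[1.0, -1.0], [0.5, 0.5]],
        treatments=["b2", "a1"],
        outcomes=[[0.5], [-0.5]],
        outcome_mask=[[1], [0]],
    )
    return Cohort([tiny_trajectory, other], d_x=2, k=1)


@pytest.fixture
def small_config() -> ModelConfig:
    return ModelConfig(d_x=2, k=1, d_z=2, m=2, enc_hidden=4, trans_hidden=4, disc_hidden=3)


@pytest.fixture
def small_params(small_config, tiny_ontology) -> ModelParams:
    return ModelParams(small_config, tiny_ontology, seed=0)


@pytest.fixture
def sim_setup():
    """Small simulated world with ground truth: (config, truth, ontology, cohort, latents)."""
    cfg = SimConfig(n_patients=12, T=6, d_z=2, d_x=3, k=2,
                    n_classes=2, treatments_per_class=2, seed=42)
    truth = make_ground_truth(cfg)
    onto = make_ontology(truth)
    cohort, latents = simulate_cohort(truth, cfg)
    return cfg, truth, onto, cohort, latents


@pytest.fixture
def default_priors() -> ClinicalPriors:
    return ClinicalPriors(
        anchor_mean=np.zeros(2),
        anchor_var=4.0 * np.ones(2),
        safe_region=SafeRegion(kind="box", lower=-5 * np.ones(2), upper=5 * np.ones(2)),
        decay_rho=0.9,
        loss_weights={"lambda_drift": 0.01, "lambda_shift": 0.01,
                      "lambda_stage": 0.0, "lambda_wd": 1e-5},
    )
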