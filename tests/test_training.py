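"""Composite objective bookkeeping, dual-loop training, gradient checks,
reproducibility and checkpoint resume."""

import copy

import numpy as np
import pytest

from responsenet.cohort import ClinicalPriors, SafeRegion
from responsenet.model import ModelConfig, ModelParams, elbo, pad_cohort
from responsenet.simulate import SimConfig, make_ground_truth, make_ontology, simulate_cohort
from responsenet.training import (
    TrainConfig,
    gradient_check,
    total_generator_loss,
    train,
)


@pytest.fixture
def small_world():
    cfg = SimConfig(n_patients=10, T=4, d_z=2, d_x=2, k=1,
                    n_classes=2, treatments_per_class=2, seed=50)
    truth = make_ground_truth(cfg)
    onto = make_ontology(truth)
    cohort, _ = simulate_cohort(truth, cfg)
    return cfg, truth, onto, cohort


@pytest.fixture
def grad_fixture(small_world):
    """Tiny (<500 parameter) instance with every loss term active."""
    cfg, truth, onto, cohort = small_world
    model_config = ModelConfig(d_x=2, k=1, d_z=2, m=2, enc_hidden=4,
                               trans_hidden=3, disc_hidden=3)
    params = ModelParams(model_config, onto, seed=3)
    n_params = sum(v.data.size for v in params.t.values())
    assert n_params <= 500
    priors = ClinicalPriors(
        anchor_mean=np.zeros(2), anchor_var=np.ones(2),
        safe_region=SafeRegion(kind="box", lower=[-0.1, -0.1], upper=[0.1, 0.1]),
        decay_rho=0.8,
        stage_curves={"II": np.zeros((4, 1))},
        loss_weights={k: 0.1 for k in ("lambda1", "lambda2", "lambda3", "lambda4",
                                       "lambda5", "lambda_sym", "lambda_align",
                                       "lambda_smooth", "lambda_stage",
                                       "lambda_drift", "lambda_shift", "lambda_wd")},
    )
    sub = cohort.subset([0, 1])
    for tr in sub:
        tr.stage = "II"
    X, A, Y, M, valid = pad_cohort(sub, params)
    batch = {"X": X[:, :3], "A": A[:, :3], "Y": Y[:, :3], "M": M[:, :3],
             "valid": valid[:, :3], "stages": [tr.stage for tr in sub]}
    tconf = TrainConfig(epochs=1, seed=7, mc_samples=1)
    return params, batch, priors, onto, tconf


class TestTotalLoss:
    def _loss(self, batch, params, priors, onto, tconf):
        rng_mc = np.random.default_rng(1)
        rng_cf = np.random.default_rng(2)
        return total_generator_loss(batch, params, priors, onto, tconf,
                                    rng_mc, rng_cf)

    def test_breakdown_reconstructs_total(self, grad_fixture):
        params, batch, priors, onto, tconf = grad_fixture
        total, breakdown = self._loss(batch, params, priors, onto, tconf)
        weights = breakdown["_weights"]
        recon = sum(weights[k] * breakdown[k] for k in weights)
        assert recon == pytest.approx(total.item(), abs=1e-10)

    def test_all_lambda_zero_reduces_to_neg_elbo(self, grad_fixture):
        params, batch, priors, onto, tconf = grad_fixture
        bare = copy.deepcopy(priors)
        for k in bare.loss_weights:
            bare.loss_weights[k] = 0.0
        total, breakdown = self._loss(batch, params, bare, onto, tconf)
        assert set(breakdown["_weights"]) == {"neg_elbo"}
        assert total.item() == pytest.approx(breakdown["neg_elbo"], abs=1e-12)

    def test_doubling_lambda2_doubles_contribution(self, grad_fixture):
        params, batch, priors, onto, tconf = grad_fixture
        # put the cumulative influence far outside the corridor so it is active
        priors = copy.deepcopy(priors)
        priors.safe_region = SafeRegion(kind="box", lower=[-1e-4] * 2, upper=[1e-4] * 2)
        _, b1 = self._loss(batch, params, priors, onto, tconf)
        doubled = copy.deepcopy(priors)
        doubled.loss_weights["lambda2"] = 2 * priors.loss_weights["lambda2"]
        _, b2 = self._loss(batch, params, doubled, onto, tconf)
        assert b1["corridor"] == pytest.approx(b2["corridor"], abs=1e-12)
        c1 = b1["_weights"]["corridor"] * b1["corridor"]
        c2 = b2["_weights"]["corridor"] * b2["corridor"]
        assert b1["corridor"] > 0
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_nonfinite_term_raises_named_error(self, grad_fixture):
        params, batch, priors, onto, tconf = grad_fixture
        params.t["dec_Wy"].data[:] = np.inf
        with pytest.raises(FloatingPointError, match="neg_elbo"):
            self._loss(batch, params, priors, onto, tconf)


class TestGradientCheck:
    TERMS = ["total", "neg_elbo", "consistency", "corridor", "anchor", "disc",
             "temporal", "sym", "align", "smooth", "stage", "drift", "shift",
             "weight_decay"]

    @pytest.mark.parametrize("term", TERMS)
    def test_analytic_matches_finite_differences(self, grad_fixture, term):
        params, batch, priors, onto, tconf = grad_fixture
        err = gradient_check(params, batch, term, priors, onto, tconf)
        assert err < 1e-3, f"term {term}: max relative error {err}"

    def test_corrupted_gradient_detected(self, grad_fixture):
        params, batch, priors, onto, tconf = grad_fixture
        err = gradient_check(params, batch, "neg_elbo", priors, onto, tconf,
                             corrupt_key="dec_by")
        assert err > 1e-1

    def test_empty_key_list_reports_zero(self, grad_fixture):
        params, batch, priors, onto, tconf = grad_fixture
        assert gradient_check(params, batch, "total", priors, onto, tconf,
                              keys=[]) == 0.0


class TestTraining:
    def test_same_seed_bitwise_identical(self, small_world, default_priors):
        _, _, onto, cohort = small_world
        tconf = TrainConfig(epochs=3, batch_size=5, seed=9)
        mc = ModelConfig(d_x=2, k=1, d_z=2, enc_hidden=8, trans_hidden=8)
        p1, h1 = train(cohort, onto, default_priors, tconf, model_config=mc)
        p2, h2 = train(cohort, onto, default_priors, tconf, model_config=mc)
        for k in p1.t:
            np.testing.assert_array_equal(p1.t[k].data, p2.t[k].data)
        assert h1 == h2

    def test_lambda4_zero_decouples_discriminator(self, small_world, default_priors):
        _, _, onto, cohort = small_world
        priors = copy.deepcopy(default_priors)
        priors.loss_weights["lambda4"] = 0.0
        tconf = TrainConfig(epochs=3, batch_size=5, seed=9, n_critic=3)
        mc = ModelConfig(d_x=2, k=1, d_z=2, enc_hidden=8, trans_hidden=8)
        p1, h1 = train(cohort, onto, priors, tconf, model_config=mc)
        p2, h2 = train(cohort, onto, priors,
                       TrainConfig(epochs=3, batch_size=5, seed=9, n_critic=1),
                       model_config=mc)
        for k in p1.generator_keys():
            np.testing.assert_array_equal(p1.t[k].data, p2.t[k].data)
        assert [r["neg_elbo"] for r in h1] == [r["neg_elbo"] for r in h2]

    def test_loss_decreases_on_small_cohort(self, small_world, default_priors):
        _, _, onto, cohort = small_world
        tconf = TrainConfig(epochs=10, batch_size=10, seed=4)
        mc = ModelConfig(d_x=2, k=1, d_z=2, enc_hidden=8, trans_hidden=8)
        _, history = train(cohort, onto, default_priors, tconf, model_config=mc)
        assert history[-1]["neg_elbo"] < history[0]["neg_elbo"]

    def test_checkpoint_resume_matches_uninterrupted(self, tmp_path, small_world,
                                                     default_priors):
        _, _, onto, cohort = small_world
        mc = ModelConfig(d_x=2, k=1, d_z=2, enc_hidden=6, trans_hidden=6)
        full = TrainConfig(epochs=10, batch_size=5, seed=13)
        p_full, h_full = train(cohort, onto, default_priors, full, model_config=mc)

        half = TrainConfig(epochs=5, batch_size=5, seed=13, checkpoint_every=5,
                           checkpoint_dir=str(tmp_path))
        train(cohort, onto, default_priors, half, model_config=mc)
        p_res, h_res = train(cohort, onto, default_priors, full, model_config=mc,
                             resume_from=tmp_path / "epoch0005")
        assert len(h_res) == len(h_full)
        for a, b in zip(h_full[5:], h_res[5:]):
            assert a["total"] == pytest.approx(b["total"], abs=1e-6)
        for k in p_full.t:
            np.testing.assert_allclose(p_res.t[k].data, p_full.t[k].data, atol=1e-6)

    def test_reduces_to_sequential_vae_and_beats_mean_baseline(self, small_world):
        cfg, truth, onto, _ = small_world
        train_cfg = SimConfig(n_patients=60, T=6, d_z=2, d_x=2, k=1,
                              n_classes=2, treatments_per_class=2, seed=60)
        truth = make_ground_truth(train_cfg)
        onto = make_ontology(truth)
        cohort, _ = simulate_cohort(truth, train_cfg)
        held, _ = simulate_cohort(truth, train_cfg, seed=61)
        bare = ClinicalPriors(loss_weights={k: 0.0 for k in
                                            ClinicalPriors().loss_weights})
        tconf = TrainConfig(epochs=25, batch_size=20, seed=5)
        mc = ModelConfig(d_x=2, k=1, d_z=2)
        params, _ = train(cohort, onto, bare, tconf, model_config=mc)

        from responsenet.evaluation import evaluate_prediction

        report = evaluate_prediction(params, held, horizon=1, n_samples=30, seed=0)
        assert report["rmse"] < report["baseline_rmse_constant_mean"]

    def test_divergence_aborts_with_last_good(self, small_world, default_priors):
        _, _, onto, cohort = small_world
        tconf = TrainConfig(epochs=4, batch_size=10, lr=1e6, seed=2)  # blow up
        mc = ModelConfig(d_x=2, k=1, d_z=2, enc_hidden=6, trans_hidden=6)
        params, history = train(cohort, onto, default_priors, tconf, model_config=mc)
        for v in params.t.values():
            assert np.all(np.isfinite(v.data))
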