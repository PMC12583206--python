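"""Simulator: seeded determinism, generative structure, counterfactual twins,
and the Kalman evidence oracle cross-checked against a joint-Gaussian form."""

import json

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from responsenet.simulate import (
    SimConfig,
    SimulationGroundTruth,
    kalman_log_evidence,
    make_ground_truth,
    make_ontology,
    simulate_cohort,
    simulate_counterfactual_pair,
)


def _manual_truth(d_z=2, d_x=2, k=2, A=None, D=None, sigma=1e-9, effects=None,
                  miss_rate=0.0):
    """Hand-assembled linear-Gaussian world for targeted scenarios."""
    classes = {"u0": "c0", "u1": "c1"}
    zeros = np.zeros(d_z)
    effects = effects or {"c0": zeros, "c1": zeros}
    return SimulationGroundTruth(
        A=A if A is not None else 0.999999 * np.eye(d_z),
        class_effects=effects,
        specific_offsets={a: zeros for a in classes},
        class_of=classes,
        C=np.eye(d_x, d_z),
        D=D if D is not None else np.eye(k, d_z),
        sigma_z=sigma, sigma_x=sigma, sigma_y=sigma,
        mu0=np.ones(d_z), sigma0=np.full(d_z, sigma**2),
        policy_weights={a: np.zeros(d_z) for a in classes},
        confounding_strength=0.0,
        miss_rate=miss_rate,
    )


class TestGroundTruth:
    def test_same_seed_bitwise_identical(self):
        cfg = SimConfig(n_patients=2, T=3, seed=9)
        s1 = json.dumps(make_ground_truth(cfg).to_dict(), sort_keys=True)
        s2 = json.dumps(make_ground_truth(cfg).to_dict(), sort_keys=True)
        assert s1 == s2

    def test_zero_spread_collapses_offsets(self):
        cfg = SimConfig(within_class_spread=0.0, seed=1)
        truth = make_ground_truth(cfg)
        for v in truth.specific_offsets.values():
            np.testing.assert_allclose(v, 0.0, atol=1e-15)
        members = [a for a, c in truth.class_of.items() if c == "class0"]
        np.testing.assert_allclose(truth.effect(members[0]), truth.effect(members[1]))

    def test_vocabulary_counting(self):
        cfg = SimConfig(n_classes=2, treatments_per_class=3, seed=0)
        truth = make_ground_truth(cfg)
        assert len(truth.class_of) == 6
        counts = {}
        for c in truth.class_of.values():
            counts[c] = counts.get(c, 0) + 1
        assert sorted(counts.values()) == [3, 3]

    def test_unstable_transition_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            _manual_truth(A=1.5 * np.eye(2))

    def test_offset_norm_matches_spread(self):
        cfg = SimConfig(within_class_spread=0.25, effect_scale=1.0, seed=3)
        truth = make_ground_truth(cfg)
        for v in truth.specific_offsets.values():
            assert np.linalg.norm(v) == pytest.approx(0.25, rel=1e-9)

    def test_serialization_round_trip(self, tmp_path):
        truth = make_ground_truth(SimConfig(seed=4, n_patients=2))
        f = tmp_path / "truth.json"
        truth.save(f)
        loaded = SimulationGroundTruth.load(f)
        np.testing.assert_array_equal(loaded.A, truth.A)
        assert loaded.class_of == truth.class_of


class TestSimulateCohort:
    def test_no_missingness_all_masks_one(self):
        cfg = SimConfig(n_patients=4, T=5, miss_rate=0.0, seed=2)
        cohort, _ = simulate_cohort(make_ground_truth(cfg), cfg)
        for tr in cohort:
            assert np.all(tr.outcome_mask == 1.0)

    def test_noise_free_identity_dynamics_constant_covariates(self):
        truth = _manual_truth()
        cfg = SimConfig(n_patients=3, T=4, d_z=2, d_x=2, k=2,
                        n_classes=2, treatments_per_class=1, seed=5,
                        sigma_z=1e-9, sigma_x=1e-9, sigma_y=1e-9, miss_rate=0.0)
        cohort, _ = simulate_cohort(truth, cfg)
        for tr in cohort:
            assert np.ptp(tr.covariates, axis=0).max() < 1e-5

    def test_empirical_missingness_rate(self):
        cfg = SimConfig(n_patients=500, T=10, k=2, miss_rate=0.2, seed=6)
        cohort, _ = simulate_cohort(make_ground_truth(cfg), cfg)
        masks = np.concatenate([tr.outcome_mask.reshape(-1) for tr in cohort])
        assert masks.size == 10000
        rate = 1.0 - masks.mean()
        sd = np.sqrt(0.2 * 0.8 / masks.size)
        assert abs(rate - 0.2) <= 5 * sd

    def test_unconfounded_assignment_uniform(self):
        cfg = SimConfig(n_patients=200, T=10, confounding_strength=0.0, seed=7)
        truth = make_ground_truth(cfg)
        cohort, _ = simulate_cohort(truth, cfg)
        acts = [a for tr in cohort for a in tr.treatments]
        n, v = len(acts), len(truth.vocabulary)
        p = 1.0 / v
        sd = np.sqrt(p * (1 - p) / n)
        for a in truth.vocabulary:
            freq = acts.count(a) / n
            assert abs(freq - p) <= 5 * sd

    def test_seeded_determinism(self):
        cfg = SimConfig(n_patients=3, T=4, seed=8)
        truth = make_ground_truth(cfg)
        c1, l1 = simulate_cohort(truth, cfg)
        c2, l2 = simulate_cohort(truth, cfg)
        np.testing.assert_array_equal(l1, l2)
        for t1, t2 in zip(c1, c2):
            np.testing.assert_array_equal(t1.outcomes, t2.outcomes)
            assert t1.treatments == t2.treatments


class TestCounterfactualTwins:
    def test_identity_intervention_identical(self):
        cfg = SimConfig(n_patients=4, T=6, seed=10)
        truth = make_ground_truth(cfg)
        cohort, _ = simulate_cohort(truth, cfg)
        a_s = cohort[1].treatments[2]
        fact, cf = simulate_counterfactual_pair(truth, cfg, (1, 3, a_s))
        np.testing.assert_array_equal(fact.outcomes, cf.outcomes)
        np.testing.assert_array_equal(fact.covariates, cf.covariates)

    def test_factual_twin_matches_cohort(self):
        cfg = SimConfig(n_patients=4, T=6, seed=10)
        truth = make_ground_truth(cfg)
        cohort, _ = simulate_cohort(truth, cfg)
        fact, _ = simulate_counterfactual_pair(truth, cfg, (2, 3, truth.vocabulary[0]))
        np.testing.assert_array_equal(fact.outcomes, cohort[2].outcomes)
        assert fact.treatments == cohort[2].treatments

    def test_twins_agree_before_intervention(self):
        cfg = SimConfig(n_patients=5, T=8, seed=11)
        truth = make_ground_truth(cfg)
        for i, s in [(0, 2), (3, 5), (4, 7)]:
            a_alt = truth.vocabulary[-1]
            fact, cf = simulate_counterfactual_pair(truth, cfg, (i, s, a_alt))
            np.testing.assert_allclose(fact.outcomes[:s], cf.outcomes[:s], atol=1e-12)
            np.testing.assert_allclose(fact.covariates[:s], cf.covariates[:s], atol=1e-12)
            assert fact.treatments[: s - 1] == cf.treatments[: s - 1]
            assert cf.treatments[s - 1] == a_alt

    def test_zero_effects_identical_outcomes_for_any_alternative(self):
        cfg = SimConfig(n_patients=3, T=5, effect_scale=0.0,
                        within_class_spread=0.0, seed=12)
        truth = make_ground_truth(cfg)
        for a_alt in truth.vocabulary:
            fact, cf = simulate_counterfactual_pair(truth, cfg, (0, 2, a_alt))
            np.testing.assert_allclose(fact.outcomes, cf.outcomes, atol=1e-12)

    def test_one_step_effect_propagation(self):
        # A = 0, D = I, sigma -> 0: cf minus factual y_{s+1} equals the
        # difference of the intervened treatments' effect vectors
        d = np.array([0.7, -0.3])
        truth = _manual_truth(A=np.zeros((2, 2)),
                              effects={"c0": np.zeros(2), "c1": d})
        cfg = SimConfig(n_patients=2, T=4, d_z=2, d_x=2, k=2, n_classes=2,
                        treatments_per_class=1, seed=13,
                        sigma_z=1e-12, sigma_x=1e-12, sigma_y=1e-12, miss_rate=0.0)
        fact, cf = simulate_counterfactual_pair(truth, cfg, (0, 2, "u1"))
        factual_effect = truth.effect(fact.treatments[1])
        expected = d - factual_effect
        np.testing.assert_allclose(cf.outcomes[2] - fact.outcomes[2], expected, atol=1e-6)

    def test_unknown_alternative_rejected(self):
        cfg = SimConfig(n_patients=2, T=3, seed=14)
        truth = make_ground_truth(cfg)
        with pytest.raises(KeyError):
            simulate_counterfactual_pair(truth, cfg, (0, 1, "nope"))
        with pytest.raises(ValueError, match="horizon"):
            simulate_counterfactual_pair(truth, cfg, (0, 99, truth.vocabulary[0]))


class TestKalmanOracle:
    def _joint_gaussian_evidence(self, truth, trajectory):
        """Independent oracle: evidence from the stacked joint Gaussian."""
        T = trajectory.T
        d_z = truth.A.shape[0]
        # moments of the stacked latent vector (z_1..z_T)
        mean_z = np.zeros(T * d_z)
        mean_z[:d_z] = truth.mu0
        for t in range(1, T):
            u = truth.effect(trajectory.treatments[t - 1])
            mean_z[t * d_z:(t + 1) * d_z] = truth.A @ mean_z[(t - 1) * d_z: t * d_z] + u
        cov_z = np.zeros((T * d_z, T * d_z))
        cov_z[:d_z, :d_z] = np.diag(truth.sigma0)
        for t in range(1, T):
            sl_prev = slice((t - 1) * d_z, t * d_z)
            sl = slice(t * d_z, (t + 1) * d_z)
            for s in range(t):
                sl_s = slice(s * d_z, (s + 1) * d_z)
                cov_z[np.ix_(range(sl.start, sl.stop), range(sl_s.start, sl_s.stop))] = (
                    truth.A @ cov_z[np.ix_(range(sl_prev.start, sl_prev.stop),
                                           range(sl_s.start, sl_s.stop))]
                )
                cov_z[np.ix_(range(sl_s.start, sl_s.stop), range(sl.start, sl.stop))] = (
                    cov_z[np.ix_(range(sl.start, sl.stop),
                                 range(sl_s.start, sl_s.stop))].T
                )
            cov_z[np.ix_(range(sl.start, sl.stop), range(sl.start, sl.stop))] = (
                truth.A @ cov_z[np.ix_(range(sl_prev.start, sl_prev.stop),
                                       range(sl_prev.start, sl_prev.stop))] @ truth.A.T
                + truth.sigma_z**2 * np.eye(d_z)
            )
        # stacked observation operator (x fully observed, y masked)
        rows, vals, noise = [], [], []
        for t in range(T):
            H_t = np.zeros((truth.C.shape[0], T * d_z))
            H_t[:, t * d_z:(t + 1) * d_z] = truth.C
            rows.append(H_t)
            vals.append(trajectory.covariates[t])
            noise.extend([truth.sigma_x**2] * truth.C.shape[0])
            m = trajectory.outcome_mask[t].astype(bool)
            if m.any():
                Hy = np.zeros((int(m.sum()), T * d_z))
                Hy[:, t * d_z:(t + 1) * d_z] = truth.D[m]
                rows.append(Hy)
                vals.append(trajectory.outcomes[t][m])
                noise.extend([truth.sigma_y**2] * int(m.sum()))
        H = np.vstack(rows)
        o = np.concatenate(vals)
        cov_o = H @ cov_z @ H.T + np.diag(noise)
        return float(multivariate_normal.logpdf(o, mean=H @ mean_z, cov=cov_o))

    @pytest.mark.parametrize("miss_rate", [0.0, 0.3])
    def test_kalman_matches_joint_gaussian(self, miss_rate):
        cfg = SimConfig(n_patients=2, T=5, d_z=2, d_x=2, k=2,
                        n_classes=2, treatments_per_class=2,
                        miss_rate=miss_rate, seed=21)
        truth = make_ground_truth(cfg)
        cohort, _ = simulate_cohort(truth, cfg)
        for tr in cohort:
            kf = kalman_log_evidence(truth, tr)
            joint = self._joint_gaussian_evidence(truth, tr)
            assert kf == pytest.approx(joint, abs=1e-8)


def test_ontology_from_truth_edges_within_classes():
    truth = make_ground_truth(SimConfig(n_classes=2, treatments_per_class=3, seed=1))
    onto = make_ontology(truth)
    assert len(onto.similarity_edges) == 2 * 3  # C(3,2) per class
    for edge in onto.similarity_edges:
        a, b = tuple(edge)
        assert onto.alpha(a) == onto.alpha(b)
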