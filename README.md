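# responsenet

Variational latent-dynamics modelling of patient treatment-response
trajectories, with ontology-informed treatment embeddings, clinical-prior
("knowledge infusion") regularization, adversarial counterfactual
training, and a fully specified synthetic-cohort simulator with known
ground truth.

## Who this is for

Researchers in biostatistics and clinical machine learning who want to
model how a patient's outcomes evolve under sequences of treatments —
forecasting future response, asking *what-if* questions about alternative
therapies, and grounding the learned dynamics in pharmacological structure
(ATC-style treatment classes, similarity kernels, safety corridors, stage
curves).  Because real EHR cohorts rarely come with counterfactual ground
truth, the package ships a simulator that does: every evaluation — effect
recovery, counterfactual error, calibration — is scored against known
truth.

## The model

Each patient contributes aligned sequences (x_t, a_t, y_t, m_t) of
covariates, treatment ids, outcomes and outcome-availability masks.  A
latent health state z_t evolves under treatment,

    z_{t+1} = f_θ(z_t, e(a_t)) + ε_t,     ε_t ~ N(0, σ²I),

with compositional treatment embeddings e(a) = E_sym(α(a)) + E_spec(a)
(class prototype + specific offset).  Outcomes decode as a heteroscedastic
Gaussian, ŷ_t = W_y·ReLU(z_t) + b_y with variance σ²(z_t); the outcome
likelihood is masked, Σ_j m_{t,j} log N(y_{t,j}; μ_j(z_t), σ_j²(z_t)).
A GRU encoder amortizes a causal diagonal-Gaussian posterior q(z_t | H_t),
trained by a reparameterized evidence lower bound.  The composite training
objective adds ontology consistency, a safety corridor on cumulative
latent deviation, KL anchoring to clinical priors, temporal smoothness,
embedding-geometry regularizers, and an adversarial discriminator over
factual versus counterfactual (z, treatment) pairs.  One-step
counterfactuals decode as ŷ^cf = D_y(f_θ(z_t, e(ã))).  See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from responsenet import (SimConfig, make_ground_truth, make_ontology,
                         simulate_cohort, ResponseNetModel)
from responsenet.evaluation import recovery_report

cfg = SimConfig(seed=1)          # 300 patients, 12 visits, 3 classes x 3 drugs
truth = make_ground_truth(cfg)
onto = make_ontology(truth)
cohort, latents = simulate_cohort(truth, cfg)

model = ResponseNetModel(d_z=4, epochs=100, batch_size=50, lr=1e-2,
                         random_state=1)
model.fit(cohort, ontology=onto)
rep = recovery_report(model.params_, truth, cohort, latents, seed=0)
print(f"mean cosine(learned class shifts, true effects): {rep['mean_cosine']:.3f}")
print(f"within-class shift distance: {rep['within_class_distance']:.3f}")
print(f"between-class shift distance: {rep['between_class_distance']:.3f}")
```

Output:

```
mean cosine(learned class shifts, true effects): 0.997
within-class shift distance: 0.113
between-class shift distance: 1.468
```

The learned per-class latent shifts point in the directions of the true
treatment effects (cosine near 1 after linear latent alignment), and
treatments within a pharmacological class induce much more similar shifts
than treatments across classes — the embedding structure the ontology
regularizers are meant to produce.

A what-if query on a fitted model:

```python
tr = cohort[0]
y_cf = model.predict_counterfactual(tr, s=5, a_alt="drug2_0", horizon=1)
```

## Command line

```bash
responsenet simulate --config run.yaml --out cohort.jsonl \
    --ontology ontology.json --truth truth.json
responsenet train --cohort cohort.jsonl --ontology ontology.json \
    --config run.yaml --out ckpt/
responsenet counterfactual --model ckpt/final --cohort cohort.jsonl \
    --query queries.json --out cf.jsonl
responsenet evaluate --model ckpt/final --cohort cohort.jsonl --out report.json
```

`run.yaml` holds the simulator, model, training and clinical-prior
sections; the schema is documented in `src/responsenet/config.py`.

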