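# hemorrhagenet

Joint **classification and prognosis prediction for cerebral hemorrhage**
from multimodal data — a grayscale image slice (CT-like) plus a vector of
bedside clinical covariates (GCS, blood pressure, age, …) per patient — with
an adaptive strategy layer for feature selection, hierarchical decision
routing and uncertainty triage.  The package is aimed at methods researchers
who want a compact, fully inspectable, CPU-only reference implementation of
this model family, testable end to end on synthetic desk-scale cohorts
without any external data.

## The model

Each sample is `x = [x_img, x_clin]` with a hemorrhage-type label
`y ∈ {0..K−1}` and a prognosis score `p ∈ [0,1]`.  The network is a late
fusion architecture:

- **Image branch** — a small conv–batchnorm–ReLU–pool stack produces a
  spatial feature map `Z ∈ R^{H'×W'×C'}`.
- **Attention (graphical propagation) layer** — positions are scored with a
  channel projection `W_att`, normalized by a softmax over all `H'·W'`
  positions, `A = softmax(Z·W_att)`, and the map is reweighted
  `Z_att = A ⊙ Z`.  Because `ΣA = 1`, the upsampled map is directly
  interpretable as a heatmap of where the model looks; it is exported as a
  PNG overlay.
- **Clinical branch + fusion** — covariates are embedded with fully
  connected layers; `h = Fusion([z; F])` with `z = Flatten(Z_att)`.
- **Heads** — a K-way softmax classifier and a sigmoid prognosis regressor.
  By default both read the fused `h`; a `head_mode: literal` switch instead
  wires the classifier to `z` and the regressor to `[z; F]` directly
  (single-layer heads).
- **Joint loss** — `L = CE + λ·(p̂ − p)²`, cross-entropy in nats; missing
  targets are masked per task.  Training uses Adam (β₁=0.9, β₂=0.999),
  weight decay 1e-4, global gradient clipping at 5.0, cosine learning-rate
  decay and early stopping on validation loss.

The adaptive strategy adds, on top of the trained network:

- **Dynamic feature selection** — relevance `R_j = mean_i |∂L/∂x_ij| ·
  Var(x_j)` per clinical covariate; spatially indexed features can be
  reweighted by a Gaussian prior over lesion locations; features above a
  threshold τ (or the top quantile) are retained.
- **Hierarchical decision routing** — a binary tree of sigmoid gates
  `f_n = σ(w_nᵀ x_sel + b_n)` over the selected features (right iff
  f_n ≥ 0.5) with Laplace-smoothed class posteriors at the leaves; gates are
  trained by gradient descent on the soft-routed cross-entropy, and expert
  corrections refine the gates (or the network) by plain gradient steps.
- **Uncertainty triage** — entropy `U = −Σ p ln p` of each posterior;
  samples with `U > δ` are flagged for expert review.  The hybrid objective
  `L_cls + λ₁‖w‖₁ + λ₂·E[U]` adds sparsity on the clinical gating weights
  and expected-uncertainty minimization.

The whole network, including backpropagation, is implemented in numpy
(`hemorrhagenet.nn`), so every gradient is explicit and the package runs
deterministically on a single CPU thread.

## Worked example

```python
import numpy as np
from hemorrhagenet import (RunConfig, SimSpec, attention_enrichment,
                           evaluate_cohort, fit, generate_cohort)

cohort = generate_cohort(SimSpec(n=600, image_size=(32, 32), n_classes=3,
                                 effect_size=1.5, seed=11))
config = RunConfig(image_size=(32, 32), n_classes=3, epochs=30, patience=8,
                   seed=1)
model, log = fit(cohort, config)
report, records = evaluate_cohort(model, cohort.split("test"))
print(report.to_table())
print(f"attention enrichment  {attention_enrichment(model, cohort.split('test')):.2f}")
```

prints

```
n evaluated       90
accuracy          100.00%
macro precision   100.00%
macro recall      100.00%
macro F1          100.00%
prognosis MSE     0.0297
prognosis MAE     0.1387
flagged fraction  2.22%
attention enrichment  4.90
```

The synthetic cohort plants a bright elliptical lesion whose horizontal
stratum defines the class, so a converged model separates the three classes
essentially perfectly; prognosis MSE (0.0297) is well below the test-split
target variance (≈0.05), i.e. the model genuinely predicts the outcome
rather than its mean; 2.2% of test posteriors exceed the entropy threshold
δ = ½·ln 3 and would be routed to expert review; and the attention maps put
4.9× more mass on lesion pixels than a uniform map would — the localization
the overlay PNGs visualize.

The same pipeline is available from the shell:

```bash
hemorrhagenet simulate --n 600 --seed 11 --out-dir cohort/
hemorrhagenet train    --cohort cohort/ --seed 1 --out-dir run/
hemorrhagenet predict  --checkpoint run/checkpoint.npz --cohort cohort/ --out-dir pred/
hemorrhagenet explain  --checkpoint run/checkpoint.npz --cohort cohort/ --ids s0000 --out-dir viz/
hemorrhagenet select   --checkpoint run/checkpoint.npz --cohort cohort/ --out-dir sel/
hemorrhagenet evaluate --checkpoint run/checkpoint.npz --cohort cohort/ --out-dir eval/
```

Every command writes a JSON run manifest (config snapshot, seed, input
digests, wall time); with a fixed seed the pipeline is byte-reproducible.

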