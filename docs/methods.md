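# Methods

This note documents the models and procedures implemented in
`hemorrhagenet`, the parameters that matter, the synthetic data the tests
run on, and the numerical and design choices made where the design was
genuinely open.

## Problem setting

Each patient contributes an image slice (grayscale, intensities in [0, 1]),
a vector of real clinical covariates, a hemorrhage-type label in
`{0..K−1}` and a prognosis score.  Prognosis is standardized to `[0, 1]`
(matching the sigmoid output head); ordinal clinical outcomes such as mRS
0–6 should be mapped linearly onto `[0, 1]` and the mapping recorded by the
caller.  Either target may be missing per sample; the loss masks the
corresponding task.  The learning problem is joint: one network minimizes
`CE(ŷ, y) + λ·(p̂ − p)²` with cross-entropy in nats.

## Network

**Image branch.**  A configurable stack of conv(3×3, same-pad) → batchnorm
→ ReLU → maxpool(2) blocks; default channel widths (8, 16, 32), so a 32×32
input yields a 4×4×32 feature map (grid stride 8).  The backbone is small by
design: the package targets desk-scale CPU experiments, and 224×224 inputs
are supported by the same code when a larger budget is available.

**Attention.**  Every grid position gets a scalar score via a shared channel
projection `W_att`; a softmax *over all positions* yields weights `A ≥ 0`,
`ΣA = 1`, and the feature map is reweighted position-wise.  The softmax over
positions (rather than a per-position sigmoid) is what makes the map a
distribution, hence directly renderable as a heatmap and measurable as
"attention mass inside the lesion".  An optional `graph_propagation` switch
adds one residual 3×3 convolution over the attended map to propagate
information between neighboring positions; it is off by default because the
desk-scale experiments do not need it.

**Heads.**  Default `head_mode: "fused"`: clinical covariates are embedded
(fully connected + ReLU, default width 16), concatenated with the flattened
attended map, passed through a fusion stack (default width 64, ReLU,
dropout 0.1), and both heads read the fused vector.  The alternative
`"literal"` mode wires the classifier directly to the flattened map and the
prognosis head to the raw concatenation `[z; F]` with single linear layers —
the minimal wiring, kept because both readings of the architecture are
defensible and the literal one is the easier to verify against closed
forms.  In both modes the flattened vector is taken *after* attention, so
the attention weights shape the learning objective rather than being a
post-hoc visualization.

**Optimization.**  Adam with β₁ = 0.9, β₂ = 0.999, decoupled weight decay
1e-4, global gradient-norm clipping at 5.0, mini-batches of 64, up to 100
epochs with early stopping (default patience 10) on validation loss, cosine
learning-rate decay from 1e-3 (an initial rate the loss curves on the
synthetic cohorts are insensitive to within 3×; it is a config field).
Best-validation parameters are restored at the end.  The entire network and
its backpropagation are written in numpy; this keeps every gradient
explicit, makes the input-gradient computation used by feature selection
trivial, and makes single-threaded runs bit-reproducible.

## Adaptive strategy

**Relevance scores.**  `R_j = mean_i |∂L/∂x_ij| · Var_j(x_j)` over a scoring
subset (≥ 2 samples).  The gradient is per-sample (the loss is backpropagated
with sum reduction so each sample's input gradient is its own), aggregated
by the mean of absolute values before multiplying by the dataset variance;
this makes `R_j` a well-defined nonnegative per-feature scalar.  Zero-variance
features score 0 with a warning.

**Gaussian spatial prior.**  A multivariate normal over lesion-centroid
coordinates, estimated from training lesion masks when available
(covariance regularized by `+1e-6·I`) or supplied in config.  The prior
multiplies the relevance of *spatially indexed* features only; plain
clinical covariates get weight 1.  Combined scores are rescaled to max 1, so
an absolute threshold τ is scale-free; the default rule retains the top 25%
and the argmax feature is always retained.

**Hierarchical routing.**  A complete binary tree (default depth 3) of
sigmoid gates over the selected features; routing goes right iff
`f_n ≥ 0.5` (ties right — a documented arbitrary convention).  Gates are
trained by full-batch gradient descent on the cross-entropy of the
soft-routed leaf mixture, while leaf posteriors are Laplace(+1)-smoothed
label frequencies under *hard* routing, recomputed each epoch
(straight-through training: soft for gradients, hard for prediction).  The
objective is non-convex; `restarts > 1` refits from different seeded
initializations and keeps the lowest-loss tree.  The tree's posterior and
the network's softmax are reported as independent outputs; no ensemble rule
is imposed because none is canonical.

**Expert feedback.**  Plain gradient steps `θ ← θ − η∇L(C)` on a corrections
set, applicable to either the tree gates or the full network.  The
implementation checks that the corrections loss did not increase and warns
otherwise (the step size is then too large for the local curvature).  On a
depth-1 tree with pure leaves the gate loss is convex, which is what the
descent tests exploit.

**Uncertainty triage.**  Shannon entropy of the class posterior with
`0·ln 0 := 0`; samples above δ are flagged.  Default δ = ½·ln K (half the
maximum entropy) — an interior point of the feasible range chosen in the
absence of a canonical value; it is a config field.  The hybrid loss adds
`λ₁‖w‖₁` on the clinical gating weights (the first clinical-branch layer by
default; the clinical slice of the prognosis head in literal mode) and
`λ₂·mean(U)` over the batch.  The L1 term contributes both a subgradient
`λ₁·sign(w)` and a proximal soft-threshold by `lr·λ₁` after the Adam step —
the subgradient drives unused weights toward zero and the proximal step
produces exact zeros as the learning rate decays; a subgradient alone never
does under Adam's sign-normalized updates.  Caveat, recorded in the
uncertainty report: λ₂ > 0 penalizes *expected* entropy and can inflate
confidence, so entropies from such runs are not calibrated error
probabilities.

## Synthetic cohorts

The generator emulates the structure of hemorrhage cohorts — subtype labels
defined by lesion location, lesion masks, bedside covariates, a continuous
outcome — without claiming radiological realism:

- **Image**: smooth low-frequency background (≈0.15–0.45) + Gaussian pixel
  noise (sd 0.05) + one bright elliptical blob (additive lift 0.3, radii
  3–6 px at 32×32).  Single lesion per image; no 3-D structure, no scanner
  artifacts.
- **Class**: the image is split into K equal-width vertical bands (the
  analogue of location-based subtype conventions such as lobar / deep /
  infratentorial); the band containing the lesion centre is the label.  The
  centre is constrained to its band, so class-conditional centroids fall in
  their stratum by construction.
- **Prognosis**: `0.5 + 0.15·z(area fraction) + 0.15·severity + ε`,
  ε ~ N(0, 0.05²), clipped to [0, 1] (clipping rate logged).  `severity` is
  a latent standard normal.
- **Covariates**: informative ones are `effect_size·severity + N(0,1)` —
  at the default effect size 1.5 their correlation with prognosis is ≈0.5,
  comfortably above the nuisance null band at n = 200 — and nuisance ones
  are independent standard normals.
- **Splits**: seeded 70/15/15.

Coefficients were fixed once so that (a) at effect_size 0 the informative
covariates are null (|r| below the n = 200 Monte-Carlo band), (b) at
effect_size ≥ 1 they are recoverable by the relevance mechanism, and (c)
the prognosis variance is split roughly equally between an image-visible
component (lesion area) and a clinical-only component (severity), so the
regression head must use both modalities to beat the target variance.

What passing tests on these cohorts do **not** show: robustness to real CT
noise, multi-lesion presentations, label noise, covariate shift between
sites, or any claim about clinical anatomy — the attention-localization
result is a statement about planted blobs, not about thalami.

## Numerical choices and conventions

- Coordinates are row-major, 0-based, (row, col); attention grid cell
  (a, b) covers the half-open pixel block `[a·s, (a+1)·s) × [b·s, (b+1)·s)`.
- Covariates are z-scored with **train-split statistics only**; missing
  cells are train-mean imputed with a per-cell flag.  Images are min-max
  scaled per image after resizing (bilinear).
- 3-D NIfTI volumes are reduced to the middle slice along the last axis.
- Cross-entropy and entropy are in nats throughout; probabilities are
  clipped at 1e-300 inside logs.
- Max-pool gradients are split evenly across ties so the gradient is
  conserved; batchnorm uses running statistics at evaluation.
- Softmax is computed with max subtraction; the logistic function is
  evaluated piecewise to avoid overflow.
- Macro averaging for classification metrics; classes absent from both
  truth and prediction are excluded from the macro mean, and a class never
  predicted gets precision 0 with a warning.
- Determinism: all randomness flows from explicit seeds
  (`numpy.random.default_rng`); on a single CPU thread
  simulate → train → predict is byte-reproducible.

## Problem sizes

The shipped experiments use 32×32 images, cohorts of 60–600 samples and
15–40 epochs — sizes at which a full train/evaluate round takes seconds on
one CPU core and the planted effects are detected with wide margins.  The
acceptance script repeats the main experiment over three seeds and reports
averages.

## Known limitations

- The conv backbone is minimal; no pretrained weights, no 3-D convolutions,
  no mixed precision or multi-device execution.
- The hierarchical tree has a fixed complete topology; structure learning is
  out of scope.
- The entropy threshold δ and the selection threshold τ are operating-point
  choices, not calibrated quantities.
- Augmentation (flips, brightness jitter, 1-px shifts) is opt-in and mild;
  heavier augmentation families are out of scope.
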