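"""Adaptive prognostic strategy: dynamic feature selection, hierarchical
decision routing and uncertainty-aware optimization.

Three cooperating mechanisms sit on top of the trained network:

* **Dynamic feature selection** scores each clinical covariate by
  ``R_j = mean_i |dL/dx_ij| * Var_j(x_j)`` — the mean absolute gradient of the
  joint loss with respect to the input feature, weighted by the feature's
  variance across the scoring subset.  Spatially indexed features can be
  reweighted by a Gaussian prior over lesion locations so selection favours
  anatomically plausible regions; plain clinical covariates get prior weight
  one.  Features whose combined score exceeds a threshold tau (or the top
  quantile) are retained; at least one feature always survives.

* **Hierarchical decision routing** is a fixed-topology binary tree whose
  internal nodes apply sigmoid gates ``f_n = sigmoid(w_n . x_sel + b_n)``
  over the selected features (right branch iff f_n >= 0.5, ties right) and
  whose leaves hold Laplace-smoothed class posteriors.  Gates are trained by
  gradient descent on the cross-entropy of the soft-routed leaf mixture;
  prediction uses hard routing.  Expert-labelled corrections refine either
  the tree or the network with plain gradient steps.

* **Uncertainty triage** computes the Shannon entropy of each class
  posterior (nats, with 0*log 0 := 0) and flags samples above a threshold
  delta for expert review.  The hybrid objective
  ``L_cls + lambda1 ||w||_1 + lambda2 E[U]`` couples sparsity of the clinical
  gating weights with expected-uncertainty minimization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import multivariate_normal

from .cohort import Cohort

__all__ = [
    "entropy", "uncertainty", "UncertaintyReport", "hybrid_loss",
    "RelevanceReport", "relevance_scores", "SpatialPrior",
    "spatial_prior_density", "estimate_spatial_prior", "select_features",
    "HierarchyTree", "route", "fit_tree", "incorporate_feedback",
]


# --------------------------------------------------------------------------
# uncertainty
# --------------------------------------------------------------------------

def entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats per row, with the 0*log(0) = 0 convention."""
    p = np.atleast_2d(np.asarray(probs, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=1)


@dataclass
class UncertaintyReport:
    entropies: np.ndarray
    delta: float
    flagged_ids: list[str]
    mean_entropy: float
    note: str | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"entropies": self.entropies.tolist(), "delta": self.delta,
                       "flagged_ids": self.flagged_ids,
                       "mean_entropy": self.mean_entropy, "note": self.note},
                      fh, indent=2)


def uncertainty(class_probs: np.ndarray, delta: float,
                ids: list[str] | None = None,
                entropy_penalized: bool = False) -> UncertaintyReport:
    """Entropy-based triage: flag every sample whose entropy exceeds delta."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    p = np.atleast_2d(np.asarray(class_probs, dtype=float))
    if np.any(np.abs(p.sum(axis=1) - 1.0) > 1e-6) or (p < -1e-12).any():
        raise ValueError("class probabilities must lie on the simplex")
    u = entropy(p)
    ids = ids if ids is not None else [str(i) for i in range(len(u))]
    flagged = [i for i, ui in zip(ids, u) if ui > delta]
    note = None
    if entropy_penalized:
        note = ("trained with an expected-entropy penalty (lambda2 > 0): "
                "posteriors may be over-confident; entropies are not "
                "calibrated probabilities of error")
    return UncertaintyReport(entropies=u, delta=float(delta), flagged_ids=flagged,
                             mean_entropy=float(u.mean()), note=note)


def hybrid_loss(class_loss: float, gating_weights: np.ndarray,
                batch_probs: np.ndarray, lambda1: float, lambda2: float) -> float:
    """L_hybrid = L_cls + lambda1 ||w||_1 + lambda2 * mean batch entropy."""
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("lambda1 and lambda2 must be >= 0")
    l1 = float(np.abs(np.asarray(gating_weights)).sum())
    mean_u = float(entropy(batch_probs).mean())
    return float(class_loss) + lambda1 * l1 + lambda2 * mean_u


# --------------------------------------------------------------------------
# relevance scores + Gaussian spatial prior + selection
# --------------------------------------------------------------------------

@dataclass
class RelevanceReport:
    feature_names: list[str]
    relevance: np.ndarray          # R_j = mean_i |dL/dx_ij| * Var_j
    mean_abs_gradient: np.ndarray
    variance: np.ndarray
    aggregation: str = "mean |grad| over subset x variance over subset"
    prior_weight: np.ndarray | None = None
    combined: np.ndarray | None = None
    retained: list[int] = field(default_factory=list)
    tau: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "feature_names": self.feature_names,
                "relevance": self.relevance.tolist(),
                "mean_abs_gradient": self.mean_abs_gradient.tolist(),
                "variance": self.variance.tolist(),
                "aggregation": self.aggregation,
                "prior_weight": None if self.prior_weight is None
                else self.prior_weight.tolist(),
                "combined": None if self.combined is None else self.combined.tolist(),
                "retained": self.retained,
                "tau": self.tau,
            }, fh, indent=2)


def relevance_scores(model, cohort_subset: Cohort) -> RelevanceReport:
    """Gradient x variance relevance of each clinical covariate.

    Backpropagates the per-sample joint loss to the clinical inputs, takes
    the mean absolute gradient across the subset and multiplies by the
    feature's variance.  Zero-variance features score 0 (with a warning).
    """
    if len(cohort_subset) < 2:
        raise ValueError("need at least 2 samples for a defined variance")
    images, clinical, y, p = cohort_subset.arrays()
    model.zero_grad()
    cache = model.forward(images, clinical, train=False)
    # sum-reduction makes dF[i] each sample's own gradient dL_i/dx_i
    model.loss_and_backward(cache, y, p, reduction="sum")
    grad = np.abs(cache["dF"]).mean(axis=0)
    var = clinical.var(axis=0)
    zero_var = var <= 0
    if zero_var.any():
        names = [cohort_subset.schema[j] for j in np.flatnonzero(zero_var)]
        warnings.warn(f"zero-variance features scored 0: {names}", stacklevel=2)
    rel = np.where(zero_var, 0.0, grad * var)
    return RelevanceReport(feature_names=list(cohort_subset.schema),
                           relevance=rel, mean_abs_gradient=grad, variance=var)


@dataclass
class SpatialPrior:
    """Gaussian prior over lesion locations (mean + SPD covariance)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        np.linalg.cholesky(self.cov)  # raises if not positive-definite


def spatial_prior_density(prior: SpatialPrior, x_spatial: np.ndarray) -> np.ndarray:
    """Multivariate normal density of spatial coordinates under the prior."""
    x = np.asarray(x_spatial, dtype=float)
    return np.asarray(multivariate_normal.pdf(x, mean=prior.mean, cov=prior.cov))


def estimate_spatial_prior(cohort: Cohort, eps: float = 1e-6) -> SpatialPrior:
    """Fit the prior to training lesion-mask centroids ((row, col) coords)."""
    cents = []
    for s, sp in zip(cohort.samples, cohort.split_assignment):
        if sp == "train" and s.lesion_mask is not None and s.lesion_mask.any():
            rr, cc = np.nonzero(s.lesion_mask)
            cents.append([rr.mean(), cc.mean()])
    if len(cents) < 2:
        raise ValueError("need >= 2 training lesion masks to estimate the prior")
    cents = np.asarray(cents)
    cov = np.cov(cents.T) + eps * np.eye(2)
    return SpatialPrior(mean=cents.mean(axis=0), cov=cov)


def select_features(report: RelevanceReport, prior: SpatialPrior | None = None,
                    tau: float | None = None, top_q: float | None = None,
                    spatial_coords: dict[int, np.ndarray] | None = None,
                    ) -> RelevanceReport:
    """Retain features whose prior-weighted relevance exceeds the threshold.

    ``spatial_coords`` maps feature index -> spatial coordinate for
    image-derived features; those get the prior density as weight, all other
    features get weight 1.  Scores are rescaled to max 1 before thresholding.
    With ``tau=None`` the top ``top_q`` fraction (default 0.25) is retained.
    The argmax feature is always retained.
    """
    d = len(report.feature_names)
    if d == 0:
        raise ValueError("empty relevance report")
    weight = np.ones(d)
    if prior is not None and spatial_coords:
        for j, coord in spatial_coords.items():
            weight[j] = float(spatial_prior_density(prior, coord))
    combined = report.relevance * weight
    peak = combined.max()
    if peak > 0:
        combined = combined / peak
    if tau is not None:
        retained = np.flatnonzero(combined > tau)
    else:
        q = 0.25 if top_q is None else top_q
        if not (0.0 < q <= 1.0):
            raise ValueError("top_q must lie in (0, 1]")
        m = int(np.ceil(q * d))
        retained = np.argsort(combined, kind="stable")[::-1][:m]
        retained = np.sort(retained)
    if retained.size == 0:
        retained = np.array([int(np.argmax(combined))])
    report.prior_weight = weight
    report.combined = combined
    report.retained = [int(j) for j in retained]
    report.tau = tau
    return report


# --------------------------------------------------------------------------
# hierarchical decision framework
# --------------------------------------------------------------------------

def _sigmoid(x):
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500))),
                    np.exp(np.clip(x, -500, 500)) /
                    (1.0 + np.exp(np.clip(x, -500, 500))))


@dataclass
class HierarchyTree:
    """Complete binary tree of sigmoid gates with leaf class posteriors.

    Internal nodes are heap-ordered (children of n are 2n+1 / 2n+2); the
    2**depth leaves hold posteriors on the K-simplex.
    """

    depth: int
    weights: np.ndarray        # (n_internal, d_sel); empty when depth == 0
    biases: np.ndarray         # (n_internal,)
    leaf_posteriors: np.ndarray  # (2**depth, K)

    def __post_init__(self) -> None:
        n_internal = 2 ** self.depth - 1
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.depth == 0:
            self.weights = self.weights.reshape(0, self.weights.shape[-1] if
                                                self.weights.size else 0)
        self.biases = np.asarray(self.biases, dtype=float).reshape(-1)
        if self.weights.shape[0] != n_internal or self.biases.size != n_internal:
            raise ValueError(f"depth-{self.depth} tree needs {n_internal} gates")
        self.leaf_posteriors = np.atleast_2d(
            np.asarray(self.leaf_posteriors, dtype=float))
        if self.leaf_posteriors.shape[0] != 2 ** self.depth:
            raise ValueError("wrong leaf count")
        if np.any(np.abs(self.leaf_posteriors.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("leaf posteriors must lie on the simplex")

    @property
    def n_leaves(self) -> int:
        return 2 ** self.depth

    def to_json(self, path: str | Path) -> None:
        nodes = []
        for n in range(2 ** self.depth - 1):
            nodes.append({"id": n, "parent": (n - 1) // 2 if n else None,
                          "w": self.weights[n].tolist(),
                          "b": float(self.biases[n])})
        leaves = [{"id": 2 ** self.depth - 1 + i,
                   "parent": (2 ** self.depth - 2 + i) // 2 if self.depth else None,
                   "posterior": post.tolist()}
                  for i, post in enumerate(self.leaf_posteriors)]
        with open(path, "w") as fh:
            json.dump({"depth": self.depth, "internal": nodes, "leaves": leaves},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "HierarchyTree":
        with open(path) as fh:
            data = json.load(fh)
        depth = data["depth"]
        d_sel = len(data["internal"][0]["w"]) if data["internal"] else 0
        w = np.array([n["w"] for n in data["internal"]], dtype=float).reshape(
            2 ** depth - 1, d_sel)
        b = np.array([n["b"] for n in data["internal"]], dtype=float)
        post = np.array([lf["posterior"] for lf in data["leaves"]], dtype=float)
        return cls(depth=depth, weights=w, biases=b, leaf_posteriors=post)


def route(tree: HierarchyTree, x_sel: np.ndarray) -> tuple[int, list[tuple[int, float]], np.ndarray]:
    """Hard-route one sample: right iff f_n >= 0.5 (ties right).

    Returns (leaf index, [(node id, gate value), ...], leaf posterior).
    """
    x = np.asarray(x_sel, dtype=float).reshape(-1)
    if tree.depth > 0 and x.size != tree.weights.shape[1]:
        raise ValueError(f"expected {tree.weights.shape[1]} selected features, "
                         f"got {x.size}")
    node = 0
    path: list[tuple[int, float]] = []
    for _ in range(tree.depth):
        f = float(_sigmoid(tree.weights[node] @ x + tree.biases[node]))
        path.append((node, f))
        node = 2 * node + 2 if f >= 0.5 else 2 * node + 1
    leaf = node - (2 ** tree.depth - 1)
    return leaf, path, tree.leaf_posteriors[leaf].copy()


def _leaf_paths(depth: int) -> list[list[tuple[int, int]]]:
    """For each leaf: the (internal node, direction) pairs along its path."""
    paths = []
    for leaf in range(2 ** depth):
        node, steps = 0, []
        for level in range(depth):
            bit = (leaf >> (depth - 1 - level)) & 1
            steps.append((node, bit))
            node = 2 * node + 2 if bit else 2 * node + 1
        paths.append(steps)
    return paths


def _soft_leaf_probs(tree: HierarchyTree, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Soft routing: P(leaf | x) as products of gate probabilities."""
    f = _sigmoid(X @ tree.weights.T + tree.biases)      # (n, n_internal)
    n = X.shape[0]
    P = np.ones((n, tree.n_leaves))
    for leaf, steps in enumerate(_leaf_paths(tree.depth)):
        for node, bit in steps:
            P[:, leaf] *= f[:, node] if bit else (1.0 - f[:, node])
    return P, f


def _hard_leaf_posteriors(tree: HierarchyTree, X: np.ndarray, y: np.ndarray,
                          n_classes: int) -> np.ndarray:
    """Laplace(+1)-smoothed label frequencies of hard-routed samples."""
    counts = np.ones((tree.n_leaves, n_classes))
    for xi, yi in zip(X, y):
        leaf, _, _ = route(tree, xi)
        counts[leaf, int(yi)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def tree_loss(tree: HierarchyTree, X: np.ndarray, y: np.ndarray) -> float:
    """Cross-entropy of the soft-routed leaf mixture (nats, mean)."""
    if tree.depth == 0:
        q = np.repeat(tree.leaf_posteriors, X.shape[0], axis=0)
    else:
        P, _ = _soft_leaf_probs(tree, X)
        q = P @ tree.leaf_posteriors
    return float(-np.log(np.clip(q[np.arange(len(y)), y.astype(int)],
                                 1e-300, None)).mean())


def _tree_gate_grads(tree: HierarchyTree, X: np.ndarray, y: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Gradients of the soft-routing cross-entropy w.r.t. gates."""
    n = X.shape[0]
    P, f = _soft_leaf_probs(tree, X)
    q = P @ tree.leaf_posteriors
    qy = np.clip(q[np.arange(n), y.astype(int)], 1e-300, None)
    loss = float(-np.log(qy).mean())
    # dL/dP[:, leaf] = -post[leaf, y] / q_y / n
    dP = -tree.leaf_posteriors[:, y.astype(int)].T / qy[:, None] / n
    df = np.zeros_like(f)
    for leaf, steps in enumerate(_leaf_paths(tree.depth)):
        for node, bit in steps:
            gate = f[:, node] if bit else (1.0 - f[:, node])
            sgn = 1.0 if bit else -1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(gate > 0, P[:, leaf] / gate, 0.0)
            df[:, node] += sgn * dP[:, leaf] * contrib
    dpre = df * f * (1.0 - f)
    dW = dpre.T @ X
    db = dpre.sum(axis=0)
    return dW, db, loss


def fit_tree(X_sel: np.ndarray, y: np.ndarray, n_classes: int, depth: int = 3,
             epochs: int = 200, lr: float = 0.5, seed: int = 0,
             restarts: int = 1) -> HierarchyTree:
    """Fit gates by gradient descent; leaves by smoothed hard-routing counts.

    Straight-through scheme: soft routing probabilities provide gradients for
    the gates; hard routing defines the leaf posteriors and predictions.
    With ``restarts > 1`` the gate optimization is repeated from different
    seeded initializations and the tree with the lowest soft-routing
    cross-entropy is kept (the objective is non-convex).
    """
    X = np.atleast_2d(np.asarray(X_sel, dtype=float))
    y = np.asarray(y)
    if restarts > 1:
        trees = [fit_tree(X, y, n_classes, depth, epochs, lr,
                          seed=seed + 7919 * r, restarts=1)
                 for r in range(restarts)]
        return min(trees, key=lambda t: tree_loss(t, X, y))
    if depth == 0:
        counts = np.ones(n_classes)
        for yi in y:
            counts[int(yi)] += 1
        return HierarchyTree(depth=0, weights=np.zeros((0, X.shape[1])),
                             biases=np.zeros(0),
                             leaf_posteriors=(counts / counts.sum())[None, :])
    rng = np.random.default_rng(seed)
    n_internal = 2 ** depth - 1
    tree = HierarchyTree(
        depth=depth,
        weights=rng.normal(0.0, 0.5, size=(n_internal, X.shape[1])),
        biases=np.zeros(n_internal),
        leaf_posteriors=np.full((2 ** depth, n_classes), 1.0 / n_classes))
    tree.leaf_posteriors = _hard_leaf_posteriors(tree, X, y, n_classes)
    for _ in range(epochs):
        dW, db, _ = _tree_gate_grads(tree, X, y)
        tree.weights -= lr * dW
        tree.biases -= lr * db
        tree.leaf_posteriors = _hard_leaf_posteriors(tree, X, y, n_classes)
    return tree


def tree_accuracy(tree: HierarchyTree, X: np.ndarray, y: np.ndarray) -> float:
    preds = [int(np.argmax(route(tree, xi)[2])) for xi in X]
    return float(np.mean(np.asarray(preds) == np.asarray(y)))


# --------------------------------------------------------------------------
# expert feedback
# --------------------------------------------------------------------------

def incorporate_feedback(target, corrections: Cohort, eta: float,
                         steps: int = 1) -> list[float]:
    """Refine a model or tree with plain gradient steps on expert corrections.

    Returns the loss trajectory (before each step plus after the last).  A
    warning is raised if a step failed to decrease the corrections loss —
    the step size is then too large for the local curvature.
    """
    if len(corrections) == 0:
        raise ValueError("empty corrections set")
    from .model import HemorrhageNet

    losses: list[float] = []
    if isinstance(target, HierarchyTree):
        X = np.stack([s.clinical for s in corrections.samples])
        y = np.array([s.class_label for s in corrections.samples])
        for _ in range(steps):
            dW, db, loss = _tree_gate_grads(target, X, y)
            losses.append(loss)
            target.weights -= eta * dW
            target.biases -= eta * db
        losses.append(tree_loss(target, X, y))
    elif isinstance(target, HemorrhageNet):
        images, clinical, y, p = corrections.arrays()
        for _ in range(steps):
            target.zero_grad()
            cache = target.forward(images, clinical, train=False)
            losses.append(target.loss_and_backward(cache, y, p))
            for par, g in zip(target.parameters(), target.gradients()):
                par -= eta * g
            target.iteration += 1
        cache = target.forward(images, clinical, train=False)
        from .model import joint_loss
        losses.append(joint_loss(cache["class_probs"], y, cache["prognosis"], p,
                                 target.config.lambda_prognosis))
    else:
        raise TypeError(f"cannot incorporate feedback into {type(target)!r}")
    if eta > 0 and losses[-1] > losses[0] + 1e-12:
        warnings.warn("corrections loss increased after feedback step; "
                      "consider a smaller learning rate", stacklevel=2)
    return losses
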