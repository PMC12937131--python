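"""HemorrhageNet: a multimodal image + clinical network with two task heads.

The image branch is a small configurable conv-batchnorm-ReLU-pool stack
producing a spatial feature map ``Z`` (H' x W' x C').  A spatial attention
layer scores every position with a shared channel projection ``W_att``,
normalizes the scores with a softmax over all positions (so the attention
mass sums to one) and reweights the map; the attended map is flattened into
``z``.  The clinical branch embeds the covariate vector through fully
connected layers; a fusion stack combines ``[z; F]`` into ``h``.

Two head wirings are supported:

* ``fused`` (default): both the K-way softmax classifier and the sigmoid
  prognosis head read the fused representation ``h``.
* ``literal``: the classifier reads ``z`` directly and the prognosis head
  reads the raw concatenation ``[z; F]`` — the minimal single-layer wiring.

The joint objective is ``L = CE + lambda * MSE`` (cross-entropy in nats),
optionally extended with an L1 sparsity term on the clinical gating weights
and a mean-entropy term (the hybrid loss used by the adaptive strategy).
Everything is differentiated by hand; ``backward`` also returns the gradient
of the loss with respect to the clinical inputs, which the dynamic feature
selection mechanism consumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .nn import (Adam, BatchNorm2D, Conv2D, Dense, Dropout, Flatten, MaxPool2D,
                 ReLU, Sequential)


@dataclass
class AttentionMap:
    """Nonnegative spatial weights over the feature grid, summing to one."""

    weights: np.ndarray      # (H', W')
    grid_stride: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("attention weights must be nonnegative")
        if abs(float(w.sum()) - 1.0) > 1e-6:
            raise ValueError(f"attention weights sum to {w.sum():.8f}, expected 1")
        self.weights = w


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def joint_loss(class_probs: np.ndarray, y: np.ndarray, prognosis_est: np.ndarray,
               p: np.ndarray, lam: float, reduction: str = "mean") -> float:
    """Multi-task loss: cross-entropy (nats) + lam * squared prognosis error.

    Missing targets (label < 0, prognosis NaN) contribute zero for that task.
    """
    class_probs = np.atleast_2d(np.asarray(class_probs, dtype=float))
    y = np.atleast_1d(np.asarray(y))
    prognosis_est = np.atleast_1d(np.asarray(prognosis_est, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    n = class_probs.shape[0]
    per = np.zeros(n)
    has_y = y >= 0
    if has_y.any():
        idx = np.flatnonzero(has_y)
        per[idx] += -np.log(np.clip(class_probs[idx, y[idx].astype(int)], 1e-300, None))
    has_p = ~np.isnan(p)
    if has_p.any():
        per[has_p] += lam * (prognosis_est[has_p] - p[has_p]) ** 2
    if reduction == "sum":
        return float(per.sum())
    if reduction == "none":
        return per
    return float(per.mean())


class HemorrhageNet:
    """Multimodal joint classification + prognosis network (numpy backend)."""

    def __init__(self, config: RunConfig, d_clin: int, seed: int | None = None):
        self.config = config
        self.d_clin = d_clin
        seed = config.seed if seed is None else seed
        rng = np.random.default_rng(seed)

        h, w = config.image_size
        blocks = []
        c_prev = 1
        for c in config.conv_channels:
            if h % 2 or w % 2:
                raise ValueError("image size must be divisible by 2 per conv block")
            blocks += [Conv2D(c_prev, c, 3, rng=rng), BatchNorm2D(c), ReLU(),
                       MaxPool2D(2)]
            h, w = h // 2, w // 2
            c_prev = c
        self.backbone = Sequential(*blocks)
        self.grid_shape = (h, w)
        self.grid_stride = config.image_size[0] // h
        self.c_feat = c_prev
        self.d_z = h * w * c_prev

        self.W_att = rng.normal(0.0, 1.0 / np.sqrt(c_prev), size=c_prev)
        self.dW_att = np.zeros_like(self.W_att)

        self.propagate = Conv2D(c_prev, c_prev, 3, rng=rng) if config.graph_propagation else None

        if config.head_mode == "fused":
            layers = []
            d_prev = d_clin
            for width in config.clinical_hidden:
                layers += [Dense(d_prev, width, rng=rng), ReLU()]
                d_prev = width
            self.clinical_branch = Sequential(*layers)
            self.d_clin_emb = d_prev
            fusion = []
            d_prev = self.d_z + self.d_clin_emb
            for width in config.fusion_hidden:
                fusion += [Dense(d_prev, width, rng=rng), ReLU(),
                           Dropout(config.dropout, rng=np.random.default_rng(seed + 1))]
                d_prev = width
            self.fusion = Sequential(*fusion)
            d_head = d_prev
            self.class_head = Dense(d_head, config.n_classes, rng=rng)
            self.prog_head = Dense(d_head, 1, rng=rng)
        else:  # literal: class <- z, prognosis <- [z; F]
            self.clinical_branch = None
            self.fusion = None
            self.class_head = Dense(self.d_z, config.n_classes, rng=rng)
            self.prog_head = Dense(self.d_z + d_clin, 1, rng=rng)

        self.iteration = 0

    # ----- parameter bookkeeping -------------------------------------------
    def _modules(self):
        mods = [self.backbone]
        if self.propagate is not None:
            mods.append(self.propagate)
        if self.clinical_branch is not None:
            mods.append(self.clinical_branch)
        if self.fusion is not None:
            mods.append(self.fusion)
        mods += [self.class_head, self.prog_head]
        return mods

    def parameters(self) -> list[np.ndarray]:
        out = [self.W_att]
        for m in self._modules():
            named = m.named_params() if isinstance(m, Sequential) else {
                k: (m, k) for k in m.params}
            out += [layer.params[k] for layer, k in named.values()]
        return out

    def gradients(self) -> list[np.ndarray]:
        out = [self.dW_att]
        for m in self._modules():
            named = m.named_params() if isinstance(m, Sequential) else {
                k: (m, k) for k in m.params}
            out += [layer.grads[k] for layer, k in named.values()]
        return out

    def zero_grad(self) -> None:
        self.dW_att = np.zeros_like(self.W_att)
        for m in self._modules():
            m.zero_grad()

    @property
    def gating_weights(self) -> np.ndarray:
        """The designated feature-gating weight matrix for the L1 penalty.

        Fused mode: the first clinical-branch layer; literal mode: the
        clinical slice of the prognosis head.
        """
        if self.clinical_branch is not None:
            return self.clinical_branch.layers[0].params["W"]
        return self.prog_head.params["W"][self.d_z:, :]

    # ----- forward pieces ---------------------------------------------------
    def encode_image(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, ..., None]
        elif x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != tuple(self.config.image_size):
            raise ValueError(f"expected images of size {self.config.image_size}, "
                             f"got {x.shape[1:3]}")
        return self.backbone.forward(x, train=train)

    def attend(self, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Softmax spatial attention: score each position, reweight channels."""
        scores = Z @ self.W_att                       # (N, H', W')
        if not np.isfinite(scores).all():
            raise FloatingPointError("non-finite attention scores")
        n, gh, gw = scores.shape
        A = softmax(scores.reshape(n, -1), axis=1).reshape(n, gh, gw)
        Z_att = A[..., None] * Z
        return A, Z_att

    def forward(self, images: np.ndarray, clinical: np.ndarray,
                train: bool = False) -> dict:
        F = np.atleast_2d(np.asarray(clinical, dtype=np.float64))
        Z = self.encode_image(images, train=train)
        A, Z_att = self.attend(Z)
        Z_head = Z_att
        if self.propagate is not None:
            Z_head = Z_att + self.propagate.forward(Z_att, train=train)
        z = Z_head.reshape(Z_head.shape[0], -1)

        cache = {"F": F, "Z": Z, "A": A, "Z_att": Z_att, "z": z, "train": train}
        if self.config.head_mode == "fused":
            F_emb = self.clinical_branch.forward(F, train=train)
            h = self.fusion.forward(np.concatenate([z, F_emb], axis=1), train=train)
            class_logits = self.class_head.forward(h, train=train)
            prog_pre = self.prog_head.forward(h, train=train)[:, 0]
            cache.update(F_emb=F_emb, h=h)
        else:
            class_logits = self.class_head.forward(z, train=train)
            prog_pre = self.prog_head.forward(
                np.concatenate([z, F], axis=1), train=train)[:, 0]
        cache["class_logits"] = class_logits
        cache["class_probs"] = softmax(class_logits, axis=1)
        cache["prog_pre"] = prog_pre
        cache["prognosis"] = sigmoid(prog_pre)
        return cache

    # convenience single-purpose APIs ---------------------------------------
    def classify(self, representation: np.ndarray) -> np.ndarray:
        """Softmax class posterior of the head over a given representation."""
        logits = self.class_head.forward(np.atleast_2d(representation))
        return softmax(logits, axis=1)

    def predict_prognosis(self, z: np.ndarray, F: np.ndarray) -> np.ndarray:
        """Sigmoid prognosis estimate from image features and covariates."""
        if self.config.head_mode != "literal":
            raise RuntimeError("direct [z; F] head only exists in literal mode")
        x = np.concatenate([np.atleast_2d(z), np.atleast_2d(F)], axis=1)
        return sigmoid(self.prog_head.forward(x)[:, 0])

    def fuse(self, z: np.ndarray, F: np.ndarray, train: bool = False) -> np.ndarray:
        if self.fusion is None:
            raise RuntimeError("literal mode has no fusion stack")
        F_emb = self.clinical_branch.forward(np.atleast_2d(F), train=train)
        return self.fusion.forward(
            np.concatenate([np.atleast_2d(z), F_emb], axis=1), train=train)

    def predict(self, images: np.ndarray, clinical: np.ndarray) -> dict:
        cache = self.forward(images, clinical, train=False)
        return {"class_probs": cache["class_probs"],
                "prognosis": cache["prognosis"],
                "attention": cache["A"]}

    def attention_maps(self, images: np.ndarray) -> list[AttentionMap]:
        Z = self.encode_image(images)
        A, _ = self.attend(Z)
        return [AttentionMap(weights=a, grid_stride=self.grid_stride) for a in A]

    # ----- loss + backward --------------------------------------------------
    def loss_and_backward(self, cache: dict, y: np.ndarray, p: np.ndarray,
                          lam: float | None = None, lambda_entropy: float = 0.0,
                          lambda_l1: float = 0.0,
                          reduction: str = "mean") -> float:
        """Accumulate parameter gradients for the (hybrid) joint loss.

        Returns the loss value.  With ``reduction='sum'`` the per-sample input
        gradient stored in ``cache['dF']`` equals each sample's own dL_i/dF_i.
        """
        probs = cache["class_probs"]
        prog = cache["prognosis"]
        n, k = probs.shape
        y = np.asarray(y)
        p = np.asarray(p, dtype=float)
        scale = 1.0 if reduction == "sum" else 1.0 / n

        loss = joint_loss(probs, y, prog, p, self.config.lambda_prognosis
                          if lam is None else lam, reduction=reduction)
        lam_eff = self.config.lambda_prognosis if lam is None else lam

        dlogits = np.zeros_like(probs)
        has_y = np.asarray(y) >= 0
        if has_y.any():
            onehot = np.zeros_like(probs)
            idx = np.flatnonzero(has_y)
            onehot[idx, y[idx].astype(int)] = 1.0
            dlogits[idx] = (probs[idx] - onehot[idx]) * scale

        if lambda_entropy > 0.0:
            logp = np.log(np.clip(probs, 1e-300, None))
            ent = -(probs * logp).sum(axis=1)
            loss += lambda_entropy * (float(ent.sum()) if reduction == "sum"
                                      else float(ent.mean()))
            dlogits += lambda_entropy * scale * (-probs * (logp + ent[:, None]))

        dprog_pre = np.zeros(n)
        has_p = ~np.isnan(p)
        if has_p.any():
            err = np.where(has_p, prog - np.nan_to_num(p), 0.0)
            dprog_pre = lam_eff * 2.0 * err * prog * (1.0 - prog) * scale

        if lambda_l1 > 0.0:
            loss += lambda_l1 * float(np.abs(self.gating_weights).sum())
            # L1 subgradient on the gating weights; the trainer additionally
            # soft-thresholds after the optimizer step for exact zeros
            if self.clinical_branch is not None:
                self.clinical_branch.layers[0].grads["W"] += \
                    lambda_l1 * np.sign(self.gating_weights)
            else:
                self.prog_head.grads["W"][self.d_z:, :] += \
                    lambda_l1 * np.sign(self.gating_weights)

        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss: {loss}")

        train = cache["train"]
        if self.config.head_mode == "fused":
            dh = self.class_head.backward(dlogits)
            dh += self.prog_head.backward(dprog_pre[:, None])
            dcat = self.fusion.backward(dh)
            dz = dcat[:, :self.d_z]
            dF_emb = dcat[:, self.d_z:]
            dF = self.clinical_branch.backward(dF_emb)
        else:
            dz = self.class_head.backward(dlogits)
            dcat = self.prog_head.backward(dprog_pre[:, None])
            dz = dz + dcat[:, :self.d_z]
            dF = dcat[:, self.d_z:]
        cache["dF"] = dF

        gh, gw = self.grid_shape
        dZ_head = dz.reshape(n, gh, gw, self.c_feat)
        if self.propagate is not None:
            dZ_att = dZ_head + self.propagate.backward(dZ_head)
        else:
            dZ_att = dZ_head

        # attention backward: Z_att = A (.) Z with A = softmax(Z W_att)
        Z, A = cache["Z"], cache["A"]
        dA = (dZ_att * Z).sum(axis=-1)                     # (N, H', W')
        dZ = A[..., None] * dZ_att
        flatA = A.reshape(n, -1)
        flatdA = dA.reshape(n, -1)
        ds = flatA * (flatdA - (flatA * flatdA).sum(axis=1, keepdims=True))
        ds = ds.reshape(n, gh, gw)
        dZ += ds[..., None] * self.W_att
        self.dW_att += np.einsum("nhw,nhwc->c", ds, Z)
        self.backbone.backward(dZ)
        return float(loss)

    # ----- checkpointing ----------------------------------------------------
    def _named_arrays(self) -> dict[str, np.ndarray]:
        arrays = {"W_att": self.W_att}
        for mi, m in enumerate(self._modules()):
            named = m.named_params() if isinstance(m, Sequential) else {
                k: (m, k) for k in m.params}
            for name, (layer, key) in named.items():
                arrays[f"m{mi}.{name}"] = layer.params[key]
            # batchnorm running statistics travel with the checkpoint
            layers = m.layers if isinstance(m, Sequential) else [m]
            for li, layer in enumerate(layers):
                if isinstance(layer, BatchNorm2D):
                    arrays[f"m{mi}.{li}.running_mean"] = layer.running_mean
                    arrays[f"m{mi}.{li}.running_var"] = layer.running_var
        return arrays

    def save(self, path, schema: list[str] | None = None) -> None:
        meta = {"config": self.config.to_dict(), "d_clin": self.d_clin,
                "iteration": self.iteration,
                "schema_hash": hashlib.sha256(
                    ",".join(schema or []).encode()).hexdigest()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self._named_arrays())

    @classmethod
    def load(cls, path) -> "HemorrhageNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            net = cls(RunConfig.from_dict(meta["config"]), meta["d_clin"])
            net.iteration = meta["iteration"]
            arrays = net._named_arrays()
            for name, arr in arrays.items():
                arr[...] = data[name]
        return net

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._named_arrays().items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self._named_arrays().items():
            v[...] = state[k]
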