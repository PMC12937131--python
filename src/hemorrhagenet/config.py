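"""Run configuration: model hyperparameters, loss weights, optimizer settings.

Optimizer defaults follow the common medical-imaging training recipe this
package targets: adaptive momentum (Adam) with beta1=0.9 / beta2=0.999, weight
decay 1e-4, global gradient-norm clipping at 5.0, mini-batches of 64, cosine
learning-rate decay and early stopping.  The desk-scale default image size is
32x32; 224x224 inputs are supported by the same backbone.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # data
    image_size: tuple[int, int] = (32, 32)
    n_classes: int = 3

    # architecture
    conv_channels: tuple[int, ...] = (8, 16, 32)   # one conv-bn-relu-pool block each
    clinical_hidden: tuple[int, ...] = (16,)
    fusion_hidden: tuple[int, ...] = (64,)
    dropout: float = 0.1
    head_mode: str = "fused"          # "fused": both heads read h; "literal": class<-z, prog<-[z;F]
    graph_propagation: bool = False   # extra 3x3 residual conv over the attended map

    # loss weights
    lambda_prognosis: float = 1.0     # balances regression vs classification
    lambda_class: float = 1.0
    lambda_reg: float = 1.0
    lambda_l1: float = 0.0            # sparsity weight on the clinical gating layer
    lambda_entropy: float = 0.0       # expected-uncertainty weight

    # thresholds
    relevance_threshold: float | None = None   # absolute tau; None -> top-quantile rule
    relevance_top_q: float = 0.25
    entropy_threshold: float | None = None     # delta; None -> ln(K)/2

    # optimizer
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 1e-4
    clip_norm: float = 5.0
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    cosine_schedule: bool = True

    # augmentation (opt-in)
    augment: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_prognosis < 0 or self.lambda_l1 < 0 or self.lambda_entropy < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.entropy_threshold is not None and self.entropy_threshold < 0:
            raise ValueError("entropy threshold must be >= 0")
        if self.head_mode not in ("fused", "literal"):
            raise ValueError("head_mode must be 'fused' or 'literal'")
        self.image_size = tuple(int(v) for v in self.image_size)
        self.conv_channels = tuple(int(v) for v in self.conv_channels)
        self.clinical_hidden = tuple(int(v) for v in self.clinical_hidden)
        self.fusion_hidden = tuple(int(v) for v in self.fusion_hidden)

    @property
    def delta(self) -> float:
        """Uncertainty flagging threshold; defaults to half the max entropy."""
        if self.entropy_threshold is not None:
            return self.entropy_threshold
        return 0.5 * math.log(self.n_classes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("image_size", "conv_channels", "clinical_hidden", "fusion_hidden"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
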