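"""Core data model: samples, cohorts and per-sample prediction records.

A :class:`Sample` pairs one grayscale image (2-D ``H x W`` in [0, 1]) with a
clinical covariate vector, an optional hemorrhage-type label in ``{0..K-1}``,
an optional prognosis target in [0, 1] and an optional binary lesion mask.
A :class:`Cohort` is an ordered collection sharing one covariate schema and a
train/val/test split assignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

SPLITS = ("train", "val", "test")


@dataclass
class Sample:
    id: str
    image: np.ndarray                   # (H, W) float in [0, 1]
    clinical: np.ndarray                # (d_clin,)
    class_label: int | None = None
    prognosis: float | None = None
    lesion_mask: np.ndarray | None = None
    imputed: np.ndarray | None = None   # boolean per-covariate imputation flags

    def validate(self, schema_len: int, n_classes: int) -> None:
        if self.image.ndim != 2 or min(self.image.shape) < 1:
            raise ValueError(f"sample {self.id}: image must be 2-D with positive dims")
        if self.clinical.shape != (schema_len,):
            raise ValueError(
                f"sample {self.id}: clinical length {self.clinical.shape} != schema {schema_len}")
        if self.class_label is not None and not (0 <= self.class_label < n_classes):
            raise ValueError(f"sample {self.id}: class label {self.class_label} >= K={n_classes}")
        if self.prognosis is not None and not (0.0 <= self.prognosis <= 1.0):
            raise ValueError(f"sample {self.id}: prognosis {self.prognosis} outside [0, 1]")
        if self.lesion_mask is not None and self.lesion_mask.shape != self.image.shape:
            raise ValueError(f"sample {self.id}: mask shape mismatch")


@dataclass
class Cohort:
    samples: list[Sample]
    schema: list[str]
    n_classes: int
    split_assignment: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not self.split_assignment:
            self.split_assignment = ["train"] * len(self.samples)
        if len(self.split_assignment) != len(self.samples):
            raise ValueError("split assignment length mismatch")
        for s in self.samples:
            s.validate(len(self.schema), self.n_classes)
        train_labels = {s.class_label for s, sp in zip(self.samples, self.split_assignment)
                        if sp == "train" and s.class_label is not None}
        missing = set(range(self.n_classes)) - train_labels
        if missing and any(sp == "train" for sp in self.split_assignment):
            warnings.warn(f"classes {sorted(missing)} absent from train split", stacklevel=2)

    def __len__(self) -> int:
        return len(self.samples)

    def split(self, name: str) -> "Cohort":
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        keep = [i for i, sp in enumerate(self.split_assignment) if sp == name]
        return Cohort([self.samples[i] for i in keep], self.schema, self.n_classes,
                      [name] * len(keep))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Stack into (images NHW1, clinical, labels, prognosis) arrays.

        Missing labels become -1, missing prognoses become NaN (both masked
        out of the loss downstream).
        """
        imgs = np.stack([s.image for s in self.samples])[..., None].astype(np.float64)
        clin = np.stack([s.clinical for s in self.samples]).astype(np.float64)
        y = np.array([-1 if s.class_label is None else s.class_label for s in self.samples])
        p = np.array([math.nan if s.prognosis is None else s.prognosis for s in self.samples])
        return imgs, clin, y, p


@dataclass
class PredictionRecord:
    """One sample's model output plus its uncertainty triage decision."""

    id: str
    class_probs: np.ndarray
    predicted_class: int
    prognosis_estimate: float
    uncertainty: float          # entropy of class_probs, in nats
    flagged: bool

    def __post_init__(self) -> None:
        self.class_probs = np.asarray(self.class_probs, dtype=float)
        k = self.class_probs.size
        if abs(float(self.class_probs.sum()) - 1.0) > 1e-6:
            raise ValueError(f"{self.id}: class_probs sum {self.class_probs.sum():.8f} != 1")
        if self.predicted_class != int(np.argmax(self.class_probs)):
            raise ValueError(f"{self.id}: predicted_class is not the argmax")
        if not (-1e-12 <= self.uncertainty <= math.log(k) + 1e-9):
            raise ValueError(f"{self.id}: entropy {self.uncertainty} outside [0, ln K]")

    @classmethod
    def from_probs(cls, id: str, class_probs: np.ndarray, prognosis_estimate: float,
                   delta: float) -> "PredictionRecord":
        from .strategy import entropy  # local import avoids a cycle
        p = np.asarray(class_probs, dtype=float)
        u = float(entropy(p[None, :])[0])
        return cls(id=id, class_probs=p, predicted_class=int(np.argmax(p)),
                   prognosis_estimate=float(prognosis_estimate),
                   uncertainty=u, flagged=bool(u > delta))
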