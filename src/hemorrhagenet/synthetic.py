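"""Synthetic desk-scale hemorrhage cohorts with planted, recoverable signal.

Each image is a smooth low-frequency background plus Gaussian pixel noise and
one bright elliptical blob standing in for a hemorrhagic lesion.  The class
label is the lesion's *location stratum*: the image is partitioned into K
equal-width vertical bands (mirroring location-based subtype conventions such
as lobar / deep / infratentorial) and the band holding the lesion centre
defines the class.  The prognosis target is a clipped linear function of the
lesion area fraction and a latent severity variable; "informative" clinical
covariates (emulating GCS, blood pressure, age and similar bedside measures)
load on that latent severity with a configurable effect size while nuisance
covariates are independent standard normals.  All randomness flows from the
spec seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, Sample

logger = logging.getLogger(__name__)

# linear model for the prognosis target (before clipping to [0, 1])
_PROG_INTERCEPT = 0.5
_PROG_AREA_COEF = 0.15      # per SD of lesion area fraction
_PROG_SEVERITY_COEF = 0.15  # per SD of latent clinical severity


@dataclass
class SimSpec:
    n: int = 60
    image_size: tuple[int, int] = (32, 32)
    n_classes: int = 3
    lesion_radius_range: tuple[float, float] = (3.0, 6.0)
    lesion_intensity_lift: float = 0.3
    n_informative_clin: int = 5
    n_nuisance_clin: int = 5
    effect_size: float = 1.5
    noise_sd: float = 0.05          # pixel noise
    prognosis_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.lesion_radius_range[0] > self.lesion_radius_range[1]:
            raise ValueError("lesion_radius_range must be (lo, hi)")
        if not (0.0 <= self.lesion_intensity_lift <= 1.0):
            raise ValueError("lesion_intensity_lift must lie in [0, 1]")

    @property
    def d_clin(self) -> int:
        return self.n_informative_clin + self.n_nuisance_clin


def _smooth_background(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Low-frequency intensity field in roughly [0.15, 0.45]."""
    yy, xx = np.mgrid[0:h, 0:w]
    fy, fx = rng.uniform(0.5, 1.5, size=2)
    phase_y, phase_x = rng.uniform(0, 2 * np.pi, size=2)
    field = (np.sin(2 * np.pi * fy * yy / h + phase_y)
             + np.sin(2 * np.pi * fx * xx / w + phase_x)) / 4.0
    return 0.3 + 0.15 * field


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def stratum_bounds(width: int, n_classes: int, k: int) -> tuple[int, int]:
    """Half-open column range [lo, hi) of vertical stratum ``k``."""
    edges = np.linspace(0, width, n_classes + 1)
    return int(np.floor(edges[k])), int(np.floor(edges[k + 1]))


def generate_cohort(spec: SimSpec) -> Cohort:
    """Generate a labelled cohort with lesion masks; deterministic given seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    r_lo, r_hi = spec.lesion_radius_range
    if 2 * r_hi >= min(h, w):
        raise ValueError(f"lesion (radius up to {r_hi}) cannot fit in a {h}x{w} image")

    n = spec.n
    labels = np.arange(n) % spec.n_classes
    rng.shuffle(labels)

    # latent clinical severity and covariates
    severity = rng.normal(size=n)
    informative = spec.effect_size * severity[:, None] + rng.normal(
        size=(n, spec.n_informative_clin))
    nuisance = rng.normal(size=(n, spec.n_nuisance_clin))
    clinical = np.concatenate([informative, nuisance], axis=1)
    schema = [f"inf_{j}" for j in range(spec.n_informative_clin)] + \
             [f"nui_{j}" for j in range(spec.n_nuisance_clin)]

    images, masks, areas = [], [], []
    for i in range(n):
        ry, rx = rng.uniform(r_lo, r_hi, size=2)
        theta = rng.uniform(0, np.pi)
        rmax = max(ry, rx)
        lo, hi = stratum_bounds(w, spec.n_classes, int(labels[i]))
        # centre stays inside its stratum (defines the class / centroid
        # invariant); the full blob only needs to fit inside the image
        c_lo = max(lo + 0.5, rmax)
        c_hi = min(hi - 0.5, w - 1 - rmax)
        if c_hi < c_lo:
            raise ValueError(
                f"lesion of radius {rmax:.1f} cannot fit with its centre in "
                f"stratum {labels[i]} (columns [{lo},{hi})) of a {h}x{w} image")
        cx = rng.uniform(c_lo, c_hi)
        cy = rng.uniform(rmax, h - 1 - rmax)
        mask = _ellipse_mask(h, w, cy, cx, ry, rx, theta)
        img = _smooth_background(rng, h, w)
        img = img + spec.lesion_intensity_lift * mask
        img = img + rng.normal(0.0, spec.noise_sd, size=(h, w))
        images.append(np.clip(img, 0.0, 1.0))
        masks.append(mask.astype(np.uint8))
        areas.append(mask.mean())

    areas = np.asarray(areas)
    z_area = (areas - areas.mean()) / (areas.std() if areas.std() > 0 else 1.0)
    raw_prog = (_PROG_INTERCEPT + _PROG_AREA_COEF * z_area
                + _PROG_SEVERITY_COEF * severity
                + rng.normal(0.0, spec.prognosis_noise_sd, size=n))
    prognosis = np.clip(raw_prog, 0.0, 1.0)
    clip_rate = float(np.mean(raw_prog != prognosis))
    if clip_rate > 0:
        logger.info("prognosis clipping rate: %.3f", clip_rate)

    # 70/15/15 split, seeded
    order = rng.permutation(n)
    n_train = max(int(round(0.7 * n)), 1)
    n_val = max(int(round(0.15 * n)), 1)
    splits = np.empty(n, dtype=object)
    splits[order[:n_train]] = "train"
    splits[order[n_train:n_train + n_val]] = "val"
    splits[order[n_train + n_val:]] = "test"
    if not (splits == "test").any():
        splits[order[-1]] = "test"

    samples = [
        Sample(id=f"s{i:04d}", image=images[i], clinical=clinical[i],
               class_label=int(labels[i]), prognosis=float(prognosis[i]),
               lesion_mask=masks[i])
        for i in range(n)
    ]
    return Cohort(samples, schema=schema, n_classes=spec.n_classes,
                  split_assignment=list(splits))


def generate_corrections(cohort: Cohort, fraction: float, seed: int = 0) -> Cohort:
    """Random labelled subsample standing in for expert-corrected cases."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    labelled = [i for i, s in enumerate(cohort.samples) if s.class_label is not None]
    if not labelled:
        raise ValueError("cohort has no labelled samples")
    rng = np.random.default_rng(seed)
    m = max(int(round(fraction * len(labelled))), 1)
    chosen = sorted(rng.choice(labelled, size=m, replace=False))
    return Cohort([cohort.samples[i] for i in chosen], cohort.schema,
                  cohort.n_classes, ["train"] * m)
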