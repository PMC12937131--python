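"""Cohort, prediction and attention-overlay input/output.

Cohort layout on disk::

    <root>/
      clinical.csv          # id, class, prognosis, [split], covariate columns
      images/<id>.png       # or .nii / .nii.gz
      masks/<id>.png        # optional binary lesion masks

Covariates are z-scored on load using *train-split* statistics only; missing
cells are imputed with the train mean and flagged per cell.  Images are
resized to the configured target and min-max scaled to [0, 1].
"""

from __future__ import annotations

import csv
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .cohort import SPLITS, Cohort, PredictionRecord, Sample
from .config import RunConfig

RESERVED_COLUMNS = ("id", "class", "prognosis", "split")


def _find_image(image_dir: Path, sample_id: str) -> Path:
    for ext in (".png", ".nii.gz", ".nii"):
        p = image_dir / f"{sample_id}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no image for id {sample_id!r} under {image_dir}")


def load_image(path: Path, target_size: tuple[int, int]) -> np.ndarray:
    """Read a PNG or NIfTI image as a 2-D float array, resized, scaled to [0,1].

    3-D NIfTI volumes are reduced to their middle slice along the last axis.
    """
    path = Path(path)
    if path.suffix == ".png":
        try:
            arr = np.asarray(Image.open(path), dtype=np.float64)
        except Exception as exc:  # noqa: BLE001 - rewrap with the offending file
            raise OSError(f"unreadable image {path}: {exc}") from exc
        if arr.ndim == 3:  # RGB(A) -> luminance
            arr = arr[..., :3].mean(axis=-1)
    else:
        import nibabel as nib
        try:
            vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"unreadable image {path}: {exc}") from exc
        vol = np.squeeze(vol)
        if vol.ndim == 3:
            vol = vol[:, :, vol.shape[2] // 2]
        if vol.ndim != 2:
            raise OSError(f"{path}: cannot reduce {vol.ndim}-D volume to a slice")
        arr = vol
    if arr.shape != tuple(target_size):
        arr = resize(arr, target_size, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        arr = (arr - lo) / (hi - lo)
    else:
        arr = np.zeros_like(arr)
    return arr


def read_cohort(image_dir: str | Path, clinical_table: str | Path,
                config: RunConfig, normalize: bool = True) -> Cohort:
    """Assemble a :class:`Cohort` from an image directory and a clinical CSV.

    The table must contain ``id``, ``class``, ``prognosis`` and at least one
    covariate column; an optional ``split`` column assigns train/val/test
    (default: all train).  With ``normalize=True`` covariates are z-scored
    using train-split mean/sd and missing cells are train-mean imputed.
    """
    image_dir = Path(image_dir)
    df = pd.read_csv(clinical_table)
    for col in ("id", "class", "prognosis"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    covars = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not covars:
        raise ValueError("clinical table has no covariate columns")
    ids = df["id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate ids in clinical table: {dupes}")

    if "split" in df.columns:
        splits = df["split"].astype(str).tolist()
        bad = sorted(set(splits) - set(SPLITS))
        if bad:
            raise ValueError(f"unknown split labels: {bad}")
    else:
        splits = ["train"] * len(df)

    X = df[covars].to_numpy(dtype=np.float64)
    imputed = np.isnan(X)
    if normalize:
        train_rows = np.array([s == "train" for s in splits])
        if not train_rows.any():
            train_rows = np.ones(len(df), dtype=bool)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(X[train_rows], axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        X = np.where(imputed, mu, X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = X[train_rows].std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    else:
        X = np.where(imputed, 0.0, X)

    mask_dir = image_dir.parent / "masks" if image_dir.name == "images" else None
    samples = []
    for i, sid in enumerate(ids):
        img = load_image(_find_image(image_dir, sid), config.image_size)
        raw_label = df["class"].iloc[i]
        label = None if pd.isna(raw_label) else int(raw_label)
        if label is not None and label >= config.n_classes:
            raise ValueError(f"id {sid}: class label {label} >= K={config.n_classes}")
        raw_p = df["prognosis"].iloc[i]
        prog = None if pd.isna(raw_p) else float(raw_p)
        mask = None
        if mask_dir is not None:
            mp = mask_dir / f"{sid}.png"
            if mp.exists():
                m = np.asarray(Image.open(mp), dtype=np.float64)
                if m.shape != tuple(config.image_size):
                    m = resize(m, config.image_size, order=0, preserve_range=True)
                mask = (m > 0).astype(np.uint8)
        samples.append(Sample(id=sid, image=img, clinical=X[i],
                              class_label=label, prognosis=prog,
                              lesion_mask=mask, imputed=imputed[i]))
    return Cohort(samples, schema=covars, n_classes=config.n_classes,
                  split_assignment=splits)


def write_cohort(cohort: Cohort, root: str | Path) -> Path:
    """Write a cohort in the standard layout (16-bit PNGs + clinical.csv)."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    has_masks = any(s.lesion_mask is not None for s in cohort.samples)
    if has_masks:
        (root / "masks").mkdir(exist_ok=True)
    rows = []
    for s, sp in zip(cohort.samples, cohort.split_assignment):
        img16 = np.clip(s.image, 0.0, 1.0)
        Image.fromarray((img16 * 65535).round().astype(np.uint16)).save(
            root / "images" / f"{s.id}.png")
        if s.lesion_mask is not None:
            Image.fromarray((s.lesion_mask > 0).astype(np.uint8) * 255).save(
                root / "masks" / f"{s.id}.png")
        row = {"id": s.id,
               "class": "" if s.class_label is None else s.class_label,
               "prognosis": "" if s.prognosis is None else s.prognosis,
               "split": sp}
        row.update({name: val for name, val in zip(cohort.schema, s.clinical)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(root / "clinical.csv", index=False)
    return root


def write_predictions(records: list[PredictionRecord], path: str | Path) -> Path:
    """Write prediction records as a CSV; order preserved."""
    if not records:
        raise ValueError("no prediction records to write")
    k = records[0].class_probs.size
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id"] + [f"p_{j}" for j in range(k)]
                   + ["predicted_class", "prognosis", "uncertainty", "flagged"])
        for r in records:
            w.writerow([r.id] + [f"{p:.10g}" for p in r.class_probs]
                       + [r.predicted_class, f"{r.prognosis_estimate:.10g}",
                          f"{r.uncertainty:.10g}", int(r.flagged)])
    return path


def read_predictions(path: str | Path, delta: float | None = None) -> list[PredictionRecord]:
    df = pd.read_csv(path)
    pcols = [c for c in df.columns if c.startswith("p_")]
    out = []
    for _, row in df.iterrows():
        out.append(PredictionRecord(
            id=str(row["id"]),
            class_probs=row[pcols].to_numpy(dtype=float),
            predicted_class=int(row["predicted_class"]),
            prognosis_estimate=float(row["prognosis"]),
            uncertainty=float(row["uncertainty"]),
            flagged=bool(int(row["flagged"]))))
    return out


def write_attention_overlay(sample: Sample, attention, path: str | Path,
                            alpha: float = 0.45) -> Path:
    """Render an attention heatmap over the sample image and save as PNG.

    The map is bilinearly upsampled to the image grid (grid position (a, b)
    covering the half-open block ``[a*s,(a+1)*s) x [b*s,(b+1)*s)``), colored
    with a perceptually uniform colormap and alpha-blended over the grayscale
    image.  The raw map is written alongside as ``<path>.npy``.
    """
    from matplotlib import cm

    h, w = sample.image.shape
    A = np.asarray(attention.weights, dtype=float)
    gh, gw = A.shape
    if h % gh or w % gw:
        raise ValueError(f"attention grid {A.shape} does not divide image {sample.image.shape}")
    heat = resize(A, (h, w), order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)
    rng = heat.max() - heat.min()
    heat_n = (heat - heat.min()) / rng if rng > 0 else np.zeros_like(heat)
    rgba = cm.magma(heat_n)[..., :3]
    gray = np.repeat(sample.image[..., None], 3, axis=-1)
    blend = (1 - alpha) * gray + alpha * rgba
    path = Path(path)
    Image.fromarray((np.clip(blend, 0, 1) * 255).round().astype(np.uint8)).save(path)
    np.save(str(path) + ".npy", A)
    return path
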