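"""Cohort-level evaluation: classification metrics, prognosis error, triage view.

Classification metrics are macro-averaged (equal class weight); classes absent
from both truth and prediction are excluded from the macro mean, and a class
with no predicted positives gets precision 0 with a warning.  Prognosis error
is reported as MSE and MAE.  ``evaluate_cohort`` additionally reports the same
metrics over the unflagged subset only (the triage utility view) — both values
are recorded without asserting that exclusion helps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .cohort import Cohort, PredictionRecord


@dataclass
class MetricsReport:
    n: int
    accuracy: float | None = None
    macro_precision: float | None = None
    macro_recall: float | None = None
    macro_f1: float | None = None
    confusion: np.ndarray | None = None
    mse: float | None = None
    mae: float | None = None
    flagged_fraction: float | None = None
    unflagged: "MetricsReport | None" = None
    note: str = "macro averaging; classes absent from truth and prediction excluded"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("confusion", "unflagged")}
        d["confusion"] = None if self.confusion is None else self.confusion.tolist()
        d["unflagged"] = None if self.unflagged is None else self.unflagged.to_dict()
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_table(self) -> str:
        """Aligned two-column text table, percentages to 2 decimals."""
        rows = [("n evaluated", f"{self.n}")]
        for label, val in (("accuracy", self.accuracy),
                           ("macro precision", self.macro_precision),
                           ("macro recall", self.macro_recall),
                           ("macro F1", self.macro_f1)):
            if val is not None:
                rows.append((label, f"{100 * val:.2f}%"))
        for label, val in (("prognosis MSE", self.mse), ("prognosis MAE", self.mae)):
            if val is not None:
                rows.append((label, f"{val:.4f}"))
        if self.flagged_fraction is not None:
            rows.append(("flagged fraction", f"{100 * self.flagged_fraction:.2f}%"))
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)


def classification_metrics(y_true, y_pred, n_classes: int) -> MetricsReport:
    """Accuracy, macro precision/recall/F1 and the K x K confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label sequences must be equal-length and non-empty")
    labels = np.arange(n_classes)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    present = np.union1d(np.unique(y_true), np.unique(y_pred))
    no_pred = [int(c) for c in present if (y_pred == c).sum() == 0]
    if no_pred:
        warnings.warn(f"classes {no_pred} never predicted; precision set to 0",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=present, zero_division=0)
    return MetricsReport(
        n=int(y_true.size),
        accuracy=float(np.trace(cm) / y_true.size),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=cm)


def regression_metrics(p_true, p_est) -> tuple[float, float]:
    """Prognosis (MSE, MAE)."""
    p_true = np.asarray(p_true, dtype=float)
    p_est = np.asarray(p_est, dtype=float)
    if p_true.shape != p_est.shape or p_true.size == 0:
        raise ValueError("prognosis vectors must be equal-length and non-empty")
    err = p_est - p_true
    return float(np.mean(err ** 2)), float(np.mean(np.abs(err)))


def predict_records(model, cohort: Cohort, delta: float | None = None
                    ) -> list[PredictionRecord]:
    """Run the model over a cohort and build per-sample prediction records."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    delta = model.config.delta if delta is None else delta
    images, clinical, _, _ = cohort.arrays()
    records = []
    for lo in range(0, len(cohort), 256):
        sl = slice(lo, min(lo + 256, len(cohort)))
        out = model.predict(images[sl], clinical[sl])
        for s, probs, prog in zip(cohort.samples[sl], out["class_probs"],
                                  out["prognosis"]):
            records.append(PredictionRecord.from_probs(
                s.id, probs, float(prog), delta))
    return records


def evaluate_cohort(model, cohort_split: Cohort, delta: float | None = None,
                    records: list[PredictionRecord] | None = None
                    ) -> tuple[MetricsReport, list[PredictionRecord]]:
    """Metrics over a split plus the flagged-excluded triage variant."""
    if records is None:
        records = predict_records(model, cohort_split, delta=delta)

    def _subset_report(keep: list[int]) -> MetricsReport:
        y_t = [cohort_split.samples[i].class_label for i in keep]
        ok = [i for i, y in zip(keep, y_t) if y is not None]
        rep = MetricsReport(n=len(ok))
        if ok:
            rep = classification_metrics(
                [cohort_split.samples[i].class_label for i in ok],
                [records[i].predicted_class for i in ok],
                cohort_split.n_classes)
        prog_idx = [i for i in keep if cohort_split.samples[i].prognosis is not None]
        if prog_idx:
            rep.mse, rep.mae = regression_metrics(
                [cohort_split.samples[i].prognosis for i in prog_idx],
                [records[i].prognosis_estimate for i in prog_idx])
        return rep

    everything = list(range(len(records)))
    report = _subset_report(everything)
    report.flagged_fraction = float(np.mean([r.flagged for r in records]))
    unflagged = [i for i in everything if not records[i].flagged]
    if unflagged:
        report.unflagged = _subset_report(unflagged)
    return report, records


def attention_enrichment(model, cohort_split: Cohort) -> float:
    """Mean lesion-localization enrichment of the attention maps.

    For each sample with a lesion mask, the attention map is spread uniformly
    within each grid cell to pixel resolution and the attention mass falling
    inside the mask is divided by the mask's area fraction; 1 means no
    localization, >1 means the model attends preferentially to the lesion.
    """
    images, _, _, _ = cohort_split.arrays()
    maps = model.attention_maps(images[..., 0])
    s = model.grid_stride
    ratios = []
    for amap, sample in zip(maps, cohort_split.samples):
        if sample.lesion_mask is None or not sample.lesion_mask.any():
            continue
        pix = np.kron(amap.weights, np.ones((s, s))) / (s * s)
        mask = sample.lesion_mask.astype(bool)
        ratios.append(float(pix[mask].sum() / mask.mean()))
    if not ratios:
        raise ValueError("no lesion masks in split")
    return float(np.mean(ratios))


def aggregate_reports(reports: list[MetricsReport]) -> dict:
    """Mean +/- sd across repeated seeded runs, per metric."""
    out = {}
    for key in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                "mse", "mae", "flagged_fraction"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        if vals:
            out[key] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals)),
                        "n_runs": len(vals)}
    return out
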