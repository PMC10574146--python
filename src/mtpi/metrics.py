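"""Pixel-level segmentation metrics: confusion matrices and prevalence-weighted scores.

The five scores reported throughout the package — WPA (weighted pixel
accuracy/precision), WRE (weighted recall), WF1, WIoU and WKs (Cohen kappa)
— are computed from a single C x C pixel-count confusion matrix. Per-class
precision, recall, F1 and IoU are combined with weights ``pi`` equal to each
class's pixel prevalence in the ground truth, so frequent classes dominate
exactly in proportion to their area. A plain macro (1/C) average is
available for comparison via ``weighting="macro"``.

Cohen's kappa uses the standard chance-corrected form
``(Po - Pe) / (1 - Pe)`` with ``Po`` the observed agreement (trace/total)
and ``Pe`` the expected agreement from the marginals; an alternative
``denominator="po"`` variant dividing by ``(1 - Po)`` is kept selectable
for comparison with sources that print that form.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

N_CLASSES = 4

#: kappa agreement bands; each entry is the inclusive upper edge of the band
KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C pixel-count table; ``counts[r, c]`` = pixels of true class c predicted as r.

    Class ids are 1-based externally (1..C); row/column 0 of ``counts``
    holds class 1.
    """

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    # per-class pixel tallies; index i is class i+1
    @property
    def tpp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fpp(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tpp

    @property
    def fnp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tpp

    @property
    def tnp(self) -> np.ndarray:
        return self.total - self.tpp - self.fpp - self.fnp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)

    def normalized(self) -> np.ndarray:
        """Row-normalised percentages: share of each true class within a predicted class."""
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(row > 0, 100.0 * self.counts / row, 0.0)
        return out


@dataclass(frozen=True)
class MetricReport:
    """The five weighted scores plus the intermediates they are built from."""

    wpa: float
    wre: float
    wf1: float
    wiou: float
    wks: float
    pi: np.ndarray = field(repr=False)
    po: float = 0.0
    pe: float = 0.0
    kappa_band: str = ""

    def as_dict(self) -> dict:
        return {
            "WPA": self.wpa,
            "WRE": self.wre,
            "WF1": self.wf1,
            "WIoU": self.wiou,
            "WKs": self.wks,
            "Po": self.po,
            "Pe": self.pe,
            "kappa_band": self.kappa_band,
            "pi": [float(p) for p in self.pi],
        }


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, n_classes: int = N_CLASSES) -> ConfusionMatrix:
    """Accumulate a pixel confusion matrix from paired class maps (values 1..C)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    for name, arr in (("pred", pred), ("truth", truth)):
        if arr.size and (arr.min() < 1 or arr.max() > n_classes):
            raise ValueError(f"{name} contains class ids outside 1..{n_classes}")
    idx = (pred.ravel().astype(np.int64) - 1) * n_classes + (truth.ravel().astype(np.int64) - 1)
    counts = np.bincount(idx, minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    return ConfusionMatrix(counts)


def class_prevalence(source) -> np.ndarray:
    """Per-class pixel share ``pi`` (sums to 1), from a ConfusionMatrix or raw labels.

    From a confusion matrix the ground-truth marginal (column sums) is used,
    so prevalence computed from an accumulated matrix matches prevalence
    computed from the raw label rasters.
    """
    if isinstance(source, ConfusionMatrix):
        counts = source.counts.sum(axis=0).astype(np.float64)
    else:
        labels = np.asarray(source)
        if labels.size == 0:
            raise ValueError("cannot compute prevalence of an empty label set")
        counts = np.bincount(labels.ravel().astype(np.int64) - 1, minlength=N_CLASSES).astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot compute prevalence: no labelled pixels")
    return counts / total


def kappa(cm: ConfusionMatrix, denominator: str = "pe") -> tuple[float, float, float, str]:
    """Cohen's kappa of a confusion matrix.

    Returns ``(wks, po, pe, band)``. ``denominator="pe"`` is the standard
    chance-corrected form (Po - Pe)/(1 - Pe); ``denominator="po"`` divides by
    (1 - Po) instead. A degenerate matrix with Pe == 1 (all mass in a single
    class on both axes) yields kappa 0 with a warning.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    po = float(np.trace(cm.counts)) / total
    row = cm.counts.sum(axis=1).astype(np.float64)
    col = cm.counts.sum(axis=0).astype(np.float64)
    pe = float((row * col).sum()) / (total * total)
    denom = (1.0 - pe) if denominator == "pe" else (1.0 - po)
    if abs(denom) < 1e-15:
        warnings.warn("degenerate confusion matrix (denominator 0); kappa set to 0")
        wks = 0.0
    else:
        wks = (po - pe) / denom
    band = kappa_band(wks)
    return wks, po, pe, band


def kappa_band(wks: float) -> str:
    """Agreement band for a kappa value; negative values fall in the lowest band."""
    for upper, name in KAPPA_BANDS:
        if wks <= upper:
            return name
    return KAPPA_BANDS[-1][1]


def weighted_metrics(
    cm: ConfusionMatrix,
    weighting: str = "prevalence",
    kappa_denominator: str = "pe",
) -> MetricReport:
    """All five weighted scores of a confusion matrix.

    Per-class precision TPP/(TPP+FPP), recall TPP/(TPP+FNP),
    F1 = 2PR/(P+R) and IoU = TPP/(TPP+FPP+FNP) are combined with
    prevalence weights ``pi`` (or uniform 1/C when ``weighting="macro"``).
    A class whose denominator is empty (never predicted and never present,
    for precision; never present, for recall) contributes 0 and is logged.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if weighting not in ("prevalence", "macro"):
        raise ValueError(f"unknown weighting {weighting!r}")
    tpp = cm.tpp.astype(np.float64)
    fpp = cm.fpp.astype(np.float64)
    fnp = cm.fnp.astype(np.float64)

    def _safe(num, den, what):
        out = np.zeros_like(num)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        if not ok.all():
            bad = [i + 1 for i in np.flatnonzero(~ok)]
            logger.warning("classes %s have empty %s denominator; contributing 0", bad, what)
        return out

    precision = _safe(tpp, tpp + fpp, "precision")
    recall = _safe(tpp, tpp + fnp, "recall")
    pr_sum = precision + recall
    f1 = np.where(pr_sum > 0, 2.0 * precision * recall / np.where(pr_sum > 0, pr_sum, 1.0), 0.0)
    iou = _safe(tpp, tpp + fpp + fnp, "IoU")

    pi = class_prevalence(cm)
    w = pi if weighting == "prevalence" else np.full(cm.n_classes, 1.0 / cm.n_classes)
    wks, po, pe, band = kappa(cm, denominator=kappa_denominator)
    return MetricReport(
        wpa=float((w * precision).sum()),
        wre=float((w * recall).sum()),
        wf1=float((w * f1).sum()),
        wiou=float((w * iou).sum()),
        wks=wks,
        pi=pi,
        po=po,
        pe=pe,
        kappa_band=band,
    )


def write_report(report: MetricReport, cm: ConfusionMatrix, out_prefix) -> None:
    """Write a metric report as JSON plus the row-normalised confusion matrix as CSV."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    norm = cm.normalized()
    with open(out_prefix.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["predicted\\true"] + [f"class{i + 1}" for i in range(cm.n_classes)])
        for r in range(cm.n_classes):
            writer.writerow([f"class{r + 1}"] + [f"{norm[r, c]:.2f}" for c in range(cm.n_classes)])
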