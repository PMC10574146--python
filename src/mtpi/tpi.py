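"""The MTPI core: layer probing, transfer-potential scoring and condition solving.

For a pre-trained network and a candidate transfer dataset, each transfer
point (TP) x gets a transfer potential index

    TPI(x) = TPI_WKs(x) / TPI_TP(x)

where ``TPI_WKs`` scores how class-discriminative the layer-x features
already are on the new data (a kappa on a feature-probe segmentation,
clipped to [0, 1]) and ``TPI_TP`` is a discrete time-cost level in
{1..Nlevel} derived from the parameter count that would remain trainable
when freezing at x. The selected TP0 maximises TPI (ties break toward the
deeper, cheaper point), and the transfer dataset size follows the linear
rule TDS0 = k_pre * LS_TP0 with k_pre = TDS_pre / LS_pre, the data-per-
parameter ratio that was demonstrably sufficient during pre-training.

Feature probing: activations at TP x are captured, bilinearly upsampled to
label resolution, and each channel is assigned to the class maximising its
standardised in-class contrast (mean inside minus mean outside, over the
global activation spread) on a calibration subset; a pixel's class score is
the mean of the channels assigned to that class and the prediction is the
per-pixel argmax. A least-squares linear read-out over channels is the
selectable alternative (``rule="linear"``). Both are interpretations of
feature-map class discriminability; calibration and evaluation subsets are
always disjoint.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import N_CLASSES, confusion_matrix, weighted_metrics
from .nets import TrainedNet, _standardise, enumerate_tps, layer_sizes

logger = logging.getLogger(__name__)

#: screening thresholds on WKs: above -> keep the pre-trained net as is,
#: below -> transfer training; the band in between is left to the operator.
SKIP_WKS = 0.8
TRANSFER_WKS = 0.6

DEFAULT_NLEVEL = 10


@dataclass(frozen=True)
class ProbeConfig:
    calibration_n: int = 50
    eval_n: int = 200
    rule: str = "standardized"   # or "linear"
    batch: int = 16
    max_fit_pixels: int = 200_000
    seed: int = 0

    def __post_init__(self):
        if self.rule not in ("standardized", "linear"):
            raise ValueError(f"unknown probe rule {self.rule!r}")
        if self.calibration_n < 1 or self.eval_n < 1:
            raise ValueError("calibration_n and eval_n must be >= 1")


@dataclass
class TpiRecord:
    x: int
    lsx: int
    tpi_tp: int
    tpi_wks: float
    tpi: float


@dataclass
class TpiCurve:
    records: list
    nlevel: int = DEFAULT_NLEVEL
    dataset_id: str = ""

    def __len__(self):
        return len(self.records)

    @property
    def tps(self):
        return [r.x for r in self.records]

    @property
    def values(self):
        return [r.tpi for r in self.records]


@dataclass
class MtpiCondition:
    tp0: int
    tds0: int
    kpre: float
    kt: float
    tds_pre: int
    ls_pre: int
    ls_tp0: int
    capped: bool = False


@dataclass
class ScreenDecision:
    decision: str   # skip | transfer | borderline
    wks: float


# ----------------------------------------------------------- feature probing

def _upsample_bilinear(act: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear upsample of (n, h, w, c) activations (align-corners)."""
    n, h, w, c = act.shape
    if (h, w) == (out_h, out_w):
        return act
    ys = np.linspace(0.0, h - 1.0, out_h)
    xs = np.linspace(0.0, w - 1.0, out_w)
    y0 = np.minimum(ys.astype(np.int64), h - 2)
    x0 = np.minimum(xs.astype(np.int64), w - 2)
    wy = (ys - y0).astype(act.dtype)
    wx = (xs - x0).astype(act.dtype)
    a = act[:, y0][:, :, x0]
    b = act[:, y0][:, :, x0 + 1]
    cc = act[:, y0 + 1][:, :, x0]
    d = act[:, y0 + 1][:, :, x0 + 1]
    wy = wy[None, :, None, None]
    wx = wx[None, None, :, None]
    return (a * (1 - wy) * (1 - wx) + b * (1 - wy) * wx
            + cc * wy * (1 - wx) + d * wy * wx)


def _captured_activations(net: TrainedNet, x: int, scenes, batch: int) -> np.ndarray:
    """Layer-x activations for a list of scenes, upsampled to label resolution."""
    out = []
    h, w = scenes[0].label.shape
    for i in range(0, len(scenes), batch):
        chunk = scenes[i:i + batch]
        imgs = _standardise(np.stack([s.image for s in chunk]))
        _, act = net.forward(imgs, capture_tp=x)
        out.append(_upsample_bilinear(act, h, w))
    return np.concatenate(out, axis=0)


def _probe_subsets(scenes, probe: ProbeConfig):
    """Disjoint seeded calibration/evaluation subsets (scaled down if scenes are few)."""
    n = len(scenes)
    if n < 2:
        raise ValueError("need at least 2 scenes to build disjoint probe subsets")
    order = np.random.default_rng(probe.seed).permutation(n)
    n_cal = min(probe.calibration_n, max(1, n // 2))
    n_eval = min(probe.eval_n, n - n_cal)
    calib = [scenes[i] for i in order[:n_cal]]
    evalset = [scenes[i] for i in order[n_cal:n_cal + n_eval]]
    return calib, evalset


def fit_probe(net: TrainedNet, x: int, calib, probe: ProbeConfig):
    """Fit the channel->class read-out on the calibration scenes.

    Returns an opaque assignment object consumed by :func:`probe_maps`:
    for the standardised rule an integer array (channel -> class index,
    -1 when a channel is unassigned is impossible here since argmax always
    picks one); for the linear rule a (channels+1, C) weight matrix.
    """
    acts = _captured_activations(net, x, calib, probe.batch)
    labels = np.stack([s.label for s in calib])
    n, h, w, c = acts.shape
    flat = acts.reshape(-1, c)
    lab = labels.reshape(-1).astype(np.int64) - 1
    if probe.rule == "standardized":
        sd = flat.std(axis=0) + 1e-9
        scores = np.empty((c, N_CLASSES))
        for cls in range(N_CLASSES):
            mask = lab == cls
            if not mask.any():
                scores[:, cls] = -np.inf
                continue
            inside = flat[mask].mean(axis=0)
            outside = flat[~mask].mean(axis=0) if (~mask).any() else 0.0
            scores[:, cls] = (inside - outside) / sd
        assignment = scores.argmax(axis=1)
        for cls in range(N_CLASSES):
            if not (assignment == cls).any():
                logger.info("probe at TP %d: no channel assigned to class %d", x, cls + 1)
        return assignment
    # linear: least-squares read-out to one-hot targets on subsampled pixels
    rng = np.random.default_rng(probe.seed)
    if flat.shape[0] > probe.max_fit_pixels:
        take = rng.choice(flat.shape[0], probe.max_fit_pixels, replace=False)
        flat, lab = flat[take], lab[take]
    design = np.concatenate([flat, np.ones((flat.shape[0], 1), flat.dtype)], axis=1)
    onehot = np.zeros((flat.shape[0], N_CLASSES), dtype=np.float32)
    onehot[np.arange(flat.shape[0]), lab] = 1.0
    weights, *_ = np.linalg.lstsq(design.astype(np.float64), onehot, rcond=None)
    return weights


def probe_maps(net: TrainedNet, x: int, scenes, probe: ProbeConfig, assignment) -> list:
    """Per-scene predicted class maps from the layer-x feature read-out."""
    maps = []
    for i in range(0, len(scenes), probe.batch):
        chunk = scenes[i:i + probe.batch]
        acts = _captured_activations(net, x, chunk, probe.batch)
        n, h, w, c = acts.shape
        if probe.rule == "standardized":
            scores = np.zeros((n, h, w, N_CLASSES), dtype=acts.dtype)
            for cls in range(N_CLASSES):
                chans = np.flatnonzero(assignment == cls)
                if chans.size:
                    scores[..., cls] = acts[..., chans].mean(axis=-1)
            # a class with no channel keeps an all-zero score map
        else:
            design = np.concatenate([acts, np.ones((n, h, w, 1), acts.dtype)], axis=-1)
            scores = design @ assignment.astype(acts.dtype)
        pred = (scores.argmax(axis=-1) + 1).astype(np.uint8)
        maps.extend(pred[j] for j in range(n))
    return maps


def tpi_mapping(net: TrainedNet, x: int, scenes, probe: ProbeConfig) -> list:
    """Class maps for all ``scenes`` from the layer-x probe.

    The channel read-out is fitted on the seeded calibration subset of
    ``scenes``; the returned list covers every input scene in order.
    """
    calib, _ = _probe_subsets(scenes, probe)
    assignment = fit_probe(net, x, calib, probe)
    return probe_maps(net, x, scenes, probe, assignment)


def tpi_wks(net: TrainedNet, x: int, scenes, probe: ProbeConfig) -> float:
    """Accuracy-potential score of TP x: probe kappa on the held-out subset, clipped to [0, 1]."""
    calib, evalset = _probe_subsets(scenes, probe)
    assignment = fit_probe(net, x, calib, probe)
    maps = probe_maps(net, x, evalset, probe, assignment)
    cm = None
    for pred, scene in zip(maps, evalset):
        m = confusion_matrix(pred, scene.label, N_CLASSES)
        cm = m if cm is None else cm + m
    wks = weighted_metrics(cm).wks
    return max(0.0, min(1.0, wks))


# ----------------------------------------------------------------- TPI algebra

def tpi_tp(lsx: int, ls0: int, nlevel: int = DEFAULT_NLEVEL, form: str = "fraction") -> int:
    """Discrete time-cost level of a TP, in {1..Nlevel}.

    The default ``fraction`` form bins the *trainable* fraction LSx/LS0, so
    cost falls as freezing deepens and fewer parameters remain to train:
    ``min(Nlevel, floor(LSx/LS0 * Nlevel) + 1)``. The ``literal`` form bins
    the frozen fraction (LS0-LSx)/LS0 instead and is kept selectable for
    comparison.
    """
    if nlevel < 2:
        raise ValueError("nlevel must be >= 2")
    if not (0 <= lsx <= ls0):
        raise ValueError(f"LSx={lsx} outside [0, LS0={ls0}]")
    frac = lsx / ls0 if form == "fraction" else (ls0 - lsx) / ls0
    return min(nlevel, int(math.floor(frac * nlevel)) + 1)


def tpi(tpi_wks_value: float, tpi_tp_value: int) -> float:
    """TPI(x) = TPI_WKs(x) / TPI_TP(x), in [0, 1]."""
    if tpi_tp_value < 1:
        raise ValueError("TPI_TP must be >= 1")
    if not (0.0 <= tpi_wks_value <= 1.0):
        raise ValueError("TPI_WKs must lie in [0, 1]")
    return tpi_wks_value / tpi_tp_value


def tpi_curve(
    net: TrainedNet,
    scenes,
    probe: ProbeConfig,
    nlevel: int = DEFAULT_NLEVEL,
    tp_form: str = "fraction",
    dataset_id: str = "",
) -> TpiCurve:
    """One TPI record per transfer point 1..T of the net, on one dataset."""
    catalog = enumerate_tps(net)
    table = layer_sizes(net, catalog)
    calib, evalset = _probe_subsets(scenes, probe)
    records = []
    for point in catalog.points:
        x = point.index
        assignment = fit_probe(net, x, calib, probe)
        maps = probe_maps(net, x, evalset, probe, assignment)
        cm = None
        for pred, scene in zip(maps, evalset):
            m = confusion_matrix(pred, scene.label, N_CLASSES)
            cm = m if cm is None else cm + m
        wks = max(0.0, min(1.0, weighted_metrics(cm).wks))
        level = tpi_tp(table.ls(x), table.ls0, nlevel, form=tp_form)
        records.append(TpiRecord(x=x, lsx=table.ls(x), tpi_tp=level, tpi_wks=wks,
                                 tpi=tpi(wks, level)))
    return TpiCurve(records, nlevel=nlevel, dataset_id=dataset_id)


def average_curves(curves: list) -> TpiCurve:
    """Pointwise mean TPI over curves sharing one TP catalog."""
    if not curves:
        raise ValueError("no curves to average")
    tps = curves[0].tps
    for c in curves[1:]:
        if c.tps != tps or c.nlevel != curves[0].nlevel:
            raise ValueError("curves do not share the same TP catalog")
    records = []
    for i, x in enumerate(tps):
        recs = [c.records[i] for c in curves]
        records.append(TpiRecord(
            x=x,
            lsx=recs[0].lsx,
            tpi_tp=recs[0].tpi_tp,
            tpi_wks=float(np.mean([r.tpi_wks for r in recs])),
            tpi=float(np.mean([r.tpi for r in recs])),
        ))
    return TpiCurve(records, nlevel=curves[0].nlevel, dataset_id="average")


def select_tp0(curve: TpiCurve) -> int:
    """TP maximising TPI; ties break toward the largest x (cheapest transfer)."""
    if not curve.records:
        raise ValueError("empty TPI curve")
    best = curve.records[0]
    for r in curve.records[1:]:
        if r.tpi >= best.tpi:
            best = r
    return best.x


def tds_rule(
    ls_tp0: int,
    tds_pre: int,
    ls_pre: int,
    tp0: int = 0,
    available: int | None = None,
) -> MtpiCondition:
    """Transfer dataset size from the linear data/parameter rule.

    ``kpre = TDSpre / LSpre`` is the pre-training data-per-parameter ratio;
    ``TDS0 = round(kpre * LS_TP0)``, floored at 1 and capped at the
    available transfer data (with a warning) when ``available`` is given.
    """
    if ls_tp0 <= 0 or tds_pre <= 0 or ls_pre <= 0:
        raise ValueError("ls_tp0, tds_pre and ls_pre must all be positive")
    kpre = tds_pre / ls_pre
    tds0 = max(1, int(math.floor(kpre * ls_tp0 + 0.5)))
    capped = False
    if available is not None and tds0 > available:
        logger.warning("TDS0=%d exceeds available transfer data (%d); capping", tds0, available)
        tds0 = available
        capped = True
    return MtpiCondition(tp0=tp0, tds0=tds0, kpre=kpre, kt=kpre, tds_pre=tds_pre,
                         ls_pre=ls_pre, ls_tp0=ls_tp0, capped=capped)


def screening_decision(wks: float) -> str:
    """skip above the keep threshold, transfer below the weak one, else borderline."""
    if wks >= SKIP_WKS:
        return "skip"
    if wks < TRANSFER_WKS:
        return "transfer"
    return "borderline"


def screen_dataset(net: TrainedNet, scenes) -> ScreenDecision:
    """Screen a dataset against the pre-trained net: skip / transfer / borderline."""
    from .nets import evaluate

    report, _ = evaluate(net, scenes)
    decision = screening_decision(report.wks)
    logger.info("screening WKs=%.4f -> %s", report.wks, decision)
    return ScreenDecision(decision=decision, wks=report.wks)


def solve_mtpi(
    net: TrainedNet,
    surveys: dict,
    probe: ProbeConfig,
    tds_pre: int,
    ls_pre: int | None = None,
    nlevel: int = DEFAULT_NLEVEL,
    tp_form: str = "fraction",
    available: int | None = None,
):
    """Full MTPI condition from per-dataset TPI curves.

    ``surveys`` maps dataset ids to scene lists; per-dataset curves are
    averaged, TP0 maximises the averaged curve, and the TDS rule converts
    LS_TP0 into TDS0. Returns ``(condition, curves, averaged_curve)``.
    """
    catalog = enumerate_tps(net)
    table = layer_sizes(net, catalog)
    if ls_pre is None:
        ls_pre = table.ls0
    curves = {
        name: tpi_curve(net, scenes, probe, nlevel=nlevel, tp_form=tp_form, dataset_id=name)
        for name, scenes in surveys.items()
    }
    averaged = average_curves(list(curves.values()))
    tp0 = select_tp0(averaged)
    condition = tds_rule(table.ls(tp0), tds_pre, ls_pre, tp0=tp0, available=available)
    logger.info("MTPI condition: TP0=%d, TDS0=%d (kpre=%.3g)", tp0, condition.tds0, condition.kpre)
    return condition, curves, averaged


# ---------------------------------------------------------------- reporting

def write_curve_csv(curve: TpiCurve, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["TP", "LSx", "TPI_TP", "TPI_WKs", "TPI"])
        for r in curve.records:
            writer.writerow([r.x, r.lsx, r.tpi_tp, f"{r.tpi_wks:.6f}", f"{r.tpi:.6f}"])


def plot_curves(curves: list, path) -> None:
    """TPI-vs-TP curve figure (TP on x, TPI on y, one line per dataset)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.plot(curve.tps, curve.values, marker="o", label=curve.dataset_id or "curve")
    ax.set_xlabel("TP (transfer point)")
    ax.set_ylabel("TPI")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
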