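"""Confusion-matrix and weighted-metric checks against brute-force pixel oracles."""

import numpy as np
import pytest

from mtpi.metrics import (
    ConfusionMatrix,
    class_prevalence,
    confusion_matrix,
    kappa,
    kappa_band,
    weighted_metrics,
)


def brute_force_cm(pred, truth, c=4):
    counts = np.zeros((c, c), dtype=np.int64)
    for p, t in zip(pred.ravel(), truth.ravel()):
        counts[p - 1, t - 1] += 1
    return counts


def brute_force_metrics(counts):
    """Direct per-class counting formulas, independent of the implementation."""
    c = counts.shape[0]
    total = counts.sum()
    out = {"WPA": 0.0, "WRE": 0.0, "WF1": 0.0, "WIoU": 0.0}
    for i in range(c):
        tpp = counts[i, i]
        fpp = counts[i, :].sum() - tpp
        fnp = counts[:, i].sum() - tpp
        pi = counts[:, i].sum() / total
        prec = tpp / (tpp + fpp) if tpp + fpp else 0.0
        rec = tpp / (tpp + fnp) if tpp + fnp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        iou = tpp / (tpp + fpp + fnp) if tpp + fpp + fnp else 0.0
        out["WPA"] += pi * prec
        out["WRE"] += pi * rec
        out["WF1"] += pi * f1
        out["WIoU"] += pi * iou
    po = np.trace(counts) / total
    pe = sum(counts[i, :].sum() * counts[:, i].sum() for i in range(c)) / total**2
    out["WKs"] = (po - pe) / (1 - pe)
    return out


def test_confusion_matrix_hand_count():
    truth = np.array([[1, 1], [2, 2]])
    pred = np.array([[1, 2], [2, 2]])
    cm = confusion_matrix(pred, truth, 4)
    assert cm.counts[0, 0] == 1   # true 1 predicted 1
    assert cm.counts[1, 0] == 1   # true 1 predicted 2
    assert cm.counts[1, 1] == 2   # true 2 predicted 2
    assert cm.total == 4


def test_confusion_matrix_diagonal_when_perfect():
    rng = np.random.default_rng(1)
    m = rng.integers(1, 5, (30, 30)).astype(np.uint8)
    cm = confusion_matrix(m, m, 4)
    assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))


def test_confusion_matrix_matches_pixel_loop_oracle():
    rng = np.random.default_rng(7)
    truth = rng.integers(1, 5, (50, 50)).astype(np.uint8)
    pred = rng.integers(1, 5, (50, 50)).astype(np.uint8)
    cm = confusion_matrix(pred, truth, 4)
    assert np.array_equal(cm.counts, brute_force_cm(pred, truth))


def test_confusion_matrix_input_errors():
    with pytest.raises(ValueError):
        confusion_matrix(np.ones((2, 2), int), np.ones((3, 3), int))
    with pytest.raises(ValueError):
        confusion_matrix(np.full((2, 2), 5), np.ones((2, 2), int), 4)


def test_accumulation_is_elementwise_sum():
    rng = np.random.default_rng(3)
    maps = [(rng.integers(1, 5, (20, 20)), rng.integers(1, 5, (20, 20))) for _ in range(5)]
    total = None
    for p, t in maps:
        m = confusion_matrix(p, t, 4)
        total = m if total is None else total + m
    allp = np.concatenate([p.ravel() for p, _ in maps])
    allt = np.concatenate([t.ravel() for _, t in maps])
    assert np.array_equal(total.counts, confusion_matrix(allp, allt, 4).counts)


@pytest.mark.parametrize("counts,expected", [
    ((25, 25, 25, 25), (0.25, 0.25, 0.25, 0.25)),
    ((97, 1, 1, 1), (0.97, 0.01, 0.01, 0.01)),
])
def test_prevalence_arithmetic(counts, expected):
    labels = np.repeat(np.arange(1, 5), counts)
    assert class_prevalence(labels) == pytest.approx(expected)


def test_prevalence_from_cm_matches_raw_labels():
    rng = np.random.default_rng(11)
    truth = rng.integers(1, 5, (40, 40))
    pred = rng.integers(1, 5, (40, 40))
    cm = confusion_matrix(pred, truth, 4)
    assert class_prevalence(cm) == pytest.approx(class_prevalence(truth))


def test_perfect_prediction_scores_one():
    cm = ConfusionMatrix(np.diag([10, 20, 30, 40]))
    rep = weighted_metrics(cm)
    for v in (rep.wpa, rep.wre, rep.wf1, rep.wiou, rep.wks):
        assert v == pytest.approx(1.0)
    assert rep.kappa_band == "almost perfect"


def test_uniform_matrix_has_zero_kappa():
    cm = ConfusionMatrix(np.full((4, 4), 25))
    wks, po, pe, band = kappa(cm)
    assert wks == pytest.approx(0.0)
    assert po == pytest.approx(pe)


@pytest.mark.parametrize("seed", range(10))
def test_weighted_metrics_match_brute_force(seed):
    rng = np.random.default_rng(seed)
    cm = ConfusionMatrix(rng.integers(0, 500, (4, 4)))
    rep = weighted_metrics(cm)
    oracle = brute_force_metrics(cm.counts.astype(np.float64))
    assert rep.wpa == pytest.approx(oracle["WPA"], abs=1e-10)
    assert rep.wre == pytest.approx(oracle["WRE"], abs=1e-10)
    assert rep.wf1 == pytest.approx(oracle["WF1"], abs=1e-10)
    assert rep.wiou == pytest.approx(oracle["WIoU"], abs=1e-10)
    assert rep.wks == pytest.approx(oracle["WKs"], abs=1e-10)


def test_class_permutation_leaves_metrics_unchanged():
    rng = np.random.default_rng(5)
    truth = rng.integers(1, 5, (30, 30))
    pred = rng.integers(1, 5, (30, 30))
    base = weighted_metrics(confusion_matrix(pred, truth, 4))
    perm = np.array([0, 3, 1, 4, 2])  # class relabelling 1..4 -> 3,1,4,2
    rep = weighted_metrics(confusion_matrix(perm[pred], perm[truth], 4))
    for attr in ("wpa", "wre", "wf1", "wiou", "wks"):
        assert getattr(rep, attr) == pytest.approx(getattr(base, attr), abs=1e-12)


def test_wiou_never_exceeds_wf1():
    for seed in range(20):
        rng = np.random.default_rng(100 + seed)
        cm = ConfusionMatrix(rng.integers(0, 200, (4, 4)))
        rep = weighted_metrics(cm)
        assert rep.wiou <= rep.wf1 + 1e-12


def test_absent_class_contributes_zero_weight():
    counts = np.zeros((4, 4), dtype=int)
    counts[:3, :3] = np.diag([10, 10, 10])
    rep = weighted_metrics(ConfusionMatrix(counts))
    assert rep.pi[3] == 0.0
    assert rep.wpa == pytest.approx(1.0)


def test_macro_weighting_flag():
    counts = np.diag([70, 10, 10, 10])
    counts[0, 1] = 10  # some true-2 predicted as 1
    cm = ConfusionMatrix(counts)
    prev = weighted_metrics(cm, weighting="prevalence")
    macro = weighted_metrics(cm, weighting="macro")
    assert prev.wre != pytest.approx(macro.wre)


def test_kappa_po_denominator_variant():
    rng = np.random.default_rng(9)
    cm = ConfusionMatrix(rng.integers(1, 100, (4, 4)))
    wks_pe, po, pe, _ = kappa(cm, denominator="pe")
    wks_po, _, _, _ = kappa(cm, denominator="po")
    assert wks_pe == pytest.approx((po - pe) / (1 - pe))
    assert wks_po == pytest.approx((po - pe) / (1 - po))


def test_degenerate_single_class_kappa_is_zero():
    counts = np.zeros((4, 4), dtype=int)
    counts[0, 0] = 100
    with pytest.warns(UserWarning):
        wks, *_ = kappa(ConfusionMatrix(counts))
    assert wks == 0.0


@pytest.mark.parametrize("value,band", [
    (0.1, "slight"), (0.20, "slight"), (0.35, "fair"), (0.55, "moderate"),
    (0.80, "substantial"), (0.81, "almost perfect"), (1.0, "almost perfect"),
    (-0.2, "slight"),
])
def test_kappa_bands(value, band):
    assert kappa_band(value) == band


# ------------------------------------------------------ property-based checks

from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

cm_arrays = hnp.arrays(np.int64, (4, 4), elements=st.integers(0, 10_000))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(counts=cm_arrays)
def test_metric_ranges_and_iou_bound_hold_for_any_matrix(counts):
    if counts.sum() == 0 or np.trace(np.outer(counts.sum(1), counts.sum(0))) == counts.sum() ** 2:
        return  # empty or degenerate single-class matrices are covered elsewhere
    rep = weighted_metrics(ConfusionMatrix(counts))
    for v in (rep.wpa, rep.wre, rep.wf1, rep.wiou):
        assert 0.0 <= v <= 1.0
    assert -1.0 <= rep.wks <= 1.0
    assert rep.wiou <= rep.wf1 + 1e-12
    assert rep.pi.sum() == pytest.approx(1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(counts=cm_arrays, perm=st.permutations(range(4)))
def test_consistent_relabelling_never_moves_the_metrics(counts, perm):
    if counts.sum() == 0:
        return
    perm = np.asarray(perm)
    base = weighted_metrics(ConfusionMatrix(counts))
    shuffled = weighted_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
    for attr in ("wpa", "wre", "wf1", "wiou", "wks"):
        assert getattr(shuffled, attr) == pytest.approx(getattr(base, attr), abs=1e-12)
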