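"""Expert consensus and pixel-level epithelium metrics."""

from collections import Counter

import numpy as np
import pytest

from epstra.evaluate import (EPITHELIUM, LUMEN, STROMA, ConfusionMetrics,
                             ExpertLabeling, benchmark_methods,
                             consensus_ground_truth, score_epithelium)


def labeling(arr, eid="e"):
    return ExpertLabeling(np.asarray(arr), expert_id=eid)


def test_single_expert_consensus_is_identity():
    lab = labeling([[0, 1], [2, 1]])
    cons = consensus_ground_truth([lab])
    assert (cons.labels == lab.labels).all()


def test_majority_vote_and_tie_priority():
    a = labeling([[EPITHELIUM]], "a")
    b = labeling([[EPITHELIUM]], "b")
    c = labeling([[STROMA]], "c")
    assert consensus_ground_truth([a, b, c]).labels[0, 0] == EPITHELIUM
    # 1-1 tie between stroma and lumen -> stroma (priority E > S > L)
    d = labeling([[STROMA]], "d")
    e = labeling([[LUMEN]], "e")
    assert consensus_ground_truth([d, e]).labels[0, 0] == STROMA
    # 1-1 tie between epithelium and lumen -> epithelium
    assert consensus_ground_truth([e, a]).labels[0, 0] == EPITHELIUM


def test_consensus_matches_per_pixel_brute_force():
    rng = np.random.default_rng(0)
    experts = [labeling(rng.integers(0, 3, (12, 12)), f"e{k}") for k in range(3)]
    cons = consensus_ground_truth(experts)
    priority = {EPITHELIUM: 0, STROMA: 1, LUMEN: 2}
    for i in range(12):
        for j in range(12):
            votes = Counter(int(lab.labels[i, j]) for lab in experts)
            top = max(votes.values())
            winner = min((lbl for lbl, n in votes.items() if n == top),
                         key=priority.get)
            assert cons.labels[i, j] == winner


def test_consensus_exclude_and_mismatch_errors():
    a = labeling([[1, 2]], "a")
    b = labeling([[2, 2]], "b")
    cons = consensus_ground_truth([a, b], exclude="a")
    assert (cons.labels == b.labels).all()
    with pytest.raises(ValueError):
        consensus_ground_truth([a, b], exclude=None) if False else \
            consensus_ground_truth([], exclude=None)
    with pytest.raises(ValueError, match="extent"):
        consensus_ground_truth([a, labeling([[1]], "c")])


def make_case(tp=97, fp=1, fn=3, tn=99):
    """Ground truth/prediction pair realizing exact confusion counts."""
    n = tp + fp + fn + tn
    gt = np.full(n, STROMA); pred = np.zeros(n, dtype=bool)
    gt[:tp + fn] = EPITHELIUM
    pred[:tp] = True                       # tp hits
    pred[tp + fn:tp + fn + fp] = True      # fp on stroma
    return pred.reshape(10, -1), ExpertLabeling(gt.reshape(10, -1), "gt")


def test_metric_arithmetic_matches_closed_form():
    pred, gt = make_case()
    m = score_epithelium(pred, gt)
    assert (m.tp, m.fp, m.fn, m.tn) == (97, 1, 3, 99)
    assert abs(m.precision - 97 / 98) < 1e-12
    assert abs(m.recall - 0.97) < 1e-12
    assert abs(m.specificity - 0.99) < 1e-12
    f1 = 2 * (97 / 98) * 0.97 / (97 / 98 + 0.97)
    assert abs(m.f1 - f1) < 1e-12
    assert m.n_scored == 200


def test_perfect_prediction_and_empty_prediction():
    pred, gt = make_case(tp=100, fp=0, fn=0, tn=100)
    m = score_epithelium(pred, gt)
    assert m.precision == m.recall == m.f1 == m.specificity == 1.0
    none = score_epithelium(np.zeros_like(pred), gt)
    assert none.recall == 0.0 and none.f1 == 0.0


def test_lumen_pixels_are_eliminated_from_scoring():
    gt = np.array([[LUMEN, LUMEN, EPITHELIUM, STROMA]])
    pred = np.array([[True, False, True, False]])
    m = score_epithelium(pred, ExpertLabeling(gt, "gt"))
    assert m.n_scored == 2 and m.tp == 1 and m.tn == 1
    with pytest.raises(ValueError, match="all lumen"):
        score_epithelium(pred, ExpertLabeling(np.full((1, 4), LUMEN), "gt"))


def test_swapping_prediction_and_truth_swaps_precision_recall():
    rng = np.random.default_rng(1)
    a = rng.random((10, 10)) > 0.5
    b = rng.random((10, 10)) > 0.5
    as_truth = lambda mask: ExpertLabeling(
        np.where(mask, EPITHELIUM, STROMA), "x")
    m_ab = score_epithelium(a, as_truth(b))
    m_ba = score_epithelium(b, as_truth(a))
    assert m_ab.precision == pytest.approx(m_ba.recall)
    assert m_ab.recall == pytest.approx(m_ba.precision)


def test_pooled_f1_between_per_fov_extremes():
    cases = [make_case(90, 5, 10, 95), make_case(60, 20, 40, 80)]
    preds = {"m": [c[0] for c in cases]}
    truths = [c[1] for c in cases]
    table = benchmark_methods(preds, truths)
    per_fov = [score_epithelium(p, t).f1 for p, t in zip(preds["m"], truths)]
    pooled = table.loc[table.method == "m", "f1"].iloc[0]
    assert min(per_fov) <= pooled <= max(per_fov)
    with pytest.raises(ValueError):
        benchmark_methods({"m": [cases[0][0]]}, truths)


def test_confusion_metrics_zero_denominators():
    z = ConfusionMetrics(0, 0, 0, 10)
    assert z.precision == 0.0 and z.recall == 0.0 and z.f1 == 0.0
    assert z.specificity == 1.0
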