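import math

import numpy as np
import pytest

from crowneval.assessment import (
    ConfusionMatrix,
    assign_outcomes,
    average_precision,
    compute_metrics,
    format_confusion_table,
    round_half_up,
)
from crowneval.geometry import BBox, buffer_point, iou
from crowneval.postprocess import Detection
from crowneval.synth import benchmark_layout


def det(xmin, ymin, xmax, ymax, conf=0.99):
    return Detection(box=BBox(xmin, ymin, xmax, ymax), confidence=conf)


def unit_ref(x):
    return BBox(x, 0.0, x + 1.0, 1.0)


class TestAssignOutcomes:
    def test_no_detections(self):
        crowns = [buffer_point((i * 3, 0), 0.5) for i in range(4)]
        others = [buffer_point((i * 3, 10), 0.5) for i in range(6)]
        cm = assign_outcomes(crowns, others, [])
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (0, 4, 0, 6)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        crowns = [buffer_point(rng.uniform(0, 20, 2), rng.uniform(0.3, 1.0)) for _ in range(10)]
        others = [buffer_point(rng.uniform(0, 20, 2), rng.uniform(0.3, 1.0)) for _ in range(10)]
        dets = []
        for _ in range(8):
            x, y = rng.uniform(0, 20, 2)
            w, h = rng.uniform(0.5, 2.5, 2)
            dets.append(det(x, y, x + w, y + h, float(rng.random())))

        # exhaustive oracle over every polygon-detection pair
        def hit(poly):
            return any(poly.intersection(d.box.to_shapely()).area > 0 for d in dets)

        tp = sum(hit(c) for c in crowns)
        fp = sum(hit(o) for o in others)
        cm = assign_outcomes(crowns, others, dets)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, 10 - tp, fp, 10 - fp)

    def test_one_detection_can_serve_multiple_polygons(self):
        crowns = [buffer_point((0, 0), 0.5), buffer_point((1.2, 0), 0.5)]
        big = det(-1, -1, 2.5, 1)  # spans both crowns
        cm = assign_outcomes(crowns, [], [big])
        assert cm.tp == 2

    def test_multiple_detections_on_one_polygon_count_once(self):
        crown = buffer_point((0, 0), 0.5)
        cm = assign_outcomes([crown], [], [det(-1, -1, 1, 1), det(-0.3, -0.3, 0.3, 0.3)])
        assert (cm.tp, cm.fn) == (1, 0)

    def test_engineered_benchmark_counts(self):
        crowns, others, dets = benchmark_layout(500, 500, 412, 2)
        cm = assign_outcomes(crowns, others, dets)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (412, 2, 88, 498)

    def test_margins_conserved(self):
        crowns, others, dets = benchmark_layout(60, 40, 25, 3)
        cm = assign_outcomes(crowns, others, dets)
        assert cm.n_target == 60 and cm.n_other == 40 and cm.total == 100


class TestComputeMetrics:
    def test_md_style_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=412, fp=2, fn=88, tn=498))
        assert m.precision == pytest.approx(412 / 414)
        assert m.recall == pytest.approx(0.824)
        assert m.overall_accuracy == pytest.approx(0.910)

    def test_hd_style_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=434, fp=24, fn=66, tn=376)).rounded()
        assert (m.precision, m.recall, m.overall_accuracy) == (0.95, 0.87, 0.90)

    def test_perfect_matrix(self):
        m = compute_metrics(ConfusionMatrix(tp=7, fp=0, fn=0, tn=5))
        assert (m.precision, m.recall, m.overall_accuracy) == (1.0, 1.0, 1.0)

    def test_undefined_precision_is_nan_not_zero(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=4, tn=6))
        assert math.isnan(m.precision)
        assert m.overall_accuracy == pytest.approx(0.6)

    def test_oa_between_class_accuracies(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 100, size=4)
            m = compute_metrics(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn)))
            acc_t = tp / (tp + fn)
            acc_o = tn / (fp + tn)
            assert min(acc_t, acc_o) - 1e-12 <= m.overall_accuracy <= max(acc_t, acc_o) + 1e-12

    def test_rounding_half_up(self):
        assert round_half_up(0.825, 2) == 0.83
        assert round_half_up(0.824, 2) == 0.82

    def test_table_formatting_margins(self):
        txt = format_confusion_table(ConfusionMatrix(tp=412, fp=2, fn=88, tn=498))
        assert "412 (TP)" in txt and "500" in txt and "1000" in txt


class TestAveragePrecision:
    def test_perfect_detections(self):
        refs = [unit_ref(3 * i) for i in range(5)]
        dets = [det(3 * i, 0, 3 * i + 1, 1, 0.9 - 0.01 * i) for i in range(5)]
        assert average_precision(dets, refs).average_precision == pytest.approx(1.0)

    def test_no_match_gives_zero(self):
        refs = [unit_ref(0)]
        dets = [det(50, 50, 51, 51, 0.9)]
        assert average_precision(dets, refs).average_precision == 0.0

    def test_empty_reference_raises(self):
        with pytest.raises(ValueError):
            average_precision([], [])

    def test_hand_computed_all_points_area(self):
        """5 refs, 6 ranked dets hitting [T,T,F,T,F,T] -> AP = 41/60."""
        refs = [unit_ref(10 * i) for i in range(5)]
        dets = [
            det(0, 0, 1, 1, 0.99),  # TP on ref 0
            det(10, 0, 11, 1, 0.95),  # TP on ref 1
            det(55, 0, 56, 1, 0.90),  # FP (no ref nearby)
            det(20, 0, 21, 1, 0.85),  # TP on ref 2
            det(0.1, 0, 1.1, 1, 0.80),  # duplicate on ref 0 -> FP
            det(30, 0, 31, 1, 0.75),  # TP on ref 3
        ]
        ap = average_precision(dets, refs, iou_thr=0.5)
        assert ap.average_precision == pytest.approx(41.0 / 60.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_all_thresholds(self, seed):
        """AP equals an independently coded all-points computation (n <= 10)."""
        rng = np.random.default_rng(seed)
        refs = [unit_ref(2.0 * i) for i in range(5)]
        dets = []
        for _ in range(10):
            x = rng.uniform(-1, 11)
            dets.append(det(x, rng.uniform(-0.4, 0.4), x + 1, 1, float(rng.random())))

        # oracle: greedy matching re-coded with plain loops, then the
        # "max precision at recall >= r" definition summed over recall steps
        order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
        taken = set()
        flags = []
        for i in order:
            best, best_v = None, 0.5
            for j, r in enumerate(refs):
                if j in taken:
                    continue
                v = iou(dets[i].box, r)
                if v >= best_v:
                    best, best_v = j, v
            if best is not None:
                taken.add(best)
            flags.append(best is not None)
        precisions, recalls = [], []
        tp = 0
        for k, f in enumerate(flags, start=1):
            tp += f
            precisions.append(tp / k)
            recalls.append(tp / len(refs))
        expected = 0.0
        prev_r = 0.0
        for r, _ in zip(recalls, precisions):
            if r > prev_r:
                p_at = max(p for p, rr in zip(precisions, recalls) if rr >= r)
                expected += (r - prev_r) * p_at
                prev_r = r
        got = average_precision(dets, refs, iou_thr=0.5).average_precision
        assert got == pytest.approx(expected)
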