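import numpy as np
import pytest

from trapscan.evaluation import (
    ConfusionCounts,
    Detection,
    DetectionSet,
    GroundTruth,
    confusion_from_matches,
    count_regression,
    evaluate_images,
    match_detections,
    rates,
)

from .oracles import brute_force_min_cost_matching, normal_equations_ols


def det(x, y, label="whitefly"):
    return Detection(bbox=(int(x) - 2, int(y) - 2, int(x) + 2, int(y) + 2),
                     label=label, centroid=(float(x), float(y)))


class TestMatching:
    def test_identical_sets_match_at_zero_distance(self):
        pts = [(10, 10, "whitefly"), (30, 40, "thrips")]
        ds = DetectionSet([det(x, y, lab) for x, y, lab in pts], image_id="a")
        res = match_detections(ds, GroundTruth(points=pts, image_id="a"))
        assert len(res.matches) == 2
        assert all(d == 0 for _, _, d in res.matches)
        assert res.unmatched_detections == [] and res.unmatched_truth == []

    def test_empty_detections_leave_truth_unmatched(self):
        truth = GroundTruth(points=[(5, 5, "thrips")], image_id="a")
        res = match_detections(DetectionSet([], image_id="a"), truth)
        assert res.matches == [] and res.unmatched_truth == [0]

    def test_greedy_equals_min_cost_assignment_on_small_instance(self):
        det_xy = [(10, 10), (13, 10), (40, 40)]
        tru_xy = [(11, 10), (41, 41)]
        ds = DetectionSet([det(x, y) for x, y in det_xy], image_id="a")
        truth = GroundTruth(points=[(x, y, "whitefly") for x, y in tru_xy], image_id="a")
        res = match_detections(ds, truth, max_dist=8)
        got = sorted((d, t) for d, t, _ in res.matches)
        want = sorted(brute_force_min_cost_matching(det_xy, tru_xy, 8))
        assert got == want

    def test_far_pairs_not_matched(self):
        ds = DetectionSet([det(0, 0)], image_id="a")
        truth = GroundTruth(points=[(100, 100, "whitefly")], image_id="a")
        res = match_detections(ds, truth, max_dist=8)
        assert res.matches == []

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (10, 2))
        truth = GroundTruth(points=[(x, y, "thrips") for x, y in pts + 1], image_id="a")
        base = [det(x, y, "thrips") for x, y in pts]
        perm = list(range(10))
        rng.shuffle(perm)
        r1 = match_detections(DetectionSet(base, image_id="a"), truth)
        r2 = match_detections(DetectionSet([base[i] for i in perm], image_id="a"), truth)
        pairs1 = sorted((d, t) for d, t, _ in r1.matches)
        pairs2 = sorted((perm[d], t) for d, t, _ in r2.matches)
        assert pairs1 == pairs2


class TestConfusion:
    def test_perfect_detection(self):
        pts = [(10, 10, "whitefly"), (20, 20, "whitefly"), (40, 40, "thrips")]
        ds = DetectionSet([det(x, y, lab) for x, y, lab in pts], image_id="a")
        truth = GroundTruth(points=pts, image_id="a")
        conf = confusion_from_matches(match_detections(ds, truth), ds, truth)
        assert (conf["whitefly"].tp, conf["whitefly"].fp, conf["whitefly"].fn) == (2, 0, 0)
        assert conf["thrips"].tp == 1

    def test_cross_label_error_counts_on_both_sides(self):
        truth = GroundTruth(points=[(10, 10, "whitefly")], image_id="a")
        ds = DetectionSet([det(10, 10, "thrips")], image_id="a")
        conf = confusion_from_matches(match_detections(ds, truth), ds, truth)
        assert conf["whitefly"].fn == 1
        assert conf["thrips"].fp == 1

    def test_universe_size_identical_across_classes(self):
        rng = np.random.default_rng(1)
        classes = ("whitefly", "thrips", "background")
        truth_pts = [
            (float(x), float(y), classes[rng.integers(3)])
            for x, y in rng.uniform(0, 200, (15, 2))
        ]
        dets = [
            det(x + rng.normal(0, 2), y + rng.normal(0, 2), classes[rng.integers(3)])
            for x, y, _ in truth_pts[:12]
        ] + [det(*rng.uniform(0, 200, 2), classes[rng.integers(3)]) for _ in range(4)]
        ds = DetectionSet(dets, image_id="a")
        truth = GroundTruth(points=truth_pts, image_id="a")
        conf = confusion_from_matches(match_detections(ds, truth), ds, truth)
        sizes = {c.tp + c.fp + c.tn + c.fn for c in conf.values()}
        assert len(sizes) == 1

    def test_matches_direct_tabulation_on_random_instance(self):
        """Counts equal an object-by-object tally over the same matching."""
        rng = np.random.default_rng(30)
        classes = ("whitefly", "thrips", "background")
        truth_pts = [
            (float(x), float(y), classes[rng.integers(3)])
            for x, y in rng.uniform(0, 300, (30, 2))
        ]
        dets = [
            det(x + rng.normal(0, 3), y + rng.normal(0, 3), classes[rng.integers(3)])
            for x, y, _ in truth_pts[:25]
        ]
        ds = DetectionSet(dets, image_id="a")
        truth = GroundTruth(points=truth_pts, image_id="a")
        res = match_detections(ds, truth)
        conf = confusion_from_matches(res, ds, truth)
        universe = len(res.matches) + len(res.unmatched_detections) + len(res.unmatched_truth)
        for c in classes:
            tp = sum(
                1 for d, t, _ in res.matches
                if dets[d].label == c and truth_pts[t][2] == c
            )
            fn = sum(
                1 for d, t, _ in res.matches
                if dets[d].label != c and truth_pts[t][2] == c
            ) + sum(1 for t in res.unmatched_truth if truth_pts[t][2] == c)
            fp = sum(
                1 for d, t, _ in res.matches
                if dets[d].label == c and truth_pts[t][2] != c
            ) + sum(1 for d in res.unmatched_detections if dets[d].label == c)
            assert (conf[c].tp, conf[c].fp, conf[c].fn) == (tp, fp, fn)
            assert conf[c].tn == universe - tp - fp - fn


class TestRates:
    def test_worked_arithmetic(self):
        r = rates(ConfusionCounts(tp=93, fn=7, fp=10, tn=90))
        assert r.tpr == pytest.approx(0.930)
        assert r.fpr == pytest.approx(0.100)
        assert r.accuracy == pytest.approx(0.915)

    def test_zero_denominator_reported_missing(self):
        r = rates(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
        assert r.tpr is None
        assert r.fpr == pytest.approx(0.2)

    def test_all_correct(self):
        r = rates(ConfusionCounts(tp=5, tn=10))
        assert (r.tpr, r.fpr, r.accuracy) == (1.0, 0.0, 1.0)


class TestCountRegression:
    def test_perfect_agreement(self):
        counts = np.array([3, 7, 11, 4, 9])
        slope, intercept, r2 = count_regression(counts, counts)
        assert (slope, intercept, r2) == (pytest.approx(1), pytest.approx(0), pytest.approx(1))

    def test_doubling_gives_slope_two(self):
        manual = np.array([2, 5, 9, 12, 20])
        slope, _, r2 = count_regression(2 * manual, manual)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_normal_equations_on_noisy_table(self):
        rng = np.random.default_rng(11)
        manual = np.arange(5, 55, 5).astype(float)
        auto = manual * 1.1 - 0.8 + rng.normal(0, 2, manual.size)
        got = count_regression(auto, manual)
        want = normal_equations_ols(manual, auto)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_zero_variance_manual_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            count_regression(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="3 images"):
            count_regression(np.array([1.0, 2]), np.array([1.0, 3]))


class TestEvaluateImages:
    def _batch(self, n_images=5, seed=0):
        rng = np.random.default_rng(seed)
        sets, truths = [], []
        for i in range(n_images):
            n = int(rng.integers(3, 10))
            pts = [
                (float(x), float(y), "whitefly" if rng.uniform() < 0.5 else "thrips")
                for x, y in rng.uniform(10, 200, (n, 2))
            ]
            truths.append(GroundTruth(points=pts, image_id=f"img{i}"))
            sets.append(
                DetectionSet([det(x, y, lab) for x, y, lab in pts], image_id=f"img{i}")
            )
        return sets, truths

    def test_perfect_detections_score_one(self):
        sets, truths = self._batch()
        report = evaluate_images(sets, truths)
        wf = report["summary"].loc["whitefly"]
        assert wf[("tpr", "mean")] == pytest.approx(1.0)
        assert wf[("fpr", "mean")] == pytest.approx(0.0)
        assert report["count_regression"]["whitefly"]["r_squared"] == pytest.approx(1.0)

    def test_half_removed_halves_tpr(self):
        sets, truths = self._batch(seed=2)
        halved = [
            DetectionSet(ds.detections[:: 2], image_id=ds.image_id) for ds in sets
        ]
        report = evaluate_images(halved, truths)
        tprs = report["per_image"]
        mean_tpr = tprs.groupby("class")["tpr"].mean()
        overall = np.nanmean([mean_tpr.get("whitefly", np.nan), mean_tpr.get("thrips", np.nan)])
        assert 0.3 <= overall <= 0.7

    def test_disjoint_ids_rejected(self):
        sets, truths = self._batch()
        for t in truths:
            t.image_id = "other_" + t.image_id
        with pytest.raises(ValueError, match="overlapping"):
            evaluate_images(sets, truths)


class TestSerialization:
    def test_coco_round_trip(self):
        from trapscan.evaluation import ground_truth_from_coco, ground_truth_to_coco

        truths = [
            GroundTruth(points=[(10.0, 20.0, "whitefly"), (30.0, 5.0, "thrips")],
                        image_id="a"),
            GroundTruth(points=[(7.5, 7.5, "background")], image_id="b"),
        ]
        back = ground_truth_from_coco(ground_truth_to_coco(truths))
        assert [t.image_id for t in back] == ["a", "b"]
        assert back[0].points == truths[0].points
        assert back[1].points == truths[1].points

    def test_count_regression_plot_written(self, tmp_path):
        from trapscan.evaluation import plot_count_regression

        manual = np.array([3.0, 8, 12, 17, 22])
        auto = manual * 1.05 + 0.3
        out = tmp_path / "scatter.png"
        slope, intercept, r2 = plot_count_regression(auto, manual, out, label="whitefly")
        assert out.exists() and out.stat().st_size > 0
        assert slope == pytest.approx(1.05)
        assert r2 == pytest.approx(1.0)
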