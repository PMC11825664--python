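import numpy as np
import pytest

from normeval import (
    AnomalyMap,
    Box,
    ContractError,
    DataError,
    ImageSample,
    UsageError,
    anomaly_map,
    binarize,
    ceiling_dice,
    dataset_f1,
    evaluate_case,
    image_score,
    stratify_lesions,
)
from normeval.detection_eval import (
    DetectionCase,
    ceiling_dice_single,
    resolve_threshold,
)


def brute_force_ceiling_dice(score_list, mask_list):
    """Independent oracle: try EVERY unique pooled score as the threshold
    (predicate score >= t) and return the best pooled Dice and threshold."""
    pooled = np.concatenate([s.ravel() for s in score_list])
    gt = np.concatenate([m.ravel().astype(bool) for m in mask_list])
    best_dice, best_t = -1.0, None
    for t in np.unique(pooled):
        pred = pooled >= t
        denom = pred.sum() + gt.sum()
        dice = 2.0 * (pred & gt).sum() / denom if denom else 0.0
        if dice > best_dice:
            best_dice, best_t = float(dice), float(t)
    return best_dice, best_t


class TestAnomalyMap:
    def test_identity_gives_zero_map(self, rng):
        px = rng.uniform(size=(16, 16))
        m = anomaly_map(ImageSample("a", px), ImageSample("a", px.copy()))
        assert np.all(m.scores == 0.0)

    def test_residual_value(self):
        x = ImageSample("a", np.array([[1.0]]))
        r = ImageSample("a", np.array([[0.25]]))
        assert anomaly_map(x, r).scores[0, 0] == pytest.approx(0.75)

    def test_symmetric_in_arguments(self, rng):
        a = ImageSample("a", rng.uniform(size=(8, 8)))
        b = ImageSample("a", rng.uniform(size=(8, 8)))
        np.testing.assert_array_equal(
            anomaly_map(a, b).scores, anomaly_map(b, a).scores
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            anomaly_map(ImageSample("a", np.zeros((4, 4))),
                        ImageSample("a", np.zeros((4, 5))))


class TestImageScore:
    def test_max_mode(self):
        scores = np.zeros((8, 8))
        scores[3, 4] = 0.9
        assert image_score(AnomalyMap("a", scores), "max") == 0.9

    def test_mean_mode_constant(self):
        assert image_score(AnomalyMap("a", np.full((4, 4), 0.3)), "mean") == (
            pytest.approx(0.3)
        )

    def test_mean_never_exceeds_max(self, rng):
        m = AnomalyMap("a", rng.uniform(size=(16, 16)))
        assert image_score(m, "mean") <= image_score(m, "max")


class TestBinarize:
    def test_strict_inequality_at_zero_threshold(self):
        m = AnomalyMap("a", np.zeros((8, 8)))
        assert binarize(m, "fixed", threshold=0.0).sum() == 0

    def test_fixed_threshold_selects_above(self):
        m = AnomalyMap("a", np.array([[0.4, 0.6]]))
        out = binarize(m, "fixed", threshold=0.5)
        np.testing.assert_array_equal(out, [[0, 1]])

    def test_healthy_quantile_matches_numpy(self, rng):
        refs = [AnomalyMap(f"h{i}", rng.uniform(size=(16, 16))) for i in range(4)]
        t = resolve_threshold("healthy_quantile", quantile=0.95,
                              reference_maps=refs)
        pooled = np.concatenate([r.scores.ravel() for r in refs])
        assert t == pytest.approx(np.quantile(pooled, 0.95), abs=1e-15)

    def test_quantile_without_references_rejected(self):
        m = AnomalyMap("a", np.zeros((4, 4)))
        with pytest.raises(UsageError):
            binarize(m, "healthy_quantile")


class TestEvaluateCase:
    def _binary(self, n_inside, n_outside):
        binary = np.zeros((128, 128), dtype=np.uint8)
        flat = binary[10:20, 10:20].ravel()
        flat[:n_inside] = 1
        binary[10:20, 10:20] = flat.reshape(10, 10)
        binary[50, 50:50 + n_outside] = 1
        return binary

    def test_exactly_ten_percent_is_detected(self):
        box = Box("lesion", 10, 10, 20, 20)
        case = evaluate_case(self._binary(10, 0), [box])
        (result,) = case.boxes
        assert result.detected
        assert result.fp_ratio == 0.0
        assert result.precision == 1.0
        assert result.f1_case == pytest.approx(1.0)

    def test_fp_ratio_one_gives_two_thirds(self):
        box = Box("lesion", 10, 10, 20, 20)
        (result,) = evaluate_case(self._binary(10, 10), [box]).boxes
        assert result.fp_ratio == pytest.approx(1.0)
        assert result.precision == pytest.approx(0.5)
        assert result.f1_case == pytest.approx(2.0 / 3.0)

    def test_nine_percent_is_missed(self):
        box = Box("lesion", 10, 10, 20, 20)
        (result,) = evaluate_case(self._binary(9, 0), [box]).boxes
        assert not result.detected
        assert result.f1_case == 0.0

    def test_brain_mask_restricts_false_positives(self):
        box = Box("lesion", 10, 10, 20, 20)
        binary = self._binary(10, 10)
        brain = np.zeros_like(binary)
        brain[:40, :40] = 1  # outside pixels at row 50 fall off the brain
        (result,) = evaluate_case(binary, [box], brain_mask=brain).boxes
        assert result.fp_ratio == 0.0
        assert result.f1_case == pytest.approx(1.0)

    def test_multiple_boxes_share_outside_pixels(self):
        binary = np.zeros((64, 64), dtype=np.uint8)
        binary[5:10, 5:10] = 1      # fills box A
        binary[30:35, 30:35] = 1    # fills box B
        binary[60, 0:5] = 1         # outside both
        boxes = [Box("a", 5, 5, 10, 10), Box("b", 30, 30, 35, 35)]
        case = evaluate_case(binary, boxes)
        for result in case.boxes:
            assert result.detected
            assert result.fp_ratio == pytest.approx(5 / 25)

    def test_min_overlap_domain(self):
        with pytest.raises(UsageError):
            evaluate_case(np.zeros((8, 8)), [Box("l", 0, 0, 4, 4)],
                          min_overlap=0.0)

    def test_monotonicity_in_outside_pixels(self):
        box = Box("lesion", 10, 10, 20, 20)
        f1s = [evaluate_case(self._binary(10, k), [box]).boxes[0].f1_case
               for k in range(0, 40, 5)]
        assert all(a >= b for a, b in zip(f1s, f1s[1:]))


class TestDatasetF1:
    def _case(self, id, f1, detected, label="lesion"):
        from normeval.detection_eval import BoxResult

        return DetectionCase(id=id, boxes=[BoxResult(
            label=label, detected=detected, overlap_fraction=0.5,
            fp_ratio=0.0 if detected else None,
            precision=1.0 if detected else 0.0, f1_case=f1,
        )])

    def test_mean_of_cases(self):
        cases = [self._case("a", 1.0, True), self._case("b", 0.0, False)]
        per_class, overall = dataset_f1(cases)
        assert overall["f1"] == pytest.approx(0.5)
        assert overall["n_detected"] == 1 and overall["n_total"] == 2
        assert per_class["lesion"]["f1"] == pytest.approx(0.5)

    def test_all_detected_no_fp(self):
        cases = [self._case(str(i), 1.0, True) for i in range(4)]
        _, overall = dataset_f1(cases)
        assert overall["f1"] == 1.0

    def test_per_class_split(self):
        cases = [self._case("a", 1.0, True, "edema"),
                 self._case("b", 0.5, True, "mass")]
        per_class, _ = dataset_f1(cases)
        assert per_class["edema"]["f1"] == 1.0
        assert per_class["mass"]["f1"] == 0.5

    def test_permutation_invariant(self):
        cases = [self._case(str(i), f1, True) for i, f1 in
                 enumerate([0.2, 0.9, 0.5])]
        assert dataset_f1(cases) == dataset_f1(cases[::-1])

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            dataset_f1([self._case("a", 1.0, True, "mystery")],
                       class_vocabulary=["lesion"])


class TestCeilingDice:
    def test_perfect_map_reaches_one(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[4:8, 4:8] = 1
        maps = [AnomalyMap("a", mask.astype(float))]
        res = ceiling_dice_single(maps, {"a": mask}, n_thresholds="exhaustive")
        assert res.dice == 1.0

    def test_constant_map_best_is_select_all(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[0:2, 0:5] = 1  # L = 10 lesion pixels, N = 256
        maps = [AnomalyMap("a", np.full((16, 16), 0.7))]
        res = ceiling_dice_single(maps, {"a": mask}, n_thresholds="exhaustive")
        assert res.dice == pytest.approx(2 * 10 / (256 + 10))
        assert res.degenerate

    def test_exhaustive_matches_brute_force(self, rng):
        for _ in range(25):
            scores = rng.uniform(size=(16, 16))
            mask = np.zeros((16, 16), dtype=np.uint8)
            ys, xs = rng.integers(0, 16, size=(2, 10))
            mask[ys, xs] = 1
            res = ceiling_dice_single(
                [AnomalyMap("a", scores)], {"a": mask},
                n_thresholds="exhaustive",
            )
            expected_dice, expected_t = brute_force_ceiling_dice([scores], [mask])
            assert res.dice == expected_dice
            assert res.threshold == expected_t

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.uniform(0.1, 1.0, size=(16, 16))
        mask = (rng.uniform(size=(16, 16)) > 0.9).astype(np.uint8)
        base = ceiling_dice_single([AnomalyMap("a", scores)], {"a": mask},
                                   n_thresholds="exhaustive")
        warped = ceiling_dice_single(
            [AnomalyMap("a", np.exp(scores))], {"a": mask},
            n_thresholds="exhaustive",
        )
        assert warped.dice == pytest.approx(base.dice, abs=1e-12)

    def test_grid_search_never_beats_exhaustive(self, rng):
        scores = rng.uniform(size=(32, 32))
        mask = (rng.uniform(size=(32, 32)) > 0.85).astype(np.uint8)
        exact = ceiling_dice_single([AnomalyMap("a", scores)], {"a": mask},
                                    n_thresholds="exhaustive")
        grid = ceiling_dice_single([AnomalyMap("a", scores)], {"a": mask},
                                   n_thresholds=100)
        assert grid.dice <= exact.dice + 1e-12

    def test_empty_stratum_flagged(self):
        res = ceiling_dice_single([], {}, stratum="small")
        assert res.n_cases == 0
        assert res.degenerate
        assert np.isnan(res.dice)

    def test_strata_aggregation(self, restored_bundles, tiny_bundle):
        _, annotations = tiny_bundle
        bundle = restored_bundles["oracle"]
        maps = [anomaly_map(x, r) for x, r in bundle.pathological_pairs()]
        results = ceiling_dice(maps, annotations.masks)
        strata = {r.stratum for r in results}
        assert strata == {"small", "medium", "large", "all"}
        all_result = next(r for r in results if r.stratum == "all")
        assert all_result.n_cases == len(maps)

    def test_missing_mask_rejected(self):
        with pytest.raises(DataError, match="ghost"):
            ceiling_dice_single([AnomalyMap("ghost", np.zeros((4, 4)))], {})


class TestStratifyLesions:
    @staticmethod
    def _masks(sizes):
        out = {}
        for i, s in enumerate(sizes):
            m = np.zeros((32, 32), dtype=np.uint8)
            m.ravel()[:s] = 1
            out[f"p{i}"] = m
        return out

    def test_quantile_mode_uses_quartiles(self):
        masks = self._masks([10, 20, 30, 40])
        strata = stratify_lesions(masks, mode="quantile")
        lo = np.percentile([10, 20, 30, 40], 25)
        hi = np.percentile([10, 20, 30, 40], 75)
        assert strata["p0"] == "small" and 10 < lo
        assert strata["p3"] == "large" and 40 >= hi
        assert strata["p1"] == "medium" and strata["p2"] == "medium"

    def test_fixed_boundary_semantics(self):
        masks = self._masks([70, 71, 569, 570])
        strata = stratify_lesions(masks, mode="fixed", cuts=(71, 570))
        assert strata["p0"] == "small"      # 70 < 71
        assert strata["p1"] == "medium"     # 71 is not < 71
        assert strata["p2"] == "medium"
        assert strata["p3"] == "large"      # 570 >= 570

    def test_equal_sizes_all_medium(self):
        strata = stratify_lesions(self._masks([25, 25, 25]))
        assert set(strata.values()) == {"medium"}

    def test_fixed_requires_ordered_cuts(self):
        with pytest.raises(UsageError):
            stratify_lesions(self._masks([5]), mode="fixed", cuts=(100, 50))
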