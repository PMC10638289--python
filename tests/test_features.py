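"""Geometric features, the cutoff classifier, and cutoff evaluation."""

import math

import numpy as np
import pytest

from chp import (
    ClassificationRule,
    FeatureRecord,
    NucleusImage,
    chromatin_density,
    classify,
    compute_profile,
    evaluate_cutoff,
    extract_features,
    ns_diagonal,
)


def record(b1max=40, hv=60, density=0.02, **kw):
    ns = math.sqrt(b1max / density) if density else 30.0
    return FeatureRecord(
        nucleus_id=kw.get("nucleus_id", "n0"),
        b1max=b1max,
        hv=hv,
        bi=kw.get("bi", 120),
        ns=ns,
        ns2=ns * ns,
        density=density,
        label=kw.get("label"),
    )


class TestNsDiagonal:
    @pytest.mark.parametrize(
        "h, w, expected",
        [(3, 4, 5.0), (1, 1, math.sqrt(2)), (10, 10, math.sqrt(200))],
    )
    def test_bounding_box_diagonal(self, h, w, expected):
        mask = np.zeros((h + 4, w + 4), bool)
        mask[2 : 2 + h, 2 : 2 + w] = True
        assert ns_diagonal(mask) == pytest.approx(expected)

    def test_sparse_mask_uses_tight_box(self):
        # only the two opposite corners are inside; box is still 3x4
        mask = np.zeros((10, 10), bool)
        mask[1, 1] = mask[3, 4] = True
        assert ns_diagonal(mask) == pytest.approx(5.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ns_diagonal(np.zeros((5, 5), bool))


class TestChromatinDensity:
    def test_reference_scale(self):
        assert chromatin_density(50, math.sqrt(1000)) == pytest.approx(0.05)

    def test_no_holes_means_zero_density(self):
        assert chromatin_density(0, 12.0) == 0.0

    def test_doubling_ns_quarters_density(self):
        assert chromatin_density(40, 20.0) == pytest.approx(4 * chromatin_density(40, 40.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chromatin_density(10, 0.0)
        with pytest.raises(ValueError):
            chromatin_density(-1, 5.0)


class TestClassify:
    def test_low_b1max_is_small_cell(self):
        assert classify(record(b1max=20)) == "small_cell"

    def test_density_splits_adeno_from_squamous(self):
        assert classify(record(b1max=40, density=0.08)) == "adeno"
        assert classify(record(b1max=40, density=0.02)) == "squamous"

    def test_boundary_values_fall_on_the_ge_side(self):
        assert classify(record(b1max=25, density=0.02)) == "squamous"
        assert classify(record(b1max=40, density=0.05)) == "adeno"

    def test_hv_stage_disabled_by_default(self):
        assert classify(record(b1max=40, hv=250, density=0.08)) == "adeno"

    def test_hv_stage_flags_non_cancerous_when_enabled(self):
        rule = ClassificationRule(hv_cutoff=100.0)
        assert classify(record(hv=150), rule) == "non_cancerous"
        assert classify(record(hv=80, b1max=20), rule) == "small_cell"

    def test_missing_hv_rejected_only_when_stage_enabled(self):
        rec = record(hv=None, b1max=20)
        assert classify(rec) == "small_cell"
        with pytest.raises(ValueError, match="hv"):
            classify(rec, ClassificationRule(hv_cutoff=100.0))

    def test_deterministic_and_order_independent(self, rng):
        recs = [record(b1max=int(b), density=float(d), nucleus_id=str(i))
                for i, (b, d) in enumerate(zip(rng.integers(5, 80, 40),
                                               rng.uniform(0.001, 0.1, 40)))]
        first = [classify(r) for r in recs]
        perm = rng.permutation(len(recs))
        assert [classify(recs[i]) for i in perm] == [first[i] for i in perm]

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            ClassificationRule(b1max_cutoff=0)


class TestEvaluateCutoff:
    def test_perfect_separation(self):
        sens, spec = evaluate_cutoff([1, 2, 9, 10], [0, 0, 1, 1], 5, "high")
        assert (sens, spec) == (1.0, 1.0)

    def test_cutoff_below_all_values_calls_everything_positive(self):
        sens, spec = evaluate_cutoff([5, 6, 7, 8], [1, 1, 0, 0], 0, "high")
        assert (sens, spec) == (1.0, 0.0)

    def test_six_point_worked_confusion_table(self):
        # positives {3,10,11}, negatives {1,2,5}, cutoff 4 (high):
        # TP=2 FN=1 TN=2 FP=1 by direct enumeration
        sens, spec = evaluate_cutoff([3, 10, 11, 1, 2, 5], [1, 1, 1, 0, 0, 0], 4, "high")
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(2 / 3)

    def test_degenerate_cutoffs(self):
        values, labels = [1.0, 2.0, 3.0], [1, 0, 1]
        assert evaluate_cutoff(values, labels, -np.inf, "high") == (1.0, 0.0)
        assert evaluate_cutoff(values, labels, np.inf, "high") == (0.0, 1.0)

    def test_low_direction_mirrors_classifier_boundary(self):
        # "positive" = value strictly below the cutoff, as for the
        # small-cell b1MAX call
        sens, spec = evaluate_cutoff([20, 25, 30], [1, 0, 0], 25, "low")
        assert (sens, spec) == (1.0, 1.0)

    def test_one_class_labels_rejected(self):
        with pytest.raises(ValueError):
            evaluate_cutoff([1, 2], [1, 1], 1.5)


class TestEndToEndScaling:
    def test_upsampling_preserves_b1max_and_divides_density_by_k2(self, ring_nucleus):
        k = 3
        rec1 = extract_features(ring_nucleus, "orig")
        up = NucleusImage(
            np.kron(ring_nucleus.intensity, np.ones((k, k), np.uint8)),
            np.kron(ring_nucleus.mask, np.ones((k, k), bool)),
        )
        reck = extract_features(up, "up")
        assert reck.b1max == rec1.b1max
        assert reck.density == pytest.approx(rec1.density / k**2)

    def test_extract_features_is_consistent_with_profile(self, ring_nucleus):
        rec = extract_features(ring_nucleus, "r", hole_threshold=1)
        prof = compute_profile(ring_nucleus, hole_threshold=1)
        assert rec.b1max == prof.b1max and rec.hv == prof.hv
        assert rec.ns2 == pytest.approx(rec.ns**2)
        assert rec.density == pytest.approx(rec.b1max / rec.ns2)
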