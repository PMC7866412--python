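"""Equal-weight and stochastic decision fusion, including the reference worked example."""

import numpy as np
import pytest

from sdfuse import (
    ConfusionMatrix,
    ScoreVector,
    ValidationError,
    calibrate_confusion,
    equal_weight_fuse,
    sdf_fuse,
    sdf_weights,
)


class TestCalibrateConfusion:
    def test_direct_counting_two_classes(self):
        cm = calibrate_confusion([0, 1, 0, 1], [0, 0, 1, 1], M=2)
        assert np.allclose(cm.values, [[0.5, 0.5], [0.5, 0.5]])

    def test_perfect_predictions_give_identity_on_predicted_classes(self):
        cm = calibrate_confusion([0, 1, 2, 1, 0], [0, 1, 2, 1, 0], M=3)
        assert np.allclose(cm.values, np.eye(3))

    def test_never_predicted_class_yields_degenerate_column(self):
        cm = calibrate_confusion([0, 1, 0, 1], [0, 1, 2, 2], M=3)
        assert list(cm.degenerate_columns) == [False, False, True]
        assert np.all(cm.values[:, 2] == 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            calibrate_confusion([0, 1], [0], M=2)


class TestEqualWeightFuse:
    def test_identical_vectors_fuse_to_their_direction(self):
        v = np.array([0.2, 0.6, 0.1, 0.05, 0.05])
        dec = equal_weight_fuse([ScoreVector(v), ScoreVector(v)])
        assert np.allclose(dec.fused_scores, v / np.linalg.norm(v))
        assert dec.stage.index == 1

    def test_reference_inputs_tie_resolves_to_earliest_stage(self, stem_scores, flower_scores):
        """The reference two-view disagreement averages to an exact Turning/Pink tie."""
        pre = 0.5 * (stem_scores.scores + flower_scores.scores)
        assert pre[0] == pre[1] == pytest.approx(0.45)
        assert np.allclose(pre, [0.45, 0.45, 0.075, 0.0125, 0.0125])
        dec = equal_weight_fuse([stem_scores, flower_scores])
        assert dec.stage.name == "Turning"  # tie broken toward the less-ripe stage

    def test_orthogonal_unit_vectors_tie_to_stage_zero(self):
        dec = equal_weight_fuse([ScoreVector(np.array([1.0, 0.0])), ScoreVector(np.array([0.0, 1.0]))])
        assert dec.stage.index == 0

    def test_all_zero_sum_is_degenerate(self):
        dec = equal_weight_fuse([ScoreVector(np.zeros(3)), ScoreVector(np.zeros(3))])
        assert dec.degenerate and dec.stage is None

    def test_single_view_rejected(self):
        with pytest.raises(ValidationError):
            equal_weight_fuse([ScoreVector(np.ones(3))])


class TestSdfWeights:
    def test_reference_worked_example(self, stem_scores, flower_scores,
                                      stem_confusion, flower_confusion):
        a1, a2 = sdf_weights([stem_scores, flower_scores], [stem_confusion, flower_confusion])
        assert np.allclose(a1.weights, [0.9 / 1.7, 0.1 / 0.25, 0, 0, 0], atol=1e-6)
        assert np.allclose(a2.weights, [0.1 / 0.14, 0.8 / 1.72, 0.1 / 0.14, 0, 0], atol=1e-6)

    def test_identical_matrices_and_winning_class_split_evenly(self, stem_confusion):
        v = ScoreVector(np.array([0.9, 0.05, 0.02, 0.02, 0.01]))
        a1, a2 = sdf_weights([v, v], [stem_confusion, stem_confusion])
        col = stem_confusion.column(0)
        expected = np.where(col > 0, 0.5, 0.0)
        assert np.allclose(a1.weights, expected)
        assert np.allclose(a2.weights, expected)

    def test_identity_matrices_disagreeing_views(self):
        eye = ConfusionMatrix(np.eye(3), ["a", "b", "c"])
        v1 = ScoreVector(np.array([0.9, 0.1, 0.0]))
        v2 = ScoreVector(np.array([0.1, 0.9, 0.0]))
        a1, a2 = sdf_weights([v1, v2], [eye, eye])
        assert np.allclose(a1.weights, [0.5, 0, 0])
        assert np.allclose(a2.weights, [0, 0.5, 0])

    def test_zero_over_zero_half_convention(self):
        eye = ConfusionMatrix(np.eye(3), ["a", "b", "c"])
        v = ScoreVector(np.array([0.9, 0.1, 0.0]))
        a1, a2 = sdf_weights([v, v], [eye, eye], zero_over_zero="half")
        assert np.allclose(a1.weights, [0.5, 0.5, 0.5])

    def test_mismatched_m_rejected(self, stem_confusion):
        with pytest.raises(ValidationError):
            sdf_weights([ScoreVector(np.ones(4)), ScoreVector(np.ones(4))],
                        [stem_confusion, stem_confusion])


class TestSdfFuse:
    def test_reference_worked_example_selects_turning(self, stem_scores, flower_scores,
                                                      stem_confusion, flower_confusion):
        """Independent hand computation of the weighted fusion on the reference inputs:
        the stem-end view's more precise Turning call outweighs the flower-end's Pink."""
        dec = sdf_fuse([stem_scores, flower_scores], [stem_confusion, flower_confusion])
        pre = np.array([0.9 / 1.7 * 0.8 + 0.1 / 0.14 * 0.1,
                        0.1 / 0.25 * 0.1 + 0.8 / 1.72 * 0.8,
                        0.1 / 0.14 * 0.1, 0.0, 0.0])
        assert np.allclose(pre, [0.494958, 0.412093, 0.071429, 0, 0], atol=1e-6)
        assert np.allclose(dec.fused_scores, pre / np.linalg.norm(pre), atol=1e-12)
        assert dec.stage.name == "Turning"
        assert [s.name for s in dec.per_view_stages] == ["Turning", "Pink"]

    def test_zero_view_contributes_nothing(self, stem_confusion, flower_confusion):
        v = ScoreVector(np.array([0.7, 0.2, 0.1, 0.0, 0.0]))
        zero = ScoreVector(np.zeros(5))
        dec = sdf_fuse([v, zero], [stem_confusion, flower_confusion])
        alpha = sdf_weights([v, zero], [stem_confusion, flower_confusion])[0].weights
        expected = alpha * v.scores
        assert np.allclose(dec.fused_scores, expected / np.linalg.norm(expected))

    def test_all_zero_fusion_is_degenerate(self):
        eye = ConfusionMatrix(np.eye(2), ["a", "b"])
        z = ScoreVector(np.zeros(2))
        # both views silent: fused vector has no mass anywhere
        dec = sdf_fuse([z, z], [eye, eye])
        assert dec.degenerate and dec.stage is None


def _random_column_stochastic(rng, M, diag_boost=0.0, positive=False):
    cols = rng.dirichlet(np.ones(M), size=M).T
    if positive:
        cols = cols + 0.05
    cols[np.arange(M), np.arange(M)] += diag_boost
    cols /= cols.sum(axis=0)
    return ConfusionMatrix(cols, [f"c{j}" for j in range(M)])


class TestFusionProperties:
    def test_fused_norm_weight_partition_and_order_invariance(self):
        rng = np.random.default_rng(101)
        for _ in range(300):
            M = int(rng.integers(2, 7))
            n_views = int(rng.integers(2, 4))
            mats = [_random_column_stochastic(rng, M) for _ in range(n_views)]
            vecs = [ScoreVector(rng.random(M)) for _ in range(n_views)]
            alphas = sdf_weights(vecs, mats)
            if len({v.argmax() for v in vecs}) == 1:
                # shared winner => all views divide the same column: weights
                # partition each coordinate (sum 1, or 0 without any mass)
                per_coord = np.sum([a.weights for a in alphas], axis=0)
                assert np.all((np.abs(per_coord - 1) < 1e-12) | (np.abs(per_coord) < 1e-12))
            dec = sdf_fuse(vecs, mats)
            if not dec.degenerate:
                assert np.linalg.norm(dec.fused_scores) == pytest.approx(1.0, abs=1e-12)
            perm = rng.permutation(n_views)
            dec_p = sdf_fuse([vecs[i] for i in perm], [mats[i] for i in perm])
            assert np.allclose(dec_p.fused_scores, dec.fused_scores)
            if not dec.degenerate:
                assert dec_p.stage == dec.stage
            assert [dec_p.per_view_stages[i] for i in np.argsort(perm)] == list(dec.per_view_stages)

    def test_agreement_preserved_under_cross_view_margin(self):
        """When every view's score for the shared winning class exceeds every
        view's score for any other class, the fused stage must be that class:
        per-coordinate weights sum to 1, so each fused coordinate is a convex
        combination across views."""
        rng = np.random.default_rng(202)
        for _ in range(500):
            M = int(rng.integers(2, 7))
            m = int(rng.integers(M))
            mats = [_random_column_stochastic(rng, M, diag_boost=2.0) for _ in range(2)]
            vecs = []
            off_max = 0.0
            raw = [rng.uniform(0, 0.6, M) for _ in range(2)]
            for r in raw:
                r[m] = 0.0
                off_max = max(off_max, r.max())
            for r in raw:
                r[m] = off_max + rng.uniform(0.01, 0.3)
                vecs.append(ScoreVector(r))
            dec = sdf_fuse(vecs, mats)
            assert dec.stage.index == m

    def test_within_view_agreement_alone_does_not_pin_the_stage(self):
        """Both views call class 0 and both matrices are diagonally dominant,
        yet the fused argmax lands on class 1: the view holding nearly all the
        weight on coordinate 1 also scores it close to its own winner. This is
        the boundary of the agreement guarantee — it needs the cross-view
        margin, not just per-view agreement."""
        cols1 = np.array([
            [0.7931, 0.10, 0.10, 0.10],
            [0.0152, 0.70, 0.10, 0.10],
            [0.0464, 0.10, 0.70, 0.10],
            [0.1453, 0.10, 0.10, 0.70],
        ])
        cols2 = np.array([
            [0.8055, 0.10, 0.10, 0.10],
            [0.0611, 0.70, 0.10, 0.10],
            [0.1227, 0.10, 0.70, 0.10],
            [0.0107, 0.10, 0.10, 0.70],
        ])
        m1 = ConfusionMatrix(cols1 / cols1.sum(axis=0), [f"c{j}" for j in range(4)])
        m2 = ConfusionMatrix(cols2 / cols2.sum(axis=0), [f"c{j}" for j in range(4)])
        v1 = ScoreVector(np.array([0.3541, 0.3219, 0.2615, 0.0625]))
        v2 = ScoreVector(np.array([0.4591, 0.4410, 0.0769, 0.0231]))
        assert v1.argmax() == v2.argmax() == 0
        dec = sdf_fuse([v1, v2], [m1, m2])
        assert dec.stage.index == 1

    def test_equivalence_with_equal_positive_confusions(self):
        """With both views sharing one strictly positive confusion matrix, the
        selected columns have full support, every weight is exactly 1/2, and
        the SDF decision coincides with equal weighting (ties aside)."""
        rng = np.random.default_rng(303)
        checked = 0
        for _ in range(1200):
            M = int(rng.integers(2, 7))
            cm = _random_column_stochastic(rng, M, positive=True)
            vecs = [ScoreVector(rng.random(M)) for _ in range(2)]
            total = vecs[0].scores + vecs[1].scores
            top = np.sort(total)[-2:]
            if top[0] == top[1]:  # exact tie: excluded by the property
                continue
            assert sdf_fuse(vecs, [cm, cm]).stage.index == equal_weight_fuse(vecs).stage.index
            checked += 1
        assert checked >= 1000
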