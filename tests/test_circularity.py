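"""Circularity pipeline: screening, matrices, MDS, alignment, spline, C."""

import math

import numpy as np
import pandas as pd
import pytest

from artbox.circularity import (
    DissimilarityMatrix,
    PerceptualConfiguration,
    SimilarityMatrix,
    affine_align,
    aggregate_similarity,
    circularity,
    circularity_report,
    combine_configurations,
    exclude_participants,
    group_dissimilarity,
    mds_embed,
    periodic_spline,
    regular_polygon_circularity,
)
from artbox.simulate import (
    ANCHORS,
    SimilarityGenSpec,
    gen_similarity_study,
)


def ratings_df(rows):
    return pd.DataFrame(rows, columns=["participant_id", "tone_a", "tone_b", "rating"])


class TestScreeningAndMatrices:
    def test_self_similarity_threshold(self):
        trials = ratings_df(
            [("good", 24, 24, 5), ("good", 24, 24, 4), ("good", 48, 48, 4),
             ("good", 48, 48, 5), ("bad", 24, 24, 3), ("bad", 48, 48, 4)]
        )
        assert exclude_participants(trials) == ["good"]

    def test_participant_without_self_trials_errors(self):
        trials = ratings_df([("p1", 24, 48, 3)])
        with pytest.raises(ValueError, match="identical-pair"):
            exclude_participants(trials)

    def test_aggregation_symmetrizes_over_order(self):
        trials = ratings_df(
            [("p", 24, 48, 4), ("p", 48, 24, 2), ("p", 24, 24, 5), ("p", 48, 48, 5)]
        )
        mat = aggregate_similarity(trials, "p")
        i, j = list(mat.labels).index(24), list(mat.labels).index(48)
        assert mat.values[i, j] == mat.values[j, i] == 3.0
        assert np.allclose(mat.values, mat.values.T)

    def test_aggregation_missing_pair_named(self):
        trials = ratings_df(
            [("p", 24, 24, 5), ("p", 48, 48, 5), ("p", 72, 72, 5), ("p", 24, 48, 3)]
        )
        with pytest.raises(ValueError, match=r"\(24, 72\)"):
            aggregate_similarity(trials, "p")

    def test_reverse_coding_and_linearity(self):
        labels = np.array([24, 48])
        m1 = SimilarityMatrix(labels, np.array([[5.0, 3.98], [3.98, 5.0]]))
        m2 = SimilarityMatrix(labels, np.array([[5.0, 2.0], [2.0, 5.0]]))
        dis = group_dissimilarity([m1, m2])
        assert dis.values[0, 1] == pytest.approx(5.0 - (3.98 + 2.0) / 2.0)
        assert dis.values[0, 0] == pytest.approx(0.0)
        with pytest.raises(ValueError):
            group_dissimilarity([m1, SimilarityMatrix(np.array([24, 72]), m2.values)])


class TestEmbeddingAndAlignment:
    def test_exact_euclidean_recovery(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        cfg = mds_embed(DissimilarityMatrix(np.arange(8), d))
        got = np.linalg.norm(cfg.points[:, None] - cfg.points[None, :], axis=-1)
        assert np.max(np.abs(got - d)) < 1e-6
        assert cfg.stress < 1e-6

    def test_zero_dissimilarity_coincident_points(self):
        pts = np.array([[0, 0], [0, 0], [1, 0], [0, 1], [1, 1.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        cfg = mds_embed(DissimilarityMatrix(np.arange(5), d))
        assert np.linalg.norm(cfg.points[0] - cfg.points[1]) < 1e-6

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3.5, 2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            mds_embed(DissimilarityMatrix(np.arange(4), d))

    @pytest.mark.parametrize(
        "transform",
        [
            lambda p: 2.0 * p @ np.array([[0.0, -1.0], [1.0, 0.0]]),  # rot + scale
            lambda p: p @ np.array([[1.0, 0.0], [0.0, -1.0]]) + [3.0, -1.0],  # refl
        ],
    )
    def test_affine_alignment_recovers_similarity_transforms(self, transform):
        rng = np.random.default_rng(2)
        ref_pts = rng.normal(size=(9, 2))
        labels = np.arange(9)
        ref = PerceptualConfiguration(labels, ref_pts)
        src = PerceptualConfiguration(labels, transform(ref_pts))
        aligned = affine_align(src, ref, anchor_labels=[0, 3, 6])
        assert np.max(np.abs(aligned.points - ref_pts)) < 1e-9

    def test_collinear_anchors_rejected(self):
        labels = np.arange(4)
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
        cfg = PerceptualConfiguration(labels, pts)
        with pytest.raises(ValueError, match="collinear"):
            affine_align(cfg, cfg, anchor_labels=[0, 1, 2])

    def test_combination_merges_anchors(self):
        lab1 = np.array([48, 120, 240, 360])
        lab2 = np.array([24, 120, 240, 360])
        p1 = np.array([[0, 1], [1, 0], [0, -1], [-1, 0.0]])
        p2 = p1 + np.array([0.2, 0.0])
        combined = combine_configurations(
            PerceptualConfiguration(lab1, p1),
            PerceptualConfiguration(lab2, p2),
            anchor_labels=[120, 240, 360],
        )
        assert combined.labels.tolist() == [24, 48, 120, 240, 360]
        i120 = combined.labels.tolist().index(120)
        assert np.allclose(combined.points[i120], [1.1, 0.0])

    def test_non_anchor_collision_rejected(self):
        lab = np.array([24, 120, 240, 360])
        cfg = PerceptualConfiguration(lab, np.eye(4, 2))
        with pytest.raises(ValueError, match="non-anchor"):
            combine_configurations(cfg, cfg, anchor_labels=[120, 240])


class TestSplineAndC:
    def test_spline_through_circle_points(self, regular_polygon):
        labels = np.arange(24, 361, 24)
        cfg = PerceptualConfiguration(labels, regular_polygon(15))
        curve = periodic_spline(cfg)
        radii = np.linalg.norm(curve.samples, axis=1)
        assert np.max(np.abs(radii - 1.0)) < 1e-3
        assert curve.C > 0.999
        assert np.allclose(curve.samples[0], curve.samples[-1])

    def test_spline_square_is_smooth_closed(self):
        cfg = PerceptualConfiguration(
            np.array([90, 180, 270, 360]),
            np.array([[1, 1], [-1, 1], [-1, -1], [1, -1.0]]),
        )
        curve = periodic_spline(cfg)
        for corner in cfg.points:
            assert np.min(np.linalg.norm(curve.samples - corner, axis=1)) < 1e-9
        assert 0 < curve.C <= 1.0 + 1e-6

    @pytest.mark.parametrize("n", range(8, 21))
    def test_spline_c_beats_polygon_c_on_ngons(self, n, regular_polygon):
        pts = regular_polygon(n)
        cfg = PerceptualConfiguration(np.arange(1, n + 1) * (360.0 / n), pts)
        assert periodic_spline(cfg).C >= circularity(pts)

    def test_duplicate_degrees_rejected(self):
        cfg = PerceptualConfiguration(
            np.array([24, 24, 48, 72]), np.arange(8.0).reshape(4, 2)
        )
        with pytest.raises(ValueError, match="duplicate"):
            periodic_spline(cfg)

    @pytest.mark.parametrize("n", range(3, 31))
    def test_regular_ngon_closed_form(self, n, regular_polygon):
        c = circularity(regular_polygon(n, radius=2.3, phase=0.7))
        assert c == pytest.approx((math.pi / n) / math.tan(math.pi / n), abs=1e-9)
        assert c == pytest.approx(regular_polygon_circularity(n), abs=1e-12)

    def test_square_quarter_pi(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert circularity(square) == pytest.approx(math.pi / 4.0, abs=1e-12)

    def test_invariance_under_similarity_transforms(self, regular_polygon):
        pts = regular_polygon(12)
        base = circularity(pts)
        rot = np.array([[0.6, -0.8], [0.8, 0.6]])
        for t in [pts @ rot, 5.0 * pts + [2, 3], pts * [1, -1]]:
            assert circularity(t) == pytest.approx(base, abs=1e-9)

    def test_isoperimetric_bound(self, regular_polygon):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 40))
            pts = regular_polygon(n) + 0.1 * rng.normal(size=(n, 2))
            try:
                assert circularity(pts) <= 1.0 + 1e-6
            except ValueError:
                pass  # degenerate draw

    def test_self_intersection_warns(self):
        bowtie = np.array([[0, 0], [2, 2], [2, 0], [0, 1.0]])  # crossing lobes
        with pytest.warns(UserWarning, match="self-intersect"):
            c = circularity(bowtie)
        assert 0 < c <= 1.0 + 1e-6

    def test_radial_noise_never_helps(self, regular_polygon):
        """Mean C over seeds decreases as radial noise grows."""
        levels = [0.0, 0.05, 0.15]
        means = []
        for noise in levels:
            cs = []
            for seed in range(12):
                rng = np.random.default_rng(seed)
                theta = 2 * np.pi * np.arange(15) / 15
                r = 1.0 + noise * rng.normal(size=15)
                pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
                cs.append(circularity(pts))
            means.append(np.mean(cs))
        assert means[0] >= means[1] >= means[2]

    def test_spline_sampling_converged(self, regular_polygon):
        cfg = PerceptualConfiguration(
            np.arange(24, 361, 24), regular_polygon(15) + 0.02
        )
        c1 = periodic_spline(cfg, samples=1000).C
        c2 = periodic_spline(cfg, samples=2000).C
        assert abs(c1 - c2) < 1e-4


class TestEndToEnd:
    def test_noise_free_circular_ratings_give_high_c(self):
        """Continuous noise-free distance-driven ratings embed on a circle."""
        spec = SimilarityGenSpec(
            n_participants_per_set=2, noise_sd=0.0, discretize=False, seed=3
        )
        trials = gen_similarity_study(spec)
        sets = {
            s: sorted(trials.loc[trials["set"] == s, "participant_id"].unique())
            for s in (1, 2)
        }
        rep = circularity_report(trials, sets, list(ANCHORS))
        assert rep["C_spline"] >= 0.9
        assert rep["C_polygon"] <= rep["C_spline"] + 1e-9

    def test_default_likert_study_gives_high_c(self):
        """The full default study (integer Likert, noise) still reaches 0.9.

        Rating noise matters here: it dithers the integer Likert rounding,
        so averaging over repeats recovers the underlying distance gradient
        that a noise-free quantized study destroys.
        """
        spec = SimilarityGenSpec(seed=3)
        trials = gen_similarity_study(spec)
        sets = {
            s: sorted(trials.loc[trials["set"] == s, "participant_id"].unique())
            for s in (1, 2)
        }
        rep = circularity_report(trials, sets, list(ANCHORS))
        assert rep["C_spline"] >= 0.9

    def test_distance_blind_ratings_break_circularity(self):
        spec = SimilarityGenSpec(
            n_participants_per_set=2, slope=0.0, intercept=3.0, noise_sd=1.0, seed=4
        )
        trials = gen_similarity_study(spec)
        sets = {
            s: sorted(trials.loc[trials["set"] == s, "participant_id"].unique())
            for s in (1, 2)
        }
        rep = circularity_report(trials, sets, list(ANCHORS))
        assert rep["C_spline"] < 0.9

    def test_single_set_path(self, small_similarity_study):
        _, trials = small_similarity_study
        one_set = trials[trials["set"] == 1]
        pids = sorted(one_set["participant_id"].unique())
        rep = circularity_report(one_set, {1: pids}, list(ANCHORS))
        assert 0.0 < rep["C_spline"] <= 1.0 + 1e-6
        assert rep["n_retained"] == len(pids)

    def test_embedding_preserves_tone_order(self, small_similarity_study):
        """Angular order of embedded points matches the true tone order."""
        _, trials = small_similarity_study
        sets = {
            s: sorted(trials.loc[trials["set"] == s, "participant_id"].unique())
            for s in (1, 2)
        }
        rep = circularity_report(trials, sets, list(ANCHORS))
        cfg = rep["configuration"]
        centred = cfg.points - cfg.points.mean(axis=0)
        angles = np.arctan2(centred[:, 1], centred[:, 0])
        # unwrap the circular sequence starting from the first label
        order = np.argsort(cfg.labels)
        a = angles[order]
        diffs = np.diff(np.concatenate([a, a[:1]]))
        diffs = (diffs + np.pi) % (2 * np.pi) - np.pi
        # all steps share one orientation: the labels wind once around the centre
        assert np.all(diffs > 0) or np.all(diffs < 0)
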