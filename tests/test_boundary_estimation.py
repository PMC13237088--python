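import numpy as np
import pytest
from sklearn.metrics import roc_curve as sk_roc_curve

from lcrbench.boundary_estimation import (
    LabeledPoint,
    bin_points,
    boundary_contour,
    fit_smooth_surface,
    lc_permissive_fraction,
    posterior_probability,
    roc_curve,
    score_points,
    split_points,
    youden_optimal,
)


def diagonal_cloud(n, seed, cut=100.0, delta=2.0):
    """Separable cloud: positives above x + y = cut; points in bins cut by
    the line are excluded so every occupied bin is class-pure."""
    rng = np.random.default_rng(seed)
    nb = round(100 / delta)
    pts = rng.uniform(0, 100, (n, 2))
    ix = np.minimum(np.floor(pts[:, 0] / delta).astype(int), nb - 1)
    iy = np.minimum(np.floor(pts[:, 1] / delta).astype(int), nb - 1)
    # a bin is cut by the line iff its interior sum range (delta*(ix+iy),
    # delta*(ix+iy) + 2*delta) contains the cut value
    s = (ix + iy).astype(float)
    mixed = (delta * s < cut - 1e-9) & (cut < delta * s + 2 * delta - 1e-9)
    pts = pts[~mixed]
    return [
        LabeledPoint(x, y, "LC" if x + y > cut else "BG") for x, y in pts
    ]


class TestBinPoints:
    def test_floor_binning(self):
        surf = bin_points([LabeledPoint(3, 7, "LC")])
        assert surf.n_pos[1, 3] == 1 and surf.n_pos.sum() == 1

    def test_top_edge_closed_into_last_bin(self):
        surf = bin_points([LabeledPoint(100, 100, "BG")])
        assert surf.n_neg[49, 49] == 1

    def test_empty_input_gives_uniform_half(self):
        surf = bin_points([])
        assert np.all(posterior_probability(surf) == 0.5)

    def test_bad_delta_rejected(self):
        with pytest.raises(ValueError):
            bin_points([], delta=3.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_points([LabeledPoint(101, 5, "LC")])


class TestPosteriorProbability:
    def test_smoothing_formula(self):
        surf = bin_points(
            [LabeledPoint(1, 1, "LC")] * 3 + [LabeledPoint(1, 1, "BG")]
        )
        assert posterior_probability(surf)[0, 0] == pytest.approx(4 / 6)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        pts = [
            LabeledPoint(x, y, "LC" if rng.random() < 0.5 else "BG")
            for x, y in rng.uniform(0, 100, (500, 2))
        ]
        prob = posterior_probability(bin_points(pts))
        assert prob.min() > 0 and prob.max() < 1

    def test_zero_pseudocount_equals_empirical_frequency(self, rng):
        pts = [LabeledPoint(1, 1, "LC")] * 7 + [LabeledPoint(1, 1, "BG")] * 3
        surf = bin_points(pts, pseudocount=0.0)
        assert posterior_probability(surf)[0, 0] == pytest.approx(0.7)

    def test_larger_pseudocount_pulls_toward_half(self):
        pts = [LabeledPoint(1, 1, "LC")] * 9 + [LabeledPoint(1, 1, "BG")]
        probs = [
            posterior_probability(bin_points(pts, pseudocount=a))[0, 0]
            for a in (0.0, 1.0, 5.0, 50.0)
        ]
        assert all(abs(b - 0.5) < abs(a - 0.5) for a, b in zip(probs, probs[1:]))


class TestRocCurve:
    def test_perfectly_separated(self):
        roc = roc_curve(
            np.array([0.9, 0.9, 0.1, 0.1]), ["LC", "LC", "BG", "BG"]
        )
        assert roc.youden_j.max() == pytest.approx(1.0)
        t = youden_optimal(roc)
        assert 0.1 < t <= 0.9

    def test_uninformative_scores(self):
        roc = roc_curve(np.full(6, 0.5), ["LC", "BG"] * 3)
        assert np.allclose(roc.tpr, roc.fpr)
        assert youden_optimal(roc) == roc.thresholds[0]

    def test_four_point_example(self):
        scores = np.array([0.8, 0.6, 0.4, 0.2])
        labels = ["LC", "BG", "LC", "BG"]
        roc = roc_curve(scores, labels, thresholds=np.array([0.4]))
        assert roc.tpr[0] == 1.0 and roc.fpr[0] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.5, 0.6]), ["LC", "LC"])

    def test_matches_brute_force_and_sklearn_on_random_scores(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.random(n).round(2)
            labels = ["LC" if rng.random() < 0.5 else "BG" for _ in range(n)]
            if len(set(labels)) < 2:
                continue
            roc = roc_curve(scores, labels)
            pos = np.array([l == "LC" for l in labels])
            # brute force per threshold
            for t, tp_rate, fp_rate in zip(roc.thresholds, roc.tpr, roc.fpr):
                calls = scores >= t
                assert tp_rate == (calls & pos).sum() / pos.sum()
                assert fp_rate == (calls & ~pos).sum() / (~pos).sum()
            # cross-check the attainable operating points against sklearn
            # (sklearn's leading point belongs to an unattainable threshold
            # above the maximal score and is skipped)
            sk_fpr, sk_tpr, sk_t = sk_roc_curve(pos.astype(int), scores)
            ours = {(round(f, 12), round(t_, 12)) for f, t_ in zip(roc.fpr, roc.tpr)}
            for f, t_, th in zip(sk_fpr, sk_tpr, sk_t):
                if th > 1.0:
                    continue
                assert (round(f, 12), round(t_, 12)) in ours

    def test_youden_optimality_exhaustive(self, rng):
        scores = rng.random(50)
        labels = ["LC" if rng.random() < 0.4 else "BG" for _ in range(50)]
        roc = roc_curve(scores, labels)
        t_star = youden_optimal(roc)
        j_star = roc.youden_j[np.searchsorted(roc.thresholds, t_star)]
        assert np.all(roc.youden_j <= j_star + 1e-12)
        winners = roc.thresholds[roc.youden_j == roc.youden_j.max()]
        assert t_star == winners.min()  # tie rule: smallest threshold


class TestBoundaryContour:
    def test_constant_surface_has_no_contour(self):
        surf = bin_points([])
        assert boundary_contour(surf, 0.9) == []

    def test_vertical_split_yields_midline(self):
        pts = [LabeledPoint(x, y, "LC" if x < 50 else "BG")
               for x in range(1, 100, 2) for y in range(1, 100, 2)]
        surf = bin_points(pts)
        contours = boundary_contour(surf, 0.5)
        xs = np.vstack(contours)[:, 0]
        assert np.all(np.abs(xs - 50) <= 2.0)

    def test_separable_diagonal_recovered_within_one_bin(self):
        train = diagonal_cloud(40000, seed=4)
        surf = bin_points(train)
        held = diagonal_cloud(10000, seed=5)
        roc = roc_curve(score_points(surf, held), [p.label for p in held])
        assert roc.youden_j.max() == 1.0
        t_star = youden_optimal(roc)
        pts = np.vstack(boundary_contour(surf, t_star))
        dist = np.abs(pts.sum(axis=1) - 100) / np.sqrt(2)
        assert (dist <= 2.0).mean() >= 0.95


class TestSmoothSurface:
    def test_recovers_planar_logistic_surface(self):
        rng = np.random.default_rng(11)
        xy = rng.uniform(0, 100, (5000, 2))
        p_true = 1 / (1 + np.exp(-0.08 * (xy[:, 1] - xy[:, 0])))
        labels = np.where(rng.random(5000) < p_true, "LC", "BG")
        pts = [LabeledPoint(x, y, l) for (x, y), l in zip(xy, labels)]
        surf = fit_smooth_surface(pts, seed=2)
        gx, gy = np.meshgrid(surf.grid_centers, surf.grid_centers, indexing="ij")
        truth = 1 / (1 + np.exp(-0.08 * (gy - gx)))
        assert np.mean(np.abs(surf.grid_prob - truth)) < 0.05

    def test_grid_values_strictly_inside_unit_interval(self):
        train = diagonal_cloud(2000, seed=9)
        surf = fit_smooth_surface(train, seed=1)
        assert surf.grid_prob.min() > 0 and surf.grid_prob.max() < 1

    def test_single_class_rejected(self):
        pts = [LabeledPoint(10, 90, "LC")] * 200
        with pytest.raises(ValueError):
            fit_smooth_surface(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_smooth_surface([LabeledPoint(1, 1, "LC"), LabeledPoint(2, 2, "BG")])


class TestSplitAndArea:
    def test_split_is_stratified_and_deterministic(self):
        pts = [LabeledPoint(i, i, "LC") for i in range(60)] + [
            LabeledPoint(i, i, "BG") for i in range(40)
        ]
        train1, held1 = split_points(pts, seed=3)
        train2, _ = split_points(pts, seed=3)
        assert [id(p) for p in train1] == [id(p) for p in train2]
        assert sum(p.label == "LC" for p in train1) == 30
        assert len(train1) + len(held1) == 100

    def test_permissive_area_contracts_with_stringency(self):
        """Raising the planted positive threshold shrinks the LC-permissive
        region monotonically."""
        areas = []
        for cut in (100.0, 112.0, 124.0):
            pts = diagonal_cloud(30000, seed=6, cut=cut)
            train, held = split_points(pts, seed=7)
            surf = bin_points(train)
            roc = roc_curve(score_points(surf, held), [p.label for p in held])
            areas.append(lc_permissive_fraction(surf, youden_optimal(roc)))
        assert areas[0] > areas[1] > areas[2]
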