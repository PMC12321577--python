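import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from gliometry.io import Config, ImageStack
from gliometry.puncta import (
    ColocPairs,
    PunctaSet,
    chance_coloc_fraction,
    colocalize,
    detect_puncta,
    puncta_per_nucleus,
    regional_relative_density,
    territory_synapse_density,
)
from gliometry.segmentation import NucleusSet, Territory
from gliometry.synth import SynthConfig, make_atlas, render_spots, sample_puncta, substream

BOX = ((0.0, 5.0), (0.0, 50.0), (0.0, 50.0))


def _pset(points):
    return PunctaSet(channel="x", centroids_um=np.asarray(points, dtype=float))


def optimal_matching_pairs(pre, post, max_dist):
    """Oracle: maximum pair count within threshold, minimum total distance."""
    a = np.asarray(pre, dtype=float).reshape(-1, 3)
    b = np.asarray(post, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return 0
    d = np.linalg.norm(a[:, None] - b[None, :], axis=2)
    big = 1e6
    cost = np.where(d <= max_dist, d, big)
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(d[ri, ci] <= max_dist))


class TestDetectPuncta:
    def test_recall_and_localization(self):
        cfg = SynthConfig(lambda_pre_per_um3=0.005, coloc_fraction=0.0, seed=8)
        truth = sample_puncta(cfg, ((0.5, 4.5), (2.0, 48.0), (2.0, 48.0)), substream(8, "p"))
        shape = (5, 250, 250)
        img = render_spots(truth.pre_centroids_um, shape, (1.0, 0.2, 0.2),
                           amplitude=1.0, background=0.01, noise_sd=0.1,
                           rng=substream(8, "n"))
        stack = ImageStack(voxels=img[None], voxel_size_um=(1.0, 0.2, 0.2),
                           channel_names=["pre"])
        det = detect_puncta(stack, "pre", Config(spot_min_response=0.05))
        n_true = len(truth.pre_centroids_um)
        assert n_true > 20
        d = np.linalg.norm(
            det.centroids_um[:, None] - truth.pre_centroids_um[None], axis=2
        )
        matched = (d.min(axis=0) < 0.5).sum()
        assert matched / n_true >= 0.95
        errs = d.min(axis=1)
        assert np.median(errs[errs < 0.5]) < 0.5  # half the coarsest voxel

    def test_blank_channel_empty(self):
        stack = ImageStack(voxels=np.zeros((1, 5, 64, 64)),
                           voxel_size_um=(1.0, 0.2, 0.2), channel_names=["pre"])
        assert len(detect_puncta(stack, "pre")) == 0

    def test_two_separated_spots(self):
        pts = np.array([[2.5, 5.0, 5.0], [2.5, 5.0, 5.0 + 4 * 0.15 * 4]])
        img = render_spots(pts, (5, 64, 64), (1.0, 0.2, 0.2))
        stack = ImageStack(voxels=img[None], voxel_size_um=(1.0, 0.2, 0.2),
                           channel_names=["pre"])
        det = detect_puncta(stack, "pre", Config(spot_min_response=0.05))
        assert len(det) == 2


class TestColocalize:
    def test_close_pair(self):
        pairs = colocalize(_pset([[0, 0, 0]]), _pset([[0, 0, 0.2]]), 0.5)
        assert len(pairs) == 1
        assert pairs.pairs[0][2] == pytest.approx(0.2)

    def test_far_no_pair(self):
        pairs = colocalize(_pset([[0, 0, 0]]), _pset([[0, 0, 1.0]]), 0.5)
        assert len(pairs) == 0

    def test_one_to_one_never_exceeds_min(self, rng):
        for _ in range(20):
            pre = rng.uniform(0, 3, size=(rng.integers(0, 10), 3))
            post = rng.uniform(0, 3, size=(rng.integers(0, 10), 3))
            pairs = colocalize(_pset(pre), _pset(post), 1.0)
            assert len(pairs) <= min(len(pre), len(post))

    def test_greedy_close_to_optimal(self):
        """Greedy equals the optimal pair count on >=99% of small instances,
        never off by more than 1."""
        rng = np.random.default_rng(123)
        agree = 0
        n_trials = 1000
        for _ in range(n_trials):
            pre = rng.uniform(0, 2.0, size=(rng.integers(1, 9), 3))
            post = rng.uniform(0, 2.0, size=(rng.integers(1, 9), 3))
            g = len(colocalize(_pset(pre), _pset(post), 0.5))
            o = optimal_matching_pairs(pre, post, 0.5)
            assert abs(g - o) <= 1
            agree += g == o
        assert agree / n_trials >= 0.99

    def test_chance_rate_matches_closed_form(self):
        """Independent channels: chance-paired fraction ~ 1 - exp(-lambda V_ball)."""
        lam_post = 0.002
        r = 0.5
        cfg = SynthConfig(lambda_pre_per_um3=0.01, lambda_post_per_um3=lam_post,
                          coloc_fraction=0.0)
        box = ((0.0, 5.0), (0.0, 100.0), (0.0, 100.0))
        rates = []
        for rep in range(50):
            t = sample_puncta(cfg, box, substream(77, "rep", rep))
            if len(t.pre_centroids_um) == 0:
                continue
            n = optimal_matching_pairs(t.pre_centroids_um, t.post_centroids_um, r)
            rates.append(n / len(t.pre_centroids_um))
        expected = chance_coloc_fraction(lam_post, r)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - expected) < 3 * max(se, 1e-5)


class TestTerritoryDensity:
    def _territory(self, side_um=10.0, depth=10.0):
        poly = np.array([[0, 0], [0, side_um], [side_um, side_um], [side_um, 0]], float)
        area = side_um**2
        return Territory(cell_id=0, polygon_um=poly, area_um2=area, volume_um3=area * depth)

    def test_exact_arithmetic(self):
        """10 pairs in 1000 um^3 -> 1e7 per mm^3."""
        terr = self._territory(side_um=10.0, depth=10.0)  # 1000 um^3
        mids = np.tile([2.5, 5.0, 5.0], (10, 1))
        pairs = ColocPairs(pairs=[(i, i, 0.1) for i in range(10)], midpoints_um=mids)
        rec = territory_synapse_density(pairs, terr)
        assert rec.density_per_mm3 == pytest.approx(1e7)

    def test_zero_pairs(self):
        rec = territory_synapse_density(
            ColocPairs(pairs=[], midpoints_um=np.empty((0, 3))), self._territory()
        )
        assert rec.n_coloc == 0 and rec.density_per_mm3 == 0.0

    def test_outside_pairs_excluded(self):
        terr = self._territory(side_um=10.0)
        mids = np.array([[2.5, 5.0, 5.0], [2.5, 50.0, 50.0]])
        pairs = ColocPairs(pairs=[(0, 0, 0.1), (1, 1, 0.1)], midpoints_um=mids)
        assert territory_synapse_density(pairs, terr).n_coloc == 1


def _grid_nuclei(n_side=5, cell_px=20, radius_px=5, pixel=0.2):
    n = n_side * n_side
    labels = np.zeros((n_side * cell_px, n_side * cell_px), dtype=np.int32)
    centroids = []
    lab = 1
    for gy in range(n_side):
        for gx in range(n_side):
            cy, cx = gy * cell_px + cell_px // 2, gx * cell_px + cell_px // 2
            yy, xx = np.mgrid[0 : labels.shape[0], 0 : labels.shape[1]]
            m = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
            labels[m] = lab
            centroids.append((cy * pixel, cx * pixel))
            lab += 1
    return NucleusSet(
        centroids_um=np.asarray(centroids),
        radii_um=np.full(n, radius_px * pixel),
        labels=labels,
        pixel_size_um=(pixel, pixel),
    )


class TestPunctaPerNucleus:
    def test_inside_outside(self):
        nuclei = _grid_nuclei(n_side=1)
        c = nuclei.centroids_um[0]
        spots = _pset([[0, c[0], c[1]], [0, c[0] + 0.2, c[1]], [0, c[0], c[1] + 0.2],
                       [0, c[0] + 3.0, c[1]], [0, 0.1, 0.1]])
        counts = puncta_per_nucleus(spots, nuclei)
        assert counts[0] == 3

    def test_poisson_mean_recovery(self):
        nuclei = _grid_nuclei(n_side=10)
        rng = np.random.default_rng(5)
        pts = []
        for i, c in enumerate(nuclei.centroids_um):
            k = rng.poisson(8)
            ang = rng.uniform(0, 2 * np.pi, k)
            rad = rng.uniform(0, 0.7, k)
            for a, r in zip(ang, rad):
                pts.append([0.0, c[0] + r * np.sin(a), c[1] + r * np.cos(a)])
        counts = puncta_per_nucleus(_pset(pts), nuclei)
        assert abs(counts.mean() - 8) < 3 * np.sqrt(8 / len(nuclei))

    def test_tie_goes_to_nearer_then_smaller_id(self):
        labels = np.zeros((20, 40), dtype=np.int32)
        labels[8:13, 8:13] = 1
        labels[8:13, 18:23] = 2
        nuclei = NucleusSet(
            centroids_um=np.array([[2.0, 2.0], [2.0, 4.0]]),
            radii_um=np.array([0.5, 0.5]),
            labels=labels,
            pixel_size_um=(0.2, 0.2),
        )
        spots = _pset([[0.0, 2.0, 3.0]])  # equidistant, inside both dilated masks
        counts = puncta_per_nucleus(spots, nuclei, margin_um=1.0)
        assert counts[0] == 1 and counts[1] == 0


class TestRegionalDensity:
    def test_relative_arithmetic(self):
        atlas = make_atlas((200, 200))
        ms_area = atlas.region_area_um2("MS")
        dls_area = atlas.region_area_um2("dLS")
        pts = []
        ys, xs = np.nonzero(atlas.labels == 1)
        for i in range(4):
            pts.append([0.0, ys[i * 50] * 0.2, xs[i * 50] * 0.2])
        ys, xs = np.nonzero(atlas.labels == 2)
        n_dls = max(1, int(round(8 * (dls_area / ms_area) / 4) * 4))
        # place spots so dLS density is exactly 2x the MS density
        n_dls = int(round(2 * 4 * dls_area / ms_area))
        step = max(1, len(ys) // n_dls)
        for i in range(n_dls):
            pts.append([0.0, ys[i * step] * 0.2, xs[i * step] * 0.2])
        out = regional_relative_density(_pset(pts), atlas)
        by = {r.region: r for r in out}
        assert by["MS"].relative_to_ms == pytest.approx(1.0)
        assert by["dLS"].relative_to_ms == pytest.approx(2.0, rel=0.15)

    def test_equal_rates_near_unity(self):
        atlas = make_atlas((200, 200))
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0, 0], [5, 40, 40], size=(4000, 3))
        out = regional_relative_density(_pset(pts), atlas)
        for r in out:
            assert r.relative_to_ms == pytest.approx(1.0, abs=0.2)

    def test_empty_ms_errors(self):
        atlas = make_atlas((200, 200))
        ys, xs = np.nonzero(atlas.labels == 2)
        pts = [[0.0, ys[0] * 0.2, xs[0] * 0.2]]
        with pytest.raises(ValueError, match="normalization undefined"):
            regional_relative_density(_pset(pts), atlas)


def test_coloc_fraction_recovery():
    """Generated colocalized fractions recovered after chance correction."""
    box = ((0.0, 5.0), (0.0, 100.0), (0.0, 100.0))
    for f in (0.1, 0.3, 0.6):
        cfg = SynthConfig(lambda_pre_per_um3=0.01, lambda_post_per_um3=0.002,
                          coloc_fraction=f, coloc_radius_um=0.3)
        chance = chance_coloc_fraction(cfg.lambda_post_per_um3, 0.5)
        est = []
        for rep in range(20):
            t = sample_puncta(cfg, box, substream(31, "f", int(f * 10), rep))
            pre, post = _pset(t.pre_centroids_um), _pset(t.post_centroids_um)
            rate = len(colocalize(pre, post, 0.5)) / len(t.pre_centroids_um)
            est.append((rate - chance) / (1 - chance))
        se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - f) < 3 * se + 0.01
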