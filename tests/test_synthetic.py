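"""Synthetic fixtures: layout constraints, rendering, scoring, recovery."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from plexuscount import (
    EXTRAGANGLIONIC,
    CapacityError,
    ClusterLabeling,
    FixtureParams,
    PeakSet,
    SyntheticGroundTruth,
    analyze_image,
    default_eps,
    render_image,
    sample_layout,
    score_clustering,
    score_detection,
)
from oracles import brute_max_matching


class TestSampleLayout:
    def test_requested_layout_bookkeeping(self, small_fixture_params):
        gt = sample_layout(small_fixture_params)
        assert gt.n_neurons == 3 + 5 + 8 + 13 + 2
        assert gt.n_ganglia == 4
        assert sorted(gt.ganglion_sizes) == [3, 5, 8, 13]
        assert int(np.sum(gt.cluster_labels == EXTRAGANGLIONIC)) == 2

    def test_same_seed_identical_truth(self, small_fixture_params):
        a = sample_layout(small_fixture_params)
        b = sample_layout(small_fixture_params)
        np.testing.assert_array_equal(a.neuron_positions, b.neuron_positions)
        np.testing.assert_array_equal(a.cluster_labels, b.cluster_labels)

    def test_spatial_invariants(self, small_fixture_params):
        p = small_fixture_params
        gt = sample_layout(p)
        eps = default_eps(p.rho)
        pos, labels = gt.neuron_positions, gt.cluster_labels
        # intra-ganglion nearest neighbor below eps
        for gid in np.unique(labels[labels >= 0]):
            members = pos[labels == gid]
            if len(members) > 1:
                d = cdist(members, members)
                np.fill_diagonal(d, np.inf)
                assert d.min(axis=1).max() < eps
        # inter-ganglion gaps and extraganglionic clearance above factor x eps
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                same = labels[i] == labels[j] and labels[i] != EXTRAGANGLIONIC
                if not same:
                    assert np.linalg.norm(pos[i] - pos[j]) > p.separation_factor * eps
        # all somata clear of the border
        soma_px = p.soma_radius_um * p.rho
        assert pos.min() >= soma_px
        assert (np.asarray(p.image_shape) - pos).min() >= soma_px

    def test_nb_size_law_mean(self):
        params = FixtureParams(
            image_shape=(4000, 4000), n_ganglia=400, n_extraganglionic=0, seed=2,
            max_ganglion_size=10**6,  # effectively untruncated: test the raw law
        )
        rng = np.random.default_rng([params.seed, 0])
        from plexuscount.synthetic import _draw_sizes

        sizes = _draw_sizes(params, rng)
        expected = 0.58 * (1 - 0.035) / 0.035 + 3
        assert np.mean(sizes) == pytest.approx(expected, abs=1.5)

    def test_overfull_canvas_raises_capacity_error(self):
        params = FixtureParams(
            image_shape=(220, 220), n_ganglia=40, sizes=[12] * 40,
            n_extraganglionic=0, seed=0,
        )
        with pytest.raises(CapacityError):
            sample_layout(params)


class TestRenderImage:
    def test_no_neurons_constant_background(self):
        params = FixtureParams(n_ganglia=0, sizes=[], n_extraganglionic=0, seed=1,
                               image_shape=(300, 300))
        gt = sample_layout(params)
        img = render_image(gt, params)
        assert np.all(img.pixels == int(params.background_intensity))

    def test_single_soma_peaks_at_planted_position(self):
        params = FixtureParams(n_ganglia=0, sizes=[], n_extraganglionic=1, seed=2,
                               image_shape=(300, 300))
        gt = sample_layout(params)
        img = render_image(gt, params)
        peak = np.unravel_index(np.argmax(img.pixels), img.pixels.shape)
        assert np.linalg.norm(np.asarray(peak) - gt.neuron_positions[0]) <= 1.0

    def test_same_seed_identical_image(self, small_fixture_params):
        p = small_fixture_params
        gt = sample_layout(p)
        np.testing.assert_array_equal(
            render_image(gt, p).pixels, render_image(gt, p).pixels
        )

    def test_end_to_end_exact_recovery(self, small_fixture_params):
        p = small_fixture_params
        gt = sample_layout(p)
        res = analyze_image(render_image(gt, p), segment=False)
        assert res.n_neurons == gt.n_neurons
        assert res.n_ganglia == gt.n_ganglia
        score = score_detection(gt, res.peaks, tol=p.soma_radius_px)
        assert score.precision == 1.0
        assert score.recall == 1.0
        assert score_clustering(gt, res.labeling, score.matches) == 1.0

    def test_recall_degrades_monotonically_with_noise(self):
        noise_levels = [0.0, 60.0, 150.0]
        mean_recall = []
        for noise in noise_levels:
            recalls = []
            for seed in (0, 1, 2):
                p = FixtureParams(
                    image_shape=(500, 500), n_ganglia=3, sizes=[3, 5, 8],
                    n_extraganglionic=2, noise_sd=noise, seed=seed,
                )
                gt = sample_layout(p)
                res = analyze_image(render_image(gt, p), segment=False)
                recalls.append(
                    score_detection(gt, res.peaks, tol=p.soma_radius_px).recall
                )
            mean_recall.append(np.mean(recalls))
        assert mean_recall[0] == 1.0
        for lo, hi in zip(mean_recall[1:], mean_recall[:-1]):
            assert lo <= hi + 0.02


def _make_gt(positions, labels=None):
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if labels is None:
        labels = np.zeros(len(positions), dtype=int)
    return SyntheticGroundTruth(
        neuron_positions=positions,
        cluster_labels=np.asarray(labels),
        rho=1.0,
        soma_radius_um=7.0,
        image_shape=(300, 300),
        seed=0,
    )


class TestScoreDetection:
    def _gt(self, positions, labels=None):
        return _make_gt(positions, labels)

    def test_perfect_detection(self):
        pos = [(10, 10), (50, 50), (90, 20)]
        gt = self._gt(pos)
        peaks = PeakSet(np.asarray(pos, dtype=float), (300, 300), 1.0)
        score = score_detection(gt, peaks, tol=2.0)
        assert score.precision == 1.0 and score.recall == 1.0

    def test_no_detections(self):
        gt = self._gt([(10, 10), (20, 20)])
        peaks = PeakSet(np.empty((0, 2)), (300, 300), 1.0)
        score = score_detection(gt, peaks, tol=2.0)
        assert score.precision is None
        assert score.recall == 0.0

    def test_one_spurious_one_missed(self, rng):
        true = rng.uniform(20, 280, size=(10, 2))
        # detections: 9 true positions jittered, plus 1 spurious far away
        det = true[:9] + rng.uniform(-0.5, 0.5, size=(9, 2))
        det = np.vstack([det, [[299.0, 299.0]]])
        gt = self._gt(true)
        peaks = PeakSet(det, (300, 300), 1.0)
        score = score_detection(gt, peaks, tol=3.0)
        assert score.precision == pytest.approx(0.9)
        assert score.recall == pytest.approx(0.9)
        assert len(score.matches) == brute_max_matching(det, true, 3.0)

    def test_greedy_matches_optimal_on_small_instances(self, rng):
        for _ in range(10):
            true = rng.uniform(0, 50, size=(5, 2))
            det = rng.uniform(0, 50, size=(5, 2))
            gt = self._gt(true)
            score = score_detection(gt, PeakSet(det, (300, 300), 1.0), tol=10.0)
            assert len(score.matches) <= brute_max_matching(det, true, 10.0)


class TestScoreClustering:
    def _labeling(self, labels):
        return ClusterLabeling(np.asarray(labels), eps_m=10.0)

    def _gt(self, labels):
        n = len(labels)
        return _make_gt(np.arange(2 * n, dtype=float).reshape(n, 2), labels)

    def test_identical_partitions(self):
        gt = self._gt([0, 0, 0, 1, 1, 1, -1])
        matches = [(i, i) for i in range(7)]
        assert score_clustering(gt, self._labeling([0, 0, 0, 1, 1, 1, -1]), matches) == 1.0

    def test_split_four_cluster(self):
        # truth: one 4-cluster; prediction: two 2-clusters
        gt = self._gt([0, 0, 0, 0])
        matches = [(i, i) for i in range(4)]
        agreement = score_clustering(gt, self._labeling([0, 0, 1, 1]), matches)
        # pairs (01)(23) agree as "same"; (02)(03)(12)(13) disagree -> 2/6
        assert agreement == pytest.approx(2 / 6)

    def test_bruteforce_pair_counting(self, rng):
        n = 30
        truth_labels = rng.integers(-1, 3, size=n)
        pred_labels = rng.integers(-1, 3, size=n)
        gt = self._gt(truth_labels)
        matches = [(i, i) for i in range(n)]
        got = score_clustering(gt, self._labeling(pred_labels), matches)
        agree = total = 0
        for i in range(n):
            for j in range(i + 1, n):
                ts = truth_labels[i] == truth_labels[j] != -1
                ps = pred_labels[i] == pred_labels[j] != -1
                agree += int(ts == ps)
                total += 1
        assert got == pytest.approx(agree / total)

    def test_undefined_below_two_matches(self):
        gt = self._gt([0])
        assert score_clustering(gt, self._labeling([0]), [(0, 0)]) is None
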