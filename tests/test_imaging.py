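import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from sglife.imaging import (
    Track,
    count_fusion_events,
    enrichment_score,
    segment_and_measure,
    track_particles,
)


def _disk_image(centers, radius=4, value=500.0, shape=(100, 100), background=50.0):
    img = np.full(shape, background)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return img


def _full_mask(shape=(100, 100)):
    return np.ones(shape, dtype=np.uint16)


class TestSegmentAndMeasure:
    def test_five_disjoint_disks_counted(self):
        centers = [(20, 20), (20, 60), (50, 40), (80, 20), (80, 70)]
        img = _disk_image(centers)
        (gs,) = segment_and_measure(img, _full_mask(), min_area=4)
        assert gs.count == 5
        assert gs.mean_area == pytest.approx(np.pi * 16, rel=0.3)

    def test_uniform_image_zero(self):
        img = np.full((50, 50), 100.0)
        (gs,) = segment_and_measure(img, _full_mask((50, 50)), min_area=4)
        assert gs.count == 0 and gs.mean_area == 0.0

    def test_touching_disks_merge_8_connected(self):
        img = _disk_image([(30, 30), (30, 37)], radius=4)
        (gs,) = segment_and_measure(img, _full_mask(), min_area=4)
        assert gs.count == 1
        # flood-fill oracle on the thresholded image
        binary = img > 200
        seen = np.zeros_like(binary)
        comps = 0
        for seed in zip(*np.nonzero(binary)):
            if seen[seed]:
                continue
            comps += 1
            stack = [seed]
            while stack:
                r, c = stack.pop()
                if not (0 <= r < 100 and 0 <= c < 100) or seen[r, c] or not binary[r, c]:
                    continue
                seen[r, c] = True
                stack += [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        assert comps == gs.count

    def test_min_area_filters_specks(self):
        img = _disk_image([(20, 20)], radius=5)
        img[70, 70] = 500.0  # single bright pixel
        (gs,) = segment_and_measure(img, _full_mask(), min_area=4)
        assert gs.count == 1

    def test_per_cell_masks(self):
        masks = np.zeros((100, 100), dtype=np.uint16)
        masks[:, :50] = 1
        masks[:, 50:] = 2
        img = _disk_image([(30, 25), (60, 25), (40, 75)])
        out = segment_and_measure(img, masks, min_area=4)
        counts = {g.cell_id: g.count for g in out}
        assert counts == {1: 2, 2: 1}

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            segment_and_measure(np.zeros((10, 10)), np.ones((5, 5)), 4)


class TestEnrichmentScore:
    def test_uniform_intensity_is_one(self):
        img = np.full((40, 40), 123.0)
        gmask = np.zeros((40, 40), bool)
        gmask[10:14, 10:14] = True
        assert enrichment_score(img, gmask, np.ones((40, 40), bool)) == pytest.approx(1.0)

    def test_hand_computed_ratio(self):
        # granules 10% of the cell at 200, the rest at 100 -> 200 / 110
        img = np.full((10, 10), 100.0)
        gmask = np.zeros((10, 10), bool)
        gmask[0, :] = True
        img[gmask] = 200.0
        score = enrichment_score(img, gmask, np.ones((10, 10), bool))
        assert score == pytest.approx(200.0 / 110.0, abs=1e-12)

    def test_invariant_to_intensity_scaling(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(50, 500, (30, 30))
        gmask = np.zeros((30, 30), bool)
        gmask[5:9, 5:9] = True
        cmask = np.ones((30, 30), bool)
        s1 = enrichment_score(img, gmask, cmask)
        s2 = enrichment_score(img * 7.3, gmask, cmask)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_no_granules_is_missing(self):
        img = np.full((20, 20), 10.0)
        assert enrichment_score(img, np.zeros((20, 20), bool), np.ones((20, 20), bool)) is None


class TestTracking:
    def test_static_particles_zero_displacement(self):
        frames = [[(10.0, 10.0), (40.0, 40.0)]] * 5
        tracks, disp = track_particles(frames, max_disp=5)
        assert disp == 0.0
        assert len(tracks) == 2
        assert all(len(t.frames) == 5 for t in tracks)

    def test_constant_velocity_displacement(self):
        frames = [[(10.0, 10.0 + 3.0 * t)] for t in range(10)]
        tracks, disp = track_particles(frames, max_disp=5)
        assert len(tracks) == 1
        assert disp == pytest.approx(3.0)

    def test_matches_hungarian_on_separated_particles(self):
        rng = np.random.default_rng(7)
        max_disp = 4.0
        pos = rng.uniform(0, 200, size=(8, 2))
        # spacing stays > 2 * max_disp across all frames (steps are small)
        while np.min(
            [np.linalg.norm(a - b) for i, a in enumerate(pos) for b in pos[i + 1:]]
        ) <= 30:
            pos = rng.uniform(0, 200, size=(8, 2))
        steps = rng.uniform(-1, 1, size=(5, 8, 2))
        frames = []
        cur = pos.copy()
        for t in range(5):
            frames.append([tuple(p) for p in cur])
            cur = cur + steps[t]
        tracks, _ = track_particles(frames, max_disp=max_disp)
        assert len(tracks) == 8
        # oracle: optimal bipartite matching frame-to-frame gives the same links
        for t in range(4):
            a = np.array(frames[t])
            b = np.array(frames[t + 1])
            cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
            rows, cols = linear_sum_assignment(cost)
            optimal = dict(zip(rows, cols))
            for tr in tracks:
                i = tr.frames.index(t)
                ai = int(np.argmin(np.linalg.norm(a - np.array(tr.positions[i]), axis=1)))
                bi = int(np.argmin(np.linalg.norm(b - np.array(tr.positions[i + 1]), axis=1)))
                assert optimal[ai] == bi

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            track_particles([[(0.0, 0.0)]])


def _track(frames, positions, areas=None):
    n = len(frames)
    return Track(frames=list(frames), positions=[tuple(p) for p in positions],
                 areas=list(areas) if areas is not None else [float("nan")] * n)


class TestFusionEvents:
    def test_constructed_merge_detected(self):
        survivor = _track(range(6), [(50, 50 + t) for t in range(6)],
                          [20, 20, 20, 42, 42, 42])
        dying = _track(range(3), [(50, 58), (50, 56), (50, 54)], [20, 20, 20])
        events = count_fusion_events([survivor, dying], merge_radius=6,
                                     image_shape=(100, 100))
        assert len(events) == 1
        assert events[0]["frame"] == 3

    def test_distant_tracks_no_event(self):
        a = _track(range(5), [(10, 10)] * 5, [20] * 5)
        b = _track(range(3), [(80, 80)] * 3, [20] * 3)
        assert count_fusion_events([a, b], merge_radius=6) == []

    def test_area_must_absorb_parent(self):
        survivor = _track(range(6), [(50, 50)] * 6, [20] * 6)  # area never grows
        dying = _track(range(3), [(50, 54)] * 3, [20] * 3)
        assert count_fusion_events([survivor, dying], merge_radius=6) == []

    def test_border_exit_not_a_fusion(self):
        survivor = _track(range(6), [(2, 50 + t) for t in range(6)],
                          [20, 20, 20, 42, 42, 42])
        dying = _track(range(3), [(2, 58), (2, 56), (2, 54)], [20, 20, 20])
        events = count_fusion_events([survivor, dying], merge_radius=6,
                                     image_shape=(100, 100), border_margin=3)
        assert events == []
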