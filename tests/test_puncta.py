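"""Puncta detection: normalization, enhancement, seeding, growth, coloc."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condensig.puncta import (
    LabeledImage,
    PunctaError,
    PunctaParams,
    Punctum,
    coloc_fraction,
    detect_puncta,
    enhance,
    find_seeds,
    grow_cluster,
    local_background,
    normalize_cell,
    puncta_per_cell,
)
from condensig.synthetic_data import PunctaSceneConfig, simulate_puncta_scene

from conftest import bfs_flood_fill


def _single_cell_image(values: np.ndarray) -> LabeledImage:
    labels = np.ones_like(values, dtype=np.int32)
    return LabeledImage(intensity=values, labels=labels)


class TestNormalizeCell:
    def test_uniform_cell_normalizes_to_one(self):
        img = _single_cell_image(np.full((8, 8), 500.0))
        norm = normalize_cell(img, 1)
        assert np.allclose(norm, 1.0)

    def test_three_value_cell(self):
        img = _single_cell_image(np.array([[1.0, 2.0, 3.0]]))
        assert np.allclose(normalize_cell(img, 1), [[0.5, 1.0, 1.5]])

    def test_values_outside_cell_masked(self):
        intensity = np.full((6, 6), 7.0)
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[2:5, 2:5] = 1
        norm = normalize_cell(LabeledImage(intensity, labels), 1)
        assert np.isnan(norm[0, 0]) and norm[3, 3] == 1.0

    def test_dark_cell_rejected(self):
        img = _single_cell_image(np.zeros((4, 4)))
        with pytest.raises(PunctaError):
            normalize_cell(img, 1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_median_is_one_for_any_positive_cell(self, seed):
        rng = np.random.default_rng(seed)
        img = _single_cell_image(rng.uniform(0.5, 100.0, size=(9, 9)))
        norm = normalize_cell(img, 1)
        assert np.median(norm[img.labels == 1]) == pytest.approx(1.0)


class TestEnhance:
    def test_constant_input_gives_near_zero(self):
        enhanced = enhance(np.full((64, 64), 3.0), PunctaParams())
        assert np.allclose(enhanced, 0.0, atol=1e-9)

    def test_bright_disk_max_inside_disk(self):
        img = np.ones((64, 64))
        rr, cc = np.ogrid[:64, :64]
        disk = (rr - 30) ** 2 + (cc - 34) ** 2 <= 9
        img[disk] = 5.0
        enhanced = enhance(img, PunctaParams())
        peak = np.unravel_index(np.argmax(enhanced), enhanced.shape)
        assert disk[peak]

    def test_translation_equivariance_away_from_borders(self):
        params = PunctaParams()

        def scene(center):
            img = np.ones((96, 96))
            rr, cc = np.ogrid[:96, :96]
            img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= 9] = 5.0
            return img

        e1 = enhance(scene((40, 40)), params)
        e2 = enhance(scene((52, 47)), params)
        p1 = np.unravel_index(np.argmax(e1), e1.shape)
        p2 = np.unravel_index(np.argmax(e2), e2.shape)
        assert (p2[0] - p1[0], p2[1] - p1[1]) == (12, 7)

    def test_oversized_footprint_rejected(self):
        with pytest.raises(PunctaError):
            enhance(np.ones((10, 10)), PunctaParams(tophat_radius_px=8))


class TestFindSeeds:
    def test_constant_image_has_no_seeds_above_cutoff(self):
        mask = np.ones((16, 16), dtype=bool)
        assert find_seeds(np.zeros((16, 16)), mask, 0.1) == []

    def test_two_separated_bumps_give_two_seeds(self):
        grid = np.zeros((32, 32))
        grid[8, 8] = 2.0
        grid[24, 20] = 3.0
        mask = np.ones_like(grid, dtype=bool)
        seeds = find_seeds(grid, mask, 1.0)
        assert seeds == [(24, 20), (8, 8)]  # descending enhanced value

    def test_cutoff_above_max_gives_empty(self):
        grid = np.zeros((8, 8))
        grid[4, 4] = 1.0
        assert find_seeds(grid, np.ones_like(grid, bool), 2.0) == []


class TestLocalBackground:
    def test_fresh_normalized_cell_background_is_one(self):
        img = _single_cell_image(np.full((5, 5), 10.0))
        norm = normalize_cell(img, 1)
        assert local_background(norm, img.labels == 1) == 1.0

    def test_assigned_bright_pixel_excluded(self):
        norm = np.array([[1.0, 1.0], [1.0, 9.0]])
        mask = np.ones((2, 2), dtype=bool)
        claimed = np.zeros((2, 2), dtype=bool)
        claimed[1, 1] = True
        assert local_background(norm, mask, claimed) == 1.0

    def test_all_assigned_raises(self):
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(PunctaError):
            local_background(np.ones((2, 2)), mask, mask.copy())

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_equals_direct_median_of_complement(self, seed):
        rng = np.random.default_rng(seed)
        norm = rng.uniform(0, 5, size=(12, 12))
        mask = rng.uniform(size=(12, 12)) < 0.7
        claimed = mask & (rng.uniform(size=(12, 12)) < 0.3)
        free = mask & ~claimed
        if not free.any():
            return
        assert local_background(norm, mask, claimed) == pytest.approx(
            np.median(norm[free])
        )


class TestGrowCluster:
    def test_isolated_pixel_gives_singleton(self):
        grid = np.zeros((8, 8))
        grid[3, 3] = 5.0
        assert grow_cluster(grid, (3, 3), 1.0) == {(3, 3)}

    def test_plateau_with_8_connectivity(self):
        grid = np.zeros((8, 8))
        grid[2:5, 2:5] = 2.0
        pixels = grow_cluster(grid, (3, 3), 1.0, connectivity=8)
        assert pixels == {(r, c) for r in range(2, 5) for c in range(2, 5)}

    def test_seed_below_threshold_rejected(self):
        with pytest.raises(PunctaError):
            grow_cluster(np.zeros((4, 4)), (1, 1), 0.5)

    @pytest.mark.parametrize("connectivity", [4, 8])
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_bfs_flood_fill(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        grid = rng.uniform(size=(64, 64))
        above = grid >= 0.5
        seeds_avail = np.argwhere(above)
        seed_px = tuple(seeds_avail[rng.integers(len(seeds_avail))])
        got = grow_cluster(grid, seed_px, 0.5, connectivity=connectivity)
        assert got == bfs_flood_fill(above, seed_px, connectivity)


class TestDetectPuncta:
    def test_empty_cells_give_no_puncta(self):
        cfg = PunctaSceneConfig(noise_sd=0.0, puncta_per_cell=0, n_cells=4, seed=1)
        img_a, _, _ = simulate_puncta_scene(cfg)
        assert detect_puncta(img_a) == []

    def test_recovers_synthetic_puncta_with_accurate_centroids(self, puncta_scene):
        cfg, img_a, _, truth = puncta_scene
        detected = detect_puncta(img_a)
        true_df = truth.true_puncta["A"]
        assert len(detected) == len(true_df)
        for p in detected:
            sub = true_df[true_df.cell_id == p.cell_id]
            d = np.hypot(sub.row - p.centroid[0], sub.col - p.centroid[1])
            assert d.min() <= 2.0

    def test_puncta_disjoint_and_inside_cells(self, puncta_scene):
        _, img_a, _, _ = puncta_scene
        detected = detect_puncta(img_a)
        seen: set[tuple[int, int]] = set()
        for p in detected:
            pixels = set(p.pixel_set)
            assert not pixels & seen
            seen |= pixels
            assert all(img_a.labels[px] == p.cell_id for px in pixels)

    def test_intensity_rescaling_invariance(self, puncta_scene):
        """Median normalization makes detections invariant to multiplying the
        image by any positive constant."""
        _, img_a, _, _ = puncta_scene
        base = detect_puncta(img_a)
        scaled = LabeledImage(img_a.intensity * 3.7, img_a.labels)
        rescaled = detect_puncta(scaled)
        assert [p.pixel_set for p in base] == [p.pixel_set for p in rescaled]

    def test_determinism(self, puncta_scene):
        _, img_a, _, _ = puncta_scene
        d1 = detect_puncta(img_a)
        d2 = detect_puncta(img_a)
        assert [p.pixel_set for p in d1] == [p.pixel_set for p in d2]

    def test_per_cell_counts(self, puncta_scene):
        cfg, img_a, _, _ = puncta_scene
        counts = puncta_per_cell(img_a, detect_puncta(img_a))
        assert (counts["n_puncta"] == cfg.puncta_per_cell).all()


class TestColocFraction:
    def _punctum(self, cell, pixels):
        return Punctum(cell_id=cell, pixel_set=sorted(pixels))

    def test_identical_sets_give_one(self):
        a = [self._punctum(1, {(0, 0), (0, 1)}), self._punctum(1, {(5, 5)})]
        table = coloc_fraction(a, list(a))
        assert table.coloc_fraction.tolist() == [1.0]

    def test_disjoint_sets_give_zero(self):
        a = [self._punctum(1, {(0, 0)})]
        b = [self._punctum(1, {(9, 9)})]
        assert coloc_fraction(a, b).coloc_fraction.tolist() == [0.0]

    def test_cell_without_a_puncta_flagged_nan(self):
        b = [self._punctum(2, {(1, 1)})]
        table = coloc_fraction([], b)
        assert table.n_puncta_a.tolist() == [0]
        assert np.isnan(table.coloc_fraction.iloc[0])

    def test_recovers_generator_coloc_fraction(self, puncta_scene):
        cfg, img_a, img_b, truth = puncta_scene
        table = coloc_fraction(detect_puncta(img_a), detect_puncta(img_b))
        assert abs(table.coloc_fraction.mean() - cfg.coloc_fraction) <= 0.1
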