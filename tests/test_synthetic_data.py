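"""Generator contracts: determinism, ground-truth self-consistency, geometry."""

import numpy as np
import pandas as pd
import pytest

from condensig.synthetic_data import (
    ConfigError,
    DecaySimConfig,
    KtrSimConfig,
    PlacementError,
    PunctaSceneConfig,
    TranslocationSceneConfig,
    decay_matrix,
    simulate_decay_traces,
    simulate_ktr_dataset,
    simulate_puncta_scene,
    simulate_translocation_pair,
)


class TestPunctaScene:
    def test_no_puncta_no_noise_gives_uniform_cells(self):
        cfg = PunctaSceneConfig(noise_sd=0.0, puncta_per_cell=0, n_cells=4, seed=1)
        img_a, img_b, _ = simulate_puncta_scene(cfg)
        for img in (img_a, img_b):
            for cid in img.cell_ids():
                vals = img.intensity[img.cell_mask(cid)]
                assert np.all(vals == cfg.background_level)

    def test_full_coloc_forces_fraction_one_everywhere(self):
        cfg = PunctaSceneConfig(coloc_fraction=1.0, n_cells=4, seed=2)
        _, _, truth = simulate_puncta_scene(cfg)
        assert all(v == 1.0 for v in truth.true_coloc_fraction.values())

    def test_seed_reproducibility_bit_identical(self):
        cfg = PunctaSceneConfig(seed=7, n_cells=4)
        a1, b1, t1 = simulate_puncta_scene(cfg)
        a2, b2, t2 = simulate_puncta_scene(cfg)
        assert np.array_equal(a1.intensity, a2.intensity)
        assert np.array_equal(b1.intensity, b2.intensity)
        assert np.array_equal(a1.labels, a2.labels)
        assert np.array_equal(t1.puncta_masks["A"], t2.puncta_masks["A"])
        pd.testing.assert_frame_equal(t1.true_puncta["B"], t2.true_puncta["B"])

    def test_cytoplasm_median_matches_background(self, puncta_scene):
        cfg, img_a, _, truth = puncta_scene
        for cid in img_a.cell_ids():
            cyto = img_a.cell_mask(cid) & (truth.puncta_masks["A"] == 0)
            med = np.median(img_a.intensity[cyto])
            assert med == pytest.approx(cfg.background_level, rel=0.02)

    def test_configured_puncta_count_placed(self, puncta_scene):
        cfg, img_a, _, truth = puncta_scene
        counts = truth.true_puncta["A"].groupby("cell_id").size()
        assert (counts == cfg.puncta_per_cell).all()
        assert len(counts) == cfg.n_cells

    def test_puncta_inside_own_cell_and_disjoint(self, puncta_scene):
        _, img_a, _, truth = puncta_scene
        mask = truth.puncta_masks["A"]
        for pid in np.unique(mask[mask > 0]):
            owners = np.unique(img_a.labels[mask == pid])
            assert len(owners) == 1 and owners[0] > 0

    def test_ground_truth_coloc_consistent_with_masks(self, puncta_scene):
        """Recomputing overlap from the noiseless label masks reproduces the
        stored per-cell colocalization exactly."""
        _, img_a, _, truth = puncta_scene
        mask_a, mask_b = truth.puncta_masks["A"], truth.puncta_masks["B"]
        for cid, expected in truth.true_coloc_fraction.items():
            ids_a = np.unique(mask_a[(img_a.labels == cid) & (mask_a > 0)])
            overlapping = sum(
                1 for pid in ids_a if np.any(mask_b[mask_a == pid] > 0)
            )
            assert overlapping / len(ids_a) == pytest.approx(expected)

    def test_impossible_placement_raises(self):
        cfg = PunctaSceneConfig(
            n_cells=1, cell_radius_px=12.0, puncta_per_cell=30,
            punctum_radius_px=(3.0, 4.0), image_height=64, image_width=64, seed=0,
        )
        with pytest.raises(PlacementError):
            simulate_puncta_scene(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"coloc_fraction": 1.5},
            {"n_cells": 0},
            {"punctum_radius_px": (5.0, 3.0)},
            {"punctum_intensity_gain": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            PunctaSceneConfig(**kwargs)


class TestTranslocationScene:
    def test_flat_enrichment_means_zero_translocation(self):
        cfg = TranslocationSceneConfig(
            edge_enrichment_pre=1.0, edge_enrichment_post=1.0, noise_sd=0.0
        )
        _, _, _, truth = simulate_translocation_pair(cfg)
        assert truth.true_translocation == 0.0

    def test_truth_is_difference_of_enrichments(self):
        cfg = TranslocationSceneConfig(edge_enrichment_pre=1.0, edge_enrichment_post=1.5)
        _, _, _, truth = simulate_translocation_pair(cfg)
        assert truth.true_translocation == pytest.approx(0.5)

    def test_seed_reproducibility(self):
        cfg = TranslocationSceneConfig(noise_sd=2.0, seed=9)
        pre1, post1, _, _ = simulate_translocation_pair(cfg)
        pre2, post2, _, _ = simulate_translocation_pair(cfg)
        assert np.array_equal(pre1, pre2) and np.array_equal(post1, post2)

    def test_ring_wider_than_cell_rejected(self):
        with pytest.raises(ConfigError):
            TranslocationSceneConfig(edge_ring_width_px=50.0, cell_radius_px=45.0)


class TestKtrDataset:
    def test_frame_count_at_defaults(self):
        assert KtrSimConfig().n_frames == 264

    def test_no_rates_means_no_pulses(self):
        cfg = KtrSimConfig(
            n_cells=20, basal_pulse_rate=0.0, neighbor_pulse_rate=0.0,
            death_rate=0.0, division_rate=0.0, seed=1,
        )
        _, truth = simulate_ktr_dataset(cfg)
        assert len(truth.pulse_labels) == 0

    def test_pulse_durations_within_configured_range(self, ktr_dataset):
        cfg, _, truth = ktr_dataset
        lo, hi = cfg.pulse_duration_min
        assert truth.pulse_durations_min
        assert all(lo <= d <= hi for d in truth.pulse_durations_min)

    def test_neighbor_rate_elevates_neighbor_pulse_counts(self):
        """With neighbor rate >> basal rate, neighbor-labeled pulses occur at a
        much higher per-frame rate than basal ones would produce."""
        for seed in (0, 1, 2):
            cfg = KtrSimConfig(
                seed=seed, basal_pulse_rate=0.05, neighbor_pulse_rate=2.0,
                death_rate=0.05, n_cells=80,
            )
            _, truth = simulate_ktr_dataset(cfg)
            labels = truth.pulse_labels
            labels = labels[~labels.is_division_artifact]
            n_neighbor = int(labels.is_neighbor_driven.sum())
            n_basal = len(labels) - n_neighbor
            assert n_neighbor > 0
            # neighbor windows cover a small minority of cell-frames, yet
            # produce a comparable or larger share of pulses
            assert n_neighbor >= 0.3 * n_basal

    def test_seed_reproducibility(self):
        cfg = KtrSimConfig(n_cells=30, seed=4)
        df1, t1 = simulate_ktr_dataset(cfg)
        df2, t2 = simulate_ktr_dataset(cfg)
        pd.testing.assert_frame_equal(df1, df2)
        pd.testing.assert_frame_equal(t1.pulse_labels, t2.pulse_labels)

    def test_traces_are_baseline_plus_bumps(self):
        """Noise-free, pulse-free traces sit exactly at the baseline ratio."""
        cfg = KtrSimConfig(
            n_cells=10, basal_pulse_rate=0.0, neighbor_pulse_rate=0.0,
            death_rate=0.0, division_rate=0.0, noise_sd=0.0, seed=2,
        )
        df, _ = simulate_ktr_dataset(cfg)
        assert np.allclose(df["ratio"], cfg.baseline_ratio)

    def test_lineage_children_duplicate_parent_history(self, ktr_dataset):
        _, df, truth = ktr_dataset
        assert truth.lineage, "default death/division rates should yield divisions"
        parent, children = next(iter(truth.lineage.items()))
        p_rows = df[df.cell_id == parent].set_index("frame")
        for child in children:
            c_rows = df[df.cell_id == child].set_index("frame")
            shared = p_rows.index.intersection(c_rows.index)
            assert len(shared) == len(p_rows)
            assert np.allclose(
                p_rows.loc[shared, "ratio"], c_rows.loc[shared, "ratio"]
            )

    def test_lineage_acyclic_and_pulse_frames_valid(self, ktr_dataset):
        cfg, df, truth = ktr_dataset
        # acyclicity: walking up parents always terminates
        parent_of = {c: p for p, cs in truth.lineage.items() for c in cs}
        for start in parent_of:
            node, hops = start, 0
            while node in parent_of:
                node = parent_of[node]
                hops += 1
                assert hops <= len(parent_of)
        last = df.groupby("cell_id")["frame"].max()
        for row in truth.pulse_labels.itertuples():
            assert 0 <= row.peak_frame <= last[row.cell_id]

    def test_low_expressors_flagged(self, ktr_dataset):
        _, df, truth = ktr_dataset
        expr = df.groupby("cell_id")["expression"].first()
        low = set(truth.low_expressor_ids)
        assert low
        assert all(expr[c] < 0.2 for c in low)
        assert all(expr[c] >= 0.2 for c in expr.index if c not in low)

    def test_non_integral_frame_count_rejected(self):
        with pytest.raises(ConfigError):
            KtrSimConfig(duration_h=22.0, frame_interval_min=7.0)


class TestDecayTraces:
    def test_noiseless_values_follow_half_life(self):
        cfg = DecaySimConfig(noise_sd=0.0, t_half_min=17.0, n_traces=2, seed=0)
        t, traces = decay_matrix(simulate_decay_traces(cfg))
        at_zero = cfg.offset + cfg.amplitude
        at_half = cfg.offset + cfg.amplitude / 2
        assert traces[0, 0] == pytest.approx(at_zero)
        idx = np.argmin(np.abs(t - cfg.t_half_min))
        expected = cfg.offset + cfg.amplitude * 2 ** (-t[idx] / cfg.t_half_min)
        assert traces[0, idx] == pytest.approx(expected)
        assert abs(expected - at_half) < 0.05  # grid point near t_half

    def test_seed_reproducibility(self):
        cfg = DecaySimConfig(seed=12)
        pd.testing.assert_frame_equal(
            simulate_decay_traces(cfg), simulate_decay_traces(cfg)
        )

    def test_invalid_half_life_rejected(self):
        with pytest.raises(ConfigError):
            DecaySimConfig(t_half_min=0.0)
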