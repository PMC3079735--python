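"""Segmentation, the area-ratio score, phenotype calls and time-lapse means."""

import numpy as np
import pytest

from ecmremodel import (
    EmptyMaskError,
    ParameterError,
    RegionMask,
    area_ratio,
    classify_phenotype,
    max_projection,
    normalize_to_control,
    region_from_polygons,
    remodeling_score,
    score_stack,
    segment_cell_region,
    timelapse_change,
    widefield_image,
)
from ecmremodel.scoring import HIGH_RANGE

from conftest import score_simulated_field


def _region(shape=(10, 10)):
    cell = np.zeros(shape, bool)
    cell[:, :4] = True
    devoid = np.zeros(shape, bool)
    devoid[:, 6:] = True
    return RegionMask(cell, devoid)


class TestAreaRatio:
    def test_hand_computed_counts(self):
        img = np.array([[95.0, 80.0], [120.0, 10.0]])
        mask = np.ones((2, 2), bool)
        # 2 high (95, 120), 2 low -> ratio 1.0
        assert area_ratio(img, mask) == 1.0

    def test_boundary_90_counts_high(self):
        img = np.array([[90.0, 89.999]])
        mask = np.ones((1, 2), bool)
        assert area_ratio(img, mask) == 1.0  # exactly one high, one low

    def test_smoothing_auto_on_zero_low(self):
        img = np.full((2, 2), 200.0)
        mask = np.ones((2, 2), bool)
        assert area_ratio(img, mask) == pytest.approx(4.5 / 0.5)

    def test_smoothing_off_raises_on_zero_low(self):
        img = np.full((2, 2), 200.0)
        with pytest.raises(ParameterError):
            area_ratio(img, np.ones((2, 2), bool), smoothing=False)

    def test_forced_smoothing(self):
        img = np.array([[95.0, 80.0], [120.0, 10.0]])
        assert area_ratio(img, np.ones((2, 2), bool), smoothing=True) == pytest.approx(
            2.5 / 2.5
        )

    def test_empty_mask(self):
        with pytest.raises(EmptyMaskError):
            area_ratio(np.zeros((3, 3)), np.zeros((3, 3), bool))


class TestRemodelingScore:
    def test_neutral_when_regions_identical(self):
        img = np.zeros((10, 10))
        img[::2, :] = 150.0  # same high/low pattern everywhere
        s = remodeling_score(img, _region())
        assert s.score_percent == pytest.approx(100.0)

    def test_degradation_scores_below_100(self):
        img = np.zeros((10, 10))
        img[::2, :] = 150.0
        img[:, :4] = 10.0  # cell region wiped
        s = remodeling_score(img, _region())
        assert s.score_percent < 100.0

    def test_accumulation_scores_above_100(self):
        img = np.zeros((10, 10))
        img[::2, :] = 150.0
        img[:, :4] = 200.0  # cell region saturated
        s = remodeling_score(img, _region())
        assert s.score_percent > 100.0

    def test_hand_worked_score(self):
        # cell: 3 high / 1 low -> 3; devoid: 1 high / 3 low -> 1/3; score 900
        img = np.zeros((2, 4))
        region = RegionMask(
            cell_mask=np.array([[1, 1, 0, 0], [1, 1, 0, 0]], bool),
            devoid_mask=np.array([[0, 0, 1, 1], [0, 0, 1, 1]], bool),
        )
        img[0, 0] = img[1, 0] = img[0, 1] = 150.0  # 3 high in cell
        img[0, 2] = 150.0  # 1 high in devoid
        s = remodeling_score(img, region)
        assert s.ratio_cell == pytest.approx(3.0)
        assert s.ratio_devoid == pytest.approx(1 / 3)
        assert s.score_percent == pytest.approx(900.0)
        assert (s.n_high_cell, s.n_low_cell) == (3, 1)
        assert not s.smoothing_applied

    def test_smoothing_applied_to_both_regions(self):
        img = np.zeros((10, 10))
        img[:, :4] = 200.0  # cell all high -> guard trips
        img[::2, 6:] = 150.0
        s = remodeling_score(img, _region())
        assert s.smoothing_applied
        assert s.ratio_cell == pytest.approx(40.5 / 0.5)
        assert s.ratio_devoid == pytest.approx(15.5 / 15.5)

    def test_overlapping_masks_rejected(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ParameterError):
            RegionMask(m, m)


class TestSegmentation:
    def test_recovers_simulated_clusters(self):
        scores, part, region, truth = score_simulated_field(3)
        inter = np.logical_and(region.cell_mask, truth.cell_mask).sum()
        union = np.logical_or(region.cell_mask, truth.cell_mask).sum()
        assert inter / union > 0.6
        assert not np.any(region.cell_mask & region.devoid_mask)

    def test_buffer_separates_regions(self):
        _, _, region, _ = score_simulated_field(3)
        from scipy.ndimage import binary_dilation

        near_cell = binary_dilation(region.cell_mask, iterations=5)
        assert not np.any(region.devoid_mask & near_cell & ~region.cell_mask)

    def test_blank_field_raises(self):
        with pytest.raises(EmptyMaskError):
            segment_cell_region(np.zeros((64, 64)))

    def test_polygon_region(self):
        region = region_from_polygons(
            (50, 50), [[(10, 10), (30, 10), (30, 30), (10, 30)]]
        )
        assert region.provenance == "manual-polygon"
        assert region.cell_mask[20, 20]  # inside the square
        assert not region.cell_mask[40, 40]
        assert region.devoid_mask[48, 48]

    def test_polygon_xy_orientation(self):
        # tall thin rectangle in (x, y) coords: x in [2, 6], y in [5, 45]
        region = region_from_polygons(
            (50, 50), [[(2, 5), (6, 5), (6, 45), (2, 45)]], buffer_um=2.0
        )
        assert region.cell_mask[25, 4]  # row=y, col=x
        assert not region.cell_mask[4, 25]

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ParameterError):
            region_from_polygons((50, 50), [[(0, 0), (1, 1)]])


class TestScoreStack:
    def test_six_scores_per_field(self):
        scores, *_ = score_simulated_field(4)
        assert len(scores) == 6
        assert {(s.layer, s.channel) for s in scores} == {
            (layer, ch)
            for layer in ("top", "middle", "bottom")
            for ch in ("tmp", "fibronectin")
        }

    def test_matches_manual_projection_scoring(self):
        scores, part, region, _ = score_simulated_field(4)
        import ecmremodel as em

        stack, _t = em.simulate_matrix_stack(em.SimulationParams(seed=4))
        scaled = em.rescale_to_225(stack, "fixed-range", lo=0.0, hi=225.0)
        for s in scores:
            proj = max_projection(scaled, s.channel, part.planes(s.layer))
            manual = remodeling_score(proj, region, HIGH_RANGE)
            assert s.score_percent == pytest.approx(manual.score_percent)


class TestClassification:
    def _scores(self, top_value):
        img = np.zeros((10, 10))
        region = _region()
        s = remodeling_score(img + 100.0, region, layer="top", channel="tmp")
        s.score_percent = top_value
        return [s]

    def test_calls(self):
        assert classify_phenotype(self._scores(30.0)).label == "degrader"
        assert classify_phenotype(self._scores(300.0)).label == "accumulator"
        assert classify_phenotype(self._scores(100.0)).label == "neutral"

    def test_margin_boundaries_are_neutral(self):
        assert classify_phenotype(self._scores(65.0), 35.0).label == "neutral"
        assert classify_phenotype(self._scores(135.0), 35.0).label == "neutral"
        assert classify_phenotype(self._scores(64.999), 35.0).label == "degrader"

    def test_requires_top_layer(self):
        s = self._scores(50.0)[0]
        s.layer = "bottom"
        with pytest.raises(ParameterError):
            classify_phenotype([s])


class TestNormalization:
    def test_control_bottom_maps_to_100(self):
        scores, *_ = score_simulated_field(6)
        normalized = normalize_to_control(scores, scores)
        bottoms = [
            normalized[i] for i, s in enumerate(scores) if s.layer == "bottom"
        ]
        # per-channel bottom mean maps to exactly 100
        assert np.mean(bottoms) == pytest.approx(100.0)

    def test_missing_control_channel(self):
        scores, *_ = score_simulated_field(6)
        control = [s for s in scores if s.channel == "tmp"]
        with pytest.raises(ParameterError):
            normalize_to_control(scores, control)


class TestTimelapse:
    def test_constant_series_zero_change(self):
        region = _region((20, 20))
        img = np.full((20, 20), 50.0)
        out = timelapse_change([(0, img), (7, img), (10, img)], region)
        np.testing.assert_allclose(out["cell_pct_change"], 0.0)
        np.testing.assert_allclose(out["devoid_pct_change"], 0.0)

    def test_hand_computed_percent_change(self):
        region = _region((20, 20))
        a = np.full((20, 20), 100.0)
        b = np.full((20, 20), 150.0)
        out = timelapse_change([(0, a), (7, b)], region)
        assert out["cell_pct_change"][0] == pytest.approx(50.0)

    def test_shape_mismatch_rejected(self):
        region = _region((20, 20))
        with pytest.raises(ParameterError):
            timelapse_change(
                [(0, np.zeros((20, 20))), (7, np.zeros((10, 10)))], region
            )

    def test_widefield_is_depth_mean(self, small_stack):
        np.testing.assert_allclose(
            widefield_image(small_stack, "tmp"),
            small_stack.channel("tmp").mean(axis=0),
        )
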