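import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from irrimap.masking import MaskLayer
from irrimap.phenology import (
    CropCalendarEntry,
    CropLookupTable,
    FlatProfileError,
    SeasonWindows,
    assign_crop_type,
    cumulative_departure_dates,
    extract_season_descriptors,
    fill_nodata_gaps,
    scale_height,
    select_training_pixels,
)
from irrimap.raster import GridSpec


def hump(sow, duration, peak, base=0.15, T=23):
    """Noise-free single-season profile peaking at `peak`."""
    t = np.arange(T, dtype=float)
    up = 1 / (1 + np.exp(-(t - (sow + 0.8)) / 0.6))
    down = 1 / (1 + np.exp(-(t - (sow + duration - 0.8)) / 0.6))
    s = up - down
    return base + (peak - base) * s / s.max()


class TestScaleHeight:
    @pytest.mark.parametrize(
        "ndvi,height",
        [(0.1, 1.0), (0.8, 100.0), (0.45, 50.5), (0.0, 1.0), (0.95, 100.0)],
    )
    def test_linear_map_with_clamped_endpoints(self, ndvi, height):
        assert scale_height(ndvi) == pytest.approx(height)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(-1, 1), st.floats(-1, 1))
    def test_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert scale_height(lo) <= scale_height(hi)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            scale_height(float("nan"))


class TestCumulativeDeparture:
    def test_hand_case(self):
        assert cumulative_departure_dates([0, 0, 1, 1, 0, 0]) == (1, 3)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-5, 5))
    def test_invariant_to_constant_shift(self, shift):
        profile = np.array([0.1, 0.15, 0.6, 0.7, 0.2, 0.1])
        assert cumulative_departure_dates(profile + shift) == cumulative_departure_dates(profile)

    def test_constant_profile_rejected(self):
        with pytest.raises(FlatProfileError):
            cumulative_departure_dates([0.3] * 10)

    @pytest.mark.parametrize("sow,duration", [(2, 6), (5, 8), (10, 7)])
    def test_recovers_generating_season_within_one_composite(self, sow, duration):
        profile = hump(sow, duration, 0.7)
        em, sen = cumulative_departure_dates(profile)
        assert abs(em - sow) <= 1
        assert abs(sen - (sow + duration - 1)) <= 1


class TestGapFilling:
    def test_short_gap_linearly_interpolated(self):
        prof = np.array([0.1, -9999.0, 0.3, 0.4])
        filled = fill_nodata_gaps(prof, -9999.0, max_gap=3)
        assert filled[1] == pytest.approx(0.2)

    def test_long_gap_disqualifies(self):
        prof = np.array([0.1, -9999.0, -9999.0, -9999.0, -9999.0, 0.5])
        assert fill_nodata_gaps(prof, -9999.0, max_gap=3) is None


class TestTrainingLattice:
    def make_mask(self, n, fill=True):
        grid = GridSpec(n, n, 0.0, n * 250.0, 250.0)
        return MaskLayer(grid, np.full((n, n), fill, dtype=bool))

    def test_full_64_grid_with_4km_spacing_gives_16_samples(self):
        assert len(select_training_pixels(self.make_mask(64))) == 16

    def test_spacing_equal_to_pixel_selects_every_masked_pixel(self):
        assert len(select_training_pixels(self.make_mask(8), 250.0, 250.0)) == 64

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            select_training_pixels(self.make_mask(8, fill=False))

    def test_deterministic_for_a_given_mask(self):
        a = select_training_pixels(self.make_mask(64))
        b = select_training_pixels(self.make_mask(64))
        np.testing.assert_array_equal(a, b)


class TestSeasonDescriptors:
    def test_single_kharif_hump_yields_fs_and_cms(self):
        descs = extract_season_descriptors(hump(2, 7, 0.7))
        pools = [d.pool for d in descs]
        assert pools == ["FS", "CMS"]
        assert descs[0].peak_ndvi == pytest.approx(descs[1].peak_ndvi)
        assert descs[0].emergence_idx < descs[0].senescence_idx

    def test_double_cropped_profile_yields_fs_and_ss_with_distinct_peaks(self):
        profile = hump(1, 8, 0.65) + hump(11, 7, 0.8) - 0.15
        descs = extract_season_descriptors(profile)
        by_pool = {d.pool: d for d in descs}
        assert {"FS", "SS"} <= set(by_pool)
        assert by_pool["SS"].peak_ndvi > by_pool["FS"].peak_ndvi

    def test_flat_profile_yields_empty_list(self):
        assert extract_season_descriptors(np.full(23, 0.2)) == []

    def test_peak_attained_within_season(self):
        for d in extract_season_descriptors(hump(3, 8, 0.75)):
            prof = hump(3, 8, 0.75)
            assert d.peak_ndvi == pytest.approx(prof[d.emergence_idx: d.senescence_idx + 1].max())


@pytest.fixture
def fixture_lookup():
    return CropLookupTable(
        [
            CropCalendarEntry(1, "Rice", "Kharif", 1, (55, 75), (7, 10), (0, 9)),
            CropCalendarEntry(1, "Maize", "Kharif", 2, (50, 80), (5, 10), (0, 9)),
            CropCalendarEntry(1, "Wheat", "Rabi", 3, (40, 90), (4, 9), (10, 18)),
        ]
    )


class TestAssignCropType:
    def make_desc(self, pool, duration, height, emergence=2):
        from irrimap.phenology import SeasonDescriptor

        return SeasonDescriptor(pool, emergence, emergence + duration - 1, duration, 0.5, height)

    def test_matching_descriptor_assigns_crop(self, fixture_lookup):
        d = self.make_desc("FS", 8, 60.0)
        assert assign_crop_type([d], fixture_lookup, 1) == "Rice"

    def test_height_outside_every_interval_is_unassigned(self, fixture_lookup):
        d = self.make_desc("SS", 8, 99.0, emergence=11)
        assert assign_crop_type([d], fixture_lookup, 1) is None

    def test_overlapping_entries_resolve_by_priority(self, fixture_lookup):
        # height 60, duration 8 matches both Rice (priority 1) and Maize (priority 2)
        d = self.make_desc("FS", 8, 60.0)
        for _ in range(3):  # repeated calls agree (pure function)
            assert assign_crop_type([d], fixture_lookup, 1) == "Rice"

    def test_unknown_zone_rejected(self, fixture_lookup):
        with pytest.raises(ValueError):
            assign_crop_type([], fixture_lookup, 9)


def test_lookup_table_tsv_roundtrip(tmp_path, fixture_lookup):
    path = fixture_lookup.to_tsv(tmp_path / "lookup.tsv")
    back = CropLookupTable.from_tsv(path)
    assert [e.crop_name for e in back.for_zone(1)] == ["Rice", "Maize", "Wheat"]
    assert back.for_zone(1)[0].height_range == (55.0, 75.0)
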