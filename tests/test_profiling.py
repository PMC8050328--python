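"""Radial quantification pipeline: binning, normalization, smoothing, fronts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reecsim as rs
from reecsim.errors import (
    InvalidParameterError,
    NormalizationError,
    ProfileError,
    UndefinedCorrelationError,
    UndefinedFrontError,
)

from conftest import make_profile


def cells_at(radii, intensities, channel="ch"):
    """Cell table with cells placed on the +x axis at the given radii."""
    radii = np.asarray(radii, dtype=float)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(radii.size),
            "x_um": radii,
            "y_um": np.zeros(radii.size),
            channel: np.asarray(intensities, dtype=float),
        }
    )
    return rs.CellTable(df)


class TestBinCells:
    def test_single_cell_lands_in_its_annulus(self):
        prof = rs.bin_cells(cells_at([75.0], [10.0]), "ch")
        assert prof.bin_edges[1] == 50.0
        assert np.isnan(prof.mfi[0])
        assert prof.mfi[1] == 10.0
        assert prof.n[1] == 1
        assert np.isnan(prof.sem[1])  # single-cell SEM is undefined, not 0

    def test_constant_intensity_gives_constant_bins(self):
        prof = rs.bin_cells(cells_at([10, 60, 60, 110, 160], [7.0] * 5), "ch")
        v = prof.mfi[prof.valid]
        assert np.allclose(v, 7.0)
        assert prof.sem[1] == 0.0  # two identical cells: SEM defined and 0

    def test_hand_computed_bins(self):
        # cells at r = 20 (I=2), 60 (I=4), 80 (I=6), 120 (I=10)
        prof = rs.bin_cells(cells_at([20, 60, 80, 120], [2, 4, 6, 10]), "ch")
        assert prof.mfi.tolist() == [2.0, 5.0, 10.0]
        assert prof.sem[1] == pytest.approx(1.0)  # sd([4,6])/sqrt(2) = 1
        assert np.isnan(prof.sem[0]) and np.isnan(prof.sem[2])

    def test_unknown_channel_and_empty_table_rejected(self):
        table = cells_at([10.0], [1.0])
        with pytest.raises(InvalidParameterError, match="channel"):
            rs.bin_cells(table, "nope")
        with pytest.raises(ProfileError):
            rs.bin_cells(table, "ch", max_radius=5.0)

    def test_out_of_chamber_cells_excluded_not_fatal(self):
        prof = rs.bin_cells(cells_at([30, 7000], [1, 99]), "ch", max_radius=6000.0)
        assert prof.n.sum() == 1

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0.0, max_value=5999.0), min_size=1, max_size=60))
    def test_count_conservation(self, radii):
        prof = rs.bin_cells(cells_at(radii, np.ones(len(radii))), "ch")
        assert prof.n.sum() == len(radii)

    def test_duplicate_cell_ids_rejected(self):
        df = pd.DataFrame(
            {"cell_id": [1, 1], "x_um": [0.0, 1.0], "y_um": [0.0, 0.0], "ch": [1.0, 2.0]}
        )
        with pytest.raises(InvalidParameterError, match="unique"):
            rs.CellTable(df)


class TestPixelRadialProfile:
    def test_constant_image(self):
        prof = rs.pixel_radial_profile(np.full((64, 64), 3.0), (32.0, 32.0), 10.0)
        assert np.allclose(prof.mfi[prof.valid], 3.0)

    def test_five_by_five_hand_enumeration(self):
        img = np.ones((5, 5))
        img[2, 2] = 5.0
        prof = rs.pixel_radial_profile(img, (2.0, 2.0), bin_width=1.0, scale=1.0)
        assert prof.mfi[0] == 5.0  # only the centre pixel has r < 1
        assert prof.mfi[1] == 1.0  # the 4+4 pixels at r = 1, sqrt(2)

    def test_radius_valued_image(self):
        # pixel value = its radius in µm -> bin means near bin centres
        h = w = 101
        scale = 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        cx = cy = 50 * scale
        img = np.hypot(xx * scale - cx, yy * scale - cy)
        prof = rs.pixel_radial_profile(img, (cx, cy), bin_width=10.0, scale=scale)
        inner = prof.valid & (prof.bin_edges[1:] <= 100.0)
        assert np.all(np.abs(prof.mfi[inner] - prof.bin_centers[inner]) <= scale / 2 + 1.0)

    def test_center_outside_image_rejected(self):
        with pytest.raises(InvalidParameterError, match="center"):
            rs.pixel_radial_profile(np.ones((10, 10)), (500.0, 0.0), 10.0)


class TestNormalizeProfile:
    def test_first_point_mode(self):
        prof = make_profile([np.nan, 4.0, 8.0])
        out = rs.normalize_profile(prof, "first_point")
        assert np.isnan(out.mfi[0]) and out.mfi[1] == 1.0 and out.mfi[2] == 2.0
        assert out.normalization.intensity_mode == "first_point"

    def test_max_mode(self):
        out = rs.normalize_profile(make_profile([2.0, 8.0, 4.0]), "max")
        assert np.nanmax(out.mfi) == 1.0
        assert np.all(out.mfi[out.valid] <= 1.0)

    def test_external_reference_consistency(self):
        prof = make_profile([4.0, 6.0])
        a = rs.normalize_profile(prof, "first_point")
        b = rs.normalize_profile(prof, "external_reference", reference=4.0)
        assert np.allclose(a.mfi, b.mfi)

    def test_zero_reference_rejected(self):
        with pytest.raises(NormalizationError):
            rs.normalize_profile(make_profile([0.0, 1.0]), "first_point")

    def test_relative_distance_modes(self):
        prof = make_profile([1.0, 2.0, 3.0, 4.0])
        out = rs.normalize_profile(prof, distance_mode="relative_to_disk_radius",
                                   disk_radius=200.0)
        assert out.bin_edges[-1] == pytest.approx(1.0)
        with pytest.raises(NormalizationError):
            rs.normalize_profile(prof, distance_mode="relative_depth")


class TestSmoothProfile:
    def test_constant_unchanged_and_window_one_identity(self):
        prof = make_profile([3.0] * 9)
        assert np.allclose(rs.smooth_profile(prof, 5).mfi, 3.0)
        bumpy = make_profile([1.0, 5.0, 2.0, 8.0, 1.0])
        assert np.allclose(rs.smooth_profile(bumpy, 1).mfi, bumpy.mfi)

    def test_truncated_edges_hand_computed(self):
        prof = make_profile([0, 0, 0, 10, 0, 0, 0])
        out = rs.smooth_profile(prof, 5)
        assert out.mfi.tolist() == [0.0, 2.5, 2.0, 2.0, 2.0, 2.5, 0.0]

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            rs.smooth_profile(make_profile([1.0, 2.0]), 4)

    def test_interior_mean_preserved_on_long_profile(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(1.0, 2.0, 60)
        out = rs.smooth_profile(make_profile(vals), 5)
        assert out.mfi[5:-5].mean() == pytest.approx(vals[5:-5].mean(), rel=0.01)


class TestHypoxicFront:
    def test_linear_ramp_interpolated(self):
        # ramp 0..100 over bin centres 25..975 µm (20 bins of 50 µm)
        centers = 50.0 * np.arange(20) + 25.0
        vals = 100.0 * centers / 975.0
        front = rs.hypoxic_front(make_profile(vals), 0.9)
        assert front.distance == pytest.approx(0.9 * 975.0, abs=1e-9)

    def test_already_above_threshold_fronts_at_first_bin(self):
        front = rs.hypoxic_front(make_profile([95.0, 96.0, 100.0, 99.0]), 0.9)
        assert front.distance == 25.0

    def test_first_crossing_wins_over_later_dip(self):
        # ramp 0->100 over 0..500 µm, plateau, dip at 650, recover: with
        # 100 µm bins the centre at 450 sits exactly at 90% of max, so the
        # first crossing (and the tie-to-smaller-distance rule) give 450
        vals = [10.0, 30.0, 50.0, 70.0, 90.0, 100.0, 60.0, 100.0]
        front = rs.hypoxic_front(make_profile(vals, bin_width=100.0), 0.9)
        assert front.distance == pytest.approx(450.0)

    def test_flat_profile_has_no_front(self):
        with pytest.raises(UndefinedFrontError):
            rs.hypoxic_front(make_profile([5.0, 5.0, 5.0]))

    def test_front_monotone_in_fraction(self):
        vals = np.linspace(0.0, 100.0, 30)
        prof = make_profile(vals)
        d = [rs.hypoxic_front(prof, f).distance for f in (0.5, 0.7, 0.9, 1.0)]
        assert all(b >= a for a, b in zip(d, d[1:]))

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance_of_front_and_normalization(self, scale):
        vals = np.array([1.0, 3.0, 7.0, 9.5, 10.0, 10.0])
        a = rs.hypoxic_front(make_profile(vals), 0.9).distance
        b = rs.hypoxic_front(make_profile(vals * scale), 0.9).distance
        assert a == pytest.approx(b)
        na = rs.normalize_profile(make_profile(vals), "max").mfi
        nb = rs.normalize_profile(make_profile(vals * scale), "max").mfi
        assert np.allclose(na, nb)


class TestFoldChangeAndArea:
    def test_fold_change_basics(self):
        assert rs.front_fold_change(800.0, 800.0) == 1.0
        assert rs.front_fold_change(1600.0, 800.0) == 2.0
        assert rs.front_fold_change(1600.0 * 3, 800.0 * 3) == pytest.approx(2.0)
        with pytest.raises(InvalidParameterError):
            rs.front_fold_change(1.0, 0.0)

    def test_identical_masks_no_change(self):
        mask = np.zeros((64, 64), bool)
        mask[16:48, 16:48] = True
        assert rs.disk_area_change(rs.DiskMask(mask, 2.0), rs.DiskMask(mask, 2.0)) == 0.0

    def test_radius_scaling(self):
        a = rs.DiskMask(radius_um=100.0)
        b = rs.DiskMask(radius_um=100.0 * np.sqrt(2))
        assert rs.disk_area_change(a, b) == pytest.approx(100.0)

    def test_rasterized_circles_match_pixel_count_oracle(self):
        def circle(r_px, size=256):
            yy, xx = np.mgrid[0:size, 0:size]
            return np.hypot(xx - size / 2, yy - size / 2) <= r_px

        m0, m1 = circle(100), circle(90)
        change = rs.disk_area_change(rs.DiskMask(m0, 1.0), rs.DiskMask(m1, 1.0))
        assert change == pytest.approx(-19.0, abs=1.0)

    def test_empty_t0_mask_rejected(self):
        with pytest.raises(ProfileError):
            rs.disk_area_change(
                rs.DiskMask(np.zeros((8, 8), bool)), rs.DiskMask(np.ones((8, 8), bool))
            )


class TestCorrelateChannels:
    def test_self_and_negation(self):
        a = make_profile([1.0, 4.0, 2.0, 8.0])
        assert rs.correlate_channels(a, a) == pytest.approx(1.0)
        neg = make_profile([-v for v in [1.0, 4.0, 2.0, 8.0]])
        assert rs.correlate_channels(a, neg) == pytest.approx(-1.0)

    def test_textbook_value(self):
        r = rs.correlate_channels(make_profile([1, 2, 3]), make_profile([1, 2, 4]))
        assert r == pytest.approx(0.982, abs=5e-4)

    def test_zero_variance_and_bin_mismatch_rejected(self):
        flat = make_profile([2.0, 2.0, 2.0])
        with pytest.raises(UndefinedCorrelationError):
            rs.correlate_channels(flat, make_profile([1.0, 2.0, 3.0]))
        with pytest.raises(ProfileError):
            rs.correlate_channels(make_profile([1.0, 2.0]), make_profile([1.0, 2.0, 3.0]))


class TestAggregateReplicates:
    def test_single_replicate_sem_undefined(self):
        prof = make_profile([1.0, 2.0])
        agg = rs.aggregate_replicates([prof])
        assert np.allclose(agg.mfi, prof.mfi)
        assert np.all(np.isnan(agg.sem))

    def test_identical_replicates_sem_zero(self):
        prof = make_profile([1.0, 2.0])
        agg = rs.aggregate_replicates([prof, prof])
        assert np.allclose(agg.sem, 0.0)

    def test_hand_computed_mean_sem(self):
        a = make_profile([1.0, 3.0])
        b = make_profile([2.0, 4.0])
        agg = rs.aggregate_replicates([a, b])
        assert agg.mfi.tolist() == [1.5, 3.5]
        # sd of two points 1 apart is sqrt(1/2)·...: sd=0.7071, SEM=0.5
        assert np.allclose(agg.sem, 0.5)
        assert agg.n.tolist() == [2, 2]

    def test_gaps_skipped_not_imputed(self):
        a = make_profile([1.0, np.nan])
        b = make_profile([3.0, 5.0])
        agg = rs.aggregate_replicates([a, b])
        assert agg.mfi.tolist() == [2.0, 5.0]
        assert agg.n.tolist() == [2, 1]

    def test_mixed_normalization_rejected(self):
        raw = make_profile([1.0, 2.0])
        normed = rs.normalize_profile(make_profile([1.0, 2.0]), "max")
        with pytest.raises(ProfileError, match="normalization"):
            rs.aggregate_replicates([raw, normed])

    def test_different_grids_interpolated_after_relative_distance(self):
        a = rs.normalize_profile(
            make_profile([1.0, 2.0, 3.0, 4.0]), "first_point",
            distance_mode="relative_to_disk_radius", disk_radius=200.0,
        )
        b = rs.normalize_profile(
            make_profile([1.0, 2.0, 3.0, 4.0, 5.0]), "first_point",
            distance_mode="relative_to_disk_radius", disk_radius=250.0,
        )
        agg = rs.aggregate_replicates([a, b])
        assert agg.bin_edges.size == a.bin_edges.size
        assert np.all(agg.n >= 1)

    def test_absolute_grids_must_match(self):
        with pytest.raises(ProfileError, match="grids"):
            rs.aggregate_replicates([make_profile([1.0, 2.0]), make_profile([1.0, 2.0, 3.0])])


class TestProfileCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        prof = make_profile([1.0, np.nan, 3.0])
        path = tmp_path / "p.csv"
        prof.to_csv(path)
        back = rs.RadialProfile.from_csv(path)
        assert np.allclose(back.bin_edges, prof.bin_edges)
        assert np.allclose(back.mfi, prof.mfi, equal_nan=True)
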