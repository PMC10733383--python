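"""Region shape metrics, AC/AE classification, dispersion and intensities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk, polygon as draw_polygon

from platefold import (
    ApicalAreaTrack,
    LabelImage,
    classify_apical_dynamics,
    dispersion_stats,
    junction_intensities,
    polygon_measures,
    read_label_image,
    read_tracks_csv,
    region_shape_metrics,
    write_tracks_csv,
)


class TestRegionShapeMetrics:
    def test_axis_aligned_rectangle(self):
        img = np.zeros((60, 80), dtype=np.int32)
        img[20:40, 20:60] = 1  # 40 px along x, 20 px along y
        df = region_shape_metrics(LabelImage(labels=img))
        assert df["aspect_ratio"].iloc[0] == pytest.approx(2.0, rel=0.01)
        assert df["orientation_deg"].iloc[0] == pytest.approx(0.0, abs=1e-6)
        assert df["area"].iloc[0] == 800

    def test_disc_is_isotropic(self):
        img = np.zeros((100, 100), dtype=np.int32)
        rr, cc = disk((50, 50), 30)
        img[rr, cc] = 1
        df = region_shape_metrics(LabelImage(labels=img))
        assert df["aspect_ratio"].iloc[0] == pytest.approx(1.0, rel=0.02)

    def test_tiny_region_flagged_degenerate(self):
        img = np.zeros((10, 10), dtype=np.int32)
        img[2, 2:4] = 1
        img[5:9, 5:9] = 2
        df = region_shape_metrics(LabelImage(labels=img)).set_index("cell_id")
        assert bool(df.loc[1, "degenerate"])
        assert np.isnan(df.loc[1, "aspect_ratio"])
        assert not bool(df.loc[2, "degenerate"])

    def test_pixel_size_scales_area_and_perimeter(self):
        img = np.zeros((30, 30), dtype=np.int32)
        img[5:25, 5:25] = 1
        a1 = region_shape_metrics(LabelImage(labels=img))
        a2 = region_shape_metrics(LabelImage(labels=img, pixel_size=0.5))
        assert a2["area"].iloc[0] == pytest.approx(a1["area"].iloc[0] * 0.25)
        assert a2["perimeter"].iloc[0] == pytest.approx(
            a1["perimeter"].iloc[0] * 0.5
        )

    def test_configurable_reference_axis(self):
        img = np.zeros((60, 80), dtype=np.int32)
        img[20:40, 20:60] = 1  # long axis along x
        df = region_shape_metrics(LabelImage(labels=img),
                                  reference_axis=(0.0, 1.0))
        assert df["orientation_deg"].iloc[0] == pytest.approx(90.0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            region_shape_metrics(LabelImage(labels=np.zeros((5, 5), int)))

    def test_agrees_with_polygon_measures_on_rasterized_polygon(self, rng):
        # convex polygons >= 200 px: pixel area within 3% of shoelace area
        for _ in range(5):
            ang = np.sort(rng.uniform(0, 2 * np.pi, 8))
            r = rng.uniform(12, 25)
            cx, cy = 40, 40
            poly = np.c_[cx + r * np.cos(ang), cy + r * np.sin(ang)]
            area, _ = polygon_measures(poly)
            if area < 200:
                continue
            img = np.zeros((80, 80), dtype=np.int32)
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], img.shape)
            img[rr, cc] = 1
            df = region_shape_metrics(LabelImage(labels=img))
            assert df["area"].iloc[0] == pytest.approx(area, rel=0.03)


class TestClassification:
    @pytest.mark.parametrize(
        "areas, label",
        [
            ([1.00, 0.70], "AC"),   # 30% decrease
            ([1.00, 1.25], "AE"),   # 25% increase
            ([1.00, 1.10], "no-change"),
            ([1.00, 0.801], "no-change"),  # just inside the 20% band
        ],
    )
    def test_threshold_convention(self, areas, label):
        tracks, freq = classify_apical_dynamics(
            [ApicalAreaTrack(1, np.arange(len(areas)), areas)]
        )
        assert tracks[0].label == label

    def test_extrema_baseline_option(self):
        tr = ApicalAreaTrack(1, np.arange(3), [1.0, 0.6, 0.95])
        assert classify_apical_dynamics([tr])[0][0].label == "no-change"
        assert classify_apical_dynamics(
            [tr], baseline="extrema"
        )[0][0].label == "AC"

    def test_frequency_table_sums_to_one(self):
        tracks = [
            ApicalAreaTrack(i, [0, 1], a)
            for i, a in enumerate([[1, 0.5], [1, 1.5], [1, 1.0], [1, 0.7]])
        ]
        _, freq = classify_apical_dynamics(tracks)
        assert freq["count"].sum() == 4
        assert freq["frequency"].sum() == pytest.approx(1.0)

    def test_track_validation(self):
        with pytest.raises(ValueError, match="2 timepoints"):
            ApicalAreaTrack(1, [0], [1.0])
        with pytest.raises(ValueError, match="positive"):
            ApicalAreaTrack(1, [0, 1], [1.0, -2.0])

    def test_csv_round_trip(self, tmp_path):
        tracks = [
            ApicalAreaTrack(1, [0, 1, 2], [10, 9, 7], true_label="AC"),
            ApicalAreaTrack(2, [0, 1, 2], [10, 10, 10], true_label="no-change"),
        ]
        p = tmp_path / "tracks.csv"
        write_tracks_csv(tracks, p)
        back = read_tracks_csv(p)
        assert [t.cell_id for t in back] == [1, 2]
        assert np.allclose(back[0].area, [10, 9, 7])
        assert back[0].true_label == "AC"


class TestDispersion:
    def test_hand_computed_example(self):
        mean, sd, cv = dispersion_stats([2, 4])
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(1.4142, abs=1e-4)
        assert cv == pytest.approx(0.4714, abs=1e-4)

    def test_constant_values_have_zero_cv(self):
        assert dispersion_stats([1, 1, 1])[2] == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            dispersion_stats([])
        with pytest.raises(ValueError):
            dispersion_stats([5.0])
        with pytest.raises(ValueError, match="zero mean"):
            dispersion_stats([-1.0, 1.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        c=st.floats(0.01, 100.0),
        n=st.integers(3, 30),
    )
    def test_cv_is_scale_invariant(self, seed, c, n):
        x = np.random.default_rng(seed).uniform(1.0, 10.0, n)
        cv1 = dispersion_stats(x)[2]
        cv2 = dispersion_stats(c * x)[2]
        assert cv2 == pytest.approx(cv1, rel=1e-9)


class TestJunctionIntensities:
    def test_constant_boundary_intensity_recovered(self):
        lab = np.zeros((12, 21), dtype=np.int32)
        lab[1:11, 1:10] = 1
        lab[1:11, 11:20] = 2
        inten = np.full(lab.shape, 7.0)
        j, v, c = junction_intensities(LabelImage(labels=lab, intensity=inten))
        assert len(j) == 1
        assert j["mean_intensity"].iloc[0] == pytest.approx(7.0)
        assert j["length_px"].iloc[0] == 10
        assert set(c["cell_id"]) == {1, 2}

    def test_single_cell_gives_empty_table(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[2:8, 2:8] = 1
        inten = np.ones(lab.shape)
        j, v, c = junction_intensities(LabelImage(labels=lab, intensity=inten))
        assert len(j) == 0
        assert len(c) == 1

    def test_vertex_pixels_reported_separately(self):
        # four quadrant cells meeting at a cross: center pixels touch >= 3 ids
        lab = np.zeros((21, 21), dtype=np.int32)
        lab[:10, :10] = 1
        lab[:10, 11:] = 2
        lab[11:, :10] = 3
        lab[11:, 11:] = 4
        inten = np.ones(lab.shape)
        j, v, c = junction_intensities(LabelImage(labels=lab, intensity=inten))
        assert len(v) >= 1
        assert len(j) == 4  # the four arms
        pairs = {tuple(r) for r in j[["cell_a", "cell_b"]].to_numpy()}
        assert pairs == {(1, 2), (1, 3), (2, 4), (3, 4)}

    def test_missing_intensity_rejected(self):
        lab = np.zeros((5, 5), dtype=np.int32)
        lab[1:4, 1:4] = 1
        with pytest.raises(ValueError, match="intensity"):
            junction_intensities(LabelImage(labels=lab))

    def test_tiff_reader_round_trip(self, tmp_path):
        import tifffile

        lab = np.zeros((12, 21), dtype=np.uint16)
        lab[1:11, 1:10] = 1
        lab[1:11, 11:20] = 2
        tifffile.imwrite(tmp_path / "lab.tif", lab)
        tifffile.imwrite(tmp_path / "int.tif",
                         np.full(lab.shape, 3.0, dtype=np.float32))
        img = read_label_image(tmp_path / "lab.tif", tmp_path / "int.tif",
                               pixel_size=0.31)
        assert img.pixel_size == 0.31
        j, _, _ = junction_intensities(img)
        assert j["length"].iloc[0] == pytest.approx(10 * 0.31)
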