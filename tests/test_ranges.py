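"""Speed filter, kernel utilization distributions, HDR contours, overlap."""
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from sympatry import ranges, simulate
from sympatry.config import ADELIE, GENTOO
from sympatry.exceptions import InputError

from conftest import quiet_config


class TestSpeedFilter:
    def test_clean_track_is_identity(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "individual": "a", "time": np.arange(200) * 60.0,
            "x": np.cumsum(rng.normal(0, 30, 200)),
            "y": np.cumsum(rng.normal(0, 30, 200))})
        out = ranges.speed_filter(df, v_max=3.0)
        pd.testing.assert_frame_equal(out, df)

    def test_single_teleporting_fix_removed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "individual": "a", "time": np.arange(100) * 60.0,
            "x": np.cumsum(rng.normal(0, 20, 100)),
            "y": np.cumsum(rng.normal(0, 20, 100))})
        df.loc[50, "x"] += 50 * 60 * 10
        out = ranges.speed_filter(df, v_max=3.0)
        assert len(out) == 99 and 50 not in out.index

    def test_endpoints_never_removed(self):
        df = pd.DataFrame({
            "individual": "a", "time": [0.0, 60.0, 120.0],
            "x": [0.0, 1e6, 0.0], "y": [0.0, 0.0, 0.0]})
        out = ranges.speed_filter(df, v_max=3.0)
        assert 0 in out.index and 2 in out.index

    def test_planted_outlier_contamination_removed(self):
        cfg = quiet_config(seed=11)
        cfg.tracks.outlier_fraction = 0.05
        tracks, _ = simulate.generate_tracks(cfg)
        out = ranges.speed_filter(tracks, v_max=3.0)
        removed = tracks.index.difference(out.index)
        outliers = tracks.index[tracks["is_outlier"]]
        frac_outliers_removed = len(removed.intersection(outliers)) / \
            max(len(outliers), 1)
        good = tracks.index[~tracks["is_outlier"]]
        frac_good_removed = len(removed.intersection(good)) / len(good)
        assert frac_outliers_removed >= 0.90
        assert frac_good_removed <= 0.01


class TestKde:
    def test_unit_mass(self):
        rng = np.random.default_rng(0)
        surf = ranges.kde2d(rng.normal(0, 500, 400),
                            rng.normal(0, 500, 400), cell=50.0)
        assert surf.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_cloud_peaks_at_centroid(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1000, 300, 2000)
        y = rng.normal(-500, 300, 2000)
        surf = ranges.kde2d(x, y, cell=50.0)
        iy, ix = np.unravel_index(np.argmax(surf.density),
                                  surf.density.shape)
        assert abs(surf.gx[ix] - x.mean()) <= 3 * surf.cell
        assert abs(surf.gy[iy] - y.mean()) <= 3 * surf.cell

    def test_mass_inside_true_half_ellipse(self):
        rng = np.random.default_rng(4)
        sigma = 1000.0
        x = rng.normal(0, sigma, 10000)
        y = rng.normal(0, sigma, 10000)
        inside = (x ** 2 + y ** 2) / sigma ** 2 <= 1.386
        assert inside.mean() == pytest.approx(0.5, abs=0.02)

    def test_too_few_points_raise(self):
        with pytest.raises(InputError):
            ranges.kde2d([0.0] * 5, [0.0] * 5)

    def test_degenerate_axis_floors_bandwidth(self):
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="bandwidth floored"):
            ranges.kde2d(np.zeros(50), rng.normal(0, 500, 50), cell=100.0)


def analytic_gaussian_surface(sigma=1000.0, cell=60.0, extent=5.5):
    """Exact bivariate normal density sampled on a grid."""
    g = np.arange(-extent * sigma, extent * sigma, cell) + cell / 2.0
    xx, yy = np.meshgrid(g, g)
    dens = np.exp(-(xx ** 2 + yy ** 2) / (2 * sigma ** 2)) / \
        (2 * np.pi * sigma ** 2)
    dens /= dens.sum() * cell * cell
    return ranges.DensitySurface(gx=g, gy=g, density=dens, cell=cell,
                                 bandwidths=(sigma, sigma), n_points=0)


@pytest.fixture(scope="module")
def gaussian_surface():
    return 1000.0, analytic_gaussian_surface()


class TestHdr:

    def test_gaussian_half_mass_area_closed_form(self, gaussian_surface):
        sigma, surf = gaussian_surface
        _, area, _ = ranges.hdr_contour(surf, 0.5)
        true = np.pi * 1.386 * sigma ** 2 / 1e6
        assert area == pytest.approx(true, rel=0.05)

    def test_contours_nest(self, gaussian_surface):
        _, surf = gaussian_surface
        g50, a50, _ = ranges.hdr_contour(surf, 0.5)
        g95, a95, _ = ranges.hdr_contour(surf, 0.95)
        assert a50 < a95
        assert g95.buffer(surf.cell).contains(g50)

    def test_near_total_mass_covers_positive_density(self, gaussian_surface):
        _, surf = gaussian_surface
        _, area, level = ranges.hdr_contour(surf, 0.999)
        cells_above = (surf.density > level).sum() * surf.cell_area / 1e6
        assert area == pytest.approx(cells_above, rel=0.10)

    def test_invalid_mass_fraction_raises(self, gaussian_surface):
        _, surf = gaussian_surface
        for m in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InputError):
                ranges.hdr_contour(surf, m)


class TestOverlap:
    def test_identical_ranges_overlap_fully(self):
        rng = np.random.default_rng(7)
        est = ranges.estimate_range(
            pd.DataFrame({"x": rng.normal(0, 800, 500),
                          "y": rng.normal(0, 800, 500)}),
            species="a", cell=100.0)
        inter, area = ranges.overlap(est, est)
        assert area == pytest.approx(est.areas_km2[0.95], rel=0.01)

    def test_distant_ranges_do_not_overlap(self):
        rng = np.random.default_rng(8)
        a = ranges.estimate_range(
            pd.DataFrame({"x": rng.normal(0, 500, 300),
                          "y": rng.normal(0, 500, 300)}),
            species="a", cell=100.0)
        b = ranges.estimate_range(
            pd.DataFrame({"x": rng.normal(100000, 500, 300),
                          "y": rng.normal(0, 500, 300)}),
            species="b", cell=100.0)
        _, area = ranges.overlap(a, b)
        assert area == 0.0

    def test_offset_unit_squares(self):
        a = box(0, 0, 1000, 1000)
        b = box(500, 0, 1500, 1000)
        _, area = ranges.overlap(a, b)
        assert area == pytest.approx(0.5 * 1000 * 1000 / 1e6)

    def test_overlap_is_symmetric(self):
        a = box(0, 0, 1000, 1000)
        b = box(300, 200, 1500, 1200)
        _, ab = ranges.overlap(a, b)
        _, ba = ranges.overlap(b, a)
        assert ab == ba


class TestRegions:
    def test_point_label_logic(self):
        a = box(0, 0, 10, 10)
        b = box(5, 0, 15, 10)
        df = pd.DataFrame({"x": [2.0, 7.0, 12.0, 50.0],
                           "y": [5.0, 5.0, 5.0, 5.0]})
        labels = ranges.assign_region(df, a, b)
        assert list(labels) == ["A_only", "overlap", "B_only", "outside"]

    def test_dive_without_nearby_fix_is_outside(self):
        dives = pd.DataFrame({
            "individual": ["a"], "start": [0.0], "behavior": ["forage"]})
        tracks = pd.DataFrame({
            "individual": ["a"], "time": [99999.0], "x": [5.0], "y": [5.0]})
        with pytest.warns(UserWarning, match="no track fix"):
            out = ranges.link_dives_to_positions(dives, tracks)
        labels = ranges.assign_region(out, box(0, 0, 10, 10),
                                      box(0, 0, 10, 10))
        assert list(labels) == ["outside"]

    def test_planted_overlap_dives_labelled_overlap(self):
        """Round trip: with range polygons that represent each species'
        true use area, planted in-zone dives label as overlap."""
        cfg = quiet_config(seed=13, days=3, dives_per_trip=15)
        tracks, _ = simulate.generate_tracks(cfg)
        tdr, truth = simulate.generate_tdr(cfg)
        from sympatry import dives as dive_mod
        det = dive_mod.analyze(tdr, correct=False)
        det = ranges.link_dives_to_positions(det, tracks)
        zone = truth.overlap_polygon
        polys = {}
        for sp in (ADELIE, GENTOO):
            ind = truth.individuals[truth.individuals["species"] == sp]
            pts = tracks[tracks["species"] == sp]
            hull = Polygon(zip(pts["x"], pts["y"])).convex_hull
            polys[sp] = hull.union(zone)
        labels = ranges.assign_region(det, polys[ADELIE], polys[GENTOO])
        det = det.assign(region=labels)
        det = det.sort_values(["individual", "start"]).reset_index(drop=True)
        td = truth.dives.sort_values(
            ["individual", "start"]).reset_index(drop=True)
        det["true_ov"] = td["in_overlap"].values
        g = det[(det["species"] == GENTOO) & det["true_ov"] &
                (det["behavior"] == "forage")]
        assert len(g) > 20
        assert (g["region"] == "overlap").mean() >= 0.95
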