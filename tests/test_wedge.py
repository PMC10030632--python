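"""Wedge-ROI construction: distance maps, bands, assembly, and areas."""

import numpy as np
import pytest

from conftest import flat_grid_mesh
from retmap.roi import circ_diff
from retmap.synth import GroundTruthConfig, add_map_noise, build_hemisphere
from retmap.wedge import (
    WedgeConfig,
    assemble_wedge,
    centers_only_area,
    clean_angles,
    geodesic_distance,
    iso_angle_distance,
    log_bands,
    meridian_wedge_rois,
    wedge_area,
)

HH_S, HH_E0 = 17.3, 0.75


class TestLogBands:
    def test_closed_form_edges(self):
        e = log_bands(1.0, 7.0, 7)
        assert e[0] == 1.0 and e[-1] == pytest.approx(7.0)
        assert e[1] == pytest.approx(7 ** (1 / 7))
        ratios = e[1:] / e[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            log_bands(0.0, 7.0)


class TestGeodesic:
    def test_line_vertices_are_zero_and_lipschitz(self, hemi_sym):
        line = hemi_sym.boundaries["v1_horizontal"]
        d = geodesic_distance(hemi_sym.mesh, line)
        assert np.allclose(d[line], 0.0)
        e, w = hemi_sym.mesh.edges()
        assert (np.abs(d[e[:, 0]] - d[e[:, 1]]) <= w + 1e-9).all()

    def test_flat_grid_matches_perpendicular_distance(self):
        mesh, idx = flat_grid_mesh(30, 30)
        # axis-aligned line source: graph distance equals |dy| exactly
        line = idx[:, 0]
        d = geodesic_distance(mesh, line)
        y = mesh.vertex_coords[:, 1]
        assert np.abs(d - y).max() <= 0.08 * max(1.0, y.max())
        # diagonal line whose perpendicular direction is an edge direction;
        # the lattice metric adds at most one axis step (parity), so compare
        # beyond a few edge lengths
        diag = np.array([idx[i, i] for i in range(30)])
        d2 = geodesic_distance(mesh, diag)
        x = mesh.vertex_coords[:, 0]
        perp = np.abs(x - y) / np.sqrt(2)
        interior = perp > 4
        assert (
            np.abs(d2[interior] - perp[interior]) / perp[interior]
        ).max() <= 0.08

    def test_empty_line_rejected(self, hemi_sym):
        with pytest.raises(ValueError):
            geodesic_distance(hemi_sym.mesh, np.array([], dtype=int))


class TestCleanAngles:
    def test_noiseless_map_is_fixed_point_away_from_folds(self, hemi_sym):
        """A linear noiseless angle map is invariant in the interior; at the
        reversal folds mean smoothing rounds the ridge tip slightly but must
        keep it on its own side of the meridian."""
        cleaned = clean_angles(
            hemi_sym.mesh, hemi_sym.retinotopy.angle, hemi_sym.retinotopy.r2
        )
        ecc = hemi_sym.retinotopy.ecc
        # fold rounding diffuses a few vertex rings inward, and the first /
        # last eccentricity rows have one-sided neighborhoods: test the
        # genuinely linear interior of the map
        interior = np.flatnonzero(
            (np.abs(hemi_sym.param) < 75)
            & (np.abs(hemi_sym.param) > 8)
            & (ecc > 0.4)
            & (ecc < 7.0)
        )
        delta = np.abs(circ_diff(cleaned[interior], hemi_sym.retinotopy.angle[interior]))
        assert delta.max() < 0.5
        v1 = hemi_sym.labels["V1"]
        signed = circ_diff(cleaned[v1], 0.0)
        assert signed.min() >= -90.0 - 1e-6 and signed.max() <= 90.0 + 1e-6
        ridge = np.abs(
            circ_diff(cleaned[v1], hemi_sym.retinotopy.angle[v1])
        )
        assert ridge.max() < 8.0  # fold attenuation stays local and bounded

    def test_denoises_ten_degree_noise_to_three_rms(self, hemi_sym):
        noisy = add_map_noise(hemi_sym.retinotopy, angle_noise_deg=10.0, seed=1)
        cleaned = clean_angles(hemi_sym.mesh, noisy.angle, noisy.r2)
        v1 = hemi_sym.labels["V1"]
        resid = circ_diff(cleaned[v1], hemi_sym.retinotopy.angle[v1])
        assert np.sqrt((resid**2).mean()) < 3.0

    def test_never_crosses_reversal_boundary(self, hemi_sym):
        """V1 vertices away from the border stay inside the hemifield."""
        noisy = add_map_noise(hemi_sym.retinotopy, angle_noise_deg=10.0, seed=2)
        inner = np.flatnonzero(np.abs(hemi_sym.param) < 80)
        # clamp input angles into the hemifield so crossings can only be
        # introduced by the smoothing itself
        ang = noisy.angle.copy()
        s = np.clip(circ_diff(ang, 0.0), -90.0, 90.0)
        ang = s % 360.0
        cleaned = clean_angles(hemi_sym.mesh, ang, noisy.r2)
        s_out = circ_diff(cleaned[inner], 0.0)
        assert s_out.min() >= -90.5 and s_out.max() <= 90.5


class TestIsoAngleDistance:
    def test_mean_of_qualifying_vertices(self):
        dist = np.array([5.0, 5.0, 2.0, np.nan])
        offset = np.array([25.0, 27.0, 80.0, 25.0])
        r2 = np.array([1.0, 1.0, 1.0, 1.0])
        got = iso_angle_distance(
            np.nan_to_num(dist, nan=np.inf), offset, r2, np.arange(4), width=25.0
        )
        assert got == 5.0

    def test_missing_band_is_nan(self):
        got = iso_angle_distance(
            np.ones(3), np.array([50.0, 60, 70]), np.ones(3), np.arange(3), 15.0
        )
        assert np.isnan(got)

    def test_iso_distance_matches_analytic_arc_length(self, hemi_sym):
        """On the symmetric mesh the 45 deg iso-angle line sits at the
        closed-form construction arc length from the meridian."""
        cfg = WedgeConfig()
        rois = meridian_wedge_rois(
            hemi_sym.mesh, hemi_sym.retinotopy.angle, hemi_sym.retinotopy.ecc,
            hemi_sym.retinotopy.r2, hemi_sym.labels["V1"], "horizontal", cfg,
        )
        edges = log_bands(*cfg.ecc_window, cfg.n_bands)
        centers = np.sqrt(edges[:-1] * edges[1:])
        analytic = HH_S * (centers / (centers + HH_E0)) * np.radians(45.0)
        assert np.allclose(rois[45.0].iso_distances, analytic, rtol=0.05)


class TestAssembly:
    def test_zero_iso_distance_reduces_to_meridian_line(self, hemi_sym):
        line = hemi_sym.boundaries["v1_horizontal"]
        dist = geodesic_distance(hemi_sym.mesh, line)
        edges = log_bands()
        wr = assemble_wedge(
            dist, hemi_sym.retinotopy.ecc, hemi_sym.labels["V1"], edges,
            np.zeros(7),
        )
        ecc_line = hemi_sym.retinotopy.ecc[line]
        expected = set(line[(ecc_line >= 1) & (ecc_line <= 7)])
        assert set(wr.vertex_ids) == expected

    def test_all_bands_missing_rejected(self, hemi_sym):
        with pytest.raises(ValueError):
            assemble_wedge(
                np.ones(hemi_sym.mesh.n_vertices), hemi_sym.retinotopy.ecc,
                hemi_sym.labels["V1"], log_bands(), np.full(7, np.nan),
            )

    def test_missing_band_interpolated_in_log_ecc(self, hemi_sym):
        line = hemi_sym.boundaries["v1_horizontal"]
        dist = geodesic_distance(hemi_sym.mesh, line)
        iso = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0])
        wr = assemble_wedge(
            dist, hemi_sym.retinotopy.ecc, hemi_sym.labels["V1"], log_bands(), iso
        )
        # log-spaced band centers are geometric, so linear-in-log
        # interpolation of the gap gives the midpoint of its neighbors
        assert wr.iso_distances[2] == pytest.approx(3.0)

    def test_monotone_nesting_across_widths(self, hemi_sym):
        noisy = add_map_noise(hemi_sym.retinotopy, seed=4)
        cleaned = clean_angles(hemi_sym.mesh, noisy.angle, noisy.r2)
        for meridian in ("horizontal", "upper-vertical", "lower-vertical"):
            rois = meridian_wedge_rois(
                hemi_sym.mesh, cleaned, hemi_sym.retinotopy.ecc, noisy.r2,
                hemi_sym.labels["V1"], meridian,
            )
            widths = sorted(rois)
            for a, b in zip(widths[:-1], widths[1:]):
                assert set(rois[a].vertex_ids) <= set(rois[b].vertex_ids)
                assert wedge_area(rois[a], hemi_sym.mesh) <= wedge_area(
                    rois[b], hemi_sym.mesh
                )

    def test_45deg_wedges_tile_the_band(self, hemi_sym):
        """The four +-45 deg wedges partition V1's 1-7 deg band: union
        within 5% of the band area, pairwise overlaps below 2%."""
        v1 = hemi_sym.labels["V1"]
        ecc = hemi_sym.retinotopy.ecc
        band_ids = v1[(ecc[v1] >= 1) & (ecc[v1] <= 7)]
        band_area = hemi_sym.mesh.vertex_area["midgray"][band_ids].sum()
        sets = {}
        for meridian in ("horizontal", "upper-vertical", "lower-vertical"):
            rois = meridian_wedge_rois(
                hemi_sym.mesh, hemi_sym.retinotopy.angle, ecc,
                hemi_sym.retinotopy.r2, v1, meridian,
            )
            sets[meridian] = set(rois[45.0].vertex_ids)
        union = set().union(*sets.values())
        union_area = hemi_sym.mesh.vertex_area["midgray"][list(union)].sum()
        assert abs(union_area - band_area) / band_area < 0.05
        names = list(sets)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ov = sets[names[i]] & sets[names[j]]
                ov_area = hemi_sym.mesh.vertex_area["midgray"][list(ov)].sum()
                assert ov_area / band_area < 0.02

    def test_vertical_wedges_symmetric_on_symmetric_mesh(self, hemi_sym):
        areas = {}
        for meridian in ("upper-vertical", "lower-vertical"):
            rois = meridian_wedge_rois(
                hemi_sym.mesh, hemi_sym.retinotopy.angle, hemi_sym.retinotopy.ecc,
                hemi_sym.retinotopy.r2, hemi_sym.labels["V1"], meridian,
            )
            areas[meridian] = wedge_area(rois[25.0], hemi_sym.mesh)
        a, b = areas.values()
        assert abs(a - b) / a < 0.02

    def test_depth_ordering_of_wedge_areas(self, hemi_sym):
        rois = meridian_wedge_rois(
            hemi_sym.mesh, hemi_sym.retinotopy.angle, hemi_sym.retinotopy.ecc,
            hemi_sym.retinotopy.r2, hemi_sym.labels["V1"], "horizontal",
        )
        w = rois[25.0]
        pial = wedge_area(w, hemi_sym.mesh, "pial")
        mid = wedge_area(w, hemi_sym.mesh, "midgray")
        white = wedge_area(w, hemi_sym.mesh, "white")
        assert pial >= mid >= white
        with pytest.raises(ValueError):
            wedge_area(w, hemi_sym.mesh, "nope")


class TestCentersOnly:
    def test_full_hemifield_range_recovers_band_area(self, hemi_sym):
        v1 = hemi_sym.labels["V1"]
        got = centers_only_area(
            hemi_sym.mesh, hemi_sym.retinotopy, v1, 0.0, 90.0
        )
        ecc = hemi_sym.retinotopy.ecc
        band = v1[(ecc[v1] >= 1) & (ecc[v1] <= 7)]
        assert got == pytest.approx(
            hemi_sym.mesh.vertex_area["midgray"][band].sum()
        )

    def test_cross_method_hva_agreement(self, hemi_adult):
        """Centers-only and wedge-ROI HVA estimates agree within 15 index
        points on a mesh with an injected asymmetry."""
        from retmap.asym import hva_index

        mesh, retino = hemi_adult.mesh, hemi_adult.retinotopy
        v1 = hemi_adult.labels["V1"]
        co = {
            m: centers_only_area(mesh, retino, v1, m, 25.0)
            for m in (0.0, 90.0, 270.0)
        }
        hva_centers = hva_index(2 * co[0.0], 2 * (co[90.0] + co[270.0]))
        areas = {}
        for meridian, m in [
            ("horizontal", 0.0), ("upper-vertical", 90.0),
            ("lower-vertical", 270.0),
        ]:
            rois = meridian_wedge_rois(
                mesh, retino.angle, retino.ecc, retino.r2, v1, meridian
            )
            areas[meridian] = wedge_area(rois[25.0], mesh)
        hva_wedge = hva_index(
            2 * areas["horizontal"],
            2 * (areas["upper-vertical"] + areas["lower-vertical"]),
        )
        assert abs(hva_wedge - hva_centers) < 15.0
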