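"""Synthetic cortex generator: gain profile, mesh law-exactness, simulators."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from retmap.qc import count_exceedances, framewise_displacement
from retmap.roi import circ_diff, map_surface_area
from retmap.synth import (
    GroundTruthConfig,
    angular_gain,
    build_hemisphere,
    gain_cumulative_deg,
    noise_sd_for_r2,
    simulate_bold,
    simulate_motion,
)

HH_S, HH_E0 = 17.3, 0.75


def wedge_index_from_gain(hva, vma, half_width=25.0):
    """Quadrature oracle: HVA/VMA indices implied by wedge integrals of the
    gain profile."""
    wint = lambda m: quad(lambda t: angular_gain(t, hva, vma), m - half_width,
                          m + half_width, limit=200)[0]
    H, U, L = wint(0) + wint(180), wint(90), wint(270)
    V = U + L
    return (H - V) / ((H + V) / 2) * 100, (L - U) / ((L + U) / 2) * 100


class TestAngularGain:
    def test_identity_when_no_asymmetry(self):
        th = np.linspace(0, 360, 721)
        assert np.allclose(angular_gain(th, 0.0, 0.0), 1.0)

    @pytest.mark.parametrize("hva,vma", [(0, 0), (80, 52), (80, 0), (40, -30)])
    def test_area_preserving_normalization(self, hva, vma):
        th = np.linspace(0, 360, 100_001)
        integral = np.trapezoid(angular_gain(th, hva, vma), th)
        assert integral == pytest.approx(360.0, abs=1e-6)

    @pytest.mark.parametrize("hva,vma", [(80, 52), (80, 0), (30, 20)])
    def test_wedge_integrals_reproduce_requested_indices(self, hva, vma):
        got_hva, got_vma = wedge_index_from_gain(hva, vma)
        assert got_hva == pytest.approx(hva, abs=1e-6)
        assert got_vma == pytest.approx(vma, abs=1e-6)

    def test_unreachable_amplitudes_raise(self):
        with pytest.raises(ValueError):
            angular_gain(np.array([0.0]), 190.0, 0.0)

    def test_cumulative_matches_numeric_integral(self):
        p = np.linspace(-270, 270, 37)
        fine = np.linspace(-270, 270, 54001)
        from retmap.synth import param_to_angle

        g = angular_gain(param_to_angle(fine), 80, 52)
        numeric = np.interp(
            p, fine, np.concatenate([[0], np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(fine))])
        )
        numeric -= np.interp(0.0, fine, np.concatenate(
            [[0], np.cumsum((g[1:] + g[:-1]) / 2 * np.diff(fine))]))
        assert np.allclose(gain_cumulative_deg(p, 80, 52), numeric, atol=1e-3)


class TestBuildHemisphere:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            GroundTruthConfig(mesh_density=200)
        with pytest.raises(ValueError):
            GroundTruthConfig(hva_amp=250)
        with pytest.raises(ValueError):
            GroundTruthConfig(hh_e0=0)

    def test_mesh_invariants(self, hemi_sym):
        mesh = hemi_sym.mesh
        assert (mesh.vertex_area["midgray"] > 0).all()
        coords3 = np.column_stack([mesh.vertex_coords, np.zeros(mesh.n_vertices)])
        tri = coords3[mesh.faces]
        total = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        ).sum()
        assert mesh.total_area() == pytest.approx(total, rel=1e-9)
        e, _ = mesh.edges()
        g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                       shape=(mesh.n_vertices,) * 2)
        n_comp, _ = connected_components(g, directed=False)
        assert n_comp == 1

    def test_depth_scaling_order(self, hemi_sym):
        va = hemi_sym.mesh.vertex_area
        assert (va["pial"] > va["midgray"]).all()
        assert (va["white"] < va["midgray"]).all()

    def test_labels_partition_and_v1_is_hemifield(self, hemi_sym):
        labels = hemi_sym.labels
        all_ids = np.sort(np.concatenate(list(labels.values())))
        assert np.array_equal(all_ids, np.arange(hemi_sym.mesh.n_vertices))
        ang = hemi_sym.retinotopy.angle[labels["V1"]]
        signed = circ_diff(ang, 0.0)
        assert signed.min() >= -90 - 1e-6 and signed.max() <= 90 + 1e-6

    def test_left_right_symmetry(self):
        cfg = GroundTruthConfig(hva_amp=80, vma_amp=52, mesh_density=2000)
        lh = build_hemisphere(cfg, "left")
        rh = build_hemisphere(cfg, "right")
        a_l = map_surface_area(lh.mesh, lh.labels["V1"])
        a_r = map_surface_area(rh.mesh, rh.labels["V1"])
        assert abs(a_l - a_r) / a_l < 0.005
        # right hemisphere represents the left hemifield
        s = circ_diff(rh.retinotopy.angle[rh.labels["V1"]], 180.0)
        assert np.abs(s).max() <= 90 + 1e-6

    def test_central_seven_degrees_is_38_percent_of_v1(self):
        cfg = GroundTruthConfig(ecc_range=(0, 90), mesh_density=20_000)
        h = build_hemisphere(cfg)
        ecc = h.retinotopy.ecc
        a7 = map_surface_area(h.mesh, h.labels["V1"], ecc=ecc, ecc_window=(0, 7))
        a90 = map_surface_area(h.mesh, h.labels["V1"], ecc=ecc, ecc_window=(0, 90))
        assert a7 / a90 == pytest.approx(0.38, abs=0.02)

    def test_areal_magnification_matches_horton_hoyt_within_5pct(self, hemi_sym):
        """Bin vertex areas between row midpoints and compare with the exact
        integral of the generating law over the same eccentricity span."""
        v1 = hemi_sym.labels["V1"]
        ecc = hemi_sym.retinotopy.ecc
        rows = np.unique(np.round(ecc, 9))
        mids = np.sqrt(rows[:-1] * rows[1:])  # midpoints in log-ecc
        for E in [1, 2, 3, 5, 6.5]:
            lo = mids[np.searchsorted(mids, E * 0.8)]
            hi = mids[np.searchsorted(mids, E * 1.2)]
            sel = v1[(ecc[v1] > lo) & (ecc[v1] < hi)]
            area = hemi_sym.mesh.vertex_area["midgray"][sel].sum()
            expected = np.pi * HH_S**2 * (
                quad(lambda e: e / (e + HH_E0) ** 2, lo, hi)[0]
            )
            assert area == pytest.approx(expected, rel=0.05)

    def test_wedge_areas_match_gain_quadrature(self):
        """+-25 deg wedge areas on a dense mesh vs the analytic construction
        integrals (within 2%)."""
        cfg = GroundTruthConfig(hva_amp=80, vma_amp=52, mesh_density=20_000)
        h = build_hemisphere(cfg)
        ecc, ang, v1 = h.retinotopy.ecc, h.retinotopy.angle, h.labels["V1"]
        ei = quad(lambda E: E / (E + HH_E0) ** 2, 1, 7)[0]
        for m, half in [(0.0, 1.0), (90.0, 0.5), (270.0, 0.5)]:
            gi = quad(lambda t: angular_gain(t, 80, 52), m - 25, m + 25)[0]
            expected = HH_S**2 * np.radians(gi) * ei * half
            d = np.abs(circ_diff(ang[v1], m))
            sel = v1[(d <= 25) & (ecc[v1] >= 1) & (ecc[v1] <= 7)]
            got = h.mesh.vertex_area["midgray"][sel].sum()
            assert got == pytest.approx(expected, rel=0.02)


class TestSimulators:
    def test_bold_deterministic_and_noise_validation(self, hemi_sym, movie96):
        ids = hemi_sym.labels["V1"][:8]
        kw = dict(noise_sd=noise_sd_for_r2(0.6), seed=7, vertex_ids=ids)
        a = simulate_bold(hemi_sym.mesh, hemi_sym.retinotopy, movie96, **kw)
        b = simulate_bold(hemi_sym.mesh, hemi_sym.retinotopy, movie96, **kw)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            simulate_bold(hemi_sym.mesh, hemi_sym.retinotopy, movie96, noise_sd=-1)

    def test_motion_trivial_and_spikes(self):
        zero = simulate_motion(20)
        assert framewise_displacement(zero).fd.sum() == 0
        spikes = sorted([3, 7, 11, 15])
        tr = simulate_motion(50, spike_frames=spikes, spike_mm=0.6)
        fd = framewise_displacement(tr)
        assert count_exceedances(fd, 0.5) == len(spikes)
        assert np.flatnonzero(fd.fd > 0.5).tolist() == [s - 1 for s in spikes]

    def test_jittered_trace_exceeds_only_at_spikes(self):
        tr = simulate_motion(
            200, spike_frames=list(range(10, 110, 10)), spike_mm=0.6,
            jitter_sd=0.02, seed=5,
        )
        fd = framewise_displacement(tr)
        assert count_exceedances(fd, 0.5) == 10

    def test_spike_frame_validation(self):
        with pytest.raises(ValueError):
            simulate_motion(10, spike_frames=[0])
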