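"""Curvature estimator: analytic recovery, sign, scaling, exclusions."""

import numpy as np
import pytest

from membrane_gate.curvature import (
    CurvatureField,
    curvature_field,
    cylindrical_chart,
    planar_chart,
    principal_curvatures,
    reference_normals,
    reference_points,
    vertex_curvature,
)
from membrane_gate.frames import LOWER, PHOSPHATE, TAIL_CARBON, MembraneFrame
from membrane_gate.pores import make_grid, pore_mask
from membrane_gate.syngen import Geometry, SynthSpec, generate_membrane, punch_pore


def _cylinder(radius, spacing=0.25, noise=0.0, seed=1):
    spec = SynthSpec(
        geometry=Geometry.CYLINDER,
        lateral_extent=10.0,
        lipid_spacing=spacing,
        noise_sd=noise,
        seed=seed,
        geometry_params={"radius": radius},
    )
    return generate_membrane(spec)


def _bump(amplitude=2.0, width=4.0, extent=20.0, spacing=0.4):
    spec = SynthSpec(
        geometry=Geometry.BUMP,
        lateral_extent=extent,
        lipid_spacing=spacing,
        noise_sd=0.0,
        seed=1,
        geometry_params={"amplitude": amplitude, "width": width},
    )
    return generate_membrane(spec)


class TestReferencePoints:
    def test_flat_membrane_reference_plane(self, flat_frame):
        chart = planar_chart(flat_frame)
        fld = reference_points(flat_frame, chart, 12, 3.0)
        z_low = flat_frame.phosphates(LOWER)[0, 2]
        ref_z = fld.ref_points[fld.valid][:, 2]
        np.testing.assert_allclose(ref_z, z_low, atol=1e-12)

    def test_single_lipid_reference_is_its_phosphate(self):
        head = np.array([5.0, 5.0, 3.0])
        pos = np.vstack([head, head + [0, 0, 0.5], head + [0, 0, 1.0]])
        frame = MembraneFrame(
            positions=pos,
            roles=[PHOSPHATE, TAIL_CARBON, TAIL_CARBON],
            leaflets=[LOWER, LOWER, LOWER],
            residue_ids=[0, 0, 0],
            box=[10.0, 10.0, 10.0],
        )
        fld = reference_points(frame, planar_chart(frame), 5, 3.0)
        assert fld.valid.sum() > 0
        for p in fld.ref_points[fld.valid]:
            np.testing.assert_allclose(p, head)

    def test_noise_averages_down_in_reference_points(self):
        spec = SynthSpec(lateral_extent=20.0, lipid_spacing=0.5, noise_sd=0.1, seed=2)
        frame = generate_membrane(spec)
        fld = reference_points(frame, planar_chart(frame), 10, 3.0)
        z_ref = fld.ref_points[fld.valid][:, 2]
        # ~110 neighbors in a 3 nm disc: the mean's sd is well under the bead sd
        assert z_ref.std() < 0.1 / 3

    def test_nonpositive_smoothing_radius_rejected(self, flat_frame):
        with pytest.raises(ValueError):
            reference_points(flat_frame, planar_chart(flat_frame), 10, 0.0)


class TestReferenceNormals:
    def test_flat_membrane_normals_point_down(self, flat_frame):
        fld = curvature_field(flat_frame, n=12, smoothing_radius=3.0)
        normals = fld.ref_normals[fld.valid]
        np.testing.assert_allclose(normals, [[0.0, 0.0, -1.0]] * len(normals), atol=1e-9)

    def test_cylinder_normals_are_radial(self):
        frame = _cylinder(5.0)
        chart = cylindrical_chart(frame)
        fld = reference_points(frame, chart, (48, 8), 0.5)
        fld = reference_normals(frame, fld, 0.5)
        ax = chart.axis_point
        P = fld.ref_points[fld.valid]
        N = fld.ref_normals[fld.valid]
        r = np.hypot(P[:, 0] - ax[0], P[:, 2] - ax[1])
        radial_in = -np.stack(
            [(P[:, 0] - ax[0]) / r, np.zeros(len(P)), (P[:, 2] - ax[1]) / r], axis=1
        )
        cos = np.sum(N * radial_in, axis=1)
        assert np.all(np.abs(N[:, 1]) < 0.05)
        assert np.all(cos > np.cos(np.radians(2.0)))

    def test_sphere_normals_within_two_degrees_of_radial(self):
        spec = SynthSpec(
            geometry=Geometry.SPHERE,
            lateral_extent=12.0,
            lipid_spacing=0.25,
            noise_sd=0.0,
            seed=1,
            geometry_params={"radius": 5.0},
        )
        frame = generate_membrane(spec)
        center = frame.meta["center"]
        fld = curvature_field(frame, n=24, smoothing_radius=0.5, chart="planar")
        P = fld.ref_points[fld.valid]
        N = fld.ref_normals[fld.valid]
        radial_in = center - P
        radial_in /= np.linalg.norm(radial_in, axis=1, keepdims=True)
        cos = np.sum(N * radial_in, axis=1)
        assert np.all(cos > np.cos(np.radians(2.0)))

    def test_degenerate_coincident_means_flagged_not_crashed(self):
        # tails exactly on the phosphate: zero-length normal
        head = np.array([5.0, 5.0, 3.0])
        frame = MembraneFrame(
            positions=np.vstack([head, head]),
            roles=[PHOSPHATE, TAIL_CARBON],
            leaflets=[LOWER, LOWER],
            residue_ids=[0, 0],
            box=[10.0, 10.0, 10.0],
        )
        fld = reference_points(frame, planar_chart(frame), 5, 3.0)
        fld = reference_normals(frame, fld, 3.0)
        assert not fld.valid.any()


class TestPrincipalCurvatures:
    @pytest.mark.parametrize("radius", [2.5, 5.0, 7.5, 10.0])
    def test_cylinder_series_recovers_reciprocal_radius(self, radius):
        frame = _cylinder(radius)
        fld = curvature_field(
            frame, n=(72, 10), smoothing_radius=0.4, chart="cylindrical"
        )
        cx = fld.C_x[fld.valid]
        cy = fld.C_y[fld.valid]
        true = 1.0 / radius
        within = np.abs(cx - true) <= 0.05 * true
        assert np.median(cx) == pytest.approx(true, rel=0.05)
        assert within.mean() >= 0.90
        assert np.all(np.abs(cy) < 0.02)

    def test_flat_membrane_is_flat(self, flat_frame):
        fld = curvature_field(flat_frame, n=12, smoothing_radius=3.0)
        assert np.all(fld.C_x[fld.valid] == 0.0)
        assert np.all(fld.C_y[fld.valid] == 0.0)
        assert np.all(fld.C_m[fld.valid] == 0.0)

    def test_sphere_mean_curvature(self):
        spec = SynthSpec(
            geometry=Geometry.SPHERE,
            lateral_extent=12.0,
            lipid_spacing=0.25,
            noise_sd=0.0,
            seed=1,
            geometry_params={"radius": 5.0},
        )
        fld = curvature_field(
            generate_membrane(spec), n=30, smoothing_radius=0.5, chart="planar"
        )
        assert np.median(fld.C_m[fld.valid]) == pytest.approx(0.2, rel=0.05)

    def test_mean_curvature_is_average_of_principal(self):
        frame = _cylinder(5.0)
        fld = curvature_field(frame, n=(48, 8), smoothing_radius=0.5)
        v = fld.valid
        np.testing.assert_array_equal(fld.C_m[v], (fld.C_x[v] + fld.C_y[v]) / 2.0)

    def test_bump_apex_positive_dimple_negative(self):
        up = curvature_field(_bump(2.0), n=20, smoothing_radius=1.0)
        down = curvature_field(_bump(-2.0), n=20, smoothing_radius=1.0)
        apex_up = up.C_m[9:11, 9:11].mean()
        apex_down = down.C_m[9:11, 9:11].mean()
        assert apex_up > 0 > apex_down
        assert apex_up == pytest.approx(-apex_down, rel=1e-6)
        # apex mean curvature of a Gaussian bump is amplitude / width^2
        assert apex_up == pytest.approx(2.0 / 16.0, rel=0.15)

    def test_doubling_coordinates_halves_curvature(self):
        frame = _bump(2.0)
        doubled = frame.copy()
        doubled.positions = frame.positions * 2.0
        doubled.box = frame.box * 2.0
        a = curvature_field(frame, n=20, smoothing_radius=1.0)
        b = curvature_field(doubled, n=20, smoothing_radius=2.0)
        v = a.valid & b.valid
        np.testing.assert_allclose(b.C_m[v], a.C_m[v] / 2.0, atol=1e-9)

    def test_pore_cells_are_excluded(self):
        spec = SynthSpec(lateral_extent=20.0, lipid_spacing=0.5, noise_sd=0.0, seed=1)
        frame = generate_membrane(spec)
        punched = punch_pore(frame, (10.0, 10.0), 3.0)
        grid = make_grid(punched, 20)
        mask = pore_mask(punched, grid)
        fld = curvature_field(punched, n=20, smoothing_radius=1.0, pore=mask)
        assert not fld.valid[mask.values].any()


class TestVertexCurvature:
    def test_apex_cell_found_under_nanoparticle(self):
        fld = curvature_field(_bump(2.0), n=20, smoothing_radius=1.0)
        cell, cm = vertex_curvature(fld, np.array([10.0, 10.0, 15.0]), 2.0)
        assert cell in {(9, 9), (9, 10), (10, 9), (10, 10)}
        assert cm == pytest.approx(fld.C_m[fld.valid].max())

    def test_flat_membrane_vertex_is_flat(self, flat_frame):
        fld = curvature_field(flat_frame, n=12, smoothing_radius=3.0)
        _, cm = vertex_curvature(fld, np.array([6.0, 6.0, 8.0]), 2.0)
        assert cm == 0.0

    def test_tie_break_is_deterministic_by_cell_index(self):
        fld = curvature_field(_bump(2.0), n=20, smoothing_radius=1.0)
        fld.C_m[:, :] = 0.25  # force an all-equal field
        cell, _ = vertex_curvature(fld, np.array([10.0, 10.0, 15.0]), 2.0)
        cell2, _ = vertex_curvature(fld, np.array([10.0, 10.0, 15.0]), 2.0)
        assert cell == cell2
        assert fld.valid[cell]

    def test_no_valid_cell_in_search_disc_rejected(self):
        fld = curvature_field(_bump(2.0), n=20, smoothing_radius=1.0)
        fld.valid[:, :] = False
        with pytest.raises(ValueError, match="search disc"):
            vertex_curvature(fld, np.array([10.0, 10.0, 15.0]), 2.0)
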