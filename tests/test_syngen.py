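"""Generator ground truth: lattices, pores, scripted paths, umbrella samples."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from membrane_gate.energetics import KB, PMFProfile
from membrane_gate.frames import LOWER, PHOSPHATE, UPPER
from membrane_gate.syngen import (
    ChargeScheme,
    Geometry,
    SynthSpec,
    TrajectoryLabel,
    TranslocationClass,
    biased_density,
    enumerate_design_grid,
    generate_membrane,
    generate_np_trajectory,
    generate_umbrella_samples,
    punch_pore,
)


class TestGenerateMembrane:
    def test_flat_noise_free_upper_leaflet_is_a_plane(self, flat_frame):
        z = flat_frame.phosphates(UPPER)[:, 2]
        assert np.ptp(z) == 0.0

    def test_lipid_count_matches_lattice_enumeration(self):
        # Brute-force lattice oracle: a head sits at (i + 1/2) * spacing for
        # every i with a full spacing inside the extent.
        extent, spacing = 37.0, 0.8
        per_axis = len([i for i in range(10_000) if (i + 1) * spacing <= extent + 1e-12])
        spec = SynthSpec(lateral_extent=extent, lipid_spacing=spacing, noise_sd=0.0)
        frame = generate_membrane(spec)
        heads = frame.phosphates(UPPER)
        assert per_axis == 46  # floor(37 / 0.8)
        assert len(heads) == per_axis**2 == 2116

    def test_cylinder_heads_sit_on_nominal_radius(self):
        spec = SynthSpec(
            geometry=Geometry.CYLINDER,
            lateral_extent=10.0,
            lipid_spacing=0.3,
            noise_sd=0.0,
            geometry_params={"radius": 2.5},
        )
        frame = generate_membrane(spec)
        low = frame.phosphates(LOWER)
        ax = frame.meta["axis_point"]
        r = np.hypot(low[:, 0] - ax[0], low[:, 2] - ax[1])
        np.testing.assert_allclose(r, 2.5, atol=1e-9)

    def test_spacing_larger_than_extent_is_empty_membrane_error(self):
        with pytest.raises(ValueError, match="empty"):
            generate_membrane(SynthSpec(lateral_extent=1.0, lipid_spacing=2.0))

    def test_identical_spec_and_seed_is_bitwise_deterministic(self):
        spec = SynthSpec(lateral_extent=10.0, noise_sd=0.15, seed=42)
        a, b = generate_membrane(spec), generate_membrane(spec)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.roles, b.roles)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SynthSpec(lateral_extent=-1.0)
        with pytest.raises(ValueError):
            SynthSpec(noise_sd=-0.1)
        with pytest.raises(ValueError):  # radius below half-thickness
            SynthSpec(
                geometry=Geometry.SPHERE,
                bilayer_thickness=4.0,
                geometry_params={"radius": 1.0},
            )


class TestPunchPore:
    def test_radius_zero_leaves_frame_unchanged(self, flat_frame):
        out = punch_pore(flat_frame, (6.0, 6.0), 0.0)
        assert np.array_equal(out.positions, flat_frame.positions)
        assert out.meta["removed_lipids"] == 0

    def test_removed_set_matches_per_lipid_distance_scan(self, noisy_frame):
        center, radius = (10.0, 10.0), 2.0
        out = punch_pore(noisy_frame, center, radius)
        # independent oracle: plain loop over head beads
        survivors = set()
        removed = 0
        for k in range(noisy_frame.n_beads):
            if noisy_frame.roles[k] != PHOSPHATE:
                continue
            p = noisy_frame.positions[k]
            dx = min(abs(p[0] - center[0]), noisy_frame.box[0] - abs(p[0] - center[0]))
            dy = min(abs(p[1] - center[1]), noisy_frame.box[1] - abs(p[1] - center[1]))
            if math.hypot(dx, dy) < radius:
                removed += 1
            else:
                survivors.add(int(noisy_frame.residue_ids[k]))
        assert out.meta["removed_lipids"] == removed
        assert set(out.residue_ids[out.roles == PHOSPHATE].tolist()) == survivors

    def test_surviving_beads_never_move(self, noisy_frame):
        out = punch_pore(noisy_frame, (10.0, 10.0), 3.0)
        kept = np.isin(noisy_frame.residue_ids, out.residue_ids)
        assert np.array_equal(out.positions, noisy_frame.positions[kept])

    @given(r=st.floats(min_value=0.0, max_value=4.0))
    def test_smaller_radius_removes_a_subset(self, noisy_frame, r):
        big = punch_pore(noisy_frame, (10.0, 10.0), 4.0)
        small = punch_pore(noisy_frame, (10.0, 10.0), r)
        assert set(big.residue_ids.tolist()) <= set(small.residue_ids.tolist())

    def test_oversized_radius_rejected(self, flat_frame):
        diag = float(np.linalg.norm(flat_frame.box[:2]))
        with pytest.raises(ValueError, match="radius"):
            punch_pore(flat_frame, (6.0, 6.0), diag / 2.0)


class TestDesignGrid:
    def test_full_grid_has_36_permutations(self):
        assert len(enumerate_design_grid()) == 36

    def test_one_chemistry_is_exactly_half(self):
        grid = enumerate_design_grid()
        hydrophobic = [d for d in grid if d.ligand_chemistry.value == "hydrophobic"]
        assert len(hydrophobic) * 2 == len(grid)

    def test_all_entries_unique_as_tuples(self):
        grid = enumerate_design_grid()
        tuples = {
            (d.core_diameter, d.charge_scheme, d.ligand_chemistry, d.ionized_count)
            for d in grid
        }
        # brute-force pairwise comparison
        for i, a in enumerate(grid):
            for b in grid[i + 1 :]:
                assert a != b
        assert len(tuples) == len(grid)

    def test_every_scheme_present(self):
        schemes = {d.charge_scheme for d in enumerate_design_grid()}
        assert schemes == set(ChargeScheme)


class TestScriptedTrajectories:
    def test_free_translocate_ends_below_membrane(self, flat_spec, reference_design):
        traj = generate_np_trajectory(
            TrajectoryLabel(TranslocationClass.FREE_TRANSLOCATE),
            reference_design,
            flat_spec,
            n_frames=250,
            seed=0,
        )
        last = traj.frames[-1]
        core_z = float(last.positions[last.roles == 3][0, 2])
        lower_mean = last.phosphates(LOWER)[:, 2].mean()
        assert core_z < lower_mean - reference_design.core_diameter / 2.0

    def test_embedment_ends_inside_bilayer(self, flat_spec, reference_design):
        traj = generate_np_trajectory(
            TrajectoryLabel(TranslocationClass.EMBEDMENT),
            reference_design,
            flat_spec,
            n_frames=250,
            seed=0,
        )
        truth = traj.meta["truth"]
        last = traj.frames[-1]
        core_z = float(last.positions[last.roles == 3][0, 2])
        assert abs(core_z - truth["z_mid"]) < flat_spec.bilayer_thickness / 2.0

    def test_outer_wrap_never_opens_a_pore(self, flat_spec, reference_design):
        from membrane_gate.pores import make_grid, pore_area, pore_mask

        traj = generate_np_trajectory(
            TrajectoryLabel(TranslocationClass.OUTER_WRAP),
            reference_design,
            flat_spec,
            n_frames=100,
            seed=0,
        )
        for frame in traj.frames[::10]:
            area = pore_area(pore_mask(frame, make_grid(frame, 15)))
            assert area == 0.0

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ValueError, match="outer_wrap"):
            TrajectoryLabel(TranslocationClass.OUTER_WRAP, true_pore_radius=2.0)

    def test_deterministic_given_seed(self, flat_spec, reference_design):
        mk = lambda: generate_np_trajectory(
            TrajectoryLabel(TranslocationClass.EMBEDMENT),
            reference_design,
            flat_spec,
            n_frames=150,
            seed=5,
        )
        a, b = mk(), mk()
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa.positions, fb.positions)

    def test_too_few_frames_rejected(self, flat_spec, reference_design):
        with pytest.raises(ValueError):
            generate_np_trajectory(
                TrajectoryLabel(TranslocationClass.EMBEDMENT),
                reference_design,
                flat_spec,
                n_frames=5,
                seed=0,
            )


class TestUmbrellaSampling:
    def test_gaussian_limit_mean_and_sd(self):
        flat = PMFProfile(np.linspace(0, 5, 501), np.zeros(501))
        ds = generate_umbrella_samples(
            flat, spring_k=5000.0, n_per_window=10_000, seed=2
        )
        sigma = math.sqrt(ds.kt / 5000.0)
        w = ds.windows[25]
        assert abs(w.samples.mean() - w.center) < 3 * sigma / math.sqrt(len(w.samples))
        assert abs(w.samples.std() - sigma) / sigma < 0.05

    def test_window_centers_tile_the_domain(self):
        flat = PMFProfile(np.linspace(0, 5, 501), np.zeros(501))
        ds = generate_umbrella_samples(flat, window_spacing=0.1, n_per_window=100)
        centers = [w.center for w in ds.windows]
        assert len(centers) == 51  # 0 to 5 nm inclusive at 0.1 nm spacing
        assert centers[0] == 0.0 and abs(centers[-1] - 5.0) < 1e-9

    def test_harmonic_truth_gives_product_of_gaussians(self):
        # G(x) = a/2 (x - mu)^2 plus bias k/2 (x - x0)^2 is Gaussian with
        # variance kT / (a + k) -- closed form.
        a, k, T = 10.0, 400.0, 305.0
        x = np.linspace(0, 5, 2001)
        truth = PMFProfile(x, 0.5 * a * (x - 2.5) ** 2)
        ds = generate_umbrella_samples(
            truth, window_spacing=0.5, spring_k=k, n_per_window=50_000,
            temperature=T, seed=3,
        )
        w = ds.windows[6]  # center 3.0
        var = KB * T / (a + k)
        mean = (a * 2.5 + k * w.center) / (a + k)
        assert abs(w.samples.mean() - mean) < 4 * math.sqrt(var / len(w.samples))
        assert abs(w.samples.var() - var) / var < 0.05

    def test_samples_follow_analytic_biased_density(self):
        # KS test against the exact biased Boltzmann density per window.
        truth = PMFProfile(np.linspace(0, 5, 501), np.zeros(501))
        ds = generate_umbrella_samples(
            truth, spring_k=1000.0, n_per_window=10_000, seed=4
        )
        grid = np.linspace(0, 5, 20_001)
        for w in ds.windows[::10]:
            dens = biased_density(truth, w.center, w.spring_k, 305.0, grid)
            cdf_grid = np.concatenate(
                [[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))]
            )
            cdf_grid /= cdf_grid[-1]
            res = stats.kstest(w.samples, lambda v: np.interp(v, grid, cdf_grid))
            assert res.pvalue > 0.01

    def test_zero_samples_per_window_rejected(self):
        flat = PMFProfile(np.linspace(0, 5, 501), np.zeros(501))
        with pytest.raises(ValueError):
            generate_umbrella_samples(flat, n_per_window=0)

    def test_domain_narrower_than_window_spacing_rejected(self):
        tiny = PMFProfile(np.linspace(0, 0.05, 11), np.zeros(11))
        with pytest.raises(ValueError, match="narrower"):
            generate_umbrella_samples(tiny, window_spacing=0.1, n_per_window=100)
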