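# membrane-gate

Analysis tools for coarse-grained simulations of nanoparticles crossing
lipid bilayers. Given bead-resolution membrane snapshots and trajectories
(phosphate heads, tail carbons, nanoparticle core and ligand beads), the
package computes the four analyses that turn raw coordinates into the
quantities such studies report:

1. **Pore detection and kinetics** — the lateral box is meshed into an
   n × n grid of columns (default 30 × 30; 1.23 nm columns for a 37 nm
   box); a column containing no phosphate head is pore, total pore area is
   the summed column area, and nucleation/reseal times are extracted with a
   persistence filter.
2. **Membrane curvature** — per grid cell, a reference point (smoothed
   lower-leaflet phosphate position) and a reference normal **Z**ᵢ (from
   the local tail-carbon mean toward the phosphate mean); adjacent cells
   give the curvature angle θᵢ and reference distance Dᵢ, the radius of
   curvature Rᵢ = Dᵢ/tan θᵢ, and the principal-direction curvatures
   C_x, C_y along the grid axes with mean curvature C_m = (C_x + C_y)/2.
3. **Translocation phenotyping** — each NP trajectory is classified into
   outer wrap, free translocate, inner attach, or embedment from the
   terminal z offset, lipid-contact fraction, and wrap coverage, with
   entry-to-exit (or entry-to-arrest) durations.
4. **Pore-nucleation energetics** — umbrella-sampling windows are combined
   by WHAM into the lipid flip-flop PMF; the barrier ΔG_flip gives the
   pore-nucleation density ρ = exp(−ΔG_flip/kT)/A_lip, and ρ(C) across
   membrane curvatures is fitted to ρ₀·e^{κC}.

Because such production trajectories are rarely redistributable, a
first-class synthetic-data module (`membrane_gate.syngen`) generates
bead-resolution membranes (flat, bump, cylinder, sphere), scripted NP
trajectories of all four outcomes, and Boltzmann-exact umbrella samples —
all with analytic ground truth, so every estimator is validated by
parameter recovery. See `docs/methods.md` for the full model description.

## Worked example

```bash
membrane-gate run examples/demo_config.yaml
```

runs the full synthetic pipeline (every parameter in the config has a
documented default, so `outdir` and `seed` alone suffice). The curvature
stage builds noise-free
membrane cylinders of radii 2.5/5/7.5/10 nm and re-estimates their
curvature from bead positions (`demo_run/curvature_cylinders.tsv`):

```
radius_nm  true_curvature_nm^-1  median_C_x_nm^-1  n_valid_cells
2.5        0.4                   0.407309          720
5          0.2                   0.202313          720
7.5        0.133333              0.134783          720
10         0.1                   0.101181          720
```

i.e. the discretized estimator recovers the analytic curvatures 0.4, 0.2,
0.13 and 0.1 nm⁻¹ within ~2%. The translocation stage scripts a
4-outcome × 3-replicate panel and recovers 12/12 labels, with pore
nucleation at 25.2 ns and a 20 ns crossing for free translocation
(`demo_run/translocation.tsv`):

```
trajectory             label             nucleation_time_ns  duration_ns
outer_wrap_rep0        outer_wrap        NA                  NA
free_translocate_rep0  free_translocate  25.2                20
...
```

The energetics stage samples umbrella windows on flip-flop PMFs whose
barrier decreases with curvature, runs WHAM, and converts barriers to
nucleation densities (`demo_run/nucleation_model.tsv`):

```
curvature_nm^-1  dG_flip_kJ_mol  rho_nm^-2
0                81.8064         1.52425e-14
0.1              68.6322         2.75021e-12
0.2              58.6956         1.38417e-10
0.4              45.6043         2.41708e-08
```

ρ rises by six orders of magnitude from flat to the most curved membrane —
highly curved membranes nucleate pores far more readily — and the
exponential fit ρ₀·e^{κC} is reported in `demo_run/manifest.json`.

Library use mirrors the CLI:

```python
from membrane_gate import SynthSpec, generate_membrane, curvature_field

spec = SynthSpec(geometry="cylinder", lateral_extent=10.0,
                 lipid_spacing=0.25, noise_sd=0.0, seed=1,
                 geometry_params={"radius": 2.5})
field = curvature_field(generate_membrane(spec), n=(72, 10),
                        smoothing_radius=0.4, chart="cylindrical")
print(field.C_x[field.valid].mean())   # ~0.407 nm^-1
```

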