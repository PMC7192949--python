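# Demo pipeline configuration: synthetic 4-outcome panel, cylinder curvature
# series, pore-area demonstration, and the curvature -> nucleation-density
# chain, at desk scale.  Run with:
#
#   membrane-gate run examples/demo_config.yaml
#
outdir: demo_run
seed: 1
stages: [syngen, pores, curvature, translocation, energetics]

# membrane / trajectories
lateral_extent: 12.0      # nm
lipid_spacing: 0.8        # nm
bilayer_thickness: 4.0    # nm
noise_sd: 0.1             # nm
n_frames: 250
n_replicates: 3
core_diameter: 2.0        # nm

# analyses
grid_n: 15                # pore grid for the 12 nm panel (cell >= spacing)
curvature_grid_n: 72      # azimuthal cells on the unwrapped cylinders
smoothing_radius: 0.4     # nm, for the small-cylinder series

# energetics
temperature: 305.0        # K
A_lip: 0.64               # nm^2
window_spacing: 0.1       # nm
spring_k: 5000.0          # kJ/mol/nm^2
n_per_window: 2000
n_bootstrap: 20
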