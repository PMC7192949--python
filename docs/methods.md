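# Methods

`membrane-gate` re-implements, as a tested library, the analysis stage of a
coarse-grained study of nanoparticle passage through lipid bilayers: pore
detection on a lateral grid, discrete membrane-curvature estimation,
classification of translocation outcomes, and the free-energy chain that
links membrane curvature to pore-nucleation density. The raw molecular
dynamics that originally produced such trajectories is out of scope; a
synthetic-data module generates bead-resolution membranes and trajectories
with analytically known ground truth so every estimator can be validated
end to end.

Units are nm, ns, kJ/mol and K throughout; `k_B = 0.008314 kJ/mol/K`.

## Synthetic membranes and trajectories (`syngen`)

Each lipid is modeled as one phosphate head bead plus three tail-carbon
beads at 0.5 nm spacing along the local inward normal — the minimal
structure the analyses need (the head marks the surface, the tails define
the normal direction). Defaults: bilayer thickness 4.0 nm
(phosphate-to-phosphate), lipid spacing 0.8 nm on the surface lattice,
isotropic Gaussian bead noise of sd 0.1 nm emulating thermal roughness.
Geometries: flat patch, Gaussian bump/dimple (amplitude A, width w; apex
mean curvature A/w²), full cylinder (axis along y), and spherical cap. For
curved geometries the nominal radius is the radius of the *lower-leaflet
phosphate surface* — the surface the curvature estimator measures — so the
ground-truth curvature is exactly 1/R.

`punch_pore` removes whole lipids whose head lies laterally within a given
radius of a center, never moving surviving beads; it is the ground-truth
generator for the pore detector.

Nanoparticles are a core bead plus a shell of ligand-terminal beads
(3 terminals/nm² of core surface, shell 0.5 nm above the core surface).
Scripted trajectories follow piecewise-linear z paths at 0.08 nm/frame
approach speed (0.4 ns/frame, the production frame interval): touch, dwell,
then — for pore-forming outcomes — a transient pore (lipids removed at the
scripted nucleation frame, restored after passage; kept open for embedment,
where the particle occupies the columns). Pore transit speed scales
inversely with core diameter (drag-like, floored at 0.06 nm/frame so each
pre-arrest step exceeds the arrest epsilon), which reproduces the growth of
translocation duration with particle size. Final configurations: outer
wrap rests on the upper leaflet inside a 0.5 nm dimple; free translocate
ends 3 nm clear below; inner attach ends with its top 0.7 nm buried in the
lower leaflet; embedment halts at the midplane. Ground truth (nucleation,
entry/exit/arrest times, duration) is computed from the noise-free path
against the same thresholds the classifier documents, and stored in
`Trajectory.meta["truth"]`.

What the generator does **not** emulate: lipid diffusion and exchange,
membrane undulation spectra, solvent and electrostatics, stochastic pore
nucleation (timing is scripted), and pore reseal driven by ion flux.
Passing tests therefore demonstrate the correctness of the *estimators*
under controlled geometry and noise, not the physics of real membranes.

Umbrella datasets are drawn by inverse-CDF sampling of the exact Boltzmann
density of a prescribed truth PMF plus harmonic bias, on a per-window grid
of step sigma/20 with linear interpolation — so samples follow the analytic
biased density to grid precision (verified by Kolmogorov–Smirnov tests).
Window centers tile the truth domain: 0.1 nm spacing over 5 nm gives the
production 51 windows.

The design grid enumerates 6 charge-size scaling schemes (Const, Half,
0.25D, 0.5D, 0.86D, D²; anchored to the 99 e / 2 nm reference) × 3 core
sizes × 2 ligand chemistries = 36 designs. The three non-reference core
sizes default to 4, 6 and 8 nm — the study design space only shows them
graphically, so the exact set is a documented assumption of this package.

## Pore detection (`pores`)

The lateral box is meshed into n × n half-open columns (default n = 30; a
37 nm box gives 1.23 nm columns). A column with no phosphate bead from
either leaflet is pore; the pore area is the summed column area. Counting
both leaflets in one column reflects that a column is membrane-free only
when neither leaflet covers it. Binning wraps periodically; a bead exactly
on a boundary belongs to the higher-index cell.

Event detection needs a persistence filter because single empty columns
occur by thermal fluctuation: nucleation is the first time the area holds
at or above `min_area` (default one column) for `min_persistence` (default
3) consecutive frames; reseal is the first later time it holds below for as
long. For a punched circular pore of radius r with lipid spacing at most
half the column edge, the detected area is within the boundary-cell bound
`perimeter × cell × √2` of πr².

## Curvature (`curvature`)

Per cell, the *reference point* is the mean position of lower-leaflet
phosphates within a smoothing radius (default 3 nm) of the cell center.
The *reference normal* is the unit vector from the mean tail-carbon
position toward the mean phosphate position of the **same** lower-leaflet
lipids. The per-lipid selection matters: selecting tail beads by their own
lateral position is blind to tilt, because on any uniformly tilted patch
the disc means of the head and tail layers sit vertically above one
another; with per-lipid means the two points describe the same effective
patch of surface and lattice-edge effects of the hard cutoff cancel. On a
noise-free 2.5 nm cylinder this is the difference between a 15% curvature
bias and agreement within 2%.

For neighbor cells along a grid axis, theta is the angle between their
normals, D the Euclidean distance between their reference points, and the
curvature magnitude tan(theta)/D (from R = D/tan(theta)). D is the 3D
chord, not its lateral projection: the projection underestimates D on
tilted surface and biases 1/R upward by 1/cos(tilt). Central differences
over (i−1, i+1) are used where both neighbors are valid, one-sided pairs at
open edges. Angles below 1e-4 rad count as flat (C = 0, avoiding the
tan→0/0 blow-up); angles above 1 rad mark the cell unresolvable. The sign
is taken from the component of the normal change along the walking
direction: positive where the surface bulges toward the upper
(extracellular) side, so a bump has C_m > 0 at the apex and its mirror
dimple C_m < 0. C_x and C_y follow the two grid axes (box axes, not
locally rotated principal directions); C_m = (C_x + C_y)/2 exactly.

Closed geometries are analyzed in an unwrapped chart with axes along the
azimuthal arc length and the cylinder axis, estimated from the data (axis =
centroid of the lower-leaflet phosphates in the cross-section plane, unwrap
radius = their mean distance from it). Grid resolution must resolve the
radius: the leading discretization error of the two-cell stencil is
~(2Δφ)²/3 with Δφ the azimuthal step per cell, so the cylinder analyses use
72 azimuthal cells (error ≲ 2% at R = 2.5 nm) and a 0.4 nm smoothing radius
(ref-point shrinkage toward the axis ≲ 0.7%). Spherical caps are analyzed
in the planar chart, which is accurate while cells stay small relative to
R·cos(tilt).

Exclusions: lipids binned into pore-mask cells, and lipids whose phosphate
deviates more than 1.5 nm from the provisional local reference surface
("out of regular conformation"), are discarded from both means; cells whose
centers lie in the pore mask are flagged invalid. `vertex_curvature`
returns the valid cell with maximal C_m within 1.5 NP radii of the particle
axis (ties: nearest to the axis, then cell index order).

## Translocation (`translocation`)

Per frame: `z_offset` is the NP core centroid z minus the local bilayer
midplane (mean of the two leaflets' phosphate surfaces within 1.5 NP radii
laterally; the disc widens by doubling and falls back to global means when
a pore empties it). `contact_fraction` is the fraction of ligand terminals
within 0.6 nm (one CG bead diameter) of any lipid bead.  `wrap_fraction`
sends 256 Fibonacci-distributed directions from the NP centroid and counts
the fraction whose angularly nearest lipid head lies within NP radius +
1 nm.

The verdict uses medians over the final 10% of frames, with thresholds in
units of the membrane half-thickness t/2: z_offset > +t/2 → outer wrap;
|z_offset| ≤ t/2 → embedment (the boundary is assigned inward); below
−t/2, contact_fraction ≥ 0.05 separates inner attach from free
translocate ("roams freely"). A trajectory that never contacts the
membrane stays outer wrap with a `no_entry` flag, preserving the four-way
taxonomy. Duration runs from membrane entry (first z_offset < +t/2) to
exit (z_offset < −t/2) for free translocate, and to motion arrest for
inner attach and embedment — arrest meaning the z_offset range stays below
0.05 nm over 25 frames (10 ns). These kinetic thresholds are conventions
of this package; the arrest criterion assumes a low-noise or smoothed
offset series and reports no arrest when thermal noise keeps the range
above epsilon.

## Energetics (`energetics`)

WHAM combines the binned biased histograms self-consistently:
p_j ∝ n_j / Σ_i N_i exp[(f_i − w_i(x_j))/k_BT], with the offsets f_i
iterated to a 1e-6 kJ/mol tolerance. Because plain fixed-point iteration
converges geometrically with rate near 1 when many windows overlap, the
offsets are first driven near the optimum of the equivalent convex
negative log-likelihood (L-BFGS with analytic gradient) and then polished
by the self-consistent loop. Bin width defaults to half the window spacing
*capped at half the narrowest biased sd* sqrt(k_BT/k): with the production
5000 kJ/mol/nm² spring the biased sd (0.023 nm) is narrower than half the
0.1 nm spacing, and bins that cannot resolve it bias the profile by the
within-bin variation of the biased density. Non-overlapping adjacent
windows raise an error naming the gap. Pointwise errors come from 50
bootstrap resamples of the per-window sample lists, re-anchored at the main
profile's minimum bin.

The flip-flop barrier dG_flip is the maximum of G along the path from the
minimum inside a start region (the outer-leaflet head-group region) to the
bilayer midplane; a profile that rises monotonically to its own endpoint is
flagged `at_edge`. The pore-nucleation density is the exact identity
ρ = exp(−dG_flip/k_BT)/A_lip with T = 305 K and A_lip = 0.64 nm² by
default (a documented assumption — the area per lipid is configurable and
was never printed by the source analyses). ρ(C) is fitted log-linearly,
ln ρ = ln ρ0 + κC, which is exact for barriers linear in curvature.

The synthetic curvature series uses truth barriers dG(C) = 80 − 100·C
kJ/mol over C ∈ {0, 0.1, 0.13, 0.2, 0.4} nm⁻¹ — a decreasing barrier whose
implied ρ(C) is an exact single exponential, matching the functional form
the fit assumes. Statistical validation is parameter recovery (the source
figures are graphical only): flat truths recover flat within 0.2 kJ/mol
with well-overlapping windows (spring 100 kJ/mol/nm², 5×10⁴ samples per
window), a harmonic truth's quadratic coefficient is recovered within 10%,
and the 80 kJ/mol barrier is recovered within twice the bootstrap error at
the production settings. At the production spring constant adjacent
windows sit 4.4 biased-sd apart, so the profile accumulates a random-walk
drift of a few kJ/mol across 51 windows at 10⁴ independent samples/window;
the bootstrap error bars capture this, and the original analyses' ~100 ns
windows correspond to far larger effective sample counts.

## Pipeline and problem sizes

`run_pipeline` executes syngen → pores → curvature → translocation →
energetics from a YAML config and writes delimited tables plus a JSON
manifest (versions, parameters, seeds, timings); identical config and seed
reproduce byte-identical tables. The shipped defaults run desk-scale
problems chosen to exercise every code path at comfortable statistics:
12–20 nm membrane patches (a few thousand beads), 250-frame trajectories,
2×10³–10⁴ umbrella samples per window. The production-scale values (37 nm
patches with 4128 lipids, 1.2 µs trajectories) remain the documented
defaults of the analysis parameters themselves (grid 30, smoothing 3 nm,
spacing 0.1 nm, spring 5000 kJ/mol/nm², T 305 K).

## Known limitations

- Replicate-to-replicate stochasticity of real translocation outcomes is
  not modeled; the classifier is deterministic per trajectory, so mixed
  triplicates can only arise from genuinely different inputs.
- Reseal kinetics on synthetic data are scripted, not emergent; the
  observation that larger pores reseal faster involves ion dynamics outside
  this package's scope.
- The curvature estimator assumes a locally single-valued surface in its
  chart; strongly overhanging membranes would need a different chart.
- XYZ trajectories do not carry residue identity; curvature normals on
  XYZ-read frames fall back to a nearest-tail-triplet heuristic (GRO and
  in-memory frames carry exact lipid grouping).
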