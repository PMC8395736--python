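# Methods

## System and units

The package analyzes coarse-grained (CG) bead models of proteins
adsorbing onto a ligand-capped gold nanoparticle. Internally all
lengths are nm, times ps, masses amu and energies kJ/mol (Gromacs
conventions); Å appears only at the PDB boundary. k_B =
0.0083145 kJ/mol·K, and the default temperature is 320 K. Beads carry
a role — `backbone`, `sidechain`, `ligand` or `core` — plus a
molecule id, a 1-based residue id, a residue type (1-letter code for
protein beads), a mass (72 amu by default, the standard 4-to-1 CG
mapping weight) and a `fixed` flag honored by the synthetic dynamics.

## Nanoparticle construction

The gold core is the set of fcc lattice points (a = 0.408 nm, bulk
gold) bounded by six {100} planes at distance `cut_100` and eight
{111} planes at `cut_111` from the carve center — a truncated
octahedron. Two non-obvious choices:

- **Carve centering.** Small clusters need not be centered on an atom:
  the carve center may sit on an atom, an octahedral or tetrahedral
  interstitial hole, or a bridge site, and the realizable cluster
  sizes differ between centerings. An atom-centered carve cannot
  produce a 314-atom cluster near 2.2 nm (309 is the closest size);
  the octahedral-hole centering produces exactly 314 atoms with a
  2.197 nm extent at cuts (1.02, 0.8245) nm. That carve is the default.
- **Calibration.** Because the carved set only changes when a cut
  crosses one of the discrete plane distances realized by lattice
  points, `calibrate_truncation` enumerates those thresholds exactly
  rather than scanning a continuous grid; every distinct cluster in
  range is visited once per centering and ranked by distance of its
  max pairwise extent from the target diameter.

Surface atoms are those with fewer than 12 neighbors within the first
fcc shell (a/√2, 10% tolerance). Ligands are grafted on surface atoms
chosen by seeded farthest-point sampling (approximately uniform
coverage; reproducible bit-for-bit per seed) and laid out as straight
radial chains at the 0.47 nm equilibrium bond length. The MUS chain
maps the sulfur to one N0 bead, the undecane chain to three C1 beads
(4:1) and the terminal sulfonate to a charged bead labeled Qa; gold
and sulfur map 1:1 and are flagged immobile. Bonded parameters
(k_bond = 1250 kJ/mol nm², harmonic-cosine angle k = 25 kJ/mol,
θ₀ = 180°) are emitted in a plain-text topology; no energies are
evaluated here. The ligand count is a free parameter (default 60):
none of the analyses depend on its exact value, only the capped-NP
SASA scales with it.

## Synthetic data

The generators exist so every analysis stage can be validated against
known ground truth without molecular dynamics.

- **Decoy proteins** are compact self-avoiding globules grown as a
  confined random walk: one backbone bead per residue (0.47 nm steps)
  plus one sidechain bead except for glycine, minimum bead separation
  0.9 × 0.47 nm, types drawn from a configurable composition (uniform
  by default). They have realistic size and packing density but no
  secondary structure, no native contacts and no chemistry — tests
  passing on decoys demonstrate correctness of the geometry pipeline,
  not biological realism.
- **Adsorption trajectories** are *scripted* (kinematic), not
  integrated: phase 1 is a reflected random walk of the rigid protein
  in a far shell, phase 2 holds the center of mass at a contact
  standoff with rotational jitter against the ligand tips, phase 3
  fixes the orientation so one surface patch faces the particle at a
  bound standoff. The bound standoff is solved by bisection on the
  actual geometry so the closest backbone bead sits 0.3 nm from the
  nearest particle bead (inside the 0.45 nm contact cutoff), and the
  final frame is the exact noiseless pose; the generator reports the
  contact patch of that frame (computed by brute force, independently
  of the analysis code) as ground truth. Per-bead thermal jitter
  (default 0.02 nm) is added in all other frames so fluctuation
  analyses see realistic noise. Scripting makes the phase breakpoints
  and the bound patch exact test oracles; the price is that no real
  kinetics, forces or induced fit are represented. A protein is moved
  as a rigid body, so the radius of gyration genuinely does not change
  on binding in synthetic runs.
- **Umbrella windows** are Metropolis chains sampling
  exp(−[U(x) + k/2 (x−c)²]/k_BT) for a known potential (harmonic,
  quartic double-well, or Morse-like well), one vectorized chain per
  window, proposal width auto-tuned to 30–60% acceptance during
  burn-in (2000 steps), thinned ×5, reflected at the domain edges.
  Acceptance rates are recorded per window.

## Analyses

- **Binding site / contacts.** A residue is in contact when its
  backbone bead lies within 0.45 nm (minimum-image) of *any*
  nanoparticle bead, ligand or core. The binding site is the contact
  set of the last frame, where binding is stable; per-residue contact
  probability is the fraction of frames in contact; binding-site
  composition is reported as percent of site residues per type and
  aggregated into classes. The default classification — hydrophobic
  {A,F,I,L,M,V,W,Y}, charged {D,E,K,R}, polar {S,T,N,Q}, others
  {G,P,C,H} — reproduces published CG contact tables to within
  per-type rounding (9 of 16 class cells exactly, the rest within
  ±2%) and is configurable.
- **Approach trace and three-step detection.** The adsorption
  observable is the distance of the protein center of mass from the
  particle center per frame. Its three plateaus (diffusive, weak
  contact, bound) are segmented by an exact dynamic program minimizing
  the total squared error of a 3-segment piecewise-constant fit over
  both breakpoints (prefix sums; ties broken to the lexicographically
  smallest pair). A fit whose adjacent segment means coincide within
  1e-9 of the series scale is flagged degenerate rather than reported
  as three phases.
- **RMSF.** Over the last-N-frame window (default 100), each frame's
  selection is Kabsch-superposed onto the window-mean structure (the
  mean is computed after aligning to the last frame and refined once);
  the RMSF is the root-mean-square deviation of each backbone bead
  about its mean. Superposition removes rigid translation/rotation
  exactly; with few beads it also absorbs a noticeable share of a
  single bead's motion, which vanishes as the selection grows.
- **Radius of gyration** is the standard mass-weighted second moment.

## SASA and capacity

Shrake–Rupley on beads: each bead's sphere is inflated by the probe
radius (0.21 nm, the CG water bead), test points are a deterministic
Fibonacci spiral (default 960; the 960→3840 difference is <0.5% on a
globule), and a point is buried if inside any neighbor's inflated
sphere. Bead radii default to 0.235 nm (half the 0.47 nm CG bead
diameter) per role-configurable table. Neighbor search uses cell lists
with edge equal to the maximum inflated diameter; a brute-force path
is retained and tested for exact agreement. For the bound complex,
SASA is computed over the protein beads only while **all** beads
occlude, so ΔSASA = SASA_free − SASA_complex is the protein surface
buried on binding; negative ΔSASA is allowed but flagged.

Capacity: N_max = SASA(capped NP)/ΔSASA with floor rounding (a
fractional protein cannot adsorb; nearest/ceiling available for
sensitivity checks). The geometric comparison methods are labeled
presets of two families — shell-area f·4(R_NP+R_p)²/R_p² and
core-area f·4R_NP²/R_p², with R_NP defaulting to 2.15 nm (half the
ligand-inclusive 4.3 nm diameter) — shipped as order-of-magnitude
reconstructions of the cited literature estimators, evaluated at both
published protein radii. In the R_p → ∞ limit the core-area family
vanishes while the shell-area family tends to 4f; both behaviors are
exercised in tests.

## WHAM

Standard self-consistent iteration on histogrammed windows: unbiased
bin probabilities from bias-weighted counts, per-window shifts from
the partition sums, iterated until the largest shift change is below
1e-6 kJ/mol (max 1e5 iterations), all in log-space for stability.
Shifts are gauged to the first window; the PMF is −k_BT ln p shifted
so its minimum is zero; bins no window populated are NaN and excluded
from the shift. Windows sharing no populated bin with any other window
abort with a diagnostic rather than converging to garbage. Binding
strength is the mean free energy over a stated unbound plateau minus
the minimum, reported negative in kcal/mol (÷4.184); per-site
strengths aggregate as mean ± sample sd (sd 0 by convention for a
single site). Errors come from a window-resampling bootstrap;
autocorrelation-based estimates are out of scope.

## Pipeline determinism and problem sizes

`run_pipeline` derives every stage seed from the config seed, so a
fixed seed yields byte-identical reports. The demo sizes — a
150-residue decoy, 60 ligands, 200 frames (50/30/120), 960 SASA
points, 16 windows × 2000 samples — run in a few seconds on one CPU
and were chosen as the smallest sizes at which every statistical check
in the test suite is comfortably stable. The umbrella bias constant,
when not set, is derived from the window spacing as k = 4k_BT/Δc² so
each window's thermal width is half the spacing, guaranteeing
histogram overlap at any window count.

## Known limitations

- No force fields, no real dynamics: all trajectories are scripted or
  user-supplied. Energetic statements come only from the umbrella/WHAM
  path on explicitly specified potentials.
- The PDB/GRO writers target the package's own bead models (role-coded
  atom names); arbitrary external structures need the XYZ + sidecar
  route for full metadata.
- Geometric capacity presets are reconstructions; their absolute
  values should be quoted with the formula, not attributed to the
  original references.
- Binary trajectory formats (XTC/TRR/DCD) are not read; convert
  externally.
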