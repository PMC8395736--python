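# corona-lab

Analysis toolkit for protein–nanoparticle corona formation with
coarse-grained (Martini-style) bead models. When a gold nanoparticle
(AuNP) capped with hydrophobic 11-mercapto-1-undecanesulfonate (MUS)
ligands enters a protein solution, blood proteins such as hemoglobin,
serum albumin, α1-antiproteinase and complement C3 adsorb onto it and
form a "corona" that controls the particle's biological fate. This
package implements the full desk-side analysis chain for that system:

- **`nanobuilder`** — carves the fcc gold core as a truncated
  octahedron ({100} and {111} cutting planes) and grafts MUS chains
  (one N0 sulfur bead, three C1 aliphatic beads, a terminal sulfonate
  bead; k_bond = 1250 kJ/mol nm², k_angle = 25 kJ/mol, θ₀ = 180°).
  A calibration search reproduces the 314-atom, 2.2 nm gold core.
- **`trajectory`** — labeled bead topologies and multi-frame
  trajectories (multi-MODEL PDB, concatenated GRO, XYZ + CSV sidecar),
  minimum-image geometry, centers of mass.
- **`synthetic`** — decoy protein globules, scripted three-phase
  adsorption trajectories (diffusion → first ligand contact → stable
  binding) with exact ground truth, and Metropolis umbrella-window
  sampling from known 1D potentials.
- **`analysis`** — binding sites (backbone beads within 0.45 nm of any
  NP bead, last stable frame), per-residue contact probabilities,
  physico-chemical class aggregation, exact three-segment change-point
  detection of the approach trace, Kabsch-superposed RMSF, radius of
  gyration.
- **`sasa`** — Shrake–Rupley solvent-accessible surface area for bead
  models (0.21 nm water-bead probe, deterministic Fibonacci test
  points).
- **`capacity`** — maximum adsorption capacity. The surface-based
  estimator is

      N_max = SASA_ligands-NP / ΔSASA,  ΔSASA = SASA_initial − SASA_final

  the capped-particle surface divided by the protein surface buried by
  one adsorption event, with floor rounding; three geometric
  literature estimators (shell-area and core-area families) ship as
  presets for comparison.
- **`pmf`** — WHAM reconstruction of the potential of mean force from
  umbrella windows and binding-strength extraction (kcal/mol,
  negative for binding), with mean ± sd aggregation over binding sites.
- **`pipeline` / `cli`** — an end-to-end orchestrated demo
  (`corona-lab run-all`), deterministic per seed.

## Worked example

The numbered scripts under `analysis/` run the whole study on
synthetic inputs and write tables under `results/`:

```bash
python analysis/01_build_nanoparticle.py --seed 1
python analysis/02_simulate_adsorption.py --seed 1
python analysis/03_contact_analysis.py
python analysis/04_conformational_analysis.py
python analysis/05_sasa_capacity.py
python analysis/06_umbrella_pmf.py --seed 1
```

Representative output:

```
calibrated carve: octahedral-centered, cuts (1.020, 0.824) nm
  -> 314 gold atoms, extent 2.197 nm, 174 surface sites
  capped with 60 MUS chains; ligand-shell radius 3.45 nm
...
three-step segmentation: breakpoints (50, 80) (scripted truth (50, 80))
...
SASA free protein:    157.01 nm^2
Delta SASA:             4.79 nm^2 (buried on binding)
SASA capped NP:       311.99 nm^2
surface-based capacity for the decoy: N_max = 65 (raw 65.13)
...
binding strength: -5.92 kcal/mol (ground truth -5.98)
```

The carve calibration recovers the published 314-atom gold core from
the 2.2 nm extent alone; the change-point detector recovers the
scripted adsorption phases exactly; the WHAM profile returns the known
25 kJ/mol well depth to within 1%. The decoy's N_max is large because
the small synthetic contact patch buries little surface — with real
proteins ΔSASA is tens of nm² and single-digit capacities result.

Or run everything in one step:

```bash
corona-lab run-all --seed 1 --out corona_run
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data design, the
numerical choices and the known limitations.
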