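"""Physical constants and unit conventions.

Internal units follow Gromacs conventions throughout the package:
lengths in nm, times in ps, masses in amu, energies in kJ/mol.
Angstrom appears only at I/O boundaries (PDB records, config files
that declare Å units).
"""

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083145

#: kJ per kcal (thermochemical calorie)
KJ_PER_KCAL = 4.184

#: Default Martini-style bead mass, amu
DEFAULT_BEAD_MASS = 72.0

#: Standard coarse-grained bond length, nm
CG_BOND_LENGTH = 0.47

#: Default bead radius for SASA (half the standard CG bead diameter), nm
DEFAULT_BEAD_RADIUS = 0.235

#: Water-bead probe radius for SASA, nm
WATER_PROBE_RADIUS = 0.21

#: Contact cutoff between protein backbone beads and nanoparticle beads, nm
CONTACT_CUTOFF = 0.45

#: Bulk fcc gold lattice constant, nm
GOLD_LATTICE_CONSTANT = 0.408

NM_PER_ANGSTROM = 0.1
ANGSTROM_PER_NM = 10.0
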