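"""Build coarse-grained MUS-capped gold nanoparticles.

The gold core is carved from a face-centered-cubic lattice as a
truncated octahedron: the atom set bounded by the six {100} planes at
distance ``cut_100`` from the carve center and the eight {111} planes
at ``cut_111``. Small fcc clusters need not be centered on an atom
site — the carve center may sit on an atom, an octahedral or
tetrahedral interstitial hole, or a bridge site, and the achievable
magic numbers differ between centerings. The 314-atom, 2.2 nm core
used as the default here requires the octahedral-hole centering.

Ligands are grafted on surface atoms (coordination number below the
fcc bulk value of 12) using farthest-point sampling so the capping
layer is approximately uniform, and each chain is laid out radially
at the equilibrium bond length. The MUS chain maps to one N0 bead for
the sulfur, three C1 beads for the undecane chain (4:1 mapping) and a
terminal charged bead for the sulfonate group; gold and sulfur map 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .constants import CG_BOND_LENGTH, GOLD_LATTICE_CONSTANT
from .trajectory import Frame, Topology, Trajectory, write_trajectory

#: carve-center offsets in units of the lattice constant
CARVE_CENTERS = {
    "atom": (0.0, 0.0, 0.0),
    "octahedral": (0.5, 0.0, 0.0),
    "tetrahedral": (0.25, 0.25, 0.25),
    "bridge": (0.25, 0.25, 0.0),
}

_P111 = np.array(
    [[1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=float
).T / np.sqrt(3.0)


class DegenerateGeometryError(ValueError):
    """Truncation cuts produced an empty solid."""


class CapacityError(ValueError):
    """More ligands requested than available surface sites."""


@dataclass(frozen=True)
class LatticeSpec:
    lattice_constant: float = GOLD_LATTICE_CONSTANT  # nm
    element_label: str = "Au"

    def __post_init__(self):
        if self.lattice_constant <= 0:
            raise ValueError("lattice_constant must be positive")


@dataclass(frozen=True)
class TruncationSpec:
    """Half-distances of the {100} and {111} cutting planes, nm."""

    cut_100: float
    cut_111: float
    center: str = "octahedral"

    def __post_init__(self):
        if self.cut_100 <= 0 or self.cut_111 <= 0:
            raise ValueError("truncation cuts must be positive")
        if self.center not in CARVE_CENTERS:
            raise ValueError(
                f"unknown carve center {self.center!r}; one of {sorted(CARVE_CENTERS)}"
            )


#: calibrated carve reproducing the 314-atom / 2.2 nm gold core
DEFAULT_TRUNCATION = TruncationSpec(cut_100=1.02, cut_111=0.828, center="octahedral")


@dataclass
class CoreModel:
    positions: np.ndarray  # (n, 3) nm, centered at centroid
    diameter: float  # max pairwise distance, nm
    n_atoms: int
    lattice: LatticeSpec = field(default_factory=LatticeSpec)

    def recompute_diameter(self) -> float:
        if self.n_atoms < 2:
            return 0.0
        return float(pdist(self.positions).max())


@dataclass(frozen=True)
class LigandTopology:
    """Bonded parameters and bead labels for one grafted MUS chain.

    The anchor is a surface gold atom (C5 bead); the chain beads listed
    here are the sulfur bead, three aliphatic beads and the terminal
    sulfonate bead.
    """

    bead_labels: tuple[str, ...] = ("N0", "C1", "C1", "C1", "Qa")
    anchor_label: str = "C5"
    bond_k: float = 1250.0  # kJ/mol nm^2
    angle_k: float = 25.0  # kJ/mol
    angle_theta0: float = 180.0  # degrees
    equilibrium_bond_length: float = CG_BOND_LENGTH  # nm

    @property
    def beads_per_ligand(self) -> int:
        return len(self.bead_labels)

    def __post_init__(self):
        if self.equilibrium_bond_length <= 0:
            raise ValueError("equilibrium bond length must be positive")


@dataclass
class CappedNPModel:
    core: CoreModel
    graft_sites: np.ndarray  # indices into core.positions
    ligand_positions: np.ndarray  # (n_ligands, beads_per_ligand, 3)
    ligand_topology: LigandTopology

    @property
    def n_ligands(self) -> int:
        return len(self.graft_sites)

    def all_positions(self) -> np.ndarray:
        """Core atoms followed by ligand beads, ligand-by-ligand."""
        if self.n_ligands == 0:
            return self.core.positions.copy()
        return np.vstack([self.core.positions, self.ligand_positions.reshape(-1, 3)])

    def max_radius(self) -> float:
        return float(np.linalg.norm(self.all_positions(), axis=1).max())

    def to_topology_frame(
        self, box: float | np.ndarray = 20.0, molecule_id: int = 1, time: float = 0.0
    ) -> tuple[Topology, Frame]:
        """Express the NP as a labeled bead structure.

        Core atoms and ligand sulfur beads carry ``fixed=True`` (they are
        held immobile, matching the rigid-core convention); residue ids
        number the core as residue 1 and each ligand as its own residue.
        """
        n_core = self.core.n_atoms
        nb = self.ligand_topology.beads_per_ligand
        roles = ["core"] * n_core + ["ligand"] * (self.n_ligands * nb)
        res_types = ["AUC"] * n_core + ["MUS"] * (self.n_ligands * nb)
        res_ids = [1] * n_core
        fixed = [True] * n_core
        for il in range(self.n_ligands):
            res_ids.extend([il + 2] * nb)
            fixed.extend([True] + [False] * (nb - 1))  # sulfur anchor bead fixed
        n = len(roles)
        top = Topology(
            molecule_id=[molecule_id] * n,
            residue_id=res_ids,
            residue_type=res_types,
            role=roles,
            fixed=fixed,
        )
        box = np.broadcast_to(np.asarray(box, float), (3,)).copy()
        pos = self.all_positions() + box / 2.0  # NP centered in the box
        return top, Frame(time=time, positions=pos, box=box)


def _fcc_points(lattice: LatticeSpec, center: str, reach: float) -> np.ndarray:
    """All fcc lattice points within ``reach`` of the carve center."""
    a = lattice.lattice_constant
    off = np.array(CARVE_CENTERS[center]) * a
    m = int(np.ceil(2.0 * reach / a)) + 2
    idx = np.array(
        [(i, j, k) for i, j, k in product(range(-m, m + 1), repeat=3) if (i + j + k) % 2 == 0]
    )
    pts = idx * (a / 2.0) - off
    return pts[np.abs(pts).max(axis=1) <= reach + a]


def carve_core(
    lattice: LatticeSpec = LatticeSpec(),
    truncation: TruncationSpec = DEFAULT_TRUNCATION,
) -> CoreModel:
    """Carve the truncated-octahedron cluster out of the fcc lattice.

    Keeps every lattice point whose distance to all six {100} planes is
    at most ``cut_100`` and to all eight {111} planes at most ``cut_111``;
    the result is re-centered at its centroid.
    """
    reach = max(truncation.cut_100, truncation.cut_111 * np.sqrt(3.0))
    pts = _fcc_points(lattice, truncation.center, reach)
    eps = 1e-9
    keep = (np.abs(pts).max(axis=1) <= truncation.cut_100 + eps) & (
        np.abs(pts @ _P111).max(axis=1) <= truncation.cut_111 + eps
    )
    sel = pts[keep]
    if len(sel) == 0:
        raise DegenerateGeometryError(
            f"cuts ({truncation.cut_100}, {truncation.cut_111}) nm leave no atoms"
        )
    sel = sel - sel.mean(axis=0)
    order = np.lexsort((sel[:, 0], sel[:, 1], sel[:, 2]))
    sel = sel[order]
    diameter = float(pdist(sel).max()) if len(sel) > 1 else 0.0
    return CoreModel(positions=sel, diameter=diameter, n_atoms=len(sel), lattice=lattice)


def calibrate_truncation(
    target_diameter: float = 2.2,
    lattice: LatticeSpec = LatticeSpec(),
    cut_range: tuple[float, float] = (0.5, 1.4),
    centers: tuple[str, ...] = ("atom", "octahedral", "tetrahedral", "bridge"),
    count_band: tuple[float, float] = (0.2, 3.0),
) -> list[tuple[TruncationSpec, int, float]]:
    """Search truncation cuts whose carved cluster best matches a diameter.

    The carved set only changes when a cut crosses one of the discrete
    plane distances realized by lattice points, so the search iterates
    over those thresholds exactly (every distinct cluster in range is
    visited once per centering). Clusters whose atom count is wildly
    incompatible with the target diameter (outside ``count_band`` times
    the solid-sphere estimate) are skipped before the costly diameter
    evaluation. Returns ``(spec, n_atoms, diameter)`` sorted by
    ``|diameter - target|`` then atom count.
    """
    a = lattice.lattice_constant
    n_est = 4.0 / a**3 * (np.pi / 6.0) * target_diameter**3
    n_lo, n_hi = count_band[0] * n_est, count_band[1] * n_est
    results = []
    for center in centers:
        pts = _fcc_points(lattice, center, reach=cut_range[1] * np.sqrt(3.0))
        m100 = np.abs(pts).max(axis=1)
        m111 = np.abs(pts @ _P111).max(axis=1)
        t100 = np.unique(np.round(m100, 9))
        t111 = np.unique(np.round(m111, 9))
        t100 = t100[(t100 >= cut_range[0]) & (t100 <= cut_range[1])]
        t111 = t111[(t111 >= cut_range[0]) & (t111 <= cut_range[1])]
        for c100 in t100:
            sel1 = m100 <= c100 + 1e-9
            prev_n = -1
            for c111 in t111:
                keep = sel1 & (m111 <= c111 + 1e-9)
                n = int(keep.sum())
                if n == prev_n or n < 2:
                    continue  # same cluster as the previous threshold
                prev_n = n
                if not n_lo <= n <= n_hi:
                    continue
                dia = float(pdist(pts[keep]).max())
                results.append(
                    (TruncationSpec(float(c100), float(c111), center), n, dia)
                )
    results.sort(key=lambda t: (abs(t[2] - target_diameter), t[1]))
    return results


def find_surface_sites(
    core: CoreModel, shell_tolerance: float = 0.1
) -> np.ndarray:
    """Indices of core atoms with fewer than 12 first-shell neighbors.

    The first shell of an fcc lattice lies at a/sqrt(2); any atom whose
    neighbor count within that distance (plus a fractional tolerance)
    falls below the bulk coordination of 12 is a surface atom. Order is
    deterministic (ascending index).
    """
    if core.n_atoms == 0:
        raise ValueError("empty core")
    if core.n_atoms == 1:
        return np.array([0])
    cutoff = core.lattice.lattice_constant / np.sqrt(2.0) * (1.0 + shell_tolerance)
    d = cdist(core.positions, core.positions)
    coordination = (d < cutoff).sum(axis=1) - 1
    return np.where(coordination < 12)[0]


def _farthest_point_sample(points: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Greedy farthest-point subset of ``points``; the start is seeded."""
    rng = np.random.default_rng(seed)
    n = len(points)
    chosen = [int(rng.integers(n))]
    mind = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, np.linalg.norm(points - points[nxt], axis=1))
    return np.array(chosen)


def graft_ligands(
    core: CoreModel,
    n_ligands: int = 60,
    topology: LigandTopology = LigandTopology(),
    seed: int = 0,
) -> CappedNPModel:
    """Attach ligand chains to well-spread surface atoms.

    Graft sites come from farthest-point sampling over the surface atoms
    (seeded, hence reproducible); each chain extends radially outward
    from its anchor in steps of the equilibrium bond length.
    """
    surface = find_surface_sites(core)
    if n_ligands > len(surface):
        raise CapacityError(
            f"{n_ligands} ligands requested but only {len(surface)} surface sites"
        )
    if n_ligands == 0:
        return CappedNPModel(
            core=core,
            graft_sites=np.array([], dtype=int),
            ligand_positions=np.zeros((0, topology.beads_per_ligand, 3)),
            ligand_topology=topology,
        )
    pick = _farthest_point_sample(core.positions[surface], n_ligands, seed)
    sites = surface[np.sort(pick)]
    anchors = core.positions[sites]
    norms = np.linalg.norm(anchors, axis=1)
    norms[norms == 0] = 1.0
    directions = anchors / norms[:, None]
    steps = np.arange(1, topology.beads_per_ligand + 1)
    lig = (
        anchors[:, None, :]
        + directions[:, None, :] * (steps * topology.equilibrium_bond_length)[None, :, None]
    )
    return CappedNPModel(
        core=core, graft_sites=sites, ligand_positions=lig, ligand_topology=topology
    )


def build_capped_np(
    diameter: float = 2.2,
    n_ligands: int = 60,
    seed: int = 0,
    lattice: LatticeSpec = LatticeSpec(),
    truncation: TruncationSpec | None = None,
    topology: LigandTopology = LigandTopology(),
) -> CappedNPModel:
    """Carve a core (default: the calibrated 314-atom carve) and cap it."""
    if truncation is None:
        if abs(diameter - 2.2) < 1e-9 and abs(lattice.lattice_constant - GOLD_LATTICE_CONSTANT) < 1e-12:
            truncation = DEFAULT_TRUNCATION
        else:
            truncation = calibrate_truncation(diameter, lattice)[0][0]
    core = carve_core(lattice, truncation)
    return graft_ligands(core, n_ligands, topology, seed)


# ---------------------------------------------------------------------------
# export


def export_structure(model: CappedNPModel, path: str | Path, format: str | None = None) -> None:
    """Write the capped NP as a single-frame PDB/GRO/XYZ structure."""
    top, frame = model.to_topology_frame()
    write_trajectory(Trajectory(top, [frame]), path, format)


def export_topology(model: CappedNPModel, path: str | Path) -> None:
    """Plain-text bonded topology: [beads], [bonds], [angles] sections.

    Bead indices are 1-based serials matching :func:`export_structure`
    output order (core first, then ligand beads chain by chain).
    """
    lt = model.ligand_topology
    n_core = model.core.n_atoms
    nb = lt.beads_per_ligand
    with open(path, "w") as fh:
        fh.write("; corona-lab capped nanoparticle topology\n")
        fh.write("[beads]\n; serial  label  role  fixed\n")
        for i in range(n_core):
            fh.write(f"{i + 1:6d}  {lt.anchor_label:<4s}  core    yes\n")
        serial = n_core + 1
        for _ in range(model.n_ligands):
            for j, label in enumerate(lt.bead_labels):
                fixed = "yes" if j == 0 else "no"
                fh.write(f"{serial:6d}  {label:<4s}  ligand  {fixed}\n")
                serial += 1
        fh.write(f"\n[bonds]\n; i  j  r0_nm  k_kJ_mol_nm2\n")
        for il in range(model.n_ligands):
            base = n_core + il * nb
            anchor_serial = int(model.graft_sites[il]) + 1
            fh.write(
                f"{anchor_serial:6d} {base + 1:6d}  "
                f"{lt.equilibrium_bond_length:.3f}  {lt.bond_k:.1f}\n"
            )
            for j in range(nb - 1):
                fh.write(
                    f"{base + j + 1:6d} {base + j + 2:6d}  "
                    f"{lt.equilibrium_bond_length:.3f}  {lt.bond_k:.1f}\n"
                )
        fh.write(f"\n[angles]\n; i  j  k  theta0_deg  k_kJ_mol\n")
        for il in range(model.n_ligands):
            base = n_core + il * nb
            for j in range(nb - 2):
                fh.write(
                    f"{base + j + 1:6d} {base + j + 2:6d} {base + j + 3:6d}  "
                    f"{lt.angle_theta0:.1f}  {lt.angle_k:.1f}\n"
                )
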