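"""Gold-core carving, surface detection, ligand grafting and export."""

from itertools import product

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist

from corona_lab.nanobuilder import (
    CapacityError,
    DEFAULT_TRUNCATION,
    DegenerateGeometryError,
    LatticeSpec,
    LigandTopology,
    TruncationSpec,
    build_capped_np,
    carve_core,
    export_structure,
    export_topology,
    find_surface_sites,
    graft_ligands,
)
from corona_lab.trajectory import read_trajectory


def brute_force_carve(lattice, truncation):
    """Independent enumeration: every fcc point tested against all 14 planes."""
    a = lattice.lattice_constant
    off = {
        "atom": (0, 0, 0),
        "octahedral": (0.5, 0, 0),
        "tetrahedral": (0.25, 0.25, 0.25),
        "bridge": (0.25, 0.25, 0),
    }[truncation.center]
    m = 12
    pts = []
    for i, j, k in product(range(-m, m + 1), repeat=3):
        if (i + j + k) % 2:
            continue
        p = np.array([i, j, k]) * a / 2.0 - np.array(off) * a
        if max(abs(p)) > truncation.cut_100 + 1e-9:
            continue
        ok = all(
            abs(sx * p[0] + sy * p[1] + sz * p[2]) / np.sqrt(3) <= truncation.cut_111 + 1e-9
            for sx, sy, sz in product((1, -1), repeat=3)
        )
        if ok:
            pts.append(p)
    pts = np.array(pts)
    return pts - pts.mean(axis=0)


class TestCarveCore:
    def test_calibrated_carve_gives_314_atom_core(self):
        core = carve_core(truncation=DEFAULT_TRUNCATION)
        assert core.n_atoms == 314
        assert 2.1 <= core.diameter <= 2.3
        assert core.diameter == pytest.approx(core.recompute_diameter())

    @pytest.mark.parametrize(
        "trunc",
        [
            DEFAULT_TRUNCATION,
            TruncationSpec(0.9, 0.9, "atom"),
            TruncationSpec(0.75, 1.1, "tetrahedral"),
        ],
    )
    def test_matches_bruteforce_lattice_enumeration(self, trunc):
        core = carve_core(truncation=trunc)
        oracle = brute_force_carve(LatticeSpec(), trunc)
        assert core.n_atoms == len(oracle)
        got = set(map(tuple, np.round(core.positions, 6)))
        want = set(map(tuple, np.round(oracle, 6)))
        assert got == want

    def test_degenerate_cut_single_atom_or_error(self):
        trunc = TruncationSpec(0.01, 0.01, "atom")
        try:
            core = carve_core(truncation=trunc)
            assert core.n_atoms == 1
        except DegenerateGeometryError:
            pass
        with pytest.raises(DegenerateGeometryError):
            carve_core(truncation=TruncationSpec(0.01, 0.01, "octahedral"))

    def test_atom_count_invariant_under_lattice_rotation(self):
        """A 90-degree rotation about z is a symmetry of both the fcc
        lattice and the {100}/{111} cut families, so the carved set maps
        onto itself."""
        core = carve_core(truncation=DEFAULT_TRUNCATION)
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        rotated = set(map(tuple, np.round(core.positions @ R.T, 6)))
        assert rotated == set(map(tuple, np.round(core.positions, 6)))

    def test_octahedral_point_group_orbits(self):
        """The octahedral-centered carve has full cubic symmetry: all 48
        signed permutations map the atom set onto itself, so every orbit
        size divides the atom count consistently."""
        core = carve_core(truncation=DEFAULT_TRUNCATION)
        pts = set(map(tuple, np.round(core.positions, 6)))
        for perm in ([0, 1, 2], [1, 2, 0], [2, 0, 1], [0, 2, 1], [1, 0, 2], [2, 1, 0]):
            for signs in product((1, -1), repeat=3):
                mapped = core.positions[:, perm] * np.array(signs)
                assert set(map(tuple, np.round(mapped, 6))) == pts

    def test_invalid_cuts_rejected(self):
        with pytest.raises(ValueError):
            TruncationSpec(-1.0, 0.5)
        with pytest.raises(ValueError):
            TruncationSpec(0.5, 0.5, center="nonsense")


class TestSurfaceSites:
    def test_matches_neighbor_census_oracle(self):
        core = carve_core(truncation=DEFAULT_TRUNCATION)
        surface = find_surface_sites(core)
        # O(n^2) census, written independently
        cutoff = 0.408 / np.sqrt(2) * 1.1
        d = cdist(core.positions, core.positions)
        want = [i for i in range(core.n_atoms) if (d[i] < cutoff).sum() - 1 < 12]
        assert surface.tolist() == want
        assert 0 < len(surface) < core.n_atoms

    def test_single_atom_is_surface(self):
        core = carve_core(truncation=TruncationSpec(0.01, 0.01, "atom"))
        assert find_surface_sites(core).tolist() == [0]

    def test_bulk_interior_atom_has_coordination_12(self):
        # a generous carve: the atom nearest the center is fully coordinated
        core = carve_core(truncation=TruncationSpec(1.3, 1.1, "atom"))
        surface = set(find_surface_sites(core).tolist())
        central = int(np.argmin(np.linalg.norm(core.positions, axis=1)))
        assert central not in surface


class TestGrafting:
    def test_zero_ligands_gives_bare_core(self):
        core = carve_core()
        model = graft_ligands(core, n_ligands=0)
        assert model.n_ligands == 0
        assert model.all_positions().shape == (core.n_atoms, 3)

    def test_seeded_grafting_is_reproducible(self):
        core = carve_core()
        a = graft_ligands(core, 60, seed=7)
        b = graft_ligands(core, 60, seed=7)
        assert np.array_equal(a.ligand_positions, b.ligand_positions)
        assert np.array_equal(a.graft_sites, b.graft_sites)
        c = graft_ligands(core, 60, seed=8)
        assert not np.array_equal(a.graft_sites, c.graft_sites)

    def test_too_many_ligands_raises(self):
        core = carve_core()
        n_surface = len(find_surface_sites(core))
        with pytest.raises(CapacityError):
            graft_ligands(core, n_surface + 1)

    def test_farthest_point_spread_beats_random_placement(self):
        """Minimal pairwise anchor distance from farthest-point sampling
        should be at least that of uniform random site choice."""
        core = carve_core()
        surface = find_surface_sites(core)
        fps_min, rand_min = [], []
        for seed in range(20):
            model = graft_ligands(core, 40, seed=seed)
            fps_min.append(pdist(core.positions[model.graft_sites]).min())
            rng = np.random.default_rng(seed)
            pick = rng.choice(surface, size=40, replace=False)
            rand_min.append(pdist(core.positions[pick]).min())
        assert min(fps_min) >= min(rand_min)
        assert np.mean(fps_min) > np.mean(rand_min)

    def test_ligand_chain_geometry(self, np_model):
        """Chains extend radially outward at the equilibrium bond length."""
        lt = np_model.ligand_topology
        for il in range(np_model.n_ligands):
            anchor = np_model.core.positions[np_model.graft_sites[il]]
            chain = np_model.ligand_positions[il]
            prev = anchor
            for bead in chain:
                assert np.linalg.norm(bead - prev) == pytest.approx(
                    lt.equilibrium_bond_length, abs=1e-9
                )
                prev = bead
            # outward: last bead farther from the center than the anchor
            assert np.linalg.norm(chain[-1]) > np.linalg.norm(anchor)

    def test_graft_sites_are_surface_atoms(self, np_model):
        surface = set(find_surface_sites(np_model.core).tolist())
        assert set(np_model.graft_sites.tolist()) <= surface


class TestExport:
    def test_structure_roundtrip_gro(self, np_model, tmp_path):
        path = tmp_path / "np.gro"
        export_structure(np_model, path)
        traj = read_trajectory(path)
        assert traj.topology.n_beads == len(np_model.all_positions())
        top, frame = np_model.to_topology_frame()
        assert np.allclose(traj.frames[0].positions, frame.positions, atol=5e-4)

    def test_bare_core_pdb_has_one_record_per_atom(self, tmp_path):
        core = carve_core()
        model = graft_ligands(core, 0)
        path = tmp_path / "core.pdb"
        export_structure(model, path)
        atom_lines = [l for l in path.read_text().splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == core.n_atoms

    def test_topology_file_counts(self, np_model, tmp_path):
        path = tmp_path / "np.top"
        export_topology(np_model, path)
        text = path.read_text()
        bonds = [
            l
            for l in text.split("[bonds]")[1].split("[angles]")[0].splitlines()
            if l.strip() and not l.strip().startswith(";")
        ]
        # each chain: anchor->first bead plus (beads-1) internal bonds
        nb = np_model.ligand_topology.beads_per_ligand
        assert len(bonds) == np_model.n_ligands * nb
        angles = [
            l
            for l in text.split("[angles]")[1].splitlines()
            if l.strip() and not l.strip().startswith(";")
        ]
        assert len(angles) == np_model.n_ligands * (nb - 2)
        assert "1250.0" in text and "180.0" in text and "25.0" in text

    def test_unknown_format_rejected(self, np_model, tmp_path):
        with pytest.raises(ValueError, match="unknown trajectory format"):
            export_structure(np_model, tmp_path / "np.xtc")


class TestDefaults:
    def test_ligand_topology_defaults(self):
        lt = LigandTopology()
        assert lt.bond_k == 1250.0
        assert lt.angle_k == 25.0
        assert lt.angle_theta0 == 180.0
        assert list(lt.bead_labels).count("C1") == 3

    def test_build_capped_np_default_is_calibrated(self):
        model = build_capped_np(n_ligands=10, seed=0)
        assert model.core.n_atoms == 314
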