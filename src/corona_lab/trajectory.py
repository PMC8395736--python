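"""Labeled coarse-grained bead structures and multi-frame trajectories.

The in-memory model is a :class:`Topology` (per-bead labels stored as
parallel numpy arrays) plus one or more :class:`Frame` objects holding
positions and an orthorhombic box. Supported on-disk formats are
multi-MODEL PDB, concatenated GRO and XYZ with a CSV sidecar carrying
the bead metadata that plain XYZ cannot express.

All coordinates are nm internally; PDB records are Å at the boundary.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .constants import ANGSTROM_PER_NM, DEFAULT_BEAD_MASS, NM_PER_ANGSTROM

ROLES = ("backbone", "sidechain", "ligand", "core")

AMINO_ACIDS_1 = "ACDEFGHIKLMNPQRSTVWY"

_AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_AA_3TO1 = {v: k for k, v in _AA_1TO3.items()}

# atom-name encoding of the bead role for formats without metadata
_ROLE_TO_NAME = {"backbone": "BB", "sidechain": "SC", "ligand": "LIG", "core": "AU"}
_NAME_TO_ROLE = {v: k for k, v in _ROLE_TO_NAME.items()}


class ParseError(ValueError):
    """Malformed structure/trajectory file (carries a line number)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class Bead:
    """A single labeled CG bead (view onto one topology row)."""

    index: int
    molecule_id: int
    residue_id: int
    residue_type: str
    role: str
    mass: float
    fixed: bool = False


class Topology:
    """Per-bead label table shared by every frame of a trajectory."""

    def __init__(
        self,
        molecule_id: Sequence[int],
        residue_id: Sequence[int],
        residue_type: Sequence[str],
        role: Sequence[str],
        mass: Sequence[float] | None = None,
        fixed: Sequence[bool] | None = None,
    ):
        n = len(residue_id)
        self.molecule_id = np.asarray(molecule_id, dtype=np.int64)
        self.residue_id = np.asarray(residue_id, dtype=np.int64)
        self.residue_type = np.asarray(residue_type, dtype="U4")
        self.role = np.asarray(role, dtype="U9")
        self.mass = (
            np.full(n, DEFAULT_BEAD_MASS)
            if mass is None
            else np.asarray(mass, dtype=float)
        )
        self.fixed = (
            np.zeros(n, dtype=bool) if fixed is None else np.asarray(fixed, dtype=bool)
        )
        self._validate()

    def _validate(self) -> None:
        n = self.n_beads
        for name in ("molecule_id", "residue_id", "residue_type", "role", "mass", "fixed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology column {name!r} has wrong length")
        bad = set(np.unique(self.role)) - set(ROLES)
        if bad:
            raise ValueError(f"unknown bead roles: {sorted(bad)}")
        if np.any(self.mass <= 0):
            raise ValueError("bead masses must be positive")
        protein = np.isin(self.role, ("backbone", "sidechain"))
        bad_res = set(self.residue_type[protein]) - set(AMINO_ACIDS_1)
        if bad_res:
            raise ValueError(f"non-canonical protein residue types: {sorted(bad_res)}")

    @property
    def n_beads(self) -> int:
        return len(self.residue_id)

    def __len__(self) -> int:
        return self.n_beads

    def bead(self, i: int) -> Bead:
        return Bead(
            index=i,
            molecule_id=int(self.molecule_id[i]),
            residue_id=int(self.residue_id[i]),
            residue_type=str(self.residue_type[i]),
            role=str(self.role[i]),
            mass=float(self.mass[i]),
            fixed=bool(self.fixed[i]),
        )

    def select(
        self,
        role: str | Sequence[str] | None = None,
        molecule_id: int | Sequence[int] | None = None,
    ) -> np.ndarray:
        """Boolean mask over beads matching all given criteria."""
        mask = np.ones(self.n_beads, dtype=bool)
        if role is not None:
            roles = (role,) if isinstance(role, str) else tuple(role)
            mask &= np.isin(self.role, roles)
        if molecule_id is not None:
            mols = (molecule_id,) if isinstance(molecule_id, int) else tuple(molecule_id)
            mask &= np.isin(self.molecule_id, mols)
        return mask

    @staticmethod
    def concatenate(parts: Iterable["Topology"]) -> "Topology":
        parts = list(parts)
        return Topology(
            np.concatenate([p.molecule_id for p in parts]),
            np.concatenate([p.residue_id for p in parts]),
            np.concatenate([p.residue_type for p in parts]),
            np.concatenate([p.role for p in parts]),
            np.concatenate([p.mass for p in parts]),
            np.concatenate([p.fixed for p in parts]),
        )


@dataclass
class Frame:
    """One snapshot: positions (nm), simulation time (ps), box edges (nm)."""

    time: float
    positions: np.ndarray
    box: np.ndarray = field(default_factory=lambda: np.array([10.0, 10.0, 10.0]))

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n_beads(self) -> int:
        return len(self.positions)


@dataclass
class Trajectory:
    """A topology plus strictly time-ordered frames."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self):
        for i, f in enumerate(self.frames):
            if f.n_beads != self.topology.n_beads:
                raise ValueError(
                    f"frame {i}: {f.n_beads} positions for "
                    f"{self.topology.n_beads} topology beads"
                )
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# geometry helpers


def center_of_mass(
    frame: Frame, topology: Topology, selection: np.ndarray | None = None
) -> np.ndarray:
    """Mass-weighted mean position of the selected beads (no PBC wrapping).

    Selections are assumed whole (not split across the periodic boundary);
    see :func:`make_whole` for repairing external inputs.
    """
    if selection is None:
        selection = np.ones(topology.n_beads, dtype=bool)
    m = topology.mass[selection]
    if m.size == 0:
        raise ValueError("empty selection")
    r = frame.positions[selection]
    return (m[:, None] * r).sum(axis=0) / m.sum()


def minimum_image_displacement(
    p: np.ndarray, q: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """Per-axis minimum-image displacement p - q in an orthorhombic box."""
    d = np.asarray(p, float) - np.asarray(q, float)
    box = np.asarray(box, float)
    return d - box * np.round(d / box)


def minimum_image_distance(p, q, box) -> float | np.ndarray:
    """Euclidean distance under the per-axis minimum-image convention."""
    d = minimum_image_displacement(p, q, box)
    return np.linalg.norm(d, axis=-1)


def make_whole(traj: Trajectory) -> Trajectory:
    """Unwrap each molecule so its beads sit in one periodic image.

    Repair pass for externally produced trajectories: within each molecule
    every bead is moved to the minimum image relative to the molecule's
    first bead. Synthetic trajectories are whole by construction.
    """
    top = traj.topology
    new_frames = []
    for f in traj.frames:
        pos = f.positions.copy()
        for mol in np.unique(top.molecule_id):
            idx = np.where(top.molecule_id == mol)[0]
            ref = pos[idx[0]]
            d = pos[idx] - ref
            pos[idx] = ref + (d - f.box * np.round(d / f.box))
        new_frames.append(Frame(f.time, pos, f.box.copy()))
    return Trajectory(top, new_frames)


# ---------------------------------------------------------------------------
# I/O: PDB (multi-MODEL), GRO (concatenated), XYZ + CSV sidecar


def _resname_for(residue_type: str, role: str) -> str:
    if role in ("backbone", "sidechain"):
        return _AA_1TO3[residue_type]
    return (residue_type or ("MUS" if role == "ligand" else "AUC"))[:4]


def _residue_type_from(resname: str, role: str) -> str:
    if role in ("backbone", "sidechain"):
        try:
            return _AA_3TO1[resname.upper()]
        except KeyError:
            raise ParseError(f"unknown protein residue name {resname!r}")
    return resname


_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_pdb(traj: Trajectory, path: str | Path) -> None:
    top = traj.topology
    mols = list(dict.fromkeys(top.molecule_id.tolist()))
    chain_of = {m: _CHAIN_IDS[i % len(_CHAIN_IDS)] for i, m in enumerate(mols)}
    with open(path, "w") as fh:
        for imodel, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {imodel:4d}\n")
            fh.write(
                f"REMARK   6 TIME_PS {frame.time:.4f} BOX_NM "
                f"{frame.box[0]:.4f} {frame.box[1]:.4f} {frame.box[2]:.4f}\n"
            )
            for i in range(top.n_beads):
                x, y, z = frame.positions[i] * ANGSTROM_PER_NM
                name = _ROLE_TO_NAME[str(top.role[i])]
                res = _resname_for(str(top.residue_type[i]), str(top.role[i]))
                fh.write(
                    "ATOM  {serial:5d} {name:<4s} {res:<4s}{chain}{resid:4d}    "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}\n".format(
                        serial=(i + 1) % 100000,
                        name=name,
                        res=res,
                        chain=chain_of[int(top.molecule_id[i])],
                        resid=int(top.residue_id[i]) % 10000,
                        x=x, y=y, z=z,
                        occ=1.0,
                        b=1.0 if top.fixed[i] else 0.0,
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pdb(path: str | Path) -> Trajectory:
    frames_raw: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                current = {"time": None, "box": (10.0, 10.0, 10.0), "rows": []}
            elif rec == "REMARK" and "TIME_PS" in line:
                parts = line.split()
                try:
                    t = float(parts[parts.index("TIME_PS") + 1])
                    b = parts[parts.index("BOX_NM") + 1 : parts.index("BOX_NM") + 4]
                    box = tuple(float(v) for v in b)
                except (ValueError, IndexError):
                    raise ParseError("malformed TIME_PS/BOX_NM remark", ln)
                if current is None:
                    current = {"time": t, "box": box, "rows": []}
                else:
                    current["time"], current["box"] = t, box
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = {"time": None, "box": (10.0, 10.0, 10.0), "rows": []}
                try:
                    name = line[12:16].strip()
                    res = line[17:21].strip()
                    chain = line[21]
                    resid = int(line[22:26])
                    x = float(line[30:38]) * NM_PER_ANGSTROM
                    y = float(line[38:46]) * NM_PER_ANGSTROM
                    z = float(line[46:54]) * NM_PER_ANGSTROM
                    bfac = line[60:66].strip()
                except ValueError:
                    raise ParseError("malformed ATOM record", ln)
                current["rows"].append((name, res, chain, resid, x, y, z, bfac))
            elif rec == "ENDMDL":
                if current is not None:
                    frames_raw.append(current)
                    current = None
    if current is not None and current["rows"]:
        frames_raw.append(current)
    if not frames_raw:
        raise ParseError("no ATOM records found")

    rows0 = frames_raw[0]["rows"]
    chains = list(dict.fromkeys(r[2] for r in rows0))
    mol_of = {c: i + 1 for i, c in enumerate(chains)}
    roles, res_types, res_ids, mol_ids, fixed = [], [], [], [], []
    for name, res, chain, resid, *_xyz, bfac in rows0:
        role = _NAME_TO_ROLE.get(name)
        if role is None:
            raise ParseError(f"unknown bead atom name {name!r}")
        roles.append(role)
        res_types.append(_residue_type_from(res, role))
        res_ids.append(resid)
        mol_ids.append(mol_of[chain])
        fixed.append(bfac == "1.00")
    top = Topology(mol_ids, res_ids, res_types, roles, fixed=fixed)

    frames = []
    for k, fr in enumerate(frames_raw):
        if len(fr["rows"]) != top.n_beads:
            raise ParseError(
                f"model {k + 1} has {len(fr['rows'])} atoms, expected {top.n_beads}"
            )
        pos = np.array([r[4:7] for r in fr["rows"]])
        t = fr["time"] if fr["time"] is not None else float(k)
        frames.append(Frame(t, pos, np.array(fr["box"])))
    return Trajectory(top, frames)


def write_gro(traj: Trajectory, path: str | Path) -> None:
    top = traj.topology
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"corona-lab CG system, t= {frame.time:.4f}\n")
            fh.write(f"{top.n_beads:5d}\n")
            for i in range(top.n_beads):
                res = _resname_for(str(top.residue_type[i]), str(top.role[i]))
                name = _ROLE_TO_NAME[str(top.role[i])]
                x, y, z = frame.positions[i]
                fh.write(
                    "{resid:>5d}{res:<5s}{name:>5s}{serial:>5d}"
                    "{x:8.3f}{y:8.3f}{z:8.3f}\n".format(
                        resid=int(top.residue_id[i]) % 100000,
                        res=res,
                        name=name,
                        serial=(i + 1) % 100000,
                        x=x, y=y, z=z,
                    )
                )
            fh.write(
                f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n"
            )


def read_gro(path: str | Path) -> Trajectory:
    frames_raw = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    n_lines = len(lines)
    while ln < n_lines:
        title = lines[ln].rstrip("\n")
        if not title.strip():
            ln += 1
            continue
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (ValueError, IndexError):
                raise ParseError("malformed time in GRO title", ln + 1)
        try:
            n = int(lines[ln + 1])
        except (ValueError, IndexError):
            raise ParseError("expected atom count", ln + 2)
        rows = []
        for i in range(n):
            line = lines[ln + 2 + i]
            try:
                resid = int(line[0:5])
                res = line[5:10].strip()
                name = line[10:15].strip()
                x = float(line[20:28])
                y = float(line[28:36])
                z = float(line[36:44])
            except (ValueError, IndexError):
                raise ParseError("malformed GRO atom line", ln + 3 + i)
            rows.append((resid, res, name, x, y, z))
        try:
            box = tuple(float(v) for v in lines[ln + 2 + n].split()[:3])
        except (ValueError, IndexError):
            raise ParseError("malformed GRO box line", ln + 3 + n)
        frames_raw.append({"time": time, "rows": rows, "box": box})
        ln += 3 + n

    if not frames_raw:
        raise ParseError("empty GRO file")
    rows0 = frames_raw[0]["rows"]
    roles, res_types, res_ids, mol_ids = [], [], [], []
    mol, prev_resid, prev_role = 1, None, None
    for resid, res, name, *_ in rows0:
        role = _NAME_TO_ROLE.get(name)
        if role is None:
            raise ParseError(f"unknown bead atom name {name!r}")
        # GRO has no chain field: start a new molecule when residue numbering
        # restarts or the role family switches protein <-> NP
        fam = "prot" if role in ("backbone", "sidechain") else "np"
        if prev_resid is not None and (
            resid < prev_resid or (prev_role is not None and fam != prev_role)
        ):
            mol += 1
        roles.append(role)
        res_types.append(_residue_type_from(res, role))
        res_ids.append(resid)
        mol_ids.append(mol)
        prev_resid, prev_role = resid, fam
    top = Topology(mol_ids, res_ids, res_types, roles)

    frames = []
    for k, fr in enumerate(frames_raw):
        if len(fr["rows"]) != top.n_beads:
            raise ParseError(f"frame {k} bead count mismatch")
        pos = np.array([r[3:6] for r in fr["rows"]])
        frames.append(Frame(fr["time"], pos, np.array(fr["box"])))
    # repair identical/non-increasing times from titles without t=
    if len({f.time for f in frames}) != len(frames):
        frames = [Frame(float(i), f.positions, f.box) for i, f in enumerate(frames)]
    return Trajectory(top, frames)


_SIDE_COLS = ["index", "molecule_id", "residue_id", "residue_type", "role", "mass", "fixed"]


def write_xyz(traj: Trajectory, path: str | Path, sidecar: str | Path | None = None) -> None:
    """XYZ trajectory plus a CSV sidecar carrying full bead metadata."""
    path = Path(path)
    top = traj.topology
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{top.n_beads}\n")
            fh.write(
                f"time={frame.time:.4f} box={frame.box[0]:.4f},"
                f"{frame.box[1]:.4f},{frame.box[2]:.4f}\n"
            )
            for i in range(top.n_beads):
                name = _ROLE_TO_NAME[str(top.role[i])]
                x, y, z = frame.positions[i]
                fh.write(f"{name:<4s} {x:12.6f} {y:12.6f} {z:12.6f}\n")
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".beads.csv")
    with open(sidecar, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SIDE_COLS)
        for i in range(top.n_beads):
            b = top.bead(i)
            w.writerow(
                [i, b.molecule_id, b.residue_id, b.residue_type, b.role,
                 repr(b.mass), int(b.fixed)]
            )


def read_xyz(path: str | Path, sidecar: str | Path | None = None) -> Trajectory:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".beads.csv")
    if not sidecar.exists():
        raise ParseError(f"XYZ sidecar label table not found: {sidecar}")
    with open(sidecar, newline="") as fh:
        rows = list(csv.DictReader(fh))
    top = Topology(
        [int(r["molecule_id"]) for r in rows],
        [int(r["residue_id"]) for r in rows],
        [r["residue_type"] for r in rows],
        [r["role"] for r in rows],
        [float(r["mass"]) for r in rows],
        [bool(int(r["fixed"])) for r in rows],
    )
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln])
        except ValueError:
            raise ParseError("expected atom count", ln + 1)
        comment = lines[ln + 1]
        time, box = float(len(frames)), (10.0, 10.0, 10.0)
        for tok in comment.split():
            if tok.startswith("time="):
                time = float(tok[5:])
            elif tok.startswith("box="):
                box = tuple(float(v) for v in tok[4:].split(","))
        pos = []
        for i in range(n):
            parts = lines[ln + 2 + i].split()
            try:
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except (ValueError, IndexError):
                raise ParseError("malformed XYZ atom line", ln + 3 + i)
        if n != top.n_beads:
            raise ParseError(f"frame {len(frames)} bead count mismatch", ln + 1)
        frames.append(Frame(time, np.array(pos), np.array(box)))
        ln += 2 + n
    return Trajectory(top, frames)


_WRITERS = {"pdb": write_pdb, "gro": write_gro, "xyz": write_xyz}
_READERS = {"pdb": read_pdb, "gro": read_gro, "xyz": read_xyz}


def _infer_format(path: str | Path, fmt: str | None) -> str:
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt not in _READERS:
        raise ValueError(f"unknown trajectory format {fmt!r} (use pdb, gro or xyz)")
    return fmt


def read_trajectory(path: str | Path, format: str | None = None) -> Trajectory:
    return _READERS[_infer_format(path, format)](path)


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    _WRITERS[_infer_format(path, format)](traj, path)


def read_structure(path: str | Path, format: str | None = None) -> tuple[Topology, Frame]:
    """Read a single-frame structure; errors if the file holds several frames."""
    traj = read_trajectory(path, format)
    return traj.topology, traj.frames[0]
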