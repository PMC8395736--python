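"""Synthetic inputs: decoy proteins, scripted adsorption, umbrella windows.

Everything downstream of the nanoparticle builder consumes trajectories
or umbrella-window samples; this module generates both from known ground
truth so every analysis stage can be validated without molecular
dynamics.

Three generators:

* :func:`make_decoy_protein` — a compact self-avoiding bead globule with
  one backbone bead per residue and one sidechain bead for every residue
  except glycine.
* :func:`make_adsorption_trajectory` — a scripted (kinematic) three-phase
  approach of a rigid protein to a capped nanoparticle: free diffusion,
  weak first contact with the ligand shell, then a stable bound pose with
  a known residue patch facing the particle. The phases are scripted
  rather than integrated so the phase boundaries and the bound patch are
  exact ground truth for the segmentation and contact analyses.
* :func:`sample_umbrella_windows` — Metropolis draws from the biased
  density ``exp(-[U(x) + k/2 (x-c)^2] / kBT)`` for a known 1D potential,
  the ground truth for WHAM validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import CG_BOND_LENGTH, CONTACT_CUTOFF, KB
from .nanobuilder import CappedNPModel
from .trajectory import AMINO_ACIDS_1, Frame, Topology, Trajectory

logger = logging.getLogger(__name__)


class PackingError(RuntimeError):
    """Self-avoiding globule packing failed after bounded retries."""


class SamplerError(RuntimeError):
    """Metropolis sampler could not reach a workable acceptance rate."""


# ---------------------------------------------------------------------------
# decoy proteins


def make_decoy_protein(
    n_residues: int,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    bond_length: float = CG_BOND_LENGTH,
    min_separation_factor: float = 0.9,
    molecule_id: int = 1,
    max_restarts: int = 60,
) -> tuple[Topology, Frame]:
    """Generate a compact self-avoiding CG protein globule.

    The backbone is grown as a confined random walk with step
    ``bond_length``; every residue except glycine gets one sidechain
    bead. No two beads (bonded pairs included) come closer than
    ``min_separation_factor * bond_length``. Residue types are drawn
    from ``composition`` (uniform over the 20 canonical types when
    omitted). Reproducible per seed.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    if composition is None:
        types = list(AMINO_ACIDS_1)
        probs = np.full(len(types), 1.0 / len(types))
    else:
        types = sorted(composition)
        probs = np.array([composition[t] for t in types], float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("composition must be a probability vector")
        probs = probs / probs.sum()
        unknown = set(types) - set(AMINO_ACIDS_1)
        if unknown:
            raise ValueError(f"unknown residue types in composition: {sorted(unknown)}")
    residue_types = rng.choice(types, size=n_residues, p=probs)

    dmin = min_separation_factor * bond_length
    # confinement radius sized for ~2 beads/residue at liquid-like density
    n_beads_est = 2 * n_residues
    radius = max(1.5 * bond_length, 0.42 * bond_length * n_beads_est ** (1.0 / 3.0) * 1.9)

    for _attempt in range(max_restarts):
        placed = _grow_globule(n_residues, residue_types, rng, bond_length, dmin, radius)
        if placed is not None:
            positions, res_ids, roles = placed
            break
        radius *= 1.06  # relax confinement and retry
    else:
        raise PackingError(
            f"could not pack {n_residues} residues after {max_restarts} restarts"
        )

    res_types_per_bead = [str(residue_types[r - 1]) for r in res_ids]
    top = Topology(
        molecule_id=[molecule_id] * len(res_ids),
        residue_id=res_ids,
        residue_type=res_types_per_bead,
        role=roles,
    )
    pos = np.array(positions)
    pos -= pos.mean(axis=0)
    return top, Frame(time=0.0, positions=pos, box=np.array([20.0, 20.0, 20.0]))


def _grow_globule(n_residues, residue_types, rng, bond_length, dmin, radius):
    positions: list[np.ndarray] = []
    res_ids: list[int] = []
    roles: list[str] = []

    def clashes(p: np.ndarray) -> bool:
        if not positions:
            return False
        arr = np.array(positions)
        return bool((np.linalg.norm(arr - p, axis=1) < dmin).any())

    prev_bb = np.zeros(3)
    for ires in range(1, n_residues + 1):
        ok = False
        for _try in range(300):
            if ires == 1:
                cand = np.zeros(3)
            else:
                step = rng.normal(size=3)
                step *= bond_length / np.linalg.norm(step)
                cand = prev_bb + step
                # soft centripetal bias keeps the walk compact
                if np.linalg.norm(cand) > radius:
                    continue
            if not clashes(cand):
                ok = True
                break
        if not ok:
            return None
        positions.append(cand)
        res_ids.append(ires)
        roles.append("backbone")
        prev_bb = cand
        if residue_types[ires - 1] != "G":
            ok_sc = False
            for _try in range(300):
                d = rng.normal(size=3)
                d *= bond_length / np.linalg.norm(d)
                sc = cand + d
                if np.linalg.norm(sc) > radius + bond_length:
                    continue
                if not clashes(sc):
                    ok_sc = True
                    break
            if not ok_sc:
                return None
            positions.append(sc)
            res_ids.append(ires)
            roles.append("sidechain")
    return positions, res_ids, roles


# ---------------------------------------------------------------------------
# scripted three-phase adsorption


@dataclass
class AdsorptionScenario:
    """Parameters of the scripted diffusive -> contact -> bound approach.

    ``contact_standoff`` and ``bound_standoff`` are center-of-mass
    distances from the nanoparticle center during the weak-contact and
    stably-bound phases; ``None`` lets the generator derive them from
    the actual protein and particle geometry so that the bound pose
    touches the ligand shell.
    """

    phase_durations: tuple[int, int, int] = (50, 30, 120)
    diffusion_step_sigma: float = 0.25  # nm per frame, free-diffusion phase
    contact_standoff: float | None = None  # nm
    bound_standoff: float | None = None  # nm
    positional_noise_sigma: float = 0.05  # nm
    bead_jitter_sigma: float = 0.02  # nm, per-bead thermal noise
    rotational_jitter_deg: float = 8.0  # weak-contact phase
    bound_gap: float = 0.3  # nm, closest protein bead to ligand tip when bound
    contact_extra: float = 0.8  # nm, contact standoff above bound standoff
    time_step: float = 100.0  # ps between frames
    seed: int = 0

    def __post_init__(self):
        if any(d < 1 for d in self.phase_durations):
            raise ValueError("all phase durations must be >= 1")
        if self.diffusion_step_sigma < 0 or self.positional_noise_sigma < 0:
            raise ValueError("noise sigmas must be non-negative")
        if (
            self.contact_standoff is not None
            and self.bound_standoff is not None
            and not self.bound_standoff < self.contact_standoff
        ):
            raise ValueError("bound_standoff must be below contact_standoff")


@dataclass
class AdsorptionResult:
    """Scripted trajectory plus its ground truth."""

    trajectory: Trajectory
    bound_patch: frozenset[int]  # residue ids in contact in the final frame
    protein_selection: np.ndarray  # bool mask over beads
    np_selection: np.ndarray
    contact_standoff: float
    bound_standoff: float
    breakpoints: tuple[int, int]  # first frame of phases 2 and 3


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotation_onto(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # pick any perpendicular axis
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-9:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        return _rotation_matrix(axis, np.pi)
    axis = np.cross(u, v)
    return _rotation_matrix(axis, np.arccos(c))


def _solve_standoff(
    prot_coords: np.ndarray, np_coords: np.ndarray, gap: float, s_hi: float
) -> float:
    """COM separation along z at which the closest bead pair gap equals ``gap``."""

    def min_dist(s: float) -> float:
        shifted = prot_coords + np.array([0.0, 0.0, s])
        return float(cdist(shifted, np_coords).min())

    hi = s_hi + 2.0
    lo = max(0.1, s_hi - 4.0)
    while min_dist(hi) < gap:  # pragma: no cover - defensive
        hi += 1.0
    while min_dist(lo) > gap and lo > 0.2:
        lo -= 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) > gap:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def make_adsorption_trajectory(
    protein: tuple[Topology, Frame],
    np_model: CappedNPModel,
    scenario: AdsorptionScenario = AdsorptionScenario(),
    contact_cutoff: float = CONTACT_CUTOFF,
) -> AdsorptionResult:
    """Script a rigid protein through the three adsorption phases.

    Phase 1: the protein center of mass random-walks in a far shell.
    Phase 2: held at the contact standoff with rotational jitter, so a
    few beads graze the ligand tips. Phase 3: a fixed orientation with a
    designated surface patch facing the particle, center of mass at the
    bound standoff plus small positional noise. The last frame is the
    exact noiseless bound pose, and the returned ``bound_patch`` is the
    set of residues whose backbone bead lies within ``contact_cutoff``
    of any nanoparticle bead in that frame (computed here by brute
    force, independently of the analysis module).

    Nanoparticle beads flagged ``fixed`` never move; the flexible ligand
    beads get small thermal jitter except in the final frame.
    """
    top_p, frame_p = protein
    rng = np.random.default_rng(scenario.seed)

    np_top, _ = np_model.to_topology_frame(box=1.0)  # box replaced below
    np_rel = np_model.all_positions()  # NP bead positions about particle center
    # the protein is its own molecule, numbered after the particle
    top_p = Topology(
        molecule_id=top_p.molecule_id - top_p.molecule_id.min() + 2,
        residue_id=top_p.residue_id,
        residue_type=top_p.residue_type,
        role=top_p.role,
        mass=top_p.mass,
        fixed=top_p.fixed,
    )
    r_tip = float(np.linalg.norm(np_rel, axis=1).max())

    base = frame_p.positions - (
        (top_p.mass[:, None] * frame_p.positions).sum(axis=0) / top_p.mass.sum()
    )
    r_prot = float(np.linalg.norm(base, axis=1).max())

    # bound pose: approach along -z; rotate the protein so the backbone bead
    # farthest from the COM points toward the particle (that region is the patch)
    bb_mask_local = top_p.select(role="backbone")
    far_bead = int(np.argmax(np.linalg.norm(base[bb_mask_local], axis=1)))
    u = base[bb_mask_local][far_bead]
    R_bound = _rotation_onto(u / np.linalg.norm(u), np.array([0.0, 0.0, -1.0]))
    bound_coords = base @ R_bound.T
    depth = float(-bound_coords[:, 2].min())  # COM -> deepest bead, toward NP

    bound = scenario.bound_standoff
    if bound is None:
        # choose the COM separation whose closest backbone-bead/NP-bead gap
        # equals bound_gap (< cutoff), so the patch is a backbone contact;
        # solved on the actual geometry
        bound = _solve_standoff(
            bound_coords[bb_mask_local], np_rel, scenario.bound_gap, r_tip + depth
        )
    contact = scenario.contact_standoff
    if contact is None:
        contact = bound + scenario.contact_extra
    if not bound < contact:
        raise ValueError(
            f"standoffs incompatible: bound {bound:.3f} >= contact {contact:.3f} nm"
        )
    if bound < r_tip - 0.5:
        raise ValueError(
            f"bound standoff {bound:.3f} nm sits deep inside the "
            f"ligand shell (tip radius {r_tip:.3f} nm)"
        )

    n1, n2, n3 = scenario.phase_durations
    n_frames = n1 + n2 + n3
    far0 = contact + 2.5 + r_prot
    half = far0 + r_prot + 2.0
    box = np.array([2 * half, 2 * half, 2 * half])
    center = box / 2.0

    full_top = Topology.concatenate([np_top, top_p])
    n_np = np_top.n_beads
    prot_sel = np.zeros(full_top.n_beads, dtype=bool)
    prot_sel[n_np:] = True
    np_sel = ~prot_sel
    lig_free = ~np_top.fixed  # flexible ligand beads

    frames = []
    # phase 1: random walk confined to a narrow far shell around far0, so the
    # diffusive plateau is genuinely the highest and flattest of the three
    com = np.array([0.0, 0.0, far0])
    lo, hi = far0 - 0.7, far0 + 0.7
    orient = np.eye(3)
    for i in range(n_frames):
        if i < n1:
            step = rng.normal(scale=scenario.diffusion_step_sigma, size=3)
            com = com + step
            r = np.linalg.norm(com)
            if r > hi:
                com *= hi / r
            elif r < lo:
                com *= lo / r
            axis = rng.normal(size=3)
            orient = _rotation_matrix(axis, rng.normal(scale=0.2)) @ orient
            coords = base @ orient.T + com
        elif i < n1 + n2:
            direction = np.array([0.0, 0.0, 1.0])
            jitter = rng.normal(scale=scenario.positional_noise_sigma, size=3)
            axis = rng.normal(size=3)
            ang = np.deg2rad(scenario.rotational_jitter_deg) * rng.normal()
            R = _rotation_matrix(axis, ang) @ R_bound
            coords = base @ R.T + direction * contact + jitter
        else:
            jitter = rng.normal(scale=scenario.positional_noise_sigma, size=3)
            if i == n_frames - 1:
                jitter = np.zeros(3)  # exact bound pose in the final frame
            coords = bound_coords + np.array([0.0, 0.0, bound]) + jitter

        np_pos = np_rel.copy()
        if i != n_frames - 1:
            # per-bead thermal noise (the final frame is the exact pose)
            if scenario.bead_jitter_sigma > 0:
                coords = coords + rng.normal(
                    scale=scenario.bead_jitter_sigma, size=coords.shape
                )
            np_pos[lig_free] += rng.normal(
                scale=scenario.positional_noise_sigma / 2.0, size=(lig_free.sum(), 3)
            )
        pos = np.vstack([np_pos + center, coords + center])
        frames.append(Frame(time=i * scenario.time_step, positions=pos, box=box))

    traj = Trajectory(full_top, frames)

    # ground-truth patch from the exact final frame, brute force
    last = frames[-1].positions
    bb_idx = np.where(prot_sel & full_top.select(role="backbone"))[0]
    d = cdist(last[bb_idx], last[np_sel])
    in_contact = (d.min(axis=1) < contact_cutoff)
    patch = frozenset(int(r) for r in full_top.residue_id[bb_idx[in_contact]])
    if not patch:
        raise ValueError("bound pose produced no contacts; lower bound_gap")

    return AdsorptionResult(
        trajectory=traj,
        bound_patch=patch,
        protein_selection=prot_sel,
        np_selection=np_sel,
        contact_standoff=float(contact),
        bound_standoff=float(bound),
        breakpoints=(n1, n1 + n2),
    )


# ---------------------------------------------------------------------------
# umbrella-window sampling from a known potential


@dataclass(frozen=True)
class PotentialSpec:
    """A known 1D potential used as WHAM ground truth.

    Forms: ``harmonic-well`` (k, x0), ``double-well`` (barrier, x1, x2 —
    quartic with minima at x1, x2 and the stated barrier at the midpoint),
    ``morse-like`` (depth, x0, width).
    """

    form: str
    parameters: dict[str, float]
    domain: tuple[float, float] = (0.0, 4.0)

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        p = self.parameters
        if self.form == "harmonic-well":
            return 0.5 * p["k"] * (x - p["x0"]) ** 2
        if self.form == "double-well":
            x1, x2, barrier = p["x1"], p["x2"], p["barrier"]
            mid = 0.5 * (x1 + x2)
            s = (x - mid) / (0.5 * (x2 - x1))
            return barrier * (s**2 - 1.0) ** 2
        if self.form == "morse-like":
            e = np.exp(-(x - p["x0"]) / p["width"])
            return p["depth"] * (1.0 - e) ** 2 - p["depth"]
        raise ValueError(f"unknown potential form {self.form!r}")

    def __post_init__(self):
        if self.domain[1] <= self.domain[0]:
            raise ValueError("empty potential domain")
        test = self(np.linspace(*self.domain, 64))
        if not np.all(np.isfinite(test)):
            raise ValueError("potential not finite on its domain")


@dataclass
class UmbrellaWindowSample:
    bias_center: float  # nm
    bias_k: float  # kJ/mol nm^2
    samples: np.ndarray  # reaction-coordinate values, nm
    temperature: float  # K
    acceptance_rate: float = float("nan")

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.bias_k <= 0:
            raise ValueError("bias_k must be positive")


def sample_umbrella_windows(
    potential: PotentialSpec,
    centers: Sequence[float],
    bias_k: float = 500.0,
    n_samples: int = 10_000,
    temperature: float = 320.0,
    seed: int = 0,
    burn_in: int = 2_000,
    thin: int = 5,
) -> list[UmbrellaWindowSample]:
    """Seeded Metropolis draws from each biased window density.

    All windows are advanced in lockstep (one vectorized chain per
    window). During burn-in the proposal width is tuned toward a
    30–60% acceptance rate; the post-burn-in rate is recorded on each
    window. Samples are reflected into the potential domain.
    """
    centers = np.asarray(centers, dtype=float)
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB * temperature)
    lo, hi = potential.domain

    def energy(x):
        return potential(x) + 0.5 * bias_k * (x - centers) ** 2

    # start at the bias centers; initial proposal from the bias width
    x = centers.copy()
    step = np.full(len(centers), max(0.5 / np.sqrt(beta * bias_k), 1e-3))
    e = energy(x)

    acc = np.zeros(len(centers))
    tune_block = 200
    for it in range(burn_in):
        x, e, accepted = _metropolis_step(x, e, step, energy, beta, lo, hi, rng)
        acc += accepted
        if (it + 1) % tune_block == 0:
            rate = acc / tune_block
            step = np.where(rate < 0.3, step * 0.7, step)
            step = np.where(rate > 0.6, step * 1.4, step)
            acc[:] = 0.0

    n_keep = n_samples
    out = np.empty((n_keep, len(centers)))
    acc[:] = 0.0
    total = 0
    for i in range(n_keep):
        for _ in range(thin):
            x, e, accepted = _metropolis_step(x, e, step, energy, beta, lo, hi, rng)
            acc += accepted
            total += 1
        out[i] = x
    rates = acc / total
    if np.any(rates <= 0):
        raise SamplerError(
            f"zero acceptance in windows {np.where(rates <= 0)[0].tolist()}"
        )
    logger.debug("umbrella sampler acceptance rates: %s", np.round(rates, 3))
    return [
        UmbrellaWindowSample(
            bias_center=float(c),
            bias_k=float(bias_k),
            samples=out[:, j],
            temperature=float(temperature),
            acceptance_rate=float(rates[j]),
        )
        for j, c in enumerate(centers)
    ]


def _metropolis_step(x, e, step, energy, beta, lo, hi, rng):
    prop = x + rng.normal(scale=step)
    # reflect into the domain
    span = hi - lo
    prop = np.where(prop < lo, 2 * lo - prop, prop)
    prop = np.where(prop > hi, 2 * hi - prop, prop)
    prop = np.clip(prop, lo, hi)  # guards pathological double reflection
    ep = energy(prop)
    accept = rng.random(len(x)) < np.exp(np.minimum(0.0, -beta * (ep - e)))
    return np.where(accept, prop, x), np.where(accept, ep, e), accept


# ---------------------------------------------------------------------------
# window file contract (plain text + JSON manifest)


def write_window_files(
    windows: Sequence[UmbrellaWindowSample], directory: str | Path, seed: int | None = None
) -> Path:
    """Write two-column sample files plus a JSON manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"windows": [], "seed": seed}
    for i, w in enumerate(windows):
        fname = f"window_{i:03d}.dat"
        with open(directory / fname, "w") as fh:
            fh.write("# index  reaction_coordinate_nm\n")
            for j, v in enumerate(w.samples):
                fh.write(f"{j:8d}  {v:.8f}\n")
        manifest["windows"].append(
            {
                "file": fname,
                "bias_center_nm": w.bias_center,
                "bias_k_kJ_mol_nm2": w.bias_k,
                "temperature_K": w.temperature,
                "acceptance_rate": w.acceptance_rate,
            }
        )
    mpath = directory / "windows.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return mpath


def read_window_files(manifest_path: str | Path) -> list[UmbrellaWindowSample]:
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    windows = []
    for w in manifest["windows"]:
        data = np.loadtxt(manifest_path.parent / w["file"])
        windows.append(
            UmbrellaWindowSample(
                bias_center=w["bias_center_nm"],
                bias_k=w["bias_k_kJ_mol_nm2"],
                samples=data[:, 1],
                temperature=w["temperature_K"],
                acceptance_rate=w.get("acceptance_rate", float("nan")),
            )
        )
    return windows
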