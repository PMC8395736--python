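"""Binding-site, contact and conformational analyses.

The binding site of a protein on the capped nanoparticle is the set of
residues whose backbone bead lies within a cutoff (default 0.45 nm,
minimum-image convention) of any nanoparticle bead — ligand or core.
Contact statistics are aggregated per residue type and per
physico-chemical class; conformational observables are the radius of
gyration, the per-residue RMSF about the window-mean structure after
Kabsch superposition, and the center-of-mass approach trace whose
three-phase structure (diffusion, first ligand contact, stable binding)
is segmented by an exact dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import CONTACT_CUTOFF
from .trajectory import (
    Frame,
    Topology,
    Trajectory,
    center_of_mass,
    minimum_image_displacement,
)

#: physico-chemical classes of the 20 canonical residues; configurable
#: through ResidueClassification (histidine and cysteine sit with the
#: structural residues here rather than with polar/charged)
DEFAULT_CLASSES = {
    "hydrophobic": frozenset("AFILMVWY"),
    "charged": frozenset("DEKR"),
    "polar": frozenset("STNQ"),
    "others": frozenset("GPCH"),
}


@dataclass(frozen=True)
class ResidueClassification:
    class_of: dict[str, str] = field(
        default_factory=lambda: {
            aa: cls for cls, members in DEFAULT_CLASSES.items() for aa in members
        }
    )

    def __post_init__(self):
        covered = set(self.class_of)
        if covered != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("classification must cover exactly the 20 canonical codes")

    @property
    def classes(self) -> list[str]:
        return list(dict.fromkeys(self.class_of.values()))


@dataclass(frozen=True)
class ContactConfig:
    cutoff: float = CONTACT_CUTOFF  # nm
    bead_roles_protein: tuple[str, ...] = ("backbone",)
    reference_frame: str = "last-frame"  # binding-site frame: last-frame | all-frames

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.reference_frame not in ("last-frame", "all-frames"):
            raise ValueError("reference_frame must be 'last-frame' or 'all-frames'")


@dataclass
class ContactProfile:
    per_residue_probability: dict[int, float]
    binding_site: frozenset[int]
    per_type_percentage: dict[str, float]
    per_class_percentage: dict[str, float] = field(default_factory=dict)


@dataclass
class SegmentationResult:
    """Optimal 3-segment piecewise-constant fit of an approach trace."""

    breakpoints: tuple[int, int]
    segment_means: tuple[float, float, float]
    sse: float
    degenerate: bool = False  # fewer than 3 genuinely distinct levels


# ---------------------------------------------------------------------------
# contacts


def contact_residues(
    frame: Frame,
    topology: Topology,
    np_selection: np.ndarray,
    protein_selection: np.ndarray | None = None,
    config: ContactConfig = ContactConfig(),
) -> frozenset[int]:
    """Residues whose selected protein bead touches any NP bead.

    Distances use the per-axis minimum-image convention; the search runs
    on a periodic KD-tree over coordinates wrapped into the box.
    """
    if protein_selection is None:
        protein_selection = ~np_selection
    prot = protein_selection & topology.select(role=config.bead_roles_protein)
    if not prot.any() or not np_selection.any():
        raise ValueError("empty protein or nanoparticle selection")
    if (prot & np_selection).any():
        raise ValueError("protein and nanoparticle selections overlap")
    box = frame.box
    p = np.mod(frame.positions[prot], box)
    q = np.mod(frame.positions[np_selection], box)
    # cKDTree with boxsize requires points strictly inside [0, box)
    p = np.where(p >= box, 0.0, p)
    q = np.where(q >= box, 0.0, q)
    tree = cKDTree(q, boxsize=box)
    dist, _ = tree.query(p, k=1)
    hit = dist < config.cutoff
    return frozenset(int(r) for r in topology.residue_id[prot][hit])


def contact_probability(
    traj: Trajectory,
    np_selection: np.ndarray,
    protein_selection: np.ndarray | None = None,
    config: ContactConfig = ContactConfig(),
) -> ContactProfile:
    """Per-residue contact fraction over frames plus binding-site makeup.

    The per-type percentages count residues of each type in the binding
    site (last frame by default) over the total binding-site size, as a
    percentage.
    """
    top = traj.topology
    if protein_selection is None:
        protein_selection = ~np_selection
    prot_res = np.unique(
        top.residue_id[protein_selection & top.select(role=config.bead_roles_protein)]
    )
    counts = {int(r): 0 for r in prot_res}
    for frame in traj.frames:
        for r in contact_residues(frame, top, np_selection, protein_selection, config):
            counts[r] += 1
    n = traj.n_frames
    prob = {r: c / n for r, c in counts.items()}

    if config.reference_frame == "last-frame":
        site = contact_residues(
            traj.frames[-1], top, np_selection, protein_selection, config
        )
    else:
        site = frozenset(r for r, c in counts.items() if c > 0)

    type_of = _residue_types(top, protein_selection)
    per_type: dict[str, float] = {}
    if site:
        for r in site:
            per_type[type_of[r]] = per_type.get(type_of[r], 0.0) + 1.0
        per_type = {t: 100.0 * c / len(site) for t, c in per_type.items()}
    return ContactProfile(
        per_residue_probability=prob,
        binding_site=site,
        per_type_percentage=per_type,
    )


def _residue_types(top: Topology, selection: np.ndarray) -> dict[int, str]:
    bb = selection & top.select(role="backbone")
    return {
        int(r): str(t) for r, t in zip(top.residue_id[bb], top.residue_type[bb])
    }


def average_profiles(profiles: list[ContactProfile]) -> ContactProfile:
    """Equal-weight average over replicas (probabilities and percentages)."""
    if not profiles:
        raise ValueError("no profiles to average")
    res = sorted({r for p in profiles for r in p.per_residue_probability})
    prob = {
        r: float(np.mean([p.per_residue_probability.get(r, 0.0) for p in profiles]))
        for r in res
    }
    types = sorted({t for p in profiles for t in p.per_type_percentage})
    per_type = {
        t: float(np.mean([p.per_type_percentage.get(t, 0.0) for p in profiles]))
        for t in types
    }
    site = frozenset().union(*[p.binding_site for p in profiles])
    return ContactProfile(prob, site, per_type)


def classify_site(
    profile: ContactProfile,
    classification: ResidueClassification = ResidueClassification(),
) -> dict[str, float]:
    """Aggregate per-type percentages into physico-chemical classes."""
    out = {cls: 0.0 for cls in classification.classes}
    for aa, pct in profile.per_type_percentage.items():
        try:
            out[classification.class_of[aa]] += pct
        except KeyError:
            raise ValueError(f"unknown residue code {aa!r}") from None
    profile.per_class_percentage = out
    return out


# ---------------------------------------------------------------------------
# center-of-mass approach trace and three-step segmentation


def com_rmsd_trace(
    traj: Trajectory,
    protein_selection: np.ndarray,
    reference: np.ndarray | None = None,
    np_selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame distance of the protein center of mass from a reference.

    The reference defaults to the nanoparticle center of mass of each
    frame (which is static for a fixed particle). This displacement
    trace is the observable whose plateaus mark the three adsorption
    steps.
    """
    top = traj.topology
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        com = center_of_mass(frame, top, protein_selection)
        if reference is not None:
            ref = np.asarray(reference, dtype=float)
        elif np_selection is not None:
            ref = center_of_mass(frame, top, np_selection)
        else:
            ref = frame.box / 2.0
        out[i] = np.linalg.norm(minimum_image_displacement(com, ref, frame.box))
    return out


def detect_three_steps(series: np.ndarray) -> SegmentationResult:
    """Exact optimal 3-segment piecewise-constant fit (dynamic programming).

    Minimizes the total squared error over both breakpoints by exhaustive
    prefix-sum search; ties prefer the lexicographically smallest
    ``(b1, b2)``. A breakpoint pair whose adjacent segment means are
    indistinguishable (within 1e-9 of the series scale) is flagged
    degenerate: the trace does not genuinely show three levels.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if n < 9:
        raise ValueError("need at least 9 frames for a three-segment fit")
    c1 = np.concatenate([[0.0], np.cumsum(y)])
    c2 = np.concatenate([[0.0], np.cumsum(y * y)])

    def sse(i: int, j: int) -> float:
        # segment cost on y[i:j]
        s, ss, m = c1[j] - c1[i], c2[j] - c2[i], j - i
        return ss - s * s / m

    # best single-segment cost for suffix y[b2:n] and all (b1, b2)
    best = (np.inf, 1, 2)
    for b1 in range(1, n - 1):
        left = sse(0, b1)
        if left >= best[0]:
            continue
        for b2 in range(b1 + 1, n):
            total = left + sse(b1, b2) + sse(b2, n)
            if total < best[0] - 1e-12:
                best = (total, b1, b2)
    total, b1, b2 = best
    means = (
        float((c1[b1] - c1[0]) / b1),
        float((c1[b2] - c1[b1]) / (b2 - b1)),
        float((c1[n] - c1[b2]) / (n - b2)),
    )
    scale = max(abs(y).max(), 1.0)
    degenerate = (
        abs(means[0] - means[1]) < 1e-9 * scale
        or abs(means[1] - means[2]) < 1e-9 * scale
    )
    return SegmentationResult(
        breakpoints=(b1, b2),
        segment_means=means,
        sse=float(max(total, 0.0)),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# superposition, RMSF, RMSD, radius of gyration


def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered coordinates P onto Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rigid-body least-squares fit of ``mobile`` onto ``target``."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    R = kabsch_rotation(mobile - cm, target - ct)
    return (mobile - cm) @ R.T + ct


def rmsd_to_reference(
    traj: Trajectory, selection: np.ndarray, reference: np.ndarray
) -> np.ndarray:
    """Conventional per-frame Kabsch RMSD of a selection to a reference."""
    out = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        fitted = superpose(frame.positions[selection], reference)
        out[i] = float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))
    return out


def rmsf(
    traj: Trajectory, selection: np.ndarray, window: int = 100
) -> dict[int, float]:
    """Per-residue RMSF over the last ``window`` frames.

    Each frame's selection is superposed (Kabsch) onto the window-mean
    structure — obtained by aligning to the last frame, averaging, and
    refitting once — and the fluctuation is the root-mean-square
    deviation of each backbone bead about its mean position.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    if window > traj.n_frames:
        raise ValueError("window longer than trajectory")
    frames = traj.frames[-window:]
    coords = np.array([f.positions[selection] for f in frames])
    ref = coords[-1]
    aligned = np.array([superpose(c, ref) for c in coords])
    mean = aligned.mean(axis=0)
    aligned = np.array([superpose(c, mean) for c in coords])
    mean = aligned.mean(axis=0)
    per_bead = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))
    res = traj.topology.residue_id[selection]
    return {int(r): float(v) for r, v in zip(res, per_bead)}


def radius_of_gyration(
    frame: Frame, topology: Topology, selection: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration of a selection, nm."""
    if selection is None:
        selection = np.ones(topology.n_beads, dtype=bool)
    m = topology.mass[selection]
    if m.size == 0:
        raise ValueError("empty selection")
    r = frame.positions[selection]
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((r - com) ** 2).sum(axis=1)).sum() / m.sum()))
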