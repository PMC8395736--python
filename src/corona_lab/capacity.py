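"""Maximum adsorption capacity of a capped nanoparticle.

The surface-based estimator defines the capacity as the ratio between
the solvent-accessible surface area of the ligand-capped nanoparticle
and the protein surface buried by a single adsorption event:

    N_max = SASA(ligands+NP) / ΔSASA,      ΔSASA = SASA_initial − SASA_final

which accounts for protein shape, conformational adaptation and ligand
displacement. Three geometric literature estimators are shipped for
comparison as labeled presets of two families — a shell-area family,

    N = f · 4 (R_NP + R_p)² / R_p²,

counting protein-sized disks on the sphere through the protein centers,
and a core-area family, N = f · 4 R_NP² / R_p², with packing fraction f.
The presets are reconstructions of the cited estimators (their exact
algebra is not restated here) and are meant for order-of-magnitude
comparison, not exact reproduction.

Counts use the floor convention: a fractional protein cannot adsorb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: method presets: (family, packing fraction)
GEOMETRIC_PRESETS: dict[str, tuple[str, float]] = {
    "wang": ("core-area", 1.0),
    "calzolai": ("shell-area", 1.0),
    "dellorco": ("shell-area", 0.93),
}

#: capped-NP radius used by the geometric methods: half the 4.3 nm
#: ligand-inclusive diameter of the 2.2 nm core
DEFAULT_NP_RADIUS = 2.15


class UndefinedCapacityError(ValueError):
    """ΔSASA is not positive: the ratio has no physical meaning."""


@dataclass(frozen=True)
class ProteinGeometry:
    """Size descriptors of one protein: mass, R_g and two principal radii."""

    name: str
    mass: float  # kDa
    r_g: float  # nm
    radius_1: float  # nm, smaller
    radius_2: float  # nm, bigger

    def __post_init__(self):
        if min(self.mass, self.r_g, self.radius_1, self.radius_2) <= 0:
            raise ValueError("all protein size descriptors must be positive")
        if self.radius_1 > self.radius_2:
            raise ValueError("radius_1 must not exceed radius_2")


#: the four abundant blood proteins used throughout as reference inputs
BLOOD_PROTEIN_GEOMETRIES = [
    ProteinGeometry("hemoglobin", mass=64.74, r_g=1.47, radius_1=2.70, radius_2=2.80),
    ProteinGeometry("serum_albumin", mass=133.14, r_g=2.64, radius_1=3.10, radius_2=3.65),
    ProteinGeometry("alpha1_antiproteinase", mass=44.38, r_g=2.16, radius_1=1.95, radius_2=3.00),
    ProteinGeometry("complement_c3", mass=185.69, r_g=4.59, radius_1=4.40, radius_2=6.65),
]


@dataclass(frozen=True)
class CapacityInputs:
    sasa_ligands_np: float  # nm^2
    delta_sasa: float  # nm^2

    def __post_init__(self):
        if self.sasa_ligands_np <= 0:
            raise ValueError("nanoparticle SASA must be positive")


def _count(raw: float, rounding: str) -> int:
    if rounding == "floor":
        return math.floor(raw)
    if rounding == "nearest":
        return round(raw)
    if rounding == "ceiling":
        return math.ceil(raw)
    raise ValueError(f"unknown rounding {rounding!r}")


def nmax_sasa(inputs: CapacityInputs, rounding: str = "floor") -> tuple[int, float]:
    """Surface-based capacity: (count, raw ratio)."""
    if inputs.delta_sasa <= 0:
        raise UndefinedCapacityError(
            f"ΔSASA = {inputs.delta_sasa:.3f} nm² must be positive"
        )
    raw = inputs.sasa_ligands_np / inputs.delta_sasa
    return _count(raw, rounding), raw


def nmax_geometric(
    method: str,
    np_radius: float = DEFAULT_NP_RADIUS,
    protein_radius: float = 1.0,
    packing_fraction: float | None = None,
    rounding: str = "floor",
) -> tuple[int, float]:
    """Geometric capacity for a method preset or bare family name.

    ``method`` is one of the presets (wang, calzolai, dellorco) or a
    family ("shell-area", "core-area"); an explicit ``packing_fraction``
    overrides the preset value.
    """
    if np_radius <= 0 or protein_radius <= 0:
        raise ValueError("radii must be positive")
    if method in GEOMETRIC_PRESETS:
        family, f = GEOMETRIC_PRESETS[method]
    elif method in ("shell-area", "core-area"):
        family, f = method, 1.0
    else:
        raise ValueError(f"unknown capacity method {method!r}")
    if packing_fraction is not None:
        f = packing_fraction
    if not 0 < f <= 1:
        raise ValueError("packing fraction must lie in (0, 1]")
    if family == "shell-area":
        raw = f * 4.0 * (np_radius + protein_radius) ** 2 / protein_radius**2
    else:
        raw = f * 4.0 * np_radius**2 / protein_radius**2
    return _count(raw, rounding), raw


def capacity_report(
    np_sasa: float,
    delta_sasa_per_protein: dict[str, float],
    geometries: list[ProteinGeometry],
    np_radius: float = DEFAULT_NP_RADIUS,
    rounding: str = "floor",
) -> pd.DataFrame:
    """Capacity table: one row per protein × method (and radius variant).

    The surface-based method uses each protein's ΔSASA; geometric
    methods are evaluated at both principal radii. Proteins with
    missing or non-positive ΔSASA keep their geometric rows and carry a
    flagged surface-based row rather than being dropped.
    """
    rows = []
    for g in geometries:
        dsasa = delta_sasa_per_protein.get(g.name)
        if dsasa is None or dsasa <= 0:
            rows.append(
                {
                    "protein": g.name, "method": "this_work", "radius_used_nm": None,
                    "mass_kDa": g.mass, "r_g_nm": g.r_g, "raw_ratio": None,
                    "n_max": None, "flag": "missing or non-positive ΔSASA",
                }
            )
        else:
            count, raw = nmax_sasa(CapacityInputs(np_sasa, dsasa), rounding)
            rows.append(
                {
                    "protein": g.name, "method": "this_work", "radius_used_nm": None,
                    "mass_kDa": g.mass, "r_g_nm": g.r_g, "raw_ratio": raw,
                    "n_max": count, "flag": "",
                }
            )
        for method in GEOMETRIC_PRESETS:
            for radius in (g.radius_1, g.radius_2):
                count, raw = nmax_geometric(
                    method, np_radius=np_radius, protein_radius=radius, rounding=rounding
                )
                rows.append(
                    {
                        "protein": g.name, "method": method, "radius_used_nm": radius,
                        "mass_kDa": g.mass, "r_g_nm": g.r_g, "raw_ratio": raw,
                        "n_max": count, "flag": "",
                    }
                )
    return pd.DataFrame(rows)
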