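"""End-to-end orchestration: build → simulate → analyze → sasa → capacity → pmf.

`run_pipeline` drives every stage of the synthetic corona study from a
single validated :class:`RunConfig`, writes per-stage tables (CSV) and
a combined JSON report, and is deterministic for a fixed seed: running
twice with the same config produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import (
    ContactConfig,
    ResidueClassification,
    classify_site,
    com_rmsd_trace,
    contact_probability,
    detect_three_steps,
    radius_of_gyration,
    rmsf,
)
from .capacity import CapacityInputs, GEOMETRIC_PRESETS, ProteinGeometry, capacity_report, nmax_sasa
from .constants import CONTACT_CUTOFF
from .nanobuilder import build_capped_np, export_structure, export_topology
from .pmf import WhamConfig, binding_strength, wham
from .sasa import SasaConfig, compute_sasa, delta_sasa
from .synthetic import (
    AdsorptionScenario,
    PotentialSpec,
    make_adsorption_trajectory,
    make_decoy_protein,
    sample_umbrella_windows,
    write_window_files,
)
from .trajectory import Frame, Trajectory, write_trajectory

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (caught before any stage runs)."""


@dataclass
class RunConfig:
    """All knobs of the demo pipeline; lengths in nm unless suffixed."""

    seed: int = 0
    out_dir: str = "corona_run"
    # nanoparticle
    np_diameter: float = 2.2
    n_ligands: int = 60
    # protein
    n_residues: int = 150
    # adsorption scenario
    phase_durations: tuple[int, int, int] = (50, 30, 120)
    diffusion_step_sigma: float = 0.25
    positional_noise_sigma: float = 0.05
    # analysis
    contact_cutoff: float = CONTACT_CUTOFF
    rmsf_window: int = 100
    # sasa
    probe_radius: float = 0.21
    n_sphere_points: int = 960
    # pmf
    well_depth_kj: float = 25.0
    well_location: float = 3.0
    well_width: float = 0.35
    n_windows: int = 16
    window_samples: int = 2000
    # None: derived from the window spacing so each window's thermal width
    # is half the spacing (guarantees histogram overlap)
    bias_k: float | None = None
    temperature: float = 320.0

    def validate(self) -> None:
        checks = [
            (self.np_diameter > 0, "np_diameter must be positive"),
            (self.n_ligands >= 0, "n_ligands must be non-negative"),
            (self.n_residues >= 1, "n_residues must be >= 1"),
            (all(d >= 1 for d in self.phase_durations), "phase durations must be >= 1"),
            (self.contact_cutoff > 0, "contact_cutoff must be positive"),
            (self.rmsf_window >= 2, "rmsf_window must be >= 2"),
            (self.rmsf_window <= sum(self.phase_durations), "rmsf_window longer than trajectory"),
            (self.probe_radius >= 0, "probe_radius must be non-negative"),
            (self.n_sphere_points >= 32, "n_sphere_points must be >= 32"),
            (self.well_depth_kj > 0, "well_depth_kj must be positive"),
            (self.n_windows >= 2, "need at least two umbrella windows"),
            (self.window_samples >= 100, "window_samples must be >= 100"),
            (self.bias_k is None or self.bias_k > 0, "bias_k must be positive"),
            (self.temperature > 0, "temperature must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "phase_durations" in data:
            data["phase_durations"] = tuple(data["phase_durations"])
        return cls(**data)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer, np.bool_)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the combined report.

    Stage failures abort the run with the failing stage named; outputs of
    completed stages are left in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    stage = "init"
    t0 = _time.perf_counter()
    try:
        stage = "build-np"
        logger.info("stage %s", stage)
        np_model = build_capped_np(
            diameter=config.np_diameter, n_ligands=config.n_ligands, seed=config.seed
        )
        export_structure(np_model, out / "nanoparticle.gro")
        export_topology(np_model, out / "nanoparticle.top")
        report["nanoparticle"] = {
            "n_core_atoms": np_model.core.n_atoms,
            "core_diameter_nm": round(np_model.core.diameter, 6),
            "n_ligands": np_model.n_ligands,
            "max_radius_nm": round(np_model.max_radius(), 6),
        }

        stage = "make-decoy"
        logger.info("stage %s", stage)
        protein = make_decoy_protein(config.n_residues, seed=config.seed + 1)
        top_p, frame_p = protein

        stage = "simulate"
        logger.info("stage %s", stage)
        scenario = AdsorptionScenario(
            phase_durations=config.phase_durations,
            diffusion_step_sigma=config.diffusion_step_sigma,
            positional_noise_sigma=config.positional_noise_sigma,
            seed=config.seed + 2,
        )
        sim = make_adsorption_trajectory(
            protein, np_model, scenario, contact_cutoff=config.contact_cutoff
        )
        traj = sim.trajectory
        write_trajectory(traj, out / "adsorption.gro")

        stage = "analyze"
        logger.info("stage %s", stage)
        ccfg = ContactConfig(cutoff=config.contact_cutoff)
        profile = contact_probability(traj, sim.np_selection, sim.protein_selection, ccfg)
        classes = classify_site(profile, ResidueClassification())
        trace = com_rmsd_trace(traj, sim.protein_selection, np_selection=sim.np_selection)
        seg = detect_three_steps(trace)
        bb = sim.protein_selection & traj.topology.select(role="backbone")
        fluct = rmsf(traj, bb, window=min(config.rmsf_window, config.phase_durations[2]))
        rg_before = radius_of_gyration(frame_p, top_p)
        rg_after = radius_of_gyration(
            traj.frames[-1], traj.topology, sim.protein_selection
        )
        _dump_json(
            {
                "per_residue_probability": {
                    str(k): round(v, 6) for k, v in profile.per_residue_probability.items()
                },
                "binding_site": sorted(profile.binding_site),
                "per_type_percentage": {k: round(v, 4) for k, v in profile.per_type_percentage.items()},
                "per_class_percentage": {k: round(v, 4) for k, v in classes.items()},
            },
            out / "contacts.json",
        )
        report["contacts"] = {
            "binding_site": sorted(profile.binding_site),
            "designated_patch": sorted(sim.bound_patch),
            "per_class_percentage": {k: round(v, 4) for k, v in classes.items()},
        }
        report["segmentation"] = {
            "breakpoints": list(seg.breakpoints),
            "true_breakpoints": list(sim.breakpoints),
            "segment_means_nm": [round(m, 4) for m in seg.segment_means],
            "degenerate": seg.degenerate,
        }
        report["conformation"] = {
            "rg_before_nm": round(rg_before, 6),
            "rg_after_nm": round(rg_after, 6),
            "rmsf_mean_nm": round(float(np.mean(list(fluct.values()))), 6),
        }
        with open(out / "rmsf.csv", "w") as fh:
            fh.write("residue_id,rmsf_nm\n")
            for r in sorted(fluct):
                fh.write(f"{r},{fluct[r]:.6f}\n")

        stage = "sasa"
        logger.info("stage %s", stage)
        scfg = SasaConfig(
            probe_radius=config.probe_radius, n_sphere_points=config.n_sphere_points
        )
        sasa_free = compute_sasa(frame_p, top_p, config=scfg, label="free protein")
        sasa_bound = compute_sasa(
            traj.frames[-1],
            traj.topology,
            selection=sim.protein_selection,
            config=scfg,
            label="protein in complex",
        )
        np_top, np_frame = np_model.to_topology_frame()
        sasa_np = compute_sasa(np_frame, np_top, config=scfg, label="capped NP")
        dsasa = delta_sasa(sasa_free, sasa_bound)
        report["sasa"] = {
            "protein_initial_nm2": round(sasa_free.total, 4),
            "protein_final_nm2": round(sasa_bound.total, 4),
            "delta_nm2": round(dsasa, 4),
            "ligands_np_nm2": round(sasa_np.total, 4),
        }

        stage = "capacity"
        logger.info("stage %s", stage)
        # decoy geometry measured from the structure itself
        half_extent = 0.5 * float(
            np.linalg.norm(
                frame_p.positions[:, None, :] - frame_p.positions[None, :, :], axis=-1
            ).max()
        )
        geom = ProteinGeometry(
            "decoy",
            mass=top_p.mass.sum() / 1000.0,
            r_g=rg_before,
            radius_1=half_extent,
            radius_2=half_extent,
        )
        table = capacity_report(
            sasa_np.total, {"decoy": dsasa}, [geom], rounding="floor"
        )
        table.to_csv(out / "capacity.csv", index=False, float_format="%.6f")
        n_this, raw = nmax_sasa(CapacityInputs(sasa_np.total, dsasa))
        report["capacity"] = {
            "this_work": {"n_max": n_this, "raw_ratio": round(raw, 6)},
            **{
                m: {
                    "n_max": int(
                        table[(table.method == m) & (table.radius_used_nm == geom.radius_1)]
                        .n_max.iloc[0]
                    )
                }
                for m in GEOMETRIC_PRESETS
            },
        }

        stage = "pmf"
        logger.info("stage %s", stage)
        potential = PotentialSpec(
            "morse-like",
            {
                "depth": config.well_depth_kj,
                "x0": config.well_location,
                "width": config.well_width,
            },
            domain=(config.well_location - 1.0, config.well_location + 3.0),
        )
        centers = np.linspace(*potential.domain, config.n_windows)
        if config.bias_k is None:
            from .constants import KB

            spacing = centers[1] - centers[0]
            bias_k = 4.0 * KB * config.temperature / spacing**2
        else:
            bias_k = config.bias_k
        windows = sample_umbrella_windows(
            potential,
            centers,
            bias_k=bias_k,
            n_samples=config.window_samples,
            temperature=config.temperature,
            seed=config.seed + 3,
        )
        write_window_files(windows, out / "windows", seed=config.seed + 3)
        edges = np.linspace(*potential.domain, 121)
        prof = wham(windows, WhamConfig(bin_edges=edges, temperature=config.temperature))
        unbound = (potential.domain[1] - 0.6, potential.domain[1])
        strength = binding_strength(prof, unbound)
        with open(out / "pmf.csv", "w") as fh:
            fh.write("bin_center_nm,free_energy_kj_mol\n")
            for c, v in zip(prof.bin_centers, prof.free_energy):
                fh.write(f"{c:.6f},{v:.6f}\n" if np.isfinite(v) else f"{c:.6f},nan\n")
        report["pmf"] = {
            "converged": prof.converged,
            "n_iterations": prof.n_iterations,
            "binding_strength_kcal_mol": round(strength, 4),
            "true_well_depth_kcal_mol": round(-config.well_depth_kj / 4.184, 4),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    elapsed = _time.perf_counter() - t0
    logger.info("pipeline complete in %.1f s", elapsed)
    cfg = asdict(config)
    cfg["phase_durations"] = list(cfg["phase_durations"])
    cfg.pop("out_dir")  # the manifest already lives in the output directory
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
    }
    _dump_json(manifest, out / "manifest.json")
    _dump_json(report, out / "report.json")
    return report
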