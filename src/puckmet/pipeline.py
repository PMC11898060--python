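"""End-to-end orchestration: simulate -> fes -> grnr -> mfep -> cvs -> sasa.

A run is described by a structured YAML config (see ``RunConfig``); each
requested stage writes its table into the output directory, a combined
``summary.json`` collects the headline numbers, and a ``MANIFEST`` lists
the stages that completed so partial runs stay inspectable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fes as fesmod
from . import mfep as mfepmod
from .ring import PartitionSpec, PuckerCoords, classify_conformer, is_reactive
from .synthetic import (
    GaussianPotential2D,
    SamplerParams,
    default_axes,
    double_well_potential,
    sample_wt_metad,
)

SUMMARY_SCHEMA_VERSION = 1

KNOWN_STAGES = ("simulate", "fes", "grnr", "mfep", "cvs", "sasa")


@dataclass
class RunConfig:
    """Validated settings for a pipeline run."""

    stages: list
    outdir: Path
    seed: int = 0
    hills_file: str | None = None
    simulate: dict = field(default_factory=dict)
    grid: dict = field(default_factory=lambda: {"n_phi": 144, "n_theta": 72})
    dialect: str = "tempered"
    average_tail: bool = True
    kT: float = fesmod.KT_300K
    grnr_mode: str = "boltzmann"
    partition: dict | None = None
    mfep: dict = field(default_factory=dict)
    cvs: dict = field(default_factory=dict)
    sasa: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.stages:
            raise ValueError("config must request at least one stage")
        unknown = set(self.stages) - set(KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.dialect not in ("tempered", "scaled"):
            raise ValueError("dialect must be 'tempered' or 'scaled'")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def partition_spec(self) -> PartitionSpec:
        if not self.partition:
            return PartitionSpec()
        return PartitionSpec(
            phi_knots=np.asarray(self.partition["phi_knots"], dtype=float),
            theta_knots=np.asarray(self.partition["theta_knots"], dtype=float),
            inclusive_side=self.partition.get("inclusive_side", "nonreactive"),
        )


def _potential_from_config(cfg: dict):
    kind = cfg.get("potential", "double_well")
    if kind == "double_well":
        return double_well_potential(asymmetry=float(cfg.get("asymmetry", 0.0)))
    if kind == "gaussians":
        return GaussianPotential2D(
            centers=cfg["centers"], widths=cfg["widths"], amplitudes=cfg["amplitudes"]
        )
    raise ValueError(f"unknown potential kind {kind!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the summary."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "dialect": config.dialect,
        "kT_kcal_mol": config.kT,
    }
    manifest = out / "MANIFEST"

    def checkpoint(stage: str):
        completed.append(stage)
        manifest.write_text("\n".join(completed) + "\n")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)

    hills = None
    if "simulate" in config.stages:
        sim = dict(config.simulate)
        potential = _potential_from_config(sim)
        params = SamplerParams(
            seed=int(sim.get("seed", config.seed)),
            n_steps=int(sim.get("n_steps", 200_000)),
            dt=float(sim.get("dt", 0.002)),
            pace=int(sim.get("pace", 75)),
            hill_height=float(sim.get("hill_height", 0.75)),
            hill_widths=tuple(sim.get("hill_widths", (0.1, 0.1))),
            bias_factor=float(sim.get("bias_factor", 15.0)),
            stop_threshold=float(sim.get("stop_threshold", 14.0)),
            start=tuple(sim["start"]) if "start" in sim else None,
        )
        traj, hills = sample_wt_metad(potential, params)
        fesmod.write_hills(hills, out / "HILLS")
        np.savetxt(out / "trajectory.tsv", traj, header="phi theta", comments="# ")
        summary["simulate"] = {"n_hills": len(hills), "n_recorded": len(traj),
                               "seed": params.seed}
        checkpoint("simulate")

    fes = None
    spec = config.partition_spec()
    if "fes" in config.stages:
        if hills is None:
            if not config.hills_file:
                raise ValueError("fes stage needs either a simulate stage or hills_file")
            hills = fesmod.read_hills(config.hills_file)
        axes = default_axes(int(config.grid["n_phi"]), int(config.grid["n_theta"]))
        if config.average_tail:
            fes = fesmod.reconstruct_fes_averaged(hills, axes, config.dialect)
        else:
            fes = fesmod.reconstruct_fes(hills, axes, config.dialect)
        fesmod.write_fes(fes, out / "fes.dat")
        report = fesmod.convergence_report(hills, axes, config.dialect)
        summary["fes"] = {
            "n_hills": len(hills),
            "fes_range_kcal_mol": float(fes.values.max()),
            "convergence": report,
        }
        # global minimum and its conformer, in puckering terms
        i, j = np.unravel_index(int(np.argmin(fes.values)), fes.values.shape)
        phi_deg = math.degrees(fes.axes[0].nodes[i]) % 360.0
        theta_deg = math.degrees(fes.axes[1].nodes[j])
        p = PuckerCoords(Q=0.55, theta=theta_deg, phi=phi_deg)
        summary["fes"]["global_minimum"] = {
            "phi_deg": phi_deg,
            "theta_deg": theta_deg,
            "conformer": classify_conformer(p).label,
            "reactive": is_reactive(p, spec),
        }
        checkpoint("fes")

    if "grnr" in config.stages:
        if fes is None:
            raise ValueError("grnr stage requires the fes stage")
        summary["grnr"] = {
            "boltzmann_kcal_mol": fesmod.delta_g_rnr(fes, spec, config.kT, "boltzmann"),
            "minimum_kcal_mol": fesmod.delta_g_rnr(fes, spec, config.kT, "minimum"),
            "mode": config.grnr_mode,
            "partition_boundary_theta_deg": [float(t) for t in spec.theta_knots],
        }
        checkpoint("grnr")

    if "mfep" in config.stages:
        if fes is None:
            raise ValueError("mfep stage requires the fes stage")
        mcfg = dict(config.mfep)
        depth = float(mcfg.get("depth_threshold", 1.0))
        basins = mfepmod.find_minima(fes, depth_threshold=depth)
        if "start" in mcfg and "end" in mcfg:
            start, end = tuple(mcfg["start"]), tuple(mcfg["end"])
        else:
            if len(basins) < 2:
                raise ValueError("fewer than two basins; give explicit mfep start/end nodes")
            start, end = basins[0].node, basins[1].node
        path = mfepmod.find_mfep(fes, start, end)
        dg_act, dg_rxn, ts = mfepmod.barrier_and_reaction_energy(path)
        mfepmod.write_path(path, out / "mfep.tsv",
                           cv_names=(fes.axes[0].name, fes.axes[1].name))
        summary["mfep"] = {
            "n_basins": len(basins),
            "start": list(start),
            "end": list(end),
            "barrier_kcal_mol": dg_act,
            "reaction_free_energy_kcal_mol": dg_rxn,
            "ts_node_index": ts,
            "ts_uncertainty_nodes": 1,
        }
        checkpoint("mfep")

    if "cvs" in config.stages:
        from .geometry import CatalyticSelection, analyze_structure

        ccfg = dict(config.cvs)
        sel = (CatalyticSelection.from_yaml(ccfg["selection_file"])
               if "selection_file" in ccfg else None)
        table = analyze_structure(ccfg["structure"], sel)
        table.to_csv(out / "cvs.tsv", sep="\t", index=False)
        summary["cvs"] = {
            "n_frames": int(len(table)),
            "cv1_mean": float(table["cv1"].mean()),
            "cv2_mean": float(table["cv2"].mean()),
        }
        checkpoint("cvs")

    if "sasa" in config.stages:
        from .sasa import atomset_from_pdb, spi

        scfg = dict(config.sasa)
        atoms = atomset_from_pdb(
            scfg["structure"], scfg["substrate_sel"], scfg["pocket_sel"],
            united_atom=bool(scfg.get("united_atom", False)),
        )
        result = spi(atoms, probe=float(scfg.get("probe", 1.4)),
                     n_points=int(scfg.get("points", 960)))
        summary["sasa"] = {
            "sasa_sub_A2": result.sasa_sub,
            "sasa_pkt_A2": result.sasa_pkt,
            "spi": result.spi,
        }
        checkpoint("sasa")

    return summary
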