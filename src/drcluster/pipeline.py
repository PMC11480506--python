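"""End-to-end orchestration: generate -> analyze -> fit, with a manifest.

A run configuration is a YAML mapping of per-stage blocks (``system``,
``simulate``, ``contacts``, ``clusters``, ``frap``, ``massfit``,
``binding``) plus global ``seed``, ``out`` and ``log_level`` keys.  Unknown
keys are rejected.  Outputs are written beside a manifest recording inputs,
parameters, seed, package version and SHA-256 checksums, so identical
config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .contacts import (
    ContactParams,
    beads_to_residues,
    central_chain_matrix,
    intra_chain_matrix,
    project_1d,
    two_chain_matrix,
)
from .clusters import cluster_kinetics, mixing_stats
from .dynamics import simulate
from .experiments import BindingCurve, FrapTraces, MassSample, synth_binding, synth_frap, synth_masses
from .fits import fit_binding, fit_frap, fit_mass_distribution
from .io import read_topology, read_xyz, write_topology, write_xyz
from .regions import builtin_regions
from .system import SystemConfig, build_system
from .topology import ChainTopology

log = logging.getLogger("drcluster")

_GLOBAL_KEYS = {"seed", "out", "log_level"}
_STAGE_KEYS = {"system", "simulate", "contacts", "clusters", "frap", "massfit", "binding"}

_STAGE_FIELDS = {
    "system": {"box_edge", "species", "salt_mM", "temperature", "chi"},
    "simulate": {"n_steps", "dt_ns", "save_every", "schedule"},
    "contacts": {"cutoff", "chain_threshold", "intra_exclusion", "mode", "stride"},
    "clusters": {"chain_threshold", "cutoff"},
    "frap": {"traces_csv", "mobile_fraction", "t_half_s", "noise_sd", "w_um",
             "no_offset", "n_frames", "frame_interval_s"},
    "massfit": {"events_csv", "components", "monomer_kda", "synthetic"},
    "binding": {"curve_csv", "kd_um", "noise_sd"},
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    out: str = "drcluster_out"
    log_level: str = "INFO"
    stages: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _GLOBAL_KEYS - _STAGE_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        stages = {}
        for name in _STAGE_KEYS & set(raw):
            block = raw[name] or {}
            bad = set(block) - _STAGE_FIELDS[name]
            if bad:
                raise ConfigError(f"unknown keys in {name!r} block: {sorted(bad)}")
            stages[name] = block
        return cls(
            seed=int(raw.get("seed", 0)),
            out=str(raw.get("out", "drcluster_out")),
            log_level=str(raw.get("log_level", "INFO")),
            stages=stages,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_config_from_block(block: dict, seed: int) -> SystemConfig:
    regions = builtin_regions()
    species = []
    for item in block.get("species", [{"region": "DR2", "copies": 33}]):
        name = item["region"]
        top = ChainTopology.from_region(regions[name])
        species.append((top, int(item["copies"])))
    cfg = SystemConfig(
        box_edge=float(block.get("box_edge", 30.0)),
        species=tuple(species),
        salt_mM=float(block.get("salt_mM", 150.0)),
        temperature=float(block.get("temperature", 300.0)),
        seed=seed,
    )
    if "chi" in block:
        cfg = cfg.with_chi(float(block["chi"]))
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    outputs: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {"stages": config.stages, "out": config.out},
        "outputs": outputs,
    }
    traj = None
    try:
        if "system" in config.stages:
            stage = "system"
            sys_cfg = _build_config_from_block(config.stages["system"], config.seed)
            frame = build_system(sys_cfg)
            sim_block = config.stages.get("simulate", {})
            traj = simulate(
                frame,
                n_steps=int(sim_block.get("n_steps", 0)),
                dt_ns=float(sim_block.get("dt_ns", 0.002)),
                save_every=int(sim_block.get("save_every", 100)),
                seed=config.seed,
                schedule=sim_block.get("schedule"),
            )
            write_topology(frame.system, out / "topology.txt")
            write_xyz(traj, out / "trajectory.xyz")
            outputs["topology"] = "topology.txt"
            outputs["trajectory"] = "trajectory.xyz"
        if "contacts" in config.stages:
            stage = "contacts"
            if traj is None:
                raise RuntimeError("contacts stage requires a system/simulate stage")
            block = config.stages["contacts"]
            params = ContactParams(
                cutoff=float(block.get("cutoff", 0.5)),
                chain_threshold=int(block.get("chain_threshold", 1)),
                intra_exclusion=int(block.get("intra_exclusion", 3)),
                stride=int(block.get("stride", 1)),
            )
            mode = block.get("mode", "central")
            if mode == "central":
                m = central_chain_matrix(traj, params)
            elif mode == "pair":
                m = two_chain_matrix(traj, params)
            elif mode == "intra":
                m = intra_chain_matrix(traj, params)
            else:
                raise ConfigError(f"unknown contacts mode {mode!r}")
            top = traj.system.chain_topology[0]
            res = beads_to_residues(m, top)
            m.to_tsv(out / "contact_matrix_bead.tsv")
            res.to_tsv(out / "contact_matrix_residue.tsv")
            prof = project_1d(res)
            with open(out / "contact_profile.tsv", "w") as fh:
                fh.write("residue\tscore\n")
                for i, s in enumerate(prof, start=1):
                    fh.write(f"{i}\t{s:.6g}\n")
            outputs["contact_matrix_bead"] = "contact_matrix_bead.tsv"
            outputs["contact_matrix_residue"] = "contact_matrix_residue.tsv"
            outputs["contact_profile"] = "contact_profile.tsv"
        if "clusters" in config.stages:
            stage = "clusters"
            if traj is None:
                raise RuntimeError("clusters stage requires a system/simulate stage")
            block = config.stages["clusters"]
            params = ContactParams(
                cutoff=float(block.get("cutoff", 0.5)),
                chain_threshold=int(block.get("chain_threshold", 1)),
            )
            kin = cluster_kinetics(traj, params)
            with open(out / "cluster_kinetics.csv", "w") as fh:
                fh.write("frame,time_ns,largest_cluster,n_clusters\n")
                for i, (t, lc, nc) in enumerate(
                    zip(kin.times, kin.largest_cluster, kin.n_clusters)
                ):
                    fh.write(f"{i},{t},{lc},{nc}\n")
            with open(out / "cluster_events.csv", "w") as fh:
                fh.write("chain,frame,event\n")
                for c, f in kin.join_events:
                    fh.write(f"{c},{f},join\n")
                for c, f in kin.leave_events:
                    fh.write(f"{c},{f},leave\n")
            outputs["cluster_kinetics"] = "cluster_kinetics.csv"
            outputs["cluster_events"] = "cluster_events.csv"
            if len(set(traj.system.chain_species)) >= 2:
                mix = mixing_stats(traj, params)
                (out / "mixing.json").write_text(
                    json.dumps(dataclasses.asdict(mix), indent=1)
                )
                outputs["mixing"] = "mixing.json"
        if "frap" in config.stages:
            stage = "frap"
            block = config.stages["frap"]
            if "traces_csv" in block:
                traces = FrapTraces.from_csv(block["traces_csv"])
            else:
                traces = synth_frap(
                    mobile_fraction=float(block.get("mobile_fraction", 0.82)),
                    t_half_s=float(block.get("t_half_s", 169.0)),
                    frame_interval_s=float(block.get("frame_interval_s", 5.0)),
                    n_frames=int(block.get("n_frames", 122)),
                    noise_sd=float(block.get("noise_sd", 0.0)),
                    w_um=float(block.get("w_um", 2.0)),
                    seed=config.seed,
                )
            fit = fit_frap(traces, no_offset=bool(block.get("no_offset", True)), with_d=True)
            (out / "frap_fit.json").write_text(
                json.dumps(
                    {
                        "mobile_fraction": fit.mobile_fraction,
                        "t_half_s": fit.t_half_s,
                        "k_per_s": fit.k,
                        "plateau": fit.plateau,
                        "d_um2_s": fit.d_um2_s,
                        "rss": fit.rss,
                        "converged": fit.converged,
                    },
                    indent=1,
                )
            )
            outputs["frap_fit"] = "frap_fit.json"
        if "massfit" in config.stages:
            stage = "massfit"
            block = config.stages["massfit"]
            if "events_csv" in block:
                sample = MassSample.from_csv(block["events_csv"])
            else:
                spec = block.get("synthetic", {"components": [[135, 67, 1.0]]})
                sample = synth_masses(
                    [tuple(c) for c in spec["components"]],
                    n_events=int(spec.get("n_events", 5000)),
                    seed=config.seed,
                )
            fit = fit_mass_distribution(
                sample,
                n_components=int(block.get("components", 1)),
                monomer_kda=block.get("monomer_kda"),
            )
            (out / "mass_fit.json").write_text(
                json.dumps(
                    {
                        "components": [dataclasses.asdict(c) for c in fit.components],
                        "degenerate": fit.degenerate,
                    },
                    indent=1,
                )
            )
            outputs["mass_fit"] = "mass_fit.json"
        if "binding" in config.stages:
            stage = "binding"
            block = config.stages["binding"]
            if "curve_csv" in block:
                curve = BindingCurve.from_csv(block["curve_csv"])
            else:
                curve = synth_binding(
                    kd_um=float(block.get("kd_um", 2.0)),
                    noise_sd=float(block.get("noise_sd", 0.0)),
                    seed=config.seed,
                )
            fit = fit_binding(curve)
            (out / "binding_fit.json").write_text(
                json.dumps(
                    {
                        "kd_um": fit.kd_um,
                        "r0": fit.r0,
                        "r_max": fit.r_max,
                        "rss": fit.rss,
                        "flagged": fit.flagged,
                    },
                    indent=1,
                )
            )
            outputs["binding_fit"] = "binding_fit.json"
    except Exception as exc:  # noqa: BLE001 — abort naming the failing stage
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        if isinstance(exc, (ConfigError,)):
            raise
        raise StageError(stage, exc) from exc

    manifest["checksums"] = {
        name: _sha256(out / rel) for name, rel in outputs.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Report-only validation of input files by expected kind.

    ``paths`` maps kind (``frap`` | ``masses`` | ``binding`` |
    ``trajectory`` — the latter as ``(xyz, topology)``) to file paths.
    Returns a list of human-readable problems; empty means valid.
    """
    import pandas as pd

    report: list[str] = []
    for kind, path in paths.items():
        try:
            if kind == "frap":
                df = pd.read_csv(path)
                missing = {"time_s", "frap", "reference", "background"} - set(df.columns)
                if missing:
                    report.append(f"{path}: FRAP CSV missing columns {sorted(missing)}")
            elif kind == "masses":
                df = pd.read_csv(path)
                if "mass_kda" not in df.columns:
                    report.append(f"{path}: mass CSV missing 'mass_kda' column")
            elif kind == "binding":
                df = pd.read_csv(path)
                missing = {"concentration_um", "anisotropy"} - set(df.columns)
                if missing:
                    report.append(f"{path}: binding CSV missing columns {sorted(missing)}")
            elif kind == "trajectory":
                xyz_path, top_path = path
                cfg = read_topology(top_path)
                try:
                    read_xyz(xyz_path, cfg)
                except ValueError as exc:
                    report.append(f"{xyz_path}: {exc}")
            else:
                report.append(f"unknown input kind {kind!r}")
        except FileNotFoundError:
            report.append(f"{path}: file not found")
        except Exception as exc:  # noqa: BLE001
            report.append(f"{path}: unreadable ({exc})")
    return report
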