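"""Plain-text trajectory and topology I/O.

Trajectories are stored as an XYZ dialect: per frame a bead-count line, a
comment line ``time=<ns> box=<nm>``, then one ``<bead-type> x y z`` line per
bead.  Chain bookkeeping travels in a separate key-value topology sidecar
(species blocks with sequence, beads per residue and copy number) from
which the System is rebuilt on read.  A single-frame GRO export is provided
for visualization.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .system import Frame, System, SystemConfig, Trajectory
from .topology import ChainTopology


def write_topology(system: System, path: str | Path) -> None:
    cfg = system.config
    lines = [
        "# drcluster topology v1",
        f"box_edge {cfg.box_edge}",
        f"salt_mM {cfg.salt_mM}",
        f"temperature {cfg.temperature}",
    ]
    for top, copies in cfg.species:
        lines += [
            f"species {top.species}",
            f"sequence {top.sequence}",
            f"beads_per_residue {top.beads_per_residue}",
            f"copies {copies}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_topology(path: str | Path) -> SystemConfig:
    box = salt = temp = None
    species: list[tuple[ChainTopology, int]] = []
    current: dict = {}

    def flush():
        if current:
            top = ChainTopology.from_sequence(
                current["species"],
                current["sequence"],
                int(current.get("beads_per_residue", 1)),
            )
            species.append((top, int(current["copies"])))

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(" ")
        if key == "species":
            flush()
            current = {"species": value}
        elif key in ("sequence", "beads_per_residue", "copies"):
            current[key] = value
        elif key == "box_edge":
            box = float(value)
        elif key == "salt_mM":
            salt = float(value)
        elif key == "temperature":
            temp = float(value)
        else:
            raise ValueError(f"unknown topology key {key!r}")
    flush()
    if box is None:
        raise ValueError("topology file missing box_edge")
    return SystemConfig(
        box_edge=box,
        species=tuple(species),
        salt_mM=salt if salt is not None else 150.0,
        temperature=temp if temp is not None else 300.0,
    )


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    sys_ = traj.system
    names = []
    for top in sys_.chain_topology:
        names.extend(top.bead_type)
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{sys_.n_beads}\n")
            fh.write(f"time={traj.times[i]:.6f} box={sys_.config.box_edge:.6f}\n")
            for name, (x, y, z) in zip(names, traj.coords[i]):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, config: SystemConfig) -> Trajectory:
    system = System.from_config(config)
    frames, times = [], []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            if n != system.n_beads:
                raise ValueError(
                    f"trajectory frame has {n} beads, topology expects "
                    f"{system.n_beads}"
                )
            comment = fh.readline().split()
            meta = dict(tok.split("=") for tok in comment if "=" in tok)
            t = float(meta.get("time", len(times)))
            box = float(meta.get("box", config.box_edge))
            if abs(box - config.box_edge) > 1e-6:
                raise ValueError("frame box does not match topology box")
            coords = np.empty((n, 3))
            for b in range(n):
                parts = fh.readline().split()
                coords[b] = [float(v) for v in parts[1:4]]
            frames.append(coords)
            times.append(t)
    return Trajectory(
        system=system,
        coords=np.asarray(frames),
        times=np.asarray(times),
        provenance={"source": str(path)},
    )


def write_gro(frame: Frame, path: str | Path, title: str = "drcluster frame") -> None:
    """Single-frame GRO export (nm) for visualization."""
    sys_ = frame.system
    with open(path, "w") as fh:
        fh.write(f"{title}, t= {frame.time:.3f}\n")
        fh.write(f"{sys_.n_beads}\n")
        for b in range(sys_.n_beads):
            chain = sys_.bead_chain[b]
            res = sys_.bead_residue[b] + 1
            top = sys_.chain_topology[chain]
            resname = top.sequence[sys_.bead_residue[b]] + "XX"
            atname = top.bead_type[sys_.bead_slot[b]][:5].replace("-", "")
            x, y, z = frame.coords[b]
            fh.write(
                f"{res % 100000:5d}{resname:<5s}{atname:>5s}{(b + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box:10.5f}{frame.box:10.5f}{frame.box:10.5f}\n")
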