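"""Multi-chain periodic systems: composition bookkeeping and initial packing.

The default conditions mirror the study setup: chains inserted at random
into a cubic 30 nm periodic box (33 copies of one region ≈ 2 mM, or 16 + 16
copies of two regions), 150 mM monovalent salt recorded as implicit-ion
bookkeeping, 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import Avogadro
from scipy.spatial import cKDTree

from .topology import ChainTopology

#: Default sticker-well depths (kJ/mol) by class-pair: opposite charges and
#: aromatic-aromatic attract, like charges and everything else are zero.
DEFAULT_EPS_SS: dict[tuple[str, str], float] = {
    ("negative", "positive"): 3.0,
    ("aromatic", "aromatic"): 3.0,
}


class PackingError(RuntimeError):
    """Raised when chains cannot be inserted into the requested box."""


@dataclass(frozen=True)
class InteractionParams:
    """Sticker-spacer pair potential parameters (nm, kJ/mol)."""

    eps_rep: float = 25.0      # soft-repulsion strength
    sigma: float = 0.47        # repulsion diameter
    r0: float = 0.50           # sticker well center
    delta: float = 0.12        # sticker well width
    eps_ss: dict = field(default_factory=lambda: dict(DEFAULT_EPS_SS))
    chi: float = 1.0           # crowding scale multiplying all well depths

    def __post_init__(self):
        if self.chi < 0:
            raise ValueError("chi must be >= 0")

    def eps_matrix(self) -> np.ndarray:
        """4x4 well-depth matrix indexed by sticker codes (0 = spacer)."""
        from .topology import STICKER_CODES

        m = np.zeros((4, 4))
        for (a, b), eps in self.eps_ss.items():
            i, j = STICKER_CODES[a], STICKER_CODES[b]
            m[i, j] = m[j, i] = eps
        return m


@dataclass(frozen=True)
class SystemConfig:
    """Box, composition and interaction parameters of one system."""

    box_edge: float                                  # nm, cubic periodic
    species: tuple[tuple[ChainTopology, int], ...]   # (topology, copies)
    salt_mM: float = 150.0
    temperature: float = 300.0                       # K
    seed: int = 0
    interactions: InteractionParams = field(default_factory=InteractionParams)

    def __post_init__(self):
        if self.box_edge <= 0:
            raise ValueError("box edge must be positive")
        for top, copies in self.species:
            if copies < 0:
                raise ValueError(f"negative copy number for {top.species}")

    @property
    def n_chains(self) -> int:
        return sum(c for _, c in self.species)

    def with_chi(self, chi: float) -> "SystemConfig":
        return replace(self, interactions=replace(self.interactions, chi=chi))


def concentration(n_chains: int, box_edge: float) -> float:
    """Molar concentration (mM) of ``n_chains`` solutes in a cubic box (nm)."""
    if box_edge <= 0:
        raise ValueError("box edge must be positive")
    if n_chains < 0:
        raise ValueError("chain count must be >= 0")
    litres = (box_edge * 1e-9) ** 3 * 1e3
    return n_chains / (Avogadro * litres) * 1e3


def ion_counts(box_edge: float, salt_mM: float, net_system_charge: int = 0) -> tuple[int, int]:
    """Implicit Na+/Cl- bookkeeping for a salt concentration plus minimal
    neutralization of the system's net charge."""
    if salt_mM < 0:
        raise ValueError("salt concentration must be >= 0")
    litres = (box_edge * 1e-9) ** 3 * 1e3
    n_salt = round(salt_mM * 1e-3 * Avogadro * litres)
    n_na, n_cl = n_salt, n_salt
    if net_system_charge > 0:
        n_cl += net_system_charge
    elif net_system_charge < 0:
        n_na += -net_system_charge
    if n_na < 0 or n_cl < 0:
        raise ValueError("neutralization would require a negative ion count")
    return n_na, n_cl


# ---------------------------------------------------------------------------
# System bookkeeping (per-bead arrays pooled over all chains)

@dataclass
class System:
    """Per-bead bookkeeping for all chains of a configured system."""

    config: SystemConfig
    chain_species: list[str]            # species name per chain
    chain_topology: list[ChainTopology]  # topology per chain (shared objects)
    bead_chain: np.ndarray              # chain id per bead
    bead_residue: np.ndarray            # residue index within chain (0-based)
    bead_slot: np.ndarray               # bead index within chain
    bead_sticker: np.ndarray            # sticker code per bead
    bead_charge: np.ndarray
    bonds: np.ndarray                   # (n_bonds, 2) global bead indices
    chain_start: np.ndarray             # first global bead index per chain

    @property
    def n_beads(self) -> int:
        return len(self.bead_chain)

    @property
    def n_chains(self) -> int:
        return len(self.chain_species)

    def beads_of_chain(self, chain: int) -> slice:
        start = self.chain_start[chain]
        return slice(start, start + self.chain_topology[chain].n_beads)

    @classmethod
    def from_config(cls, config: SystemConfig) -> "System":
        chain_species, chain_topology = [], []
        for top, copies in config.species:
            for _ in range(copies):
                chain_species.append(top.species)
                chain_topology.append(top)
        bead_chain, bead_residue, bead_slot = [], [], []
        stickers, charges, bonds, starts = [], [], [], []
        offset = 0
        for cid, top in enumerate(chain_topology):
            starts.append(offset)
            nb = top.n_beads
            bead_chain.append(np.full(nb, cid))
            bead_residue.append(top.bead_residue)
            bead_slot.append(np.arange(nb))
            stickers.append(top.bead_sticker)
            charges.append(top.bead_charge)
            bonds.append(top.bonds + offset)
            offset += nb
        return cls(
            config=config,
            chain_species=chain_species,
            chain_topology=chain_topology,
            bead_chain=np.concatenate(bead_chain) if bead_chain else np.zeros(0, int),
            bead_residue=np.concatenate(bead_residue) if bead_residue else np.zeros(0, int),
            bead_slot=np.concatenate(bead_slot) if bead_slot else np.zeros(0, int),
            bead_sticker=np.concatenate(stickers) if stickers else np.zeros(0, int),
            bead_charge=np.concatenate(charges) if charges else np.zeros(0, int),
            bonds=np.concatenate(bonds) if bonds else np.zeros((0, 2), int),
            chain_start=np.asarray(starts, dtype=np.int64),
        )

    @property
    def net_charge(self) -> int:
        return int(self.bead_charge.sum())

    def ion_bookkeeping(self) -> dict:
        n_na, n_cl = ion_counts(
            self.config.box_edge, self.config.salt_mM, self.net_charge
        )
        return {
            "salt_mM": self.config.salt_mM,
            "n_Na": n_na,
            "n_Cl": n_cl,
            "net_protein_charge": self.net_charge,
        }


@dataclass
class Frame:
    """Bead coordinates (nm, wrapped into [0, box)) at one time point."""

    system: System
    coords: np.ndarray          # (n_beads, 3)
    time: float = 0.0           # ns

    @property
    def box(self) -> float:
        return self.system.config.box_edge

    def wrapped(self) -> "Frame":
        return Frame(self.system, np.mod(self.coords, self.box), self.time)


@dataclass
class Trajectory:
    """Ordered frames sharing one system; times strictly increasing."""

    system: System
    coords: np.ndarray          # (n_frames, n_beads, 3)
    times: np.ndarray           # (n_frames,) ns
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.coords) != len(self.times):
            raise ValueError("coords/times length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Frame:
        return Frame(self.system, self.coords[i], float(self.times[i]))

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


# ---------------------------------------------------------------------------
# Packing

def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _random_walk_chain(
    top: ChainTopology, rng: np.random.Generator, b0: float, sigma: float,
    max_attempts: int = 200,
) -> np.ndarray:
    """Self-avoiding random walk conformation centred at the origin."""
    nb = top.n_beads
    for _ in range(max_attempts):
        coords = np.zeros((nb, 3))
        ok = True
        for i in range(1, nb):
            if top.beads_per_residue == 2:
                # BB beads bond to the previous BB, SC beads to their own BB
                p = i - 2 if i % 2 == 0 else i - 1
                p = max(p, 0)
            else:
                p = i - 1
            placed = False
            for _ in range(50):
                step = rng.standard_normal(3)
                step *= b0 / np.linalg.norm(step)
                cand = coords[p] + step
                prior = coords[:i]
                if len(prior):
                    d = np.linalg.norm(prior - cand, axis=1)
                    # allow the bonded parent to sit at b0 < sigma
                    mask = np.ones(i, dtype=bool)
                    mask[p] = False
                    if np.any(d[mask] < sigma):
                        continue
                coords[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return coords - coords.mean(axis=0)
    raise PackingError(f"could not grow a self-avoiding conformation for {top.species}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def build_system(
    config: SystemConfig,
    b0: float = 0.38,
    max_attempts_per_chain: int = 500,
) -> Frame:
    """Insert chains at random positions/orientations with σ exclusion.

    Chains are grown as self-avoiding random walks and inserted one at a
    time; an insertion is rejected whenever any inter-chain minimum-image
    bead distance falls below σ.  Deterministic for a given config seed.
    Implicit-ion counts are recorded in the returned frame's system.
    """
    rng = np.random.default_rng(config.seed)
    system = System.from_config(config)
    box = config.box_edge
    sigma = config.interactions.sigma
    placed: list[np.ndarray] = []
    tree = None
    all_coords = np.zeros((0, 3))
    for cid, top in enumerate(system.chain_topology):
        inserted = False
        for _ in range(max_attempts_per_chain):
            conf = _random_walk_chain(top, rng, b0, sigma)
            extent = 2 * np.linalg.norm(conf, axis=1).max() if len(conf) > 1 else 0.0
            if extent >= box:
                raise PackingError(
                    f"chain {top.species} extent {extent:.1f} nm does not fit the "
                    f"{box:.1f} nm box; use a larger box"
                )
            rot = _random_rotation(rng)
            pos = rng.uniform(0, box, size=3)
            cand = np.mod(conf @ rot.T + pos, box)
            if tree is not None:
                if tree.query_ball_point(cand, sigma, return_length=True).sum() > 0:
                    continue
            placed.append(cand)
            all_coords = np.concatenate([all_coords, cand])
            tree = cKDTree(all_coords, boxsize=box)
            inserted = True
            break
        if not inserted:
            raise PackingError(
                f"failed to insert chain {cid} ({top.species}) after "
                f"{max_attempts_per_chain} attempts; use a larger box"
            )
    return Frame(system, all_coords, 0.0)


def plant_clusters(
    config: SystemConfig,
    partition: list[set[int]],
    seed: int = 0,
    contact_distance: float = 0.45,
    separation: float = 1.6,
) -> Frame:
    """Construct a frame whose chain clusters are exactly ``partition``.

    Chains of one planted set are laid out as parallel straight rods spaced
    ``contact_distance`` apart (every adjacent rod pair shares bead contacts
    below the 0.5 nm cutoff, chaining the whole set together); distinct sets
    are separated by more than ``separation`` (> 3x cutoff).  Purely
    geometric — no cluster detection is run.
    """
    system = System.from_config(config)
    ids = sorted(i for s in partition for i in s)
    if ids != list(range(system.n_chains)):
        raise ValueError("partition must cover every chain id exactly once")
    box = config.box_edge
    b0 = 0.38
    rng = np.random.default_rng(seed)

    # extent of each planted group: rod length x (n_chains * spacing)
    groups = [sorted(s) for s in partition]
    extents = []
    for g in groups:
        rod = max(system.chain_topology[c].n_beads for c in g) * b0
        width = (len(g) - 1) * contact_distance
        extents.append((rod, width))
    pitch = max(max(r, w) for r, w in extents) + separation
    n_per_side = max(1, int(box // pitch))
    if n_per_side**3 < len(groups):
        raise PackingError(
            f"box {box} nm too small to separate {len(groups)} planted groups "
            f"by {separation} nm"
        )
    coords = np.zeros((system.n_beads, 3))
    order = rng.permutation(len(groups))
    cells = [
        (i, j, k)
        for i in range(n_per_side)
        for j in range(n_per_side)
        for k in range(n_per_side)
    ]
    for gi, cell in zip(order, cells):
        center = (np.asarray(cell) + 0.5) * (box / n_per_side)
        for row, cid in enumerate(groups[gi]):
            top = system.chain_topology[cid]
            nb = top.n_beads
            xs = (np.arange(nb) - (nb - 1) / 2) * b0
            chain = np.zeros((nb, 3))
            chain[:, 0] = xs
            chain[:, 1] = (row - (len(groups[gi]) - 1) / 2) * contact_distance
            sl = system.beads_of_chain(cid)
            coords[sl] = center + chain
    coords += rng.uniform(0, 0.005, size=3)  # global jitter, breaks exact ties
    return Frame(system, np.mod(coords, box), 0.0)
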