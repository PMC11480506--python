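"""Contact-map analysis of multi-chain coarse-grained trajectories.

Two beads are in contact when their minimum-image distance is strictly
below the cutoff (default 0.5 nm).  Chains sharing at least a threshold
number of inter-chain bead contacts are "interacting"; the connected
components of that chain graph are the clusters.  Within the largest
cluster of each frame a central chain (maximum degree) is identified and
the contacts between its beads and the beads of its graph-adjacent
neighbors are averaged over those neighbors, then over contributing
frames, yielding a (beads x beads) score matrix.  Bead-level matrices are
reduced to residue level by taking the maximum score over all bead pairs
of each residue pair, and to 1D per-residue profiles by symmetrizing and
summing over partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .system import Frame, Trajectory
from .topology import ChainTopology


class NoContributingFramesError(RuntimeError):
    """No frame contained a qualifying cluster; there is nothing to average."""


@dataclass(frozen=True)
class ContactParams:
    """Contact definition and frame selection."""

    cutoff: float = 0.5           # nm, strict less-than
    chain_threshold: int = 1      # min bead contacts for chains to interact
    intra_exclusion: int = 3      # min |bead slot difference| for intra contacts
    frame_start: int = 0
    frame_stop: int | None = None
    stride: int = 1

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.chain_threshold < 1:
            raise ValueError("chain threshold must be >= 1")
        if self.intra_exclusion < 1:
            raise ValueError("intra exclusion must be >= 1")


@dataclass
class ContactMatrix:
    """Square contact-score matrix with its normalization metadata."""

    values: np.ndarray
    level: str                    # "bead" | "residue"
    mode: str                     # "central" | "pair" | "intra"
    frames_contributing: int
    frames_total: int
    cutoff: float
    species: str
    symmetrized: bool = False
    beads_per_residue: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if np.any(v < 0):
            raise ValueError("contact scores must be non-negative")
        self.values = v

    def to_tsv(self, path: str | Path, ld_start: int | None = None) -> None:
        """Write as tab-delimited text; labels in LD numbering when the
        species' first residue position is supplied."""
        n = self.values.shape[0]
        if self.level == "residue" and ld_start is not None:
            labels = [str(ld_start + i) for i in range(n)]
        else:
            labels = [str(i + 1) for i in range(n)]
        with open(path, "w") as fh:
            fh.write(f"# level: {self.level}\n# mode: {self.mode}\n")
            fh.write(f"# frames_contributing: {self.frames_contributing}\n")
            fh.write(f"# frames_total: {self.frames_total}\n")
            fh.write(f"# cutoff_nm: {self.cutoff}\n# species: {self.species}\n")
            fh.write("\t" + "\t".join(labels) + "\n")
            for lab, row in zip(labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def _selected_frames(traj: Trajectory, params: ContactParams):
    stop = params.frame_stop if params.frame_stop is not None else traj.n_frames
    for idx in range(params.frame_start, stop, params.stride):
        yield traj.frame(idx)


def bead_contacts(frame: Frame, params: ContactParams) -> np.ndarray:
    """Unordered contacting bead pairs (global indices, i < j).

    Excludes bonded pairs and intra-chain pairs whose along-chain bead
    separation is below the exclusion window; inter-chain pairs are never
    excluded.  Distances use the minimum-image convention.
    """
    sys_ = frame.system
    box = frame.box
    coords = np.mod(frame.coords, box)
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    i, j = pairs[:, 0], pairs[:, 1]
    # strict '<' cutoff (the tree query is inclusive)
    d = coords[i] - coords[j]
    d -= box * np.round(d / box)
    keep = np.einsum("ij,ij->i", d, d) < params.cutoff**2
    pairs = pairs[keep]
    i, j = pairs[:, 0], pairs[:, 1]
    same_chain = sys_.bead_chain[i] == sys_.bead_chain[j]
    sep = np.abs(sys_.bead_slot[i] - sys_.bead_slot[j])
    keep = ~same_chain | (sep >= params.intra_exclusion)
    if len(sys_.bonds):
        n = sys_.n_beads
        bond_keys = np.sort(sys_.bonds[:, 0] * n + sys_.bonds[:, 1])
        bond_keys = np.unique(
            np.concatenate([bond_keys, sys_.bonds[:, 1] * n + sys_.bonds[:, 0]])
        )
        keep &= ~np.isin(i * n + j, bond_keys)
    return pairs[keep]


def chain_contact_counts(frame: Frame, params: ContactParams) -> dict[tuple[int, int], int]:
    """Number of contacting bead pairs per unordered chain pair."""
    pairs = bead_contacts(frame, params)
    sys_ = frame.system
    counts: dict[tuple[int, int], int] = {}
    ci = sys_.bead_chain[pairs[:, 0]]
    cj = sys_.bead_chain[pairs[:, 1]]
    inter = ci != cj
    for a, b in zip(ci[inter], cj[inter]):
        key = (int(min(a, b)), int(max(a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def interaction_graph(frame: Frame, params: ContactParams) -> nx.Graph:
    """Undirected chain graph: edge iff inter-chain bead contacts >= threshold."""
    g = nx.Graph()
    g.add_nodes_from(range(frame.system.n_chains))
    for (a, b), c in chain_contact_counts(frame, params).items():
        if c >= params.chain_threshold:
            g.add_edge(a, b, contacts=c)
    return g


def _single_species(traj: Trajectory) -> ChainTopology:
    tops = {id(t): t for t in traj.system.chain_topology}
    names = {t.species for t in tops.values()}
    if len(names) != 1:
        raise ValueError(f"all chains must be one species, found {sorted(names)}")
    return traj.system.chain_topology[0]


def _largest_cluster(graph: nx.Graph) -> set[int] | None:
    clusters = [c for c in nx.connected_components(graph) if len(c) >= 2]
    if not clusters:
        return None
    # largest; ties broken toward the cluster containing the lowest chain id
    return max(clusters, key=lambda c: (len(c), -min(c)))


def _central_chain(
    cluster: set[int], graph: nx.Graph, counts: dict[tuple[int, int], int]
) -> int:
    def total_contacts(c: int) -> int:
        return sum(
            counts.get((min(c, n), max(c, n)), 0) for n in graph.neighbors(c)
        )

    return min(
        cluster,
        key=lambda c: (-graph.degree(c), -total_contacts(c), c),
    )


def central_chain_matrix(traj: Trajectory, params: ContactParams) -> ContactMatrix:
    """Central-chain neighbor-averaged bead contact matrix.

    Per frame containing at least one cluster of >= 2 chains: within the
    largest cluster the maximum-degree chain is central (ties: most bead
    contacts, then lowest id); entry (i, j) of the frame matrix is the
    fraction of the central chain's graph neighbors whose bead j contacts
    central bead i.  The result is the mean over contributing frames.
    """
    top = _single_species(traj)
    nb = top.n_beads
    sys_ = traj.system
    acc = np.zeros((nb, nb))
    contributing = 0
    total = 0
    for frame in _selected_frames(traj, params):
        total += 1
        pairs = bead_contacts(frame, params)
        counts: dict[tuple[int, int], int] = {}
        ci = sys_.bead_chain[pairs[:, 0]]
        cj = sys_.bead_chain[pairs[:, 1]]
        inter = ci != cj
        for a, b in zip(ci[inter], cj[inter]):
            key = (int(min(a, b)), int(max(a, b)))
            counts[key] = counts.get(key, 0) + 1
        g = nx.Graph()
        g.add_nodes_from(range(sys_.n_chains))
        for (a, b), c in counts.items():
            if c >= params.chain_threshold:
                g.add_edge(a, b)
        cluster = _largest_cluster(g)
        if cluster is None:
            continue
        central = _central_chain(cluster, g, counts)
        neighbors = list(g.neighbors(central))
        if not neighbors:
            continue
        frame_m = np.zeros((nb, nb))
        ip, jp = pairs[inter][:, 0], pairs[inter][:, 1]
        cip, cjp = ci[inter], cj[inter]
        for n_chain in neighbors:
            m = np.zeros((nb, nb), dtype=bool)
            sel = (cip == central) & (cjp == n_chain)
            m[sys_.bead_slot[ip[sel]], sys_.bead_slot[jp[sel]]] = True
            sel = (cjp == central) & (cip == n_chain)
            m[sys_.bead_slot[jp[sel]], sys_.bead_slot[ip[sel]]] = True
            frame_m += m
        acc += frame_m / len(neighbors)
        contributing += 1
    if contributing == 0:
        raise NoContributingFramesError(
            "no frame contained a cluster of >= 2 chains"
        )
    return ContactMatrix(
        values=acc / contributing,
        level="bead",
        mode="central",
        frames_contributing=contributing,
        frames_total=total,
        cutoff=params.cutoff,
        species=top.species,
        beads_per_residue=top.beads_per_residue,
    )


def two_chain_matrix(traj: Trajectory, params: ContactParams) -> ContactMatrix:
    """Two-chain contact matrix: entry (i, j) is the fraction of frames in
    which bead i of chain 0 contacts bead j of chain 1.  Every selected
    frame contributes (contact-free frames contribute zeros)."""
    if traj.system.n_chains != 2:
        raise ValueError("two-chain mode requires exactly 2 chains")
    top = _single_species(traj)
    nb = top.n_beads
    sys_ = traj.system
    acc = np.zeros((nb, nb))
    total = 0
    for frame in _selected_frames(traj, params):
        total += 1
        pairs = bead_contacts(frame, params)
        ci = sys_.bead_chain[pairs[:, 0]]
        cj = sys_.bead_chain[pairs[:, 1]]
        inter = ci != cj
        m = np.zeros((nb, nb), dtype=bool)
        ip, jp = pairs[inter][:, 0], pairs[inter][:, 1]
        sel = ci[inter] == 0
        m[sys_.bead_slot[ip[sel]], sys_.bead_slot[jp[sel]]] = True
        m[sys_.bead_slot[jp[~sel]], sys_.bead_slot[ip[~sel]]] = True
        acc += m
    if total == 0:
        raise ValueError("no frames selected")
    return ContactMatrix(
        values=acc / total,
        level="bead",
        mode="pair",
        frames_contributing=total,
        frames_total=total,
        cutoff=params.cutoff,
        species=top.species,
        beads_per_residue=top.beads_per_residue,
    )


def intra_chain_matrix(
    traj: Trajectory, params: ContactParams, species: str | None = None
) -> ContactMatrix:
    """Within-chain contact matrix, averaged over frames and chain copies,
    respecting the along-chain exclusion window."""
    sys_ = traj.system
    if species is None:
        top = _single_species(traj)
        species = top.species
    else:
        matching = [t for t in sys_.chain_topology if t.species == species]
        if not matching:
            raise ValueError(f"species {species!r} not present")
        top = matching[0]
    chain_ids = [
        c for c, t in enumerate(sys_.chain_topology) if t.species == species
    ]
    nb = top.n_beads
    acc = np.zeros((nb, nb))
    total = 0
    for frame in _selected_frames(traj, params):
        total += 1
        pairs = bead_contacts(frame, params)
        ci = sys_.bead_chain[pairs[:, 0]]
        same = ci == sys_.bead_chain[pairs[:, 1]]
        for cid in chain_ids:
            sel = same & (ci == cid)
            m = np.zeros((nb, nb), dtype=bool)
            si = sys_.bead_slot[pairs[sel, 0]]
            sj = sys_.bead_slot[pairs[sel, 1]]
            m[si, sj] = True
            m[sj, si] = True
            acc += m
    if total == 0:
        raise ValueError("no frames selected")
    return ContactMatrix(
        values=acc / (total * len(chain_ids)),
        level="bead",
        mode="intra",
        frames_contributing=total,
        frames_total=total,
        cutoff=params.cutoff,
        species=species,
        symmetrized=True,
        beads_per_residue=top.beads_per_residue,
    )


def beads_to_residues(m: ContactMatrix, topology: ChainTopology) -> ContactMatrix:
    """Reduce a bead-level matrix to residue level by taking the maximum
    score over all bead pairs of each residue pair."""
    if m.level != "bead":
        raise ValueError("input must be bead-level")
    nb = topology.n_beads
    if m.values.shape[0] != nb:
        raise ValueError(
            f"matrix dimension {m.values.shape[0]} != topology beads {nb}"
        )
    nres = topology.n_residues
    bpr = topology.beads_per_residue
    reduced = m.values.reshape(nres, bpr, nres, bpr).max(axis=(1, 3))
    return ContactMatrix(
        values=reduced,
        level="residue",
        mode=m.mode,
        frames_contributing=m.frames_contributing,
        frames_total=m.frames_total,
        cutoff=m.cutoff,
        species=m.species,
        symmetrized=m.symmetrized,
        beads_per_residue=1,
    )


def project_1d(m: ContactMatrix) -> np.ndarray:
    """Per-residue contact score: symmetrize, then sum over partners."""
    if m.level != "residue":
        raise ValueError("1D projection expects a residue-level matrix")
    sym = (m.values + m.values.T) / 2
    return sym.sum(axis=1)
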