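"""Cluster detection and kinetics over chain-interaction graphs.

A cluster is a connected component of the per-frame chain graph; components
of size 1 are "free" chains.  Kinetics are scored frame-to-frame at the
saved-frame resolution: a join event is a chain that is free at frame t and
clustered at t+1, a leave event the reverse.  For mixed systems the
heterotypic edge fraction is compared with the random-partner expectation
``2 p_A p_B / (p_A + p_B)^2`` where p are chain count fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .contacts import ContactParams, interaction_graph, _central_chain, chain_contact_counts
from .system import Trajectory


@dataclass
class ClusterPartition:
    """Per-frame chain partitions with central-chain annotation."""

    frames: list[list[set[int]]]         # per frame: list of components
    centrals: list[dict[int, int]]       # per frame: {component index -> central chain}
    times: np.ndarray

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def largest_sizes(self) -> np.ndarray:
        return np.array(
            [max(len(c) for c in comps) if comps else 0 for comps in self.frames]
        )


@dataclass
class ClusterKinetics:
    times: np.ndarray
    largest_cluster: np.ndarray          # chains in the largest component
    n_clusters: np.ndarray               # components of size >= 2
    join_events: list[tuple[int, int]]   # (chain, frame index of arrival)
    leave_events: list[tuple[int, int]]
    dwell_segments: dict[int, list[tuple[int, int]]]  # chain -> [start, end] frame spans
    free_fraction: dict[str, float]      # per species, averaged over frames
    status: str = "ok"


def find_clusters(graph: nx.Graph) -> list[set[int]]:
    """Connected components, singletons included, sorted by lowest member."""
    return sorted(
        (set(c) for c in nx.connected_components(graph)), key=min
    )


def partition_trajectory(traj: Trajectory, params: ContactParams) -> ClusterPartition:
    frames, centrals, times = [], [], []
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        g = interaction_graph(frame, params)
        comps = find_clusters(g)
        counts = chain_contact_counts(frame, params)
        cent: dict[int, int] = {}
        for ci, comp in enumerate(comps):
            if len(comp) >= 2:
                cent[ci] = _central_chain(comp, g, counts)
        frames.append(comps)
        centrals.append(cent)
        times.append(traj.times[i])
    return ClusterPartition(frames=frames, centrals=centrals, times=np.asarray(times))


def _in_cluster(comps: list[set[int]], chain: int) -> bool:
    for c in comps:
        if chain in c:
            return len(c) >= 2
    raise KeyError(chain)


def kinetics_from_partition(
    partition: ClusterPartition, species: list[str]
) -> ClusterKinetics:
    """Event bookkeeping from a stored partition sequence (recomputable)."""
    n_frames = partition.n_frames
    if n_frames < 2:
        return ClusterKinetics(
            times=partition.times,
            largest_cluster=partition.largest_sizes(),
            n_clusters=np.array(
                [sum(len(c) >= 2 for c in f) for f in partition.frames]
            ),
            join_events=[],
            leave_events=[],
            dwell_segments={},
            free_fraction=_free_fractions(partition, species),
            status="too-short" if n_frames < 2 else "ok",
        )
    chains = sorted(set().union(*partition.frames[0]))
    joins, leaves = [], []
    dwell: dict[int, list[tuple[int, int]]] = {c: [] for c in chains}
    open_start: dict[int, int | None] = {c: None for c in chains}
    for f, comps in enumerate(partition.frames):
        for c in chains:
            inc = _in_cluster(comps, c)
            if inc and open_start[c] is None:
                open_start[c] = f
                if f > 0:
                    joins.append((c, f))
            elif not inc and open_start[c] is not None:
                dwell[c].append((open_start[c], f - 1))
                open_start[c] = None
                leaves.append((c, f))
    for c in chains:
        if open_start[c] is not None:
            dwell[c].append((open_start[c], n_frames - 1))
    return ClusterKinetics(
        times=partition.times,
        largest_cluster=partition.largest_sizes(),
        n_clusters=np.array([sum(len(c) >= 2 for c in f) for f in partition.frames]),
        join_events=joins,
        leave_events=leaves,
        dwell_segments=dwell,
        free_fraction=_free_fractions(partition, species),
        status="ok",
    )


def _free_fractions(partition: ClusterPartition, species: list[str]) -> dict[str, float]:
    labels = sorted(set(species))
    free_counts = {s: 0.0 for s in labels}
    totals = {s: species.count(s) for s in labels}
    for comps in partition.frames:
        for comp in comps:
            if len(comp) == 1:
                (c,) = comp
                free_counts[species[c]] += 1
    n = max(partition.n_frames, 1)
    return {s: free_counts[s] / (totals[s] * n) for s in labels if totals[s]}


def cluster_kinetics(traj: Trajectory, params: ContactParams) -> ClusterKinetics:
    partition = partition_trajectory(traj, params)
    return kinetics_from_partition(partition, traj.system.chain_species)


@dataclass
class MixingSummary:
    observed_hetero_fraction: float | None
    expected_hetero_fraction: float
    enrichment: float | None
    free_fraction: dict[str, float]
    n_inter_edges: int
    status: str = "ok"


def mixing_stats(traj: Trajectory, params: ContactParams) -> MixingSummary:
    """Two-species mixing: heterotypic edge fraction pooled over frames
    versus the random-partner expectation; undefined ratios are flagged
    rather than propagated as NaN."""
    species = traj.system.chain_species
    labels = sorted(set(species))
    if len(labels) < 2:
        raise ValueError("mixing statistics require >= 2 species")
    hetero = 0
    total = 0
    for i in range(traj.n_frames):
        g = interaction_graph(traj.frame(i), params)
        for a, b in g.edges():
            total += 1
            if species[a] != species[b]:
                hetero += 1
    p = {s: species.count(s) / len(species) for s in labels}
    pa, pb = p[labels[0]], p[labels[1]]
    expected = 2 * pa * pb / (pa + pb) ** 2
    partition = partition_trajectory(traj, params)
    free = _free_fractions(partition, species)
    if total == 0:
        return MixingSummary(
            observed_hetero_fraction=None,
            expected_hetero_fraction=expected,
            enrichment=None,
            free_fraction=free,
            n_inter_edges=0,
            status="no-inter-chain-edges",
        )
    obs = hetero / total
    return MixingSummary(
        observed_hetero_fraction=obs,
        expected_hetero_fraction=expected,
        enrichment=obs / expected,
        free_fraction=free,
        n_inter_edges=total,
    )
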