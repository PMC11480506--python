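"""Independent brute-force re-implementations used as test oracles.

Everything here is written against the contact/cluster definitions
directly — O(n^2) minimum-image loops and set-based transitive closure —
and deliberately shares no code with the production implementation.
"""

from __future__ import annotations

import numpy as np


def min_image_dist(a, b, box):
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d -= box * np.round(d / box)
    return float(np.sqrt((d**2).sum()))


def brute_bead_contacts(frame, params):
    """All unordered bead pairs (i < j) strictly closer than the cutoff,
    excluding bonded pairs and intra-chain pairs inside the exclusion
    window."""
    sys_ = frame.system
    coords = np.mod(frame.coords, frame.box)
    bonded = {(min(a, b), max(a, b)) for a, b in map(tuple, sys_.bonds)}
    out = set()
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            if sys_.bead_chain[i] == sys_.bead_chain[j]:
                if abs(int(sys_.bead_slot[i]) - int(sys_.bead_slot[j])) < params.intra_exclusion:
                    continue
            if min_image_dist(coords[i], coords[j], frame.box) < params.cutoff:
                out.add((i, j))
    return out


def brute_chain_counts(frame, params):
    counts = {}
    sys_ = frame.system
    for i, j in brute_bead_contacts(frame, params):
        a, b = int(sys_.bead_chain[i]), int(sys_.bead_chain[j])
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        counts[key] = counts.get(key, 0) + 1
    return counts


def brute_edges(frame, params):
    return {
        pair for pair, c in brute_chain_counts(frame, params).items()
        if c >= params.chain_threshold
    }


def brute_components(n_nodes, edges):
    """Connected components by repeated set expansion (transitive closure)."""
    comps = [{i} for i in range(n_nodes)]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            ca = next(c for c in comps if a in c)
            cb = next(c for c in comps if b in c)
            if ca is not cb:
                comps.remove(cb)
                ca |= cb
                changed = True
    return sorted(comps, key=min)


def brute_central_chain(cluster, edges, counts):
    def degree(c):
        return sum(1 for a, b in edges if c in (a, b))

    def total(c):
        return sum(
            v for (a, b), v in counts.items() if c in (a, b)
            and (min(a, b), max(a, b)) in edges
        )

    return min(cluster, key=lambda c: (-degree(c), -total(c), c))


def brute_central_matrix(traj, params):
    """Frame-by-frame re-derivation of the central-chain averaged matrix."""
    sys_ = traj.system
    nb = sys_.chain_topology[0].n_beads
    acc = np.zeros((nb, nb))
    contributing = 0
    for fi in range(traj.n_frames):
        frame = traj.frame(fi)
        counts = brute_chain_counts(frame, params)
        edges = {p for p, c in counts.items() if c >= params.chain_threshold}
        comps = brute_components(sys_.n_chains, edges)
        clusters = [c for c in comps if len(c) >= 2]
        if not clusters:
            continue
        cluster = max(clusters, key=lambda c: (len(c), -min(c)))
        central = brute_central_chain(cluster, edges, counts)
        neighbors = [
            b if a == central else a
            for a, b in edges
            if central in (a, b)
        ]
        if not neighbors:
            continue
        contacts = brute_bead_contacts(frame, params)
        fm = np.zeros((nb, nb))
        for n_chain in neighbors:
            m = np.zeros((nb, nb))
            for i, j in contacts:
                ci, cj = int(sys_.bead_chain[i]), int(sys_.bead_chain[j])
                if ci == central and cj == n_chain:
                    m[sys_.bead_slot[i], sys_.bead_slot[j]] = 1
                elif cj == central and ci == n_chain:
                    m[sys_.bead_slot[j], sys_.bead_slot[i]] = 1
            fm += m
        acc += fm / len(neighbors)
        contributing += 1
    if contributing == 0:
        return None
    return acc / contributing


def brute_beads_to_residues(values, bead_residue):
    nres = int(max(bead_residue)) + 1
    out = np.zeros((nres, nres))
    nb = len(bead_residue)
    for p in range(nres):
        for q in range(nres):
            best = 0.0
            for i in range(nb):
                if bead_residue[i] != p:
                    continue
                for j in range(nb):
                    if bead_residue[j] != q:
                        continue
                    best = max(best, values[i, j])
            out[p, q] = best
    return out


def brute_project_1d(values):
    n = len(values)
    sym = np.zeros_like(values, dtype=float)
    for p in range(n):
        for q in range(n):
            sym[p, q] = (values[p, q] + values[q, p]) / 2
    return np.array([sym[p, :].sum() for p in range(n)])
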