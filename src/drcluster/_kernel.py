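"""Compiled integration kernel (numba) for the overdamped Langevin stepper.

The kernel advances a block of steps with a Verlet neighbor list rebuilt by
an O(n^2) scan whenever any bead has drifted more than half the skin.  The
numpy reference path in :mod:`drcluster.dynamics` defines the model; this
kernel reproduces it step for step (identical force law, identical noise
stream supplied by the caller) and exists only for speed.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAS_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAS_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _rebuild(coords, box, r_list, bonded, pair_i, pair_j):
    n = coords.shape[0]
    m = 0
    r2 = r_list * r_list
    for i in range(n):
        for j in range(i + 1, n):
            if bonded[i, j]:
                continue
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            if dx * dx + dy * dy + dz * dz < r2:
                pair_i[m] = i
                pair_j[m] = j
                m += 1
    return m


@njit(cache=True)
def run_block(
    coords,          # (n, 3) in-place
    box,
    noise,           # (steps, n, 3) pre-scaled by step_sd
    chi_steps,       # (steps,)
    mobility,        # dt / gamma
    bonds,           # (n_bonds, 2)
    bonded,          # (n, n) bool
    sticker,         # (n,) int codes
    eps_matrix,      # (4, 4)
    sigma,
    eps_rep,
    r0,
    delta,
    b0,
    k_bond,
    r_cut,
    skin,
):
    """Advance ``noise.shape[0]`` steps; returns 0 on success, the 1-based
    failing step if coordinates become non-finite."""
    n = coords.shape[0]
    steps = noise.shape[0]
    max_pairs = n * (n - 1) // 2
    pair_i = np.empty(max_pairs, dtype=np.int64)
    pair_j = np.empty(max_pairs, dtype=np.int64)
    ref = coords.copy()
    m = _rebuild(coords, box, r_cut + skin, bonded, pair_i, pair_j)
    forces = np.empty((n, 3))
    half_skin2 = (skin / 2) ** 2
    two_d2 = 2 * delta * delta
    inv_d2 = 1.0 / (delta * delta)
    att_cut = r0 + 4 * delta
    for s in range(steps):
        chi = chi_steps[s]
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        for p in range(m):
            i = pair_i[p]
            j = pair_j[p]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > att_cut * att_cut:
                continue
            r = np.sqrt(r2)
            if r < 1e-9:
                r = 1e-9
            fmag = 0.0
            if r < sigma:
                fmag += 2.0 * eps_rep / sigma * (1.0 - r / sigma)
            if chi > 0.0:
                eps = chi * eps_matrix[sticker[i], sticker[j]]
                if eps > 0.0 and r < att_cut:
                    dr = r - r0
                    fmag += -eps * np.exp(-dr * dr / two_d2) * dr * inv_d2
            if fmag != 0.0:
                fx = fmag * dx / r
                fy = fmag * dy / r
                fz = fmag * dz / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-9:
                r = 1e-9
            fmag = -k_bond * (r - b0)
            fx = fmag * dx / r
            fy = fmag * dy / r
            fz = fmag * dz / r
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
        drift = 0.0
        for i in range(n):
            for k in range(3):
                x = coords[i, k] + forces[i, k] * mobility + noise[s, i, k]
                if not np.isfinite(x):
                    return s + 1
                x = x % box
                coords[i, k] = x
            dx = coords[i, 0] - ref[i, 0]
            dy = coords[i, 1] - ref[i, 1]
            dz = coords[i, 2] - ref[i, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > drift:
                drift = d2
        if drift > half_skin2:
            m = _rebuild(coords, box, r_cut + skin, bonded, pair_i, pair_j)
            for i in range(n):
                ref[i, 0] = coords[i, 0]
                ref[i, 1] = coords[i, 1]
                ref[i, 2] = coords[i, 2]
    return 0
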