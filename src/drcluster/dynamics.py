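"""Overdamped Langevin dynamics for the sticker–spacer chain model.

This is a bespoke stand-in for a full coarse-grained force-field run: the
analysis layer only needs trajectories with tunable, reversible chain
clustering.  Potential energy terms (nm, kJ/mol):

* harmonic bonds, ``U = k/2 (r - b0)^2`` with b0 = 0.38 nm, k = 500;
* soft repulsion between all bead pairs, ``U = eps_rep (1 - r/sigma)^2``
  for r < sigma (sigma = 0.47 nm);
* Gaussian sticker wells between attractive class pairs,
  ``U = -chi * eps_ss * exp(-(r - r0)^2 / (2 delta^2))`` with r0 = 0.50 nm,
  delta = 0.12 nm, truncated at r0 + 4 delta.

Each bead follows ``dx = -grad(U)/gamma dt + sqrt(2 kB T dt / gamma) xi``
with gamma set so a free bead diffuses ``bead_diffusivity`` (default
1 nm^2/ns) at the configured temperature.  The crowding scale chi can be
driven by a time schedule to mimic adding or washing out a crowding agent.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .system import Frame, SystemConfig, Trajectory

KB = 8.314462618e-3  # kJ/mol/K

BOND_B0 = 0.38       # nm
BOND_K = 500.0       # kJ/mol/nm^2


class IntegrationError(RuntimeError):
    """Raised when coordinates or energies become non-finite."""


def _chi_function(
    schedule: Callable[[float], float] | Sequence[tuple[float, float]] | None,
    default_chi: float,
) -> Callable[[float], float]:
    if schedule is None:
        return lambda t: default_chi
    if callable(schedule):
        return schedule
    points = sorted(schedule)

    def step(t: float) -> float:
        chi = default_chi
        for t0, value in points:
            if t >= t0:
                chi = value
        return chi

    return step


def _bond_keys(bonds: np.ndarray, n: int) -> np.ndarray:
    lo = np.minimum(bonds[:, 0], bonds[:, 1])
    hi = np.maximum(bonds[:, 0], bonds[:, 1])
    return np.sort(lo * n + hi)


def _nonbonded_pairs(
    coords: np.ndarray, box: float, r_cut: float, bond_keys: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(r_cut, output_type="ndarray")
    if len(pairs) and len(bond_keys):
        keys = pairs[:, 0] * len(coords) + pairs[:, 1]  # query_pairs gives i<j
        pairs = pairs[~np.isin(keys, bond_keys)]
    return pairs[:, 0], pairs[:, 1]


def _pair_forces(
    coords: np.ndarray,
    box: float,
    i: np.ndarray,
    j: np.ndarray,
    sticker: np.ndarray,
    eps_matrix: np.ndarray,
    chi: float,
    sigma: float,
    eps_rep: float,
    r0: float,
    delta: float,
    forces: np.ndarray,
    energy: bool = False,
) -> float:
    d = coords[i] - coords[j]
    d -= box * np.round(d / box)
    r = np.sqrt(np.einsum("ij,ij->i", d, d))
    r = np.maximum(r, 1e-9)
    fmag = np.zeros_like(r)        # force magnitude along d (positive = repulsive)
    u = 0.0
    rep = r < sigma
    if np.any(rep):
        fmag[rep] += 2 * eps_rep / sigma * (1 - r[rep] / sigma)
        if energy:
            u += float(np.sum(eps_rep * (1 - r[rep] / sigma) ** 2))
    if chi > 0:
        eps = chi * eps_matrix[sticker[i], sticker[j]]
        att = (eps > 0) & (r < r0 + 4 * delta)
        if np.any(att):
            dr = r[att] - r0
            g = np.exp(-(dr**2) / (2 * delta**2))
            # U = -eps g  =>  F_r = -dU/dr = -eps g dr / delta^2
            fmag[att] += -eps[att] * g * dr / delta**2
            if energy:
                u += float(np.sum(-eps[att] * g))
    fv = (fmag / r)[:, None] * d
    np.add.at(forces, i, fv)
    np.add.at(forces, j, -fv)
    return u


def _bond_forces(
    coords: np.ndarray, box: float, bonds: np.ndarray, forces: np.ndarray,
    energy: bool = False,
) -> float:
    if not len(bonds):
        return 0.0
    i, j = bonds[:, 0], bonds[:, 1]
    d = coords[i] - coords[j]
    d -= box * np.round(d / box)
    r = np.maximum(np.linalg.norm(d, axis=1), 1e-9)
    fmag = -BOND_K * (r - BOND_B0)
    fv = (fmag / r)[:, None] * d
    np.add.at(forces, i, fv)
    np.add.at(forces, j, -fv)
    if energy:
        return float(np.sum(0.5 * BOND_K * (r - BOND_B0) ** 2))
    return 0.0


def potential_energy(frame: Frame, chi: float | None = None) -> float:
    """Total potential energy (kJ/mol) of a frame."""
    sys_ = frame.system
    p = sys_.config.interactions
    chi = p.chi if chi is None else chi
    coords = np.mod(frame.coords, frame.box)
    n = len(coords)
    forces = np.zeros_like(coords)
    bond_keys = _bond_keys(sys_.bonds, n) if len(sys_.bonds) else np.zeros(0, int)
    r_cut = max(p.sigma, p.r0 + 4 * p.delta)
    i, j = _nonbonded_pairs(coords, frame.box, r_cut, bond_keys)
    u = _pair_forces(
        coords, frame.box, i, j, sys_.bead_sticker, p.eps_matrix(), chi,
        p.sigma, p.eps_rep, p.r0, p.delta, forces, energy=True,
    )
    u += _bond_forces(coords, frame.box, sys_.bonds, forces, energy=True)
    return u


def simulate(
    start: Frame,
    n_steps: int,
    dt_ns: float = 0.002,
    save_every: int = 100,
    seed: int = 0,
    schedule: Callable[[float], float] | Sequence[tuple[float, float]] | None = None,
    bead_diffusivity: float = 1.0,   # nm^2/ns for a free bead
    config: SystemConfig | None = None,
    engine: str = "auto",
) -> Trajectory:
    """Integrate overdamped Langevin dynamics from ``start``.

    ``schedule`` optionally drives the crowding scale chi over time, either
    as a callable ``t_ns -> chi`` or a list of ``(t_ns, chi)`` breakpoints
    (step function).  The start frame is always the first saved frame.
    Reproducible for fixed seed and parameters (per engine: the compiled
    and numpy engines share the same model and noise stream but may differ
    at floating-point roundoff).
    """
    system = start.system
    cfg = config or system.config
    p = cfg.interactions
    kt = KB * cfg.temperature
    gamma = kt / bead_diffusivity
    step_sd = np.sqrt(2 * kt * dt_ns / gamma)
    if step_sd >= p.sigma / 4:
        raise ValueError(
            f"dt too large: per-step displacement SD {step_sd:.3f} nm must be "
            f"< sigma/4 = {p.sigma / 4:.3f} nm"
        )
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if engine not in ("auto", "numba", "numpy"):
        raise ValueError("engine must be 'auto', 'numba' or 'numpy'")
    from ._kernel import HAS_NUMBA

    use_kernel = engine == "numba" or (engine == "auto" and HAS_NUMBA)
    if engine == "numba" and not HAS_NUMBA:
        raise RuntimeError("numba engine requested but numba is unavailable")
    if use_kernel:
        return _simulate_kernel(
            start, n_steps, dt_ns, save_every, seed, schedule,
            bead_diffusivity, cfg, step_sd, gamma,
        )
    chi_of = _chi_function(schedule, p.chi)
    rng = np.random.default_rng(seed)
    box = cfg.box_edge
    coords = np.mod(np.array(start.coords, dtype=np.float64), box)
    n = len(coords)
    eps_matrix = p.eps_matrix()
    r_cut = max(p.sigma, p.r0 + 4 * p.delta)

    # Verlet neighbor list: pairs within r_cut + skin, rebuilt once any bead
    # has moved further than skin/2 since the last build.
    skin = 0.6
    bonded = np.zeros((n, n), dtype=bool)
    if len(system.bonds):
        bonded[system.bonds[:, 0], system.bonds[:, 1]] = True
        bonded[system.bonds[:, 1], system.bonds[:, 0]] = True

    def build_list(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tree = cKDTree(c, boxsize=box)
        pairs = tree.query_pairs(r_cut + skin, output_type="ndarray")
        if len(pairs):
            pairs = pairs[~bonded[pairs[:, 0], pairs[:, 1]]]
        return pairs[:, 0], pairs[:, 1]

    vi, vj = build_list(coords)
    ref = coords.copy()

    saved = [coords.copy()]
    times = [start.time]
    mobility = dt_ns / gamma
    for step in range(1, n_steps + 1):
        t = start.time + step * dt_ns
        chi = chi_of(t)
        forces = np.zeros_like(coords)
        _pair_forces(
            coords, box, vi, vj, system.bead_sticker, eps_matrix, chi,
            p.sigma, p.eps_rep, p.r0, p.delta, forces,
        )
        _bond_forces(coords, box, system.bonds, forces)
        coords = coords + forces * mobility + step_sd * rng.standard_normal((n, 3))
        if not np.all(np.isfinite(coords)):
            raise IntegrationError(f"non-finite coordinates at step {step}")
        coords = np.mod(coords, box)
        d = coords - ref
        d -= box * np.round(d / box)
        if np.max(np.einsum("ij,ij->i", d, d)) > (skin / 2) ** 2:
            vi, vj = build_list(coords)
            ref = coords.copy()
        if step % save_every == 0 or step == n_steps:
            frame = Frame(system, coords.copy(), t)
            if not np.isfinite(potential_energy(frame, chi=chi)):
                raise IntegrationError(f"non-finite energy at step {step}")
            saved.append(coords.copy())
            times.append(t)

    return Trajectory(
        system=system,
        coords=np.asarray(saved),
        times=np.asarray(times, dtype=float),
        provenance=_provenance(
            "numpy", n_steps, dt_ns, save_every, seed, bead_diffusivity,
            p.chi, schedule, system,
        ),
    )


def _provenance(engine, n_steps, dt_ns, save_every, seed, bead_diffusivity,
                chi, schedule, system) -> dict:
    return {
        "engine": engine,
        "n_steps": n_steps,
        "dt_ns": dt_ns,
        "save_every": save_every,
        "seed": seed,
        "bead_diffusivity": bead_diffusivity,
        "chi": chi,
        "schedule": list(schedule) if isinstance(schedule, (list, tuple)) else None,
        "ions": system.ion_bookkeeping(),
    }


def _simulate_kernel(
    start: Frame,
    n_steps: int,
    dt_ns: float,
    save_every: int,
    seed: int,
    schedule,
    bead_diffusivity: float,
    cfg: SystemConfig,
    step_sd: float,
    gamma: float,
) -> Trajectory:
    from ._kernel import run_block

    system = start.system
    p = cfg.interactions
    chi_of = _chi_function(schedule, p.chi)
    rng = np.random.default_rng(seed)
    box = cfg.box_edge
    coords = np.mod(np.array(start.coords, dtype=np.float64), box)
    n = len(coords)
    eps_matrix = p.eps_matrix()
    r_cut = max(p.sigma, p.r0 + 4 * p.delta)
    bonded = np.zeros((n, n), dtype=np.bool_)
    bonds = system.bonds.astype(np.int64)
    if len(bonds):
        bonded[bonds[:, 0], bonds[:, 1]] = True
        bonded[bonds[:, 1], bonds[:, 0]] = True
    sticker = system.bead_sticker.astype(np.int64)
    mobility = dt_ns / gamma

    saved = [coords.copy()]
    times = [start.time]
    done = 0
    while done < n_steps:
        block = min(save_every, n_steps - done)
        # boundary-aligned blocks so every saved frame ends a block
        to_boundary = save_every - (done % save_every)
        block = min(block, to_boundary)
        step_ids = done + 1 + np.arange(block)
        t_steps = start.time + step_ids * dt_ns
        chi_steps = np.array([chi_of(t) for t in t_steps])
        noise = step_sd * rng.standard_normal((block, n, 3))
        bad = run_block(
            coords, box, noise, chi_steps, mobility, bonds, bonded, sticker,
            eps_matrix, p.sigma, p.eps_rep, p.r0, p.delta, BOND_B0, BOND_K,
            r_cut, 0.6,
        )
        if bad:
            raise IntegrationError(
                f"non-finite coordinates at step {done + bad}"
            )
        done += block
        if done % save_every == 0 or done == n_steps:
            t = start.time + done * dt_ns
            frame = Frame(system, coords.copy(), t)
            if not np.isfinite(potential_energy(frame, chi=chi_of(t))):
                raise IntegrationError(f"non-finite energy at step {done}")
            saved.append(coords.copy())
            times.append(t)

    return Trajectory(
        system=system,
        coords=np.asarray(saved),
        times=np.asarray(times, dtype=float),
        provenance=_provenance(
            "numba", n_steps, dt_ns, save_every, seed, bead_diffusivity,
            p.chi, schedule, system,
        ),
    )
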