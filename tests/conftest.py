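"""Shared fixtures: small sticker-spacer systems and simulation caches.

The scaled-down demonstration system used for regime tests — 12 copies of a
short multivalent sticker peptide in a 13 nm periodic box — trades chain
length for encounter rate so that the inert (chi = 0) and clustering
(chi = 4) regimes separate within desk-scale run lengths.
"""

from __future__ import annotations

import numpy as np
import pytest

from drcluster.clusters import partition_trajectory
from drcluster.contacts import ContactParams
from drcluster.dynamics import simulate
from drcluster.system import SystemConfig, build_system
from drcluster.topology import ChainTopology

#: Short multivalent test peptide: alternating acidic/basic/aromatic stickers.
STICKY_SEQ = "DKFDKF"

REGIME_BOX = 13.0
REGIME_COPIES = 12
REGIME_STEPS = 400_000
REGIME_DT = 0.002
REGIME_SAVE = 5000
REGIME_CHI_HIGH = 4.0
REGIME_SEEDS = (1, 2, 3, 4, 5)


def sticky_topology() -> ChainTopology:
    return ChainTopology.from_sequence("STK6", STICKY_SEQ)


def regime_config(chi: float, seed: int) -> SystemConfig:
    return SystemConfig(
        box_edge=REGIME_BOX,
        species=((sticky_topology(), REGIME_COPIES),),
        seed=seed,
    ).with_chi(chi)


def run_regime(chi: float, seed: int, schedule=None, steps: int = REGIME_STEPS):
    cfg = regime_config(chi, seed)
    frame = build_system(cfg)
    return simulate(
        frame,
        n_steps=steps,
        dt_ns=REGIME_DT,
        save_every=REGIME_SAVE,
        seed=seed,
        schedule=schedule,
    )


def largest_fraction_last_half(traj) -> float:
    part = partition_trajectory(traj, ContactParams())
    sizes = part.largest_sizes()
    half = sizes[len(sizes) // 2 :]
    return float(half.mean()) / traj.system.n_chains


@pytest.fixture(scope="session")
def regime_fractions():
    """Mean largest-cluster fractions over 5 seeds for chi = 0 and chi = 6.

    Computed once per session; reused by the unit and acceptance suites.
    """
    inert = [largest_fraction_last_half(run_regime(0.0, s)) for s in REGIME_SEEDS]
    sticky = [
        largest_fraction_last_half(run_regime(REGIME_CHI_HIGH, s))
        for s in REGIME_SEEDS
    ]
    return np.array(inert), np.array(sticky)


@pytest.fixture(scope="session")
def reversal_trajectory():
    """One run whose chi drops from the clustering value to 0 mid-course."""
    switch_t = REGIME_STEPS * REGIME_DT / 2
    schedule = [(0.0, REGIME_CHI_HIGH), (switch_t, 0.0)]
    return run_regime(REGIME_CHI_HIGH, seed=11, schedule=schedule)
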