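# drcluster

Tools for studying how intrinsically disordered regions (DRs) of the IRE1α
ER-lumenal domain (LD, residues 24–443) drive its clustering into
condensates. The package bundles four things that normally live in separate
scripts:

1. **Region bookkeeping** — the LD's disordered segments (DR1 131–152,
   DR2 307–358, DR3 369–389, linker 390–443) with their peptide sequences,
   coordinate mapping between LD numbering and chain-internal positions,
   and residue-class composition.
2. **A sticker–spacer condensate simulator** — multi-chain overdamped
   Langevin dynamics in a periodic cubic box. Charged (D/E vs K/R) and
   aromatic (F/Y/W) residues act as attractive "stickers" (Gaussian wells,
   depth scaled by a crowding factor χ); everything else is an inert
   spacer with soft repulsion. Clustering is reversible: dropping χ to
   zero mid-run disperses the clusters, the in-silico analogue of washing
   out a crowding agent.
3. **Contact-map analysis** of multi-chain trajectories — bead contacts at
   a 0.5 nm minimum-image cutoff, per-frame chain-interaction graphs and
   cluster detection, central-chain neighbor-averaged contact matrices,
   two-chain and intra-chain modes, bead→residue reduction by maximum, and
   1D per-residue contact profiles.
4. **Quantification fits** behind the wet-lab readouts — FRAP three-ROI
   processing and one-phase-association fitting
   (`Y(t) = Plateau·(1 − e^{−Kt})`, mobile fraction = Plateau,
   t½ = ln 2 / K) with the Soumpasis closed form `D = 0.224·w²/t½`;
   mass-photometry calibration (BSA ladder) and Gaussian-mixture mass
   fitting with oligomer assignment; and single-site binding isotherms
   `r(L) = r0 + (r_max − r0)·L/(Kd + L)`.

Every input the pipeline needs can be generated synthetically with known
ground truth (trajectories, planted cluster configurations, FRAP traces,
mass-photometry event lists, binding curves), so the full analysis is
reproducible without downloads.

## Worked example

```python
import drcluster as dc
from drcluster.topology import ChainTopology

# a 12-copy system of a short multivalent sticker peptide, 13 nm box
top = ChainTopology.from_sequence("STK6", "DKFDKF")
cfg = dc.SystemConfig(box_edge=13.0, species=((top, 12),), seed=1).with_chi(4.0)
traj = dc.simulate(dc.build_system(cfg), n_steps=400_000, dt_ns=0.002,
                   save_every=5000, seed=1)
kin = dc.cluster_kinetics(traj, dc.ContactParams())
print(kin.largest_cluster[-5:])        # -> [7 7 7 7 7] (7 of 12 chains)

# FRAP parameter recovery at the values reported for LD condensates
traces = dc.synth_frap(mobile_fraction=0.82, t_half_s=169.0,
                       frame_interval_s=5.0, n_frames=122, seed=0)
fit = dc.fit_frap(traces)
print(round(fit.mobile_fraction, 3), round(fit.t_half_s, 1))  # -> 0.82 169.0
```

With deep sticker wells (χ = 4) most chains condense into one cluster;
with χ = 0 the same system stays dispersed (mean largest-cluster fraction
0.088 vs 0.708 over five seeds — see `analysis/02_cluster_regimes.py`).
The FRAP fitter returns the generator's ground truth exactly on noiseless
curves: mobile fraction 82%, t½ = 169 s.

The numbered scripts under `analysis/` run the full story and write their
tables to `results/`: region catalogue and system bookkeeping (33 chains
in a 30 nm box ≈ 2 mM, 150 mM salt ≈ 2439 ion pairs), the two clustering
regimes and their reversal, contact maps with per-residue profiles (the
strongest inter-chain contacts fall on sticker residues), two-species
mixing (an inert peptide stays 99% free while sticky chains cluster), and
the quantification fits (FRAP 82%/169 s and 27.6%/281.5 s; D = 0.18 µm²/s;
masses 135/157/147/95 kDa; Kd 2 µM and 20 µM).

A `drcluster` command-line interface wraps the same functions
(`drcluster regions`, `simulate`, `contacts`, `clusters`, `frap`,
`massfit`, `binding`, `pipeline`, `validate`); see `--help`.

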