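# Methods

## Scope and design

The package re-implements, as a tested pipeline, the computational layer
of a condensate study of the IRE1α lumenal domain: the multi-chain
coarse-grained simulations that probe whether its disordered regions
self-associate, the contact-map analysis of those trajectories, and the
quantitative fits (FRAP, mass photometry, binding isotherms) behind the
reported numbers. The original trajectories come from a residue-resolved
force field run on HPC hardware; reproducing that machinery is not the
goal here. Instead the simulator is a bespoke sticker–spacer model whose
only job is to produce multi-chain trajectories with tunable, reversible
clustering on a desk-scale budget, so that the analysis layer — which *is*
reproduced in full — can be exercised and validated end to end.

## Region model

LD numbering is 1-based and inclusive. Built-ins: DR1 (131–152), DR2
(307–358), DR3 (369–389), the linker-region peptide (369–443; the chain
simulated in multi-copy systems), cLD (24–389) and LD (24–443). DR3 is
stored as the 369–389 slice of the linker peptide because the two
conventions overlap: results prose distinguishes DR3 from the 390–443
linker, while the simulated peptide spans 369–443. Both are exposed;
neither is treated as canonical. cLD/LD are boundary-only (sequences
loadable from FASTA). Residue classes: negative {D,E}, positive {K,R},
aromatic {F,Y,W}, hydrophobic {A,I,L,M,V}, polar {C,H,N,Q,S,T}, other
{G,P} — every canonical residue in exactly one class.

## Sticker–spacer simulator

Chains are bead polymers (default one bead per residue; a two-bead
backbone/sidechain mapping exists mainly to exercise the bead→residue
aggregation rule). Potential terms (nm, kJ/mol):

- harmonic bonds: b₀ = 0.38 nm, k = 500 kJ·mol⁻¹·nm⁻²;
- soft repulsion between all bead pairs: U = ε_rep(1 − r/σ)² for r < σ,
  with ε_rep = 25, σ = 0.47 nm;
- Gaussian sticker wells between attractive class pairs:
  U = −χ·ε_ss·exp(−(r − r₀)²/2δ²), r₀ = 0.50 nm, δ = 0.12 nm, truncated
  at r₀ + 4δ. Default well depths ε_ss = 3 kJ/mol for opposite charges
  and for aromatic–aromatic; like charges and all other pairs are zero.
  The single crowding knob χ ≥ 0 scales all well depths (the in-silico
  proxy for a crowding agent).

Dynamics are overdamped Langevin: Δx = −∇U·dt/γ + √(2k_BT·dt/γ)·ξ, with γ
chosen so a free bead diffuses 1 nm²/ns at 300 K. The default time step
is dt = 0.002 ns. Two constraints set it: the enforced stability bound
(per-step displacement SD below σ/4) and well resolution — at dt = 0.005
the per-step noise (0.10 nm) is comparable to the well width δ, beads
jump across the wells, and binding becomes spuriously weak; at dt = 0.002
(0.089 nm) bound dimers are stable on the 100 ns scale. Ions are
bookkeeping only: Na⁺/Cl⁻ counts for the configured salt concentration
(150 mM default) plus minimal neutralization are recorded in trajectory
provenance, never simulated; electrostatics enter solely through the
class-pair attraction matrix.

Initial packing inserts chains as self-avoiding random walks at random
positions and orientations, rejecting any placement with an inter-chain
bead distance below σ. How the original study handled insertion overlap
is not stated; σ-exclusion is this package's choice. A compiled (numba)
kernel with a Verlet neighbor list integrates the dynamics; a pure-numpy
engine implements the identical model and serves as the reference in
tests (the two agree to floating-point roundoff over short runs; over
long runs they are independently valid realizations).

### Study conditions and the scaled-down demonstration system

The configuration defaults mirror the study setup: a 30 nm cubic periodic
box, 33 copies of one region (≈ 2 mM) or 16 + 16 copies of two regions,
150 mM salt, 300 K. Those systems (1,700+ beads, multi-µs equilibration)
are too slow for a test suite, so the regime demonstrations use a
scaled-down surrogate chosen once: 12 copies of the 6-residue multivalent
sticker peptide DKFDKF in a 13 nm box, 800 ns (4·10⁵ steps), five seeds.
Short chains keep the diffusive encounter rate high; the composition
concentrates the same sticker chemistry (D/K charge pairing, F/F
aromatics) that the contact analysis attributes to DR2 and the linker.
χ = 0 is the inert regime (DR1-like: mean largest-cluster fraction 0.09);
χ = 4 (well depth 12 kJ/mol ≈ 4.8 k_BT per sticker pair) is the
clustering regime (DR2/linker-like: mean fraction 0.71, every seed ≥ 0.58),
chosen over deeper wells because it keeps the clusters liquid-like — chains
exchange, and dropping χ to zero mid-run disperses the clusters within
tens of ns, mirroring crowding-agent wash-out. What these tests show is
that the *analysis layer* correctly distinguishes and quantifies the two
regimes of a model with known behaviour; they say nothing about the real
peptides' force-field energetics.

## Contact-map analysis

Two beads are in contact when their minimum-image distance is strictly
below the cutoff (0.5 nm; "nearer than" is read as strict). Bonded pairs
are excluded, as are intra-chain pairs whose along-chain bead separation
is below the exclusion window (default 3). Two chains interact when they
share at least `chain_threshold` (default 1) inter-chain bead contacts;
clusters are connected components of that graph, with components of
size 1 reported as free chains.

Central-chain averaging, per frame: frames with no cluster of ≥ 2 chains
contribute nothing; otherwise the largest cluster is analyzed (tie →
cluster containing the lowest chain id; `--all-clusters` semantics are
future work) and its central chain is the one with maximum degree in the
cluster's graph (tie → most total bead contacts → lowest id). The frame
matrix entry (i, j) is the fraction of the central chain's graph-adjacent
neighbors whose bead j contacts central bead i — contacts are counted
only against neighbors, not the whole cluster. The final matrix is the
mean over contributing frames; both the contributing and total frame
counts are stored, because the source does not state whether contact-free
frames enter the average (they do not, here). Two-chain mode drops the
central-chain notion: entry (i, j) is the fraction of *all* frames in
which bead i of chain 1 contacts bead j of chain 2. Bead matrices reduce
to residue level by taking the maximum score over the bead pairs of each
residue pair, and to a 1D profile by symmetrizing ((M + Mᵀ)/2, applied at
projection time only) and summing over partners.

Determinism note: because ties in cluster and central-chain selection are
broken by chain id, relabelling chains can change the result in exactly
tied frames; the relabelling-invariance property therefore holds for
configurations whose per-frame selections are unambiguous, and the test
suite checks it on such a configuration. Correctness of the production
path (spatial hashing via a periodic k-d tree) is defined by a brute-force
O(n²)-per-frame re-implementation that the tests run on randomized small
systems.

## Cluster kinetics and mixing

Events are scored frame-to-frame at the saved-frame resolution with no
hysteresis: a join is free→clustered between consecutive frames, a leave
the reverse; dwell segments are maximal in-cluster runs. For two-species
systems the mixing statistic is the heterotypic fraction of inter-chain
edges pooled over frames, compared with the random-partner expectation
2p_Ap_B/(p_A + p_B)² (p = chain count fractions); the source reports
mixing only qualitatively, so this enrichment ratio is a constructed
metric. Zero inter-chain edges yields a flagged undefined result, not
NaN.

## Quantification fits

All fits are deterministic: fixed, documented initializations, no random
restarts.

**FRAP.** Three-ROI processing: background-subtract the FRAP and
reference traces; divide by the per-frame bleaching factor
(ref − bg)/mean pre-bleach (ref − bg); renormalize so the mean pre-bleach
level is 1 and the first post-bleach point is 0. The recovery is fit to
one-phase association Y(t) = Y₀ + (Plateau − Y₀)(1 − e^{−Kt}), by default
with no offset (Y₀ = 0); t½ = ln 2/K exactly, and the mobile fraction is
defined as the fitted plateau of the normalized curve (the source reports
mobile fractions without a formula; this matches its normalization).
Diffusion coefficients use the Soumpasis closed form D = 0.224 w²/t½ for
a uniform circular spot of radius w — implemented as the single formula
(the alternative half-time relation for Gaussian spots is documented but
not a second code path). The bleach-spot radius behind the reported D
values is not printed, so D is reproducible only at formula level. The
synthetic FRAP generator uses the same single-exponential recovery (not a
2D reaction–diffusion model) with an acquisition-bleach envelope and
Gaussian noise.

**Mass photometry.** Contrast→mass calibration is an OLS line through a
standard ladder; the default ladder is BSA monomer/dimer/trimer at
66.4/132.8/199.2 kDa (sequence mass of the mature chain; the source names
the species, not the numbers — override as needed). Mass distributions
are fit as Gaussian mixtures by EM on the event list (bin-width
independent, equivalent at desk precision to the source's histogram fit),
with deterministic quantile-based initialization; components whose SD
collapses below 0.5 kDa trigger a degeneracy-flagged refit with one
component fewer. Oligomer states are the nearest integer multiple of a
supplied monomer mass. Synthetic event lists are exact (untruncated)
Gaussian draws: truncating a broad component (e.g. SD 67 kDa at mean
135 kDa) at zero would bias its mean by +3.6 kDa, larger than the ±3 kDa
recovery tolerance the reported values imply, so positivity is enforced
only for measured samples.

**Binding.** Single-site isotherm r(L) = r₀ + (r_max − r₀)L/(Kd + L),
initialized at r₀ = min, r_max = max, Kd = geometric mid-grid. Flat
curves and Kd estimates pinned to the grid bounds are flagged
unidentifiable; generation warns when the concentration grid does not
bracket the ground-truth Kd.

## Numerical choices and degenerate inputs

- Cutoff boundary: strict `<`; contacts exactly at the cutoff distance do
  not count (measure-zero in practice, pinned by tests at 0.49/0.50/0.51).
- The k-d tree neighbor query is inclusive, so a strict post-filter is
  applied; coordinates are always wrapped into [0, box) before queries.
- Zero contributing frames in central-chain averaging raise an explicit
  error rather than returning a silent zero matrix.
- Flat FRAP and binding curves return flagged, non-converged fits instead
  of raising.
- Trajectories shorter than two frames yield empty kinetics with a
  status flag.
- The mass-fit SD floor (0.5 kDa) is far below any real peak width and
  only guards EM collapse on point-mass samples.

## Limitations

- The simulator is a stand-in: no force-field fidelity, implicit ions, no
  barostat (fixed box), single-bead hydrodynamics. Passing regime tests
  validates the analysis pipeline, not the energetics of the real
  peptides.
- Mobile fractions and half-times are recovered from synthetic data
  generated with the reported values as ground truth; they are
  parameter-recovery checks, not re-measurements.
- The mixing enrichment is a constructed statistic with an edge-level
  null; a permutation test is the obvious extension.
- Binary trajectory formats (XTC/TRR) are out of scope; the XYZ dialect
  plus topology sidecar is the only trajectory exchange format.
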