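# Methods

This note documents the models, numerical choices and limitations behind
`camdesign`. Reduced units are used throughout the synthetic systems: the
thermal energy kT sets the energy scale (kT = 1 unless stated), lengths
share the contact-cutoff unit (4.5 "Å-equivalents"), and time is measured
in integrator steps.

## Synthetic world (`toyworld`)

The package replaces three external resources with testable synthetic
stand-ins whose ground truth is emitted alongside the data.

**Toy potentials.** Shipped analytic surfaces with vectorized energies and
gradients: a harmonic well ½k|x−c|²; a tilted double well
V(x) = (x²−1)² + h·x (minima near ±1, unit barrier at 0; negative h lowers
the x = +1 "active" basin), optionally padded with harmonic orthogonal
dimensions; and the standard four-Gaussian Müller–Brown surface. Every
gradient is validated against central finite differences at 100 random
points (relative tolerance 1e-5).

**Dynamics.** Overdamped (first-order) Langevin integration by
Euler–Maruyama: x ← x − (dt/γ)(∇V + k_r(x − anchor)) + √(2 kT dt/γ)·ξ.
First-order dynamics samples the same stationary (Boltzmann) distribution
as thermostatted second-order dynamics at a fraction of the cost, which is
all the downstream free-energy machinery needs. Stability constraint of the
explicit scheme: (k_r + max curvature)·dt/γ must stay below 2; configuration
defaults respect this pairing (e.g. the toy pipeline uses restraint 50 with
dt = 0.01, while the Müller–Brown benchmark uses restraint 1e4 with
dt = 1e-5). Discretization bias of the stationary variance is
O(k·dt/2) and covered by the 5 % tolerance of the harmonic-well check.

**Planted contact geometry.** Fixture generators must realize an *arbitrary*
planted residue contact graph exactly. Residue markers sit on a widely
spaced lattice (10 cutoffs apart); each planted pair receives a dedicated
"interaction site" on a second lattice far from the markers, holding one
bridge atom from each residue of the pair — 2.0 units apart for a planted
contact, 13.5 for a planted non-contact. Distinct sites are at least one
lattice spacing apart, so no spurious contacts can arise; the construction
is deterministic and non-physical by design (a residue's bridge atom may be
far from its marker), which is irrelevant to the contact and correlation
observables the analyzers consume. Structure-ensemble members add Gaussian
coordinate noise; the generator rejects noise scales large enough
(> margin/6 σ) to flip a planted contact.

**Correlated fluctuations.** Marker displacements are multivariate normal
with a block correlation matrix (within-community ρ_w on the diagonal
blocks, ρ_b off them; checked for positive semi-definiteness), applied
rigidly to all atoms of a residue, independently per Cartesian component,
with per-coordinate amplitude 0.2. The amplitude is ≈ 8σ below the contact
margins, so planted occupancies stay exactly 0 or 1 while measured
correlations match the targets. `contact_prob_within`/`between` are edge
probabilities of the planted random graph — planted edges are
always-in-contact, non-edges never.

**Toy stability table.** An additive map (position, amino acid, state) →
energy; a sequence's score in a state is the sum over positions (missing
entries 0) plus Gaussian replicate noise seeded by a hash of
(seed, sequence, state, replicate), making every replicate reproducible and
replicate 0 ≠ replicate 1 as a real scorer's repacking stochasticity would
be.

What the toy world does **not** emulate: real force fields, membrane and
solvent environments, backbone plasticity, scorer systematic error, and any
coupling between the contact network and the stability table beyond the
planted entries. Passing tests demonstrate the *algorithms* recover planted
truths under controlled conditions, not that the pipeline's biological
predictions are accurate.

## String method with swarms (`stringpath`)

Images live in scaled CV space (each CV divided by its declared scale so
distances and RMSDs are commensurable; scales default to 1). Defaults: 18
images, fixed endpoints, 32 swarms per image. Per iteration every image —
including fixed endpoints, whose positions never move — is (1) equilibrated
under a harmonic CV restraint to the image (default constant 1e4 in reduced
units; the restrained walker fluctuates by √(kT/k_r) ≈ 0.01 at kT = 1),
then (2) launches its swarm of short unbiased trajectories. The endpoint
swarms contribute no image updates but supply the end-basin sampling the
Markov model needs. The image update is the standard endpoint-drift
estimator, equilibrated CV point + mean(end − start), followed by
piecewise-linear equal-arclength reparameterization (output points lie on
the polyline through the proposed points at uniform arclength; fixed
endpoints are preserved bitwise). RNG streams derive from
(seed, iteration, image, swarm), so batched evaluation order cannot change
results and full runs are bit-reproducible.

Convergence: strings are averaged image-wise over blocks of B iterations
(default 20) and the mean per-image displacement between consecutive block
averages is compared to a tolerance (default 1e-3). On the Müller–Brown
benchmark (dt = 1e-5, kT = 1 against barriers of order 100, 300 iterations)
the converged 18-image string lies within ~0.02 reduced units (mean per
image) of a dense zero-temperature steepest-descent string — the
deterministic minimum-energy path the stochastic method should approach at
low noise.

Restrained dynamics requires an invertible CV map; for the toy engines this
means full raw-coordinate CV sets. Distance and RMSD CVs (including the
four activation-microswitch presets: CWxP/PIF/NPxxY motif RMSDs and the
TM3–TM6 ionic-lock Cα distance) evaluate on structures and serve analysis
projections.

## Markov state models and free-energy surfaces (`felmsm`)

Input are swarm (start, end) pairs from the last N iterations of a string
run (N configurable, default 40 in the pipeline; the count equals
N × images × swarms on complete histories). Optional tICA solves the
symmetrized time-lagged generalized eigenproblem on mean-free data (lag =
one swarm by default); k-means (seeded, scikit-learn) discretizes (k = 20
in the toy pipeline; choose ~100 for richer systems). Counts are
(state(start) → state(end)); estimation restricts to the largest strongly
connected set and reports discarded states. The reversible estimator is the
standard self-consistent detailed-balance fixed point
x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j), iterated to 1e-13 on π; row
sums are renormalized to cancel float drift, and the returned model
satisfies row-stochasticity (1e-12), stationarity (1e-10) and detailed
balance (1e-8). A non-reversible row-normalized fallback exists for
diagnostics. Note the reversible estimator assumes sampled flows are
balanced; transition pairs should come from trajectories (or swarms at
equilibrated starts), not from arbitrarily reweighted start states.

Free-energy surfaces: each sample in model state i carries weight π_i/n_i;
F(bin) = −kT_proj·ln(Σ weights), shifted so the occupied minimum is exactly
0; empty bins are masked, never interpolated. Grid default 40×40 over the
sampled range padded 5 %; kT_proj defaults to the engine temperature.
Samples landing in discarded microstates raise by default (`drop` is
opt-in) so silent data loss cannot occur.

## Contact comparison and ΔΔG scanning

Contacts: minimum heavy-atom distance < 4.5 (strict), sequence-adjacent
pairs (|Δindex| ≤ 1) excluded, frequencies exact ratios of member counts.
Exclusivity defaults presence_min = 0.5, absence_max = 0 ("present in at
least half the target-state members, absent from the other state"); both
configurable, and the filter is monotone in both thresholds. The
dopamine-receptor worked example ships a *synthetic reconstruction* of the
twelve inactive-exclusive contact pairs (see
`statecontacts.D2R_INACTIVE_CONTACTS_SYNTHETIC`): the pairings are not
authoritative, only the documented residue membership is, which is exactly
what position selection consumes.

ΔΔG: substitutions exclude glycine and proline (backbone perturbers) and
the wild type (17 targets; 18 when the wild type is itself G or P).
Replicates are paired — mutant minus wild type within the same replicate
index — which cancels replicate-common noise; the decision value is the
mean over 3 replicates. Per position the ΔΔG argmin is selected when
negative, plus the runner-up when negative and within δ (default 0.5 energy
units) of the best; exact ties break by one-letter code. Antisymmetry under
active/inactive relabeling is an enforced invariant. External scorer output
drops in through a TSV adapter whose scores are mutational ΔG values
relative to wild type per (position, mutant, state, replicate).

## Dynamic networks (`allonet`)

Edges: contact in strictly more than 75 % of frames (an edge at exactly the
threshold is rejected). Node markers are the first atom of each residue
(Cα-like) — configurable via the trajectory container. Correlations are
Pearson-form normalized displacement covariances; linear mutual information
is out of scope. Weights w = −log|C| with |C| clipped into [ε, 1]
(ε = 1e-6). Floyd–Warshall is implemented directly with successor
reconstruction; nodes are processed in sorted order with strict-improvement
relaxation, so co-optimal ties resolve deterministically toward the
smallest intermediate node. Edge betweenness delegates to networkx's
weighted Brandes implementation (unnormalized; co-optimal paths split
equally). Communities: Girvan–Newman driven by weighted betweenness on the
−log|C| weights, scoring every partition encountered (including the
initial one) by modularity with |C| edge weights, returning the maximum.
Exact planted-partition recovery requires communities that are well
embedded in the *contact graph*; sparse graphs with singly attached nodes
can legitimately split those nodes off first.

## Pipeline (`workflow`) and its design choices

The toy pipeline couples stages through one deliberate shortcut: each
scanned mutant's landscape is the two-basin potential
V(x, y) = (x²−1)² + h·x + ½y², with tilt h = `ddg_tilt_coupling` × the
mutant's *computed* mean ΔΔG (coupling 0.2 by default), so a negative ΔΔG
lowers the active basin at x = +1. This encodes the design hypothesis — relative
active-state stabilization tilts the activation equilibrium — in the
simplest landscape that lets the string + MSM stage measure it. The ranking
statistic is the MSM-weighted active-basin population (x > 0) minus the
wild-type baseline; it is an artifact-defined scalar standing in for visual
landscape comparison. Study conditions of the synthetic system: a planted
stabilizer ΔΔG of −6 (representative of the strongly stabilizing end of
real per-mutation scans), replicate σ = 0.05, 4 members per state with
coordinate noise 0.1, string stage at kT = 0.5 against a unit barrier with
5 images, 32 swarms, 80 iterations, last 40 for the MSM. At these
conditions the planted mutant's population shift (≈ +0.4) clears the
sampling scatter of planted-neutral mutants (≈ ±0.2) across seeds.

Configuration is pydantic-validated (unknown keys rejected before any stage
runs); the fully resolved config is written next to the outputs. All
artifacts are plain text (PDB, XYZ at full float precision, TSV, JSON,
GraphML); string JSON round-trips bitwise. The manifest records per-stage
status, artifacts, seeds and wall time; wall time aside, a rerun with the
same config and seed reproduces every stage artifact byte for byte. Stage
failure halts the run with completed stages marked reusable (CLI exit
codes: 0 ok, 1 validation error, 2 stage failure). Ligand-response
(agonist-stimulation) normalization is deliberately excluded from the assay
arithmetic; only baseline percent-of-reference activity and expression are
computed, per plate.

## Known limitations

- The toy ΔΔG → landscape-tilt coupling is linear and noiseless; real
  free-energy shifts need not track scanner ΔΔG at all — that disagreement
  is precisely what the string + MSM stage exists to detect in real use.
- The string engine contract covers in-process toy engines only; no
  external MD backends.
- tICA is linear; k-means microstates are Voronoi cells in that space.
  No implied-timescale or Chapman–Kolmogorov model selection is provided
  beyond eigenvalue reporting, and no committor analysis.
- Cross-receptor residue correspondence (for mixed-receptor ensembles) is
  by user-supplied index mapping; no generic-numbering service is called.
- Girvan–Newman is O(E²·V log V) as used here — fine for residue networks
  of hundreds of nodes, not for much larger graphs.
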