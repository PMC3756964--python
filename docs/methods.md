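# Methods

## Scope and representation

The package implements the low-resolution (rigid-body) stage of
protein–protein docking and its evaluation machinery. Both partners are
kept internally rigid; the only degrees of freedom are the six rigid-body
coordinates of the mobile partner (the ligand) relative to the fixed one
(the receptor). All-atom refinement is out of scope: energy-based
analyses accept any energy column, with the low-resolution total as the
default.

Structures are reduced to backbone atoms (N, CA, C, O) plus one centroid
pseudo-atom per residue. The centroid is the arithmetic mean of the
side-chain heavy atoms — a deterministic, hydrogen-free reading of the
pseudo-atom's role as the interaction center of the side chain — with CA
as the fallback for glycine or side-chain-less residues. A residue
without CA is a fatal input error (CA anchors the metrics and the
encounter geometry); a residue missing another backbone atom is dropped
with a warning rather than reconstructed. Alternate locations resolve to
the highest occupancy (ties: first encountered); insertion-coded residues
stay distinct.

A pose maps a mobile-partner point `x` to `R (x − c) + c + t`, where `c`
is the mobile partner's center of mass over interaction sites, fixed at
model build time. Perturbing about the *current* center of mass then
composes as a left rotation product plus a translation sum, which keeps
Monte-Carlo proposals cheap and exactly invertible. Rotating about the
center of mass (rather than an arbitrary frame origin) keeps the
translation and rotation step sizes independently interpretable.

## Energy function

`E = w_c·contact + w_v·vdw + w_e·env + w_p·pair`, weights 2.0/1.0/1.0/1.0.

* **contact**: −0.25 REU per residue (over both partners) with ≥ 1
  cross-partner centroid within 6 Å. Counting residues, not pairs,
  reproduces the defining equivalence of the cap: 40 contacting residues
  ↔ −10 REU. With the cap enabled the term is bounded below at −10 REU,
  which prevents over-stabilization of spuriously large interfaces but
  also flattens gradients around large-interface optima — hence half of
  all sampling runs capped and half uncapped (shotgun: half the decoys;
  replica: half the trajectories).
* **vdw**: the functional form of the overlap penalty is a design choice
  here: a soft quadratic, `Σ (r_clash − d)²/r_clash` over cross-partner
  interaction-site pairs (backbone + centroid) with `d < r_clash = 3 Å`.
  It is smooth, non-negative, cheap, and its scale is compatible with the
  0.1-REU slide-into-contact threshold (one site pair overlapping by
  ~0.55 Å crosses the threshold). `r_clash` and the site set are
  configurable.
* **env/pair**: tabulated potentials. The env table maps (residue type,
  cross-partner centroid neighbor count within 10 Å, clamped to the
  table range); the pair table maps residue-type pairs in centroid
  contact (< 6 Å) and must be symmetric. The shipped defaults are
  *synthetic stand-ins* (env proportional to Kyte–Doolittle hydropathy ×
  burial; pair from charge products and hydrophobic pairing, magnitudes
  ≤ ~0.1 REU so contact dominates), generated in code and replaceable by
  user-supplied TSV tables.

**Encounter restraint**: a flat-bottom harmonic between the two center
atoms (the CA nearest each partner's center of mass): zero for center
distance `d ≤ d0 = R1 + R2 + g`, else `k (d − d0)²`, with `R_i` the
maximal center-to-site distance of partner i, gap `g = 8 Å`, and
`k = 0.25 REU/Å²`. Only `k`'s positivity matters for its role (confining
unbound replicas to touching range); any pose with touching partners has
`d ≤ d0`, so the restraint never biases the bound ensemble. It is kept
out of the reported interchain total and added only to the sampling
energy, so post-hoc energy filters are unaffected.

## Movers and initial placement

Uniform rotations are drawn from the Haar measure by the z-y-z Euler
construction (α, γ uniform on [0, 2π); β = arccos z, z uniform on
[−1, 1]); correctness is asserted against the (1 − cos θ)/π angle density.
The perturbation mover draws Gaussian per-axis translations (sd 0.7 Å)
and builds its rotation in two steps: three Gaussian z-y-z Euler angles
(magnitude 5°) are converted to axis–angle, the angle is kept, and it is
applied about a fresh unbiased axis from the Marsaglia (x, y)-disc
construction. Axis uniformity over the full sphere makes the proposal
density symmetric — the Metropolis prerequisite — which the tests verify
empirically (forward and reverse increment distributions coincide). The
resulting angle distribution is checked to be positive and unimodal; its
exact shape is deliberately not asserted.

Initial placements rotate both partners independently by uniform
rotations about their centers of mass (composed into one relative pose)
and then slide the ligand along the center–center axis in 1 Å steps:
outward while the clash score is ≥ 0.1 REU, then inward until it exceeds
0.1 REU. The returned pose therefore satisfies a first-touch contract —
clash > 0.1, one step further out ≤ 0.1 — and the search errors out
beyond 500 Å of travel. The slide direction (the line joining partner
centers) is a design choice; the distance being slid is otherwise
underdetermined.

## Protocols

**Shotgun**: per decoy, a fresh random placement followed by 500
Metropolis steps at fixed β (default: the ladder's middle level, a
choice, configurable) with step sizes rescaled every 50 steps by
`clamp(acceptance/0.5, 0.5, 2.0)` (floor 1e-4) toward 50% acceptance.
The output is the lowest-energy pose visited. Adaptation formally breaks
stationarity, so it is confined to shotgun; replica trajectories use
fixed move parameters.

**ReplicaDock**: each trajectory couples one replica per ladder level
with a shared energy (including the encounter term). Swaps between
adjacent levels alternate even/odd pairs at every swap event (every
1,000 steps), accepted with `min(1, exp((β_i − β_j)(E_i − E_j)))` and
exchanging configurations between levels. Snapshots of *all* levels are
recorded every 1,000 steps, giving the exact record-count law
`trajectories × levels × steps/stride` (60,000 at the full cadence of
4 × 3 × 5×10⁶/10³). Per-pair exchange attempts and acceptances are
logged and written into the decoy-table header.

**Temperature ladder**: the defaults β = (1.8, 0.75, 0.3) REU⁻¹ were
calibrated once on the shipped toy complex so that the coldest level is
bound-dominated (~100% of snapshots in contact), the hottest
unbound-dominated (~95% without contact), and adjacent exchange rates
land near 25% (measured ~15–23%). The ladder is fully configurable and
`tune_ladder` bisects the spacing ratio of a geometric ladder against a
target exchange rate using short pilot runs.

**Filtering**: drops the hottest level (configurable), removes rows with
total interchain score strictly above 10 REU, and optionally keeps the
`top_k` lowest totals (ties by trajectory, then step). The energy filter
acts on the weighted total: the published protocols phrase one filter in
terms of the contact term, but that term is ≤ 0 by construction, so the
total-score reading is the only consistent one; the cutoff is exposed.

## Evaluation

CAPRI conventions on the reduced representation, with the interaction
sites playing the role of heavy atoms: native contacts are cross-partner
residue pairs with any site pair < 5 Å in the reference; interface
residues have any cross-partner site < 10 Å; `I_rms` is the backbone RMSD
over interface residues after optimal (Kabsch) superposition on those
residues; `L_rms` superposes receptors and measures ligand backbone RMSD;
`f_nat` = recovered/native contacts. `f_non_nat` defaults to the CAPRI
denominator (non-native decoy contacts / total decoy contacts, ≤ 1); a
native-contact denominator, which can exceed 1, is available behind a
flag for comparison with summaries that use it. Hits: `I_rms ≤ 2.5 Å`.

**Clustering** is deterministic greedy leader clustering over the top-n
(default 2,000) lowest-energy decoys in ascending-energy order: a decoy
joins the first cluster whose founder (= its lowest-energy member, the
representative) is within 5 Å ligand backbone RMSD, else founds a new
cluster; ranking is by size, ties by representative energy. Greedy
leader in energy order is O(n·k), reproducible, and makes the
representative's optimality structural rather than incidental.

**Native-basin overlap**: the region is bounded by the reference
ensemble's 50th-percentile energy and 75th-percentile `I_rms`; the count
`n` of decoys inside maps to none (0), magic points (1–2), sporadic
(3–9) or dense (≥ 10). The two count thresholds are reconstructions
(exposed as configuration, not asserted as canonical), and any reference
ensemble may be supplied — the analysis is not tied to a particular way
of generating the reference.

**Landscape maps** bin the receptor→ligand center direction into a
(θ, φ) grid (36 × 72 default) and report per-cell populations and
minimum energies, with empty cells distinct from zero (NaN).
**Percentile normalization** shifts all ensembles of a target so the
global maximum is 0, divides by |mean of the 10 lowest pooled energies|,
and reports lower-percentile boundaries (5/1/0.1% default); the formula
is scale-invariant and degenerate (all-equal) input is an error.

## Synthetic fixtures

`make_toy_complex` builds poly-alanine pseudo-proteins with ideal-geometry
backbones whose interface is a flat 5.2 Å lattice of matched residue
columns. The cross-partner gap alternates between 3.4 Å (just above the
3 Å clash radius) and 5.85 Å (just under the 6 Å contact cutoff), and
four tight columns are laterally staggered by 2.6 Å. This mixture makes
the native pose a *strict* optimum of the uncapped contact+clash score
under coarse perturbations — compression or tilt triggers the clash term,
any ~2 Å lateral or outward move breaks wide-column contacts — which a
brute-force grid scan verifies in the tests (a smooth matched-curvature
interface was considered and rejected: its rotational near-symmetry
leaves ties in the binary contact count). Non-interface residues are
buried > 9 Å from every cross-partner centroid, so the native contact
count is exact by construction and re-verified by brute force at build
time. Coordinates get a ±0.02 Å seeded jitter so different seeds give
distinct models without threatening any margin.

The toy complexes emulate the *geometry* of a docking problem (a unique
funneled native basin, controllable contact counts), not the statistics
of real interfaces: residue diversity, backbone flexibility, shape
irregularity and realistic env/pair signals are absent. Passing tests
therefore demonstrate correctness of scoring, sampling and evaluation
machinery — not predictive accuracy on real complexes, which depends on
the potentials supplied.

`make_toy_landscape` provides enumerable state spaces (two-state,
discretized quadratic well, seeded rugged 1-D) whose Boltzmann
distributions are computed by direct summation — the exact oracles for
the Metropolis and replica-exchange engines. Movers on landscapes are
either periodic neighbor steps or uniform jumps; both are symmetric, and
the jump mover's O(1) mixing keeps goodness-of-fit tests statistically
valid at modest chain lengths. `make_decoy_fixture` produces decoy sets
with exact accuracy strata (< 1 Å near-native vs co-located > 20 Å far
poses) for hit-calling, clustering and overlap tests with known ground
truth.

## Numerical choices and problem sizes

Quaternions are renormalized at every composition (norm drift < 1e-9 over
10⁶ compositions); quaternion algebra is hand-coded for Monte-Carlo speed
and cross-checked against scipy's Rotation in the tests. Superpositions
use scipy's Kabsch implementation. Distances use strict inequalities at
cutoffs (`< 6`, `< 3`, `< 5`, `< 10`); the decoy energy filter keeps the
boundary (strictly greater is removed); the hit threshold is inclusive
(`≤ 2.5`). Degenerate slide input with coincident partner centers falls
back to a fixed +z axis for determinism. Non-finite proposal energies
are rejected with a warning; a non-finite *initial* replica energy aborts
the trajectory.

The test suite and the worked examples run the full protocols at reduced
cadence (e.g. 2 × 3 × 10⁴ steps with 10³-step strides, 10⁵–10⁶-step chains
on enumerable landscapes), sizes chosen so every statistical check keeps
comfortable power while the whole suite completes in a few minutes on one
core; the record-count law and all contracts are cadence-independent.

## Known limitations

* Internal (backbone/side-chain) flexibility is not modeled; targets
  whose binding requires conformational change are outside the method's
  reach by construction.
* The shipped env/pair tables are labeled stand-ins; quantitative
  energies on real proteins require supplying measured tables.
* Replica trajectories run sequentially in one process; no MPI/GPU
  parallelism.
* mmCIF input, hydrogen handling, and residue repair/renumbering are not
  supported.
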