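# replidock

Rigid-body protein–protein docking at low resolution, with two sampling
strategies: classic **shotgun sampling** (many independent short
Monte-Carlo minimizations from random starts) and **ReplicaDock** —
temperature replica-exchange Metropolis Monte Carlo, in which the coldest
replica behaves like the bound state and the hottest like the unbound
state, so trajectories repeatedly bind, unbind, and re-bind somewhere
else. The package is aimed at method developers and students of docking
energy landscapes: every stage — scoring, sampling, evaluation — runs
end-to-end on synthetic two-body complexes with a known native pose, so
no structure downloads are needed, while real PDB files of two binding
partners are accepted the same way.

## Model

Structures are reduced to a residue-centroid representation: the backbone
atoms N, CA, C, O plus one **centroid pseudo-atom** per residue (the mean
of the side-chain heavy atoms; CA for glycine). Chains are assigned to
two partners, a fixed receptor and a mobile ligand whose six rigid-body
degrees of freedom (a unit quaternion **q** and translation **t**) are
the only variables.

The interchain score (in Rosetta Energy Units, REU) is

```
E = 2.0 · E_contact + 1.0 · E_vdw + 1.0 · E_env + 1.0 · E_pair
```

* `E_contact = −0.25 · n`, where `n` is the number of residues with at
  least one cross-partner centroid within 6 Å; optionally capped below at
  −10 REU (the score of 40 contacting residues). Half of all sampling
  uses the cap, half does not.
* `E_vdw = Σ (r_clash − d)² / r_clash` over cross-partner site pairs with
  `d < r_clash = 3 Å` — a soft overlap penalty.
* `E_env`, `E_pair` — tabulated statistical potentials over cross-partner
  centroid neighbor counts (10 Å) and residue-type contact pairs. The
  shipped default tables are synthetic stand-ins (hydropathy and charge
  complementarity); supply measured tables as TSV for production use.

Sampling uses a symmetric rigid-body proposal (Gaussian translations,
sd 0.7 Å; rotations of Gaussian-Euler-derived angle about a uniformly
random axis, magnitude 5°), accepted by the Metropolis criterion
`min(1, exp(−β ΔE))`. Shotgun runs 500 steps per decoy with step sizes
adapted every 50 steps toward 50% acceptance and outputs the best pose
visited. ReplicaDock runs 4 trajectories of 3 coupled replicas
(β = 1.8, 0.75, 0.3 REU⁻¹ by default, tunable with `tune-ladder`) for
5×10⁶ steps, attempts neighbor swaps every 1,000 steps with probability
`min(1, exp((β_i − β_j)(E_i − E_j)))`, and snapshots all levels every
1,000 steps — 60,000 decoys per target at full scale. A flat-bottom
**encounter restraint** `k (d − d0)²` beyond `d0 = R1 + R2 + 8 Å`
(partner radii plus a gap) keeps unbound replicas within touching range
without biasing bound poses.

Decoys are evaluated with CAPRI-style metrics against the bound
reference — interface RMSD (`I_rms`), ligand RMSD (`L_rms`), fraction of
native contacts (`f_nat`) and of non-native contacts (`f_non_nat`) — with
hits defined as `I_rms ≤ 2.5 Å`. Ensemble analyses include greedy leader
clustering ranked by size, classification of native-basin overlap against
a reference ensemble (none / magic points / sporadic / dense), spherical
population and minimum-energy landscape maps, and percentile energy
normalization for cross-method comparison.

## Worked example

```sh
# a synthetic 30+20-residue complex with exactly 40 native contacts
replidock fixture --kind complex --out toy.pdb
replidock score --pdb toy.pdb --receptor-chains R --ligand-chains L
```

prints

```
contact=-10.000 vdw=0.000 env=0.000 pair=0.000 total=-20.000
```

— 40 contacting residues at −0.25 REU each reach the −10 REU capping
point exactly (capped and uncapped coincide), no sites overlap, and the
default weights double the contact term into a −20 REU total.

```sh
replidock fixture --kind decoys --out decoys.tsv   # 10 near + 90 far decoys
replidock metrics --decoys decoys.tsv --native toy.pdb \
    --receptor-chains R --ligand-chains L | tail -1
replidock cluster --decoys decoys.tsv --native toy.pdb \
    --receptor-chains R --ligand-chains L
```

prints

```
# hit_fraction	0.1000
rank	size	representative	rep_energy
1	90	10	0.000
2	10	1	-20.000
```

— exactly the 10 near-native decoys are hits, and clustering at 5 Å
recovers the two constructed groups: the far group (90 members, zero
interchain energy) and the near-native group (10 members, −20 REU
representative).

Sampling works the same way from Python:

```python
import numpy as np, replidock as rd

toy = rd.make_toy_complex(30, 20, 40, seed=7)
config = rd.ReplicaConfig(n_trajectories=2, n_steps=10_000,
                          swap_stride=1000, snapshot_stride=1000)
table = rd.run_replica_dock(toy.model, config, np.random.default_rng(0))
len(table)          # 60 == 2 trajectories x 3 levels x 10 snapshots
```

## File formats

* **PDB** (wwPDB v3.3 ATOM records) for structures; centroid models are
  written with the pseudo-atom named `CEN`.
* **Decoy tables**: TSV with fixed columns (trajectory, level, step, cap
  flag, per-term energies, total, pose as unit quaternion + translation).
* **Potential tables**: TSV with `[env]` and `[pair]` sections
  (see `replidock.centroid_energy.save_tables`).
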