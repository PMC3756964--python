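"""Synthetic two-body complexes and enumerable toy landscapes.

Every sampler, energy term and metric in the package is testable without
external data through two kinds of fixture:

* :func:`make_toy_complex` builds a pair of pseudo-proteins (poly-alanine
  residue geometry on a deterministic lattice scaffold) whose native pose
  has an exactly known number of cross-partner centroid contacts, and is
  designed so that the native pose is the strict minimum of the uncapped
  contact+clash score over coarse rigid-body perturbations.
* :func:`make_toy_landscape` builds small enumerable state spaces whose
  Boltzmann distribution is computable by direct summation — the exact
  oracle for Metropolis and replica-exchange correctness.

Interface construction: matched residue columns across a flat lattice
(spacing 5.2 Å), with the cross-partner gap alternating between a tight
value (3.4 Å, just above the clash radius — compression or tilt triggers
the overlap penalty) and a wide value (5.85 Å, just under the contact
cutoff — any coarse lateral or outward move breaks those contacts).  The
two populations together make the native pose strictly optimal against
2 Å / 15 degree perturbations; non-interface residues are buried well
outside both cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .centroid_energy import ScoreWeights, total_interchain_cen
from .model_io import LIGAND, RECEPTOR, CentroidModel, ValidationError
from .rigid_geometry import (
    RigidPose,
    quat_from_axis_angle,
    random_unit_axis,
)
from .samplers import DecoyRecord

_LATTICE_SPACING = 5.2
_GAP_TIGHT = 3.4
_GAP_WIDE = 5.85
_CA_OFFSET = 1.5
_JITTER = 0.02


@dataclass
class ToyComplex:
    """A synthetic complex: centroid model + its known native pose."""

    model: CentroidModel
    native_pose: RigidPose
    native_contacts: int

    def energy_fn(self, capped: bool = False):
        """Uncapped (default) contact+clash toy score, pose -> REU."""
        weights = ScoreWeights(cap_enabled=capped)

        def fn(pose: RigidPose) -> float:
            return total_interchain_cen(self.model, pose, weights, None).total

        return fn


def _lattice_points(n: int, spacing: float) -> np.ndarray:
    """First n integer-lattice points scaled by spacing, sorted by norm
    then lexicographically (deterministic spiral from the origin)."""
    r = 1
    while (2 * r + 1) ** 2 < n:
        r += 1
    r += 1
    pts = [
        (i * spacing, j * spacing)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
    ]
    pts.sort(key=lambda p: (math.hypot(*p), p[0], p[1]))
    return np.array(pts[:n])


def _residue_atoms(centroid: np.ndarray, outward: np.ndarray):
    """Ideal-geometry backbone for one pseudo-residue: CA offset from the
    centroid along ``outward`` (away from the interface), N/C/O in the
    perpendicular plane."""
    u = outward / np.linalg.norm(outward)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    ca = centroid + _CA_OFFSET * u
    n = ca + 1.46 * t1
    c = ca - 1.52 * t1 + 0.3 * t2
    o = c + 1.23 * t2
    return np.array([n, ca, c, o]), centroid


def make_toy_complex(
    n_res_receptor: int, n_res_ligand: int, native_contacts: int, seed: int
) -> ToyComplex:
    """Build a deterministic complementary two-body complex.

    At the returned native pose (the identity), exactly ``native_contacts``
    residues have a cross-partner centroid within the 6 Å contact cutoff;
    the count is verified by brute-force pairwise distances before
    returning.
    """
    if min(n_res_receptor, n_res_ligand) < 3:
        raise ValidationError("each partner needs at least 3 residues")
    if native_contacts < 2 or native_contacts > n_res_receptor + n_res_ligand:
        raise ValidationError(
            f"cannot realize {native_contacts} contacting residues with "
            f"{n_res_receptor}+{n_res_ligand} residues"
        )
    # balanced interface split, shifted if one partner lacks capacity
    k_a = native_contacts // 2 + native_contacts % 2
    k_b = native_contacts - k_a
    if k_a > n_res_receptor:
        k_b += k_a - n_res_receptor
        k_a = n_res_receptor
    if k_b > n_res_ligand:
        k_a += k_b - n_res_ligand
        k_b = n_res_ligand
    if k_a > n_res_receptor or k_b < 1 or k_a < 1:
        raise ValidationError("interface split infeasible for requested sizes")

    rng = np.random.default_rng(seed)
    p = min(k_a, k_b)
    cols = _lattice_points(p, _LATTICE_SPACING)
    gaps = np.where(np.arange(p) % 2 == 0, _GAP_TIGHT, _GAP_WIDE)
    tight_cols = [i for i in range(p) if i % 2 == 0]

    rec_centroids = [np.array([x, y, 0.0]) for x, y in cols]
    lig_centroids = [np.array([x, y, g]) for (x, y), g in zip(cols, gaps)]

    # stagger a few tight-column ligand centroids laterally: their pairs
    # stay in contact and clash-free at the native pose, but any coarse
    # compressing move with a lateral component drives one of them inside
    # the clash radius, keeping the native pose a strict optimum
    stagger = [(2.6, 0.0), (-2.6, 0.0), (0.0, 2.6), (0.0, -2.6)]
    for off, col in zip(stagger, tight_cols[1:]):
        lig_centroids[col] = lig_centroids[col] + np.array([off[0], off[1], 0.0])

    # extra interface residues of the larger side fan out laterally around
    # the *opposing* partner's residue of a tight column, so each extra
    # keeps one guaranteed cross-partner contact without clashing
    def _extras(n_extra: int, opposite_of, own_z) -> list[np.ndarray]:
        out = []
        for j in range(n_extra):
            col = tight_cols[j % len(tight_cols)]
            radius = 1.0 + 0.45 * (j // len(tight_cols))
            phi = 2.399963 * (j + 1)  # golden-angle fan
            lx, ly = opposite_of(col)
            out.append(
                np.array([lx, ly, own_z])
                + radius * np.array([math.cos(phi), math.sin(phi), 0.0])
            )
        return out

    rec_centroids += _extras(
        k_a - p, lambda c: lig_centroids[c][:2], 0.0
    )
    lig_centroids += _extras(
        k_b - p, lambda c: rec_centroids[c][:2], float(_GAP_TIGHT)
    )

    # buried (non-interface) residues: compact layers far from every
    # cross-partner centroid
    def _spares(n_spare: int, z0: float, direction: float) -> list[np.ndarray]:
        out = []
        per_layer = 16
        for j in range(n_spare):
            layer, idx = divmod(j, per_layer)
            lat = _lattice_points(per_layer, 3.5)[idx]
            out.append(np.array([lat[0], lat[1], z0 + direction * 3.5 * layer]))
        return out

    rec_centroids += _spares(n_res_receptor - k_a, -7.0, -1.0)
    lig_centroids += _spares(n_res_ligand - k_b, 13.0, +1.0)

    backbone, centroid, partner = [], [], []
    for i, c in enumerate(rec_centroids):
        out = np.array([0.0, 0.0, -1.0])
        jit = rng.uniform(-_JITTER, _JITTER, 3)
        bb, cen = _residue_atoms(np.asarray(c) + jit, out)
        backbone.append(bb)
        centroid.append(cen)
        partner.append(RECEPTOR)
    for i, c in enumerate(lig_centroids):
        out = np.array([0.0, 0.0, 1.0])
        jit = rng.uniform(-_JITTER, _JITTER, 3)
        bb, cen = _residue_atoms(np.asarray(c) + jit, out)
        backbone.append(bb)
        centroid.append(cen)
        partner.append(LIGAND)

    n_total = len(partner)
    chain = np.where(np.array(partner) == RECEPTOR, "R", "L")
    resnum = np.concatenate(
        [np.arange(1, n_res_receptor + 1), np.arange(1, n_res_ligand + 1)]
    )
    model = CentroidModel(
        backbone=np.array(backbone),
        centroid=np.array(centroid),
        restype=np.full(n_total, "ALA"),
        partner=np.array(partner),
        chain=chain,
        resnum=resnum,
    )
    native = RigidPose.identity()
    # brute-force verification of the declared contact count
    from .centroid_energy import count_contacts

    observed = count_contacts(model, native, cutoff=6.0)
    if observed != native_contacts:
        raise ValidationError(
            f"construction yielded {observed} contacts, requested {native_contacts}"
        )
    return ToyComplex(model=model, native_pose=native, native_contacts=native_contacts)


# ---------------------------------------------------------------------------
# Enumerable landscapes
# ---------------------------------------------------------------------------

@dataclass
class ToyLandscape:
    """A finite state space with explicit energies: the exact sampling oracle."""

    kind: str
    states: np.ndarray
    energies: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.states)

    def boltzmann(self, beta: float) -> np.ndarray:
        """Exact stationary probabilities at inverse temperature beta."""
        w = np.exp(-beta * (self.energies - self.energies.min()))
        return w / w.sum()

    def energy_fn(self):
        energies = self.energies

        def fn(idx: int) -> float:
            return float(energies[idx])

        return fn

    def neighbor_mover(self):
        """Symmetric proposal: step to a uniformly chosen periodic neighbor
        (for two states, propose the other state)."""
        n = self.n_states

        if n == 2:
            def mover(idx: int, rng: np.random.Generator) -> int:
                return 1 - idx
        else:
            def mover(idx: int, rng: np.random.Generator) -> int:
                step = 1 if rng.random() < 0.5 else -1
                return (idx + step) % n

        return mover

    def jump_mover(self):
        """Symmetric global proposal: a uniformly chosen *other* state.
        Mixes in O(1) steps, so goodness-of-fit tests against the exact
        distribution have near-independent samples."""
        n = self.n_states

        def mover(idx: int, rng: np.random.Generator) -> int:
            j = int(rng.integers(n - 1))
            return j if j < idx else j + 1

        return mover


def make_toy_landscape(kind: str, **params) -> ToyLandscape:
    """Build an enumerable landscape: ``two_state`` (energies 0 and
    ``delta_e``), ``quadratic_well`` (grid of 0.5 k x^2) or ``rugged_1d``
    (seeded uniform energies)."""
    if kind == "two_state":
        delta_e = float(params.get("delta_e", 1.0))
        return ToyLandscape(
            kind=kind,
            states=np.array([0.0, 1.0]),
            energies=np.array([0.0, delta_e]),
        )
    if kind == "quadratic_well":
        k = float(params.get("k", 1.0))
        n = int(params.get("n_states", 101))
        half_width = float(params.get("half_width", 5.0))
        x = np.linspace(-half_width, half_width, n)
        return ToyLandscape(kind=kind, states=x, energies=0.5 * k * x * x)
    if kind == "rugged_1d":
        n = int(params.get("n_states", 100))
        amplitude = float(params.get("amplitude", 3.0))
        seed = int(params.get("seed", 0))
        rng = np.random.default_rng(seed)
        return ToyLandscape(
            kind=kind,
            states=np.arange(n, dtype=float),
            energies=rng.uniform(0.0, amplitude, n),
        )
    raise ValidationError(f"unknown landscape kind: {kind}")


# ---------------------------------------------------------------------------
# Decoy fixtures with known accuracy strata
# ---------------------------------------------------------------------------

def make_decoy_fixture(
    toy: ToyComplex, n_near: int, n_far: int, seed: int,
    far_shift: float = 30.0,
):
    """A decoy table with exactly known accuracy strata.

    ``n_near`` decoys are perturbed by less than 1 Å from the native pose;
    ``n_far`` decoys are co-located around a pose displaced ``far_shift``
    (> 20) Å outward.  Ground truth for hit calling (near = hit),
    clustering (two clusters) and overlap classification is exact by
    construction.
    """
    from .model_io import DecoyTable

    if n_near < 0 or n_far < 0:
        raise ValidationError("decoy counts must be >= 0")
    if n_near + n_far == 0:
        raise ValidationError("fixture needs at least one decoy")
    if far_shift <= 20.0:
        raise ValidationError("far decoys must be displaced more than 20 Å")
    rng = np.random.default_rng(seed)
    weights = ScoreWeights(cap_enabled=False)
    records = []

    def record(pose: RigidPose, idx: int) -> DecoyRecord:
        e = total_interchain_cen(toy.model, pose, weights, None)
        return DecoyRecord(
            pose=pose, energies=e, level=0, step=idx, traj=0, capped=False
        )

    idx = 0
    for _ in range(n_near):
        axis = random_unit_axis(rng)
        dq = quat_from_axis_angle(axis, math.radians(rng.uniform(0.0, 0.3)))
        dt = rng.uniform(-0.15, 0.15, 3)
        records.append(record(toy.native_pose.compose_left(dq, dt), idx))
        idx += 1
    far_base = np.array([0.0, 0.0, far_shift])
    for _ in range(n_far):
        dt = far_base + rng.uniform(-0.1, 0.1, 3)
        records.append(record(toy.native_pose.translated(dt), idx))
        idx += 1
    return DecoyTable.from_records(records, meta={"fixture": f"near={n_near} far={n_far}"})
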