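"""Decoy evaluation: CAPRI-style accuracy metrics and ensemble analysis.

Metrics follow the CAPRI assessment conventions on the reduced
representation (the interaction sites — backbone atoms plus the centroid
pseudo-atom — play the role of heavy atoms):

* native contacts: cross-partner residue pairs with any site pair < 5 Å in
  the reference complex;
* interface residues: residues with any cross-partner site < 10 Å in the
  reference;
* ``I_rms``: backbone RMSD over interface residues after optimal
  superposition on those residues;
* ``L_rms``: ligand backbone RMSD after superposing the receptors;
* ``f_nat``: recovered native contacts / native contacts;
* ``f_non_nat``: non-native decoy contacts / total decoy contacts (CAPRI
  denominator; a native-contact denominator is available behind a flag).

A decoy with ``I_rms <= 2.5`` Å is a *hit*.  Ensemble analyses: greedy
leader clustering ranked by size, native-basin overlap classification
against a reference ensemble (lower-left region bounded by the reference's
50th energy and 75th I_rms percentiles), spherical population/energy
landscape maps, and percentile energy normalization for cross-method
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .model_io import CentroidModel, DecoyTable, ValidationError
from .rigid_geometry import RigidPose


# ---------------------------------------------------------------------------
# CAPRI metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapriMetrics:
    I_rms: float
    L_rms: float
    f_nat: float
    f_non_nat: float


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimal RMSD between matched point sets after optimal superposition."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    _, rssd = Rotation.align_vectors(Pc, Qc)
    return float(rssd / np.sqrt(len(P)))


def _superpose_transform(P_from: np.ndarray, P_to: np.ndarray):
    """Rigid transform (R, t) minimizing |R x + t - P_to| over matched points."""
    cf = P_from.mean(axis=0)
    ct = P_to.mean(axis=0)
    rot, _ = Rotation.align_vectors(P_to - ct, P_from - cf)
    R = rot.as_matrix()
    return R, ct - R @ cf


def _site_coords(model: CentroidModel, pose: RigidPose | None):
    """(n, 5, 3) per-residue site coordinates (N, CA, C, O, centroid) with
    the pose applied to the mobile partner."""
    coords = np.concatenate(
        [model.backbone, model.centroid[:, None, :]], axis=1
    ).copy()
    if pose is not None:
        coords[model.mask_B] = pose.apply(coords[model.mask_B], model.mobile_center)
    return coords


def _contact_pairs(
    coords: np.ndarray, mask_A: np.ndarray, mask_B: np.ndarray, cutoff: float
) -> set:
    """Cross-partner residue pairs with any site pair closer than cutoff."""
    A = coords[mask_A].reshape(-1, 3)
    B = coords[mask_B].reshape(-1, 3)
    nA = int(mask_A.sum())
    nB = int(mask_B.sum())
    d = cdist(A, B).reshape(nA, 5, nB, 5)
    dmin = d.min(axis=(1, 3))
    ia, ib = np.nonzero(dmin < cutoff)
    return set(zip(ia.tolist(), ib.tolist())), dmin


def capri_metrics(
    model: CentroidModel,
    decoy_pose: RigidPose,
    reference_pose: RigidPose,
    contact_cutoff: float = 5.0,
    interface_cutoff: float = 10.0,
    fnonnat_native_denominator: bool = False,
) -> CapriMetrics:
    """CAPRI accuracy metrics of a posed decoy against the bound reference.

    Both conformations are poses of the same model, so the residue
    correspondence is exact.  Raises :class:`ValidationError` when the
    reference has no cross-partner contacts (not a complex).
    """
    ref = _site_coords(model, reference_pose)
    dec = _site_coords(model, decoy_pose)
    native, dmin_ref = _contact_pairs(ref, model.mask_A, model.mask_B, contact_cutoff)
    if not native:
        raise ValidationError("reference complex has no cross-partner contacts")
    decoy_contacts, _ = _contact_pairs(dec, model.mask_A, model.mask_B, contact_cutoff)
    recovered = len(native & decoy_contacts)
    f_nat = recovered / len(native)
    non_native = len(decoy_contacts - native)
    if fnonnat_native_denominator:
        f_non_nat = non_native / len(native)
    else:
        f_non_nat = non_native / len(decoy_contacts) if decoy_contacts else 0.0

    # interface residues from the reference (10 Å heavy-atom criterion)
    iface_A = (dmin_ref < interface_cutoff).any(axis=1)
    iface_B = (dmin_ref < interface_cutoff).any(axis=0)
    iface_mask = np.zeros(model.n_residues, dtype=bool)
    iface_mask[np.nonzero(model.mask_A)[0][iface_A]] = True
    iface_mask[np.nonzero(model.mask_B)[0][iface_B]] = True
    ref_iface = ref[iface_mask][:, :4, :].reshape(-1, 3)
    dec_iface = dec[iface_mask][:, :4, :].reshape(-1, 3)
    i_rms = _kabsch_rmsd(dec_iface, ref_iface)

    # ligand RMSD after superposing the receptors
    R, t = _superpose_transform(
        dec[model.mask_A][:, :4, :].reshape(-1, 3),
        ref[model.mask_A][:, :4, :].reshape(-1, 3),
    )
    dec_lig = dec[model.mask_B][:, :4, :].reshape(-1, 3) @ R.T + t
    ref_lig = ref[model.mask_B][:, :4, :].reshape(-1, 3)
    l_rms = float(np.sqrt(np.mean(np.sum((dec_lig - ref_lig) ** 2, axis=1))))
    return CapriMetrics(I_rms=i_rms, L_rms=l_rms, f_nat=f_nat, f_non_nat=f_non_nat)


def table_capri_metrics(
    table: DecoyTable,
    model: CentroidModel,
    reference_pose: RigidPose,
    **kwargs,
) -> pd.DataFrame:
    """CAPRI metrics for every row of a decoy table."""
    rows = [
        capri_metrics(model, pose, reference_pose, **kwargs)
        for pose in table.poses()
    ]
    return pd.DataFrame(
        {
            "I_rms": [m.I_rms for m in rows],
            "L_rms": [m.L_rms for m in rows],
            "f_nat": [m.f_nat for m in rows],
            "f_non_nat": [m.f_non_nat for m in rows],
        }
    )


def call_hits(
    table: DecoyTable,
    model: CentroidModel,
    reference_pose: RigidPose,
    threshold: float = 2.5,
):
    """Hit calling: a decoy is a hit iff its I_rms <= threshold (Å).

    Returns ``(hit_fraction, flags, i_rms)``.
    """
    if len(table) == 0:
        raise ValidationError("cannot call hits on an empty table")
    i_rms = np.array(
        [
            capri_metrics(model, pose, reference_pose).I_rms
            for pose in table.poses()
        ]
    )
    flags = i_rms <= threshold
    return float(flags.mean()), flags, i_rms


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    members: list
    representative: int
    representative_energy: float

    @property
    def size(self) -> int:
        return len(self.members)


def ligand_rmsd_matrix(poses: list, model: CentroidModel) -> np.ndarray:
    """Pairwise ligand backbone RMSD between poses (receptors fixed)."""
    coords = [
        pose.apply(model.bb_B.reshape(-1, 3), model.mobile_center) for pose in poses
    ]
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = np.sqrt(
                np.mean(np.sum((coords[i] - coords[j]) ** 2, axis=1))
            )
    return out


def cluster_decoys(
    table: DecoyTable,
    model: CentroidModel,
    rmsd_cutoff: float = 5.0,
    top_n: int = 2000,
    energy_col: str = "total",
) -> list[Cluster]:
    """Greedy leader clustering of the lowest-energy decoys.

    The ``top_n`` lowest-energy decoys are visited in ascending energy
    order; each joins the first existing cluster whose representative
    (its lowest-energy member, i.e. its founder) is within ``rmsd_cutoff``
    of its ligand backbone RMSD, else founds a new cluster.  Clusters are
    ranked by size, ties broken by lower representative energy.
    """
    if len(table) == 0:
        raise ValidationError("cannot cluster an empty table")
    df = table.df
    order = df.sort_values(
        [energy_col, "traj", "step"], kind="mergesort"
    ).index.to_numpy()[:top_n]
    poses = table.poses()
    lig_bb = model.bb_B.reshape(-1, 3)
    coords = {i: poses[i].apply(lig_bb, model.mobile_center) for i in order}
    energies = df[energy_col].to_numpy()
    clusters: list[Cluster] = []
    for idx in order:
        placed = False
        for cl in clusters:
            rep = cl.representative
            rmsd = np.sqrt(
                np.mean(np.sum((coords[idx] - coords[rep]) ** 2, axis=1))
            )
            if rmsd <= rmsd_cutoff:
                cl.members.append(int(idx))
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(
                    members=[int(idx)],
                    representative=int(idx),
                    representative_energy=float(energies[idx]),
                )
            )
    clusters.sort(key=lambda c: (-c.size, c.representative_energy))
    return clusters


# ---------------------------------------------------------------------------
# Native-basin overlap classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapRegion:
    """Lower-left region in the energy vs I_rms plane derived from a
    reference ensemble: its 50th energy percentile and 75th I_rms
    percentile."""

    energy_ceiling: float
    i_rms_ceiling: float

    @classmethod
    def from_reference(
        cls, energies: np.ndarray, i_rms: np.ndarray
    ) -> "OverlapRegion":
        energies = np.asarray(energies, dtype=float)
        i_rms = np.asarray(i_rms, dtype=float)
        if energies.size == 0 or energies.size != i_rms.size:
            raise ValidationError("reference ensemble must be non-empty and matched")
        return cls(
            energy_ceiling=float(np.percentile(energies, 50)),
            i_rms_ceiling=float(np.percentile(i_rms, 75)),
        )


@dataclass(frozen=True)
class OverlapClass:
    category: str  # none | magic_points | sporadic | dense
    n: int
    region: OverlapRegion


def classify_native_overlap(
    energies: np.ndarray,
    i_rms: np.ndarray,
    reference_energies: np.ndarray,
    reference_i_rms: np.ndarray,
    t_magic: int = 2,
    t_dense: int = 10,
) -> OverlapClass:
    """Count decoys inside the reference-derived overlap region and
    classify: none (0), magic_points (1..t_magic), sporadic
    (t_magic < n < t_dense), dense (n >= t_dense)."""
    region = OverlapRegion.from_reference(reference_energies, reference_i_rms)
    energies = np.asarray(energies, dtype=float)
    i_rms = np.asarray(i_rms, dtype=float)
    inside = (energies <= region.energy_ceiling) & (i_rms <= region.i_rms_ceiling)
    n = int(inside.sum())
    if n == 0:
        category = "none"
    elif n <= t_magic:
        category = "magic_points"
    elif n < t_dense:
        category = "sporadic"
    else:
        category = "dense"
    return OverlapClass(category=category, n=n, region=region)


# ---------------------------------------------------------------------------
# Landscape maps
# ---------------------------------------------------------------------------

def landscape_map(
    table: DecoyTable,
    model: CentroidModel,
    n_theta: int = 36,
    n_phi: int = 72,
    energy_col: str = "total",
):
    """Spherical population and minimum-energy maps of a decoy set.

    Each decoy is assigned the (theta, phi) direction of the mobile
    partner's center as seen from the fixed partner's center; returns
    ``(population, min_energy)`` grids of shape (n_theta, n_phi), with
    empty cells holding population 0 and energy NaN.
    """
    population = np.zeros((n_theta, n_phi), dtype=int)
    min_energy = np.full((n_theta, n_phi), np.nan)
    energies = table.df[energy_col].to_numpy()
    for row, pose in enumerate(table.poses()):
        v = pose.mobile_center_position(model.mobile_center) - model.com_A
        r = np.linalg.norm(v)
        if r < 1e-12:
            theta, phi = 0.0, 0.0
        else:
            theta = np.arccos(np.clip(v[2] / r, -1.0, 1.0))
            phi = np.arctan2(v[1], v[0])
        it = min(int(theta / np.pi * n_theta), n_theta - 1)
        ip = min(int((phi + np.pi) / (2 * np.pi) * n_phi), n_phi - 1)
        population[it, ip] += 1
        e = energies[row]
        if np.isnan(min_energy[it, ip]) or e < min_energy[it, ip]:
            min_energy[it, ip] = e
    return population, min_energy


# ---------------------------------------------------------------------------
# Percentile energy normalization
# ---------------------------------------------------------------------------

def normalize_energy_percentiles(
    ensembles: dict[str, np.ndarray],
    percentiles: tuple = (5.0, 1.0, 0.1),
) -> pd.DataFrame:
    """Cross-method percentile comparison of energy ensembles for one target.

    All energies are shifted so the maximum across ensembles is 0, then
    divided by the absolute mean of the 10 lowest (post-shift) energies
    across ensembles; the table reports each requested lower-percentile
    boundary per ensemble.
    """
    if not ensembles:
        raise ValidationError("no ensembles given")
    arrays = {k: np.asarray(v, dtype=float) for k, v in ensembles.items()}
    for name, arr in arrays.items():
        if arr.size < 10:
            raise ValidationError(f"ensemble {name!r} has fewer than 10 entries")
    pooled = np.concatenate(list(arrays.values()))
    shift = pooled.max()
    shifted = {k: v - shift for k, v in arrays.items()}
    ten_lowest = np.sort(np.concatenate(list(shifted.values())))[:10]
    divisor = abs(float(ten_lowest.mean()))
    if divisor < 1e-12:
        raise ValidationError("degenerate ensembles: normalization divisor is zero")
    rows = {
        name: [float(np.percentile(arr / divisor, p)) for p in percentiles]
        for name, arr in shifted.items()
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{p:g}" for p in percentiles]
    )
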