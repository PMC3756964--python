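"""The low-resolution interchain score and the encounter restraint.

The interchain centroid score is a weighted sum of four terms, evaluated
between the two partners only (intra-partner energies are constant under
rigid-body motion and ignored):

* ``interchain_contact`` — rewards contacting residues: every residue with
  at least one cross-partner centroid within the contact cutoff (6 Å)
  contributes −0.25 REU, so 40 contacting residues score −10 REU, the
  default cap value.  The optional cap bounds the reward from below to
  avoid over-stabilizing spuriously large interfaces.
* ``interchain_vdw`` — a soft quadratic overlap penalty on interaction
  sites (backbone atoms + centroid): site pairs closer than ``r_clash``
  (3 Å) add ``(r_clash - d)^2 / r_clash``.
* ``interchain_env`` / ``interchain_pair`` — tabulated statistical
  potentials over cross-partner centroid neighbor counts (10 Å sphere) and
  residue-type pairs in centroid contact.

The encounter restraint is a flat-bottom harmonic on the distance between
the two partner center atoms (the CA nearest each partner's center of
mass): zero while the partners can touch, ``k (d - d0)^2`` beyond
``d0 = R1 + R2 + gap``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model_io import CentroidModel, ValidationError
from .rigid_geometry import RigidPose

AMINO_ACIDS = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

# Kyte-Doolittle hydropathy, used only to seed the synthetic default tables
_KD = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
_CHARGE = {"ARG": 1.0, "LYS": 1.0, "HIS": 0.5, "ASP": -1.0, "GLU": -1.0}


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreWeights:
    """Term weights and contact-term settings of the interchain score."""

    w_contact: float = 2.0
    w_vdw: float = 1.0
    w_env: float = 1.0
    w_pair: float = 1.0
    cap_enabled: bool = True
    cap_value: float = -10.0
    contact_cutoff: float = 6.0
    r_clash: float = 3.0

    def __post_init__(self):
        if min(self.w_contact, self.w_vdw, self.w_env, self.w_pair) < 0:
            raise ValidationError("weights must be >= 0")
        if self.cap_value >= 0:
            raise ValidationError("cap_value must be negative")
        if self.contact_cutoff <= 0 or self.r_clash <= 0:
            raise ValidationError("cutoffs must be positive")

    def with_cap(self, enabled: bool) -> "ScoreWeights":
        return replace(self, cap_enabled=enabled)


@dataclass
class EnergyBreakdown:
    """Per-term interchain energies (REU) and their weighted total.

    ``total`` covers the four interchain terms; the optional flat-bottom
    ``encounter`` penalty is kept separate so that filtering on the
    interchain score is unaffected by the restraint.  ``mc_energy`` is the
    quantity sampled by the Monte-Carlo protocols.
    """

    contact: float
    vdw: float
    env: float
    pair: float
    total: float
    encounter: float | None = None

    @property
    def mc_energy(self) -> float:
        return self.total + (self.encounter or 0.0)


@dataclass(frozen=True)
class EncounterParams:
    """Flat-bottom restraint geometry derived once from the model.

    ``center_idx_1/2`` index the CA used as each partner's center atom (CA
    nearest the partner's center of mass, local per-partner index); ``R1``
    and ``R2`` are each partner's maximal center-to-site distances; the
    penalty turns on beyond ``R1 + R2 + gap``.
    """

    center_idx_1: int
    center_idx_2: int
    R1: float
    R2: float
    gap: float = 8.0
    k: float = 0.25

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValidationError("partner radii must be positive")
        if self.gap < 0 or self.k <= 0:
            raise ValidationError("gap must be >= 0 and k > 0")

    @property
    def flat_radius(self) -> float:
        return self.R1 + self.R2 + self.gap

    @classmethod
    def from_model(
        cls, model: CentroidModel, gap: float = 8.0, k: float = 0.25
    ) -> "EncounterParams":
        ca_A = model.bb_A[:, 1, :]
        ca_B = model.bb_B[:, 1, :]
        i1 = int(np.argmin(np.linalg.norm(ca_A - model.com_A, axis=1)))
        i2 = int(np.argmin(np.linalg.norm(ca_B - model.com_B, axis=1)))
        R1 = float(np.max(np.linalg.norm(model.sites_A - ca_A[i1], axis=1)))
        R2 = float(np.max(np.linalg.norm(model.sites_B - ca_B[i2], axis=1)))
        return cls(center_idx_1=i1, center_idx_2=i2, R1=R1, R2=R2, gap=gap, k=k)


# ---------------------------------------------------------------------------
# Statistical potential tables
# ---------------------------------------------------------------------------

class StatPotentialTable:
    """Tabulated environment and pair potentials.

    ``env``: (type, cross-partner neighbor count) -> REU, with counts
    clamped to the tabulated range.  ``pair``: symmetric (type, type) ->
    REU for residue pairs in centroid contact.
    """

    def __init__(self, env: pd.DataFrame, pair: pd.DataFrame):
        self.env = env.astype(float)
        self.pair = pair.astype(float)
        if not np.all(np.isfinite(self.env.to_numpy())):
            raise ValidationError("non-finite env table entries")
        if not np.all(np.isfinite(self.pair.to_numpy())):
            raise ValidationError("non-finite pair table entries")
        missing = set(AMINO_ACIDS) - set(self.env.index)
        if missing:
            raise ValidationError(f"env table missing residue types: {sorted(missing)}")
        if list(self.pair.index) != list(self.pair.columns):
            raise ValidationError("pair table must be square with matching labels")
        if not np.allclose(self.pair.to_numpy(), self.pair.to_numpy().T, atol=1e-9):
            raise ValidationError("pair table must be symmetric")
        self.max_neighbors = int(self.env.columns.astype(int).max())
        self._env_arr = self.env.to_numpy()
        self._env_index = {t: i for i, t in enumerate(self.env.index)}
        self._pair_arr = self.pair.to_numpy()
        self._pair_index = {t: i for i, t in enumerate(self.pair.index)}

    def env_lookup_rows(self, types: np.ndarray) -> np.ndarray:
        try:
            rows = np.array([self._env_index[t] for t in types])
        except KeyError as exc:
            raise ValidationError(f"residue type {exc} absent from env table") from None
        return rows

    def pair_lookup_rows(self, types: np.ndarray) -> np.ndarray:
        try:
            rows = np.array([self._pair_index[t] for t in types])
        except KeyError as exc:
            raise ValidationError(f"residue type {exc} absent from pair table") from None
        return rows

    @classmethod
    def zeros(cls, max_neighbors: int = 10) -> "StatPotentialTable":
        cols = list(range(max_neighbors + 1))
        env = pd.DataFrame(0.0, index=AMINO_ACIDS, columns=cols)
        pair = pd.DataFrame(0.0, index=AMINO_ACIDS, columns=AMINO_ACIDS)
        return cls(env, pair)


def default_tables(max_neighbors: int = 10) -> StatPotentialTable:
    """Synthetic stand-in statistical tables.

    These are *not* a statistical survey of protein interfaces: the env
    term favors burial of hydrophobic residues proportionally to their
    Kyte-Doolittle hydropathy, and the pair term rewards opposite-charge
    and hydrophobic-hydrophobic contacts.  Magnitudes are kept small
    relative to the contact term.  Supply measured tables via
    :func:`load_tables` for production use.
    """
    cols = list(range(max_neighbors + 1))
    env = pd.DataFrame(0.0, index=AMINO_ACIDS, columns=cols)
    for aa in AMINO_ACIDS:
        scale = -_KD[aa] / 4.5 * 0.05
        env.loc[aa] = [scale * n for n in cols]
    pair = pd.DataFrame(0.0, index=AMINO_ACIDS, columns=AMINO_ACIDS)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            v = 0.03 * _CHARGE.get(a, 0.0) * _CHARGE.get(b, 0.0)
            if _KD[a] >= 2.5 and _KD[b] >= 2.5:
                v -= 0.02
            pair.loc[a, b] = v
    return StatPotentialTable(env, pair)


def save_tables(table: StatPotentialTable, path: str | Path) -> None:
    """Write a table file: two TSV sections headed ``[env]`` and ``[pair]``."""
    with open(path, "w") as fh:
        fh.write("[env]\n")
        table.env.to_csv(fh, sep="\t", index_label="restype")
        fh.write("[pair]\n")
        table.pair.to_csv(fh, sep="\t", index_label="restype")


def load_tables(path: str | Path) -> StatPotentialTable:
    """Read a table file written by :func:`save_tables` (or user-supplied)."""
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("[") and s.endswith("]"):
            current = s[1:-1].lower()
            sections[current] = []
        elif current is not None and s:
            sections[current].append(line)
    if "env" not in sections or "pair" not in sections:
        raise ValidationError("table file must contain [env] and [pair] sections")
    env = pd.read_csv(io.StringIO("\n".join(sections["env"])), sep="\t", index_col=0)
    env.columns = [int(c) for c in env.columns]
    pair = pd.read_csv(io.StringIO("\n".join(sections["pair"])), sep="\t", index_col=0)
    return StatPotentialTable(env, pair)


# ---------------------------------------------------------------------------
# Energy terms
# ---------------------------------------------------------------------------

def _posed_centroids_B(model: CentroidModel, pose: RigidPose) -> np.ndarray:
    return pose.apply(model.cent_B, model.mobile_center)


def _posed_sites_B(model: CentroidModel, pose: RigidPose) -> np.ndarray:
    return pose.apply(model.sites_B, model.mobile_center)


def count_contacts(
    model: CentroidModel, pose: RigidPose, cutoff: float = 6.0
) -> int:
    """Number of residues (over both partners) with at least one
    cross-partner centroid within ``cutoff`` Å."""
    d = cdist(model.cent_A, _posed_centroids_B(model, pose))
    within = d < cutoff
    return int(within.any(axis=1).sum() + within.any(axis=0).sum())


def interchain_contact(
    model: CentroidModel, pose: RigidPose, weights: ScoreWeights = ScoreWeights()
) -> float:
    """Contact reward: -0.25 REU per contacting residue, optionally capped."""
    raw = -0.25 * count_contacts(model, pose, weights.contact_cutoff)
    if weights.cap_enabled:
        return max(raw, weights.cap_value)
    return raw


def interchain_vdw(
    model: CentroidModel, pose: RigidPose, r_clash: float = 3.0
) -> float:
    """Soft quadratic overlap penalty over cross-partner interaction sites."""
    d = cdist(model.sites_A, _posed_sites_B(model, pose))
    overlap = r_clash - d[d < r_clash]
    if overlap.size == 0:
        return 0.0
    return float(np.sum(overlap * overlap) / r_clash)


def interchain_env(
    model: CentroidModel, pose: RigidPose, table: StatPotentialTable,
    neighbor_cutoff: float = 10.0,
) -> float:
    """Environment score: per residue, the tabulated value at its
    cross-partner centroid neighbor count (clamped to the table range)."""
    d = cdist(model.cent_A, _posed_centroids_B(model, pose))
    within = d < neighbor_cutoff
    counts_A = np.minimum(within.sum(axis=1), table.max_neighbors)
    counts_B = np.minimum(within.sum(axis=0), table.max_neighbors)
    rows_A = table.env_lookup_rows(model.restype[model.mask_A])
    rows_B = table.env_lookup_rows(model.restype[model.mask_B])
    arr = table._env_arr
    return float(arr[rows_A, counts_A].sum() + arr[rows_B, counts_B].sum())


def interchain_pair(
    model: CentroidModel, pose: RigidPose, table: StatPotentialTable,
    contact_cutoff: float = 6.0,
) -> float:
    """Pair score summed over cross-partner residue pairs in centroid contact."""
    d = cdist(model.cent_A, _posed_centroids_B(model, pose))
    ia, ib = np.nonzero(d < contact_cutoff)
    if ia.size == 0:
        return 0.0
    rows_A = table.pair_lookup_rows(model.restype[model.mask_A])
    rows_B = table.pair_lookup_rows(model.restype[model.mask_B])
    return float(table._pair_arr[rows_A[ia], rows_B[ib]].sum())


def encounter_penalty(
    model: CentroidModel, pose: RigidPose, params: EncounterParams
) -> float:
    """Flat-bottom restraint: 0 while the partners can touch, harmonic
    (``k (d - d0)^2``) once the center atoms exceed ``d0 = R1 + R2 + gap``."""
    ca1 = model.bb_A[params.center_idx_1, 1, :]
    ca2 = pose.apply(model.bb_B[params.center_idx_2, 1, :], model.mobile_center)
    d = float(np.linalg.norm(ca2 - ca1))
    d0 = params.flat_radius
    if d <= d0:
        return 0.0
    return params.k * (d - d0) ** 2


def total_interchain_cen(
    model: CentroidModel,
    pose: RigidPose,
    weights: ScoreWeights = ScoreWeights(),
    tables: StatPotentialTable | None = None,
    encounter: EncounterParams | None = None,
) -> EnergyBreakdown:
    """Full interchain score with per-term breakdown.

    ``total = w_contact*contact + w_vdw*vdw + w_env*env + w_pair*pair``;
    the encounter penalty, if requested, is reported separately.
    """
    contact = interchain_contact(model, pose, weights)
    vdw = interchain_vdw(model, pose, weights.r_clash)
    if tables is None:
        env = 0.0
        pair = 0.0
    else:
        env = interchain_env(model, pose, tables)
        pair = interchain_pair(model, pose, tables, weights.contact_cutoff)
    total = (
        weights.w_contact * contact
        + weights.w_vdw * vdw
        + weights.w_env * env
        + weights.w_pair * pair
    )
    enc = None if encounter is None else encounter_penalty(model, pose, encounter)
    return EnergyBreakdown(
        contact=contact, vdw=vdw, env=env, pair=pair, total=total, encounter=enc
    )


def make_energy_fn(
    model: CentroidModel,
    weights: ScoreWeights = ScoreWeights(),
    tables: StatPotentialTable | None = None,
    encounter: EncounterParams | None = None,
):
    """Scalar pose -> REU function (the Monte-Carlo sampling energy)."""

    def energy(pose: RigidPose) -> float:
        return total_interchain_cen(model, pose, weights, tables, encounter).mc_energy

    return energy
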