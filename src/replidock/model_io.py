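"""Structure I/O and the two-partner centroid reduction.

Reads standard PDB files (via :mod:`gemmi`), assigns chains to the two
binding partners (``A`` = fixed receptor, ``B`` = mobile ligand), reduces
each residue to backbone atoms plus a single side-chain centroid
pseudo-atom, and persists decoy sets with their scores as TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("replidock")

BACKBONE_ATOMS = ("N", "CA", "C", "O")
#: atom names excluded from the side-chain centroid
_NON_SIDECHAIN = {"N", "CA", "C", "O", "OXT"}

RECEPTOR = "A"
LIGAND = "B"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """One residue: identity plus a name -> (3,) coordinate map (Å)."""

    chain: str
    number: int
    icode: str
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)


@dataclass
class Structure:
    """An all-atom (heavy-atom) structure of up to two binding partners.

    ``partner_of_chain`` maps each chain id to ``"A"`` (fixed receptor) or
    ``"B"`` (mobile ligand); it is empty until :func:`assign_partners` is
    called.
    """

    residues: list[Residue]
    partner_of_chain: dict[str, str] = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def validate(self) -> None:
        if not self.residues:
            raise ValidationError("structure has no residues")
        for r in self.residues:
            for name, xyz in r.atoms.items():
                if not np.all(np.isfinite(xyz)):
                    raise ValidationError(
                        f"non-finite coordinate for atom {name} of residue "
                        f"{r.chain}{r.number}{r.icode}"
                    )
        if self.partner_of_chain:
            labels = set(self.partner_of_chain.values())
            if labels != {RECEPTOR, LIGAND}:
                raise ValidationError("both partners must be non-empty")


def read_pdb(path: str | Path) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    HETATM records, waters and hydrogens are skipped.  Alternate locations
    are resolved to the highest-occupancy conformer (ties: first
    encountered).  Coordinates are in Å.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValidationError(f"{path} contains no models")
    residues: list[Residue] = []
    for chain in st[0]:
        for res in chain:
            if res.het_flag != "A" or res.is_water():
                continue
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                occ = atom.occ
                if atom.name not in atoms or occ > best_occ[atom.name]:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
                    best_occ[atom.name] = occ
            if atoms:
                residues.append(
                    Residue(
                        chain=chain.name,
                        number=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip() or "",
                        name=res.name,
                        atoms=atoms,
                    )
                )
    if not residues:
        raise ValidationError(f"{path} contains no usable ATOM records")
    s = Structure(residues=residues)
    s.validate()
    return s


def assign_partners(
    structure: Structure,
    receptor_chains: Sequence[str],
    ligand_chains: Sequence[str],
) -> Structure:
    """Label chains as receptor (partner A) or ligand (partner B).

    Chains in neither list are dropped with a logged warning.  Overlapping
    or unknown chain ids raise :class:`ValidationError`.
    """
    rec = list(receptor_chains)
    lig = list(ligand_chains)
    if not rec or not lig:
        raise ValidationError("both chain lists must be non-empty")
    overlap = set(rec) & set(lig)
    if overlap:
        raise ValidationError(f"chains in both partners: {sorted(overlap)}")
    present = set(structure.chains)
    unknown = (set(rec) | set(lig)) - present
    if unknown:
        raise ValidationError(f"chains not present in structure: {sorted(unknown)}")
    keep = set(rec) | set(lig)
    dropped = sorted(present - keep)
    if dropped:
        logger.warning("dropping unassigned chains: %s", ", ".join(dropped))
    residues = [r for r in structure.residues if r.chain in keep]
    mapping = {c: RECEPTOR for c in rec}
    mapping.update({c: LIGAND for c in lig})
    out = Structure(residues=residues, partner_of_chain=mapping)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Centroid reduction
# ---------------------------------------------------------------------------

class CentroidModel:
    """Residue-level reduction of a two-partner structure.

    Per residue: the four backbone atoms (N, CA, C, O), one centroid
    pseudo-atom (arithmetic mean of side-chain heavy atoms; CA for glycine
    or side-chain-less residues), the residue type, the partner label and
    the source chain/number.

    Interaction *sites* are the backbone atoms plus the centroid; several
    per-partner arrays are precomputed for fast scoring.  The mobile
    partner's rotation center (``mobile_center``) is the mean of its sites
    and is the fixed reference point for every :class:`~replidock.rigid_geometry.RigidPose`.
    """

    def __init__(
        self,
        backbone: np.ndarray,
        centroid: np.ndarray,
        restype: np.ndarray,
        partner: np.ndarray,
        chain: np.ndarray,
        resnum: np.ndarray,
        icode: np.ndarray | None = None,
    ):
        self.backbone = np.asarray(backbone, dtype=float)  # (n, 4, 3)
        self.centroid = np.asarray(centroid, dtype=float)  # (n, 3)
        self.restype = np.asarray(restype)
        self.partner = np.asarray(partner)
        self.chain = np.asarray(chain)
        self.resnum = np.asarray(resnum, dtype=int)
        self.icode = (
            np.asarray(icode)
            if icode is not None
            else np.full(len(self.restype), "", dtype=object)
        )
        n = len(self.restype)
        if not (
            self.backbone.shape == (n, 4, 3)
            and self.centroid.shape == (n, 3)
            and len(self.partner) == n
        ):
            raise ValidationError("inconsistent centroid-model array shapes")
        if not (np.all(np.isfinite(self.backbone)) and np.all(np.isfinite(self.centroid))):
            raise ValidationError("non-finite coordinates in centroid model")
        self.mask_A = self.partner == RECEPTOR
        self.mask_B = self.partner == LIGAND
        if not self.mask_A.any() or not self.mask_B.any():
            raise ValidationError("both partners must be non-empty")
        self._cache()

    def _cache(self) -> None:
        self.cent_A = self.centroid[self.mask_A]
        self.cent_B = self.centroid[self.mask_B]
        self.bb_A = self.backbone[self.mask_A]
        self.bb_B = self.backbone[self.mask_B]
        self.sites_A = np.concatenate(
            [self.bb_A.reshape(-1, 3), self.cent_A], axis=0
        )
        self.sites_B = np.concatenate(
            [self.bb_B.reshape(-1, 3), self.cent_B], axis=0
        )
        self.com_A = self.sites_A.mean(axis=0)
        self.com_B = self.sites_B.mean(axis=0)
        #: rotation center of the mobile partner, fixed for the model's lifetime
        self.mobile_center = self.com_B.copy()

    @property
    def n_residues(self) -> int:
        return len(self.restype)

    @property
    def n_receptor(self) -> int:
        return int(self.mask_A.sum())

    @property
    def n_ligand(self) -> int:
        return int(self.mask_B.sum())

    def transformed(self, rotation: np.ndarray, shift: np.ndarray) -> "CentroidModel":
        """Apply a common rigid transform x -> R x + shift to *both* partners."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(shift, dtype=float)
        return CentroidModel(
            backbone=self.backbone @ R.T + t,
            centroid=self.centroid @ R.T + t,
            restype=self.restype.copy(),
            partner=self.partner.copy(),
            chain=self.chain.copy(),
            resnum=self.resnum.copy(),
            icode=self.icode.copy(),
        )


def to_centroid(structure: Structure) -> CentroidModel:
    """Reduce a partner-assigned :class:`Structure` to a :class:`CentroidModel`.

    The centroid is the arithmetic mean of side-chain heavy atoms; glycine
    (or a residue with no side-chain heavy atoms) uses CA.  A residue
    lacking CA is fatal; residues missing another backbone atom are dropped
    with a warning (no reconstruction is attempted).
    """
    if not structure.partner_of_chain:
        raise ValidationError("assign_partners must be called before to_centroid")
    bb, cent, types, partners, chains, nums, icodes = [], [], [], [], [], [], []
    for r in structure.residues:
        if "CA" not in r.atoms:
            raise ValidationError(
                f"residue {r.chain}{r.number}{r.icode} lacks a CA atom"
            )
        missing = [a for a in BACKBONE_ATOMS if a not in r.atoms]
        if missing:
            logger.warning(
                "dropping residue %s%s%s: missing backbone atom(s) %s",
                r.chain, r.number, r.icode, ",".join(missing),
            )
            continue
        side = [xyz for name, xyz in r.atoms.items() if name not in _NON_SIDECHAIN]
        c = np.mean(side, axis=0) if side else r.atoms["CA"].copy()
        bb.append([r.atoms[a] for a in BACKBONE_ATOMS])
        cent.append(c)
        types.append(r.name)
        partners.append(structure.partner_of_chain[r.chain])
        chains.append(r.chain)
        nums.append(r.number)
        icodes.append(r.icode)
    if not bb:
        raise ValidationError("no complete residues remain after reduction")
    return CentroidModel(
        backbone=np.array(bb),
        centroid=np.array(cent),
        restype=np.array(types),
        partner=np.array(partners),
        chain=np.array(chains),
        resnum=np.array(nums),
        icode=np.array(icodes, dtype=object),
    )


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a standard PDB file (ATOM records)."""
    st = gemmi.Structure()
    st.name = "replidock"
    model = gemmi.Model("1")
    by_chain: dict[str, list[Residue]] = {}
    for r in structure.residues:
        by_chain.setdefault(r.chain, []).append(r)
    for chain_id, residues in by_chain.items():
        chain = gemmi.Chain(chain_id)
        for r in residues:
            res = gemmi.Residue()
            res.name = r.name
            res.seqid = gemmi.SeqId(r.number, r.icode or " ")
            res.het_flag = "A"
            for name, xyz in r.atoms.items():
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(_guess_element(name))
                a.occ = 1.0
                a.pos = gemmi.Position(*map(float, xyz))
                res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except OSError as exc:  # unwritable path
        raise IOError(f"cannot write PDB to {path}: {exc}") from exc


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            # PDB convention: first alphabetic char of a standard protein
            # heavy-atom name is the element (N, C, O, S)
            return ch.upper() if ch.upper() in "NCOS" else "C"
    return "C"


def centroid_model_to_structure(
    model: CentroidModel, coords_override: np.ndarray | None = None
) -> Structure:
    """Rebuild a :class:`Structure` from a centroid model.

    The centroid pseudo-atom is written with atom name ``CEN`` so that a
    read/reduce round trip reproduces the centroid exactly.
    ``coords_override`` (n, 5, 3: N, CA, C, O, CEN) substitutes posed
    coordinates.
    """
    residues: list[Residue] = []
    partner_map: dict[str, str] = {}
    for i in range(model.n_residues):
        if coords_override is not None:
            coords = coords_override[i]
            bb = coords[:4]
            cen = coords[4]
        else:
            bb = model.backbone[i]
            cen = model.centroid[i]
        atoms = {name: bb[j].copy() for j, name in enumerate(BACKBONE_ATOMS)}
        atoms["CEN"] = np.array(cen, dtype=float)
        chain = str(model.chain[i])
        residues.append(
            Residue(
                chain=chain,
                number=int(model.resnum[i]),
                icode=str(model.icode[i]),
                name=str(model.restype[i]),
                atoms=atoms,
            )
        )
        partner_map[chain] = str(model.partner[i])
    return Structure(residues=residues, partner_of_chain=partner_map)


# ---------------------------------------------------------------------------
# Decoy tables
# ---------------------------------------------------------------------------

#: fixed column schema of a decoy table; one row per recorded snapshot
DECOY_COLUMNS = [
    "traj", "level", "step", "capped",
    "contact", "vdw", "env", "pair", "encounter", "total",
    "qw", "qx", "qy", "qz", "tx", "ty", "tz",
]

_ENERGY_COLS = ["contact", "vdw", "env", "pair", "encounter", "total"]
_POSE_COLS = ["qw", "qx", "qy", "qz", "tx", "ty", "tz"]


class DecoyTable:
    """An ordered set of decoy records with the fixed column schema.

    Thin wrapper over a :class:`pandas.DataFrame`; ``meta`` carries run
    provenance (seeds, exchange statistics) for the TSV header.
    """

    def __init__(self, df: pd.DataFrame, meta: dict | None = None):
        missing = [c for c in DECOY_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"decoy table missing columns: {missing}")
        self.df = df.loc[:, DECOY_COLUMNS].reset_index(drop=True)
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return len(self.df)

    def poses(self) -> list:
        from .rigid_geometry import RigidPose

        out = []
        for row in self.df[_POSE_COLS].to_numpy():
            out.append(RigidPose(quat=row[:4], translation=row[4:]))
        return out

    @classmethod
    def from_records(cls, records: Iterable, meta: dict | None = None) -> "DecoyTable":
        rows = []
        for rec in records:
            q = rec.pose.quat
            t = rec.pose.translation
            e = rec.energies
            rows.append(
                dict(
                    traj=rec.traj, level=rec.level, step=rec.step,
                    capped=int(rec.capped),
                    contact=e.contact, vdw=e.vdw, env=e.env, pair=e.pair,
                    encounter=e.encounter if e.encounter is not None else 0.0,
                    total=e.total,
                    qw=q[0], qx=q[1], qy=q[2], qz=q[3],
                    tx=t[0], ty=t[1], tz=t[2],
                )
            )
        if not rows:
            raise ValidationError("cannot build a decoy table from zero records")
        return cls(pd.DataFrame(rows, columns=DECOY_COLUMNS), meta=meta)


def write_decoy_table(table: DecoyTable, path: str | Path) -> None:
    """Write a decoy table as TSV: energies to 3 decimals, pose as 7 numbers
    (unit quaternion w,x,y,z then translation x,y,z) at round-trip precision."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty decoy table")
    df = table.df.copy()
    for c in _ENERGY_COLS:
        df[c] = df[c].map(lambda v: f"{v:.3f}")
    for c in _POSE_COLS:
        df[c] = df[c].map(lambda v: f"{v:.8f}")
    try:
        with open(path, "w") as fh:
            for k, v in table.meta.items():
                fh.write(f"# {k}: {v}\n")
            df.to_csv(fh, sep="\t", index=False)
    except OSError as exc:
        raise IOError(f"cannot write decoy table to {path}: {exc}") from exc


def read_decoy_table(path: str | Path) -> DecoyTable:
    """Read a TSV decoy table written by :func:`write_decoy_table`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            text = line[1:].strip()
            if ":" in text:
                k, v = text.split(":", 1)
                meta[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return DecoyTable(df, meta=meta)
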