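"""Structure data model and PDB I/O.

A docking pose is held in a reduced representation: backbone heavy atoms
(N, CA, C, O) plus CB and a sidechain centroid per residue.  The ligand's
placement relative to the receptor is carried by a rigid "jump" transform,
the six rigid-body docking degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geom import RigidTransform

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

COARSE_ATOMS = ("N", "CA", "C", "O", "CB", "centroid")


class ChainNotFoundError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


@dataclass(frozen=True)
class Residue:
    """One residue in the coarse representation.

    ``seq_id`` keeps the author numbering from the source file; algorithms
    index residues densely by list position instead.
    """

    chain_id: str
    seq_id: int
    aa: str
    N: np.ndarray
    CA: np.ndarray
    C: np.ndarray
    O: np.ndarray
    CB: np.ndarray | None = None
    centroid: np.ndarray | None = None
    cb_is_virtual: bool = False

    def __post_init__(self) -> None:
        for name in ("N", "CA", "C", "O", "CB", "centroid"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))

    def replace(self, **kw) -> "Residue":
        return _dc_replace(self, **kw)

    def coarse_coords(self) -> np.ndarray:
        """Stack of available coarse atom coordinates, shape (k, 3)."""
        return np.array([getattr(self, a) for a in COARSE_ATOMS if getattr(self, a) is not None])

    def backbone_coords(self) -> np.ndarray:
        """N, CA, C, O coordinates, shape (4, 3)."""
        return np.array([self.N, self.CA, self.C, self.O])

    def transformed(self, T: RigidTransform) -> "Residue":
        kw = {}
        for name in COARSE_ATOMS:
            v = getattr(self, name)
            if v is not None:
                kw[name] = T.apply(v)
        return self.replace(**kw)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_id)


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB position from backbone N/CA/C (tetrahedral geometry)."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def _transform_residues(residues: Sequence[Residue], T: RigidTransform) -> tuple[Residue, ...]:
    return tuple(r.transformed(T) for r in residues)


class CoarsePose:
    """Two-partner docking pose.

    The receptor is stored in global coordinates.  The ligand is stored in
    its own local frame together with a rigid ``jump`` transform; the
    ligand's global coordinates are ``jump`` applied to the local ones.
    Rigid-body moves therefore only touch the jump, while backbone moves
    edit residue coordinates directly (receptor: global frame, ligand:
    local frame — backbone operators are frame-covariant so this is safe).
    """

    def __init__(
        self,
        receptor: Sequence[Residue],
        ligand_local: Sequence[Residue],
        jump: RigidTransform | None = None,
    ):
        self.receptor: tuple[Residue, ...] = tuple(receptor)
        self.ligand_local: tuple[Residue, ...] = tuple(ligand_local)
        self.jump: RigidTransform = jump if jump is not None else RigidTransform.identity()
        self._ligand_cache: tuple[Residue, ...] | None = None

    def validate(self) -> "CoarsePose":
        """Check receptor/ligand residue-key disjointness (not done per-copy:
        pose construction is on the MC hot path)."""
        rk = {r.key for r in self.receptor}
        lk = {r.key for r in self.ligand_local}
        if rk & lk:
            raise ValueError("receptor and ligand residue sets overlap")
        return self

    @property
    def ligand(self) -> tuple[Residue, ...]:
        """Ligand residues in global coordinates (jump applied; cached)."""
        if self._ligand_cache is None:
            self._ligand_cache = _transform_residues(self.ligand_local, self.jump)
        return self._ligand_cache

    def all_residues(self) -> tuple[Residue, ...]:
        return self.receptor + self.ligand

    def with_jump(self, jump: RigidTransform) -> "CoarsePose":
        return CoarsePose(self.receptor, self.ligand_local, jump)

    def with_receptor(self, receptor: Sequence[Residue]) -> "CoarsePose":
        return CoarsePose(receptor, self.ligand_local, self.jump)

    def with_ligand_local(self, ligand_local: Sequence[Residue]) -> "CoarsePose":
        return CoarsePose(self.receptor, ligand_local, self.jump)

    def receptor_centroid(self) -> np.ndarray:
        return np.mean([r.CA for r in self.receptor], axis=0)

    def ligand_centroid(self) -> np.ndarray:
        # via the local frame, avoiding a full ligand transform
        local = np.mean([r.CA for r in self.ligand_local], axis=0)
        return self.jump.apply(local)

    def copy(self) -> "CoarsePose":
        return CoarsePose(self.receptor, self.ligand_local, self.jump)


def parse_chain_spec(spec: str) -> tuple[list[str], list[str]]:
    """Split a chain spec like ``"A_B"`` into receptor and ligand chain lists."""
    if "_" not in spec:
        raise ValueError(f"chain spec {spec!r} must contain '_' separating receptor/ligand")
    rec, lig = spec.split("_", 1)
    if not rec or not lig:
        raise ValueError("chain spec must name at least one chain on each side")
    return list(rec), list(lig)


def _residues_from_atom_array(arr, chain_ids: Iterable[str]) -> list[Residue]:
    import biotite.structure as struc

    residues: list[Residue] = []
    for chain_id in chain_ids:
        mask = arr.chain_id == chain_id
        if not mask.any():
            raise ChainNotFoundError(f"chain not found: {chain_id!r}")
        chain = arr[mask]
        for res_id in np.unique(chain.res_id):
            res_atoms = chain[chain.res_id == res_id]
            names = list(res_atoms.atom_name)
            coords = {n: res_atoms.coord[i] for i, n in enumerate(names)}
            if any(req not in coords for req in ("N", "CA", "C")):
                logger.warning(
                    "dropping residue %s:%d — incomplete backbone", chain_id, int(res_id)
                )
                continue
            res_name = str(res_atoms.res_name[0])
            aa = THREE_TO_ONE.get(res_name, "X")
            side = [
                res_atoms.coord[i]
                for i, n in enumerate(names)
                if n not in _BACKBONE_NAMES and not n.startswith("H")
            ]
            cb = coords.get("CB")
            cb_virtual = False
            if cb is None:
                cb = virtual_cb(coords["N"], coords["CA"], coords["C"])
                cb_virtual = True
            if side:
                centroid = np.mean(side, axis=0)
            elif aa == "G":
                centroid = coords["CA"].copy()
            else:
                centroid = cb.copy()
            o = coords.get("O")
            if o is None:
                # approximate carbonyl O along the CA->C direction
                d = coords["C"] - coords["CA"]
                o = coords["C"] + 1.231 * d / np.linalg.norm(d)
                logger.warning("residue %s:%d missing O — synthesized", chain_id, int(res_id))
            residues.append(
                Residue(
                    chain_id=chain_id,
                    seq_id=int(res_id),
                    aa=aa,
                    N=coords["N"],
                    CA=coords["CA"],
                    C=coords["C"],
                    O=o,
                    CB=cb,
                    centroid=centroid,
                    cb_is_virtual=cb_virtual,
                )
            )
    return residues


def read_pdb(path: str | Path, chain_spec: str) -> CoarsePose:
    """Read a two-partner pose from a PDB file.

    ``chain_spec`` is of the form ``"A_B"`` — receptor chains before the
    underscore, ligand chains after.  Waters/hetero records are skipped,
    only MODEL 1 and the first altloc are used, and residues missing any of
    N/CA/C are dropped with a warning.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    rec_chains, lig_chains = parse_chain_spec(chain_spec)
    pdb_file = PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arr = pdb_file.get_structure(model=1, altloc="first")
    arr = arr[~arr.hetero]
    receptor = _residues_from_atom_array(arr, rec_chains)
    ligand = _residues_from_atom_array(arr, lig_chains)
    if not receptor or not ligand:
        raise EmptyStructureError(f"no parseable residues in {path} for spec {chain_spec!r}")
    return CoarsePose(receptor, ligand).validate()


_PDB_ATOM_FMT = (
    "ATOM  {serial:5d} {name:^4s}{altloc:1s}{resname:3s} {chain:1s}"
    "{resseq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
    "          {element:>2s}\n"
)


def write_pdb(pose: CoarsePose, path: str | Path) -> None:
    """Write the pose as standard fixed-column ATOM records.

    Real atoms only (virtual CB for glycine is not emitted, so a round trip
    re-derives it identically); TER records separate chains.
    """
    if not pose.receptor or not pose.ligand_local:
        raise ValueError("cannot write an empty pose")
    path = Path(path)
    lines: list[str] = []
    serial = 1

    def emit(residues: Sequence[Residue]) -> None:
        nonlocal serial
        prev_chain = None
        for res in residues:
            if prev_chain is not None and res.chain_id != prev_chain:
                lines.append("TER\n")
            prev_chain = res.chain_id
            atoms = [("N", res.N, "N"), ("CA", res.CA, "C"), ("C", res.C, "C"), ("O", res.O, "O")]
            if res.CB is not None and not res.cb_is_virtual:
                atoms.append(("CB", res.CB, "C"))
            resname = ONE_TO_THREE.get(res.aa, "UNK")
            for name, coord, element in atoms:
                # PDB convention: atom names of <4 chars start in column 14
                disp_name = f" {name}" if len(name) < 4 else name
                lines.append(
                    _PDB_ATOM_FMT.format(
                        serial=serial, name=disp_name, altloc=" ", resname=resname,
                        chain=res.chain_id, resseq=res.seq_id, icode=" ",
                        x=coord[0], y=coord[1], z=coord[2],
                        occ=1.00, b=0.00, element=element,
                    )
                )
                serial += 1
        lines.append("TER\n")

    emit(pose.receptor)
    emit(pose.ligand)
    lines.append("END\n")
    path.write_text("".join(lines))


@dataclass(frozen=True)
class DihedralRecord:
    """Backbone dihedrals in degrees, in (-180, 180]; ``None`` marks undefined."""

    phi: float | None
    psi: float | None
    omega: float | None


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees in (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


CHAIN_BREAK_CN = 2.0  # angstrom; C(i)-N(i+1) beyond this is a chain break


def backbone_dihedrals(residues: Sequence[Residue]) -> list[DihedralRecord]:
    """Phi/psi/omega per residue; termini and chain breaks are ``None``."""
    if len(residues) < 2:
        raise ValueError("need at least 2 residues for dihedrals")
    n = len(residues)

    def connected(i: int) -> bool:
        a, b = residues[i], residues[i + 1]
        if a.chain_id != b.chain_id:
            return False
        return float(np.linalg.norm(b.N - a.C)) <= CHAIN_BREAK_CN

    records = []
    for i, res in enumerate(residues):
        phi = psi = omega = None
        if i > 0 and connected(i - 1):
            phi = dihedral_angle(residues[i - 1].C, res.N, res.CA, res.C)
        if i < n - 1 and connected(i):
            nxt = residues[i + 1]
            psi = dihedral_angle(res.N, res.CA, res.C, nxt.N)
            omega = dihedral_angle(res.CA, res.C, nxt.N, nxt.CA)
        records.append(DihedralRecord(phi, psi, omega))
    return records


@dataclass(frozen=True)
class SecStructBoxes:
    """Dihedral-space boxes for the helix/strand assignment (config-exposed)."""

    helix_phi: tuple[float, float] = (-100.0, -30.0)
    helix_psi: tuple[float, float] = (-80.0, -5.0)
    strand_phi: tuple[float, float] = (-180.0, -40.0)
    strand_psi_hi: tuple[float, float] = (90.0, 180.0)
    strand_psi_lo: tuple[float, float] = (-180.0, -170.0)
    min_helix_run: int = 4
    min_strand_run: int = 3


def assign_secstruct(
    residues: Sequence[Residue], boxes: SecStructBoxes | None = None
) -> list[str]:
    """Per-residue H/E/L labels from phi/psi box membership with run-length filters."""
    boxes = boxes or SecStructBoxes()
    dihedrals = backbone_dihedrals(residues)

    def in_box(v: float | None, box: tuple[float, float]) -> bool:
        return v is not None and box[0] <= v <= box[1]

    raw = []
    for rec in dihedrals:
        if in_box(rec.phi, boxes.helix_phi) and in_box(rec.psi, boxes.helix_psi):
            raw.append("H")
        elif in_box(rec.phi, boxes.strand_phi) and (
            in_box(rec.psi, boxes.strand_psi_hi) or in_box(rec.psi, boxes.strand_psi_lo)
        ):
            raw.append("E")
        else:
            raw.append("L")

    # enforce minimum run lengths; short runs fall back to loop
    labels = ["L"] * len(raw)
    i = 0
    while i < len(raw):
        j = i
        while j < len(raw) and raw[j] == raw[i]:
            j += 1
        run = j - i
        if raw[i] == "H" and run >= boxes.min_helix_run:
            labels[i:j] = ["H"] * run
        elif raw[i] == "E" and run >= boxes.min_strand_run:
            labels[i:j] = ["E"] * run
        i = j
    return labels
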