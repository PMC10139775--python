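"""Protein backbone containers, PDB input, dihedrals and distances.

A protein is reduced to its backbone trace: per residue the N, CA and C
atoms plus a one-letter amino-acid code.  Residues missing any of the
three atoms are dropped on input and a chain break is recorded, so that
torsions are never computed across a gap.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .geometry import UndefinedDihedralError, dihedral

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_WITH_UNKNOWN = AA_ALPHABET + "X"


class EmptyStructureError(ValueError):
    """A chain with no complete backbone residues."""


@dataclass
class ProteinStructure:
    """Backbone record: sequence plus N/CA/C coordinates in Angstrom.

    ``chain_break_after`` holds residue indices i such that the chain is
    discontinuous between residue i and residue i+1 (0-based, after any
    incomplete residues were dropped).
    """

    sequence: str
    coords_N: np.ndarray
    coords_CA: np.ndarray
    coords_C: np.ndarray
    chain_break_after: frozenset = field(default_factory=frozenset)
    id: str = ""

    def __post_init__(self):
        self.coords_N = np.asarray(self.coords_N, dtype=np.float64)
        self.coords_CA = np.asarray(self.coords_CA, dtype=np.float64)
        self.coords_C = np.asarray(self.coords_C, dtype=np.float64)
        self.chain_break_after = frozenset(self.chain_break_after)
        L = len(self.sequence)
        if L < 2:
            raise ValueError(f"structure needs at least 2 residues, got {L}")
        for name, arr in (
            ("coords_N", self.coords_N),
            ("coords_CA", self.coords_CA),
            ("coords_C", self.coords_C),
        ):
            if arr.shape != (L, 3):
                raise ValueError(f"{name} must have shape ({L}, 3), got {arr.shape}")
        bad = set(self.sequence) - set(AA_WITH_UNKNOWN)
        if bad:
            raise ValueError(f"illegal residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DihedralTable:
    """Backbone phi/psi per residue with validity flags.

    phi[0] and psi[L-1] are undefined by construction; angles spanning a
    chain break or a degenerate geometry are flagged invalid too.
    """

    phi: np.ndarray
    psi: np.ndarray
    phi_valid: np.ndarray
    psi_valid: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def backbone_dihedrals(s: ProteinStructure) -> DihedralTable:
    """phi_i = torsion(C_{i-1}, N_i, CA_i, C_i); psi_i = torsion(N_i, CA_i, C_i, N_{i+1})."""
    L = len(s)
    phi = np.zeros(L)
    psi = np.zeros(L)
    phi_valid = np.zeros(L, dtype=bool)
    psi_valid = np.zeros(L, dtype=bool)
    breaks = s.chain_break_after
    for i in range(L):
        if i > 0 and (i - 1) not in breaks:
            try:
                phi[i] = dihedral(s.coords_C[i - 1], s.coords_N[i], s.coords_CA[i], s.coords_C[i])
                phi_valid[i] = True
            except UndefinedDihedralError:
                pass
        if i < L - 1 and i not in breaks:
            try:
                psi[i] = dihedral(s.coords_N[i], s.coords_CA[i], s.coords_C[i], s.coords_N[i + 1])
                psi_valid[i] = True
            except UndefinedDihedralError:
                pass
    return DihedralTable(phi, psi, phi_valid, psi_valid)


def ca_distance_matrix(s: ProteinStructure) -> np.ndarray:
    """Symmetric L x L Euclidean distance matrix between CA atoms."""
    return squareform(pdist(s.coords_CA))


# ---------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C")


def read_pdb_backbone(path) -> list[ProteinStructure]:
    """Read the backbone of every chain of the first model of a PDB file.

    Residues lacking any of N/CA/C are dropped, with a chain break
    recorded before the next kept residue.  Alternate locations resolve
    to the first one (altLoc ' ' or 'A').
    """
    from biotite.structure.io.pdb import PDBFile
    import biotite.structure as struc
    from biotite.sequence import ProteinSequence

    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1, altloc="first")
    structures = []
    seen = []
    for cid in atoms.chain_id:
        if cid not in seen:
            seen.append(cid)
    for cid in seen:
        chain = atoms[atoms.chain_id == cid]
        seq_parts = []
        coords = {k: [] for k in _BACKBONE}
        breaks = set()
        prev_res_id = None
        pending_break = False
        for res in struc.residue_iter(chain):
            names = list(res.atom_name)
            if not all(n in names for n in _BACKBONE):
                pending_break = True
                continue
            rid = int(res.res_id[0])
            if prev_res_id is not None and (pending_break or rid - prev_res_id != 1):
                breaks.add(len(seq_parts) - 1)
            pending_break = False
            prev_res_id = rid
            try:
                letter = ProteinSequence.convert_letter_3to1(res.res_name[0])
            except Exception:
                letter = "X"
            seq_parts.append(letter if letter in AA_WITH_UNKNOWN else "X")
            for n in _BACKBONE:
                coords[n].append(res.coord[names.index(n)])
        if not seq_parts:
            raise EmptyStructureError(f"chain {cid!r} has no complete backbone residues")
        if len(seq_parts) < 2:
            continue
        structures.append(
            ProteinStructure(
                sequence="".join(seq_parts),
                coords_N=np.array(coords["N"]),
                coords_CA=np.array(coords["CA"]),
                coords_C=np.array(coords["C"]),
                chain_break_after=frozenset(breaks),
                id=str(cid),
            )
        )
    if not structures:
        raise EmptyStructureError("no chain with at least two complete residues")
    return structures
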