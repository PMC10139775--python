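"""Synthetic backbones with analytically known geometry.

Chains are grown residue by residue from ideal internal coordinates
(bond lengths/angles fixed at standard backbone values), so the phi/psi
torsions recovered from the emitted coordinates equal the requested ones
to machine precision.  Three generators cover the canonical secondary
structures: an ideal alpha-helix (phi=-57, psi=-47 degrees), an ideal
beta-strand (phi=-120, psi=+120) and a random coil with uniform
torsions.  Together with on-disk PDB round-tripping this gives every
downstream module a fully testable data source with no external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import place_atom
from .structure import AA_ALPHABET, ProteinStructure

# standard backbone internal coordinates (Angstrom / radians)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_C_N_CA = np.deg2rad(121.7)
ANGLE_N_CA_C = np.deg2rad(111.2)
ANGLE_CA_C_N = np.deg2rad(116.2)

HELIX_PHI = np.deg2rad(-57.0)
HELIX_PSI = np.deg2rad(-47.0)
STRAND_PHI = np.deg2rad(-120.0)
STRAND_PSI = np.deg2rad(120.0)

GENERATOR_TYPES = ("helix", "strand", "coil")


@dataclass
class BackboneSpec:
    """Internal-coordinate description of one backbone.

    phi[i] is consumed for residues 1..L-1 and psi[i] for residues
    0..L-2; the terminal phi[0] / psi[L-1] entries are ignored (those
    torsions do not exist).
    """

    n_residues: int
    phi: np.ndarray
    psi: np.ndarray
    sequence: str
    omega: float = np.pi
    bond_lengths: tuple = (BOND_N_CA, BOND_CA_C, BOND_C_N)  # N-CA, CA-C, C-N
    bond_angles: tuple = (ANGLE_C_N_CA, ANGLE_N_CA_C, ANGLE_CA_C_N)  # C-N-CA, N-CA-C, CA-C-N

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.psi = np.asarray(self.psi, dtype=np.float64)
        if self.n_residues < 2:
            raise ValueError("n_residues must be at least 2")
        if self.phi.shape != (self.n_residues,):
            raise ValueError("phi must have one value per residue")
        if self.psi.shape != (self.n_residues,):
            raise ValueError("psi must have one value per residue")
        if len(self.sequence) != self.n_residues:
            raise ValueError("sequence length must equal n_residues")
        if any(b <= 0 for b in self.bond_lengths):
            raise ValueError("bond_lengths must be positive")


def build_chain(spec: BackboneSpec, id: str = "") -> ProteinStructure:
    """Grow N/CA/C coordinates from the internal coordinates in ``spec``."""
    L = spec.n_residues
    b_n_ca, b_ca_c, b_c_n = spec.bond_lengths
    a_c_n_ca, a_n_ca_c, a_ca_c_n = spec.bond_angles
    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    # first residue in the xy-plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (b_n_ca, 0.0, 0.0)
    C[0] = CA[0] + b_ca_c * np.array(
        [-np.cos(a_n_ca_c), np.sin(a_n_ca_c), 0.0]
    )
    for i in range(1, L):
        # psi of residue i-1 sets N_i; omega sets CA_i; phi of residue i sets C_i
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], b_c_n, a_ca_c_n, spec.psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], b_n_ca, a_c_n_ca, spec.omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], b_ca_c, a_n_ca_c, spec.phi[i])
    return ProteinStructure(
        sequence=spec.sequence, coords_N=N, coords_CA=CA, coords_C=C, id=id
    )


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def _uniform_spec(n: int, phi: float, psi: float, rng: np.random.Generator) -> BackboneSpec:
    return BackboneSpec(
        n_residues=n,
        phi=np.full(n, phi),
        psi=np.full(n, psi),
        sequence=_random_sequence(n, rng),
    )


def _check_length(n: int) -> None:
    if n < 3:
        raise ValueError("generators need n >= 3 residues")


def make_ideal_helix(n: int, seed: int = 0, id: str = "") -> ProteinStructure:
    """Ideal alpha-helix; the sequence is random under the seed."""
    _check_length(n)
    rng = np.random.default_rng(seed)
    return build_chain(_uniform_spec(n, HELIX_PHI, HELIX_PSI, rng), id=id)


def make_ideal_strand(n: int, seed: int = 0, id: str = "") -> ProteinStructure:
    """Ideal extended beta-strand; the sequence is random under the seed."""
    _check_length(n)
    rng = np.random.default_rng(seed)
    return build_chain(_uniform_spec(n, STRAND_PHI, STRAND_PSI, rng), id=id)


def make_random_coil(n: int, seed: int = 0, id: str = "") -> ProteinStructure:
    """Coil with phi/psi sampled uniformly from (-pi, pi]."""
    _check_length(n)
    rng = np.random.default_rng(seed)
    phi = np.pi - rng.uniform(0.0, 2.0 * np.pi, size=n)
    psi = np.pi - rng.uniform(0.0, 2.0 * np.pi, size=n)
    return build_chain(
        BackboneSpec(n_residues=n, phi=phi, psi=psi, sequence=_random_sequence(n, rng)),
        id=id,
    )


_GENERATORS = {
    "helix": make_ideal_helix,
    "strand": make_ideal_strand,
    "coil": make_random_coil,
}


@dataclass
class ToyDataset:
    """Labelled mixture of generated structures (label = generator type)."""

    structures: list
    labels: np.ndarray
    class_names: tuple = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.structures)


def make_toy_dataset(
    n_proteins: int,
    length_range: tuple = (20, 40),
    class_count: int = 3,
    seed: int = 0,
) -> ToyDataset:
    """A balanced helix/strand/coil mixture with generator-type labels."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be at least 1")
    if not 1 <= class_count <= len(GENERATOR_TYPES):
        raise ValueError(
            f"class_count must be in [1, {len(GENERATOR_TYPES)}], got {class_count}"
        )
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    structures = []
    labels = []
    for k in range(n_proteins):
        cls = k % class_count
        n = int(rng.integers(lo, hi + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        structures.append(
            _GENERATORS[GENERATOR_TYPES[cls]](n, seed=sub_seed, id=f"p{k:04d}")
        )
        labels.append(cls)
    return ToyDataset(
        structures=structures,
        labels=np.array(labels, dtype=np.int64),
        class_names=GENERATOR_TYPES[:class_count],
    )


def write_pdb(structure: ProteinStructure, path) -> None:
    """Write the backbone as single-model, single-chain ATOM records."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from biotite.sequence import ProteinSequence

    L = len(structure)
    atoms = struc.AtomArray(3 * L)
    coords = np.empty((3 * L, 3))
    names = ("N", "CA", "C")
    elements = ("N", "C", "C")
    per_res = (structure.coords_N, structure.coords_CA, structure.coords_C)
    for i in range(L):
        res3 = ProteinSequence.convert_letter_1to3(structure.sequence[i])
        for a, (name, elem, arr) in enumerate(zip(names, elements, per_res)):
            idx = 3 * i + a
            coords[idx] = arr[i]
            atoms.atom_name[idx] = name
            atoms.element[idx] = elem
            atoms.res_id[idx] = i + 1
            atoms.res_name[idx] = res3
    atoms.coord = coords
    atoms.chain_id[:] = "A"
    atoms.hetero[:] = False
    atoms.set_annotation("occupancy", np.ones(3 * L))
    atoms.set_annotation("b_factor", np.zeros(3 * L))
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
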