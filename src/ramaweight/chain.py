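"""Coarse-grained torsion-angle chain: topology, kinematics, LJ energy.

The molecular system is a linear chain of residues, three backbone
beads (N, CA, C) per residue, with fixed bond lengths and bond angles.
The only free variables are the backbone torsions phi (C-N-CA-C) and
psi (N-CA-C-N); the peptide torsion omega (CA-C-N-CA) is fixed trans.
The physical force field E_ff is a plain 12-6 Lennard-Jones energy
over bead pairs at topological separation of at least three bonds.

phi of the first residue and psi of the last are undefined (they
would require atoms outside the chain) and are stored as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .torus_density import wrap_angle

__all__ = [
    "ChainTopology",
    "Conformation",
    "ForceFieldParams",
    "place_chain",
    "lj_energy",
    "chain_energy",
    "measure_dihedrals",
    "write_pdb",
]

ATOMS_PER_RESIDUE = 3
ATOM_NAMES = ("N", "CA", "C")

# standard backbone geometry (Engh-Huber-like), overridable via config
DEFAULT_BOND_LENGTHS = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
DEFAULT_BOND_ANGLES_DEG = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7}
OMEGA = np.pi  # trans peptide


@dataclass(frozen=True)
class ChainTopology:
    """A linear chain of ``n_residues`` with fixed internal geometry."""

    n_residues: int
    bond_lengths: dict = field(default_factory=lambda: dict(DEFAULT_BOND_LENGTHS))
    bond_angles_deg: dict = field(default_factory=lambda: dict(DEFAULT_BOND_ANGLES_DEG))

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if any(v <= 0 for v in self.bond_lengths.values()):
            raise ValueError("bond lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return ATOMS_PER_RESIDUE * self.n_residues

    def internal_geometry(self):
        """Per-atom (bond length, bond angle) arrays for chain building.

        Index i holds the bond (i-1, i) and the angle at atom i-1.
        """
        n = self.n_atoms
        r = np.zeros(n)
        theta = np.zeros(n)
        bl = self.bond_lengths
        ba = {k: np.deg2rad(v) for k, v in self.bond_angles_deg.items()}
        for i in range(1, n):
            kind = i % ATOMS_PER_RESIDUE  # 0=N, 1=CA, 2=C
            r[i] = {0: bl["C-N"], 1: bl["N-CA"], 2: bl["CA-C"]}[kind]
        for i in range(2, n):
            at = (i - 1) % ATOMS_PER_RESIDUE  # atom at the vertex
            theta[i] = {0: ba["C-N-CA"], 1: ba["N-CA-C"], 2: ba["CA-C-N"]}[at]
        return r, theta

    def free_torsion_atoms(self) -> np.ndarray:
        """Atom indices whose placement torsion is a free phi or psi.

        Atom 3i (N of residue i >= 1) carries psi_{i-1}; atom 3i+2
        (C of residue i >= 1) carries phi_i.  Atoms at index 3i+1 carry
        the fixed omega.  Ascending order: psi_0, phi_1, psi_1, ...,
        phi_{n-1}; length 2*(n_residues - 1).
        """
        idx = []
        for i in range(3, self.n_atoms):
            if i % ATOMS_PER_RESIDUE != 1:
                idx.append(i)
        return np.array(idx, dtype=np.int64)

    def interior_residue_torsion_atoms(self):
        """Torsion-array indices of (phi, psi) for residues 1..n-2.

        These are the residues with both backbone torsions defined,
        i.e. the ones contributing to the Ramachandran energy.
        """
        res = np.arange(1, self.n_residues - 1)
        phi_atoms = ATOMS_PER_RESIDUE * res + 2
        psi_atoms = ATOMS_PER_RESIDUE * (res + 1)
        return phi_atoms.astype(np.int64), psi_atoms.astype(np.int64)

    def to_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "bond_lengths": dict(self.bond_lengths),
            "bond_angles_deg": dict(self.bond_angles_deg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainTopology":
        return cls(
            n_residues=int(d["n_residues"]),
            bond_lengths=dict(d.get("bond_lengths", DEFAULT_BOND_LENGTHS)),
            bond_angles_deg=dict(d.get("bond_angles_deg", DEFAULT_BOND_ANGLES_DEG)),
        )


@dataclass
class Conformation:
    """Backbone torsions of a chain; undefined terminal torsions are NaN."""

    phi: np.ndarray  # (n_residues,), phi[0] = NaN
    psi: np.ndarray  # (n_residues,), psi[-1] = NaN

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 1:
            raise ValueError("phi and psi must be equal-length 1D arrays")
        defined_phi, defined_psi = self.phi[1:], self.psi[:-1]
        if not (np.all(np.isfinite(defined_phi)) and np.all(np.isfinite(defined_psi))):
            raise ValueError("defined torsions must be finite")
        self.phi = np.concatenate([[np.nan], wrap_angle(defined_phi)])
        self.psi = np.concatenate([wrap_angle(defined_psi), [np.nan]])

    @property
    def n_residues(self) -> int:
        return self.phi.size

    def free_vector(self) -> np.ndarray:
        """Flat vector [psi_0, phi_1, psi_1, ..., phi_{n-1}]."""
        out = []
        for i in range(1, self.n_residues):
            out.append(self.psi[i - 1])
            out.append(self.phi[i])
        return np.array(out)

    @classmethod
    def from_free_vector(cls, x, n_residues: int) -> "Conformation":
        x = np.asarray(x, dtype=float)
        if x.size != 2 * (n_residues - 1):
            raise ValueError("free vector length must be 2*(n_residues-1)")
        phi = np.full(n_residues, np.nan)
        psi = np.full(n_residues, np.nan)
        for i in range(1, n_residues):
            psi[i - 1] = x[2 * (i - 1)]
            phi[i] = x[2 * (i - 1) + 1]
        return cls(phi, psi)

    def full_torsion_array(self, topology: ChainTopology) -> np.ndarray:
        """Per-atom torsion array for the chain builder (omega fixed trans)."""
        tor = np.zeros(topology.n_atoms)
        for i in range(3, topology.n_atoms):
            kind = i % ATOMS_PER_RESIDUE
            res = i // ATOMS_PER_RESIDUE
            if kind == 0:
                tor[i] = self.psi[res - 1]
            elif kind == 1:
                tor[i] = OMEGA
            else:
                tor[i] = self.phi[res]
        return tor


@dataclass(frozen=True)
class ForceFieldParams:
    """Parameters of the 12-6 Lennard-Jones nonbonded energy (k_BT, A)."""

    epsilon: float = 0.3
    sigma: float = 2.5
    min_separation: int = 3  # minimum bond-count separation of included pairs
    r_cut: float = 0.0  # <= 0: no truncation

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma <= 0:
            raise ValueError("need epsilon >= 0 and sigma > 0")

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "sigma": self.sigma,
            "min_separation": self.min_separation,
            "r_cut": self.r_cut,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        return cls(**d)


def place_chain(topology: ChainTopology, conformation: Conformation) -> np.ndarray:
    """Cartesian coordinates (n_atoms, 3) for the given torsions.

    The first atom sits at the origin, the second on +x, the third in
    the xy-plane; bond lengths and angles come from the topology.
    """
    if conformation.n_residues != topology.n_residues:
        raise ValueError("conformation does not match topology")
    r, theta = topology.internal_geometry()
    tor = conformation.full_torsion_array(topology)
    return _kernels.place_chain_kernel(r, theta, tor)


def lj_energy(coords, params: ForceFieldParams) -> float:
    """Lennard-Jones energy of a bead configuration.

    Pairs closer than ``params.min_separation`` bonds along the chain
    are excluded.  A coincident included pair gives +inf.
    """
    coords = np.ascontiguousarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
        raise ValueError("coords must be (n, 3) with n >= 1")
    return float(
        _kernels.lj_energy_kernel(
            coords, params.epsilon, params.sigma, params.min_separation, params.r_cut
        )
    )


def chain_energy(
    topology: ChainTopology, conformation: Conformation, params: ForceFieldParams
) -> float:
    """E_ff of a conformation: LJ energy of the placed chain."""
    return lj_energy(place_chain(topology, conformation), params)


def measure_dihedrals(coords, topology: ChainTopology) -> Conformation:
    """Recover (phi, psi) per residue from Cartesian coordinates.

    Inverse of :func:`place_chain` on its image.  Raises on collinear
    atom triples, where the dihedral is undefined.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coords inconsistent with topology")
    n = topology.n_residues
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def dihedral(i0, i1, i2, i3):
        for a, b, c in ((i0, i1, i2), (i1, i2, i3)):
            v1 = coords[b] - coords[a]
            v2 = coords[c] - coords[b]
            cr = np.cross(v1, v2)
            if np.linalg.norm(cr) < 1e-10 * np.linalg.norm(v1) * np.linalg.norm(v2):
                raise ValueError(f"collinear atoms {a},{b},{c}: dihedral undefined")
        return float(
            _kernels.dihedral_kernel(coords[i0], coords[i1], coords[i2], coords[i3])
        )

    for i in range(n):
        N, CA, C = 3 * i, 3 * i + 1, 3 * i + 2
        if i > 0:
            phi[i] = dihedral(C - 3, N, CA, C)  # C(i-1)-N-CA-C
        if i < n - 1:
            psi[i] = dihedral(N, CA, C, C + 1)  # N-CA-C-N(i+1)
    return Conformation(phi, psi)


def write_pdb(coords, topology: ChainTopology, path) -> None:
    """Write beads as minimal PDB ATOM records (one chain, N/CA/C names)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.atom_name = np.array([ATOM_NAMES[i % 3] for i in range(n)])
    arr.res_id = np.array([i // 3 + 1 for i in range(n)])
    arr.res_name = np.array(["GLY"] * n)
    arr.chain_id = np.array(["A"] * n)
    arr.element = np.array(["N" if i % 3 == 0 else "C" for i in range(n)])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)
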