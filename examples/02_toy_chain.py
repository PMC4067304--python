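"""Build a coarse-grained torsion chain and evaluate its energies.

Places an 8-residue chain (3 backbone beads per residue) from random
backbone torsions, measures the torsions back from the coordinates,
and evaluates the Lennard-Jones and Ramachandran energies.
"""

import numpy as np

from ramaweight import (
    ChainTopology,
    Conformation,
    ForceFieldParams,
    chain_energy,
    measure_dihedrals,
    place_chain,
    rama_potential,
)
from ramaweight.chain import write_pdb
from ramaweight.experiments import make_toy_density

rng = np.random.default_rng(0)
topo = ChainTopology(8)
conf = Conformation.from_free_vector(
    rng.uniform(-np.pi, np.pi, 2 * (topo.n_residues - 1)), topo.n_residues
)
coords = place_chain(topo, conf)
back = measure_dihedrals(coords, topo)
err = np.nanmax(np.abs(np.concatenate([back.phi - conf.phi, back.psi - conf.psi])))

density = make_toy_density()
e_rama = sum(
    float(rama_potential(density, conf.phi[i], conf.psi[i]))
    for i in range(1, topo.n_residues - 1)
)
e_ff = chain_energy(topo, conf, ForceFieldParams())

print(f"atoms                    : {coords.shape[0]}")
print(f"torsion round-trip error : {err:.2e} rad")
print(f"E_ff (Lennard-Jones)     : {e_ff:.3f} kT")
print(f"E_rama (backbone term)   : {e_rama:.3f} kT")
# E_ff is the physical nonbonded energy; E_rama sums the statistical
# backbone potential over the six interior residues.  Random torsions
# typically score poorly (positive E_rama) against the density.

write_pdb(coords, topo, "chain.pdb")
print("wrote chain.pdb")
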