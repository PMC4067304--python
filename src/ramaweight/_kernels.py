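"""Numba kernels for the hot paths of the torsion-chain sampler.

These are thin numerical routines; the documented public API lives in
:mod:`ramaweight.chain`, :mod:`ramaweight.restraints` and
:mod:`ramaweight.remc`.  Conventions: internal coordinates are stored
per atom (bond length to the previous atom, bond angle at the previous
atom, torsion about the previous bond); dihedrals follow the IUPAC
sign convention (cis = 0, trans = +/-pi).
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@njit(cache=True)
def place_chain_kernel(bond_r, bond_theta, torsions):
    """Build Cartesian coordinates from internal coordinates (NeRF).

    bond_r[i]   : length of the bond (i-1, i), i >= 1
    bond_theta[i]: angle at atom i-1 between atoms (i-2, i-1, i), i >= 2
    torsions[i] : dihedral (i-3, i-2, i-1, i), i >= 3
    """
    n = bond_r.shape[0]
    coords = np.zeros((n, 3))
    if n > 1:
        coords[1, 0] = bond_r[1]
    if n > 2:
        coords[2, 0] = coords[1, 0] - bond_r[2] * np.cos(bond_theta[2])
        coords[2, 1] = bond_r[2] * np.sin(bond_theta[2])
    for i in range(3, n):
        a = coords[i - 3]
        b = coords[i - 2]
        c = coords[i - 1]
        r = bond_r[i]
        theta = bond_theta[i]
        phi = torsions[i]
        bcx = c[0] - b[0]
        bcy = c[1] - b[1]
        bcz = c[2] - b[2]
        nb = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nb
        bcy /= nb
        bcz /= nb
        abx = b[0] - a[0]
        aby = b[1] - a[1]
        abz = b[2] - a[2]
        # n = unit(ab x bc), m = n x bc
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        d1 = -r * np.cos(theta)
        d2 = r * np.sin(theta) * np.cos(phi)
        d3 = -r * np.sin(theta) * np.sin(phi)  # sign matches the IUPAC measurement
        coords[i, 0] = c[0] + d1 * bcx + d2 * mx + d3 * nx
        coords[i, 1] = c[1] + d1 * bcy + d2 * my + d3 * ny
        coords[i, 2] = c[2] + d1 * bcz + d2 * mz + d3 * nz
    return coords


@njit(cache=True)
def dihedral_kernel(p0, p1, p2, p3):
    """Signed dihedral of four points, IUPAC convention (cis = 0)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
    m1 = np.cross(n1, b2 / nb2)
    x = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    y = m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]
    return np.arctan2(y, x)


@njit(cache=True)
def lj_energy_kernel(coords, epsilon, sigma, min_sep, rcut):
    """12-6 Lennard-Jones over pairs at topological separation >= min_sep.

    On a linear chain the bond separation of beads i, j is |i - j|.
    rcut <= 0 disables truncation.  A coincident included pair yields
    +inf (not an exception).
    """
    n = coords.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + min_sep, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 == 0.0:
                return np.inf
            if rcut > 0.0 and r2 > rcut * rcut:
                continue
            s2 = sigma * sigma / r2
            s6 = s2 * s2 * s2
            e += 4.0 * epsilon * (s6 * s6 - s6)
    return e


@njit(cache=True)
def basis_energy_kernel(phi, psi, pk, sk, kf, lf, coeffs):
    """Ramachandran potential at one (phi, psi) from the Fourier basis."""
    e = 0.0
    for j in range(coeffs.shape[0]):
        a = kf[j] * phi
        t1 = np.cos(a) if pk[j] == 0 else np.sin(a)
        b = lf[j] * psi
        t2 = np.cos(b) if sk[j] == 0 else np.sin(b)
        e += coeffs[j] * t1 * t2
    return e


@njit(cache=True)
def rama_energy_kernel(torsions, phi_atoms, psi_atoms, pk, sk, kf, lf, coeffs):
    """Sum of the Ramachandran potential over interior residues.

    phi_atoms[m], psi_atoms[m] index the torsion entries holding
    (phi, psi) of interior residue m.
    """
    e = 0.0
    for m in range(phi_atoms.shape[0]):
        e += basis_energy_kernel(
            torsions[phi_atoms[m]], torsions[psi_atoms[m]], pk, sk, kf, lf, coeffs
        )
    return e


@njit(cache=True)
def data_energy_kernel(coords, pair_i, pair_j, d_obs, gamma, sigma):
    """Negative log lognormal likelihood of observed distances."""
    e = 0.0
    for m in range(pair_i.shape[0]):
        dx = coords[pair_i[m], 0] - coords[pair_j[m], 0]
        dy = coords[pair_i[m], 1] - coords[pair_j[m], 1]
        dz = coords[pair_i[m], 2] - coords[pair_j[m], 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        r = np.log(d_obs[m]) - np.log(gamma * d)
        e += np.log(d_obs[m]) + np.log(sigma) + LOG_SQRT_2PI + 0.5 * r * r / (sigma * sigma)
    return e


@njit(cache=True)
def pair_distances_kernel(coords, pair_i, pair_j):
    n = pair_i.shape[0]
    out = np.empty(n)
    for m in range(n):
        dx = coords[pair_i[m], 0] - coords[pair_j[m], 0]
        dy = coords[pair_i[m], 1] - coords[pair_j[m], 1]
        dz = coords[pair_i[m], 2] - coords[pair_j[m], 2]
        out[m] = np.sqrt(dx * dx + dy * dy + dz * dz)
    return out


@njit(cache=True)
def torsion_sweep_kernel(
    torsions,
    free_idx,
    bond_r,
    bond_theta,
    epsilon,
    sigma_lj,
    min_sep,
    rcut,
    phi_atoms,
    psi_atoms,
    pk,
    sk,
    kf,
    lf,
    coeffs,
    pair_i,
    pair_j,
    d_obs,
    gamma,
    sigma_err,
    lam,
    beta,
    w,
    step,
    normals,
    uniforms,
):
    """One random-walk Metropolis pass over all free torsions.

    Targets exp(-(lam*E_data + beta*E_ff + beta*w*E_rama)).  The
    proposal is a wrapped Gaussian per torsion; ``normals`` and
    ``uniforms`` supply one draw per free torsion.  Returns the final
    (E_data, E_rama, E_ff) and the number of accepted moves.
    Torsions are modified in place.
    """
    coords = place_chain_kernel(bond_r, bond_theta, torsions)
    e_ff = lj_energy_kernel(coords, epsilon, sigma_lj, min_sep, rcut)
    e_rama = rama_energy_kernel(torsions, phi_atoms, psi_atoms, pk, sk, kf, lf, coeffs)
    e_data = data_energy_kernel(coords, pair_i, pair_j, d_obs, gamma, sigma_err)
    total = lam * e_data + beta * e_ff + beta * w * e_rama
    n_acc = 0
    for t in range(free_idx.shape[0]):
        idx = free_idx[t]
        old = torsions[idx]
        prop = old + step * normals[t]
        # wrap to [-pi, pi)
        prop = np.mod(prop + np.pi, 2.0 * np.pi) - np.pi
        torsions[idx] = prop
        new_coords = place_chain_kernel(bond_r, bond_theta, torsions)
        new_ff = lj_energy_kernel(new_coords, epsilon, sigma_lj, min_sep, rcut)
        new_rama = rama_energy_kernel(
            torsions, phi_atoms, psi_atoms, pk, sk, kf, lf, coeffs
        )
        new_data = data_energy_kernel(new_coords, pair_i, pair_j, d_obs, gamma, sigma_err)
        new_total = lam * new_data + beta * new_ff + beta * w * new_rama
        if np.log(uniforms[t]) < total - new_total:
            total = new_total
            e_ff = new_ff
            e_rama = new_rama
            e_data = new_data
            n_acc += 1
        else:
            torsions[idx] = old
    return e_data, e_rama, e_ff, n_acc
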