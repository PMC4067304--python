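"""Density of states over (E_data, E_rama) and the evidence curve Z(w).

Multiple-histogram reweighting (WHAM) combines the energy histograms
recorded at the different (lambda, w) replicas into one estimate of
the density of states g(E_data, E_rama), whose base measure already
contains the fixed Boltzmann factor exp(-beta*E_ff) (beta is not
tempered here).  The coupled fixed-point equations are

    g(b)  = sum_k n_k(b) / sum_k N_k exp(f_k - lam_k e_d(b) - beta w_k e_r(b))
    f_k   = -log sum_b g(b) exp(-lam_k e_d(b) - beta w_k e_r(b))

iterated in log space to a tolerance on the replica log-normalizers.

From g the model evidence of the data under the prior defined by
weight w follows as a two-dimensional sum,

    log Z(w) = log sum_b g(b) e^{-e_d(b) - beta w e_r(b)}
             - log sum_b g(b) e^{-beta w e_r(b)},

up to a w-independent constant, and its derivative is
-beta (<E_rama>_posterior - <E_rama>_prior).  The optimal weight
maximizes log Z(w); equivalently the posterior and prior mean
Ramachandran energies cross there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.special import logsumexp

from .remc import ReplicaSchedule, TraceSet

__all__ = [
    "DensityOfStates",
    "EvidenceCurve",
    "estimate_dos",
    "log_evidence",
    "expected_rama_energy",
    "optimal_weight",
]


@dataclass
class DensityOfStates:
    """Binned 2D density of states over (E_data, E_rama)."""

    edges_data: np.ndarray
    edges_rama: np.ndarray
    log_g: np.ndarray  # (n_d, n_r); -inf on empty bins
    f_k: np.ndarray  # replica log-normalizers
    schedule: ReplicaSchedule
    converged: bool
    n_iter: int
    overlap_connected: bool
    counts: np.ndarray | None = None

    @property
    def centers_data(self) -> np.ndarray:
        return 0.5 * (self.edges_data[:-1] + self.edges_data[1:])

    @property
    def centers_rama(self) -> np.ndarray:
        return 0.5 * (self.edges_rama[:-1] + self.edges_rama[1:])

    def occupied(self) -> np.ndarray:
        return np.isfinite(self.log_g)

    def flat(self):
        """(log_g, e_d, e_r) restricted to occupied bins."""
        occ = self.occupied()
        cd, cr = np.meshgrid(self.centers_data, self.centers_rama, indexing="ij")
        return self.log_g[occ], cd[occ], cr[occ]

    def to_dict(self) -> dict:
        return {
            "edges_data": self.edges_data.tolist(),
            "edges_rama": self.edges_rama.tolist(),
            "log_g": np.where(np.isfinite(self.log_g), self.log_g, None).tolist(),
            "f_k": self.f_k.tolist(),
            "schedule": self.schedule.to_dict(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "overlap_connected": bool(self.overlap_connected),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "DensityOfStates":
        log_g = np.array(
            [[-np.inf if v is None else v for v in row] for row in d["log_g"]]
        )
        return cls(
            edges_data=np.asarray(d["edges_data"]),
            edges_rama=np.asarray(d["edges_rama"]),
            log_g=log_g,
            f_k=np.asarray(d["f_k"]),
            schedule=ReplicaSchedule.from_dict(d["schedule"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            overlap_connected=d["overlap_connected"],
        )


def _bin_edges(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    pad = 0.01 * max(hi - lo, 1e-12)
    return np.linspace(lo - pad, hi + pad, n_bins + 1)


def _replicas_connected(counts: np.ndarray) -> bool:
    """Union-find over replicas joined through shared occupied bins."""
    K = counts.shape[0]
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    occ = counts.reshape(K, -1) > 0
    for b in range(occ.shape[1]):
        ks = np.nonzero(occ[:, b])[0]
        for other in ks[1:]:
            ra, rb = find(ks[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    return len({find(k) for k in range(K)}) == 1


def estimate_dos(
    traces: TraceSet,
    schedule: ReplicaSchedule | None = None,
    bins=(64, 64),
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> DensityOfStates:
    """Estimate the density of states by multiple-histogram reweighting.

    Parameters
    ----------
    traces : TraceSet
        Per-replica (E_data, E_rama, E_ff) records.
    bins : (int, int) or (ndarray, ndarray)
        Bin counts, or explicit bin edges for (E_data, E_rama).
    tol : float
        Convergence threshold on the maximum change of the replica
        log-normalizers f_k (after removing their common shift).

    Empty bins carry zero mass (log g = -inf); no smoothing is
    applied.  Bin representatives are bin centers.
    """
    schedule = schedule if schedule is not None else traces.schedule
    K = len(schedule)
    if K != traces.n_replicas or any(len(e) == 0 for e in traces.energies):
        raise ValueError("need one non-empty trace per replica")
    all_ed = np.concatenate([e[:, 0] for e in traces.energies])
    all_er = np.concatenate([e[:, 1] for e in traces.energies])
    if isinstance(bins[0], (int, np.integer)):
        edges_d = _bin_edges(all_ed, int(bins[0]))
    else:
        edges_d = np.asarray(bins[0], dtype=float)
    if isinstance(bins[1], (int, np.integer)):
        edges_r = _bin_edges(all_er, int(bins[1]))
    else:
        edges_r = np.asarray(bins[1], dtype=float)

    nd, nr = len(edges_d) - 1, len(edges_r) - 1
    counts = np.zeros((K, nd, nr))
    for k, e in enumerate(traces.energies):
        h, _, _ = np.histogram2d(e[:, 0], e[:, 1], bins=[edges_d, edges_r])
        counts[k] = h
    n_tot = counts.sum(axis=0)
    occ = n_tot > 0
    if not occ.any():
        raise ValueError("no occupied bins")
    connected = _replicas_connected(counts)
    if not connected:
        warnings.warn(
            "replica histograms do not overlap into a single connected set; "
            "the density of states (and any evidence derived from it) is unreliable"
        )

    cd = 0.5 * (edges_d[:-1] + edges_d[1:])
    cr = 0.5 * (edges_r[:-1] + edges_r[1:])
    e_d = np.broadcast_to(cd[:, None], (nd, nr))[occ]
    e_r = np.broadcast_to(cr[None, :], (nd, nr))[occ]
    log_n = np.log(n_tot[occ])
    N_k = np.array([len(e) for e in traces.energies], dtype=float)
    lam = schedule.lambdas
    w = schedule.weights
    beta = schedule.betas
    # A[k, b] = -lam_k e_d(b) - beta_k w_k e_r(b)
    A = -lam[:, None] * e_d[None, :] - (beta * w)[:, None] * e_r[None, :]

    f = np.zeros(K)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per occupied bin
        log_den = logsumexp(np.log(N_k)[:, None] + f[:, None] + A, axis=0)
        log_g = log_n - log_den
        f_new = -logsumexp(log_g[None, :] + A, axis=1)
        f_new = f_new - f_new[0]
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol * max(1.0, np.max(np.abs(f))):
            converged = True
            break
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations")

    log_den = logsumexp(np.log(N_k)[:, None] + f[:, None] + A, axis=0)
    log_g_occ = log_n - log_den
    log_g = np.full((nd, nr), -np.inf)
    log_g[occ] = log_g_occ
    return DensityOfStates(
        edges_data=edges_d,
        edges_rama=edges_r,
        log_g=log_g,
        f_k=f,
        schedule=schedule,
        converged=converged,
        n_iter=it,
        overlap_connected=connected,
        counts=counts,
    )


def _check_dos(dos: DensityOfStates, force: bool):
    if not (dos.converged or force):
        raise RuntimeError("density of states not converged (pass force=True to override)")


def log_evidence(dos: DensityOfStates, w: float, beta: float = 1.0,
                 force: bool = False) -> float:
    """log Z(w): log(posterior normalizer / prior normalizer).

    The data weight lambda is fixed at 1 in the evidence definition.
    The value is defined up to a single w-independent additive
    constant.
    """
    _check_dos(dos, force)
    log_g, e_d, e_r = dos.flat()
    if log_g.size == 0:
        raise ValueError("no support for evidence at this w")
    post = logsumexp(log_g - e_d - beta * w * e_r)
    prior = logsumexp(log_g - beta * w * e_r)
    return float(post - prior)


def expected_rama_energy(dos: DensityOfStates, w: float, beta: float = 1.0,
                         with_data: bool = True, force: bool = False) -> float:
    """<E_rama> under the reweighted posterior or prior at weight w."""
    _check_dos(dos, force)
    log_g, e_d, e_r = dos.flat()
    log_wts = log_g - beta * w * e_r
    if with_data:
        log_wts = log_wts - e_d
    log_wts = log_wts - logsumexp(log_wts)
    return float(np.exp(log_wts) @ e_r)


@dataclass
class EvidenceCurve:
    """log Z over a weight grid and the selected optimal weight."""

    w_grid: np.ndarray
    log_z: np.ndarray
    e_rama_post: np.ndarray
    e_rama_prior: np.ndarray
    w_star: float
    w_cross: float | None
    at_boundary: bool
    degenerate: bool = False
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "w_grid": self.w_grid.tolist(),
            "log_z": self.log_z.tolist(),
            "e_rama_post": self.e_rama_post.tolist(),
            "e_rama_prior": self.e_rama_prior.tolist(),
            "w_star": float(self.w_star),
            "w_cross": None if self.w_cross is None else float(self.w_cross),
            "at_boundary": bool(self.at_boundary),
            "degenerate": bool(self.degenerate),
            "meta": self.meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceCurve":
        return cls(
            w_grid=np.asarray(d["w_grid"]),
            log_z=np.asarray(d["log_z"]),
            e_rama_post=np.asarray(d["e_rama_post"]),
            e_rama_prior=np.asarray(d["e_rama_prior"]),
            w_star=d["w_star"],
            w_cross=d["w_cross"],
            at_boundary=d["at_boundary"],
            degenerate=d.get("degenerate", False),
            meta=d.get("meta", {}),
        )

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w": self.w_grid,
                "log_z": self.log_z,
                "e_rama_post": self.e_rama_post,
                "e_rama_prior": self.e_rama_prior,
            }
        )


def optimal_weight(
    dos: DensityOfStates,
    w_grid,
    beta: float = 1.0,
    force: bool = False,
) -> EvidenceCurve:
    """Locate the weight maximizing the model evidence.

    Evaluates log Z on the grid, refines the argmax by golden-section
    search between its neighbors, and independently reports the
    crossing point of the posterior and prior mean Ramachandran
    energies (the stationarity condition of the evidence); the two
    agree within grid resolution.  An argmax at the grid boundary is
    flagged (the replica ladder should be extended).  A flat
    Ramachandran energy makes every weight optimal; this degeneracy is
    reported rather than resolved.
    """
    w_grid = np.asarray(w_grid, dtype=float)
    if w_grid.size < 2:
        raise ValueError("w grid must contain at least two points")
    log_z = np.array([log_evidence(dos, w, beta, force) for w in w_grid])
    post = np.array(
        [expected_rama_energy(dos, w, beta, True, force) for w in w_grid]
    )
    prior = np.array(
        [expected_rama_energy(dos, w, beta, False, force) for w in w_grid]
    )

    _, _, e_r = dos.flat()
    degenerate = float(np.ptp(e_r)) < 1e-12 or float(np.ptp(log_z)) < 1e-12
    i = int(np.argmax(log_z))
    at_boundary = i in (0, w_grid.size - 1)
    if degenerate:
        w_star = float(w_grid[i])
        w_cross = None
    elif at_boundary:
        w_star = float(w_grid[i])
        w_cross = w_star
    else:
        try:
            res = minimize_scalar(
                lambda w: -log_evidence(dos, w, beta, force),
                bracket=(w_grid[i - 1], w_grid[i], w_grid[i + 1]),
                method="golden",
                options={"xtol": 1e-7},
            )
        except ValueError:  # not a strict bracket (flat neighbors)
            res = minimize_scalar(
                lambda w: -log_evidence(dos, w, beta, force),
                bounds=(w_grid[i - 1], w_grid[i + 1]),
                method="bounded",
            )
        w_star = float(np.clip(res.x, w_grid[i - 1], w_grid[i + 1]))
        w_cross = _crossing(dos, w_grid, post - prior, i, beta, force)
    return EvidenceCurve(
        w_grid=w_grid,
        log_z=log_z,
        e_rama_post=post,
        e_rama_prior=prior,
        w_star=w_star,
        w_cross=w_cross,
        at_boundary=at_boundary,
        degenerate=degenerate,
    )


def _crossing(dos, w_grid, diff, i_max, beta, force):
    """Root of <E_R>_post - <E_R>_prior nearest the evidence argmax."""

    def gap(w):
        return expected_rama_energy(dos, w, beta, True, force) - expected_rama_energy(
            dos, w, beta, False, force
        )

    sign = np.sign(diff)
    for j in range(len(w_grid) - 1):
        lo = max(0, i_max - 1 - j)
        hi = min(len(w_grid) - 1, i_max + j)
        for a in range(lo, hi):
            if sign[a] == 0:
                return float(w_grid[a])
            if sign[a] * sign[a + 1] < 0:
                return float(brentq(gap, w_grid[a], w_grid[a + 1], xtol=1e-8))
    return None
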