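"""Maximum-entropy Fourier densities for backbone dihedral angles.

The joint distribution of a residue's backbone torsions (phi, psi) is
modelled as a maximum-entropy density on the torus,

    p(phi, psi) = exp(-E(phi, psi)) / Z,

where the Ramachandran potential E is a linear combination of
two-dimensional cosine/sine products

    E(phi, psi) = sum_j  g_j * T1_j(k_j * phi) * T2_j(l_j * psi),

with T1, T2 in {cos, sin} and frequencies k, l below the expansion
order M.  The constant function and products containing sin(0 * x)
(identically zero) are excluded, so the basis for M = 5 has exactly 80
members.  Fitting the coefficients g by maximum likelihood is the
maximum-entropy estimate; a zero-mean Gaussian prior with precision tau
regularizes the fit, and tau itself is updated analytically.

Everything is expressed in radians on the principal interval
[-pi, pi); file interfaces use degrees.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "AngleSample",
    "BasisFunction",
    "MaxEntDensity",
    "PrecisionState",
    "FitResult",
    "enumerate_basis",
    "eval_basis",
    "rama_potential",
    "log_partition",
    "fit_maxent",
    "update_precision",
    "sample_density",
    "wrap_angle",
    "read_angle_table",
    "write_angle_table",
]

TAU_MAX_DEFAULT = 1e6
DEFAULT_GRID_N = 128
BASIS_TAG = "cc-cs-sc-ss/lex(k,l)/v1"

TWO_PI = 2.0 * np.pi


def wrap_angle(angle):
    """Reduce an angle (radians) to the principal interval [-pi, pi)."""
    return np.mod(np.asarray(angle, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass(frozen=True)
class AngleSample:
    """A single (phi, psi) observation for one residue type."""

    phi: float
    psi: float
    residue_type: str = "GENERIC"

    def __post_init__(self):
        if not (np.isfinite(self.phi) and np.isfinite(self.psi)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "phi", float(wrap_angle(self.phi)))
        object.__setattr__(self, "psi", float(wrap_angle(self.psi)))


class BasisFunction(NamedTuple):
    """Descriptor of one basis member: trig kinds and integer frequencies."""

    phi_kind: str  # "cos" or "sin"
    psi_kind: str
    k: int
    l: int


def enumerate_basis(order: int) -> list[BasisFunction]:
    """Enumerate the non-constant 2D Fourier basis for a given order.

    Ordering is deterministic: the four trig-product blocks cos*cos,
    cos*sin, sin*cos, sin*sin in that sequence, each block in
    lexicographic (k, l) order with k, l in {0, ..., order-1}.  The
    constant (cos0*cos0) and every product containing sin(0*x) are
    dropped.  For order 5 this yields 80 functions.
    """
    if not isinstance(order, (int, np.integer)) or order < 1:
        raise ValueError(f"order must be a positive integer, got {order!r}")
    basis: list[BasisFunction] = []
    freqs = range(order)
    for pk, sk in (("cos", "cos"), ("cos", "sin"), ("sin", "cos"), ("sin", "sin")):
        for k in freqs:
            if pk == "sin" and k == 0:
                continue
            for l in freqs:
                if sk == "sin" and l == 0:
                    continue
                if pk == "cos" and sk == "cos" and k == 0 and l == 0:
                    continue  # the constant
                basis.append(BasisFunction(pk, sk, k, l))
    return basis


def _basis_index_arrays(order: int):
    """Integer encodings of the basis for vectorized evaluation."""
    basis = enumerate_basis(order)
    pk = np.array([0 if b.phi_kind == "cos" else 1 for b in basis], dtype=np.int64)
    sk = np.array([0 if b.psi_kind == "cos" else 1 for b in basis], dtype=np.int64)
    k = np.array([b.k for b in basis], dtype=np.int64)
    l = np.array([b.l for b in basis], dtype=np.int64)
    return pk, sk, k, l


def eval_basis(phi, psi, order: int) -> np.ndarray:
    """Evaluate all basis functions at (phi, psi).

    Accepts scalars or broadcasting arrays; returns an array with the
    basis dimension last, aligned with :func:`enumerate_basis`.
    """
    pk, sk, k, l = _basis_index_arrays(order)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    shape = np.broadcast_shapes(phi.shape, psi.shape)
    phi, psi = np.broadcast_to(phi, shape), np.broadcast_to(psi, shape)
    # trig tables: (2, order, *shape) -> index by (kind, freq)
    freqs = np.arange(order)
    ang_phi = freqs.reshape((order,) + (1,) * phi.ndim) * phi  # (order, *shape)
    ang_psi = freqs.reshape((order,) + (1,) * psi.ndim) * psi
    tab_phi = np.stack([np.cos(ang_phi), np.sin(ang_phi)])  # (2, order, *shape)
    tab_psi = np.stack([np.cos(ang_psi), np.sin(ang_psi)])
    vals = tab_phi[pk, k] * tab_psi[sk, l]  # (K, *shape)
    return np.moveaxis(vals, 0, -1)


@dataclass
class MaxEntDensity:
    """A fitted maximum-entropy density on the torus.

    Attributes
    ----------
    order : int
        Number of frequencies per dimension (M).
    coeffs : ndarray
        Expansion coefficients over the non-constant basis.
    log_norm : float
        log of the normalization constant Z, by periodic trapezoidal
        quadrature at resolution ``grid_n``.
    grid_n : int
        Quadrature resolution used for ``log_norm``.
    """

    order: int
    coeffs: np.ndarray
    log_norm: float = field(default=np.nan)
    grid_n: int = DEFAULT_GRID_N
    tau: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        expected = len(enumerate_basis(self.order))
        if self.coeffs.shape != (expected,):
            raise ValueError(
                f"coeffs must have length {expected} for order {self.order}, "
                f"got shape {self.coeffs.shape}"
            )
        if not np.isfinite(self.log_norm):
            self.log_norm = log_partition(self.coeffs, self.order, self.grid_n)

    def potential(self, phi, psi):
        return rama_potential(self, phi, psi)

    def log_pdf(self, phi, psi):
        return -self.potential(phi, psi) - self.log_norm

    def pdf(self, phi, psi):
        return np.exp(self.log_pdf(phi, psi))

    def to_dict(self) -> dict:
        return {
            "order": int(self.order),
            "basis": BASIS_TAG,
            "coeffs": self.coeffs.tolist(),
            "log_norm": float(self.log_norm),
            "grid_n": int(self.grid_n),
            "tau": None if self.tau is None else float(self.tau),
            "provenance": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaxEntDensity":
        if d.get("basis", BASIS_TAG) != BASIS_TAG:
            raise ValueError(f"unknown basis ordering tag {d.get('basis')!r}")
        return cls(
            order=int(d["order"]),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            log_norm=float(d["log_norm"]),
            grid_n=int(d.get("grid_n", DEFAULT_GRID_N)),
            tau=d.get("tau"),
            meta=dict(d.get("provenance", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "MaxEntDensity":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class PrecisionState:
    """Precision of the zero-mean Gaussian prior on the coefficients."""

    tau: float
    tau_max: float = TAU_MAX_DEFAULT
    degenerate: bool = False

    def __post_init__(self):
        if not (self.tau > 0):
            raise ValueError("tau must be positive")
        if self.tau > self.tau_max:
            object.__setattr__(self, "tau", self.tau_max)


def rama_potential(density: MaxEntDensity, phi, psi):
    """Ramachandran potential E(phi, psi) in k_BT units."""
    b = eval_basis(phi, psi, density.order)
    return b @ density.coeffs


def _torus_grid(grid_n: int):
    """Uniform periodic grid on [-pi, pi) (endpoint excluded)."""
    return np.linspace(-np.pi, np.pi, grid_n, endpoint=False)


def log_partition(coeffs, order: int, grid_n: int = DEFAULT_GRID_N) -> float:
    """log of the torus integral of exp(-E) by the 2D trapezoidal rule.

    On a uniform periodic grid the trapezoidal rule reduces to the
    rectangle rule and converges spectrally for smooth integrands.
    """
    if grid_n < 16:
        raise ValueError("grid_n must be at least 16")
    coeffs = np.asarray(coeffs, dtype=float)
    g = _torus_grid(grid_n)
    energy = eval_basis(g[:, None], g[None, :], order) @ coeffs
    if not np.all(np.isfinite(energy)):
        raise FloatingPointError("non-finite Ramachandran energy on quadrature grid")
    m = energy.min()
    return float(np.log(np.exp(-(energy - m)).mean()) - m + np.log(4.0 * np.pi**2))


@dataclass
class FitResult:
    density: MaxEntDensity
    precision: PrecisionState
    converged: bool
    n_cycles: int
    grad_max_norm: float

    def __iter__(self):  # allow ``density, precision = fit_maxent(...)``
        return iter((self.density, self.precision))


def _as_angle_arrays(samples):
    if isinstance(samples, np.ndarray):
        arr = np.asarray(samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("angle array must have shape (n, 2)")
        return wrap_angle(arr[:, 0]), wrap_angle(arr[:, 1])
    phi = np.array([s.phi for s in samples], dtype=float)
    psi = np.array([s.psi for s in samples], dtype=float)
    return phi, psi


def fit_maxent(
    samples,
    order: int,
    precision="auto",
    tol: float = 1e-6,
    grid_n: int = DEFAULT_GRID_N,
    tau_max: float = TAU_MAX_DEFAULT,
    tau_init: float = 10.0,
    max_cycles: int = 50,
) -> FitResult:
    """Fit a maximum-entropy density to (phi, psi) samples.

    Minimizes the per-sample negative log-posterior

        J(g) = log Z(g) + mean_i E(phi_i, psi_i) + tau/(2N) * ||g||^2,

    which is convex in g.  The gradient is analytic (model expectation
    of the basis minus its empirical mean, plus the ridge term), so a
    quasi-Newton minimizer is used.  With ``precision="auto"``,
    coefficient optimization alternates with the analytic precision
    update tau = K/||g||^2 until tau changes by less than 1e-3
    relative, or 50 cycles.

    Parameters
    ----------
    samples : sequence of AngleSample or (n, 2) ndarray of radians
    order : int
        Expansion order M (>= 2 for a non-trivial fit).
    precision : "auto" | float | PrecisionState
    tol : float
        Gradient max-norm target for the inner optimization.
    """
    phi, psi = _as_angle_arrays(samples)
    n = phi.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    basis = enumerate_basis(order)
    K = len(basis)

    grid = _torus_grid(grid_n)
    B_grid = eval_basis(grid[:, None], grid[None, :], order).reshape(-1, K)
    b_mean = eval_basis(phi, psi, order).mean(axis=0)

    def model_expectation(g):
        energy = B_grid @ g
        wts = np.exp(-(energy - energy.min()))
        wts /= wts.sum()
        return wts @ B_grid, energy

    def objective(g, tau):
        energy = B_grid @ g
        m = energy.min()
        logz = np.log(np.exp(-(energy - m)).mean()) - m + np.log(4 * np.pi**2)
        j = logz + b_mean @ g + 0.5 * tau / n * (g @ g)
        wts = np.exp(-(energy - m))
        wts /= wts.sum()
        grad = -(wts @ B_grid) + b_mean + tau / n * g
        return j, grad

    auto = isinstance(precision, str) and precision == "auto"
    if auto:
        tau = float(tau_init)
    elif isinstance(precision, PrecisionState):
        tau = precision.tau
    else:
        tau = float(precision)
        if tau <= 0:
            raise ValueError("precision must be positive")

    g = np.zeros(K)
    converged = False
    prec = PrecisionState(tau, tau_max=tau_max)
    cycles = 0
    for cycles in range(1, (max_cycles if auto else 1) + 1):
        res = minimize(
            objective,
            g,
            args=(tau,),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": tol, "ftol": 1e-14, "maxiter": 2000},
        )
        g = res.x
        if not auto:
            converged = bool(res.success) or float(np.abs(res.jac).max()) < 10 * tol
            break
        prec = update_precision(g, tau_max=tau_max)
        if abs(prec.tau - tau) <= 1e-3 * tau:
            tau = prec.tau
            converged = True
            break
        tau = prec.tau
    _, grad = objective(g, tau)
    gmax = float(np.abs(grad).max())
    if auto:
        converged = converged and gmax < max(10 * tol, 1e-4)
    if not converged:
        warnings.warn(
            f"maxent fit did not fully converge (gradient max-norm {gmax:.2e}); "
            "returning the best iterate"
        )
    prec = prec if auto else PrecisionState(tau, tau_max=tau_max)
    density = MaxEntDensity(
        order=order,
        coeffs=g,
        log_norm=log_partition(g, order, grid_n),
        grid_n=grid_n,
        tau=prec.tau,
        meta={
            "n_samples": int(n),
            "tol": tol,
            "precision_mode": "auto" if auto else "fixed",
            "converged": converged,
            "cycles": cycles,
        },
    )
    return FitResult(density, prec, converged, cycles, gmax)


def update_precision(coeffs, tau_max: float = TAU_MAX_DEFAULT) -> PrecisionState:
    """Analytic type-II maximum-likelihood update of the prior precision.

    For a zero-mean isotropic Gaussian prior over K coefficients the
    evidence-maximizing precision is tau = K / ||g||^2, capped at
    ``tau_max``.  A zero coefficient vector is degenerate and returns
    the cap with a flag.
    """
    g = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("coefficients must be finite")
    ss = float(g @ g)
    if ss == 0.0:
        return PrecisionState(tau_max, tau_max=tau_max, degenerate=True)
    return PrecisionState(min(g.size / ss, tau_max), tau_max=tau_max)


def sample_density(
    density: MaxEntDensity, n: int, seed, grid_n: int = 256
) -> np.ndarray:
    """Draw (phi, psi) samples from the density, reproducibly.

    Grid-based sampler: cell probabilities from the density at cell
    centers, then a uniform jitter within the chosen cell.  Accurate to
    O(h^2) in distribution at resolution ``grid_n``.

    Returns an (n, 2) array of radians in [-pi, pi).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h = TWO_PI / grid_n
    centers = -np.pi + (np.arange(grid_n) + 0.5) * h
    energy = eval_basis(centers[:, None], centers[None, :], density.order) @ density.coeffs
    p = np.exp(-(energy - energy.min())).ravel()
    p /= p.sum()
    idx = rng.choice(p.size, size=n, p=p)
    i, j = np.divmod(idx, grid_n)
    phi = centers[i] + rng.uniform(-0.5 * h, 0.5 * h, size=n)
    psi = centers[j] + rng.uniform(-0.5 * h, 0.5 * h, size=n)
    return np.column_stack([wrap_angle(phi), wrap_angle(psi)])


# ---------------------------------------------------------------------------
# file interfaces (degrees at the boundary, radians inside)

def read_angle_table(path) -> pd.DataFrame:
    """Read a TSV with columns residue_type, phi_deg, psi_deg."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue_type", "phi_deg", "psi_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"angle table missing columns: {sorted(missing)}")
    return df


def write_angle_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def angles_from_table(df: pd.DataFrame, residue_type: str | None = None) -> np.ndarray:
    """Extract an (n, 2) radian array, optionally for one residue type."""
    if residue_type is not None:
        df = df[df["residue_type"] == residue_type]
    return np.column_stack(
        [wrap_angle(np.deg2rad(df["phi_deg"])), wrap_angle(np.deg2rad(df["psi_deg"]))]
    )


def fit_angle_table(df: pd.DataFrame, order: int = 5, **kwargs) -> dict[str, MaxEntDensity]:
    """Fit one density per residue type plus a pooled GENERIC fallback."""
    out: dict[str, MaxEntDensity] = {}
    out["GENERIC"] = fit_maxent(angles_from_table(df), order, **kwargs).density
    for rtype, sub in df.groupby("residue_type"):
        if len(sub) >= 2 and rtype != "GENERIC":
            out[str(rtype)] = fit_maxent(angles_from_table(sub), order, **kwargs).density
    return out
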