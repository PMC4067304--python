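"""Probabilistic models linking conformations to distance data.

Observed inter-bead distances are modelled with a lognormal
likelihood: log d_obs is Gaussian around log(gamma * d_calc) with
error sigma, where gamma is a global calibration scale and d_calc the
plain Euclidean bead distance.  For bounds-only data (solid-state
style restraints) a latent "experimental" distance per restraint is
estimated inside its [lower, upper] interval and plugged into the same
lognormal link; gamma is fixed at 1 in that mode, leaving the error as
the only model parameter.

Nuisance parameters are sampled by Gibbs updates.  The module-level
defaults reproduce the standard reference priors (Jeffreys on sigma^2,
flat on log gamma); the replica-exchange sampler passes
weakly-informative proper priors and a tempering weight so that
likelihood-off replicas remain well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels

__all__ = [
    "DistanceRestraint",
    "RestraintSet",
    "NuisanceParams",
    "neg_log_lognormal",
    "data_energy",
    "gibbs_update_sigma",
    "gibbs_update_gamma",
    "gibbs_update_aux_distances",
    "read_restraint_table",
    "write_restraint_table",
]

EXACT = "exact"
BOUNDS = "bounds"


@dataclass(frozen=True)
class DistanceRestraint:
    """One distance observation (or interval) between two beads."""

    atom_i: int
    atom_j: int
    kind: str = EXACT
    d_obs: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.atom_i == self.atom_j:
            raise ValueError("restraint must link two distinct beads")
        if self.kind == EXACT:
            if self.d_obs is None or self.d_obs <= 0:
                raise ValueError("exact restraint needs d_obs > 0")
        elif self.kind == BOUNDS:
            if self.lower is None or self.upper is None:
                raise ValueError("bounds restraint needs lower and upper")
            if not (0 < self.lower <= self.upper):
                raise ValueError("need 0 < lower <= upper")
        else:
            raise ValueError(f"unknown restraint kind {self.kind!r}")


class RestraintSet:
    """An ordered collection of restraints with array views."""

    def __init__(self, restraints):
        self.restraints = list(restraints)
        self.atom_i = np.array([r.atom_i for r in self.restraints], dtype=np.int64)
        self.atom_j = np.array([r.atom_j for r in self.restraints], dtype=np.int64)
        self.kinds = np.array([r.kind for r in self.restraints])

    def __len__(self):
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    @property
    def is_bounds_mode(self) -> bool:
        return bool(np.any(self.kinds == BOUNDS))

    @property
    def d_obs(self) -> np.ndarray:
        """Observed distances for exact restraints (NaN for bounds)."""
        return np.array(
            [r.d_obs if r.kind == EXACT else np.nan for r in self.restraints]
        )

    @property
    def bounds(self):
        lower = np.array(
            [r.lower if r.kind == BOUNDS else np.nan for r in self.restraints]
        )
        upper = np.array(
            [r.upper if r.kind == BOUNDS else np.nan for r in self.restraints]
        )
        return lower, upper

    def observations(self, nuisance: "NuisanceParams") -> np.ndarray:
        """Effective observed distance per restraint.

        Exact restraints use d_obs; bounds restraints use the current
        auxiliary distance estimate.
        """
        obs = self.d_obs
        mask = self.kinds == BOUNDS
        if mask.any():
            if nuisance.aux_distances is None:
                raise RuntimeError("bounds-mode restraints need aux_distances")
            aux = np.asarray(nuisance.aux_distances, dtype=float)
            if aux.size != int(mask.sum()):
                raise RuntimeError("one aux distance per bounds restraint required")
            obs[mask] = aux
        return obs

    def calc_distances(self, coords) -> np.ndarray:
        coords = np.ascontiguousarray(coords, dtype=float)
        return _kernels.pair_distances_kernel(coords, self.atom_i, self.atom_j)


@dataclass
class NuisanceParams:
    """Scale gamma, lognormal error sigma, and bounds-mode aux distances."""

    gamma: float = 1.0
    sigma: float = 0.3
    aux_distances: np.ndarray | None = None

    def __post_init__(self):
        if self.gamma <= 0 or self.sigma <= 0:
            raise ValueError("gamma and sigma must be positive")
        if self.aux_distances is not None:
            self.aux_distances = np.asarray(self.aux_distances, dtype=float)


def neg_log_lognormal(d_obs, d_calc, gamma: float, sigma: float):
    """Negative log density of the lognormal distance model.

    -log p(d_obs | d_calc, gamma, sigma) =
        log(d_obs * sigma * sqrt(2*pi))
        + (log d_obs - log(gamma * d_calc))^2 / (2 sigma^2)
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if np.any(d_obs <= 0) or np.any(d_calc <= 0) or gamma <= 0 or sigma <= 0:
        raise ValueError("all arguments of the lognormal model must be positive")
    resid = np.log(d_obs) - np.log(gamma * d_calc)
    return np.log(d_obs * sigma * np.sqrt(2 * np.pi)) + 0.5 * resid**2 / sigma**2


def data_energy(coords, restraints: RestraintSet, nuisance: NuisanceParams) -> float:
    """Total negative log-likelihood E_data of the restraint set.

    Pure function of the coordinates and current nuisance parameters;
    bounds-mode terms treat the auxiliary distances as observations.
    """
    if len(restraints) == 0:
        return 0.0
    obs = restraints.observations(nuisance)
    gamma = 1.0 if restraints.is_bounds_mode else nuisance.gamma
    d_calc = restraints.calc_distances(coords)
    return float(np.sum(neg_log_lognormal(obs, d_calc, gamma, nuisance.sigma)))


# ---------------------------------------------------------------------------
# Gibbs updates of the nuisance parameters

def gibbs_update_sigma(
    residuals,
    seed,
    weight: float = 1.0,
    prior_shape: float = 0.0,
    prior_scale: float = 0.0,
) -> float:
    """Draw sigma from its conditional posterior.

    With residuals r_i = log d_obs - log(gamma d_calc), a likelihood
    tempering ``weight`` and an inverse-gamma prior IG(prior_shape,
    prior_scale) on sigma^2, the conditional is
    IG(prior_shape + weight*n/2, prior_scale + weight*sum(r^2)/2).
    Defaults (0, 0) give the Jeffreys prior 1/sigma^2, hence
    IG(n/2, sum(r^2)/2) at weight 1.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 1:
        raise ValueError("need at least one residual")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = prior_shape + 0.5 * weight * r.size
    scale = prior_scale + 0.5 * weight * float(r @ r)
    if shape <= 0 or scale <= 0:
        # degenerate conditional (all residuals zero under a Jeffreys prior)
        warnings.warn("degenerate sigma conditional; using regularized draw")
        shape = max(shape, 1.0)
        scale = max(scale, 1e-6)
    var = scale / rng.gamma(shape)
    return float(np.sqrt(var))


def gibbs_update_gamma(
    d_obs,
    d_calc,
    sigma: float,
    seed,
    weight: float = 1.0,
    prior_log_mean: float = 0.0,
    prior_log_sd: float = np.inf,
) -> float:
    """Draw the distance scale gamma from its conditional posterior.

    log gamma is Gaussian: with a flat prior (prior_log_sd = inf) its
    mean is mean(log d_obs - log d_calc) and its variance
    sigma^2 / (weight * n).  A finite prior_log_sd shrinks towards
    prior_log_mean and keeps the weight-0 case proper.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_obs.size < 1 or d_obs.size != d_calc.size:
        raise ValueError("need matching non-empty d_obs and d_calc")
    if np.any(d_obs <= 0) or np.any(d_calc <= 0) or sigma <= 0:
        raise ValueError("distances and sigma must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    diffs = np.log(d_obs) - np.log(d_calc)
    prec_data = weight * d_obs.size / sigma**2
    prec_prior = 0.0 if np.isinf(prior_log_sd) else prior_log_sd**-2
    prec = prec_data + prec_prior
    if prec <= 0:
        raise ValueError("gamma conditional improper: weight 0 with a flat prior")
    mean = (prec_data * diffs.mean() + prec_prior * prior_log_mean) / prec
    return float(np.exp(mean + rng.normal() / np.sqrt(prec)))


def gibbs_update_aux_distances(
    lower,
    upper,
    d_calc,
    gamma: float,
    sigma: float,
    seed,
    weight: float = 1.0,
) -> np.ndarray:
    """Draw bounds-mode auxiliary distances inside their intervals.

    The conditional of each latent observation d is the lognormal
    likelihood term viewed as a density in d, truncated to
    [lower, upper].  In x = log d the tempered conditional is Gaussian
    with variance sigma^2/weight and mean log(gamma*d_calc) +
    (1-weight)*sigma^2/weight; at weight 0 it degenerates to a uniform
    draw on [lower, upper].  Zero-width intervals return the bound.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if np.any(lower <= 0) or np.any(lower > upper):
        raise ValueError("need 0 < lower <= upper")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(lower.shape)
    degenerate = upper == lower
    out[degenerate] = lower[degenerate]
    free = ~degenerate
    if weight <= 0:
        out[free] = rng.uniform(lower[free], upper[free])
        return out
    mu = np.log(gamma * d_calc[free]) + (1.0 - weight) * sigma**2 / weight
    sd = sigma / np.sqrt(weight)
    a = (np.log(lower[free]) - mu) / sd
    b = (np.log(upper[free]) - mu) / sd
    x = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
    out[free] = np.exp(x)
    return out


# ---------------------------------------------------------------------------
# TSV interface:  i  j  kind  d_obs  lower  upper   (unused fields empty)

def read_restraint_table(path) -> RestraintSet:
    df = pd.read_csv(path, sep="\t")
    required = {"i", "j", "kind"}
    if required - set(df.columns):
        raise ValueError("restraint table needs columns i, j, kind")
    out = []
    for _, row in df.iterrows():
        kind = str(row["kind"])
        out.append(
            DistanceRestraint(
                atom_i=int(row["i"]),
                atom_j=int(row["j"]),
                kind=kind,
                d_obs=_opt(row.get("d_obs")),
                lower=_opt(row.get("lower")),
                upper=_opt(row.get("upper")),
            )
        )
    return RestraintSet(out)


def write_restraint_table(restraints: RestraintSet, path) -> None:
    rows = []
    for r in restraints:
        rows.append(
            {
                "i": r.atom_i,
                "j": r.atom_j,
                "kind": r.kind,
                "d_obs": r.d_obs,
                "lower": r.lower,
                "upper": r.upper,
            }
        )
    pd.DataFrame(rows, columns=["i", "j", "kind", "d_obs", "lower", "upper"]).to_csv(
        path, sep="\t", index=False
    )


def _opt(v):
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)
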