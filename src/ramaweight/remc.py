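"""Combined posterior and replica-exchange Monte Carlo sampler.

The tempered posterior over a state x (torsions + nuisance
parameters) is

    pi(x) ~ exp(-(lambda * E_data + beta * E_ff + beta * w * E_rama)) p(theta)

where lambda weights the experimental data, beta is the inverse
temperature of the force field, and w is the weight of the
knowledge-based Ramachandran potential.  w is treated as an additional
temperature-like parameter: a ladder of replicas spans w from a
maximum (default 5) down to 0 with data fully on, then switches the
data off through a lambda leg, and finally covers the prior (lambda=0)
across the same w grid so that prior averages are represented.

Local moves are wrapped-Gaussian random-walk Metropolis over each free
torsion, followed by Gibbs updates of the nuisance parameters.  Swaps
between neighboring replicas alternate deterministically over
even/odd pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .chain import ChainTopology, Conformation, ForceFieldParams
from .restraints import (
    BOUNDS,
    NuisanceParams,
    RestraintSet,
    gibbs_update_aux_distances,
    gibbs_update_gamma,
    gibbs_update_sigma,
)
from .torus_density import MaxEntDensity, _basis_index_arrays

__all__ = [
    "PosteriorParams",
    "ReplicaSchedule",
    "default_schedule",
    "TraceSet",
    "ToyMoleculeSystem",
    "TorsionState",
    "total_neg_log_posterior",
    "local_sweep",
    "swap_log_ratio",
    "run_remc",
]


@dataclass(frozen=True)
class PosteriorParams:
    """Temperature-like parameters of one replica."""

    beta: float = 1.0
    lam: float = 1.0
    w: float = 0.0

    def __post_init__(self):
        if self.beta < 0 or self.lam < 0 or self.w < 0:
            raise ValueError("beta, lambda and w must be non-negative")


@dataclass
class ReplicaSchedule:
    """Ordered ladder of replica parameters."""

    params: list[PosteriorParams]

    def __post_init__(self):
        if len(self.params) < 1:
            raise ValueError("schedule must contain at least one replica")
        for a, b in zip(self.params, self.params[1:]):
            if a == b:
                raise ValueError("neighboring replicas must differ in a parameter")

    def __len__(self):
        return len(self.params)

    def __iter__(self):
        return iter(self.params)

    def __getitem__(self, i):
        return self.params[i]

    @property
    def lambdas(self):
        return np.array([p.lam for p in self.params])

    @property
    def weights(self):
        return np.array([p.w for p in self.params])

    @property
    def betas(self):
        return np.array([p.beta for p in self.params])

    def to_dict(self):
        return {
            "params": [
                {"beta": p.beta, "lam": p.lam, "w": p.w} for p in self.params
            ]
        }

    @classmethod
    def from_dict(cls, d):
        return cls([PosteriorParams(**p) for p in d["params"]])


def default_schedule(
    w_max: float = 5.0,
    n_w: int = 11,
    bridge_lambdas=(0.7, 0.5, 0.35, 0.25, 0.18, 0.12, 0.08, 0.05, 0.03, 0.015, 0.007, 0.003),
    beta: float = 1.0,
) -> ReplicaSchedule:
    """Three-leg (w, lambda) ladder.

    Leg 1: data on (lambda=1), w descending from w_max to 0.
    Leg 2: at w=0, lambda descending through ``bridge_lambdas`` to 0.
    Leg 3: data off (lambda=0), w ascending back to w_max, so every w
    on the grid has a lambda=0 replica for prior averages.
    """
    w_grid = np.linspace(w_max, 0.0, n_w)
    params = [PosteriorParams(beta, 1.0, w) for w in w_grid]
    params += [PosteriorParams(beta, l, 0.0) for l in bridge_lambdas]
    params += [PosteriorParams(beta, 0.0, w) for w in w_grid[::-1]]
    return ReplicaSchedule(params)


def total_neg_log_posterior(e_data: float, e_rama: float, e_ff: float,
                            params: PosteriorParams) -> float:
    """lambda*E_data + beta*E_ff + beta*w*E_rama.

    Additive constants from the nuisance-parameter priors are not
    included; they are common to all replicas of a run.
    """
    return params.lam * e_data + params.beta * (e_ff + params.w * e_rama)


def swap_log_ratio(energies_a, energies_b, params_a: PosteriorParams,
                   params_b: PosteriorParams) -> float:
    """Log Metropolis ratio for exchanging the states of two replicas.

    With U_p(x) = lam_p*E_data(x) + beta_p*(E_ff(x) + w_p*E_rama(x)),
    the ratio is [U_a(x_a)+U_b(x_b)] - [U_a(x_b)+U_b(x_a)]; acceptance
    is min(1, exp(ratio)).
    """
    ua_a = total_neg_log_posterior(*energies_a, params_a)
    ub_b = total_neg_log_posterior(*energies_b, params_b)
    ua_b = total_neg_log_posterior(*energies_b, params_a)
    ub_a = total_neg_log_posterior(*energies_a, params_b)
    return (ua_a + ub_b) - (ua_b + ub_a)


# ---------------------------------------------------------------------------
# the toy-molecule system


@dataclass
class TorsionState:
    """Sampler state: free torsions plus nuisance parameters."""

    torsions: np.ndarray  # per-atom torsion array (omega entries fixed)
    nuisance: NuisanceParams
    energies: tuple | None = None  # cached (E_data, E_rama, E_ff)

    def copy(self) -> "TorsionState":
        aux = self.nuisance.aux_distances
        return TorsionState(
            self.torsions.copy(),
            NuisanceParams(
                self.nuisance.gamma,
                self.nuisance.sigma,
                None if aux is None else aux.copy(),
            ),
            self.energies,
        )


@dataclass
class SweepStats:
    n_proposed: int
    n_accepted: int

    @property
    def acceptance(self) -> float:
        return self.n_accepted / max(self.n_proposed, 1)


class ToyMoleculeSystem:
    """Bundles topology, force field, restraints and the torsion density.

    Provides the state initialization, the local Metropolis-within-
    Gibbs sweep and energy evaluation used by :func:`run_remc`.

    Nuisance priors: sigma^2 ~ InvGamma(sigma_prior_shape,
    sigma_prior_scale) and log gamma ~ N(0, gamma_prior_sd^2) —
    weakly informative and proper so that data-off (lambda = 0)
    replicas remain well defined.
    """

    def __init__(
        self,
        topology: ChainTopology,
        ff_params: ForceFieldParams,
        restraints: RestraintSet,
        density: MaxEntDensity,
        estimate_gamma: bool = True,
        estimate_sigma: bool = True,
        sigma_prior_shape: float = 2.0,
        sigma_prior_scale: float = 0.02,
        gamma_prior_sd: float = 0.5,
    ):
        self.topology = topology
        self.ff = ff_params
        self.restraints = restraints
        self.density = density
        self.estimate_gamma = estimate_gamma and not restraints.is_bounds_mode
        self.estimate_sigma = estimate_sigma
        self.sigma_prior = (sigma_prior_shape, sigma_prior_scale)
        self.gamma_prior_sd = gamma_prior_sd

        self._bond_r, self._bond_theta = topology.internal_geometry()
        self._free_idx = topology.free_torsion_atoms()
        self._phi_atoms, self._psi_atoms = topology.interior_residue_torsion_atoms()
        self._pk, self._sk, self._kf, self._lf = _basis_index_arrays(density.order)
        self._coeffs = np.asarray(density.coeffs, dtype=float)
        self._bounds_mask = restraints.kinds == BOUNDS
        lower, upper = restraints.bounds
        self._lower = lower[self._bounds_mask]
        self._upper = upper[self._bounds_mask]

    # -- state handling -----------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> TorsionState:
        tor = np.zeros(self.topology.n_atoms)
        from .chain import ATOMS_PER_RESIDUE, OMEGA

        for i in range(3, self.topology.n_atoms):
            tor[i] = OMEGA if i % ATOMS_PER_RESIDUE == 1 else rng.uniform(-np.pi, np.pi)
        aux = None
        if self.restraints.is_bounds_mode:
            aux = rng.uniform(self._lower, self._upper)
        state = TorsionState(tor, NuisanceParams(1.0, 0.3, aux))
        state.energies = self.energies(state)
        return state

    def _obs_vector(self, state: TorsionState) -> np.ndarray:
        return self.restraints.observations(state.nuisance)

    def energies(self, state: TorsionState):
        """(E_data, E_rama, E_ff) of a state."""
        coords = _kernels.place_chain_kernel(
            self._bond_r, self._bond_theta, state.torsions
        )
        e_ff = _kernels.lj_energy_kernel(
            coords, self.ff.epsilon, self.ff.sigma, self.ff.min_separation, self.ff.r_cut
        )
        e_rama = _kernels.rama_energy_kernel(
            state.torsions, self._phi_atoms, self._psi_atoms,
            self._pk, self._sk, self._kf, self._lf, self._coeffs,
        )
        if len(self.restraints) == 0:
            e_data = 0.0
        else:
            gamma = 1.0 if self.restraints.is_bounds_mode else state.nuisance.gamma
            e_data = _kernels.data_energy_kernel(
                coords, self.restraints.atom_i, self.restraints.atom_j,
                self._obs_vector(state), gamma, state.nuisance.sigma,
            )
        return float(e_data), float(e_rama), float(e_ff)

    def conformation(self, state: TorsionState) -> Conformation:
        n = self.topology.n_residues
        x = state.torsions[self._free_idx]
        return Conformation.from_free_vector(x, n)

    # -- MCMC kernel --------------------------------------------------------

    def sweep(
        self,
        state: TorsionState,
        params: PosteriorParams,
        step: float,
        rng: np.random.Generator,
    ) -> SweepStats:
        """One Metropolis pass over the torsions + nuisance Gibbs updates.

        Mutates ``state`` in place and refreshes its cached energies.
        """
        n_free = self._free_idx.size
        normals = rng.standard_normal(n_free)
        uniforms = rng.random(n_free)
        gamma = 1.0 if self.restraints.is_bounds_mode else state.nuisance.gamma
        obs = (
            self._obs_vector(state)
            if len(self.restraints)
            else np.empty(0, dtype=float)
        )
        e_data, e_rama, e_ff, n_acc = _kernels.torsion_sweep_kernel(
            state.torsions, self._free_idx, self._bond_r, self._bond_theta,
            self.ff.epsilon, self.ff.sigma, self.ff.min_separation, self.ff.r_cut,
            self._phi_atoms, self._psi_atoms,
            self._pk, self._sk, self._kf, self._lf, self._coeffs,
            self.restraints.atom_i, self.restraints.atom_j, obs,
            gamma, state.nuisance.sigma,
            params.lam, params.beta, params.w, step, normals, uniforms,
        )
        if len(self.restraints):
            e_data = self._gibbs_nuisance(state, params, rng)
        state.energies = (float(e_data), float(e_rama), float(e_ff))
        return SweepStats(n_free, int(n_acc))

    def _gibbs_nuisance(self, state, params, rng) -> float:
        coords = _kernels.place_chain_kernel(
            self._bond_r, self._bond_theta, state.torsions
        )
        d_calc = self.restraints.calc_distances(coords)
        nz = state.nuisance
        a0, b0 = self.sigma_prior
        gamma = 1.0 if self.restraints.is_bounds_mode else nz.gamma
        if self.restraints.is_bounds_mode and self._bounds_mask.any():
            aux = gibbs_update_aux_distances(
                self._lower, self._upper, d_calc[self._bounds_mask],
                gamma, nz.sigma, rng, weight=params.lam,
            )
            nz.aux_distances = aux
        obs = self._obs_vector(state)
        if self.estimate_gamma:
            nz.gamma = gibbs_update_gamma(
                obs, d_calc, nz.sigma, rng, weight=params.lam,
                prior_log_mean=0.0, prior_log_sd=self.gamma_prior_sd,
            )
            gamma = nz.gamma
        if self.estimate_sigma:
            resid = np.log(obs) - np.log(gamma * d_calc)
            nz.sigma = gibbs_update_sigma(
                resid, rng, weight=params.lam, prior_shape=a0, prior_scale=b0
            )
        return _kernels.data_energy_kernel(
            coords, self.restraints.atom_i, self.restraints.atom_j,
            obs, gamma, nz.sigma,
        )


def local_sweep(system, state, params: PosteriorParams, step: float, rng) -> SweepStats:
    """One local sweep of ``system`` at ``params`` (delegates to the system)."""
    if step < 0:
        raise ValueError("step size must be >= 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return system.sweep(state, params, step, rng)


# ---------------------------------------------------------------------------
# the replica-exchange driver


@dataclass
class TraceSet:
    """Recorded per-replica energy traces of one REMC run."""

    energies: list  # per replica: (n_records, 3) array of (E_data, E_rama, E_ff)
    sweep_index: np.ndarray  # sweep number of each record
    schedule: ReplicaSchedule
    seed: int
    thinning: int
    swap_attempts: np.ndarray  # per neighbor pair
    swap_accepts: np.ndarray
    steps: np.ndarray  # frozen per-replica step sizes
    audit: list = field(default_factory=list)  # (replica, sweep, state) tuples

    @property
    def n_replicas(self) -> int:
        return len(self.energies)

    def swap_acceptance(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.swap_accepts / np.maximum(self.swap_attempts, 1)

    def save(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for k, e in enumerate(self.energies):
            df = pd.DataFrame(e, columns=["E_data", "E_rama", "E_ff"])
            df.insert(0, "sweep", self.sweep_index)
            df.to_csv(d / f"replica_{k:03d}.tsv", sep="\t", index=False)
        manifest = {
            "schedule": self.schedule.to_dict(),
            "seed": int(self.seed),
            "thinning": int(self.thinning),
            "swap_attempts": self.swap_attempts.tolist(),
            "swap_accepts": self.swap_accepts.tolist(),
            "steps": self.steps.tolist(),
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "TraceSet":
        import pathlib

        d = pathlib.Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        schedule = ReplicaSchedule.from_dict(manifest["schedule"])
        energies = []
        sweep_index = None
        for k in range(len(schedule)):
            df = pd.read_csv(d / f"replica_{k:03d}.tsv", sep="\t")
            sweep_index = df["sweep"].to_numpy()
            energies.append(df[["E_data", "E_rama", "E_ff"]].to_numpy())
        return cls(
            energies=energies,
            sweep_index=sweep_index,
            schedule=schedule,
            seed=manifest["seed"],
            thinning=manifest["thinning"],
            swap_attempts=np.asarray(manifest["swap_attempts"]),
            swap_accepts=np.asarray(manifest["swap_accepts"]),
            steps=np.asarray(manifest["steps"]),
        )


def run_remc(
    system,
    schedule: ReplicaSchedule,
    n_sweeps: int,
    seed,
    swap_interval: int = 5,
    burn_in: int = 0,
    thinning: int = 1,
    step_init: float = 0.5,
    tune_steps: bool = True,
    tune_interval: int = 50,
    audit_interval: int = 0,
    abort_after_nonfinite: int = 100,
) -> TraceSet:
    """Replica-exchange Monte Carlo over the given parameter ladder.

    Each sweep runs one local pass per replica; every ``swap_interval``
    sweeps, neighbor swaps are attempted on alternating even/odd
    pairs.  Step sizes are tuned towards 20-50% acceptance during
    burn-in only, then frozen (tuning during sampling would violate
    detailed balance).  Energies are recorded after burn-in at the
    given thinning; ``audit_interval`` > 0 additionally stores full
    state copies for audits.  Deterministic given the seed.
    """
    if n_sweeps <= burn_in:
        raise ValueError("n_sweeps must exceed burn_in")
    rng = np.random.default_rng(seed)
    K = len(schedule)
    states = [system.init_state(rng) for _ in range(K)]
    steps = np.full(K, float(step_init))
    acc_counts = np.zeros(K)
    prop_counts = np.zeros(K)
    nonfinite_run = np.zeros(K, dtype=int)
    n_pairs = max(K - 1, 0)
    swap_attempts = np.zeros(n_pairs, dtype=np.int64)
    swap_accepts = np.zeros(n_pairs, dtype=np.int64)
    records = [[] for _ in range(K)]
    sweep_index = []
    audit = []
    swap_round = 0

    for sweep in range(n_sweeps):
        for k in range(K):
            stats = system.sweep(states[k], schedule[k], steps[k], rng)
            acc_counts[k] += stats.n_accepted
            prop_counts[k] += stats.n_proposed
            e = states[k].energies
            if not all(np.isfinite(v) for v in e):
                nonfinite_run[k] += 1
                if nonfinite_run[k] >= abort_after_nonfinite:
                    raise RuntimeError(
                        f"replica {k} (lam={schedule[k].lam}, w={schedule[k].w}) "
                        f"has persistent non-finite energy"
                    )
            else:
                nonfinite_run[k] = 0

        if tune_steps and sweep < burn_in and (sweep + 1) % tune_interval == 0:
            for k in range(K):
                if prop_counts[k] == 0:
                    continue
                rate = acc_counts[k] / prop_counts[k]
                if rate < 0.2:
                    steps[k] *= 0.7
                elif rate > 0.5:
                    steps[k] *= 1.4
            acc_counts[:] = 0.0
            prop_counts[:] = 0.0

        if n_pairs and (sweep + 1) % swap_interval == 0:
            start = swap_round % 2
            swap_round += 1
            for k in range(start, n_pairs, 2):
                swap_attempts[k] += 1
                ratio = swap_log_ratio(
                    states[k].energies, states[k + 1].energies,
                    schedule[k], schedule[k + 1],
                )
                if np.log(rng.random()) < ratio:
                    states[k], states[k + 1] = states[k + 1], states[k]
                    swap_accepts[k] += 1

        if sweep >= burn_in and (sweep - burn_in) % thinning == 0:
            sweep_index.append(sweep)
            for k in range(K):
                records[k].append(states[k].energies)
            if audit_interval and len(sweep_index) % audit_interval == 0:
                for k in range(K):
                    audit.append((k, sweep, states[k].copy()))

    return TraceSet(
        energies=[np.asarray(r, dtype=float) for r in records],
        sweep_index=np.asarray(sweep_index, dtype=np.int64),
        schedule=schedule,
        seed=seed if isinstance(seed, (int, np.integer)) else -1,
        thinning=thinning,
        swap_attempts=swap_attempts,
        swap_accepts=swap_accepts,
        steps=steps,
        audit=audit,
    )
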