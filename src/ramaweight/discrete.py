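"""A small enumerable system for validating the sampler and WHAM.

Each state is an integer with fixed energies (E_data, E_rama, E_ff).
Because the state space is tiny, the stationary distribution of any
replica and the exact evidence curve can be computed by direct
summation, which makes this system the standard correctness check for
the replica-exchange sampler and the density-of-states estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .remc import PosteriorParams, SweepStats

__all__ = ["DiscreteState", "DiscreteSystem"]


@dataclass
class DiscreteState:
    index: int
    energies: tuple | None = None

    def copy(self) -> "DiscreteState":
        return DiscreteState(self.index, self.energies)


class DiscreteSystem:
    """Finite state space with fixed per-state energy triples."""

    def __init__(self, e_data, e_rama, e_ff=None):
        self.e_data = np.asarray(e_data, dtype=float)
        self.e_rama = np.asarray(e_rama, dtype=float)
        self.e_ff = (
            np.zeros_like(self.e_data) if e_ff is None else np.asarray(e_ff, dtype=float)
        )
        if not (self.e_data.shape == self.e_rama.shape == self.e_ff.shape):
            raise ValueError("energy vectors must have equal length")
        self.n_states = self.e_data.size

    def energy_triple(self, index: int):
        return (
            float(self.e_data[index]),
            float(self.e_rama[index]),
            float(self.e_ff[index]),
        )

    def init_state(self, rng: np.random.Generator) -> DiscreteState:
        i = int(rng.integers(self.n_states))
        return DiscreteState(i, self.energy_triple(i))

    def energies(self, state: DiscreteState):
        return self.energy_triple(state.index)

    def total_energy(self, index: int, params: PosteriorParams) -> float:
        return params.lam * self.e_data[index] + params.beta * (
            self.e_ff[index] + params.w * self.e_rama[index]
        )

    def sweep(
        self,
        state: DiscreteState,
        params: PosteriorParams,
        step: float,
        rng: np.random.Generator,
    ) -> SweepStats:
        """One Metropolis proposal from the uniform distribution over states.

        The ``step`` argument is ignored (kept for interface parity
        with the continuous system).
        """
        prop = int(rng.integers(self.n_states))
        delta = self.total_energy(prop, params) - self.total_energy(state.index, params)
        accepted = np.log(rng.random()) < -delta
        if accepted:
            state.index = prop
        state.energies = self.energy_triple(state.index)
        return SweepStats(1, int(accepted))
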