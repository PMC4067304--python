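"""Shared test utilities: trace slicing and block-error estimation."""

import numpy as np

from ramaweight import TraceSet, estimate_dos


def slice_traces(traces: TraceSet, lo: int, hi: int) -> TraceSet:
    return TraceSet(
        energies=[e[lo:hi] for e in traces.energies],
        sweep_index=traces.sweep_index[lo:hi],
        schedule=traces.schedule,
        seed=traces.seed,
        thinning=traces.thinning,
        swap_attempts=traces.swap_attempts,
        swap_accepts=traces.swap_accepts,
        steps=traces.steps,
    )


def block_dos_estimates(traces: TraceSet, bins, n_blocks: int = 10):
    """Independent DOS estimates from consecutive trace blocks.

    The spread of any reweighted quantity over the blocks gives its
    Monte Carlo standard error (divided by sqrt(n_blocks) for the
    full-trace estimate).
    """
    n = min(len(e) for e in traces.energies)
    size = n // n_blocks
    out = []
    for b in range(n_blocks):
        sub = slice_traces(traces, b * size, (b + 1) * size)
        out.append(estimate_dos(sub, bins=bins))
    return out


def block_se(values, n_blocks: int):
    """SE of the full-sample estimate from per-block values."""
    return np.std(values, ddof=1) / np.sqrt(n_blocks)


def lattice_edges(values, spacing=0.5):
    """Uniform bin edges whose centers coincide with lattice values."""
    lo = np.min(values) - spacing / 2
    hi = np.max(values) + spacing
    return np.arange(lo, hi, spacing)


def aligned_edges(values, spacing=0.5):
    """Bins centered exactly on the (lattice) energy values of the toy.

    WHAM uses bin centers as energy representatives; for discrete
    systems the edges must therefore be chosen so that each distinct
    value is a center, or the estimate acquires a discretization bias.
    """
    return lattice_edges(values, spacing)
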