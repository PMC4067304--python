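# Methods

This note records the models, priors, numerical choices and study
conditions implemented in `ramaweight`, and what the synthetic
experiments do and do not demonstrate.

## Maximum-entropy torsion densities

A residue's backbone torsion pair (φ, ψ) is modelled on the torus as
p(φ,ψ) = exp(−E(φ,ψ))/Z with E = Σ_j g_j B_j, where {B_j} are all
products T₁(kφ)·T₂(lψ), T ∈ {cos, sin}, k, l < M.  Products containing
sin(0·x) vanish identically and the constant is excluded; at the
default order M = 5 this leaves exactly 80 functions.  The basis
ordering is fixed (cc, cs, sc, ss blocks, lexicographic (k, l)) and
recorded in density files.

Fitting minimizes the convex objective

    J(g) = log Z(g) + (1/N) Σ_i E(φ_i, ψ_i) + (τ/2N) ‖g‖²,

i.e. the negative log-posterior under a zero-mean isotropic Gaussian
prior with precision τ on the coefficients.  The gradient is analytic
(model expectation of the basis minus its empirical mean plus the
ridge term), so L-BFGS is used; the contract is the stated
gradient-norm postcondition, not a particular minimizer.  Z is
evaluated by the two-dimensional trapezoidal rule on a uniform
periodic 128² grid (the periodic trapezoid converges spectrally;
doubling the grid changes log Z by < 1e−6 for the densities used
here).  With `precision="auto"`, coefficient optimization alternates
with the analytic type-II maximum-likelihood update τ = K/‖g‖²
(K = number of coefficients, capped at 1e6) until τ changes by less
than 1e−3 relative or 50 cycles.  The prior precision multiplies the
*total* penalty ‖g‖²/2 — it does not grow with the sample size — which
is what makes the τ = K/‖g‖² update a stable fixed point: for
structured data the penalty becomes negligible at large N, while for
featureless data τ escalates to the cap and the fit shrinks to the
uniform density.

Sampling from a density is grid-based (cell probabilities at 256²
cell centers, uniform jitter within the chosen cell), reproducible
given a seed, and accurate to O(h²) in distribution.

## The toy molecule

The molecular system is a linear chain of n residues with three
backbone beads (N, CA, C) per residue, fixed bond lengths
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å) and fixed bond angles
(111.0°, 116.2°, 121.7°); the peptide torsion ω is fixed trans.  The
free variables are ψ₀, (φ, ψ) of the interior residues, and φ_{n−1};
φ of the first and ψ of the last residue are undefined.  Coordinates
are built by standard internal-coordinate chain extension, and the
builder and the four-atom dihedral measurement are exact inverses.

E_ff is a plain 12-6 Lennard-Jones energy, ε = 0.3 k_BT, σ = 2.5 Å,
over bead pairs at least 3 bonds apart, untruncated by default.
These values put the 1-4 bead distances (2.5–3.8 Å depending on
torsion) in the repulsive-to-minimum region, so the force field
genuinely prefers some torsion combinations — the weighting problem is
non-trivial — without freezing the chain.

The Ramachandran term of a conformation sums the fitted potential
over the interior residues (those with both torsions defined); a
single shared density is used for all residues of the toy chain.

### Why the canonical toy density is centro-symmetric

The example density (`make_toy_density`) is fitted to a two-basin
mixture — helix-like (−63°, −43°) and extended (−120°, 135°), wrapped
Gaussian spreads of 18° and 30° — together with the mirror image of
every sample, making E(φ,ψ) = E(−φ,−ψ) exact up to fit tolerance.
This mirrors the physics of the model system: the coarse-grained
chain carries no side-chain beads, so it is achiral — its mirror
conformation (all torsions negated) has identical pair distances and
identical E_ff, exactly as glycine's Ramachandran statistics are
centro-symmetric because glycine is achiral.  With a chiral density
the distance data could not distinguish the two mirror modes while
their backbone energies differed, and the inferred weight would
depend on which mode a replica happened to occupy.

## Distance likelihood and nuisance parameters

Observed distances follow the lognormal model: log d_obs is Gaussian
with mean log(γ·d_calc) and standard deviation σ, where d_calc is the
Euclidean bead distance of the single current conformation (no r⁻⁶
ensemble averaging — one conformation per state).  For bounds-only
restraints a latent observation per restraint is sampled inside its
[lower, upper] interval from the truncated lognormal conditional and
used as d_obs; γ is fixed at 1 in bounds mode, leaving σ as the only
model parameter.

Gibbs updates (all seeded):

- σ² | rest ~ InvGamma(a₀ + λn/2, b₀ + λΣr²/2), r the log-residuals
  and λ the likelihood tempering weight.
- log γ | rest ~ Normal with precision 1/s₀² + λn/σ² shrinking the
  mean of (log d_obs − log d_calc) towards 0.
- latent bounds observations: truncated Gaussian in log-distance with
  variance σ²/λ (uniform on the interval at λ = 0).

At the module level the defaults are the standard reference priors
(a₀ = b₀ = 0, i.e. Jeffreys on σ²; s₀ = ∞, flat on log γ).  Inside
the replica-exchange sampler weakly-informative proper priors are
used instead — a₀ = 2, b₀ = 0.02 (σ around 0.1, broad) and s₀ = 0.5 —
because data-off (λ = 0) replicas would otherwise have improper
conditionals.  The prior factors are common to all replicas and drop
out of every evidence difference.

## Replica-exchange sampling

The tempered target of a replica is
exp(−(λE_data + βE_ff + βwE_rama))·p(θ), β fixed at 1.  A sweep is
one wrapped-Gaussian random-walk Metropolis pass over the free
torsions followed by the nuisance Gibbs updates.  Step sizes are
tuned towards 20–50 % acceptance during burn-in only, then frozen
(tuning during sampling would break detailed balance).  Neighbor
swaps use the standard two-replica Metropolis ratio and alternate
deterministically over even/odd pairs every few sweeps.

The default ladder has three legs: λ = 1 with w descending 5 → 0 over
11 values; a λ-bridge at w = 0 through
{0.7, 0.5, 0.35, 0.25, 0.18, 0.12, 0.08, 0.05, 0.03, 0.015, 0.007, 0.003};
and λ = 0 with w ascending 0 → 5, so every w on the grid has a
data-off replica and prior averages are directly represented.  The
bridge is geometric because the scale of E_data between neighboring
λ replicas grows roughly like 1/λ.  (A three-parameter ladder that
also tempers β is expressible through the schedule type but is not
the default.)

A six-state discrete system with fixed (E_data, E_rama, E_ff) triples
serves as the enumerable correctness oracle for the sampler and for
everything downstream.

## Density of states and evidence

The replica traces of (E_data, E_rama) are combined by
multiple-histogram reweighting into a binned density of states g
whose base measure absorbs exp(−βE_ff); the fixed-point equations

    g(b) = Σ_k n_k(b) / Σ_k N_k exp(f_k − λ_k e_d(b) − β w_k e_r(b))
    f_k  = −log Σ_b g(b) exp(−λ_k e_d(b) − β w_k e_r(b))

are iterated in log space (initialization f = 0, tolerance 1e−8 on
the gauge-fixed f, at most 10⁴ iterations).  Bin representatives are
bin centers; empty bins carry zero mass, no smoothing.  Default
binning is 64×64 equal-width over the observed ranges ±1 %.  For
discrete systems the tests pass explicit lattice-centered edges:
with arbitrary edges the center-as-representative convention incurs a
discretization bias that the six-state oracle comparison would
misattribute to the estimator.  Disconnected replica histograms (no
path of shared occupied bins) are detected and flagged; the evidence
is then labelled unreliable rather than silently wrong.

The evidence at data weight 1 is a two-dimensional sum,

    log Z(w) = log Σ_b g(b) e^{−e_d(b) − βw e_r(b)}
             − log Σ_b g(b) e^{−βw e_r(b)},

defined up to a w-independent constant.  Its derivative equals
−β(⟨E_rama⟩_post − ⟨E_rama⟩_prior) identically on the binned
representation, so the finite-difference identity test is exact up to
step error.  The optimal weight is the grid argmax refined by
golden-section search between its neighbors; the crossing of the two
mean-energy curves is located independently by root bracketing and
must agree within grid resolution.  An argmax at the grid boundary is
flagged (the ladder should be extended); a flat E_rama makes every
weight optimal and is reported as degenerate.  Nuisance parameters
are marginalized by construction: the recorded E_data already
reflects the Gibbs-sampled θ.

## Synthetic experiments and study conditions

`generate_reference` draws torsions residue-wise from the density
tempered to a chosen weight w₀, then equilibrates them with Metropolis
sweeps under the full prior exp(−(E_ff + w₀E_rama)) (300 sweeps by
default), so the reference is a draw from the model at that weight —
including the correlation between force field and backbone potential
that motivates weighting in the first place.  Remaining clashes (any
included pair below 0.7σ) are removed by greedy relaxation under E_ff;
the antimode variant instead places all torsions at the density's
energy maximum (plus 0.05 rad of jitter) and skips prior
equilibration.

`generate_restraints` takes all bead pairs at ≥ 3 bonds separation
with reference distance below an 8 Å cutoff, draws
d_obs = γ·d_ref·exp(σz) with γ = 1 and σ = 0.1 (10 % lognormal noise,
solution-NMR-like), and retains each candidate independently with
probability f (the completeness parameter).  Bounds mode emits
±width/2 intervals around d_obs, clipped positive.

Default experiment scale: 8 residues (24 beads, 14 free torsions,
~200 candidate restraints), 34 replicas, 3000 sweeps with 1000
burn-in and thinning 2, evidence on a 26-point w grid over [0, 5].
The sparse-data series uses 6 residues with 2500 sweeps and data
generated at w₀ = 2: abundant data that genuinely comply with the
backbone statistics can support a high weight, and the question is
whether sparser data stop supporting it.  One experiment takes tens
of seconds on a single CPU; the chain builder, energies and Metropolis
sweep are numba-compiled.

## What the toy experiments show — and what they do not

The recovery experiment (restraints generated at w₀ = 2, ten seeds)
checks that the evidence machinery is calibrated: the selected w*
scatters around w₀ (roughly ±1 at this data volume) and its seed
interval brackets it.  The antimode experiment checks the opposite
limit: data that contradict the density force w* to the boundary at
0.  The sparsification series reproduces the qualitative sparse-data
behavior — flattening evidence and non-increasing median w* as f
drops through {1.0, 0.5, 0.25}.

None of this involves real proteins: there are no side chains, no
hydrogen bonds, no per-residue densities trained on structure
databases, and distance data on an achiral chain cannot break mirror
symmetry.  Passing tests demonstrate the correctness and internal
calibration of the estimator on a system where ground truth is
computable, not the field accuracy of any particular weight.

## Known limitations

- Single weight only: one statistical energy term is weighted;
  multi-term weighting would require a higher-dimensional density of
  states.
- The data weight λ is fixed at 1 in the evidence; λ enters only
  through the replica ladder.
- WHAM bin centers bias the evidence slightly when E_data spans a
  wide range; the bias is nearly w-independent and cancels in the
  argmax, but absolute log Z values carry it.
- At very low completeness the evidence becomes nearly flat and the
  selected weight is noise-dominated (boundary hits at 0 or w_max);
  the boundary flag marks these runs.
- Step-size tuning is frozen after burn-in; very sharp posteriors
  (hundreds of tight restraints) mix slowly in the data-on leg and
  rely on replica exchange for equilibration.
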