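# ramaweight

Bayesian weighting of a knowledge-based backbone dihedral-angle
("Ramachandran") potential against a physical force field and
experimental distance data.

## The problem

Structure determination from NMR distance data combines a likelihood
for the measurements with a conformational prior.  The prior is
usually a Boltzmann distribution of a physical force field E_ff, but
much of what we know about protein backbones lives in database
statistics: the joint density p(φ, ψ) of the backbone torsions.
Turning that density into a potential E_rama = −log p and adding it to
the prior raises an awkward question: **how strongly should the
statistical term be weighted?**  Too small and it does nothing; too
large and it double-counts structure already captured by the force
field and forces everything helical.

`ramaweight` implements a Bayesian answer.  The prior is extended to

    p(x | w) ∝ exp(−β (E_ff(x) + w · E_rama(x))),

and the weight w is selected by maximizing the model evidence

    Z(w) = ∫ p(D | x, θ) p(x | w) p(θ) dx dθ,

the probability of the data D under the prior defined by w.  The
derivative of log Z(w) is −β(⟨E_rama⟩_posterior − ⟨E_rama⟩_prior), so at
the optimum the mean backbone energy with and without the data cross —
the data neither improve nor worsen the backbone statistics.

The machinery:

- **Torsion density estimation** (`torus_density`): maximum-entropy
  densities on the torus, p(φ,ψ) ∝ exp(−Σ_j g_j B_j(φ,ψ)) over the
  2-D Fourier basis of cosine/sine products with frequencies below an
  order M (80 non-constant functions at M = 5), fitted by convex
  maximum likelihood with an automatically estimated Gaussian prior
  precision on the coefficients.
- **A desk-scale molecule** (`chain`): a coarse-grained chain, three
  backbone beads per residue with fixed bond geometry; free variables
  are the (φ, ψ) torsions; E_ff is a 12-6 Lennard-Jones energy.
- **Distance likelihood** (`restraints`): lognormal model with scale γ
  and error σ sampled by Gibbs updates; an interval-bound variant
  estimates latent observed distances inside [lower, upper] bounds.
- **Replica-exchange MC** (`remc`): the Ramachandran weight w is
  treated as an additional temperature-like parameter; a ladder of
  replicas spans w (data on), bridges the data weight λ from 1 to 0,
  and covers the prior at every w.
- **Evidence estimation** (`wham`): multiple-histogram reweighting
  combines the replica traces into a 2-D density of states over
  (E_data, E_rama), from which log Z(w), the posterior/prior mean
  backbone energies, and the optimal weight w* follow.
- **Synthetic experiments** (`experiments`): generators for reference
  conformations and noisy restraints (with a completeness parameter f
  for sparse-data studies) and an end-to-end driver.

## Worked example

```sh
python examples/04_estimate_weight.py
```

generates an 8-residue reference conformation from the prior at weight
w₀ = 2, synthesizes noisy distance restraints from its contact pairs,
samples a 34-replica (w, λ) ladder, and selects the weight by evidence
maximization.  Output:

```
restraints used        : 135
optimal weight w*      : 2.468
energy-crossing weight : 2.468
argmax at grid edge    : False
log Z span over grid   : 2.14
artifacts in weight_run/
```

The selected weight lands near the generating value 2 (seed-to-seed
scatter is roughly ±1), and the independent crossing construction
(where ⟨E_rama⟩ with data equals ⟨E_rama⟩ without) agrees with the
evidence argmax.  Data generated to *contradict* the density — torsions
at its antimode — drive w* to 0 instead.  The other examples cover
density fitting, chain kinematics, the sampler, and the sparse-data
trend; a thin CLI (`ramaweight --help`) wraps the same functions.

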