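# poissnap

Inference of birth–death–diffusion dynamics from single-instant "snapshot"
observations of particle positions — the data produced by smFISH-style
imaging of subcellular RNA, where individual molecules are resolved in fixed
cells and every cell has its own geometry.

## The problem

In each cell, particles (e.g. nuclear mRNA) are produced at a gene site
`z ∈ (0, L)` at rate `λ`, diffuse, degrade at rate `μ`, and leave instantly
at the domain ends (absorbing boundaries).  Fixation destroys the dynamics:
the data are the positions of the particles alive at one instant, in each of
`M` heterogeneous cells.  Rates are nondimensionalized by `L0²/D`
(reference length squared over diffusivity) — only these combinations are
identifiable from clockless snapshots.

The statistical core is that the snapshot positions form a spatial Poisson
point process whose intensity `u` solves

```
0 = u''(x) + λ δ(x − z) − μ u(x),   u(0) = u(L) = 0,
```

with the closed-form solution (`s = √μ`)

```
u(x) = (λ/s) · sinh(s·min(x,z)) · sinh(s·(L − max(x,z))) / sinh(s·L),
E[N] = (λ/μ) · [1 − sech(s L/2) · cosh(s (L − 2z)/2)].
```

This gives an exact likelihood
`ℓ(λ, μ) = Σᵢ log u(xᵢ) − E[N]` per cell, a 2×2 Fisher information
`I_ij = ∫ ∂ᵢu ∂ⱼu / u dx` for D-optimal experiment design, and a conjugate
Gibbs-in-Metropolis posterior sampler (Gamma prior on `λ` is conjugate given
`μ`).  Joint uncertainty is summarized by the area of the 89% highest-density
posterior region (convex hull of the top-density posterior samples).

The package provides:

* `poissnap.model` — closed-form intensity, expected counts, analytic
  derivatives, nondimensionalization, and a finite-difference BVP solver as
  an independent oracle;
* `poissnap.simulate` — trajectory-level simulation (Euler–Maruyama with
  Brownian-bridge absorption; validates the point-process theorem) and fast
  direct Poisson sampling;
* `poissnap.likelihood` / `poissnap.information` — exact and binned
  likelihoods, Fisher information (closed-form, quadrature, and
  heterogeneity-averaged), binning information loss;
* `poissnap.bayes` — the sampler and HDPR summaries;
* `poissnap.heterogeneity` — Beta/Gamma cell-geometry populations and the
  repeated-inference comparison across heterogeneity scenarios;
* `poissnap.io` / `poissnap.experiments` — tabular formats and reproducible
  experiment drivers.

## Worked example

Fit the rates from 500 synthetic snapshots at a known truth
(`examples/04_bayesian_fit.py`):

```python
from poissnap import (CellGeometry, NondimParams, PriorSpec, hdpr,
                      sample_posterior, simulate_snapshot_set)

truth = NondimParams(lam=500.0, mu=10.0)
geom = CellGeometry(L=1.0, z=0.5)
data = simulate_snapshot_set(truth, [geom] * 500, mode="direct", seed=3)
chains = sample_posterior(data, PriorSpec(), n_iter=6000, n_burn=1000,
                          n_chains=4, seed=2)
region = hdpr(chains, data, PriorSpec())
```

prints (via the example script):

```
posterior mean lam = 513.8  (truth 500)
posterior mean mu  = 10.28  (truth 10)
89% central interval lam: [479.8, 548.2]
89% central interval mu : [9.04, 11.54]
89% HDPR area = 44.7, contains truth: True
mu acceptance rate = 0.31, ESS = {'lam': 4288.0..., 'mu': 4179.5...}
```

With 500 cells the posterior concentrates within a few percent of the
generating rates; the HDPR area shrinks like `1/M`, so doubling the number
of imaged cells halves the joint-uncertainty area.  The remaining scatter of
the posterior means across datasets is the Cramér–Rao floor (about 4% on
`λ`, 8% on `μ` at this design), not sampler error.

The other scripts in `examples/` demonstrate the intensity profile against
the numerical BVP solve, the two snapshot generators against the analytic
count law, D-optimal source placement (centered for fast degradation,
off-center for slow), and the repeated-inference heterogeneity experiment —
at slow degradation, cell-to-cell variability in geometry *reduces*
posterior uncertainty.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at the given seed: the nondimensional rates of the
worked rescaling example, the log–log slope of HDPR area versus number of
snapshots (repeated simulate-and-fit at the benchmark truth), and the pooled
posterior means of both rates recovered from an M=500 synthetic study, and
writes them as JSON.  Runtime is a few minutes on one CPU.
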