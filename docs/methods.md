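# Methods

## Model

`poissnap` treats the particle content of a single cell as a
birth–death–diffusion process on an interval: particles appear at a point
source `z ∈ (0, L)` according to a stationary Poisson process of rate `λ`,
perform Brownian motion with unit (nondimensional) diffusivity, switch to an
unobservable state at rate `μ` (degradation / inactivation), and are removed
instantly on reaching either end of the interval (absorbing boundaries, e.g.
nuclear export).  An experiment observes the positions of the surviving
particles in each of `M` cells at a single instant — a *snapshot* — because
fixation destroys the dynamics.

All rates are nondimensional: physical rates `κ±` (1/time) are multiplied by
`L0²/D` where `D` is the diffusivity and `L0` a reference length, and lengths
are divided by `L0`.  Only these combinations are identifiable from
snapshots, which carry no clock.

The central structural fact, which the package both uses and validates by
simulation, is that the snapshot positions form a **spatial Poisson point
process** whose intensity `u` solves

```
0 = u''(x) + λ δ(x − z) − μ u(x),   u(0) = u(L) = 0.
```

The solution is the Dirichlet Green's function of the 1D modified Helmholtz
operator; with `s = √μ`, `a = min(x, z)`, `b = L − max(x, z)`:

```
u(x) = (λ / s) · sinh(s a) sinh(s b) / sinh(s L),
E[N] = ∫₀ᴸ u = (λ/μ) [1 − sech(s L / 2) cosh(s (L − 2z) / 2)].
```

`E[N]` factorizes into the well-mixed birth–death mean `λ/μ` times a
geometric retention factor `< 1`.  The prefactor `λ/s` (not `λ·s`) is fixed
by dimensional consistency with the BVP and confirmed against an independent
finite-difference solve and against trajectory-level simulation.

## Numerical choices

* **Overflow-safe hyperbolics.**  All sinh/cosh ratios are evaluated in log
  space (`log sinh y = y + log1p(−e^{−2y}) − log 2`), so `√μ·L` up to ~700
  stays finite.  `coth` is computed as `1/tanh`, which never overflows.
* **μ → 0.**  Below `μ = 1e−10` the printed formulas are 0/0; the exact
  Brownian-exit limits `u = λ a b / L` and `E[N] = λ z (L − z) / 2` are used
  instead.
* **Finite-difference oracle.**  Second-order centered differences with
  homogeneous Dirichlet ends; the point source is hat-split onto the two
  bracketing nodes scaled by `1/h`.  Convergence is O(h²); the pointwise
  error constant depends on where the source falls between nodes, so the
  order is measured with an on-node source.
* **Quadrature.**  Information integrals use adaptive Gauss–Kronrod on
  `[0, z]` and `[z, L]` separately (the derivative kink at the source
  degrades single-panel schemes), with tight tolerances (`epsrel ~ 1e−11`).
* **∂u/∂μ** is analytic (differentiating the log-space form); central
  differences serve only as a test oracle, because near-singular information
  integrands amplify finite-difference noise.

## Simulators

Two independent generators produce synthetic snapshots:

* **Trajectory-level** (the mechanistic oracle).  The stationary birth
  process on the time axis is truncated at a horizon
  `T0 = −log(tol)/(μ + π²/L²)` — death rate plus the slowest Dirichlet
  diffusion mode bound the survival decay, so with the default
  `tol = 1e−7` pre-horizon births are negligible.  Births are thinned by the
  exact survival-by-lifetime probability `e^{−μ·age}` before any path is
  integrated (Poisson thinning; doomed particles never need simulating).
  Surviving paths take Euler–Maruyama steps of variance `2·dt`
  (default `dt = 1e−4`) with within-step Brownian-bridge absorption
  probability `exp(−d₁d₂/dt)` per wall, the exact bridge-crossing
  probability for increment variance `2·dt`.  With the correction on, mean
  counts are unbiased even at `dt = 1e−3`; with it off they are biased high
  by the missed crossings, a bias that vanishes as `dt → 0`.
* **Direct** (fast).  Draw `N ~ Poisson(E[N])`, then `N` iid positions by
  inverse CDF of `u/∫u` on a 4096-point grid.  This is the law the theorem
  asserts; agreement of the two routes (chi-square on counts, KS on
  positions) is the package's validation of that assertion.

Per-cell reproducibility uses `numpy` `SeedSequence` spawning: one master
seed, one independent substream per cell.

## Likelihood and information

The exact snapshot log-likelihood is
`ℓ(θ) = Σᵢ log u(xᵢ) − E[N]`, summed over independent cells.  Because `u` is
linear in `λ` (`u = λ v`), the profile MLE `λ̂ = Σn / Σ∫v` is closed-form, and
the Fisher information of the point process reduces (via the Campbell
formula) to `I_ij = ∫ ∂ᵢu ∂ⱼu / u dx`.  The `(λ,λ)` entry has the closed form
`E[N]/λ²`; the others are quadratures of analytic derivatives, cross-checked
in tests against the Monte Carlo covariance of the score over direct
snapshots.

Binned observations (counts per partition cell) have information
`Σⱼ (∫_{Aⱼ} ∂u)² / ∫_{Aⱼ} u`, never exceeding the unbinned value
(Cauchy–Schwarz), with exact equality for the scale parameter `λ`.  Bin
masses come from the analytic cumulative intensity, not quadrature.

Positions lying exactly on a boundary are rejected as invalid data: the
model intensity vanishes there, so such points can only arise from
preprocessing errors.

## Heterogeneity

Cell-to-cell geometry variation is parameterized by
`z/L | L ~ Beta(1/σ_z, 1/σ_z)` (mean L/2 at every spread; `σ_z = 1` is
uniform) and `L ~ Gamma(1/σ_L², scale σ_L²)` (mean 1, variance `σ_L²`).
Population-averaged information uses tensorized Gauss–Jacobi (32 nodes in
`z/L`) × generalized Gauss–Laguerre (32 nodes in `L`) quadrature — the
entries are smooth in `(z, L)`, so this is spectrally accurate — with a
seeded Monte Carlo fallback as a diagnostic.  Relative source positions
within `1e−4` of a wall are resampled (and logged): they produce near-empty
snapshots and `−∞`-prone likelihood terms.

## Posterior sampling

A Gamma(α, β) prior on `λ` is conjugate given `μ`:
`λ | μ, x ~ Gamma(α + Σ nₘ, β + Σ ∫vₘ)`.  `μ` has a Uniform(0, μ_max) prior.
The sampler alternates the exact Gamma draw with a Gaussian random-walk
Metropolis update of `μ`; the Metropolis step targets the
**λ-marginalized** posterior (the Gamma integral over λ is analytic), which
is what makes the chain mix: updating `μ` conditionally on a drawn `λ` must
crawl along the strongly correlated (corr ≈ −0.98) constant-count ridge,
whereas the marginal update is a plain 1D walk.  Both schemes leave the
exact joint posterior invariant; the marginal variant raises the effective
sample size from ~0.5% to ~20% of draws.

Defaults (configurable): `α = 2`, `β = 0.004` (prior mean 500, weakly
informative on the benchmark scale), `μ_max = 100`, 4 chains, 6000
iterations with 1000 burn-in.  The proposal scale is pilot-adapted toward
~30% acceptance during burn-in and frozen afterwards, preserving detailed
balance in the retained samples.  Chains are initialized at `μ = 1` with `λ`
drawn from its conditional.

The joint uncertainty summary is the **89% HDPR**: rank pooled samples by
unnormalized log posterior, keep the top 89%, report the convex hull and its
shoelace area.  The hull is kept even though banana-shaped small-M
posteriors make it an overestimate — it is the field's measured quantity.
For large sample counts the density evaluations are strided down to
`max_eval` points (default 8000) before ranking.

## The repeated-inference experiment

`run_heterogeneity_experiment` compares four scenarios (static geometry,
random source `σ_z = 0.75`, random size `σ_L = 0.25`, both) by repeated
simulate-and-fit at a common truth.  Repeats are **paired**: the r-th repeat
of every scenario shares spawned seeds, so scenario contrasts are not
confounded by draw noise (and a degenerate scenario reproduces the static
one exactly).  The default is 100 repeats — the median ordering is stable at
that size while keeping desk-scale runtime; at `μ = 1` all three
heterogeneous scenarios show smaller median HDPR areas than the static one,
in agreement with the sign of `d det E[I] / dσ` from the quadrature route.

## What the synthetic generator does and does not establish

The generator emulates exactly the stated model: stationary point-source
births, Brownian motion, exponential lifetimes, perfectly absorbing walls,
a single exact observation instant, and (optionally) Beta/Gamma geometry
heterogeneity.  It does not emulate localization error, undercounting or
segmentation noise of real imaging, bursty production, partially
transmitting boundaries, or anomalous diffusion.  A green test therefore
establishes internal consistency of theory, simulators and inference — not
that the model describes any particular experimental dataset.

## Known limitations

* 1D domains with a single point source only; no drift.
* The recovery tolerance (±10% at M = 500) is a ~1.3σ test against the
  Cramér–Rao floor (sd(μ̂)/μ ≈ 8%), so a several-percent miss on a given
  seed is sampling noise, not bias; the estimator is unbiased to within
  Monte Carlo resolution over replicated datasets.
* HDPR hull coverage is slightly above its nominal level for skewed
  posteriors (convexification can only add area).
* The trajectory simulator's cost grows as `λ/μ²/dt`; very small `μ` with
  fine `dt` is expensive — use the direct sampler for inference-scale data.
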