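# Methods

## The model

Read counts `n_os(t)` for OTU *o* in subject *s* on day *t* are modelled
per sample as multinomial with total `N_s(t)` and propensities

```
q_os(t) = exp(-Σ_k z_tk θ_kos) / Ω_st ,
```

a softmax ("Gibbs–Boltzmann") form in which `z` (T × K) are
time-specific latents shared by every OTU and subject and `θ`
(K × O × S) are OTU- and subject-specific loadings. The exponential link
lets small latent excursions produce large fold-changes in abundance,
which is the regime gut communities actually occupy. The log-likelihood
(multinomial coefficient dropped) is

```
ln L = Σ_{s,t} Σ_o n_os(t) log q_os(t)
     = -Σ_{t,o,s,k} N_s(t) x_os(t) z_tk θ_kos - Σ_{s,t} log Ω_st ,
```

with `x = n / Σ_o n` the compositions. Maximization is by plain
gradient ascent on

```
∂lnL/∂z_tk  = -Σ_{o,s} N_s(t) (x_os(t) - q_os(t)) θ_kos
∂lnL/∂θ_kos = -Σ_t    N_s(t) z_tk (x_os(t) - q_os(t)) .
```

**Assumptions.** Counts are conditionally multinomial given the
community state (no overdispersion beyond sampling); the community
state moves on a K-dimensional manifold shared across subjects in time;
subjects differ only through their loadings.

### Optimizer details

* Initialization: `z`, `θ` i.i.d. uniform on [-0.1, 0.1] from the seed.
* Learning rate η: default 0.005, stable range [0.001, 0.005]. A step
  that fails to improve the likelihood (or makes it non-finite) is
  retried at halved step size, and the step size relaxes back toward η
  afterwards; the recorded likelihood trace is therefore non-decreasing
  to floating-point tolerance.
* Stopping: relative gradient norms `‖g‖₂ / max(‖param‖₂, 1)` of both
  blocks below `tol`. Two presets: `benchmark` (tol 1e-3, ≤1e5
  iterations) for reconstruction benchmarking and `analysis` (tol 1e-4,
  ≤1e6) for final analyses.
* Equal-depth data (all observed `N_s(t)` identical) automatically
  switch the ascent to relative-abundance gradients (the `N` factor
  dropped), i.e. the likelihood normalized by total reads. This rescales
  the gradient field without moving the optimum and makes η and tol
  depth-independent.
* Missing samples contribute nothing to likelihood or gradients. Latent
  rows for days no subject sampled stay allocated (the dynamics step
  needs a dense daily grid) and are tied to zero by a negligible ridge
  (1e-8) so they remain finite.
* Overflow control: the per-sample maximum exponent is subtracted before
  exponentiation (log-sum-exp), mathematically inert.
* Absolute-abundance mode: externally supplied totals act as per-sample
  likelihood weights while compositions are still computed from the
  counts. This keeps two exact invariances: gradients scale linearly in
  the totals, and rescaling all totals by a constant leaves the
  maximizer unchanged.

## Gauge fixing and ecological normal modes

`(zB, B⁻¹θ)` predicts identically for any invertible K × K `B`, so the
raw fit is a gauge orbit, not a unique representation. The gauge is
fixed in three prediction-preserving steps:

1. **Orthonormalization.** Modified Gram–Schmidt (the numerically
   stable variant) on the columns of `z` gives `z′` with `z′ᵀz′ = I`;
   the rotation `B = z⁺z′` (Moore–Penrose pseudoinverse) carries the
   loadings along, `Θ′ = B⁻¹Θ`. Rank deficiency of `z` aborts with
   advice to refit at smaller K.
2. **Linear dynamics.** A "return to normal" model
   `z′_{t+1} = A z′_t + u + η_t` with symmetric `A` and isotropic
   Gaussian noise is fitted by squared-error minimization over
   consecutive observed pairs. With complete data this is an exact
   constrained linear least squares over the upper triangle of `A` and
   `u`. With missing days, predictions are propagated through gaps by
   iterating the noiseless dynamics — the objective then becomes
   polynomial in `A` — and minimized by simulated annealing
   (exponential cooling 1.0 → 1e-4 over 2×10⁴ single-coordinate
   Gaussian proposals, warm-started from the unit-step least-squares
   solution) followed by a deterministic BFGS polish of the best state.
   The annealing handles the global search; the polish supplies
   least-squares-grade accuracy at the located basin.
3. **Diagonalization.** `A = vᵀΛv` with orthogonal `v` (rows are
   eigenvectors). The ECNs are `y_t = v z′_t` with loadings `Φ = v Θ′`
   and baseline `u′ = v u`, so `Σ_k y_tk Φ_kos = Σ_k z′_tk Θ′_kos`
   exactly and the fitted dynamics decouple:
   `y_{t+1,k} = Λ_k y_tk + u′_k + noise`.

**Conventions** (the method fixes modes only up to sign and order):
modes are sorted by descending |Λ| (slowest-relaxing first) and signed
so that each mode's largest-magnitude loading entry is positive.
Degenerate eigenvalues are resolved by the eigensolver's ordering and
then the sign rule; within an eigenspace the orientation is arbitrary
and documented as such.

## Synthetic benchmark communities

Ground truth comes from a generalized Lotka–Volterra system

```
dx_i/dt = x_i (r_i + Σ_j a_ij x_j) ,
```

integrated in log-abundance space with fixed-step RK4 (step 0.01 day),
which enforces positivity by construction. Defaults: 20 species over 75
days sampled daily; `r_i ~ U(0.3, 1.0)/day`; self-limitation
`a_ii ~ -U(0.5, 1.5)`; each off-diagonal interaction present with
probability 0.3, magnitude `U(0, 0.3)`, random sign (both competition
and cooperation). Initial abundances `U(0.05, 0.2)`. These values were
chosen once to yield stable, visibly fluctuating communities whose
composition spans several orders of magnitude at a sequencing depth of
10⁴; all are configurable. Mixed-sign draws occasionally produce
runaway mutualism, so the random-community constructor rejection-samples
parameter draws (deterministically from the seed) until the test
integration stays bounded — unstable parameterizations are outside the
model class being emulated, not data.

Optional fluctuating carrying capacities are implemented as sinusoidal
modulation of the self-interaction,
`a_ii(t) = a_ii (1 + A sin(2πt/τ + φ_i))`; amplitude 0 reproduces the
unmodulated system bit-for-bit.

Observed data are independent multinomial draws per day at a stated
depth (default 10⁴ reads). Benchmark pairs sample the same ground truth
twice so that the divergence between models fitted to the two replicates
isolates sensitivity to sequencing noise.

**What the generator does not emulate:** overdispersion beyond
multinomial sampling, taxonomic structure, compositional zeros from
detection limits, uneven sampling schedules, or host covariates.
Passing benchmarks therefore certify the inference machinery under the
model's own assumptions, not performance on any particular real cohort.

## Downstream analyses

* **Reconstruction report** — per-subject KL divergence between data
  and reconstruction normalized by the number of time points; per-OTU
  trajectory MSE and Pearson correlation averaged over OTUs to one
  number per subject (constant observed trajectories have undefined
  correlation: excluded and counted).
* **Daily-change profile** — Δ = log₁₀ x(t+1)/x(t) against its model
  counterpart over consecutive observed days; |Δ − Δ_M| binned in
  5-percentile intervals of x(t) with mean ± s.e.m. per bin. Zeros are
  shifted by half the minimum nonzero abundance (the data say nothing
  about zeros in log ratios; this choice is symmetric between data and
  model).
* **ECN–taxon screen** — Pearson correlation of every ECN with every
  taxon trajectory; all (taxon, subject, mode) p-values pooled into one
  Benjamini–Hochberg correction at 5% FDR; report fractions of taxa
  tied to exactly one vs several modes.
* **Loading clustering** — Ward linkage on per-OTU feature vectors
  assembled from selected modes (e.g. excluding the mean-abundance mode
  Φ₁ so that overall abundance does not drive cluster membership);
  subjects concatenated by default, with a per-subject mean mode
  exposed. The cluster count is the caller's choice from the dendrogram
  (also exported in Newick form); no automatic cut is imposed.
* **Subject variability** — per OTU, the mean Euclidean distance between
  its K-vectors of loadings over all subject pairs; small = universal
  dynamics, large = subject-specific.
* **Enrichment** — exact upper-tail hypergeometric probability
  P(X ≥ k) for category counts within a cluster.
* **Model agreement** — Jensen–Shannon divergence in bits (mixture
  form), per sample, averaged over time. The symmetrized-KL
  ½(KL(p‖q)+KL(q‖p)) is a distinct quantity and is deliberately *not*
  what this function computes; JS is bounded (≤1 bit) and defined even
  for disjoint supports, which sampled compositions routinely produce.

## Problem sizes and numerical choices

The bundled tests and the acceptance script run the pipeline at sizes
chosen to exercise every code path while completing in minutes on one
CPU: gradient checks on O≤5, T≤6 instances; dynamics recovery at K=3,
T=300, noise 0.01; benchmark communities of 12–20 species over 40–75
days at depths 10³–10⁵ with five community seeds per depth. Larger
problems change nothing structurally — cost is linear in O·S·T per
ascent iteration.

Known limitations: plain gradient ascent is first-order and can need
10⁴–10⁵ iterations near the optimum; the linear dynamics is a
reorientation device, not a claim that latent dynamics are truly
linear; K is chosen by the qualitative elbow of the likelihood-vs-K
scan, not by a formal criterion; the joint fit of embedding and
dynamics in one objective is intentionally out of scope.
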