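# embed — ecological normal modes for longitudinal microbiome data

Gut microbial communities measured day after day by 16S/shotgun
sequencing produce an OTU × sample count table per subject: noisy,
compositional, often with missing days, and far too high-dimensional to
read directly. `embed` decomposes such multi-subject time series into a
small number of shared temporal modes and per-OTU, per-subject loadings,
then rotates those modes into a unique orthonormal basis — the
**ecological normal modes (ECNs)** — in which community dynamics
decouple. It is aimed at microbiome researchers who want an
interpretable low-dimensional description of longitudinal cohorts
(dietary interventions, antibiotic courses, developmental series) and a
principled way to ask which taxa follow which collective dynamic.

## The model

Counts are multinomial per sample with softmax propensities

```
q_os(t) = exp(-Σ_k z_tk θ_kos) / Ω_st
```

where `z` (T × K) are time latents shared by all OTUs and subjects and
`θ` (K × O × S) are loadings. The log-likelihood
`Σ n_os(t) log q_os(t)` is maximized by gradient ascent. Because
`(zB, B⁻¹θ)` predicts identically for any invertible `B`, the raw fit
is not unique; the gauge is fixed without changing a single prediction
by (i) Gram–Schmidt orthonormalization `z → z′`, `Θ → B⁻¹Θ` with
`B = z⁺z′`, (ii) fitting symmetric linear dynamics
`z′_{t+1} = A z′_t + u + noise`, and (iii) diagonalizing `A = vᵀΛv` to
obtain ECNs `y_t = v z′_t`, loadings `Φ = v Θ′`, and decoupled
per-mode dynamics `y_{t+1,k} = Λ_k y_tk + u′_k + noise`.

The package also ships the benchmark generator (generalized
Lotka–Volterra communities sampled as multinomial reads) and the
downstream analyses: reconstruction metrics, daily-change error
profiles, ECN–taxon correlation screening under BH FDR control, Ward
clustering of loadings, subject-variability ranking, hypergeometric
enrichment, and Jensen–Shannon model-agreement divergence. See
`docs/methods.md` for the full account.

## Worked example

Simulate a 12-species community for 40 days, sample 10⁴ reads/day, fit
K = 3 modes, and score the reconstruction:

```sh
embed simulate --species 12 --days 40 --depth 10000 --seed 7 --out sim
embed fit --input sim/counts_rep1.tsv --k 3 --seed 7 --out model
embed analyze --model model --input sim/counts_rep1.tsv \
      --task reconstruction --out analysis
```

which prints

```
Gibbs-Boltzmann tensor factorization
====================================================
OTUs: 12   subjects: 1   time points: 41 (41 observed samples)
latent dimension K:      3
mode:                    normalized (equal depth)
converged:               True (30300 iterations, 0 backtracks)
rel. gradient (z, theta): 1.000e-03, 8.263e-04  (tol 0.001)
log-likelihood:          -2.337143 (per read)
seed: 7   learning rate: 0.005
Ecological normal modes
====================================================
K = 3 modes, 41 time points, 12 OTUs x 1 subjects
dynamics fit: analytic (residual 4.7539e-01, 40 pairs)
mode  eigenvalue   baseline u'
   1      0.9196       0.0073
   2      0.4049       0.0198
   3      0.0677       0.1455
Reconstruction report
  time-normalized KL (mean over subjects): 0.000465
  per-OTU MSE, subject-averaged:  6.226e-06
  per-OTU Pearson, subject-avg:   0.8931
  constant OTUs excluded: 0
```

Reading the output: the fit converged (both relative gradients under
the 1e-3 benchmark tolerance); the three ECNs relax at rates
Λ = 0.92, 0.40, 0.07 per day — mode 1 is the slow, near-persistent
component, mode 3 decorrelates almost immediately. The reconstruction
matches the observed compositions to a per-day KL of ~5e-4 and tracks
individual OTU trajectories at mean Pearson r = 0.89. The `model/`
directory holds `ecns.tsv` (T × K), per-subject loading tables,
eigenvalues, the rotation, and a diagnostics JSON recording seed and
settings, so the run is fully reproducible.

The same objects are available as a library:

```python
from embed import EMBED, read_otu_table

data = read_otu_table("sim/counts_rep1.tsv")
res = EMBED(data, k=3).fit(seed=7)      # EMBEDResults
ecn = res.to_ecn()                      # ECNResults
print(res.summary()); print(ecn.summary())
q = ecn.propensities(mode_subset=[2, 3])  # partial reconstruction
```

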