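# Methods

## Model

For n individuals genotyped at q biallelic markers (allele dosages
Z ∈ {0,1,2}ⁿˣ𝑞) with phenotype y, the package works with the mixed linear
model

    y = W α + Z γ + u + ε,
    u ~ MVN(0, σ_g² K),   ε ~ N(0, σ² Iₙ),   γ_k ~ N(0, σ_k²),

where W holds fixed-effect covariates (at minimum an intercept), γ is the
vector of random marker effects, u is a polygenic background term with known
relatedness matrix K, and the per-marker variances carry a scaled
inverse-chi-square prior, σ_k² ~ χ⁻²(ν, S) — the BayesA hierarchy. Marginally
var(y) = σ² (λ_γ Z Zᵀ + λ_g K + Iₙ) with λ_γ = σ_γ²/σ², λ_g = σ_g²/σ².

## Stage 1 — variance-ratio estimation and whitening

Because most markers are unlinked to the trait, stage 1 sets λ_γ = 0 and
estimates λ_g on the reduced model y = W α + u + ε by REML. A single
eigendecomposition K = U D Uᵀ turns every candidate λ_g into an O(n)
evaluation of the restricted likelihood (the EMMA device): with
v_i = λ d_i + 1, the profile objective is

    f(λ) = (n−c) log RSS_GLS(λ) + Σ_i log v_i + log|WᵀV⁻¹W|,

minimized over log₁₀ λ ∈ [−5, 5] by a coarse grid scan (41 points) followed
by bounded Brent refinement in the bracketing interval; the λ = 0 boundary is
compared explicitly. The grid scan matters: the profile can be multimodal or
extremely flat, where Brent alone stalls on a shoulder.

**Degenerate optima.** When q ≫ n, the marker-derived GRM comes close to
explaining the phenotype entirely and the REML optimum can assign essentially
all variance to the polygenic term — the infinite-heritability solution
σ̂² → 0 — either at the upper search bound or at an enormous interior λ, with
the profile nearly flat over several decades (observed: Δ(−2 log L) < 4
between λ ≈ 10 and λ = 10⁵ at n = 1000, q = 10,000). Such a λ̂ is useless
downstream: B = λK + I degenerates to a multiple of K, the +I part that
protects low-variance directions vanishes, and the whitened regression loses
most of its signal. The estimator therefore detects degeneracy — REML
residual variance below 1% of the phenotypic variance, or argmin at the
upper bound — and reports the *profile-likelihood 95% lower confidence
limit*: the smallest λ whose −2 log LR against the degenerate optimum is
≤ 3.84, with a warning. In the flat-profile regime this lands in the same
statistical equivalence class while keeping the whitening operator
well-conditioned.

When K is numerically a multiple of the identity, λ_g and σ² are not
separately identifiable; the estimator returns λ̂_g = 0 with a warning.

Whitening uses the symmetric inverse square root: B = λ̂_g K + Iₙ = Q Λ Qᵀ,
C = Q Λ^(−1/2) Qᵀ, and (y_c, W_c, Z_c) = (Cy, CW, CZ). If cov(y) = σ²B, then
cov(y_c) = σ²Iₙ: the polygenic term is absorbed into homoscedastic noise.
B shares K's eigenvectors, so the same decomposition serves both stages.
Eigenvalues of B are floored at 1e−10 (logged) as a roundoff guard; λ̂_g = 0
short-circuits to C = Iₙ exactly, making the unwhitened reduction
bit-reproducible.

## Stage 2 — EM for BayesA

On the (possibly whitened) data the EM algorithm treats the marker variances
as missing data:

* **E-step**: σ̂_k² = (γ̂_k² + S)/(ν + 1) — the reciprocal of the posterior
  expectation of the precision under the conjugate χ⁻² prior.
* **M-step**: coordinate ascent on the log-posterior — a Gauss–Seidel sweep
  of ridge-shrunken single-marker regressions
  γ̂_k = z_kᵀ r₍₋ₖ₎ / (z_kᵀz_k + σ²/σ̂_k²) over markers in column order with an
  incrementally maintained residual (O(nq) per sweep, numba-jitted), then the
  fixed effects, then σ̂² = ‖r‖²/n (floored at 1e−12).

Integrating the variances out analytically gives the scaled-t marginal
objective

    L(α, γ, σ²) = −n/2 log σ² − ‖r‖²/(2σ²) − (ν+1)/2 Σ_k log(γ_k² + S),

whose stationary points coincide with the EM fixed points and which the
iteration never decreases (generalized-EM argument: every block update
increases the E-step surrogate). `log_posterior_trace` records L per
iteration and the test suite asserts the ascent on every fit. Note that
substituting the E-step variances directly into the complete-data
log-posterior produces a (ν+3)/2 log-penalty whose stationary points do *not*
match the update equations; the marginal form above is the internally
consistent objective.

**Convergence.** The stopping rule is *relative*:
rms(Δγ) < tol · (1e−3 + rms(γ)) with tol = 0.02 by default — a sweep stops
the iteration once it moves the effect vector by less than ~2% of the
vector's own scale — plus a *contraction guard*: the rule may only fire from
iteration 2 onward and only while the step norm is non-increasing. Three
observations dictated this design. (i) Near the γ = 0 saddle of the
non-convex marginal objective the steps are tiny but *growing*
(multiplicative escape); a bare step-size criterion stops there with an
essentially empty model — the guard rules this out. (ii) The max-norm of the
steps never settles at q ≫ n: a handful of correlated (post-whitening)
markers keep trading effect mass inside a flat ridge of the posterior long
after the fit is stable; the RMS norm averages this exchange away. (iii) No
absolute threshold is meaningful at q ≫ n because the MAP itself is
degenerate — the objective is unbounded as σ² → 0, and the iteration drifts
toward exact in-sample interpolation indefinitely at a slow, roughly
self-similar rate. The relative rule stops where prediction quality and
marker ranking have plateaued (iteration counts in the tens at the default
problem sizes); running far beyond that point only pursues the interpolation
limit, where marker ranking is unchanged but the raw-scale fit of the
*whitened* model deteriorates.

**Prior defaults.** ν = 4, S = 0.01. These are weakly informative: S sets the
scale of a "negligible" effect (√S ≈ 0.1 trait units per allele) and keeps
the marginal objective bounded at γ_k = 0; ν controls tail weight. Both are
exposed in `PriorConfig`. Effect shrinkage is monotone: weaker with larger S,
stronger with larger ν.

**Iteration cap** 200; initialization: α by least squares on W alone, γ = 0,
σ² = var of that residual.

**GEBV.** Marker effects are invariant under the linear whitening transform,
so GEBV_i = (Z γ̂)_i is computed on the original dosage scale. The polygenic
term u, absorbed into the whitened residual, is *not* added back as a BLUP
component; with the near-interpolating in-sample fits at q ≫ n its marginal
contribution to the reported correlations is negligible, and leaving it out
keeps GEBV a pure marker predictor. Evaluation is in-sample (fit and score on
the same individuals) by default, matching the headline simulation protocol;
cross-validation is available through the library but not part of the
benchmark.

## Baselines

All baselines consume the same inputs and emit the same `EMFit` schema.

* **emBA** — identical EM, no whitening stage (λ ≡ 0 path; exact reduction).
* **emRR** — Bayesian ridge: one shared variance
  σ̂_γ² = (Σ γ̂_k² + S)/(q + ν) refreshed per iteration, so every marker shares
  one shrinkage ratio. Its trace records the analogous marginal objective
  with the shared variance integrated out. Initialized by moment matching
  (half the phenotypic variance attributed to markers) to avoid the
  degenerate all-null fixed point.
* **emML** — Gaussian maximum likelihood on the equivalent GBLUP covariance
  σ_γ² Z Zᵀ + σ² I. The ratio is found by profile ML on the eigenbasis of
  Z Zᵀ (grid + Brent, λ = 0 boundary included); γ̂ is the conditional
  posterior mean. Not iterative, so no ascent trace.
* **emBC** — spike-and-slab mean-field variational EM: γ_k = δ_k b_k with
  δ_k ~ Bern(π) and slab b_k ~ N(0, σ_γ²) (spike = point mass at zero). Each
  sweep updates the slab posterior N(m_k, v_k) and inclusion probability p_k
  per marker against the residual of expected effects; σ_γ² and π use the
  exact evidence-bound maximizers ((Σ p(m²+v) + S)/(Σ p + ν + 2) and mean p),
  and σ² uses the expected residual sum of squares including the posterior
  variance term. The trace records the ELBO, which every block update
  provably increases. Reported γ̂_k = p_k m_k.
* **emEN** — deliberately not implemented (raises `NotImplementedError`): a
  combined L1/L2 fitter is numerically fragile on p ≫ n genomic data and is
  outside this package's supported surface.

Baselines can be run on pre-whitened data (`--whiten`) for
background-controlled variants; emBAI is exactly emBA composed with stage 1.

## Synthetic data

The generator reproduces the benchmark study conditions:

* genotypes: q independent markers, allele frequency p_k ~ U[0.1, 0.5], HWE
  dosages Binomial(2, p_k); monomorphic columns are redrawn;
* experiment 1: a single QTN at marker 98 with heritability h² = 0.1;
* experiment 2: 50 QTNs drawn uniformly among markers with MAF > 0.3, total
  variance share 0.5, equal per-QTN variance, random effect signs;
* population mean 10.0, residual variance σ_e² = 10.0; polygenic background
  σ_g² = m · σ_e² with multiplier m ∈ {2, 5, 10}; sample sizes 500/1000/2000,
  q = 10,000 by default.

Two conventions deserve note, since the verbal description "heritability 0.1"
and "m times polygenic background" leaves the denominators open. A component
with target share h of phenotypic variance receives variance
h/(1−h) · (σ_g² + σ_e²) (so the share is exact in expectation, and the rule
degenerates correctly at σ_g² = 0); the polygenic multiplier is anchored on
the residual variance, the only absolute variance the protocol fixes. Effect
sizes are solved from the *realized* allele frequency of the chosen marker
(a² · 2p(1−p) = target variance). u is drawn from MVN(0, σ_g² K) with K the
VanRaden GRM of the simulated markers themselves (jittered Cholesky), i.e.
the background is exactly K-structured — the assumption stage 1 exploits.
Phenotype components (genetic, polygenic, residual) are stored so realized
variance shares and error decompositions are recomputable exactly; identical
scenario + seed reproduces the dataset bit for bit.

What the generator does **not** emulate: linkage disequilibrium (markers are
independent, so the AUC positives are exactly the causal columns and no LD
window is needed), dominance/epistasis, minor-allele-count artifacts,
genotyping error or missingness, and population structure in the fixed
effects. Passing benchmarks here therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Kinship

VanRaden method-1 GRM: K = M Mᵀ / (2 Σ p_k(1−p_k)) with M the 2p-centered
dosages — symmetric and PSD by construction, diagonal mean ≈ 1 under HWE.
Monomorphic markers are rejected by name. User-supplied kinship CSVs override
the GRM; mild asymmetry (> 1e−10) is repaired by (K+Kᵀ)/2 with a warning. K
is deliberately not blended toward the identity: B = λ̂_g K + I provides the
regularization.

## Metrics

MSE and MAE compare phenotype with the fitted values Wα̂ + Zγ̂; Pearson r
(sample correlation) compares phenotype with the GEBV Zγ̂. QTN-recovery AUC
scores each marker by |γ̂_k| against binary labels at the true QTN positions,
computed by the rank statistic with ties averaged (equivalently
P(score₊ > score₋) + ½P(tie)); it is invariant under monotone transforms of
the score, so |γ̂| vs γ̂² is immaterial.

## Benchmark scale and numerical choices

The full-scale checks run q = 10,000 markers with 10 replicates per scenario
cell over {n = 1000, 2000} × {m = 2, 5} (plus the n = 2000, m = 2 cell of
experiment 1) — enough replication for mean AUCs/correlations with standard
errors well below the comparison tolerances, while one replicate costs a few
seconds (GRM + eigendecomposition dominate; the EM sweeps are O(nq) each).
Replicate seeds derive from a master seed via `SeedSequence` keyed on
(experiment, n, m, replicate), so each cell's results are independent of grid
iteration order. Other constants: eigenvalue floor 1e−10 in the whitening
operator; σ² floor 1e−12; inclusion-probability logit clipped at ±35 in emBC;
incremental residuals refreshed exactly every 25 sweeps to cap floating-point
drift.

## Limitations

Single trait only; no MCMC reference sampler; in-sample evaluation of the
benchmark (the protocol it mirrors does the same — out-of-sample accuracy
will be materially lower at q ≫ n); the REML boundary rule is a pragmatic
regularization of a genuinely unidentified regime, not a resolution of it;
VCF input is not supported (dosage CSV and PLINK RAW cover the intended
workflows).
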