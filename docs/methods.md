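# Methods

This note documents the models implemented in `genembed`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical choices that matter for reproducing results.

## Forward model

**Neuronal layer.** Each of R regions carries one state; dynamics are the
bilinear approximation `dx/dt = (A + Σ_j u_j B^(j)) x + C u`. All coupling
rates are in Hz; inputs are dimensionless boxcars in {0, 1} held
piecewise-constant on the micro-time grid. Self-connections (diagonal of A)
are negative, around −1 Hz, so the resting state x = 0 is stable; a
`stability_check` (all eigenvalues of A in the left half-plane) guards
integration and can be overridden explicitly.

**Haemodynamic layer.** The classical balloon model per region:

    ds/dt = x − κs − γ(f − 1)         vasodilatory signal
    df/dt = s                          inflow
    τ dv/dt = f − v^(1/α)              venous volume
    τ dq/dt = f·E(f,ρ)/ρ − v^(1/α)·q/v deoxyhaemoglobin, E(f,ρ) = 1−(1−ρ)^(1/f)

with BOLD observation `y = 100·V0·(k1(1−q) + k2(1−q/v) + k3(1−v))`,
k1 = 7ρ, k2 = 2, k3 = 2ρ − 0.2, V0 = 0.02 — the coefficient set appropriate
for 1.5 T acquisitions, matching the study design the synthetic cohorts
emulate. Defaults: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2.0 s, α = 0.32,
ρ = 0.32. The rest point (x = 0, s = 0, f = v = q = 1) is an exact fixed
point, so zero activity produces exactly zero signal.

**Integration.** Fixed-step classical Runge–Kutta (RK4) at
micro_dt = TR/16 by default. Inputs switch only at micro-bin edges, so block
designs are integrated at full fourth order between switches. The public
two-stage path (`integrate_neuronal` → `integrate_bold`) interpolates the
neuronal trajectory with a cubic spline inside RK4 substeps; because the
trajectory has derivative kinks at input switches, the coupled path is
second-order accurate there. The declared integrator tolerance is 1e-3
(percent-signal units) at the default resolution — halving the step changes
sampled BOLD by less than this, and at fine steps (dt = 0.0125 s) the
integrator matches an adaptive reference (rtol 1e-11) to better than 1e-6
relative. The inverter uses an internal batched integrator that propagates
neuronal and haemodynamic states jointly for many parameter vectors at once;
it agrees with the two-stage path to ~1e-3 of the signal at default
resolution, far below measurement noise at any realistic SNR.

**Driving-input convention.** For the working-memory network, the "visual"
input consists of the individual 500 ms stimulus events of *both* task
conditions and drives visual cortex only; the "wm" input is the 2-back block
boxcar and modulates VC→DLPFC and DLPFC→PC. Whether rest-fixation events
should also drive visual cortex is unknowable from the protocol description;
the per-trial reading is the default and any other convention can be encoded
with `design_from_events`.

## Inversion (variational Laplace)

Per-subject inversion maximises the Laplace free energy

    F = ln p(y|μ̂) + ln p(μ̂) + ½ ln|Σ̂| + (d/2) ln 2π

by Gauss–Newton ascent with Levenberg-style damping (damping inflates the
curvature diagonal and grows ×4 on rejected steps, shrinks ÷4 on accepted
ones starting from 0). A step is accepted only if it increases F — including
the ½ ln|Σ̂| Occam term evaluated at the candidate — so the recorded trace is
non-decreasing by construction. Each outer iteration also takes one damped
Newton step on the per-region noise log-precisions (Gaussian prior,
mean 0, variance 1). Convergence: |ΔF| < 0.01 nats or 128 iterations.

Parameterisation: neuronal parameters raw (priors: off-diagonal A, B, C
~ N(0, 1/16); A-diagonal ~ N(−1, 1/256)); haemodynamic parameters as
log-scalings of their defaults (~ N(0, 0.0156), i.e. ±13% at one SD). The
tight self-connection and haemodynamic priors reflect that these quantities
are physiologically constrained; the coupling priors shrink toward zero so
that evidence, not the optimizer, decides which connections carry signal.

Gradients are forward finite differences (step 1e-4·(1+|θ|)) on the batched
integrator — robust to the ODE nonlinearity, and exact for linear maps,
which is what makes the closed-form equivalence test meaningful: with a
linear observation map and fixed noise precision the scheme reproduces the
conjugate posterior and the *exact* log evidence to 1e-6. The reported Σ̂ is
the inverse of the undamped curvature at the accepted optimum (the damped
inverse would break that exactness; at convergence the damping is ~0
anyway).

Noise is i.i.d. Gaussian per region with region-specific precision — no
temporal autocorrelation. This is the weakest point of the observation
model for real fMRI (see Limitations).

## Generative score space

The score space stacks the neuronal posterior means only — haemodynamic and
noise parameters are excluded by a name audit — giving 12 features for the
three-region network: nine A entries, two working-memory modulations, one
driving gain, in the order conventionally printed for this network
(column-major by source region). Comparator spaces: pairwise Pearson
correlations of the regional time courses (3 features, "functional
connectivity") and per-region mean/SD of voxelwise effect estimates
(6 features, "regional activity"). Eigenvariate convention: first
right-singular vector of the voxel-centred matrix scaled by σ₁/√(voxels),
sign fixed by non-negative mean loading.

Confounds are removed feature-by-feature by OLS on confounds + intercept
*before* standardization (the order in which such analyses report doing it);
constant confound columns are dropped with a log entry rather than treated
as an error, because they are collinear with the intercept and carry no
information. Standardization uses the sample (n−1) SD, recorded in the
preprocessing log. Standardization is global by default; per-fold scaling
inside cross-validation is available via the transformer classes and is the
more conservative practice.

## Mixture model and model-order selection

Likelihood: `p(x|z, μ, Λ) = Π_k N(x | μ_k, Λ_k^{-1})^{z_k}` with Dirichlet
mixing weights; inference is mean-field VB (Dirichlet + Gaussian–Wishart
factors), coordinate ascent until |ΔELBO| < 1e-6 with up to 500 iterations,
best of 5 restarts. The first restart is initialised from Ward agglomeration
(deterministic, good at finding compact unequal-size partitions); later
restarts use seeded k-means++ one-hot responsibilities softened by 5%.
Empty components are pruned at reporting time only, never mid-optimisation,
so per-K free energies stay comparable.

**Priors.** Two modes:

* *Fixed conjugate prior* (`GmmPrior`): α₀ = 1, m₀ = 0, β₀ = 1,
  ν₀ = d + 2, W₀ = I/ν₀. In this mode K = 1 inference is exact, and the
  test suite pins the ELBO to the closed-form marginal likelihood
  (multivariate Student) at n = 1 and, via the chain rule, at n = 2.
* *Adaptive prior* (`AdaptiveGmmPrior`, the default): identical structure
  but W₀^{-1} = diag(u) with u_j ~ Gamma(2, 2) learned conjugately, β₀ = 0.1,
  ν₀ = d + 2, α₀ = 1. The scales are shared by all components and use the
  same hyperprior for every candidate K, so free energies remain comparable
  across K.

The adaptive mode exists because a single fixed Wishart scale must commit,
a priori, to how much tighter clusters are than the pooled data. On z-scored
coupling estimates that ratio varies by orders of magnitude across features
(a self-connection estimated to ±0.003 Hz sits next to a modulation spread
over ±0.2 Hz), and no fixed scale both detects genuinely tight multi-cluster
structure and stays calibrated on unclustered data — wide scales can make
the free energy prefer one cluster even when initialised at a
perfectly-separated true partition, tight scales carve spurious clusters out
of a single Gaussian cloud. Learning per-feature scales resolves the
dilemma: on a homogeneous cloud the posterior scales match the pooled
variance and K = 1 wins; on clustered data they shrink toward the
within-cluster scale and the evidence rewards the true K. With n only a few
times d (e.g. 40 subjects in 12 dimensions) selection near the detection
threshold remains noisy — occasionally off by one in either direction — and
single-cloud calibration is clean from roughly n ≥ 5d.

Model-order selection fits K = 1..K_max (default 6; 5 in the cohort-scale
studies below) and picks the highest free energy, ties toward smaller K. The
winning margin is reported as a log Bayes factor; under equal model priors a
margin of 3 corresponds to a posterior model probability of 95.3%.

## Validation statistics

* **Purity**: fraction of subjects whose external class is the majority
  class of their cluster; always ≥ ξ, the largest-class fraction.
* **Balanced purity**: `bp = (1 − 1/J)(purity − ξ)/(1 − ξ) + 1/J` with J the
  number of external classes: 1 for perfect agreement, 1/J for a
  composition-proportional assignment, whatever the imbalance. (A variant
  replacing 1/J by 1/n is provided behind a flag for comparison; it does not
  reach the 1/J chance anchors.)
* **Balanced accuracy**: mean of sensitivity and specificity.
* **Infraliminal probability**: with flat-prior beta-binomial posteriors for
  the two class-wise accuracies, the probability that their mean is ≤ 0.5,
  computed on a 4096-point grid (matches a 10⁶-draw Monte Carlo oracle to
  ±0.002).
* **ANOVA / regression**: classical one-way F across clusters for continuous
  external variables, and OLS of an external score on the feature matrix
  with the overall F on (d, n−d−1) degrees of freedom; both are calibrated
  to 5% ± 1% type-I error in the test suite.
* **Per-feature discriminability**: pooled-variance two-sample t-tests with
  Bonferroni correction across exactly the d features tested.
* **Wald comparison** of two classifiers' accuracies: unpaired two-proportion
  z test — anti-conservative when both classifiers score the same subjects,
  which is noted wherever it is reported.

The supervised baseline is a linear SVM (C = 1, LIBSVM backend) under
seeded stratified 5-fold cross-validation with pooled predictions, so each
subject is predicted exactly once by a model that never saw it.

## Synthetic cohorts

`table1_cohort()` encodes the three printed patient-subgroup coupling
profiles (sizes 9/24/7 — the printed sizes sum to 40, as one of the 41
patients lacked clinical scores) with per-parameter dispersions equal to the
printed standard errors. Since within-cluster SDs were not published, the
SE-scale default gives tight clusters; `sd_multiplier` explores overlap, and
×√n approximates the empirical between-patient SD. External scores are
Gaussian with the printed means/SDs (15.6 ± 2.3, 19.6 ± 1.4, 27.9 ± 4.1),
truncated at zero as symptom scales are non-negative. Confound effects
default to zero because the printed profiles are post-residualization
estimates; a (3 × 12) effect matrix on z-scored (sex, handedness, age) can
be supplied to rehearse the residualization stage. `two_group_cohort()`
adds a *declared, synthetic* control profile (no control coupling table was
ever published): controls differ from the pooled patient profile chiefly in
much stronger working-memory modulations (0.70 and 0.40 Hz vs 0.145 and
0.043) so that the groups are essentially non-overlapping, which is what
"well-separated" is taken to mean here.

What the generators do **not** emulate: scanner drift, motion, physiological
and temporally autocorrelated noise, regional signal dropout, haemodynamic
variability beyond log-normal parameter scatter, and any misspecification of
the network structure. Passing tests therefore demonstrate internal
consistency of the pipeline under its own assumptions — a necessary, not
sufficient, condition for performance on real data.

## Problem sizes used in the behavioural studies

Cohort-scale studies use the feature-level generator (40 or 83 subjects,
12 features) with K_max = 5 and 5 restarts, 20 seeds per claim. Parameter
recovery inverts 20 subjects drawn from the middle cluster profile on a
reduced n-back design (2 blocks per condition, ~100 scans) at SNR 1, where
SNR is signal SD pooled over regions against a common noise SD — the
regions driven only through weak couplings then operate far below SNR 1,
which is the realistic hard case. These sizes are the package's reference
conditions for its own regression tests; larger designs simply sharpen the
same behaviour.

## Known limitations

* White observation noise; real fMRI noise is autocorrelated, so free
  energies on real data are optimistic.
* One neuronal state per region (no excitatory/inhibitory split), bilinear
  coupling only, deterministic dynamics: no stochastic or spectral variants.
* Finite-difference Jacobians cost d+1 integrations per iteration; the
  batched integrator keeps a 3-region subject at ~1 s, but scaling to many
  regions would warrant adjoint or sensitivity equations.
* Mixture model-order selection with n close to d is near its detection
  threshold (see above); reported log Bayes factors should be read together
  with the full free-energy profile.
* Voxelwise GLM estimation is out of scope: regional-activity features
  consume precomputed effect estimates.
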