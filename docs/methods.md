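# Methods

## The problem

SNP heritability analyses usually ignore gene–environment (GxE) interaction.
When many environmental variables E (N×L) have been measured per individual,
two questions arise: how much phenotypic variance do GxE interactions explain,
and which combination of the measured environments drives them?  `gxeherit`
implements two method-of-moments estimators that answer these questions
without ever forming an N×N kernel matrix, so they run on biobank-scale data
in O(N·M·L·B) time.

## Models

Genotypes X (N×M) are standardized columnwise (mean 0, variance 1 with
denominator N, so tr(XXᵀ/M) = N).  K = XXᵀ/M is the genomic relationship
matrix.  C (N×D) holds the covariates; the environments are always appended
to C, so D > L, and covariates are handled by projection with
W = I − C(CᵀC)⁻¹Cᵀ (applied implicitly through a thin QR of C).

**MEMMA** gives every environment its own interaction component:

    y ~ N(Cα, θ₁·K + Σ_l θ_{l+1}·K_l + θ_{L+2}·I),
    K_l = F_l F_lᵀ / M,   F_l = diag(E_l) X.

Haseman–Elston moment matching yields the linear system T·θ = c with
T_kl = tr(W K_k W K_l W) and c_k = yᵀW K_k W y, solved analytically.
Per-component heritability is h²_k = θ_k·tr(W K_k W) / Σ_j θ_j·tr(W K_j W).
Raw moment estimates may be negative; we report both the raw vector and a
zero-truncated copy, and the headline PVE uses the truncated one.  The signs
of interaction weights are unidentifiable here (each K_l is quadratic in
E_l), so MEMMA cannot produce an environmental score.

**GPLEMMA** instead assumes a single linear environmental score η = Ew
modulates genetic effects:

    y ~ N(Cα, σβ²·K + σγ²·K2(w) + σe²·I),
    K2(w) = diag(Ew) K diag(Ew).

The interaction scale is absorbed into the weights (w̃ = σγ·w), and
θ = (σβ², w̃, σe²) minimizes the covariance-matching objective

    S(θ) = || W(yyᵀ − Cov(y))W ||²_F,

a non-linear least-squares problem in L+2 parameters solved by
Levenberg–Marquardt.  The fitted w̃ yields the score direction (unit norm,
sign fixed so the largest-magnitude weight is positive), its scale ‖w̃‖
(the implied σγ), and the variance partition
(σβ²·tr(WKW), tr(W K2(w̃) W), σe²·(N−D)) normalized to PVE.

When a single linear score truly drives the interactions, MEMMA's total GxE
PVE and GPLEMMA's GxE PVE estimate the same quantity (σ²_{w_l} = σγ²w_l²);
GPLEMMA is the constrained model and has smaller sampling variance.

## Randomized trace estimation

All kernel-product traces use Hutchinson's estimator,
tr(A) ≈ (1/B)·Σ_b z_bᵀA z_b with Gaussian probes z_b ~ N(0, I).  One
streaming pass over genotype blocks accumulates everything the estimators
need: u_b = XXᵀWz_b, v_{b,l} = XXᵀ(E_l ⊙ Wz_b),
H_lm = E_lᵀ diag(Wy) XXᵀ diag(Wy) E_m, and the data quadratic forms
yᵀWXXᵀWy and yᵀWy.  Each trace is then assembled as a Gram product of
operator words applied to the probes — e.g.
tr(W K_k W K_l W) = (1/B)Σ_b (W K_k W z_b)ᵀ(W K_l W z_b) — rather than from
shortcut inner-product formulas.  This keeps every projection W in place,
makes the estimated moment matrices symmetric PSD by construction, and one
probe set shared across all terms positively correlates their errors, which
stabilizes the solves.  Data-side quadratic forms are computed exactly;
tr(W) enters as the exact N − D.

Default B = 100 probes (CLI `--probes`); the trace s.e. scales like √(2/B).
Several expressions that look like approximations are exact identities in
this scheme, e.g. Σ_l w̃_l v_{b,l} = XXᵀ((Ew̃) ⊙ Wz_b), and
tr(W K2(w̃) W) = (1/B)Σ_b ‖Xᵀ((Ew̃) ⊙ Wz_b)‖²/M ≥ 0 — the GxE variance
attribution is nonnegative by construction (see Limitations).

## Levenberg–Marquardt details

* **Jacobian.** ∂/∂w̃_l of the quadratic form contributes the symmetrized,
  factor-2 term W(diag(E_l) K diag(η̃) + diag(η̃) K diag(E_l))W; the data-side
  gradient entry is 2·Σ_m w̃_m H_lm / M.  The analytic JᵀJ and Jᵀε are
  validated against central finite differences of the dense model
  (relative error < 1e-4 in tests; observed ~1e-12).
* **Damping schedule.** μ₀ = 1e-3 · mean diag(JᵀJ); accepted steps divide μ
  by 3, rejected ones multiply by 2 and retry (classic multiplicative
  schedule; all factors configurable).
* **Initialization.** Each restart draws w̃ = (1/L)·1 + N(0, (2/L²)I), solves
  the 3-component linear moment system with kernels {K, K2(w̃), I} for
  (σβ², σγ², σe²), floors negative solutions at 1e-6 (moment negativity is
  sampling noise; LM needs a finite start), and starts from
  (σ̂β², √σ̂γ²·w̃, σ̂e²).  Ten restarts by default; the solution with the
  lowest S is kept.
* **Convergence.** Relative S decrease < 1e-6 on three consecutive accepted
  steps, or 200 iterations.  S is strictly decreasing over accepted steps by
  construction.
* Per-iteration cost is O(N·L²·B); the LM stage is negligible next to the
  single O(N·M·L·B) streaming pass at the problem sizes below.

Two interchangeable objective backends implement S/JᵀJ/Jᵀε: the randomized
(`HutchinsonObjective`) production path and an exact dense backend
(`DenseObjective`) for small problems.  With the dense backend the LM fixed
point matches an independent generic NLLS solver (scipy `least_squares`)
to < 1e-4 relative parameter error in tests.

## Synthetic data

The generator emulates a biobank-style GxE study:

* Genotypes: independent SNPs, dosage ~ Binomial(2, p), p ~ U(0.05, 0.5),
  monomorphic columns resampled.  No LD, MAF-architecture coupling,
  relatedness, or population structure — so passing recovery tests show
  estimator correctness under the assumed covariance model, not robustness
  to real-data confounding.
* Environments: standard Gaussian, or ordinal Binomial(n, p) with
  n ∈ {3,4,5} and p ~ U(0, 0.5), standardized.
* Interaction weights: L_active entries of the alternating decreasing
  sequence w_i = (−1)^i·(1 − i/(2·L_active)) (a square-root-magnitude
  variant is available via `weight_form="sqrt"`; the linear form is the
  default reading of the design).
* Phenotype: y = Cα + Xβ + (η⊙X)γ + ε with spike-and-slab β (M_G non-zeros)
  and γ (M_GxE non-zeros), ε Gaussian.  C is the leading genetic PC (power
  iteration).  Reference design: N=25K, M=100K, L=30, L_active=6, M_G=2500,
  M_GxE=1250, h²_G=20%, h²_GxE=5%, covariate fraction 1%; causal counts are
  defined at M=100K and scale pro rata with M.
* **Exact variance budget:** each fixed component is rescaled so its
  in-sample variance fraction of var(y) hits the target exactly, with
  var(y)=1; the noise vector is residualized against the fixed components so
  the budget closes.  Small in-sample cross-covariances among the fixed
  components remain and are recorded in `SimTruth.fractions["cross"]`
  (the four fractions plus this cross term sum to 1 exactly).  This makes
  parameter-recovery tests sharp.
* Variants: three pairwise-orthogonal scores with disjoint interaction SNP
  sets, per-score scales set through the singular values of Λ = WΓᵀ
  (defaults 80, 60, 40); and a misspecified phenotype
  y = α_s·S² + y_baseline where S is itself heritable (30%, 2500 causal
  SNPs at M=100K pro rata) and replaces the last environment column.

The (+SQE) pre-screen regresses y on [C | E_l²] per environment (so it
adjusts for the linear environmental terms already in C, rather than testing
marginally) and appends squared columns with p < 0.01/L to C.

## Problem sizes used in the test suite

Full-scale replication (N=100K, M=300K, and the biobank analyses the method
targets) is out of desk scope.  The packaged checks use:

* Recovery battery: 10 datasets at N=5000, M=10000, L=10, L_active=6,
  M_G=250, M_GxE=125, B=50 probes, 10 LM restarts.
* Null calibration: 200 datasets at N=2000, M=5000, L=5, B=10, 2 restarts.
* MEMMA/GPLEMMA concordance: 15 datasets at N=2000, M=5000, L=5, B=30,
  3 restarts.
* Screen calibration: 1000 null datasets at N=150, L=5.
* Dense-oracle and Jacobian checks: N ≤ 50, M ≤ 60, L ≤ 3.

## Known behavior and limitations

* **Small-sample upward bias of the GxE PVE.**  Both constrained estimators
  (GPLEMMA, and MEMMA after zero-truncation) are built from nonnegative
  quadratic forms, so their GxE estimates overshoot when the per-component
  sampling noise is comparable to the signal.  At the reduced recovery scale
  (N=5000, M=10000) the mean GPLEMMA GxE PVE is ≈7% against a simulated 5%,
  shrinking to ≈6.7% at N=10000 and ≈5.8% at N=20000 (same M), while MEMMA's
  signed (raw) estimate is centered on the truth.  The bias decreases with N
  and grows with L; at biobank scale it is small.  Under a complete null the
  GPLEMMA GxE PVE is strictly positive by construction — its null mean
  cannot be zero; use MEMMA's raw components for signed null inference.
* MEMMA standard errors are not computed (no jackknife implemented);
  `ComponentEstimates.se` is reserved.
* Quantitative traits only; no binary-trait or liability-scale support, no
  single-SNP GxE tests, a single score only (no multi-score partition), no
  BGEN/VCF dosages, no distributed execution.
* Determinism is guaranteed at one BLAS thread; multi-threaded runs may
  differ in the last bits through accumulation order.
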