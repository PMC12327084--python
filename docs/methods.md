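# Methods

This note records the models, the synthetic-data design and the numerical
choices behind `dmriage`, in enough detail to reproduce or audit any stage.

## Units and acquisition model

b-values are stored internally in ms/µm² and diffusivities in µm²/ms, so the
fixed compartment priors are the familiar numbers d∥ = 1.7 and
Diso = 3.0 µm²/ms.  FSL-dialect I/O (s/mm²) divides by 1000 on load.  Volumes
with b ≤ 0.05 ms/µm² (50 s/mm²) count as b0; shells are distinct b-values
after rounding to a 0.05 ms/µm² grid, tolerating scanner-reported jitter.
Neither threshold is a measured fact about any particular scanner — they are
conventions, configurable at the call sites.  The default synthetic scheme
mirrors a two-shell lifespan protocol: three b0 volumes plus 30
quasi-uniform (spherical Fibonacci) directions repeated at b = 1 and
b = 2 ms/µm².

Wherever a model needs a fixed S0, it uses the mean over b0 volumes; no fit
silently re-estimates it.

## Mean-signal DKI

Powder averaging is the arithmetic mean of a shell's directional signals.
For synthetic schemes whose directions form a Gauss–Legendre × uniform-azimuth
product grid, `powder_average` accepts matching quadrature weights, making
the average an exact spherical integral; this is what turns the
configuration-invariance of MSD/MSK into a machine-precision identity in the
tests, while the 30-direction arithmetic mean agrees to ~2%.

The cumulant model `log S̄(b)/S0 = −b·MSD + b²/6·MSD²·MSK` (the O(b³)
remainder is truncated) is fitted by WLLS on the design `[1, −b, b²/6]`:
an OLS first pass, weights equal to the squared predicted signals, exactly
one reweighting iteration.  With the two-shell design this is an exact
interpolation on noise-free data, which is why the brute-force
(grid + polish) oracle agrees to ~1e-13.  MSD is clipped at zero with a
flag; MSK is deliberately *not* constrained non-negative — implausible
negative kurtosis estimates are themselves a data-quality signal and are
reported with a flag.

## Full DKI

The 22-parameter log-linear model (log S0, six tensor elements, fifteen
MD²·W elements with multinomial multiplicities in the design) uses the same
one-step WLLS convention.  Scalar kurtosis metrics are computed numerically
from the apparent kurtosis K(n) = (MD/D(n))²·W(n): MK as the mean over a
1000-point spherical Fibonacci set, RK over 180 equally spaced directions in
the plane perpendicular to the principal eigenvector, AK along it.  The
numerical (rather than closed-form) averaging is an implementation choice;
its discretization error is far below the tolerances used anywhere in the
pipeline (the Gaussian-tensor check comes back < 1e-6).

## NODDI

The three-compartment model with Watson-dispersed sticks:

* Watson normalization M(1/2, 3/2, κ) = ∫₀¹ e^{κt²} dt via
  `scipy.special.hyp1f1`, switching to the asymptotic expansion
  e^κ/(2κ)·Σ(2m−1)!!/(2κ)^m above κ = 700 (beyond κ ≈ 709 the true value
  exceeds double range and saturates at +inf; all internal weight
  computations are shifted into the log domain, so no working path can
  overflow at any κ).
* Eia by fixed-order spherical quadrature: 60-point Gauss–Legendre in
  t = cos θ on [0, 1] (antipodal symmetry) × 60 uniform azimuths,
  self-normalized so the b = 0 attenuation is exactly 1.  The dense
  (240×240) oracle agrees to ~1e-14 over κ ∈ [0.1, 64] — far inside the
  1e-4 contract.  κ > 1e5 uses the analytic parallel-stick form.
* Eea in closed form: ⟨De⟩ = d⊥I + (d∥−d⊥)(τ₁μμᵀ + (1−τ₁)/2(I−μμᵀ)) with
  τ₁ = ₁F₁(3/2,5/2,κ)/(3·₁F₁(1/2,3/2,κ)) and the tortuosity constraint
  d⊥ = d∥(1−Fia).

The fit holds S0 at the b0 mean and minimizes unweighted squared residuals
on signal amplitudes over (Fiso, Fia, κ, μ).  μ initializes from the
log-linear DTI principal eigenvector; a coarse grid over
Fiso ∈ {0,…,0.9} × Fia ∈ {0.1,…,0.9} × κ ∈ {0.25,…,32} (ties broken toward
the lowest objective, then the lowest Fiso) seeds a Levenberg–Marquardt
refinement in transformed coordinates (logistic fractions initialized at
least 0.03 from the boundary so the transform keeps a live gradient, log κ
clipped to [0.01, 128], spherical angles for μ).  A second fixed mid-range
start (0.15, 0.55, 3.0) guards the Fiso/Fia trade-off degeneracy near the
boundary.  Voxels with Fiso > 0.9 are unidentifiable in (NDI, ODI); the
degenerate convention (NDI → 0, ODI → 1, flagged) is applied as an explicit,
separate step.

Estimator accuracy at the default design: noise-free recovery over the
5×5×5 acceptance grid is exact to ~1e-6 per parameter.  Under Rician noise
at SNR = 20, NDI and ODI recover with median absolute errors ≈ 0.044 and
0.012, while Fiso sits at ≈ 0.05 — the identifiability limit of this
63-volume protocol for the free-water fraction, not an optimizer artifact
(fits reach lower objectives than the ground truth, and a Rician-likelihood
refinement did not improve the medians, which is why the simpler pinned
least-squares objective is kept).

## Rician noise

Magnitude noise is applied as √((v+ε₁)² + ε₂²), ε ~ N(0, σ²), σ = S0/SNR,
to every volume including b0.  This reproduces the Rayleigh floor at v = 0
(mean σ√(π/2)) and the upward bias of low-SNR shells that motivates the
robustness of mean-signal metrics.

## Synthetic cohort

The generator produces, for n = 636 participants with uniform ages 18–88 and
a balanced two-level sex variable, per-(participant, ROI, metric) values in
standardized units:

y = ω_r(t1·a + t2·q) + β·x + L·(s∘η) + √u·ε_p + √u_roi·e

with a the population-standardized age, q the orthogonalized quadratic
((a²−1)/√0.8 for uniform a), x = ±½ sex, η age-free unit-normal factor
innovations, ε participant-level and e ROI-level residuals.  Full factor
scores are γ₁a + γ₂q + s·η, so the age effects flow mainly *through* the
factors — matching the observation that the latent factors, not the
individual metrics, carry the ageing signal — and the direct corrections
c = t − Lγ folded into (t1, t2) hold each metric's population
(R²_linear, ΔR²_quadratic) exactly at its target.

Defaults are the emulated study conditions: per-metric signed targets
(FA −0.20/0, MSD +0.41/+0.13, MSK −0.25/−0.09, NDI −0.14/−0.07,
ODI +0.01/+0.05, Fiso +0.27/+0.04), a 1% sex-variance share, and a 6×3
loading pattern — F1 microstructure (+MSK +NDI +FA, −MSD), F2 free water
(+MSD +Fiso), F3 complexity (+ODI −FA).  Loading magnitudes were solved
once, by population algebra with no sampled data, so that (i) three
correlation-scale eigenvalues exceed 1 (Kaiser retains 3), (ii) the three
retained components carry ≈95% of the 6-metric variance, and (iii) the
per-metric uniqueness stays near 0.03; the resulting population eigenvalues
are (3.43, 1.16, 1.11, …).  Factor-score trajectories default to an
inverted-U for F1 (decline-dominant), an accelerating increase for F2 and a
mild increase for F3.  Per-ROI age-effect multipliers ω_r (linspace
0.7–1.3, mean exactly 1) make the per-ROI R² ranking non-trivial while
leaving the global (ROI-averaged) targets intact.  The 12-metric variant
adds MD/RD/AD (free-water-like) and MK/RK/AK (microstructure-like) rows
plus a fourth, age-free latent source loading only on MK/RK/AK; its
population λ₄ ≈ 0.50 keeps Kaiser at 3 while pushing the 95%-variance count
to ≥4.

**Ground truth for factor recovery.**  Because all factor scores share the
age terms, the planted pattern matrix is identified only up to a rotation of
its span; the well-defined recovery target is the *population varimax
solution* — PCA + varimax applied to the exact population correlation matrix
implied by the configuration (computed analytically, no sampling).  The
generator returns it alongside the raw loadings; the raw span is separately
checked via principal angles (≤5°) after age removal.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: registration and atlas-warping error, motion and
Gibbs artefacts, white-matter hyperintensities, spatially correlated noise
across ROIs, non-uniform age sampling, and any non-Gaussian tail structure
of real metric distributions.  The planted-factor model is an idealization:
real metric covariance is not exactly low-rank plus diagonal.

## Cohort statistics

* Hierarchical R²: age is centred and scaled before polynomial expansion
  (increments are affine-invariant); increments accumulate in the order
  linear → quadratic → sex → sex×age, each as an R² difference of nested OLS
  fits, floored at 0.
* Outlier passes are single-pass by construction: residual mode (global
  stage) removes participants with any |standardized residual| > 5 across
  metrics, then refits once; value mode (ROI stage) removes participants
  with any |z| > 5, after which the survivors are re-standardized.  Sex is
  dropped from all stages after the global models.
* Subgroup correlations use inclusive bounds [28,47], [48,67], [68,87];
  Pearson r is computed by vectorized matrix algebra with exact t-distribution
  p-values (verified identical to `scipy.stats.pearsonr`), and
  Benjamini–Hochberg FDR (`statsmodels.multitest`) is applied jointly across
  the full subgroup × metric × ROI grid (Benjamini–Yekutieli behind a flag).
* Factor extraction is PCA of the column correlation matrix of the pooled
  participant×ROI observation matrix (rows with any missing metric dropped
  with a logged count), loadings = eigenvector·√eigenvalue, Kaiser retention
  (strictly > 1), then varimax without row normalization
  (statsmodels GPA, tol 1e-10; an independent pairwise-rotation oracle backs
  it in the tests), with each factor's largest-|loading| entry made
  positive.  Factor scores are regression scores X L(LᵀL)⁻¹, averaged per
  participant before age-profile fitting.

## Problem sizes and determinism

Default experiment sizes — 125 noise-free + 100 noisy NODDI fits, 1000
MSDKI oracle comparisons, 500 null FDR replicates, 200 cohort replicates for
the R² partition, one full cohort per factor-analysis variant — were chosen
so the whole verification cycle completes in a few minutes on a single CPU
while keeping Monte-Carlo error well below the decision margins (the R²
means, for instance, carry a standard error of ~0.004 at 200 replicates).
Every stochastic step takes an explicit seed; a master seed expands into
fixed offsets per stage, and repeated runs are byte-identical.

## Known limitations

* Fiso recovery at SNR = 20 sits at the 0.05 median-error boundary (see the
  NODDI section); protocols with more b0 volumes or a third shell would be
  required to do better.
* The 12-metric synthetic variant needs 5 components for 95% cumulative
  variance at the default residual level (the structural point — more than
  three — is what the pipeline tests).
* DKI fitting is unconstrained: no positive-definiteness, no RESTORE-style
  outlier rejection; implausible fits are flagged, not repaired.
* The NODDI fit uses least squares on amplitudes rather than a Rician
  likelihood; at the SNRs simulated here the difference was measured to be
  negligible, but at substantially lower SNR a likelihood-based refinement
  would be the right extension.
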