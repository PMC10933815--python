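# Methods

## The decomposition

Stage 1 of dual regression extracts, for one subject, the network
timeseries `D = (GᵀG)⁻¹GᵀX` from the voxel-by-time BOLD matrix
`X ∈ ℝ^{N×T}` and the group spatial maps `G ∈ ℝ^{N×K}` (signed Z-statistic
weights, one column per resting-state network).  Three per-network scalars
summarize the subject:

* **network amplitude** `a_k = sd(d_k)` — the conventional summary of a
  network's fluctuation strength;
* **temporal synchrony** `â_k = sd(d̂_k)`, where `D̂` is the same regression
  applied to the voxelwise z-scored data `X̂`.  Setting every voxel's SD to
  one removes raw fluctuation size, so `â_k` responds only to how
  coherently the map's voxels move together (and to the map weights);
* **BOLD amplitude** `ȧ_k` — the mean of per-voxel timeseries SDs over
  the voxels with `|g_k| > 3.29` (two-sided normal quantile for
  P = 10⁻³).  Two weighted alternatives are provided (`gᵀv/N` and
  `sqrt((g∘g)ᵀ(v∘v))`); across subjects the three variants correlate
  above 0.9 on the standard synthetic cohort.

Because `sd(c·x) = c·sd(x)` and z-scoring is invariant to per-voxel
positive affine maps, amplitude and BOLD amplitude are homogeneous of
degree one in the data while synchrony is homogeneous of degree zero.
When every voxel has the same SD σ and zero mean, `a_k = σ·â_k` exactly;
`sigma_identity_check` verifies this identity on demand.

Numerical choices: the regression is solved with an LAPACK least-squares
factorization (gelsd), never an explicit inverse; `GᵀG` condition numbers
above 10¹² are rejected with the offending value in the error.  All SDs
use the sample (T−1) denominator; the choice cancels in every
across-subject correlation but matters when comparing against closed
forms, which the tests do with the explicit `sqrt(n/(n−1))` factor.
Thresholding uses the strict inequality `|g| > z`.  `(GᵀG)⁻¹` is always
applied even though it is constant across subjects; exactness is
preferred over the micro-optimization.

The threshold sweep recomputes synchrony from suprathreshold voxels only.
For network k the regression keeps all K map columns but restricts the
rows to `mask_k` — i.e. row k of `(G_mᵀG_m)⁻¹G_mᵀX̂_m` — so with a zero
threshold it reproduces the full regression exactly; a single-column
variant (`mode="single"`) is available for comparison.

## The synthetic cohort

The generator plants both amplitude factors independently so every
downstream stage can be validated against ground truth.  A voxel whose
primary network is k follows, for subject s,

    x_i(t) = σ_{s,k} · ( √ρ_{s,k} · sign(g_ki) · s_k(t)
                         + √(1−ρ_{s,k}) · ε_i(t) + noise_sd · η_i(t) )

with `s_k` shared latent network signals, `ε_i` independent band-limited
noise and `η_i` white noise.  Key design points:

* **Latent signals** are white Gaussian noise low-pass filtered at 0.1 Hz
  for TR = 0.735 s (a 4th-order Butterworth, filtfilt), then standardized
  to exact unit sample SD.  The exact standardization matters: realized-SD
  fluctuations of a shared signal would hit every voxel of a network at
  once and correlate amplitude with BOLD amplitude spuriously at finite T.
  The 0.1 Hz cut-off is a convention, exposed in the config.
* **Between-network correlation** is induced by mixing independent
  factors through the Cholesky factor of the target matrix, giving an
  analytic true FC for oracle tests.  On top of that,
  `fc_synchrony_coupling` (γ, default 1) scales network k's participation
  in the shared factors by `ρ_k^{γ/2}`: more-synchronous networks couple
  more strongly to the rest of the brain, which is what makes
  amplitude–FC correlations positive within and across subjects, as in
  real resting-state data.  γ = 0 restores the decoupled model with the
  configured latent correlation exactly.
* **The noise term sits inside the σ factor** so that the two planted
  factors act exactly independently: scaling `voxel_sd_range` by c
  multiplies every amplitude measure by c to rounding error and leaves
  synchrony untouched.  An additive unscaled noise term would break this
  separability, which the test suite asserts at 1e−10.
* **Planted covariation structure.** Per-subject synchrony values mix a
  shared factor per cluster (a fixed 2-block partition of the networks)
  with network-specific variation, weighted 0.7/0.3, so amplitude
  covariation is block structured and Ward clustering can be scored
  against the planted partition.  Voxel-SD scales instead share one
  global factor, so BOLD-amplitude covariation carries no block
  structure — clustering amplitude or synchrony recovers the partition,
  clustering BOLD amplitude does not.
* **Defaults are the emulated acquisition conditions**: T = 490 timepoints at
  TR = 0.735 s, K = 6 networks over N = 400 voxels for desk-scale runs,
  S = 200 subjects, synchrony ρ ~ U(0.2, 0.9), voxel-SD scale
  σ ~ U(0.8, 1.2), relative noise 0.5.  The ±20% σ spread encodes that
  intersubject variation in raw BOLD fluctuation size is modest relative
  to synchrony variation; under these conditions synchrony explains
  roughly 70% of amplitude variance and BOLD amplitude roughly 25%,
  with recovery correlations of planted ρ and σ above 0.95.
* **Geometry** is a flat 1-D voxel grid (contiguous network blocks,
  `overlap_fraction` of each support shared with the next network,
  `neg_weight_fraction` of weights negative).  No downstream computation
  uses spatial adjacency; NIfTI export reshapes into a padded 3-D box
  purely for interoperability.
* **Phenotypes** are linear in the z-scored cluster means of the planted
  factors plus confound leakage and unit Gaussian noise; missingness is
  completely at random.  What the generator does *not* emulate:
  hemodynamic response shapes, spatially realistic anatomy, scanner
  artifacts and motion, non-MCAR missingness, non-linear
  phenotype–imaging relations.  Passing tests therefore demonstrate the
  estimators' algebra and statistical calibration, not robustness to
  those real-data complications.

## Connectivity, clustering, associations

**Netmats.** Partial correlations from the inverse covariance
(`C_ij = −P_ij/√(P_ii P_jj)`), optional ridge `λ·mean(diag(cov))` on the
diagonal (default 0 — appropriate when T ≫ K), full correlation behind a
flag.  Per-network summary FC is the mean of |r|, of positive r, and of
negative r over the network's off-diagonal row; an empty sign class is a
missing value, not a zero.

**Clustering.** Ward linkage on Euclidean distances between rows of the
across-subject correlation matrix (each network's correlation profile is
its feature vector); `sqrt(2(1−r))` pairwise dissimilarity available as an
alternative — both recover a planted 2-block partition exactly.  Cluster
amplitudes are unweighted means of member networks, reported per subject.

**Deconfounding** residualizes each column on the confounds plus an
intercept using complete rows, preserving NaNs; it is idempotent and
leaves residuals orthogonal to every confound at 1e−10.

**Imputation** is iterative soft-thresholded SVD completion: standardize
columns, mean-fill, replace missing cells by the reconstruction with
singular values shrunk by `λ = shrinkage·s₁`, iterate to a relative
tolerance.  Because iterating directly at a tiny λ barely moves the
imputed cells, the solver anneals λ geometrically from 0.3·s₁ down to the
target with warm starts — the standard path strategy for nuclear-norm
problems — which recovers a noiseless rank-1 matrix to 1e−6 as λ→0.
Observed entries are returned bit-exactly.  Default shrinkage 0.1,
tol 1e−6, max 200 iterations per level.  Imputed tables feed only the
regression models; correlations use pairwise-complete original data.

**Mass correlation** reports Pearson r with t-distribution p-values
(n−2 df), −log₁₀ p computed in log space so associations far beyond float
underflow remain finite, a Bonferroni flag at α/(number of variables) and
a stringent flag at P = 10⁻²⁰ (≈ |r| > 0.05 at n = 37,842).  The optional
age adjustment residualizes age from both sides and is exactly equivalent
to explicit residualization.  With two measure columns the signed
difference of −log₁₀ p is attached per variable.

**Dependent correlations.** Two overlapping correlations r(x₁,y), r(x₂,y)
on one sample are compared with Dunn & Clark's z using Hittner's
backtransformed-average modification: the covariance term
`c(r₁₂, r̄) = (r₁₂(1−2r̄²) − ½r̄²(1−2r̄²−r₁₂²))/(1−r̄²)²` uses
`r̄ = tanh((z₁+z₂)/2)`, and `z = (z₁−z₂)√((n−3)/(2−2c))`.  The plain-mean
variant (`dunn1969`) is exposed behind a flag.  Identical or affinely
identical measures return p = 1 by construction.  Calibration: type-I
error at α = 0.05 sits inside its binomial 95% interval over 2000 null
replicates (n = 500, r₁ = r₂ = 0.3, r₁₂ = 0.6), and decisions agree with
a swap-permutation oracle under strong alternatives.

**Regressions.** Per network and measure, OLS of the z-scored measure on
z-scored predictors (systolic blood pressure, body fat %, haemoglobin,
sleep duration, age) plus sex (0/1, not normalized) and the derived
columns age×sex, age², age²×sex built from z-scored age and raw sex
without re-normalization.  Bonferroni correction is applied within each
(measure, predictor) family across the networks; the family choice is a
convention and is documented where used.  Two-sided p-values throughout.

## Design decisions that were genuinely open

* `v` in the BOLD-amplitude definitions is the vector of per-voxel
  standard deviations (not variances): only SDs make all variants
  homogeneous of degree one, which the halving behaviour requires.
* The restricted regression of the threshold sweep keeps all K columns
  (see above); the single-column variant is switchable.
* Bonferroni families: networks × FC types for the amplitude–FC table;
  networks within (measure, predictor) for the regression panel.
* Ridge default 0 for netmats since T ≫ K in the emulated acquisition.
* Missingness is MCAR; nothing downstream estimates a missingness model.
* The 2-block partition is fixed (first half / second half of networks);
  cluster count defaults to 2 with the full linkage exported for other
  cuts.

## Problem sizes

Default test and acceptance runs use the standard cohort (S = 200,
T = 490, K = 6, N = 400), a designed FC cohort (K = 10, T = 490, S = 100,
γ = 2 — the stronger coupling is needed for per-network FC claims to be
statistically powered at desk scale), 2000 replicates for test
calibration, and 400–500 replicates for regression calibration.  The full
suite runs in about a minute on one CPU.

## Known limitations

Voxel geometry is abstract; overlap is between consecutive networks only.
The generator's FC–synchrony coupling is a one-parameter stand-in for
whatever mechanism couples amplitude and connectivity in real data.
Partial-correlation summaries at small K are noisy, and per-subject
within-subject correlations over few networks are accordingly unstable.
No hemodynamic model, no motion, no multi-site structure.
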