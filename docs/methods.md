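# Methods

This note documents the models, the synthetic data, the numerical
choices and the known limitations of `gliomicro`. Units follow the
internal convention: b-values in ms/µm² (1000 s/mm² = 1 ms/µm²),
diffusivities in µm²/ms, so all exponents are O(1).

## Acquisition model

The protocol is two-shell linear tensor encoding: one b = 0 volume plus
25 near-uniform directions (Fibonacci hemisphere) at b = 1.25 and
b = 2.5 ms/µm². Shells are identified by greedy centroid clustering of
b-values within a tolerance (default 50 s/mm²). Gradient directions use
the FSL image-space dialect and are never reoriented; phantoms are
generated in the same frame, which removes any sign/flip ambiguity.
ROIs are in-plane discs of a physical diameter (default 6.0 mm) rendered
on the voxel grid; the physical diameter is authoritative, voxel counts
follow from the grid spacing.

## Tissue signal model

A voxel is a three-compartment system:

* intra-neurite **stick** with parallel diffusivity Da and zero
  perpendicular diffusivity,
* extra-neurite axially symmetric Gaussian (**zeppelin**) with
  independent De∥ and De⊥ (no tortuosity coupling in the simulator),
* isotropic free-water **ball** (d = 3.0 µm²/ms).

Stick and zeppelin are dispersed by a Watson or Bingham orientation
distribution. The Bingham density follows the convention in which the
two concentration parameters suppress probability along the two axes
perpendicular to the fiber, so κ₁ = κ₂ = κ reduces exactly to the
Watson distribution with concentration κ; dispersion fans preferentially
toward the κ₂ axis. The Watson normalization is the closed form
4π·M(1/2, 3/2, κ); the Bingham constant is computed by dense
Gauss–Legendre quadrature (128 × 128, machine precision at the κ ranges
used) and cross-checked in the tests against an independent
Dirichlet-moment series (on the sphere, (x², y², z²) ~ Dirichlet(½,½,½)).

Kernel–ODF convolution uses a product Gauss–Legendre × trapezoid grid
with the dense polar band rotated onto the principal orientation
(default 60 × 60 nodes; the simulator stays accurate for κ up to a few
hundred). ODF values are renormalized on the grid so convolution
weights sum to one exactly; b = 0 samples are set to S0 identically.

Rician noise is the magnitude of (S + N(0,σ)) + i·N(0,σ) with
σ = S0/SNR. The study does not state an SNR; the default SNR = 30 is a
typical 3 T diffusion value and is a configuration choice, not a
reported one.

## Model fitting

**DTI / DKI.** Two-step weighted linear least squares on log-signals
(OLS pre-pass, weights = squared predicted signals). DTI uses only
b ≤ 1.25 data; DKI uses both shells and fits 22 parameters
(lnS0, 6 D, 15 V) with W = V/MD². Directional kurtosis is
K_app(g) = V_app(g)/D_app(g)² per the log-quadratic signal form; MK is
the mean of K_app over a 250-point uniform set, AK evaluates it along
the principal eigenvector, RK averages a 64-point circle in the
perpendicular plane. Directional kurtosis is softly clipped to
[−3/7, 10] (clip + flag, not a constrained solver). Degenerate tensors
(λ₁ ≈ λ₂) fall back to the fixed eigendecomposition ordering and are
flagged. AWF uses the K_max convention: AWF = K_max/(K_max + 3) with
K_max the maximum directional kurtosis over a 724-point set, clamped at
zero for negative maxima.

**NODDI (Watson and Bingham).** Fixed intrinsic diffusivities
d∥ = 1.7 and d_iso = 3.0 µm²/ms and the tortuosity coupling
De⊥ = d∥(1 − V_ic) — the published model's own form, deliberately
different from the uncoupled simulator; the recovery tests therefore
generate data under the coupled assumption (`noddi_truth`). The fit is
deterministic: an 8 × 8 × 30 grid over (V_ic, ODI, orientation) whose
tissue predictions are precomputed per scheme, with V_iso solved in
closed form per candidate (the model is linear in V_iso), followed by
bounded Nelder–Mead from the three best grid candidates. The Bingham
variant parameterizes (κ₁, κ₂) as κ₁ = cot(π·ODI₁/2), κ₂ = κ₁/c with
c ≥ 1, so the ordering constraint holds by construction; it is
initialized from the Watson fit with three secondary-axis angles.
Conventions: ODI = (2/π)arctan(1/κ); Bin-ODI = (2/π)arctan(1/√(κ₁κ₂));
DAI = (2/π)arctan((κ₁−κ₂)/κ₂), 1 when κ₂ = 0 < κ₁, 0 when κ₁ = κ₂.
The DAI formula is a documented convention (the source literature's
exact variant is not restated in the clinical analysis this mirrors,
and the quantity was non-significant there, so no printed value
constrains it). Voxels with fitted V_iso ≥ 0.95 are flagged
ICVF-unidentifiable.

**SMI.** Per shell, signals are projected onto even real spherical
harmonics (lmax = 4; 15 coefficients from 25 directions) and collapsed
into rotational invariants S_l = ‖c_l‖/√(4π(2l+1)), so S₀ at b = 0
equals the b0 signal. The forward map factorizes as
S_l(b) = s0·p_l·|K_l(b)| with K_l(b) = ∫₀¹ K(b,ξ)P_l(ξ)dξ (64-point
Gauss–Legendre; the stick kernel's K₂ is negative, hence the magnitude
convention matching the norm-based invariants). The l = 4 band is kept,
with p₄ tied to p₂ through the Watson ODF family (interpolated κ grid
up to 10⁶ plus the analytic delta limit).

Estimation is two-stage and deterministic given a seed:

1. *Polynomial regression.* 50 000 parameter sets are sampled from
   documented priors — (f, fw) uniform on the simplex, Da, De∥ ~ U(0,3),
   De⊥ ~ U(0, De∥), p₂ ~ U(0,1) — mapped through the kernel, and a cubic
   polynomial regression from the six invariants to the six parameters
   is fitted once per protocol. Its per-parameter training R² is
   attached to every fit so the weak identifiability of (Da, De∥) at a
   two-shell LTE protocol is visible to users.
2. *Exact inversion with branch selection.* The noise-free two-shell
   problem is two-branched: multi-start root finding shows that e.g.
   (f, Da, De∥, De⊥, fw) = (0.5, 2.2, 1.5, 0.6, 0.05) shares its
   invariants exactly with (0.16, 2.44, 1.54, 0.23, 0.15). A regression
   alone therefore averages branches and cannot recover parameters
   pointwise — its error at such points (~0.1 on f) is the Bayes limit
   under the priors, not a fitting defect. The second stage runs
   trust-region least squares from a fixed 12-point start set (the
   regression estimate plus a frozen quasi-random design) and keeps,
   among near-exact solutions, the Da ≥ De∥ branch with the largest
   intra-neurite fraction: the spurious dual systematically has a
   markedly lower f and De⊥ than brain tissue supports. The number of
   distinct branches found is reported per voxel.

**CSD / AFD.** The single-fiber response is estimated from voxels above
an FA threshold (default 0.7) by projecting their b = 2.5 shell onto
even Legendre polynomials in (g·e₁) and averaging; a large coefficient
CV across voxels flags a contaminated response. Deconvolution follows
the Tournier scheme: SH forward matrix scaled by 4π·r_l/(2l+1),
Tikhonov-reweighted nonnegativity on a 724-point grid, iterated until
the active set stabilizes (cap 50). AFD-total is the fODF's sphere
integral √(4π)c₀₀; lobes are watershed basins of the positive fODF on a
dense Fibonacci mesh (steepest-ascent assignment, antipodal basins
merged), AFD-max is the largest lobe integral and AFD-sum the sum of
lobes above a relative threshold (default 0.1 × largest). Because the
lmax = 4 fODF may carry small negative ripples, lobe sums are only
bounded by the total integral for non-negative fODFs.

## Statistics

Continuous two-group comparisons are routed by Shapiro–Wilk at
α = 0.05 on each group: pooled-variance t-test when both pass (Welch
when Levene rejects homogeneity), otherwise Mann–Whitney U with normal
approximation and tie correction. Categorical tables use Pearson
chi-square without continuity correction — this convention reproduces
the published clinical-table p-values this package re-tests (margin
0.010, grading 0.020 at N = 47 with unknown grades dropped, midline
0.882, location 0.571, size 0.154); the published gender row (0.971) is
not reproducible under any standard convention and is not asserted.
ROC analysis computes the AUC by the Mann–Whitney identity with
half-credit ties, flips orientation (flagged) so AUC ≥ 0.5, takes
DeLong variance for the 95% CI and the paired Z-test, and picks the
operating point at maximal Youden J (ties → lowest threshold). No
multiple-testing correction is applied to the per-metric p-values,
mirroring the source analysis; a Benjamini–Hochberg column is emitted
alongside.

ROI aggregation averages ROI means with equal weights (not pooled
voxels); both raw and contralateral-WM-normalized features can be
produced, since the source analysis is ambiguous about which entered
its ROC table.

## OPLS-DA

Labels are coded ±1 and centered; X is mean-centered and unit-variance
scaled (the common chemometrics default). Orthogonal components are
removed sequentially (w from X'y; w_o ∝ p − (w'p)w; deflation by
t_o·p_o'), then a single predictive component is fitted. With
n_ortho = 0 the model is exactly PLS1 (tested against an independent
NIPALS oracle). VIP is the predictive-component variant
√p·|w|, whose squared values average to one. Q2Y = 1 − PRESS/SS with
stratified 7-fold out-of-fold predictions, seed-reproducible. The
permutation test refits on label permutations, records (R2Y, Q2Y)
against |corr(y_perm, y)| and reports the OLS intercepts including the
unpermuted point; both the training-score and cross-validated-score
ROCs are emitted, since reports of this model class do not always say
which is quoted.

A Q2Y-maximizing forward-addition rule for the number of orthogonal
components (stop at ΔQ2Y < 0.01, cap 3) is implemented
(`n_ortho="auto"`), but the pipeline default is a fixed single
orthogonal component: on the synthetic cohorts the auto rule
measurably degrades out-of-fold performance at n = 48 (component-count
selection overfits inside the folds).

## Synthetic cohorts: what they emulate and what they do not

The **feature-level** generator draws the 21 per-patient metrics
directly from a per-group effect table. For the `paper-like` preset the
effect size of each metric is set from its reported single-feature ROC
AUC, d = √2·Φ⁻¹(AUC), with the reported sign (higher AFD/AWF/FA/
AK/MK/RK/ICVF/Bin-ICVF/De∥/f, lower AD/MD/RD/De⊥/fw in recurrence; Da,
ODI, Bin-ODI, DAI null), so each metric's two-group separability matches
its reported discriminability by construction. Cross-metric correlation
uses two latents per patient — a global severity factor
(ρ_global = 0.15) and one factor per reconstruction family
(ρ_family = 0.35) — yielding the strong-within-family /
weak-across-family block structure seen in such data. Marginals remain
exactly Gaussian with the stated means and SDs. The `null` preset zeroes
every effect. Clinical covariates are drawn with the published per-group
category frequencies (descriptive only).

The **signal-level** generator simulates small 4D volumes whose tumor
ROI voxels come from group-shifted microstructure truths (recurrence:
higher stick fraction, lower free water and De⊥) plus a fixed healthy
contralateral white-matter ROI, with Rician noise; it exercises the full
fit → aggregate → statistics path.

What passing tests therefore show: the estimators recover their own
generating models, the statistics are calibrated (pooled null type-I
error 0.03–0.07; mean null Q2Y ≤ 0), and the multiparametric model adds
discriminative value over single metrics under realistic effect sizes.
What they do not show: robustness to real-tissue deviations (exchange,
noise floor, partial volume beyond three compartments, anatomy,
B-tensor shapes β ≠ 1), none of which are modeled.

One calibration check is known to sit at its own threshold: requiring
the model's out-of-fold AUC to beat the *in-sample maximum* of 21
single-feature AUCs in ≥ 90% of 100 cohorts compares an honest statistic
with one carrying max-statistic optimism (~+0.02–0.03 AUC at n = 48).
Measured over 1000 cohorts the win probability is 0.883 ± 0.010 — the
model's population AUC (~0.95) exceeds every single feature's (best
0.885 by construction), but this finite-sample operationalization falls
marginally short of 0.90 and the corresponding test is expected to fail
by a small margin.

## Problem sizes and determinism

Recovery suites use single voxels to a few hundred voxels per model;
calibration uses 200 null and 100 effect cohorts of 48 patients and a
200-permutation test — sizes chosen so the whole suite runs in a few
minutes on one CPU. Every stochastic stage derives its generator from
an explicit seed (`numpy` `SeedSequence` with named spawn keys); the
NODDI and CSD fits and the SMI refinement stage contain no randomness
at all, and pipeline reruns with the same config and seed are
byte-identical.
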