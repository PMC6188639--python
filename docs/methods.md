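# Methods

## Model family and conventions

A stimulus is a raster image flattened to a column vector in
last-dimension-first order (colour band fastest); luminance is in cd/m²
after an explicit calibration scalar (no canonical default exists, so it is
always a configuration value).  A model is a feed-forward cascade of layers
`x^i = N^(i)(L^i x^{i-1})`.  Jacobians are rows-of-outputs ×
columns-of-inputs; `sign(0) = 0` everywhere, so all nonlinearities are odd
and map 0 to 0.  Matrix-valued parameters are flattened row-wise in the
packed parameter vector Θ, and the derivative of a linear stage with respect
to its own weights uses the block-replication identity
`B(vᵀ)_d · vect(ΔLᵀ) = ΔL·v`.

## Nonlinearities

**Divisive normalization (DN).**  With energy `e = |y|^γ` and denominator
`D(e) = b + H·e` (`b > 0`, `H ≥ 0`), the response is
`x = D_sign(y)·D_{D(e)}^{-1}·e`.  Its input Jacobian is
`D_sign·D_{D}^{-1}·[I − D_{e/D}·H]·D_{γ|y|^{γ-1}}·D_sign`; the interaction
is subtractive (reduces the slope), and for γ ≠ 1 the recombination of the
linear filters is itself signal dependent.  Parameter Jacobians for γ, b and
H, and for the Gaussian-kernel parameterization
`H_kk' = c_k·dp/(2πσ_k²)·exp(−Δ²_{kk'}/2σ_k²)` (intra-subband only, row
pool `Σ_k' H_kk' ≈ c_k`), are closed form; `σ_k` and `c_k` parameterize row
k of H, so `∇_σ N` and `∇_c N` are diagonal, with entries
`−sign(y_k)·e_k/D_k²·(Fe)_k` and `−sign(y_k)·e_k/D_k²·(Ge)_k`, where
`F = ∂H/∂σ` and `G = H/c`.  Sharing parameters across sensors (e.g. one σ
per subband) is expressed by right-multiplying these Jacobians with a binary
structure matrix.  The analytic inverse is
`y = D_sign(x)·[(I − D_|x|·H)^{-1}·D_b·|x|]^{1/γ}`; it exists iff the
spectral radius of `D_|x|·H` is below 1, and a truncated Neumann series
(default order 10, with an a-posteriori residual check at 1e-8) can replace
the linear solve.  Two numerical choices: for γ < 1 the `|y|^{γ-1}` factor
in the Jacobian floors |y| at η = 1e-6 (stimulus units) to stay bounded —
this affects the Jacobian only, never the forward map; and at `y_k = 0` the
sign factors null the corresponding row/column of the Jacobian, which we
keep (zero sensitivity exactly at the origin).  The γ-derivative requires
`log|y|` and therefore rejects inputs with exact zeros.

**Wilson–Cowan steady state.**  `0 = −αx + μW f(x) + λy` with a named,
swappable sigmoid (default `tanh`, unit slope).  The inverse is closed form;
the forward map is computed by damped fixed-point iteration
(`κ = 0.8`, tol 1e-10, max 10000 iterations, root-solver fallback), and a
sufficient contraction condition `α > μ‖W‖_∞ sup|f'|` is enforced at
construction (it is sufficient, not necessary — a deliberate conservatism
since general uniqueness conditions are not available in closed form).  The
forward Jacobian is the matrix inverse of
`∇N^{-1} = (αI − μW·D_{f'(x)})/λ`.

**Two-gamma tone mapping.**  `x = sign(y)|y|^{γ(|y|)}` with
`γ(a) = γ_H − (γ_H−γ_L)·μ₁^m/(μ₁^m + a^m)`.  Below a patch radius ε
(default 1e-3 in normalized input units) the curve is replaced by
`sign(y)(a₁|y|² + a₂|y|)` with `a₁ = (ε g'(ε) − g(ε))/ε²`,
`a₂ = (2g(ε) − ε g'(ε))/ε`, `g(a) = a^{γ(a)}` — these coefficients make the
patched curve C¹ at ε (verified as a unit test) and give a finite slope a₂
at 0.  The inverse is a per-component monotone root find (closed-form on the
quadratic branch, bracketed Brent outside); monotonicity of the curve is
checked on a grid at construction and non-monotone parameter combinations
are rejected.

## Global calculus

`∇_{x0}S` is the ordered product of per-layer `∇_y N^(i)·L^i`; `∇_Θ S`
concatenates, per layer and parameter, the local derivative propagated
through the remaining layers.  `∇_Θ S^{-1} = −(∇_{x0}S)^{-1}∇_Θ S` links the
decoder's parameter sensitivity to the forward quantities.  All analytic
expressions are validated against an independent central finite-difference
oracle (default step `1e-6·max(1,|value|)`); Jacobians are materialized
densely (the package targets desk scale, d ≲ 4096), with a lazy
vector–Jacobian product for the MAD gradient.

## Geometry and information

Perceptual distance is the Euclidean distance between responses (a
non-quadratic response norm would forfeit the quadratic-form expansion that
makes the metric `M = JᵀJ` and its eigen-structure available).  Sensitivity
is `det M` (Gram determinant for rectangular Jacobians, with a warning).
Multi-information reduction is estimated as
`ΔMI = Σh(x⁰_k) − Σh(x^n_k) + E[log₂|det ∇S|]` with equal-width histogram
marginal entropies (⌈n^{1/3}⌉ bins, Miller–Madow bias correction); the
identity `ΔMI = Δh + jac_term` holds by construction, samples with singular
Jacobians are dropped and counted, and everywhere-singular models are
rejected.

**A structural note on Δh.**  Because the per-cell stimulus ensembles of the
luminance × contrast grid are affine copies of one another, their
multi-information `MI(x⁰)` is identical across cells; hence the luminance
and contrast dependence of Δh and of the Jacobian term must cancel in their
sum wherever ΔMI itself is flat.  Since the Jacobian term varies strongly
across the grid (that variation *is* the sensitivity trend), Δh varies
comparably under these study conditions — measured with the package
defaults, the range of Δh across the 7×9 grid is of the same order as (in
fact larger than) the range of ΔMI, for both per-sample and ensemble-level
moment adjustment.  The corresponding near-constancy claim in the acceptance
suite is therefore expected to fail under these conditions; the estimator
itself is validated against the Gaussian closed form (exact for invertible
linear maps on correlated Gaussians).

## MAD synthesis

From a seeded white-noise start on the RMSE sphere, each step moves along
±λ·∇D_P, removes the component parallel to the Euclidean-distance gradient,
and solves analytically for the constant ν that re-projects onto the sphere
(of the two roots, the one nearer the pre-projection point; λ is halved when
no real root exists).  A backtracking line search enforces monotone distance
traces, the step grows by 1.3 after each accepted move, and the default
initial step is `0.1·radius/|∇D_P|`.  The analytic route takes the
eigenvectors of `M(x_A)` with extremal eigenvalues; in patch mode (default
patch size 0.65 deg) the metric keeps only its diagonal blocks, so the
global extremal directions are per-patch eigenvectors embedded in the full
space (exact when the model is genuinely patch-separable; edge artifacts
are accepted otherwise).  Ties between extremal eigenvalues are broken
deterministically and flagged.

## Fitting

Three differentiable objectives: quadratic response matching, inverse
consistency `‖x⁰ − S^{-1}(x_exp)‖²`, and the Pearson correlation between
mean opinion scores and model distances (items with exactly zero response
difference have an undefined distance derivative and are dropped with a
warning rather than regularized).  Positive parameters (γ, b, c, σ) are
optimized in log space; the driver offers plain gradient ascent/descent
(fixed step with backtracking and 1.5× growth, optional mini-batching with
default batch 48, early stopping on a held-out objective with patience 20)
and an L-BFGS mode wrapped around the same analytic gradients.  All runs are
seeded and reproducible.

## Decoding

The analytic decoder inverts the cascade layer by layer with
ridge-regularized pseudoinverses (Tikhonov term `1e-8·σ_max²` by default;
the packaged example models use exact inversion since their stages are
square and well conditioned).  The measurement simulator adds Gaussian
stimulus noise (σ in cd/m²), blurs the response in each subband's own
spatial domain (width in deg, converted through that subband's sampling
density), applies a recording gain, and adds Fano-scaled Gaussian response
noise with variance `F·|recorded response|` — signed responses make a
literal Poisson draw undefined, so the variance-to-mean-magnitude ratio is
the property that is kept.  The Fano factor is defined in recorded units,
so the recording gain fixes the noise regime: the default gain of 50 puts
recorded magnitudes at O(1)–O(10), where F = 0.02 is a genuinely
low-distortion perturbation of the reduced model's responses.  Baselines are
ridge-floored linear regression and RBF kernel ridge with cross-validated
ridge strength and a median-distance kernel width; they are trained only at
the central luminance/contrast condition (5000 pairs at full scale; the desk
profile uses 500) and the per-cell MAE is averaged over 5 measurement draws
because a 16×16 field does not self-average the noise the way a megapixel
image does.

## Example models

**Cartoon model** (3 pixels, 2 layers): brightness `x¹ = (y¹)^{γ₁}` with
γ₁ = 0.65 (the only exponent with an experimental anchor), then
`y² = G·F·x¹` with the fixed orthonormal analyzer F (DC/low/high rows,
|det F| = 0.99949 at the printed 3-decimal precision) and band-pass gains
G = diag(0.8, 1, 0.2), then `x² = sign(y²)|y²|/(b+|y²|)` with H = I
(no inter-sensor interaction) and default b = 5 — a package default chosen
so responses sit in (−1, 1) mid-saturation over the 25–80 cd/m² fixture
range, not an experimentally derived value.  Its sensitivity factorizes in
closed form as
`γ₁^{2d}·∏(y¹_k)^{2(γ₁−1)}·det(F)²·∏G_kk²·∏[(1−|x²_k|)/(b_k+|y²_k|)]²`,
and the first-order impact of perturbing analyzer row k is
`Δx²_k = [(1−|x²_k|)/(b_k+|y²_k|)]·G_kk·(ΔF_k·x¹)`; both equal the generic
chain-rule machinery to 1e-8 (the closed form keeps det(F)² explicitly —
it is 1 only for an exactly orthonormal F, and dropping it would already
exceed that tolerance at the printed rounding).

**Reduced four-layer model** (16×16, dimension preserving, 16 samples/deg
so the field subtends 1 deg): (1) point-wise brightness DN with γ = 0.65,
b = 30 (input energies reach `160^{0.65} ≈ 27`); (2) deviation from a
Gaussian local mean (σ = 0.125 deg, subtracted fraction 0.8 — full
subtraction would annihilate the DC and break invertibility) normalized by
a Gaussian neighbourhood pool (γ = 1, b = 1, σ = 0.1 deg, pool c = 0.4);
(3) a band-pass CSF-like gain `max(0.1, (f/f_p)e^{1−f/f_p})`, f_p = 4 cpd,
applied in the orthogonal 2-d DCT domain (the 0.1 floor keeps the stage
invertible), with spatial masking (γ = 0.65, b = 2, σ = 0.08 deg, c = 0.4);
(4) a 2-level orthogonal db2 wavelet (periodized, so the matrix is square
and orthogonal) with intra-subband Gaussian masking, one shared σ = 0.1 deg
and pool c = 0.4 per subband via structure matrices (γ = 0.65, b = 2).
With b of the order of each layer's peak energy and pools c < 0.5, the
spectral radius of `D_|x|·H` stays below `max|x|·c < 1` by construction; on
the fixture grid the measured maximum is ≈ 0.11.  A "mixed" variant swaps
layer 1 for a two-gamma curve on calibrated [0, 1] luminance and layer 4
for a Wilson–Cowan stage with a row-normalized Gaussian kernel, exercising
the modularity of the cascade contract.

## Synthetic data

Natural-like images are 1/f Gaussian random fields — they reproduce the
spectral falloff and local correlation that the sensitivity, efficiency and
decoding analyses depend on, but none of the higher-order structure of real
scenes (no edges, no occlusions, no non-Gaussian statistics), so passing
tests certify the machinery on this model class, not performance on real
imagery.  Contrast is RMS contrast (std/mean) throughout.  Grid cells are
clipped into the display range [0, 160] cd/m² with alternating rescale/clip
iterations; cells whose final moments deviate more than 0.5% from target are
flagged infeasible (only extreme high-luminance × high-contrast corners).
Pixel ensembles (e.g. the 3-pixel sets) use an AR-like correlation `ρ^|i−j|`
with ρ = 0.9 and exact per-sample moment adjustment — note that removing
each tiny sample's own mean anti-correlates residuals at d = 3; the source
correlation survives visibly at larger d.  Synthetic opinion scores are a
monotone link of the generating model's distance plus observer noise
(default s.d. 5% of the signal spread), with a self-audit warning if the
rank correlation with the true distance drops below 0.8.  All generators are
pure functions of (spec, seed).

## Problem sizes

The packaged analyses run at desk scale by choice: 16×16 fields, 63-cell
grids, 500 training pairs for the decoding comparison with 5 measurement
repeats per cell, 2000 samples per cell for information maps (1e5 for the
Gaussian cross-check), and ≥50 random instances per finite-difference
validation.  Every quantity scales up by raising the corresponding
parameters.

## Known limitations

* Feed-forward cascades only; no feedback, no temporal dynamics (the
  Wilson–Cowan stage is used at steady state).
* The ΔMI estimator requires dimension-preserving cascades.
* The DN γ-derivative is undefined at exact zeros of y; the stimulus
  Jacobian for γ < 1 uses the documented |y| floor.
* Patch-mode MAD ignores inter-patch interactions by construction.
* The calibrated parameter values of full-scale psychophysical models are
  out of scope; the four-layer example is a reduced analog with documented
  package defaults.
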