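# Methods

`tendonscale` re-implements, as a tested pipeline on synthetic data, the
multiscale analysis of how dynamic loading and healing alter tendon: cyclic
tensile metrics at the macroscale, a fiber-recruitment account of the
nonlinear toe region, a fibrous-matrix constitutive law driving a
finite-element model of cell-generated stress transmission, organization
statistics from polarized-light / SHG / nuclear images, and the stepwise
regression linking the scales.  This note records the models, the defaults
and why, and what the synthetic study does and does not show.

## Fiber recruitment (toe-region mechanics)

Crimped collagen fibers begin to bear load once the tissue displacement `x`
exceeds their individual slack length.  Slack lengths are modeled as Gaussian
(mean `mu`, SD `sigma`, both mm); each recruited fiber is a linear spring of
stiffness `K_avg` (N/mm).  The population force is either the explicit sum
over `N` sampled fibers (`discrete` mode) or its expectation

    F(x) = K_tot [ (x - mu) Phi(z) + sigma phi(z) ],   z = (x - mu) / sigma,

with `K_tot = K_avg N` and `Phi`, `phi` the standard normal CDF/PDF.  The
expectation form is the default for fitting (the discrete form converges to
it at the usual `N^(-1/2)` Monte-Carlo rate, which the tests verify).  The
uncrimping probability is implemented as the standard normal CDF
`Phi((L0 - mu)/sigma)` — the only normalization under which the probability
ranges over (0, 1) and the expectation force above is its integral.
Fitting uses `(mu, log sigma, log K_tot)` coordinates for positivity with a
deterministic five-point multistart over the displacement range, and warns
when the fitted recruitment band `mu ± 2 sigma` is not bracketed by the
sampled displacements (toe or linear region unobserved — the fit is then an
extrapolation).

Defaults used by the generators: `mu = 0.15 mm`, `sigma = 0.05 mm`,
`K_tot = 20 N/mm` with a 5 mm gauge length and 0.4 mm² cross-section — a
3% mean slack strain with a toe that closes by ~5–6% strain and ~7 N at
10% strain, representative of a small stamped tendon specimen under a 10 N
load cell.  Fatigue damage is emulated as a fractional increase of `mu`
(default +10% per decade of high-magnitude cycles) and of `sigma` (+5%),
matching the observation that high-magnitude long-duration loading elevates
predicted slack lengths.

## Cyclic and equilibrium mechanics

Cycles are segmented at rising zero-crossings of the linearly detrended
displacement at the protocol frequency (the source analysis does not state a
detection method; crossings of the detrended signal are robust to peak
drift).  Partial first/last cycles are discarded.  Per cycle: displacement
and strain extrema, tangent stiffness `(F_max - F_min)/(d_max - d_min)`,
dynamic modulus `(sigma_max - sigma_min)/(eps_max - eps_min)`, hysteresis as
the shoelace area of the stress-strain loop (positive clockwise = 
dissipative; negative areas indicate a non-dissipative loop and are left
signed), and laxity `(d_peak,i - d_peak,1)/L_gauge` (zero for cycle 1 by
definition; comparable only within a loading magnitude).  Frequency sweeps
are fitted per frequency with a linear-in-parameters sinusoid (sin, cos,
offset, drift); `|E*|` is the stress/strain amplitude ratio and `tan(delta)`
the tangent of the phase lag wrapped to [0, pi/2).  Equilibrium stress is
the mean stress over the last 10% of a stress-relaxation hold (no window is
prescribed by the source; 10% of a 100 s hold averages ~3 relaxation time
constants after the transient at the defaults).  `Delta s_eq` between 1%
and 10% strain indexes strain stiffening and is emitted both absolute and
as a percentage.

## Fibrous-matrix constitutive law

The Cauchy stress is an isotropic compressible neo-Hookean part plus a
fiber part acting along the principal stretch directions:

    sigma = kappa (J - 1) I + G dev(Bbar)/J
          + (1/J) sum_a f'(lambda_a) lambda_a (n_a x n_a)

with `Bbar = J^(-2/3) B` (the standard isochoric convention; the source
leaves the bar undefined) and the piecewise fiber response `f'` equal to 0
below `lambda1`, `E_f ((L - l1)/(l2 - l1))^n (L - l1)/(n + 1)` between the
critical stretches, and
`E_f [ (l2 - l1)/(n + 1) + ((1 + L - l2)^(m+1) - 1)/(m + 1) ]` above
`lambda2` — continuous with continuous derivative at both breakpoints
(checked to 1e-4·E_f).  The fiber sum runs over all three principal
stretches with no tension-only switch beyond the `lambda < lambda1` zero
branch.  `(kappa, G)` may be specified through an equivalent isotropic
Young's modulus `E_b` with Poisson ratio `nu = 0.30` by default (the source
does not state its value; 0.30 keeps the ground matrix clearly
compressible, and the mapping is exposed).

The uniaxial response solves the lateral stretch for zero transverse stress
by a vectorized Newton iteration constrained to lateral contraction
(`a <= 1`); without that constraint a second, spurious equilibrium with
laterally engaged fibers exists and derails the solve.  Parameter fitting is
bounded least squares in log/offset coordinates with data-driven breakpoint
initialization (tangent-modulus profile) plus a small deterministic
multistart; identifiability is reported via the Jacobian condition number
and explicit warnings when the curve never reaches `lambda1` or `lambda2`.
The numerical tangent is a central-difference derivative of the Kirchhoff
stress under symmetric velocity-gradient perturbations (Voigt order 11, 22,
33, 12, 13, 23); major symmetry is monitored and its loss flags a fiber
branch crossing inside the perturbation stencil.  No closed-form tangent
tensors are provided.

## Cell contraction and stress transmission

A single cell is an ellipsoidal cavity (axisymmetric about the tendon axis)
in an infinite-by-proxy matrix: quarter-domain `(r, z)` mesh from the cavity
surface to a fixed outer boundary at `R_out = 100 µm`, 3-node axisymmetric
triangles graded from 1 µm elements at the cell to 6 µm at the far field.
The mesher blends the cavity ellipse into the outer circle (transfinite
rays), grades layer thickness geometrically, smooths interior nodes, and
rejects meshes with a minimum angle below 15°.  Contraction is applied as a
prescribed affine displacement of the cavity surface reaching 5% volume
loss (isotropic scale `0.95^(1/3)`, or axial-only scale 0.95 for polarized
contraction); the outer boundary is fixed — a doubling of `R_out` changes
the fitted exponent by <3%, which guards the choice.  The quasi-static
finite-deformation equilibrium is solved by Newton increments
(element-level finite-difference tangents, sparse direct solves, automatic
increment cutback).

Displacement magnitude is sampled along rays from the cell surface,
angularly averaged, and fitted as `u(r) ~ r^-eta` by ordinary least squares
of `log u` on `log r` over `[1.2 a, 0.5 R_out]` measured from the cell
center (no fit range is prescribed by the source; the window excludes the
near-surface boundary layer and the fixed-wall region).  Independent
oracles: the exact linear-elastic solution `u = A r + B/r²` for the bounded
spherical cavity (the pure `r^-2` law is its infinite-domain limit; at
`0.5 R_out` the bounded solution already deviates from `r^-2` by
`(r/R_out)^3 ≈ 12%`, so comparisons use the bounded form) and a 1-D
spherically symmetric reduced solver under the same law.

With 5% volume contraction the radial stretch at the cell surface is only
~3.4%, so the fiber engagement threshold must sit essentially at
`lambda1 = 1` for fibers to participate at all; the baseline uninjured
parameter set is `E_b = 1 MPa`, `E_f/E_b = 30`, `lambda1 = 1.0`,
`lambda2 = 1.005`, `n = 2`, `m = 10`, giving `eta ≈ 1.1` (displacement
felt at ~10 cell radii).  Healing is emulated by a softer, longer-toe
matrix (`E_f/E_b = 3–6`, `lambda2 - lambda1 = 0.02`) and fatigue by a
delayed, weak fiber response (`lambda1 = 1.01`, `lambda2 = 1.06`,
`E_f/E_b = 1`); both give `eta ≈ 2` — transmission collapses to the
isotropic limit, reproducing the qualitative ordering uninjured <
healing ≈ fatigue.  The effective exponent `eta_eff` scales `eta` by the
mean inter-cell spacing ratio, `eta_eff = eta (c_ref/c)^(1/2)` for areal
cellularity (exponent 1/3 for volumetric counts); the scaling rule is an
interpretation — the source states the idea but no formula — and is
recorded in the run provenance.

## Organization imaging

Polarized light: images are divided into 10×10 px regions (the "100 px²"
grid is read as area; the side is configurable) spaced 20 px, averaged, and
each region's intensity-vs-polarizer-angle curve fitted with
`A sin²(2(theta_p - theta_f)) + B`.  The model is linear in
`(1, cos 4theta_p, sin 4theta_p)`, so the fit is exact least squares; the
minimum-intensity angle `theta_f` is wrapped to (-45°, 45°] about the
loading axis (fiber angles are only defined modulo 90° under crossed
polarizers).  Regions whose amplitude is below 3× the fit residual RMS are
flagged low-signal and excluded from dispersion statistics (no exclusion
rule is stated by the source; the 3× floor rejects contrast-free regions
without touching clean fits).

Circular statistics: axial angles of period `P` are scaled by `k = 360/P`,
and `CSD = sqrt(-2 ln Rbar)/k` (degrees) with `Rbar` the resultant length —
invariant to rotation and relabeling modulo the period; `Rbar = 0`
(antipodal cancellation) is flagged degenerate.  The re-alignment strain is
the breakpoint of a continuous two-segment least-squares fit of CSD vs
strain (grid search plus bounded refinement); data fitted as well by one
line are flagged degenerate.  Dispersion ground truth everywhere is von
Mises on the doubled (period 180°) or quadrupled (period 90°) angle — the
standard circular analogue of a Gaussian for axial data — so generator
truths have closed-form CSDs to test against.

SHG: per-window dominant orientation from the second moments of the
windowed Fourier power spectrum (Hann taper, DC removed); the spectral
principal axis is rotated 90° to the fiber axis.  Windows whose anisotropic
spectral energy falls below 5% of the image maximum are masked.  Nuclei:
global Otsu threshold (or an explicit level), connected components, a
minimum-area filter, and per-component second-moment ellipses giving
`nAR = major/minor` and orientation; `nCSD` is the period-180 CSD of
nucleus orientations.  F-actin: percentile contrast stretch, Otsu
threshold, percent positive pixels per ROI.

## Regression stage

Outliers: the 2.2·IQR fence beyond the quartiles (linear-interpolation
quartiles; a zero-IQR column flags nothing).  Candidates are screened by
bivariate Pearson correlation (categoricals through treatment-coded
indicators, reference levels uninjured / quasi-static), gated by the
collinearity tolerance `1 - R_k² >= 0.01` (near-duplicates removed one at a
time), then backward stepwise OLS: remove the largest partial-F p-value
above 0.10, allow re-entry below 0.05 (the source quotes an entry threshold,
so re-entry is implemented and switchable), report the Durbin-Watson
statistic of the final residuals and flag values below 1.08.

A structural caveat the tests respect: with ~9 null candidates and a 0.10
removal threshold, the probability that backward selection retains *no*
spurious predictor is bounded near `0.9^9 ≈ 0.39` by construction, so
"exact support recovery" cannot be a high-probability event under these
thresholds.  The suite therefore asserts support *containment* (the planted
predictors {cellularity, nCSD, healing} for nAR are all retained in ≥85% of
replicates; measured ~96%) and bounds the median number of extras (≤1)
rather than asserting exact recovery.

## Synthetic study and its limits

`pipeline.run_study` runs uninjured and 2-week-healing groups under
quasi-static, low/1k and high/1k loading: record generation → mechanics →
recruitment fit → polarized-light CSD vs strain → SHG and nuclei at 1% and
10% strain → F-actin → FE contraction → per-specimen regression table →
stepwise fit, writing CSV/JSON outputs stamped with a config hash and a
provenance file (versions, seed, scaling rule).  All randomness derives
from one seed through independent spawned streams; identical configs give
byte-identical numeric outputs.  The demo and acceptance runs use a
moderately coarsened mesh (1.5 µm near / 9 µm far) and 3 load increments,
which the refinement study shows changes profiles by well under 1%.

What passing tests show — and do not.  The generators reproduce the
*statistical structure* the estimators assume (sinusoidal sweeps with a
pure injected phase lag rather than a full viscoelastic model; exponential
stress relaxation; von Mises axial dispersion; elliptical non-overlapping
nuclei; additive Gaussian noise).  Passing therefore demonstrates that each
estimator inverts its forward model at realistic noise levels and that the
mechanistic orderings across groups follow from the constitutive physics —
not that the specific animal-study effect sizes are reproduced: the
original specimen-level measurements are not publicly deposited, so group
means, printed R² values and correlation tables cannot be re-derived here.
Inter-specimen variance structure is likewise unreported and is exposed as
free generator parameters.

## Numerical choices and known limitations

- FE elements are constant-strain triangles with one-point quadrature;
  hoop strain uses the centroid radius (no axis singularity since centroids
  lie off-axis).  Newton tolerance 1e-8 relative; the 1-D reduced solver
  additionally accepts stagnation at the finite-difference Jacobian noise
  floor (≤1e4× tolerance) rather than iterating forever.
- The lateral-stretch solve and the 2×2 eigenvector extraction both guard
  explicitly against degenerate/diagonal states (two candidate eigenvector
  formulas, the larger-norm one used; near-isotropic states are insensitive
  to the choice because the two fiber terms coincide).
- Power-law fits are taken in center-distance coordinates; profiles start
  one element beyond the cavity and stop one element short of the wall.
- No viscoelastic or damage extension of the constitutive law, no
  stress-fiber feedback, no cell-cell simulations, no 3-D meshes, no
  z-stack (3-D) segmentation; mechanics has no failure/UTS analysis.
- The regression stage models specimens as exchangeable rows; it does not
  model the repeated-measures structure a full mixed model would.
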