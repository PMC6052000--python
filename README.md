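# tendonscale

Multiscale tendon mechanics and organization analysis: how dynamic loading
(quasi-static, low- or high-magnitude cyclic) and healing alter tendon from
the whole-tissue force-displacement curve down to the shape of tenocyte
nuclei, and how far a contracting cell can transmit displacement through
the surrounding fibrous extracellular matrix.

The package is aimed at tissue-biomechanics and mechanobiology researchers
who work with cyclic tensile tests, polarized-light / SHG / fluorescence
imaging of collagenous tissue, and continuum models of cell-matrix
interaction.  Because raw specimen data of the motivating animal study are
not publicly available, every input is produced by a first-class synthetic
generator with known ground truth, and the whole chain is validated against
independent oracles (quadrature, Monte-Carlo, closed-form elasticity, a
reduced 1-D solver, analytic circular statistics).

## What it computes

**Macroscale mechanics** (`mechanics`): per-cycle stiffness, dynamic
modulus, hysteresis and laxity; `|E*|` and `tan(delta)` from frequency
sweeps; equilibrium stress after relaxation holds, with
`Delta s_eq = s_eq(10%) - s_eq(1%)` as the strain-stiffening index.

**Fiber recruitment** (`recruitment`): tendon's toe region as progressive
uncrimping of fibers with Gaussian slack lengths; the expected force is

    F(x) = K_tot [ (x - mu) Phi(z) + sigma phi(z) ],  z = (x - mu)/sigma,

fitted to ramp data to estimate the mean slack length `mu` (elevated after
fatigue loading), `sigma` and the recruited stiffness `K_tot`.

**Fibrous constitutive law + FE contraction** (`constitutive`,
`contraction`): Cauchy stress `sigma = kappa(J-1)I + G dev(Bbar)/J +
(1/J) sum_a f'(lambda_a) lambda_a n_a⊗n_a` with a piecewise strain-
stiffening fiber response between critical stretches `lambda1 < lambda2`.
An axisymmetric finite-element model contracts an ellipsoidal cell by 5%
volume inside this matrix and fits the displacement decay
`u(r) ∝ r^-eta`; small `eta` = long-range stress transmission.  A
cellularity-scaled `eta_eff` compares groups per unit inter-cell spacing.

**Organization imaging** (`imaging`): region-wise `A sin²(2(theta_p -
theta_f)) + B` fits to polarized-light stacks, circular standard deviation
(CSD) of fiber angles, the bilinear re-alignment transition strain, Fourier
(spectral second-moment) SHG fiber orientation, nuclear aspect ratio (nAR)
and nuclear disorganization (nCSD), and percent-positive F-actin.

**Regression** (`regression`): 2.2·IQR outlier fences, Pearson screening,
backward stepwise OLS with a collinearity tolerance gate (1 - R² ≥ 0.01)
and the Durbin-Watson diagnostic (flag below 1.08).

**Pipeline** (`pipeline`, `tendon` CLI): the full synthetic study across
healing × loading groups with deterministic seeding and config-hashed
outputs.

## Worked example

```python
from tendonscale.constitutive import FibrousMatrixParams
from tendonscale.contraction import (CellGeometry, MeshSpec, build_mesh,
                                     solve_contraction, radial_profile,
                                     fit_power_law)

cell = CellGeometry(a=5.0)                       # 5 µm cell, 5% contraction
mesh = build_mesh(cell, MeshSpec(1.0, 6.0, 100.0))

uninjured = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=30.0, lambda1=1.0,
                                            lambda2=1.005, n=2, m=10)
fatigued = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=1.0, lambda1=1.01,
                                           lambda2=1.06, n=2, m=10)
for name, p in [("uninjured", uninjured), ("fatigued", fatigued)]:
    field = solve_contraction(mesh, p, cell)
    fit = fit_power_law(radial_profile(field))
    print(f"{name}: eta = {fit.eta:.2f} (R2 = {fit.r_squared:.3f})")
```

prints

```
uninjured: eta = 1.11 (R2 = 0.953)
fatigued: eta = 2.04 (R2 = 1.000)
```

i.e. in the strain-stiffening uninjured matrix the contraction field decays
with exponent ~1.1 — the cell is mechanically "visible" roughly ten radii
away — while the fatigued matrix (delayed, weak fiber engagement) behaves
like an isotropic solid with the classical cavity exponent 2, so the
displacement dies off within a couple of cell radii.

The full synthetic study (mechanics → recruitment → imaging → FE →
regression for five loading/healing groups) runs with

```bash
tendon run --seed 1 --out study_out
```

and writes `summary.csv` (one row per group: `Delta s_eq`, `|E*|`,
`tan(delta)`, slack length, CSD/nCSD and their strain responses, nAR /
`Delta nAR`, F-actin, `eta`, `eta_eff`), `specimens.csv`,
`regression.json` and `provenance.json`.

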