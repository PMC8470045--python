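# Methods

## Model and assumptions

`oralpk` analyses per-oral drug disposition with a linear two-compartment
model: GIT amount `x1` (mg) and blood amount `x2` (mg), first-order
transfer constants `ka` (absorption), `ke1` (GIT elimination), `ke2`
(blood elimination), all 1/h. The structure encodes donor control — the
absorption flow is `ka·x1`, independent of the blood amount — which is a
deliberate simplification of the Fick picture (a true membrane flux
depends on the concentration difference across the membrane). The model
is linear, so predictions scale with the dose; saturable kinetics,
repeated dosing and intravenous routes are out of scope.

The state-space system is required to be a positive compartmental
system: Metzler `A`, nonpositive diagonal, nonnegative `b`, `c`, and
column-wise diagonal dominance. These are verified structurally
(per-condition flags, never exceptions) rather than assumed, and Kalman
rank tests confirm observability and controllability, which hold for
this structure exactly when `ka > 0`. Rank is decided from singular
values with a relative threshold of 1e-10 × the largest singular value —
scale-free and ample for well-conditioned 2×2 systems.

## Identification and identifiability

Only `(b0, a1, a0)` of `G(s) = b0/(s² + a1·s + a0)` are identifiable
from input/output data. The package fits them by unweighted nonlinear
least squares of the impulse response on *amounts* (concentrations are
converted first via the total blood volume; no weighting is applied, as
amounts are the modelled quantity and the assay error model is unknown).
Internally the optimizer works in `(b0, λ1, λ2)` with bounds keeping the
decay rates positive, a numerically stable confluent limit
`b0·M0·t·e^{−λt}` when `|λ1−λ2| ≤ 1e-10·max(λ1, λ2)`, and 8
deterministic starts on a log-spaced grid of `(λ1, λ2)` pairs spanning
`1/t_max` to `10/t_min` of the positive sampling times (biexponential
objectives are multi-modal; the multi-start is deterministic so fits are
exactly reproducible). The best of the starts by residual sum of
squares is kept, and coefficients map back as `a1 = λ1+λ2`,
`a0 = λ1·λ2`.

Rate-constant recovery applies `ka = b0`,
`ke2 = (a1 ± sqrt(a1²−4a0))/2`, `ke1 = a1 − b0 − ke2`, returning the
minus-root (smaller `ke2`) branch first. A discriminant within
`1e-9·a1²` of zero collapses to a single, fully identified branch;
a discriminant below `−1e-9·a1²` raises (complex poles admit no real
compartmental realization of this structure). Branches with negative
`ke1` are retained but flagged as non-compartmental, so the caller sees
the full algebraic picture.

On the packaged study table, the refit coefficients differ from the
historically reported triplets by roughly 8–20 % per coefficient while
achieving about half their residual sum of squares — the original
analysis evidently minimized a different, unreported objective. The
package therefore treats the reported coefficient sets as given inputs
for endpoint reproduction and validates its own fitter by synthetic-data
recovery (exact at zero noise; median |Δb0|/b0 ≈ 2 % at 5 % assay CV
with 6 animals per point over 100 replicates). A practical corollary:
the unique parameter `ka` is robust across objectives (refit ≈ 49 %
increase vs the reported 51.3 %), but branch-dependent endpoints such as
per-branch bioavailability are sensitive to the unidentifiable
`(ke1, ke2)` split and should only be compared across conditions for a
consistently chosen branch and objective.

## Simulation

Two routes with one contract. The analytic route evaluates the exact
impulse response and its integrals in closed form (`expm1`-based, with
the repeated-root and zero-rate limits handled explicitly). The numeric
route integrates the ODEs with the dose as a rectangle (default width
0.083333 h, height dose/width) using LSODA at rtol 1e-8 / atol 1e-10 mg,
splitting the integration at the rectangle's two discontinuities so the
adaptive stepper never crosses them; this is the physically faithful
picture in which `x1` cannot jump and trajectories emanate smoothly from
the origin. Mass balance (delivered = `x1 + x2` + cumulative
eliminations) holds to better than 1e-6 of the dose on both routes.

An equal-area rectangle of width `w` shifts the response by about `w/2`,
so the default-width rectangle agrees with the impulse response only to
order `λ·w/2` (~2–3 % for the study's rate constants) — an inherent
property of the input approximation, not an integration error; with
`w = 1e-4` h agreement is within 1e-3 relative for `t ≥ 0.1` h. The
default output grid is 0–12 h at 0.01 h steps.

## Endpoints

Total absorbed amount and F use the closed forms above. The horizon is
an explicit parameter, default 12 h: the endpoint values reported for
the with-tenside condition (8.919179 mg, F = 17.83835 %) are reproduced
at this horizon with the smaller-`ke1` branch (the infinite-horizon
value would be 9.430 mg). For the tenside-free condition no
horizon/branch combination reproduces the historically reported
4.384808 mg exactly — the closest, 12 h with the smaller-`ke1` branch,
gives 4.3948 mg (~0.2 % off); the discrepancy is documented rather than
resolved and the package's own closed-form identity serves as the check
there. The ~2× bioavailability ratio between the conditions holds at
the 12 h horizon (17.84/8.79 ≈ 2.03).

The reciprocal-molecular-weight CMC figure (`1/MW` mole/L for a 0.001 %
w/v solution) is dimensionally questionable — 0.001 % w/v is 0.01 g/L,
i.e. 0.01/MW mole/L — so `cmc_molar_as_printed` reproduces the
arithmetic verbatim but returns a record with an explicit caveat flag.

## Synthetic data

The generator emulates the destructive-sampling design behind the study
table: fixed sampling times 0–6 h, six animals per time point (each
sampled once), 50 mg dose, 200 g body weight, group means recorded.
The mean concentration curve is the exact impulse response `x2(t)/TBV`;
per-animal values are mean × (1 + ε) with ε ~ N(0, CV²) truncated at −1
(multiplicative noise, because assay error scales with concentration and
no error model was reported; default CV 5 %, a typical colorimetric-assay
figure). The tenside condition scales `ka` by an explicit factor,
leaving `ke1`, `ke2` unchanged. A single integer seed drives one
`numpy` Generator for both conditions, so datasets are bit-reproducible.

Not emulated, hence untested against real-data features: inter-animal
body-weight variation, the ~8 % acetylated drug fraction,
within-condition model misspecification, and any concentration
dependence of the tenside effect. Passing recovery tests therefore show
the estimator is correct under the stated noise model, not that the
two-compartment structure is correct for any particular drug.

## Numerical and design choices

- Zero-discriminant tolerance `1e-9·a1²`; repeated-root switch at
  `|λ1−λ2| ≤ 1e-10·max`; round-trip identity holds to 1e-9 relative.
- The Laplace variable is never materialized; transfer functions exist
  only as coefficient records `(b0, a1, a0)`.
- Structural checks generalize to n×n (used for a 3-compartment chain in
  the tests); only `build_system` is specific to the 2-compartment
  structure.
- The t = 0 sample (amount 0) is kept in fits; the impulse response also
  passes through 0 there, so it carries no bias.
- All pipeline report numbers are rounded to six decimals and serialized
  with sorted keys, making reports byte-stable for a fixed input.
- Problem sizes: simulation grids of ~1200 points, an endpoint
  quadrature grid of 0.001 h, and a 100-replicate recovery study —
  chosen so the full chain re-runs in seconds on a single core while
  leaving quadrature error orders of magnitude below the comparison
  tolerances.

## Known limitations

Two-compartment, linear, single-dose only; the fitter assumes the dose
enters as an impulse at a known time (the rectangle is a
simulation-side device only); no confidence intervals beyond the
residual sum of squares; branch selection for endpoints is the caller's
explicit choice, since the data cannot make it.
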