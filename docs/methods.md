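# Methods

## The model and its assumptions

The network is reduced to two species. Lin28 protein (φ after rescaling) is
produced constitutively and degraded in a let-7-dependent, saturable way;
mature let-7 (ψ) is produced at a basal stimulus-driven rate α plus an
autocatalytic Hill term that Lin28 inhibits, and decays linearly:

    dφ/dτ = 1 − φψ/(ψ + γ)
    dψ/dτ = ε (α + γ₁ψ²/(γ₂ + ψ² + γ₃φ) − ψ)

Assumptions inherited from this coarse-graining: the multi-step biogenesis
cascade (Drosha, exportin-5, Dicer, TUT4-mediated uridylation) is collapsed
into effective production/inhibition terms; family members of let-7 and
Lin28 are not distinguished; the positive autoregulation of let-7 is valid
for weak miRNA–target binding and high miRNA abundance; all reactions are
deterministic mass-action/Hill kinetics — intrinsic reaction stochasticity
is out of scope, only extrinsic (stimulus) fluctuations are modeled.

The dimensional model uses rates in h⁻¹ and concentrations in arbitrary
units (no absolute concentration scale is implied by the biology here).
`nondimensionalize` maps the eight rate constants onto the six groups with
the scalings φ = β_P[Lin28]/α_P, ψ = β_M[let-7]/α_P, τ = β_P t,
γ₁ = Γ₁/α_P, γ = κ_P β_M/α_P, γ₂ = Γ₂β_M²/α_P², γ₃ = Γ₃β_M²/(α_Pβ_P),
ε = β_M/β_P. This is the unique scaling under which every dimensionless
group above is consistent and the dimensionless equations are exactly the
scaled image of the dimensional ones (property-tested). A `Scales` record
makes the map invertible; inversion validates that the recorded let-7
concentration scale equals α_P/β_M.

## Parameters

| group | meaning                                         | default / range |
|-------|-------------------------------------------------|-----------------|
| α     | basal let-7 production relative to Lin28's      | 0 – 0.4 (stimulus axis) |
| γ₁    | positive-feedback strength                      | 2.0 – 5.0 |
| γ₂    | Hill saturation constant                        | 1.0 (fixed) |
| γ₃    | Lin28-inhibition efficiency                     | 0 – 2.5 |
| γ     | half-saturation of let-7-driven Lin28 turnover  | 0.1 – 2 |
| ε     | degradation-rate ratio β_M/β_P                  | 0.375 from 4 h / 1.5 h half-lives; < 1 because miRNAs outlive proteins |

ε multiplies the whole ψ equation, so it never moves steady states or the
switch classification — it only sets the let-7 time scale (verified by an
invariance test). With γ₃ = 0 the ψ equation decouples from φ, and γ
becomes irrelevant to let-7 behavior (also asserted).

## Steady states and folds

At equilibrium φ_s = (ψ_s + γ)/ψ_s (equivalently ψ_s(φ_s − 1) = γ), so the
branch is parameterized by ψ: α(ψ) = ψ − γ₁ψ²/D(ψ) with
D(ψ) = γ₂ + ψ² + γ₃(ψ + γ)/ψ. Clearing denominators turns the fixed-α
steady-state condition into the quartic

    (ψ − α)(ψ³ + (γ₂+γ₃)ψ + γ₃γ) = γ₁ψ³

solved by the companion-matrix method, Newton-polished, then filtered:
roots must be real, strictly positive, and must zero both un-cleared
right-hand sides to 1e-9 (clearing 1/ψ can introduce spurious roots, e.g.
ψ = 0 when γ₃ = 0). ψ = 0 is allowed as a dynamical state but is not an
equilibrium of the full system (the Lin28 balance has no root there), so
it is excluded from the search. Stability comes from the eigenvalues of
the analytic Jacobian; eigenvalue real parts within 1e-8 of zero are
labeled `degenerate` (fold points) rather than forced into stable/saddle.
An independent oracle — dense sign-change scan of α(ψ) − α plus bisection
— agrees with the quartic route on hundreds of random draws.

Folds solve dα/dψ = 0. The derivative simplifies to
1 − γ₁(2(γ₂+γ₃)ψ + 3γ₃γ)/D(ψ)², scanned on a log grid over ψ ∈ [1e-4, 100]
(2000 points) and refined by Brent's method to machine precision. The local
maximum of α(ψ) (smaller ψ) ends the off branch, the local minimum ends the
on branch.

Two boundaries in γ₁ delimit the regimes:

* **cusp** (monostable → bistable): the fold condition gives
  γ₁ = D(ψ)²/(2(γ₂+γ₃)ψ + 3γ₃γ) pointwise; folds exist exactly above the
  minimum of this function over ψ > 0, found by bounded scalar
  minimization on the log axis. Closed form at γ₃ = 0: (8√3/9)√γ₂, i.e.
  8√3/9 ≈ 1.5396 at ψ = 1/√3 for γ₂ = 1.
* **one-way** (bistable → irreversible): the on-state fold sits at α = 0.
  Eliminating γ₁ reduces this to the depressed cubic
  ψ³ − (γ₂+γ₃)ψ − 2γ₃γ = 0; γ₁* = D(ψ*)/ψ* at its positive root. At γ₃ = 0
  this is exactly γ₁* = 2√γ₂.

## Switch classification

`classify_gamma1` labels branch geometry: no folds → `monostable`; folds
with the on-state fold at α > 0 → `bistable`; at α ≤ 0 → `one_way` (the on
state survives total stimulus withdrawal; the boundary case α = 0 is
deliberately one-way). A fold window lying entirely above the
physiological stimulus ceiling (α_max, default 0.4, configurable) is
reported `monostable` within that window. Phase diagrams over an α axis
label each cell at its own stimulus: a cell is bistable/one-way only if
its α lies strictly inside the fold window. `classify_point` counts stable
states at one operating point and, for a single stable state, decides
on/off by whether its ψ lies above the larger fold ψ (below the cusp the
split point is the would-be cusp ψ). Default grid 201×201 in the CLI;
the analysis scripts use 121×81, which resolves every regime boundary to
better than the cell size.

## Time courses

Classical fixed-step RK4, default dt = 0.01 dimensionless time. Halving dt
moves terminal states by < 1e-8 (audited in a test); non-finite states
raise an error carrying the step index. The stimulus is held constant
within a step.

Extrinsic noise: "Gaussian stimulus noise of mean 0.2, variance 0.05" is
not by itself a well-posed continuous-time noise model, so the generator
holds α piecewise constant and redraws it i.i.d. from N(mean, variance)
every `redraw_interval` (default = dt = 0.01). The stationary variance of
ψ therefore depends on `redraw_interval` — faster redraw means more
averaging and smaller ψ fluctuations — which is why only orderings across
ε, not absolute fluctuation amplitudes, are treated as results. Negative
draws are clipped at zero by default (production rates cannot be
negative). Clipping raises the realized stimulus mean from 0.2 to
E[max(N(0.2, 0.05), 0)] ≈ 0.223 and shifts the operating point
accordingly; the stationary-mean test therefore disables clipping, and
fidelity experiments can do the same via `clip_at_zero=False`.

Switch timing: `switch_time` reports the first crossing of
off + 0.95·(on − off). On/off levels are explicit arguments (the stable
branch values at the operating α are the natural choice) because the
off/on ranges are a labeling convention, not a model quantity. Default
initial condition is the off-branch steady state at the operating α when
one exists, else ψ(0) = 0.05 with φ(0) on its nullcline; the choice is
recorded in `Trajectory.meta`. With γ₃ = 0 the ψ equation is ε·f(ψ), so
switch times scale exactly as 1/ε — the ratio 3.75 between ε = 0.1 and
ε = 0.375 is a closed-form consequence, and the integrator reproduces it
to < 0.1%.

## Synthetic data and recovery

`make_dataset` emulates replicate time-course measurements of mature
let-7: one deterministic model trajectory (default horizon 30 time units,
dt = 0.02, 101 evenly spaced observation times) observed n times with
i.i.d. additive Gaussian noise on ψ only — mature let-7 is the species a
qPCR/reporter time course actually measures; Lin28 observations are not
generated by default. Replicates share the initial state, as biological
replicates of one protocol would. What the generator does *not* emulate:
intrinsic molecular noise, cell-to-cell parameter variability,
non-Gaussian measurement error, and unknown initial conditions — so
passing recovery tests demonstrate identifiability of the fitting
machinery under the stated noise model, not robustness to everything real
data do.

`recover_parameters` minimizes summed squared ψ residuals over any subset
of (α, γ₁, ε) — the three groups the physiological analysis varies — with
scipy's bounded trust-region-reflective least squares, 10 starts (first at
the bound midpoint, the rest uniform within bounds, seeded). No
likelihood model beyond least squares is claimed. ε is bounded away from
zero (1e-3) because the dynamics degenerate there. Datasets whose
noise-free model output is constant are flagged non-identifiable when ε is
free (ε drops out at equilibrium). Under the default design
(5 trajectories, noise sd 0.01) all three parameters come back within a
fraction of a percent; the acceptance threshold of 5% leaves a wide
margin.

## Numerical defaults

root residual 1e-9 · fold tangency 1e-8 · bisection to ~1e-12 in ψ ·
Jacobian-vs-finite-difference agreement 1e-6 relative · CSV output 12
significant digits · all randomness through `numpy.random.default_rng`
with explicit integer seeds.

## Known limitations

* The bistable stimulus window cannot be made exactly (0.01, 0.17) for
  γ = 0.1, γ₂ = 1, γ₃ = 0.5 by any single γ₁: when the on-state fold is at
  α ≈ 0.01 (γ₁ ≈ 2.46) the off-state fold sits at α ≈ 0.18, not 0.17. The
  tests accept the window to ±0.02 and flag the 0.18-vs-0.17 residual as a
  property of this branch geometry.
* The noise model is a modeling choice (piecewise-constant redraws);
  white-noise SDE limits would need a different discretization and would
  change absolute fluctuation amplitudes.
* No numerical continuation is implemented; the explicit α(ψ)
  parameterization covers this model but would not generalize to systems
  without a closed nullcline elimination.
* Concentrations are in arbitrary units throughout; only dimensionless
  statements are quantitative.
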