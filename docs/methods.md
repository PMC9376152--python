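# Methods

## Model

`crawlby` iterates a two-dimensional map for nondimensional adult
consumer density `p` and adult resource density `n` at reproductive
pulse times `m = 0, 1, 2, …`:

    p_{m+1} = δ_p p_m + γ_p p_m n_m / (1 + σ n_m²)
    n_{m+1} = δ_n n_m exp(−γ_n p_m / (1 + σ n_m²)) + R n_m exp(−p_m) / (1 + n_m)

The map is the exact pulse-to-pulse discretization of an impulsive
system: exponential adult mortality between pulses (per-pulse survivals
`δ_p = e^{−d_P}`, `δ_n = e^{−d_N}`), a Type IV (unimodal) functional
response `n/(1 + σn²)` expressing group defense, consumer recruitment
proportional to consumption, and Beverton–Holt resource recruitment
thinned by predation on offspring (`e^{−p}` is the offspring's
consumption-survival probability under an exponential survival
distribution). Because the within-pulse dynamics are linear in each
state given the other, the discretization involves no integrator and no
truncation error. `nondimensionalize` maps the eight dimensional
parameters onto the six map parameters (`γ_p = γ_P/β`,
`γ_n = γ_N e^{−d_P}/γ_S`, `σ = σ_N/β²`, state scaling `p = γ_S P`,
`n = β N`); the commuting-square equivalence of the two forms is
property-tested to 1e-10 relative tolerance.

### Assumptions

- Adults only; juveniles appear solely through the pulse terms.
- Group defense acts on both adult consumption and offspring predation
  through the same `1 + σn²` denominator (adults) and total consumer
  pressure `e^{−p}` (offspring).
- Self-replenishment `R > 1 − δ_n`: without it the resource dies out
  even without consumers and no carrying capacity exists. The
  constructor accepts such parameter sets (so that `validate_params` can
  report them); every operation that needs `n*` raises.
- Group-defense relevance `n* > 1/√σ` (carrying capacity above the
  consumption peak) is a warning, not an error: all formulas remain
  valid without it, but defense then never shields sub-equilibrium
  resource densities.
- `σ = 0` is accepted as the defense-free limit: the functional response
  becomes linear, and the interior saddle pair — whose existence is what
  group defense contributes — is reported as absent (the quadratic for
  the coexistence resource density degenerates and its upper root
  diverges).

## Parameters

| parameter | meaning | default (study baseline) |
|---|---|---|
| `δ_p` | consumer per-pulse survival | 0.9 |
| `δ_n` | resource per-pulse survival | 0.8 |
| `γ_p` | consumer conversion intensity | figure-dependent (1, 3, or relative to `γ_p*`) |
| `γ_n` | scaled attack rate | 1 |
| `σ` | group-defense strength (consumption peaks at `n = 1/√σ`) | 2.67 |
| `R` | per-capita resource recruits | 2 |

All are dimensionless; defaults are the values used across the study's
figures, under which `n* = 9`, `γ_p* ≈ 2.4141` and, at `γ_p = 3`,
`λ₁ ≈ 1.02427`.

## Equilibria and stability

The catalog always contains extinction `(0,0)` and carrying capacity
`(0, n*)`, plus up to two interior equilibria. Interior resource
coordinates solve the consumer self-replacement condition
`(1 − δ_p)(1 + σn²) = γ_p n`; for each root below `n*` the consumer
coordinate is the unique positive root of the recruitment balance
`1 = δ_n e^{−γ_n p/(1+σn²)} + R e^{−p}/(1 + n)`, which is strictly
decreasing in `p` and positive at `p = 0` exactly when `n < n*`. The
bracket is grown geometrically from 1 (the balance tends to −1 as
`p → ∞`, so a sign change always exists) and resolved by Brent's method
to ~1e-12. Below the bifurcation both branches lie in the first
quadrant; above it the upper branch exits through `p < 0` and only the
low-resource saddle remains — the catalog therefore holds 0, 1 or 2
interior entries.

Stability is classified from the analytic Jacobian's eigenvalue moduli
with a nonhyperbolicity band `| |λ| − 1 | < 1e-9`, wide enough to flag
the transcritical point at double precision yet narrower than any
hyperbolic case exercised in the tests. The analytic Jacobian is
verified against central finite differences (step `1e-6·max(1,|x|)`,
relative tolerance 1e-5).

## Log-space iteration

Transients here routinely pass through densities like `e^{−150}`:
linear-space iteration underflows (and, for large consumer loads,
overflows). `simulate` therefore iterates the exact log transform

    ℓp' = ℓp + log(δ_p + γ_p q),   q = 1/(e^{−ℓn} + σ e^{ℓn})
    ℓn' = ℓn + logaddexp(log δ_n − γ_n e^{ℓp − log(1+σe^{2ℓn})},
                         log R − e^{ℓp} − log1p(e^{ℓn}))

where the two resource-recruitment channels are combined by log-sum-exp
so the update stays exact when both are far below underflow. A zero
coordinate is carried as `−inf`, for which the update reduces *exactly*
to the one-dimensional sub-map on that axis; no artificial density floor
is introduced, preserving the forward invariance of the axes that the
transient theory relies on. Linear-space iteration is kept for
cross-validation and raises on overflow rather than saturating, since
the transients of interest live near the floating-point boundaries;
log- and linear-space trajectories agree to 1e-8 relative tolerance over
50-step orbits wherever the linear orbit is representable (tested over
100 random initial conditions).

## Observed transient times

The study's figures plot "observed" recovery and escape times without a
formal definition, so the package fixes one per regime:

- **Recovery** (extinction crawl-by): the first pulse at which the
  resource series strictly increases, matching "recovery will begin".
  Direction comparisons are made in log space with tolerance 1e-12;
  ties count as no change. A threshold-crossing mode is available.
- **Escape** (carrying-capacity crawl-by): the first pulse at which the
  resource falls below half its carrying capacity. A first-strict-
  decrease reading is *not* usable here: starting from
  `(ε, n* − ε)` the consumer depresses recruitment by O(ε) immediately,
  so the resource drifts downward from the very first pulse at every ε
  and the direction-based time is identically 1. The half-`n*` crossing
  marks the actual collapse, which lags the consumer's rise to O(1) by
  an ε-independent offset and therefore reproduces the predicted
  `1/log λ₁` scaling (measured slope 41.62 vs 41.70 at `γ_p = 3`). The
  direction mode remains available via `mode="direction"`.
- **Ghost escape**: `τ = min{M : n_M > n^, p_M < p^}` with `(p^, n^)`
  the upper interior saddle — the first entry into the region from
  which the resource rises and the consumer falls monotonically
  (`monotone_after` re-checks this on every trajectory; tolerance as
  above, with sub-tolerance steps counting as ties since the approach
  to equilibrium eventually stalls at machine precision).

The analytic crawl-by estimates take the order-of-magnitude constants
as 1 — `log(p₀)/(−log δ_p)` and `log(1/ε)/log λ₁` — and the scaling
tests assert only regression slopes (within 15%), never intercepts,
since only the rates are theoretically determined.

## Ghost sweep and power-law fit

`tau_sweep` sets `γ_p = γ_p* − ε` over a geometric grid (default 12
points spanning `[10⁻³, 10⁻¹]·γ_p*`, horizon 5·10⁴ — large enough that
every default-grid escape completes while keeping the sweep in seconds
on one CPU), simulates from a common initial state, and records τ;
unreached escapes are dropped with a warning. `fit_power_law` is
ordinary least squares of `log τ` on `log ε`, reporting
`A = exp(intercept)`, `B = −slope` and the log–log r². The fit
recovers a known generating law within 5% on noiseless synthetic data;
exponents for genuine sweeps are reported as fitted, with no attempt to
derive `A`, `B` from model structure.

### Sensitivity of τ to the initial state

The escape time is governed by a race each time the resource climbs
back through the consumption window `n^∨ < n < n^`: the consumer blooms
while the resource transits, and the orbit escapes on the first transit
for which the consumer's peak stays below `p^`. The consumer's floor —
hence the race outcome — is set by the depth of the preceding resource
crash, which grows rapidly with the initial consumer load. At the
baseline ghost parameters (`γ_p = 0.9912 γ_p*`), trajectories from
`p₀ ≲ 1` cycle for 10⁴–10⁵ pulses (e.g. τ = 11568 from `(1, 1)`,
13 collapse–recovery cycles from `(0.5, 1)`), while `p₀ = 10` crashes
the resource to ~e^{−140}, the consumer dies to ~3·10⁻⁷ before recovery,
and the orbit escapes on its first transit (τ = 199). Reported escape
times should therefore always be read jointly with the initial state;
the figure-level defaults use the published initial conditions verbatim.

## Degenerate inputs and numerical choices

- State comparisons default to relative tolerance 1e-8 (double
  precision compounded over ~10² steps).
- Fixed-point residuals are required < 1e-10 under the map itself.
- Discriminant exactly zero (tangent interior branches) returns both
  coincident roots; negative discriminant returns none.
- `validate_params` never raises: it reports each condition as
  pass/fail/warn so invalid regimes can be inspected programmatically.
- CSV output uses `repr` formatting, making every float round-trip
  exact; the model is deterministic, so outputs are byte-identical
  across runs.

## Limitations

- The map is deterministic; demographic stochasticity — which can cut
  long transients short by killing rare survivors — is out of scope.
- Juvenile stages have no explicit dynamics; transient times in a
  stage-structured extension may differ.
- `A` and `B` of the ghost power law are purely empirical fits; no
  discrete-time analogue of the continuous-time limit-cycle theory is
  attempted.
- Observed-time definitions are reasonable conventions, not unique: the
  recovery/escape times shift by O(1) constants under alternative
  thresholds, though their scaling slopes do not.
- The `σ = 0` limit reports no interior equilibria by convention (the
  defense-generated pair), even though the degenerate single root of
  the linear self-replacement condition can lie in the first quadrant
  above the bifurcation.
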