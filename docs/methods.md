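# Methods

## Model

The state is a 15-vector in the fixed order
(T_N, T_h, T_c, T_r, D_N, D, M_N, M, C, N, A, H, IL12, IL10, IL6).
Naive pools (T_N, D_N, M_N) are produced at constant rates (Ā_TN, Ā_DN,
Ā_M) and converted into activated pools by mass-action terms whose
drivers are the cytokines and cell types known to activate each
compartment; every activation term appears with opposite sign in the
corresponding naive equation, so naive + activated chains telescope to
sources minus sinks (this is asserted as a property test). Cancer cells
grow logistically with carrying capacity C̄₀, with the intrinsic rate
λ_C augmented by IL-6 (λ_CIL6) and adipocytes (λ_CA), and die at
δ_C + δ_CTc·T_c. Adipocytes follow an independent logistic law
(λ_A, δ_A, Ā₀). The necrotic pool receives the fraction ᾱ_NC = 1.5 of
the cancer death flux and decays at δ_N. The four cytokines are
produced proportionally to their cellular sources and decay linearly.

Assumptions worth making explicit: T-cell activation is proportional to
the naive pool (no saturation), macrophages are a single activated
compartment, no spatial structure, no resources (oxygen, nutrients)
beyond the two carrying capacities, and no treatment terms.

All computation happens in the nondimensional frame: each variable is
divided by its maximum over all mice and sampling times, so every
observation lies in [0, 1]. Time is not rescaled, so all 57 rates are
per day. The fixed constants are C̄₀ = 2, Ā₀ = 2, ᾱ_NC = 1.5; they are
never estimated (keeping estimation linear). Parameter order is frozen
in `parameters.PARAM_NAMES` (33 production rates, 21 decay/inhibition
rates, 3 sources); every matrix in the package indexes against it. The
published fitted vector ships verbatim as `table3_params.json`.

## Estimation

Because each equation is linear in the rates given the state, the
15×57 parameter Jacobian ∂f/∂θ evaluated at an observed state is one
15-row block of the design matrix, and A·θ equals the stacked RHS
exactly (tested at random θ). Derivative targets b use the wide central
difference at interior sampling times and first-order one-sided
differences at the first and last times. The four-point design was
genuinely open here: pure central differencing would leave only two
usable times per mouse. Default is `endpoints="onesided"` (180 rows);
`"interior-only"` (90 rows) is available to probe sensitivity to that
choice. All mice are fitted jointly into a single θ (a per-mouse model
can be built by passing a one-mouse dataset).

The unconstrained solution is minimum-norm least squares via SVD; the
bounded problem (θ ≥ θ_min = 10⁻⁵) is solved with BVLS (exact
active-set) when the system has at least as many rows as columns, and
the trust-region reflective solver otherwise. Correctness is defined by
the KKT conditions — zero gradient on free coordinates, nonnegative
gradient at the bound — which the tests check directly rather than
trusting any particular algorithm.

Identifiability: the design built from four sampling days is full rank
at machine precision but has condition number ~4·10⁶. Reports therefore
carry both the machine-precision rank and an *effective rank* counting
singular values above 10⁻³ of the largest; directions below that
threshold are practically non-identifiable and typically surface as
rates pinned at the bound. Nothing fails on ill-conditioning; it is
reported.

## Simulation

`integrate` solves the nondimensional system with LSODA and the analytic
state Jacobian, rtol 10⁻⁸ / atol 10⁻¹⁰, on a daily output grid over
[0, 126] by default (126 d = 18 weeks, the sensitivity horizon). The
first output state is the initial condition exactly; nonnegativity is
structural (every loss term is proportional to its own variable), and
only sub-tolerance negative excursions are clipped to zero. Initial
conditions are the day-0 rows of the dataset, nondimensionalized.
Perturbation envelopes scale chosen rates independently within
[1−f, 1+f] (default f = 0.20), either at all 2^k sign corners (k ≤ 12)
or with a seeded 256-point Latin hypercube, and take pointwise min/max
over trajectories; the unperturbed vector is always included, so the
baseline lies inside the band.

## Sensitivity analysis

The forward (direct differential) method advances the state jointly
with S = ∂x̄/∂θ (15×57), dS/dt = (∂f/∂x̄)S + ∂f/∂θ, S(0) = 0, using
forward Euler with step 0.01 d over 126 d. First-order convergence and
agreement with central finite differences of independently integrated
trajectories (relative step 10⁻⁴) to better than 10⁻³ are both tested.
Implementation note: the Euler sweep is batched over parameter vectors,
so the 115 quadrature nodes below are advanced in one vectorized loop.

Output functionals: "cancer" is the C̄ row of S; "total_cells" is the
weighted row sum T_h+T_c+T_r+D_N+D+0.2·M_N+M+C+N+A (naive T cells
excluded as a lymphatic compartment, naive macrophages down-weighted to
20%), computed in dimensional units via the per-variable scales so the
sum is physically meaningful.

The neighborhood average ŝ integrates s(θ) over the axis-aligned box
Ω = ∏ [θ_e(1−0.1), θ_e(1+0.1)] and normalizes by its volume, making ŝ a
box average; an unnormalized integral would differ by one constant
common to all parameters and leave rankings unchanged, and rankings are
the quantity of interest. The quadrature is a level-1
Smolyak/Clenshaw–Curtis sparse grid: 2·57+1 = 115 nodes — the box
center (weight 1 − 57/3, negative as usual for Smolyak) plus both
endpoints per axis (weight 1/6 each). Weights sum to 1; the rule is
exact for sums of per-coordinate cubics and is validated against a
dense Gauss–Legendre tensor grid on low-dimensional integrands. A rate
equal to zero degenerates its box coordinate to a point; that is
documented behavior, not an error. Ranking is by |ŝ| descending with
ties broken by canonical parameter order; signs are retained in the
report (positive means increasing the rate increases the output).

## Bifurcation scans

A scan replaces one rate with each value of a grid (default 201 points
on [0, 0.2]), re-integrates from each mouse's day-0 state, and records
dimensional cancer abundance at t = 42 d. This is a fixed-time
parameter sweep, not a continuation/eigenvalue analysis. The interval
[0, 0.2] spans roughly 2–30× the fitted magnitudes of the six most
cancer-sensitive rates.

## Synthetic data and what passing tests mean

`generate_study` integrates the model from known rates per pseudo-mouse
(defaults: the three day-0 states, sampling days {0, 14, 28, 42}) and
applies multiplicative log-normal noise x·exp(σz), z ~ N(0,1), σ = 0 by
default. Log-normal noise was chosen because the variables span four
orders of magnitude, so additive noise would drown the small
populations; the real data's noise model is unknown and this is an
explicit stand-in. Synthetic series are generated and fitted in the
nondimensional frame with unit scales — re-normalizing a synthetic
dataset by its own maxima would silently rescale the true rates.

The generator emulates the *structure* the estimator assumes (sparse
per-mouse sampling of exact model trajectories); it does not emulate
deconvolution error, RNA-seq count noise, model misspecification, or
inter-mouse parameter heterogeneity. Recovery results therefore show
that the finite-difference + bounded-least-squares scheme is consistent
(errors shrink with denser sampling; the six cancer-sensitive rates are
recovered to ≲1% median error from 41 noise-free days), not that the
biological rates from the real four-point dataset are accurate.

## The published rate vector vs. the refit

The bundled published vector reproduces the published *steady state*:
with its values, C̄* = C̄₀(1 − δ_C/λ_C) ≈ 0.98 ≈ 1, i.e. dimensional
cancer saturates near the observed maximum. It does not reproduce the
sampled-time *kinetics*: its net cancer growth rate (~0.004/d) is far
smaller than the slope implied by the data (~0.06/d), so integrating it
for 42 days leaves cancer near its initial value (the acceptance suite
computes exactly this and reports the discrepancy rather than masking
it). Refitting the embedded dataset with this package yields
λ_C ≈ 0.10, δ_C ≈ 0.039 and tracks the day-42 cancer data to −3…−20%
per mouse. Consequences: analyses tied to the published vector
(forward simulation to day 42; the top-6 sensitivity set, where the
cytotoxic-kill rate δ_CTc enters the top 6 for mice 1 and 3) disagree
in part with the published narrative, and the corresponding acceptance
tests fail honestly. The ranking's #1 parameter (δ_C) and the
bifurcation monotonicities are robust to this and hold for both vectors.

## Numerical choices and degenerate inputs

- Adipocyte closed form: logistic with effective rate r = λ_A − δ_A and
  capacity Ā₀(1 − δ_A/λ_A); the r = 0 case is the algebraic decay
  A₀/(1 + λ_A A₀ t/Ā₀), implemented with expm1 so r → 0 is continuous.
- States are validated (finite, nonnegative) at public entry points
  only; the integrator's internal evaluations are unvalidated.
- Euler divergence (non-finite states) raises with the failing time.
- Duplicate sampling times are rejected; derivative estimation needs at
  least three times.
- All stochastic stages (noise, Latin hypercube) take explicit seeds and
  are bit-reproducible.

## Default problem sizes

Sensitivity rankings use 115 sparse-grid nodes × 12 600 Euler steps per
mouse (~8 s each, batched); bifurcation scans 201 grid points × 6 rates
× 3 mice; synthetic recovery 41 sampling days × 3 pseudo-mice. The full
test suite runs in about a minute on one CPU.

## Known limitations

- Four sampling days cannot identify 57 rates; roughly half the fitted
  vector sits at the lower bound. The package reports this; it cannot
  fix it.
- Endpoint differencing (first-order) biases the slope estimates at the
  first/last days; the `interior-only` mode exists to quantify that.
- The sparse-grid level is fixed at 1 by default; higher levels would
  need a nested-rule generalization.
- Cytokine units are arbitrary gene-expression scores; only the
  nondimensional frame is meaningful for them.
- The tumor-composition calculator takes tumor sizes as given; the
  mapping from deconvolution fractions to absolute counts is upstream
  of this package.
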