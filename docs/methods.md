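# Methods

## Model and assumptions

The package implements the mean-field dynamics of a two-group SIS process
under assortative mixing. The two groups are of equal size (the simulator
allows unequal sizes as an extension); every individual interacts at most
once per period; the partner is drawn from the other group with
probability *m* and uniformly from the own group otherwise. There is no
spontaneous infection in the SIS variant, so (0, 0) is always stationary.
Parameters may be read as per-period probabilities or continuous-time
rates; the package treats them uniformly as rates, since only the
effective adoption rates λᵢ = p·υᵢ/δᵢ matter for equilibria and the
recovery rates merely rescale time (tested: equilibria are invariant to
rescaling δᵢ).

Group orientation is canonicalised to λ₁ ≤ λ₂ at construction and the swap
is recorded; the CLI restores the caller's order in outputs. The
degenerate case λ₁ = λ₂ is admitted and handled by the same code paths
(all curves are constant in *m*); the extreme mixing levels m = 0 and
m = 1 are handled by continuity of the same formulas, with the m = 1
reaction function reducing to its linear branch.

## Equilibrium computation

Stationarity of one group given the other is a downward-opening quadratic
in ρᵢ that is non-negative at 0 and equals −1 at 1, so its largest root —
the stable branch — always lies in [0, 1). `reaction_sis` evaluates it in
closed form, switching to the rationalised root expression when the linear
coefficient is non-positive to avoid cancellation.

`solve_equilibrium` first decides existence of the endemic state
analytically (λ₂ > 1 and either λ₁λ₂ > 1 or m < m̄) and otherwise returns
the origin. When the state exists it is the largest fixed point of the
composed reaction map h(ρ₂) = R₂(R₁(ρ₂)); h(ρ) − ρ is positive just above
0 and negative at 1, so Brent's method on that bracket is globally
convergent. This replaces a damped fixed-point iteration with warm-started
continuation along the curve: the bracketed scalar solve costs ≈30 cheap
closed-form evaluations per grid point (a 201-point curve takes ~15 ms),
so continuation machinery would add complexity without measurable benefit.
Residuals at the returned state are checked against 1e-11 and stability is
certified by the Jacobian (eigenvalue real parts ≤ 1e-8 count as stable,
covering the marginal cases at thresholds).

An equilibrium component below 1e-9 counts as extinct; near the mixing
threshold the analytic m̄ (whose denominator is bounded away from zero in
the admissible region by AM–GM) decides, and `equilibrium_curve` inserts
grid points at m̄ and m̄ − 1e-6 so the extinction of the endemic branch is
resolved to 1e-6 on the default 201-point grid.

The ODE integrator (LSODA, rtol 1e-10/atol 1e-12) serves as the
independent oracle for the algebraic solver. Without an explicit horizon
it extends the integration in doubling chunks until the stationarity
residual max|ρ̇ᵢ| falls below tolerance; states are clipped to [0, 1] with
a warning if the overshoot exceeds 1e-9.

## Regime classification and Pareto analysis

Regions are assigned with precedence A → B → E → C → D, with inequalities
within 1e-9 of equality recorded as boundary flags. The region-E condition
λ₁^{3/4}(λ₂ + 1) ≥ λ₂^{3/4}(λ₁ + 1) compares g(λ) = λ^{3/4}/(λ + 1)
between the groups; g peaks at λ = 3, which is why region E requires
λ₂ > 3 — the same fact the acceptance script recovers numerically. The
C/D split (is the resistant-group curve non-monotonic?) is decided by a
numeric monotonicity scan of the equilibrium curve on a 101-point grid;
the closed-form boundary candidate λ₁ = √λ₂/(λ₂ − √λ₂ + 1) is kept as a
cross-check only, because the scan is what the definition states.

Monotonicity detection filters finite differences below an absolute
tolerance of 1e-7 (solver noise is ~1e-14, real curve increments on the
default grid are ~1e-3) and classifies the surviving sign sequence;
curves with more than one significant sign change are rejected rather
than force-fitted. Interior extrema are refined by parabolic
interpolation of the three neighbouring grid points.

Pareto dominance is evaluated pairwise on the curve's own grid: level m is
dominated when some grid level m′ is weakly better for both groups (within
1e-9) and strictly better for one (beyond 1e-9), under a single
orientation flag (infection undesirable by default; the logic is symmetric
under flipping it). Contiguous dominated points are merged into intervals;
the reported witness is chosen to dominate the whole interval when such a
common witness exists.

## General state-conditional model

The §-free statement of the model: both transitions depend on the
partner's state through the exposure Iᵢ = (1 − m)ρᵢ + mρⱼ, with rate
bundles constrained to 0 < υ|S < υ|I < 1 and 0 < δ|I < δ|S < 1. The
printed dynamics carry no separate interaction probability p; the package
takes them at face value (p absorbed into the rates). Because υ|S > 0 the
stationarity quadratic is positive at 0 and negative at 1, so the reaction
function is strictly interior — there is no extinction in this model — and
strictly increasing in ρⱼ. Curvature is classified by the sign of
(υ|I − υ|S) − (δ|S − δ|I) with a 1e-12 band for the linear case. The
equilibrium is again a bracketed scalar root of the composed reaction map;
in the concave–concave case uniqueness is inherited and additionally
asserted in tests by running the monotone corner iterations from (0, 0)
and (1, 1) and requiring agreement within 1e-8. For mixed curvature
uniqueness is not guaranteed: the solver emits a warning and compares the
two corner limits instead of asserting uniqueness.

## Finite-population simulator

Updating is synchronous against start-of-period states, matching the
per-period probability structure from which the mean dynamics are derived;
partner sampling is one-sided (each agent draws its own partner and reads
its state). Consequently the expected one-period update is exactly one
Euler step of the ODE with unit step (`deterministic_step`, tested against
`sis_rhs`). Own-group partners exclude the agent itself via an
index-shift draw; this is an O(1/N) correction to the mean-field term.
Replicate streams are spawned from a single `SeedSequence`, giving bitwise
reproducibility for a fixed seed; multipliers, initial conditions and the
dynamics use separate child streams so that switching heterogeneity off
leaves the trajectory stream untouched (σ = 0 reproduces the homogeneous
run exactly).

Within-group heterogeneity multiplies υᵢ by per-agent lognormal draws with
mean 1 and log-scale σ (applied to susceptibility only, the simplest
within-group spread). Extinct replicates are flagged and excluded from the
quasi-stationary summary, which averages the last 20% of periods.

The generator emulates the study conditions of the mean-field analysis: a
well-mixed two-group population with binary states and identical
within-group rates. It does not emulate contact networks, degree
heterogeneity, varying population size or asynchronous updating, so
agreement between the simulator and the ODE speaks to finite-size
stochastic effects only, not to network realism.

## Problem sizes and numerical choices

The default curve grid is 201 points on [0, 1]; classification scans use
101. The stochastic consistency check uses N ∈ {100, 1000, 10000} per
group, 2000 periods and 20 replicates at the reference rates λ = (2, 5)
via (p, υ, δ) = (1, (0.4, 0.5), (0.2, 0.1)) and m = 1 — sizes at which the
quasi-stationary bias (~2·10⁻⁴ at N = 10⁴) is resolved but the whole
ensemble still runs in well under a minute. Random-draw oracle tests
sample λ₁ ∈ [0.2, 3], λ₂ ∈ [1.1, 5] excluding neighbourhoods of the
critical manifolds (|λ₁λ₂ − 1| < 0.1, |λᵢ − 1| < 0.05, |m − m̄| < 0.05):
at criticality the dynamics converge algebraically rather than
exponentially, so no fixed horizon reaches a 1e-6 endpoint match there —
a property of the model, not of the solver.

The threshold-constant searches in `scripts/acceptance.py` are pure
bisections on solver-based indicators. The regime-E entry search declares
an average-infection curve non-decreasing when its total drawdown
(running-maximum minus value) stays at solver precision (≤ 1e-12) while
its total rise exceeds 1e-6: near λ₁ = λ₂ the curve flattens like
(λ₂ − λ₁)², so the rise floor forces λ₂ − λ₁ large enough that any true
non-monotonicity produces a drawdown orders of magnitude above solver
noise, making the indicator scale-free where any fixed larger tolerance
would misclassify.

## Known limitations

- No closed form for the interior equilibrium at 0 < m < 1 (the fixed
  point solves a quartic); everything interior is numerical.
- The C/D boundary is located only to the resolution of the monotonicity
  scan; labels within ~1e-7 of the boundary carry a flag rather than a
  guarantee.
- The simulator's synchronous, one-sided-contact scheme is one of several
  microfoundations with the same mean field; event-driven (Gillespie)
  dynamics are out of scope.
- Mixed concave/convex conditional-rate bundles may admit multiple
  interior states; the package reports and warns rather than resolving
  the full bifurcation structure.
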