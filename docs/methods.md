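# Methods

## Model

The GINAR(1) process is the stationary first-order integer-valued
autoregression

    X_t = ρ∘X_{t−1} + B_t·G_t,

where `ρ∘X` is binomial thinning (each of the X current "individuals"
survives independently with probability ρ), `B_t ~ Bernoulli(1−ρ)` and
`G_t ~ geometric(p)` independently. Our geometric convention throughout is
support {0, 1, 2, …} with `P(X = j) = (1−p)^j p`, mean (1−p)/p — stated
explicitly because many libraries count trials rather than failures. Under
this convention the innovation `ε = B·G` has the zero-inflated geometric law

    P(ε = 0) = p(1−ρ) + ρ,   P(ε = j) = (1−ρ)(1−p)^j p  (j ≥ 1),

which is exactly what makes geometric(p) the stationary marginal (the
probability generating functions factor), and the lag-k autocorrelation is
ρᵏ. Parameters: p ∈ (0, 1); ρ ∈ [0, 1). ρ = 0 is supported as the iid
limit — useful because every run-length quantity then has a closed form
used as a test oracle. ρ = 1 is rejected (a frozen, non-ergodic chain).

The transition law is the convolution of a binomial(i, ρ) survivor count
with the innovation, evaluated in closed form with log-gamma binomial
coefficients (overflow-safe to states of a few hundred). The truncated
transition matrix on {0..n} is never renormalised; each row's deficit is
kept as auditable tail mass, and the default n is the smallest with
marginal tail (1−p)^(n+1) < 1e−12.

## Run-length engine

The chart signals at the first t with X_t > U. Run lengths are discrete
phase-type on the substochastic block Q = [p_ij], i, j ≤ U — a finite block
of the infinite chain, so exact. ARL and SDRL come from linear solves
against (I − Q) (never an explicit inverse): a = (I−Q)⁻¹1 gives E[RL_u] =
a_u and E[RL_u²] = e_u'(I+Q)(I−Q)⁻²1. Survival probabilities are obtained
by propagating the initial row vector one step at a time until P(RL > m)
falls below a cutoff (default 1e−12, hard cap 10⁶ steps). The hazard is
λ(m) = P(RL = m)/P(RL ≥ m) with P(RL ≥ m) = survival[m−1].

**Overall run length.** When monitoring starts cold, the initial state is
the first monitored count itself, X_1 ~ geometric(p). We read this
literally: a signal is possible already at t = 1, with probability
P(X_1 > U) = (1−p)^(U+1), so with the defective vector π_u = (1−p)^u p
(u ≤ U),

    P(RL > m) = π' Q^(m−1) 1  (m ≥ 1),   E[RL] = 1 + π'(I−Q)⁻¹1,

and E[RL²] = 1 + 2π'(I−Q)⁻²1 + π'(I−Q)⁻¹1. The alternative reading — X_1
as an unmonitored warm-up state — changes the in-control ARL of the worked
example by about one sample and is not what the engine computes. The
literal convention is confirmed against direct Monte-Carlo simulation of
the process recursion, including at the admissibility boundary
p = ρ/(ρ+1), where the two conventions differ most.

**Perron root.** ξ is taken from a dense eigendecomposition of Q and
cross-checked by power iteration on Q + cI (the shift makes the real
Perron root strictly dominant regardless of primitivity); disagreement
beyond 1e−10 raises rather than returning a silent average. The run-length
tail is geometric-like with ratio ξ; hazards converge to 1 − ξ from either
start, which the engine verifies numerically at large m.

## Ordering verifiers

All verifiers return a verdict, the minimal signed margin, and — on
failure — the indices of the first violation so the offending minor or
tail sum can be recomputed by hand. The default tolerance is 1e−12:
entries are probabilities of order 1, the properties are exact when true,
and only floating-point rounding can produce spurious tiny negatives.

- `is_tp2`: all 2×2 minors non-negative. The exhaustive O(n⁴) scan is the
  reference (truncated rows contain zeros, for which the adjacent-minor
  shortcut is not sufficient); the adjacent scan is provided for strictly
  positive matrices.
- `is_pf2_sequence`: log-concavity f(x+1)² ≥ f(x)f(x+2); the geometric pmf
  is the equality case.
- `lr_le` / `st_le`: likelihood-ratio order via the division-free
  cross-product criterion f(x)g(y) ≥ f(y)g(x) for x < y (blocked so long
  run-length grids never materialise an n² array); usual order via
  survival dominance.
- `kalmykov_le`: row i of the smaller matrix stochastically below row m of
  the larger whenever i ≤ m. For transition-matrix inputs tail sums are
  computed as complements 1 − Σ_{j<l} entries, which is *exact* for rows
  of a stochastic chain; literal window sums over the stored columns are
  used for raw arrays. The distinction matters: with window sums, the
  stochastically larger matrix leaks more mass past the truncation edge
  and produces spurious violations of order 1e−10 at low levels.

## A negative result the verifiers surface

The transition matrix of the GINAR(1) process is **not** totally positive
of order 2 for any ρ > 0, although TP2 is the classical route to the
run-length shape results below. The obstruction is structural: the
innovation is zero-inflated geometric, and

    ε(1)² − ε(0)ε(2) = −ρ(1−ρ)p(1−p)² < 0,

so the innovation is never log-concave, and rows 0 and 1 of the matrix are
not likelihood-ratio ordered — the ratio p₁ⱼ/p₀ⱼ = (1−ρ) + ρ·ε(j−1)/ε(j)
jumps at j = 1 because of the inflated zero mass, then drops. At
(p, ρ) = (0.63, 0.165) the minor on rows (0,1), columns (1,2) equals
−0.00196 — far beyond rounding, and confirmed by brute-force simulation of
the one-step transition probabilities. `is_tp2` therefore reports a
violation, with witness, on every autocorrelated GINAR(1) matrix.

Remarkably, the *consequences* classically derived from TP2 all hold
numerically for this chart, and the package tests them directly rather
than inferring them: the zero-start run length is PF2/IHR, the head-start
run length is DHR, the head-start hazard dominates pointwise, run lengths
are lr-ordered in the initial state, st-ordered in p, and the overall ARL
is increasing in p on the admissible interval (ρ/(ρ+1), 1) — verified over
randomised admissible parameter sweeps as well as the worked example. The
Kalmykov comparison between transition matrices at p ≤ p′ (shared ρ) also
holds exactly. `verify_corollaries` aggregates all of these into one
report; the CLI `verify` additionally reports the TP2 check and thus exits
non-zero — honestly — on autocorrelated inputs.

## Synthetic data

The simulator implements the defining recursion itself (sequential
thinning, innovations drawn as Bernoulli×geometric products — not
inverse-CDF sampling of the innovation law), with all randomness through
one seeded generator. The bundled scenarios mirror the worked example: an
in-control series of 144 counts at (0.63, 0.165), the same length at a
10% downward shift in p, and an iid ρ = 0 series. This emulates the
marginal, the autocorrelation, and the Markov dependence of real
monitoring data, but not features the model excludes — overdispersion
beyond geometric, seasonality, trend, or measurement error — so passing
tests validate the chart's mathematics, not the adequacy of the GINAR(1)
model for any particular data set. The moment estimator
(p̂ = 1/(1 + mean), ρ̂ = lag-1 autocorrelation clipped to [0, 1)) is
deliberately minimal plumbing for the monitoring workflow; likelihood
fitting is out of scope.

## Numerical choices and problem sizes

- Tolerances: 1e−12 on probability-scale margins; 1e−6 relative between
  the ARL from the linear solve and the summed survival series; 1e−6 on
  hazard convergence to 1 − ξ.
- Run-length horizons: tail cutoff 1e−12 (about 10,900 steps for the
  worked example) where the tail matters; looser cutoffs with an explicit
  step cap in the bulk property sweeps, which operate on truncated common
  grids.
- Monte-Carlo oracle sizes: 10⁵ paths for ARL cross-checks (vectorised
  across paths), T = 10⁵ for marginal/autocorrelation recovery — both
  give 3-standard-error bands a few per mille wide.
- Degenerate inputs: constant series make ρ̂ unidentified (error, not a
  silent 0); percentile requests beyond the computed horizon raise with
  advice to lower the cutoff; U = 0 charts and ρ = 0 processes are fully
  supported.

## Known limitations

Lower one-sided and two-sided charts, CUSUM/EWMA statistics, and
steady-state ARL variants beyond the overall run length are out of scope,
as are negative-binomial-thinning (NGINAR) and zero-modified relatives of
the process. The chart cannot detect *increases* in p (decreases in the
mean): the ARL grows with p, and the profile tooling surfaces this rather
than hiding it. The overall ARL at the exact boundary p = ρ/(ρ+1) of the
admissibility interval is small (≈ 2.7 for the worked chart) because at
that parameter the marginal mean equals 1/ρ and P(X_1 > U) is already
large; the boundary itself sits outside the strict admissibility condition
and is reported for orientation only.
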