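# Methods

This note documents the models, conventions and numerical choices behind
`lifeineq`, in the order the data flows: life tables → distributions →
indices → normalization → robustness → decomposition → panels → synthetic
data.

## Life tables and age-at-death distributions

A `LifeTable` is a single-year-of-age period table on integer ages
0..A_top, with the last interval [A_top, ∞) open. Construction from death
rates follows the standard recursion: for closed unit intervals
qx = mx / (1 + (1 − ax)·mx), lx by survival products from the radix,
dx = lx·qx, Lx = l(x+1) + ax·dx; the open interval has qx = 1 and
ax = 1/mx, so ex(A_top) = ax(A_top) exactly whenever survivors reach it.
Validation enforces qx ∈ [0,1], non-increasing lx, non-negative dx, and
Σdx = l₀ to 2·10⁻³ of the radix (loose enough for the integer-rounded
counts of printed HMD files, tight enough to catch real corruption).

The `AgeAtDeathDistribution` carries the normalized death shares d and the
within-interval mean ages x̄ = x + a(x). Two x̄ conventions exist and are
never mixed silently: the life-table convention (default a = 0.5 when no
table supplies ax) and the point-mass convention x̄ = x used by worked
examples and by the maximal-inequality benchmark. The open interval's mass
sits at the finite age A_top + 1/m(A_top); e₀ is always Σ dₓ x̄ₓ by
construction, which agrees with the table's ex(0) to well under 0.05 years
on every generated table (both are exposed; recomputation is the default).
The HMD period 1×1 reader accepts the standard layout (preamble, header
line starting `Year`, `110+`-style open age, `.` for missing) and the
writer round-trips all numeric fields at printed precision.

## Inequality indices

AID is evaluated both as the defining O(n²) double sum and through an
O(n log n) sorted cumulative form; the two agree to 1e-12 and the fast form
is the default. σ and CV are ordinary weighted moments of (d, x̄). e† is
Σ dₓ·e(x̄ₓ) with the remaining expectancy e(·) linearly interpolated from
the ex column at x + ax (clamped at the top age); evaluation at integer
ages is available via `at="integer"`. The interpolation choice matters
little at HMD granularity (the two options differ by a few percent) but is
stated because no canonical discrete quadrature for e† exists.

## The maximal-inequality benchmark and normalized indices

Among distributions with mean e₀ and support in [0, ω], the two-point
distribution M(e₀, ω) — mass s₁ = 1 − e₀/ω at exact age 0, the rest at
exact age ω — maximizes the Gini-type and variance-type indices. The
benchmark uses exact point masses (not interval-shifted x̄): the closed
forms below hold only under this convention.

Closed-form values on M, each unit-tested against direct evaluation:

| index | value on M(e₀, ω) |
|---|---|
| AID, e† | e₀(ω − e₀)/ω |
| G, H | (ω − e₀)/ω |
| σ | √(e₀(ω − e₀)) |
| CV | √((ω − e₀)/e₀) |

Maximality of M is a theorem for AID and G (the classical extremal
property of the Gini on bounded support) and for σ and CV (the
Bhatia–Davis inequality σ² ≤ e₀(ω − e₀) with equality exactly at the
two-point distribution). It is **not** true for e† and H: a
young-death-heavy schedule (e.g. near-exponential mortality) has
e† close to e₀, which exceeds e₀(ω − e₀)/ω whenever e₀ is well below ω
(the uniform density on [0, ω] attains the bound exactly). The normalized
e†* and H* are therefore reported as ratios to the benchmark value — a
meaningful reference, and < 1 for every rectangularized modern schedule —
but they are not guaranteed to stay below 1 for pre-transition mortality.
The test suite asserts the ≤-benchmark property, and I* ∈ [0, 1], for
AID, G, σ and CV only.

Normalization requires 0 < e₀ < ω and no death mass above ω (an error is
raised otherwise; HMD-style tables topping out near 113 never trigger it
at the default ω = 122, the oldest recorded age at death). AID* ≡ G*
holds to machine precision by algebra; G*(A, ω) = G·ω/(ω − e₀) decreases
strictly in ω and converges to the classical G, linking the bounded and
unbounded views of lifespan inequality.

## ω-robustness of comparisons

Viewed as functions of ω on (max e₀, ∞), two populations' G* curves are
ratios of linear functions and cross at most once, at

    ω* = (G_A·e₀_B − G_B·e₀_A) / (G_A − G_B).

A comparison is *complete* when no crossing lies above the admissible
floor (default 122 years, configurable), *partial* when ω* exceeds it, and
a *tie* only for identical (G, e₀). Equal Ginis with different e₀ never
cross: the larger e₀ carries the larger correcting factor ω/(ω − e₀) for
every ω. The closed form is verified in-tree against Brent root-finding
(1e-9 absolute, for crossings up to ω* = 2000 — beyond that the difference
curve is numerically flat and no root-finder resolves below ~1e-9) and
against dense grid scans for single-crossing. Panel-level
`rank_consistency` counts unordered pairs whose ranking is invariant over
an ω range, with an independent brute-force grid mode as audit path; ranks
at fixed ω break exact ties by smaller e₀, explicitly.

## Age decomposition

`horiuchi_decompose` attributes I(lt₂) − I(lt₁) to ages by the
continuous-change method: each age-specific rate m(x) travels a
proportional (log-linear) path from table 1 to table 2, split into
n_steps equal substeps; within a substep the contribution of age x is the
index difference from moving m(x) alone across the substep with all other
rates at the substep midpoint, rebuilding the full life table from rates
at every evaluation. Ages with a zero rate on either side fall back to an
additive-linear path and are flagged in the result. Closed-interval ax is
held at table 1's values along the path; the open interval keeps ax = 1/mx.

The additivity residual shrinks as O(n_steps⁻²). At the default
n_steps = 20 it is ≤ 1e-4 of the total change for the dimensionless
indices (G, G*, CV, H) on decade-scale mortality changes — the method's
typical use — and ~3e-4 for the extreme full-transition jump
(e₀ 31 → 83); the absolute indices (AID, σ, e†), whose changes are whole
years, need n_steps ≈ 80 for the same relative gap. The decomposition is
antisymmetric under swapping its arguments to the same tolerance.

The *threshold age* reported from a decomposition is the first age of the
final maximal run of positive (inequality-increasing) contributions; it is
absent when no positive run exists or when contributions are positive from
age 0. This convention stays defined for improvement-only scenarios where
contributions below the improved ages are exactly zero. Note the sign
structure: under a broad mortality decline, improvements just above
retirement ages can still *reduce* Gini inequality — only improvements
above the threshold age (≈82 for the low-mortality synthetic table) raise
it, and the normalized Gini's contributions at old ages are uniformly
larger in magnitude than the classical Gini's on such scenarios.

## Panel analytics

`build_panel` computes every index per (population, sex, year) under
either a fixed ω or a year-specific record-lifespan step series
(non-decreasing, looked up at the latest record standing in each year),
erroring when ω would fall at or below any table's top mean age at death.
Rolling correlations pool all country-year observations in a centred
5-year window (equal weight per observation, not per country) and return
an absent value below 3 points or under zero variance. Joint-change
quadrants classify consecutive-year relative changes (v₂ − v₁)/v₁ of e₀
and an index (log-changes optional); exactly-zero changes are counted and
reported as ties, never assigned to a quadrant, and shares are over the
classified pairs. `max_inequality_curve` emits the bounding curves for
scatter plots — an inverted parabola peaking at ω/2 for AID, a straight
line reaching 0 at e₀ = ω for G; every panel point lies on or below its
curve.

## Synthetic data

The generator emulates the epidemiological transition with the Siler
hazard m(x) = a₁e^(−b₁x) + a₂ + a₃e^(b₃x). Presets:
high-mortality (a₁ = 0.25, b₁ = 1.1, a₂ = 0.010, a₃ = 3.2e-4, b₃ = 0.085;
q₀ ≈ 0.22, e₀ ≈ 31) and low-mortality (a₁ = 0.004, b₁ = 1.6, a₂ = 5e-4,
a₃ = 3.5e-5, b₃ = 0.085; q₀ ≈ 0.004, e₀ ≈ 83), chosen so that the
transition spans the e₀ ≈ 30s → 80s range of long national series while
every rate declines: parameters interpolate log-linearly over years, and
with b₃ shared and all level parameters falling, m(x, t) is monotone
decreasing in t at every age, so e₀ rises strictly in the noise-free mode.
Populations within a panel differ by a single multiplicative frailty-style
level factor (lognormal, σ = 0.08) drawn once per population from the
seeded stream; the optional stochastic mode observes rates as
Poisson(m(x)·exposure)/exposure death counts. A synthetic record-lifespan
series rises linearly from 113 to 122 over the panel years — above every
table's top mean age at death (110 + a(110⁺) ≈ 113), mirroring how the
real record series sits above national top ages.

What the generator does *not* emulate: period shocks (wars, epidemics),
cohort effects, old-age mortality deceleration/plateaus, and
between-population heterogeneity richer than a level shift. Consequently,
synthetic populations are far more similar to one another than real
countries are — pairwise ω-robustness on a synthetic panel is much lower
than on heterogeneous real data — and passing tests demonstrate the
correctness of the estimators and decompositions, not empirical claims
about any real population.

## Problem sizes and determinism

The test and acceptance runs use 10,000 random distributions for the
maximality suite, 1,000 for the identity and ω* suites, decade-step Siler
pairs for the Horiuchi suite (40–100 pairs), and 111-age tables
throughout; all random draws come from `numpy.random.default_rng` seeded
explicitly, and the acceptance script derives every stream from its
`--seed` argument.
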