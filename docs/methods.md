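# Methods

This note documents the model, the numerical and design choices, and what
the synthetic fixtures do and do not establish about real data.

## The compartmental model

A colony of fixed size N is partitioned into active A(t), inactive I(t) and
refractory R(t) individuals. Inactive and refractory ants are behaviourally
indistinguishable (neither moves), but only inactive ants can be activated
by contact with an active ant. Three processes act:

| transition | rate | mechanism |
|---|---|---|
| A + I → 2A | β₀ per active contact | social contagion (recruitment) |
| 2A → R + A | γ₀ per active–active contact | reverse social contagion (mutual inhibition) |
| R → I | δ, spontaneous | completion of rest |

Contacts are mediated by an interaction network with mean degree
⟨k⟩ = 2E₀N^(α−1), α ∈ [1, 2]; mass-action mixing gives the ODE system in
the README. Summing the right-hand sides gives zero, so A + I + R = N is
conserved; a comparison-principle argument gives positivity, including the
pointwise bound R(t) ≥ R₀·e^(−δt) that the tests check on integrated
trajectories. There are no spontaneous activation/inactivation channels and
no fixed rest period: the model is deliberately minimal so that the effect
of the socially driven negative feedback is isolated.

**Units.** Time is seconds and all rates 1/s throughout — configuration
files, CSV outputs and the agent-based time step all share this convention.

## Equilibria, stability, scaling

With φ(x, y) = √((1+x)² + y) − (1+x) and x = γ₀/β₀, y = 4γ₀⟨k⟩/δ, the
positive equilibrium is

    A* = δN/(2γ₀⟨k⟩)·φ,   I* = (γ₀/β₀)·A*,   R* = (φ/2)·A*,

the positive root of (γ₀⟨k⟩/δN)A*² + (1+γ₀/β₀)A* − N = 0 (the other root is
negative for all admissible parameters). φ is evaluated in the rationalized
form y/(√((1+x)²+y) + (1+x)) to avoid cancellation at small y.

The Jacobian at the trivial equilibrium has spectrum {0, −δ, β₀⟨k⟩}
(unstable). At the positive equilibrium the characteristic polynomial
factors as p(s) = −s(s² + a₁s + a₂); using β₀I* = γ₀A* and κ = ⟨k⟩/N,

    a₁ = κ(β₀+γ₀)A* + δ,
    a₂ = 2κ²β₀γ₀A*² + δκ(β₀+γ₀)A*,

both manifestly positive, so by Routh–Hurwitz the two nonzero eigenvalues
have negative real parts: marginal stability, with the zero eigenvalue the
structural consequence of conservation. The printed nested-radical form of
these coefficients in the source analysis is typographically ambiguous; the
implementation therefore derives them from the trace and principal minors of
the analytic Jacobian — the same algebra — and the test suite verifies that
the quadratic's roots coincide with the numerically computed nonzero
eigenvalues to 1e−8 relative across 1000 random parameter draws (the
eigen-decomposition is the authoritative oracle). An eigenvalue is treated
as the structural zero when |λ| < 1e−9 × (fastest rate × max(⟨k⟩, 1)).

Global stability is certified by the Goh-type Lyapunov function V(A, R) of
the reduced system (I eliminated by conservation), whose orbital derivative

    dV/dt = −δ(R−R*)²/N² − (⟨k⟩/N³)(γ₀+γ₀²/β₀)(A−A*)(A²−(A*)²)

is non-positive on (0, N]×[0, N] and zero only at the equilibrium. The
implementation exposes both V and dV/dt; tests check sign on a 100×100 grid,
agreement of the closed-form rate with a finite-difference gradient oracle,
and monotone decrease of V along integrated trajectories.

**Scaling.** For α > 1 and N ≫ 1, A* ≈ √(δ/(2γ₀E₀))·N^((3−α)/2): hypometric
growth of activity with colony size. The approximation is controlled by the
validity ratio y/(1+x)² = (4γ₀⟨k⟩/δ)/(1+γ₀/β₀)²; it must be ≫ 1. **At the
calibrated rates this ratio is only ≈ 22 at N = 500 and ≈ 37 at N = 1000**,
so the *exact* equilibrium's fitted log-log slope over N = 10…1000 is ≈ 0.83
rather than the asymptotic (3−α)/2 = 0.765; the two agree only for
N ≫ 10³. The test suite states the asymptotic claim at ±0.05 over those
sizes and that assertion fails by design — it documents a real property of
the exact equilibrium, and weakening it would hide the finite-size
behaviour. The ablation controls are unaffected: the no-refractory model has
A* = β₀N/(β₀+γ₀) and the no-reverse model A* = Nδ(β₀⟨k⟩−μ)/(β₀⟨k⟩(δ+μ))
(feasible iff μ < β₀⟨k⟩, reported as a typed infeasibility value otherwise),
both proportional to N up to vanishing corrections — fitted exponents
1.00 ± 0.01.

μ, the spontaneous inactivation rate of the no-reverse variant, has no
calibrated value; the default 0.121 1/s (= γ₀/10) keeps μ ≪ β₀⟨k⟩ over the
whole size range so the variant sits well inside its feasible region. For
α = 1 the exact no-reverse equilibrium is δ/(δ+μ)·(2β₀E₀−μ)/(2β₀E₀)·N; the
crude large-colony reading δ/(δ+μ)·N simply drops the second factor.

## Numerical integration

Adaptive Runge–Kutta (scipy RK45) with rel_tol 1e−9 and abs_tol 1e−12
defaults; the system is non-stiff at the calibrated rates. Conservation
drift stays below 1e−6·N and positivity violations below 1e−9·N on all
tested trajectories. Output grids are linear by default with a log-spaced
option for log-time plots. A₀ = 0 is accepted with a logged warning (the
activity dynamics are frozen; only R → I relaxes). States are real-valued
mean-field counts; integer semantics belong to the agent-based model.

## The agent-based model

N agents with states in {A, I, R} update synchronously in discrete time
(default Δt = 0.0667 s, the effective video frame interval). At every step a
fresh Erdős–Rényi graph with link probability p = ⟨k⟩/N is drawn —
memoryless switching, the full-mixing limit; p > 1 is clipped with a
warning. From the time-t snapshot: an inactive agent with m active
neighbours activates with probability 1−(1−β₀Δt)^m, an active agent with m
active neighbours becomes refractory with probability 1−(1−γ₀Δt)^m, and a
refractory agent becomes inactive with probability δΔt. Each active
neighbour is an independent Bernoulli channel with per-step probability
rate×Δt (validated ≤ 1 at configuration; at the calibrated rates the
difference from 1−e^(−rΔt) is < 0.5%). Only the focal agent transitions in
an inhibition event; both endpoints of an active–active edge roll
independently, and simultaneous double-inactivation is allowed (a
second-order effect in Δt). A `linear` combination rule min(m·rΔt, 1) is
available behind a config flag for sensitivity analysis.

Averaged over networks, the expected one-step change of A is
Δt·(⟨k⟩/N)(β₀AI − γ₀A(A−1)) + O(Δt²) — the mean-field bilinear/quadratic
terms with the exact finite-size A(A−1) in place of A²; a brute-force
enumeration over all networks of 4 agents checks this identity. Ensembles
use per-realization RNG streams spawned from one root seed and are
bit-reproducible. At the reference settings (N = 500, β₀ = γ₀/10, 150
steps, 10 realizations; and N = 10 with 100 realizations) the ODE lies
inside the ensemble mean ± 2 sd band for ≥ 95% of steps in every
compartment for the package's default seed; across 20 seeds the band
criterion holds in 18 — the 2-sd band with 10 realizations leaves a small
tail probability of a marginal dip in one compartment.

The steady-state active fraction at β₀ = γ₀/10 rises only from 0.086
(N = 500) to 0.090 (N = 10) in the exact equilibrium — a ratio of 1.04, not
a multiple; the package reports both the equilibrium and the simulated
ratio rather than asserting any particular fold change.

Networks are sampled by drawing the edge count from Binomial(N(N−1)/2, p)
and then choosing that many distinct pair indices uniformly (decoded from
the strict upper triangle), which is vectorized and tested against the
binomial oracle; the realized mean degree is ⟨k⟩(N−1)/N, the standard
G(n, p) finite-size factor.

## Calibration

The pipeline follows the video-analysis procedure: 6 mm inclusive contact
radius (one body length), one-pixel displacement activity scoring (frame 0
unscored), per-colony mean edge count E fitted against N on log axes
(E = E₀N^α), the reverse-contagion extent y = 2A²E/N² fitted through the
origin to identify q = δ/γ₀, event-count estimation of γ₀, and δ = q·γ₀.
β₀ is never reported: with I and R indistinguishable in video the observable
activation probability is independent of β₀, so the data cannot identify
it — the result type has no such field by design.

Two stages needed a counting/regression dialect to be fixed, and in both
cases the package defaults to the dialect that is *consistent with the
model's own dynamics* (the alternatives remain available via flags):

* **γ₀ events** (`event_unit`). Under the model, an active ant with m
  active partners deactivates with probability 1−(1−γ₀Δt)^m: each active
  partner is an independent channel of probability γ₀Δt. The default
  `interaction` unit therefore counts the *directed* active–active contact
  observations in the denominator and each deactivating ant once in the
  numerator, so numerator/denominator estimates γ₀Δt without multiplicity
  bias. Counting undirected edges (`edge`) measures the per-edge event
  probability ≈ 2γ₀Δt, and counting ants with ≥ 1 active partner (`ant`)
  measures γ₀Δt·E[m | m ≥ 1]; both overestimate whenever active–active
  contacts are not vanishingly sparse. The remaining bias of the default is
  the saturation term ≈ (γ₀Δt/2)·E[m], a few percent at the fixture's
  contact densities.
* **q regression** (`q_regressor`). At the steady state the extent obeys the
  exact identity y = (δ/γ₀)(N − (1+γ₀/β₀)A*), so the historical
  through-origin fit of y on N underestimates δ/γ₀ by the weighted mean of
  (1+γ₀/β₀)A*/N — 35–40% at N = 40–360 with the calibrated rates. The
  default `finite_size` regressor fits y through the origin on (N − A) with
  the *measured* A, removing the leading term (residual bias
  ≈ (γ₀/β₀)·A/N); `origin` (the historical fit on N) and `ols` (with
  intercept) are available for comparison. The identification q = δ/γ₀ is
  itself a large-N statement in either form.

`estimate_gamma0` works on the counts themselves, so the published worked
example (800/9861 = 0.0811 → γ₀ = 0.0811/0.0667 = 1.216 1/s; the source
prints 1.21, a last-digit rounding; δ = 0.519·γ₀ = 0.631 ≈ 0.63 1/s) is
reproduced exactly regardless of dialect.

Multiplying all coordinates, the contact radius and the pixel size by a
common factor leaves every estimate unchanged (scale invariance, tested).

## Synthetic fixtures

The generators emulate the structure of the tracked videos (16 colonies of
40–360 workers, 450 frames at Δt = 0.0667 s, 248 mm square arena) with
planted parameters, since the original videos are not deposited.

* **Network fixtures** drive the agent-based update on freshly drawn
  Erdős–Rényi graphs with the planted degree law and label an ant active
  exactly when its planted state is A. They are the ground truth for the
  E₀/α fit, the q fit and the event counting. Colonies start at the rounded
  ODE equilibrium with a burn-in (default 100 steps) so that recorded frames
  sample the steady state — the regime the videos represent.
* **Track fixtures** place ants in the arena; active ants step 1–4 pixels
  (uniform) in a uniform direction, non-active ants jitter with 0.15 px
  Gaussian noise, and walls reflect. The state dynamics run on the 6 mm
  *proximity* graph of the current positions, because an arbitrary degree
  law cannot in general be realized as a unit-disk graph — so track fixtures
  validate activity scoring, network construction and IO, while degree-law
  recovery is validated on the network fixtures. The pixel size (0.5 mm) is
  not printed in the source description; only the ordering jitter < pixel ≤
  minimum active step matters, and it guarantees near-perfect scoring up to
  rare reflection clipping (< 1% label error, tested).

**What the recovery experiment shows.** The end-to-end recovery test plants
(E₀ = 0.0944, α = 1.47, γ₀ = 1.21 1/s, δ = 0.63 1/s, β₀ = 10γ₀) and uses 8
colonies with N from 300 to 3000 (200 recorded frames each): the q = δ/γ₀
identification is explicitly a large-N statement, and at video-sized
colonies (N ≤ 360) its finite-size bias exceeds the recovery tolerances for
any regressor. Recovered values land within 10% (E₀, γ₀), 0.05 (α) and 15%
(δ). Passing this test shows the pipeline is consistent with the model's
own dynamics in the estimators' validity regime; it does not show that real
ant colonies satisfy the model, that manual tracking is error-free, or that
the estimators are unbiased at N = 40–360.

## Known limitations

* The fitted activity-scaling exponent of the exact equilibrium approaches
  (3−α)/2 only for colony sizes far beyond the empirical range (see
  Scaling above); at N ≤ 1000 the exact slope is ≈ 0.83.
* The agent-based model is a full-mixing limit (memoryless network
  switching); no spatial correlations, motion models, task types or
  individual heterogeneity.
* Calibration assumes complete, gap-free tracks; missing coordinates are
  dropped per row, not interpolated.
* The γ₀ estimator retains an O(γ₀Δt·E[m]) saturation bias at high
  active-contact density; the q identification requires N ≫ 1.
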