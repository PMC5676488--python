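# Methods

## Model and assumptions

The package analyzes a planar population model of effector (immune) cells
`x` and immunogenic tumor cells `y` in nondimensional form:

    dx/dt = σ + α·x·y/(1+y) − μ·x(t−τ)·y(t−τ) − δ·x
    dy/dt = f·y·(1−β·y) − x·y

Immune recruitment saturates in tumor burden (Michaelis–Menten term), tumor
growth is logistic, and the bilinear terms describe effector kill of tumor
cells and tumor-induced effector inactivation.  Only the inactivation term
is delayed: the loss of an engaged effector cell is registered a fixed lag τ
after the encounter.  All six parameters are strictly positive; with the
delayed and instantaneous states equal, the delayed field reduces exactly to
the ODE field, which the code exploits throughout (τ = 0 is never a special
case, only a shortcut).

The dimensional model (eight constants s, p, g, m, d, a, b, n) maps onto
the six nondimensional ones via σ = s/(ng²), α = p/(ng), μ = m/n,
δ = d/(ng), f = a/(ng), β = bg, with states scaled by the Michaelis constant
g and time by n·g.  `nondimensionalize` returns the time-scale factor so
delays and periods can be converted back.

## Equilibria

The tumor-free state is (σ/δ, 0).  Substituting the prey-nullcline identity
x = f(1 − βy) into the effector balance and clearing the (1+y) denominator
reduces positive equilibria to a cubic a₁y³ + a₂y² + a₃y + a₄ = 0 with
a₁ = fβμ, a₂ = f(−αβ + βδ − μ + βμ), a₃ = fα − fδ + fβδ − fμ + σ,
a₄ = σ − fδ.  The test suite re-derives these coefficients symbolically at
run time; a mismatch would be a build error, not a runtime branch.

Roots are taken from the companion-matrix spectrum (numpy.roots) rather than
Cardano's formula — the companion route degrades gracefully near double
roots, which matter because the root-count regimes include
discriminant-zero boundaries — and each candidate is then Newton-polished on
the original 2-D system with the analytic Jacobian.  Accepted equilibria
have residual < 1e-9; roots with a coordinate below 1e-10 are treated as
coincident with an axis and dropped with a log warning; polished roots
closer than 1e-6 (relative) are merged and reported once with multiplicity.

The advisory table mapping parameter inequalities to root counts is
internally inconsistent (two cases share hypotheses but draw different
conclusions, and some of its symbols are undefined), so `regime_report`
counts roots directly and only flags whether a matched case agrees.

## Linear stability (no delay)

At positive equilibria the equilibrium identities collapse the Jacobian to
J = [[−σ/x*, αx*/(1+y*)² − μx*], [−y*, −fβy*]]; this simplified form is used
only when the residual certifies the identities (< 1e-9), the raw partials
otherwise.  Eigenvalues come from the 2×2 trace/discriminant closed form —
exact control of the conjugate-pair convention — with the general solver
kept as a test oracle.  |Re λ| < 1e-10 is classified `center_candidate` and
theorem-boundary equalities are annotated as linearization-inconclusive.

Three analytic certificates are evaluated with their inequality values
attached: the invasion threshold (f vs σ/δ), the global-elimination
certificate (σ > fδ and δβ > μ > α; local stability plus the Dulac function
1/y on the invariant box [0, 2σ/δ] × [0, 2/β] excludes cycles), and the
tumor-burden threshold at positive equilibria from the sign of
h(y*) = a(y*+1)² + α with a = (σfβ − μx*²)/x*².  Since the trace is always
negative there, sign(det J) = sign(h) decides: h > 0 stable, h < 0 saddle,
with the threshold y_th = √(αx*²/(μx*² − fσβ)) − 1 separating the branches
when a < 0.  The certificate is always cross-checked against the eigenvalue
classification; a disagreement is reported as an explicit inconsistency
record (none occurs in the tested regimes).

## Delay analysis

The linearization splits into an instantaneous part J0 and a delayed part
J1 = [[−μy*, −μx*], [0, 0]].  The characteristic equation is
λ² + Bλ + C + (Dλ + E)e^(−λτ) = 0 with B = −tr J0, C = det J0, D = −tr J1,
and E = J1₀₀J0₁₁ − J1₀₁J0₁₀ = μy*(fβy* − x*), derived from the determinant
expansion rather than transcribed; the τ = 0 reductions B + D = −tr(J0+J1)
and C + E = det(J0+J1) are asserted in tests, as is agreement of the scalar
form with det(λI − J0 − J1e^(−λτ)) at random complex arguments.

Purely imaginary roots require ω² to solve
w² + (B² − 2C − D²)w + (C² − E²) = 0; the positive real roots give ω± and
each yields critical delays τ_j = (θ + 2πj)/ω, with θ ∈ [0, 2π) recovered by
atan2 from the exact pair cos θ = [E(ω²−C) − DBω²]/(E² + D²ω²),
sin θ = ω[D(ω²−C) + BE]/(E² + D²ω²).  The atan2 route is algebraically
equivalent to an arccos case split but immune to sign errors at cos θ = ±1.

Transversality is computed from the full implicit derivative
dλ/dτ = λ(Dλ+E)e^(−λτ) / (2λ + B + (D − τ(Dλ+E))e^(−λτ)); the classical
sign shortcut (the sign of the quartic-discriminant square root) is only a
logged consistency check.  When |Re dλ/dτ| < 1e-10 (tangential crossing,
i.e. a double root of the ω-quartic) the sign of d²Re λ/dτ² is estimated by
Newton root-tracking across τ and the result is flagged degenerate.

The verdict logic: C + E < 0 pins a real right-half-plane root for every τ
(a real root can only cross at λ = 0, which requires C + E = 0), so the
equilibrium is unstable for all delays.  Otherwise the τ = 0 root count
seeds a schedule in which each crossing moves one conjugate pair in the
direction of its transversality sign; a single ω branch from a stable start
is a clean Hopf at τ₀, two branches give finitely many stability switches
(the ω+ crossings recur faster, so instability eventually wins).

**Rightmost-root oracle.**  Chebyshev collocation of the linear DDE on
[−τ, 0] (differentiation matrix with the θ = 0 row replaced by the DDE's
boundary condition) approximates the spectrum; the leading approximations
are Newton-refined on the analytic characteristic function and deduplicated.
All residual tolerances are relative to the natural magnitude
|λ|² + |B||λ| + |C| + |D||λ| + |E| of the characteristic terms, which keeps
the oracle reliable on stiff parameter sets where D and ω reach 10³–10⁴.
The independent first-crossing oracle scans a τ grid for the sign change of
the rightmost real part and refines it by bisection; it confirms the
closed-form τ₀ to 1e-6 on every tested parameter set (in practice to
machine precision).  The node count grows with τ (capped at 128), which is
adequate because Newton refinement supplies the final accuracy.

## Center-manifold normal form

Time is rescaled by τ₀ so the delay interval is [−1, 0] and the critical
eigenvalue is iω₀τ₀ (the classical Hassard–Kazarinoff–Wan setting).  The
critical eigenfunctions q(θ) = (1, ρ)ᵀe^(iω₀τ₀θ) and
q*(s) = Dn(1, ρ*)e^(iω₀τ₀s) are obtained as numerical null vectors of the
characteristic matrix M(iω₀) = iω₀I − J0 − J1e^(−iω₀τ₀) and its conjugate
(closed forms exist — ρ = −y*/(fβy* + iω₀) — and are asserted in tests, but
the null-vector route carries its own residual certificate).  The
normalizer Dn enforces ⟨q*, q⟩ = 1 under the bilinear pairing
⟨ψ, φ⟩ = ψ̄(0)φ(0) + τ₀e^(−iω₀τ₀)ψ̄(0)J1φ(0)·I (the double-integral term of
the formal adjoint pairing, evaluated in closed form for exponential
arguments); biorthogonality ⟨q*, q̄⟩ = 0 then holds automatically and is
asserted to 1e-10.

The nonlinearity enters through exact second/third-order partial tensors of
the rhs with respect to (x, y, x_lag, y_lag), generated by symbolic
differentiation (sympy) and validated against central finite differences.
This single source of truth avoids transcribing any published g-coefficient
expression.  With U = (q(0), q(−1)) the quadratic coefficients are full
tensor contractions, g20 = τ₀ q̄*(0)·B(U, U) etc.; the second-order manifold
terms are

    W20(θ) = (i g20/ω₀τ₀) q(0)e^(iω₀τ₀θ) + (i ḡ02/3ω₀τ₀) q̄(0)e^(−iω₀τ₀θ) + E1 e^(2iω₀τ₀θ)
    W11(θ) = (−i g11/ω₀τ₀) q(0)e^(iω₀τ₀θ) + (i ḡ11/ω₀τ₀) q̄(0)e^(−iω₀τ₀θ) + E2

with the constant vectors solving M(2iω₀)E1 = B(U, U) and M(0)E2 = B(U, Ū)
(a singular M(0) would signal a degenerate Hopf and raises).  Every linear
solve asserts a residual < 1e-10.  Then

    c1(0) = i/(2ω₀τ₀)(g20g11 − 2|g11|² − |g02|²/3) + g21/2,
    μ₂ = −Re c1(0)/Re λ'(τ₀),  β₂ = 2 Re c1(0),
    T₂ = −(Im c1(0) + μ₂ Im λ'(τ₀))/(ω₀τ₀).

Convention (asserted in output metadata): μ₂ > 0 means periodic orbits exist
for τ > τ₀; β₂ < 0 means they are orbitally stable; the bifurcation is
labelled supercritical exactly when the orbit is stable.  The period
correction uses ε² = (τ − τ₀)/μ₂ with period ≈ (2π/ω₀)(1 + T₂ε²) in
original time.  All algebra is complex throughout — no real/imaginary
hand-splitting — to eliminate conjugate-bookkeeping errors.

## Simulation

The DDE is integrated by the method of steps: each window [kτ, (k+1)τ] runs
an adaptive RK45 with dense output (default rtol 1e-9, atol 1e-12), and the
lagged state is evaluated from the previous window's interpolant, so
interpolation error is controlled by the integrator tolerance.  τ = 0 falls
back to the plain ODE path.  Histories default to a constant state at the
equilibrium perturbed by a configurable relative size (default 1e-2) — the
study setting itself does not fix histories, so this convention is recorded
in every trajectory's metadata.

Diagnostics discard the first half of the span (configurable), declare
convergence when the last tenth of uniformly resampled states stays within
1e-6 of a supplied equilibrium, and otherwise peak-detect the tumor
component: five successive peak intervals agreeing within 2% define a
period; monotonically expanding peak envelopes are flagged growing;
anything else is undecided.  These defaults are tuned to be robust on the
slow focus (|Re λ| ≈ 0.037) of the flagship set.  Well past τ₀ the limit
cycle develops multi-peak structure (period doubling), which the strict
interval test deliberately reports as undecided rather than forcing a
period.

## Synthetic scenarios

The flagship fixture is the parameter set derived from Kuznetsov & Taylor's
1994 measurements (σ=0.1181, α=1.131, μ=0.00311, δ=0.3743, f=1.636,
β=0.002) — three positive equilibria, a delay-robust low-tumor focus, a
saddle, and a high-tumor node with a supercritical Hopf at τ₀ ≈ 0.991.
Random scenarios rejection-sample the six parameters log-uniformly on
[1e-3, 10] (the fixture itself spans four orders of magnitude) until a
regime's inequalities hold: global elimination, three equilibria, a
Hopf-bearing stable equilibrium (C² < E²), or delay-independent stability.
Sampling is deterministic given the seed, capped at 1e5 draws so
contradictory inequality sets fail fast rather than hang.

What the synthetic regimes do *not* emulate: measurement noise, parameter
uncertainty, non-constant histories, or any biological heterogeneity —
passing tests show the analysis machinery is internally consistent and
agrees with independent numerics on this model class, not that the model
fits any particular tumor system.

## Problem sizes and numerical choices

Default test and verification sizes: 1000 random draws for the zero-delay
equivalence property; 200 parameter sets for the cubic-versus-grid-scan
oracle; 500 equilibria for the certificate/eigenvalue agreement sweep; 50
seeded Hopf-bearing sets for the closed-form/continuation τ₀ agreement;
DDE simulations to t = 500–700 at rtol 1e-8 for the bifurcation
cross-checks; 100 random starts for the global-elimination check.  These
sizes make the full suite run in well under a minute of CPU for the
analytic parts plus a few minutes for the simulation cross-checks, while
keeping every tolerance at the level stated above.

Known limitations: single discrete delay only (no distributed or multiple
delays); no continuation of periodic-orbit branches (simulation diagnostics
stand in); no degenerate (Bautin, zero-Hopf, double-Hopf) normal forms —
those cases raise explicit degenerate errors instead; the advisory
root-count case table is reported but never trusted over direct counting.
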