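# tumordyn

Dynamical analysis of a delayed effector-cell/immunogenic-tumor model:
equilibria, stability certificates, delay-induced stability switches and Hopf
bifurcation, center-manifold normal form, and direct DDE simulation that
cross-validates every analytic result.

## The model

Effector (immune) cells `E` attack an immunogenic tumor `T`.  Immune
stimulation saturates with tumor burden (Michaelis–Menten), effector cells
are inactivated by contact with tumor cells, and that inactivation acts with
a discrete lag τ (the time for an engaged effector cell to be withdrawn from
the fight).  After rescaling both populations by the Michaelis constant and
time by the kill rate, the nondimensional system is

    dx/dt = σ + α·x·y/(1+y) − μ·x(t−τ)·y(t−τ) − δ·x
    dy/dt = f·y·(1−β·y) − x·y

with effector density `x`, tumor density `y`, and six positive constants:
σ (baseline effector influx), α (immune-response amplitude), μ (effector
inactivation rate), δ (effector death rate), f (tumor growth rate), and β
(inverse tumor carrying capacity).

The package answers, analytically and numerically:

- **Where are the steady states?**  The tumor-free state `(σ/δ, 0)` always
  exists; positive equilibria are the roots of a cubic in `y` (0–3 of them).
- **Are they stable?**  Closed-form 2×2 eigenvalues plus analytic
  certificates: the invasion threshold `f` vs `σ/δ`, a global-elimination
  certificate (`σ > fδ`, `δβ > μ > α`, Dulac function `1/y` on an invariant
  box), and a tumor-burden threshold from the sign of
  `h(y*) = a(y*+1)² + α`, `a = (σfβ − μx*²)/x*²`.
- **Does the delay destabilize them?**  The linearized characteristic
  equation is transcendental, `λ² + Bλ + C + (Dλ + E)e^(−λτ) = 0`; crossing
  frequencies solve a quartic in ω, each yields critical delays
  `τ_j = (θ + 2πj)/ω`, and the transversality sign of `dReλ/dτ` builds a
  stability-switch schedule.  An independent pseudospectral rightmost-root
  oracle confirms every crossing.
- **What bifurcates?**  At a Hopf point the center-manifold normal form
  yields `c1(0)` and the classification quantities μ₂ (direction), β₂
  (orbital stability), T₂ (period correction).
- **Does simulation agree?**  A method-of-steps DDE integrator with dense
  interpolants, plus orbit diagnostics (convergence / period / amplitude),
  closes the loop.

## Worked example

The flagship parameter set (derived from Kuznetsov & Taylor's 1994
measurements) is σ=0.1181, α=1.131, μ=0.00311, δ=0.3743, f=1.636, β=0.002:

```python
from tumordyn import positive_equilibria, classify, delay_verdict, normal_form_at
from tumordyn.scenarios import kuznetsov_fixture

params = kuznetsov_fixture().params
eqs = positive_equilibria(params)   # three: y* = 0.366269, 300.188, 441.757
for eq in eqs:
    print(eq.point, classify(params, eq).classification)
print(delay_verdict(params, eqs[2]).verdict)
print(normal_form_at(params, eqs[2]).classification)
```

prints

```
(1.6348015691405624, 0.36626860007254325) stable_focus
(0.6537838429448106, 300.18829686689135) saddle
(0.19057033846433825, 441.75733122216833) stable_node
hopf_at_tau0
supercritical
```

E1 (low tumor burden) is a stable focus with eigenvalues
−0.036720 ± 0.599722i and remains stable for **every** delay (no crossing
frequency exists).  E2 is a saddle for every delay.  E3 (high tumor burden)
is a stable node for τ = 0 but has a single crossing frequency
ω₀ = 1.002788, so it loses stability at the critical delay

    τ₀ = 0.990969,   λ'(τ₀) = 1.006248 − 0.865944i,

where the normal form gives c1(0) = −3.950511 − 2.765563i, hence
μ₂ = 3.926 > 0 and β₂ = −7.901 < 0: a **supercritical** Hopf bifurcation —
for τ just above τ₀ a stable limit cycle of period ≈ 2π/ω₀ = 6.27 appears,
on which tumor and effector populations coexist in sustained oscillation.
Direct DDE simulation at τ = 1.05·τ₀ finds exactly that (period 6.77, tumor
amplitude ≈ 105), and at τ = 0.95·τ₀ the oscillation decays back to E3.

The `examples/` directory walks through each capability
(`python examples/01_equilibria_and_stability.py`, …), and the `tumordyn`
command exposes the same pipeline from the shell
(`tumordyn report --config <params.yaml>`).

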