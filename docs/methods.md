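# Methods

## The model

`fracbioheat` simulates the temperature of perfused, metabolically active
breast tissue loaded with therapeutic nanoparticles during mild hyperthermia
(heating tumour-bearing tissue to roughly 40–45 °C). The energy balance is a
Pennes-type bioheat equation extended three ways: the tissue is treated as a
porous matrix exchanging heat with flowing blood, thermal radiation is folded
in through the linearised Rosseland approximation, and the time derivative is
a Caputo fractional derivative of order α ∈ (0, 1] that endows the tissue
with thermal memory (α = 1 recovers the classical equation).

After nondimensionalisation (lengths by the slab thickness *a*, time by
*a²/α₁* with α₁ = k_b/(ρc_p)_b the blood thermal diffusivity, temperature by
the blood–reference gap θ_b − θ₀), the governing equation on y ∈ [0, 1] is

    D_t^α θ = D ∂²θ/∂y² − c θ + s,

with

    D = (r_k / r_cp) (1 + 4R/3),   c = γ − λ/r_cp,   s = γ + β/r_cp,

where r_cp = (ρc_p)_nf/(ρc_p)_b and r_k = k_nf/k_b are the nanofluid property
ratios, R the radiation parameter, γ the blood-perfusion parameter, λ the
metabolic heat-source parameter and β the porous-structure parameter. This
coefficient reading is the unique one under which the dimensional energy
balance, divided by (ρc_p)_nf and rescaled, reproduces the dimensionless
equation term by term; the test suite verifies it mechanically by integrating
the dimensional equation directly (`solve_fd_dimensional`) and overlaying the
rescaled result on the dimensionless solve to 1e−10.

Nanofluid properties use the volume-weighted mixing rules for ρ and (ρc_p)
and the Hamilton–Crosser correlation for conductivity with shape factor
m = 3/ψ (sphericity ψ): sphere 3.0, brick 3.7, cylinder 4.9, platelet 5.7,
blade 8.6. All values are configuration-overridable, because published
shape-effect rankings in this literature are not always consistent with any
single standard m-table.

## Two independent solution routes

**Laplace route (production).** The Caputo transform rule
L{D_t^α f} = q^α F − q^{α−1} f(0) turns the PDE into a two-point ODE with the
closed-form solution

    θ̄(y, q) = F_p(q) + (θ_L/q − F_p) sinh((1−y)μ)/sinh μ
                      + (θ_R/q − F_p) sinh(yμ)/sinh μ,
    μ = sqrt((q^α + c)/D),   F_p = (θ_init q^α + s)/(q (q^α + c)).

This two-boundary form is algebraically identical to the textbook
A·cosh + B·sinh representation but is exact at both walls by construction
and, rewritten with decaying exponentials only, evaluates stably for |μ| up
to ~700. Principal branches are used for q^α and the square root; all
inversion contours keep Re q > 0, so no branch cut is crossed.

**Finite-difference route (oracle).** The Caputo derivative is discretised
by the L1 scheme with weights b_j = (j+1)^{1−α} − j^{1−α} and the full
history retained; space uses implicit central differences, giving an
unconditionally stable tridiagonal solve per step. At α = 1 the scheme
degenerates exactly to backward Euler (checked to 1e−10 against an
independent dense-matrix integrator). The two routes agree within 1e−2
max-absolute over an (α, φ, R) validation matrix; the dominant residual is
the finite-difference startup error at the incompatible hot-wall corner
(the boundary jumps from 37 to 45 at t = 0⁺), which decays with the time
step at the expected order.

## Numerical inversion

*Durbin* (default): trapezoidal discretisation of the Bromwich integral on
the shifted contour Re q = a, with T = 2·t_max and a·T = 6, N = 2000 terms.
Two refinements matter in practice and are both on by default:

1. **Tail subtraction.** Transforms of functions with f(0⁺) ≠ 0 decay like
   f(0⁺)/q, so the raw series converges like 1/N. The limit
   c₀ = lim q F(q) is estimated at a large real frequency (q = 1e8), c₀/q is
   subtracted, and c₀ added back exactly.
2. **Series acceleration.** The remaining truncation error — dominated by
   wall boundary-layer terms of the form e^{−(1−y)√(q^α/D)}/q — is removed
   by Wynn's epsilon algorithm applied to the complex partial sums (the
   classical Honig–Hirdes refinement). What is left is the contour aliasing
   floor ~ e^{−2aT} ≈ 6e−6 relative to the temperature scale.

*Zakian*: the standard five conjugate-pair rational approximation,
f(t) ≈ (2/t) Σ Re[K_i F(α_i/t)]. On transforms with only poles it is
essentially exact (~1e−7); on branch-point transforms (fractional powers,
e^{−√q}) it degrades to ~1e−3, and on this model at times long relative to
the dominant decay its error reaches a few times 1e−2. It therefore serves
as the cross-check, not the production path; the cross-method test asserts
agreement within 1% of the boundary-temperature span on t ∈ [0.05, 2].

t = 0 is never inverted (both formulas are singular there); the initial
value is written directly.

## Boundary-value conventions

Two equivalent modes exist. The default "printed" mode carries the physical
temperatures (initial 37, walls 37 and 45) directly through the dimensionless
equations, matching the transform-domain convention common in this
literature. The "physical" mode uses the strict scaling (0, 0, 1). The two
differ by the affine map θ_printed = 37 + 8·θ_physical once the source term
is remapped as s_physical = (s_printed − 37c)/8; the test suite verifies the
map numerically.

## Nusselt number and enhancement tables

The wall heat-transfer rate is summarised as

    Nu = −(k_nf/k_b)(1 + 4R/3) ∂θ/∂y |_{y=0, t=t_eval},

with the gradient obtained by inverting the analytic transform-domain
derivative (no finite-difference noise at the wall); t_eval = ∞ uses the
closed-form steady state. The defining formula and the parameter set behind
published absolute Nu values are not recoverable from the literature this
package accompanies, so absolute Nu values are reported as the model's own
output, while the published enhancement *percentages* are regenerated
exactly from the published Nu columns: enhancement is
100·(Nu − Nu_base)/Nu_base computed in exact rational arithmetic and
truncated (not rounded) toward zero at three decimals — truncation is the
convention that reproduces every published percentage cell, rounding fails
four of them by one final digit.

## Fractional relaxation is slow

A point often missed: for α < 1 the approach to the steady state is
algebraic, ~t^{−α} (Mittag-Leffler tail), not exponential. A configuration
that reaches the steady profile to 1e−3 by t ≈ 25 at α = 1 needs t ≈ 6·10³
at α = 0.8 and t ≈ 10⁵ at α = 0.6. The long-time tests assert both the
1e−3 band at those horizons and the t^{−α} decay rate itself.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.8 | Caputo order (thermal memory; 1 = classical) |
| R | 0.5 | Rosseland radiation parameter |
| γ | 1.0 | blood-perfusion parameter |
| λ | 0.5 | metabolic heat-source parameter |
| β | 0.5 | porous-structure parameter |
| φ | 0.02 | particle volume fraction (validated range [0, 0.1]) |
| particle / shape | gold / platelet | strongest published enhancement combination |
| θ boundary mode | printed (37/37/45) | see above |

The dimensional symbols (slab thickness, perfusion rate ω_b, metabolic
coefficient Q_m, porous source ε/K, Stefan–Boltzmann group) enter only
through γ, λ, β, R and are not separately stored; `DimensionalSetup`
documents the mapping and is used by the consistency tests.

## Problem sizes

The validation matrix uses a 21-point comparison grid with a 101-point,
400-step finite-difference mesh, refined ×4 in time for fractional orders
and ×8 for α = 1 (where the scheme is memoryless and O(nt)); the analytic
inversion suite uses N = 2000 Durbin terms. These sizes put every check
one to two orders of magnitude inside its tolerance while keeping the whole
suite interactive (seconds).

## Known limitations

- One-dimensional single-layer slab; no momentum equation, so no viscosity
  model and no flow-dependent convection.
- Constant properties; no temperature-dependent perfusion or metabolic rate.
- The E-field (microwave power deposition) source is out of scope; heating
  enters through the boundary values and the metabolic/porous sources.
- Zakian inversion should not be trusted at long times or for strongly
  fractional transforms (see above); it is provided as a cross-check.
- c < 0 (metabolic gain exceeding perfusion) has no bounded steady state in
  general; the steady-state helper evaluates the trigonometric analogue and
  raises near its poles.
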