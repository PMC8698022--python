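# Methods

## Scope and model

The package models the equilibrium mole fraction y₂ of a heavy solid solute
in supercritical CO₂ by the compressed-gas route: the pure-solid fugacity
(sublimation pressure × Poynting correction, with the solid-phase fugacity
coefficient taken as 1) is equated with the fluid-phase fugacity
y₂·φ₂·P. The working expression is

    y₂ = (P₂ˢᵘᵇ/P) · exp(v₂ˢP/RT) / φ₂

Because drug-like solids have sublimation pressures in the µPa–mPa range
while operating pressures are 10–35 MPa, the simplified Poynting
convention exp(v₂ˢP/RT) is the default everywhere; the full form
exp[v₂ˢ(P−P₂ˢᵘᵇ)/RT] is available behind `full_poynting=True` and differs
by less than v₂ˢ·P₂ˢᵘᵇ/RT relative (≈10⁻¹⁰ at 1 mPa) — the test suite
asserts this bound.

## Equations of state

RK, SRK and PR are implemented in the generalized form
P = RT/(v−b) − a(T)/[(v+δ₁b)(v+δ₂b)] with (δ₁, δ₂) = (1, 0) for RK/SRK and
(1±√2) for PR. The attraction parameter carries the alpha function
internally: α = √(Tc/T) (RK), the Soave form with
s = 0.48 + 1.574ω − 0.176ω² (SRK), and the PR form with
κ = 0.37464 + 1.54226ω − 0.26992ω². Full-precision Ω and κ constants are
used, and the PR alpha is applied to (1 − √Tr): the frequently reprinted
"(1 − Tr)" variant is a typographical corruption — it breaks the defining
property α(Tc) = 1, which the tests assert exactly.

Volume roots are obtained from the analytic (Cardano/trigonometric)
solution of the cubic and polished by Newton iteration on the pressure
residual to 10⁻¹² relative; roots below the covolume are discarded and the
largest surviving root is the fluid branch used throughout. Equivalence
with a generic polynomial root finder is asserted on 1000 random draws.
CO₂ constants default to Tc = 304.13 K, Pc = 7.3773 MPa, ω = 0.2239
(standard literature values) and are overridable; engineering cubics put
the CO₂ density at 313.15 K / 15 MPa within ~5–15% of the reference value
(PR 747, SRK 677 vs ~780 kg/m³), which is accepted: the package's density
role is as a correlation variable, not a property standard.

## Fugacity routes

**Classical.** The closed-form ln φ₂ of the generalized cubic with
quadratic van der Waals mixing, evaluated at the mixture fluid root. Cross
attraction either as a₁₂ = √(a₁₁a₂₂)(1−k₁₂) (direct) or by
Lorentz–Berthelot combining of the critical constants with k₁₂ correcting
the geometric-mean Tc; in the latter case the cross attraction is the
EoS's own a(T) evaluated on the cross pseudo-component (for RK this is
exactly 0.42748·R²T_c12^2.5/(P_c12·√T), the classical combining
prescription), with the cross acentric factor taken as the arithmetic
mean. The closed form is validated against direct numerical quadrature of
the thermodynamic definition (finite-difference ∂P/∂n₂, 1/V-substituted
integral) to 10⁻⁶ relative.

**Schmitt–Reid infinite dilution.** The modified-PR form drops all terms
of order y₂, excludes the interaction parameter (a₁₂ = √(a₁a₂)) and
treats (a₂, b₂) as temperature-independent adjustables:

    ln φ₂ = (b₂/b₁)(Z−1) − ln[P(V−b₁)/RT]
            − a₁/(√8·RT·b₁) · (2√(a₂/a₁) − b₂/b₁) · ln[(V+(1+√2)b₁)/(V+(1−√2)b₁)]

with V, Z from pure CO₂. This is implemented as stated because it is the
unique form that (i) reduces to the pure-CO₂ PR fugacity coefficient when
solute ≡ solvent and (ii) equals the y₂→0 limit of the classical PR
expression with k₁₂ = 0 — both identities are asserted to machine/1e-8
precision. Widely circulated transcriptions with "V − 2b₁" or "2a₂a₁" in
place of V + (1−√2)b₁ and 2√(a₂/a₁) fail both identities.

At finite y₂ the classical φ₂ depends on composition, so y₂ is solved by
fixed-point iteration y₂ ← (P₂ˢᵘᵇ/P)·E/φ₂(y₂), seeded at the φ₂ = 1
estimate, converged to 10⁻¹⁰ relative (≤200 iterations); agreement with
bisection on the defining residual and insensitivity to a 10× seed change
are tested.

## Regression

All fits minimize the global AARD with seeded multi-start Nelder–Mead
(default 8 starts; simplex tolerances 10⁻¹⁰, ≤5000 evaluations per
start). Strictly positive parameters (P₂ˢᵘᵇ, a₂, b₂) are optimized in log
space, k₁₂ in linear space. State points where the forward model fails
contribute a fixed 10³% penalty so the simplex can leave unphysical
regions; the final result is recomputed cleanly and flagged unconverged if
any point still fails. Initial values are data-driven: per-isotherm P₂ˢᵘᵇ
from the geometric mean of y₂·P·φ₂/E at k₁₂ = 0, and a₂ by inverting the
infinite-dilution expression for the data-implied fugacity coefficient at
b₂ = v₂ˢ. Identical seeds give bitwise-identical results. Modes:

* one global k₁₂ + one free P₂ˢᵘᵇ per isotherm (classical);
* k₁₂ alone with P₂ˢᵘᵇ supplied (classical, fixed);
* temperature-independent (a₂, b₂) with P₂ˢᵘᵇ supplied (Schmitt–Reid).

On noiseless synthetic data all three recover their generating parameters
essentially exactly (the 1%-recovery check in the acceptance suite is
conservative).

## Sublimation-pressure estimation from solubility data

The three-step procedure: (1) fit the pooled MST collapse
T·ln(y₂P[Pa]) = A′ + B′ρ + C′T and flag points whose standardized residual
about the line exceeds z = 2 (one shot; an exactly collinear collapse is
detected and never flagged); (2) refit MST on the retained points and take
Aₛ = C′ — fitting with P in Pa is the unit convention under which the
intercept is directly the Clausius–Clapeyron intercept in ln Pa; (3) fit
Bartle's ln(y₂P/1 bar) = a + b/T + c(ρ−700 kg/m³) and take Bₛ = ΔHₛ = −bR
(exact by construction). MST's density unit is configurable (kg/m³
default, mol/cm³ selectable); it rescales only B′, which is never consumed
downstream.

Two properties of this estimator deserve emphasis, and the test suite is
explicit about both:

* On data *consistent with the correlations* (ln(y₂P) exactly
  Clausius–Clapeyron plus density terms) the pipeline recovers the
  generating (Aₛ, Bₛ) to numerical precision, and re-running it on the
  cleaned subset is exactly idempotent.
* On data generated by the **EoS forward model**, C′ and b absorb the
  temperature dependence of ln φ₂ at fixed density (the solvation
  contribution), so the estimate is an *effective* sublimation model: for
  the penicillin-G-shaped fixture the estimated enthalpy is ~63 kJ/mol
  against a generating 85.3 kJ/mol, and the estimated P₂ˢᵘᵇ(T) differs
  from the generating curve by orders of magnitude. This is a property of
  density-correlation estimators, not an implementation defect (the dual
  validation above isolates it), and it is why the estimated pair should
  be used as a unit — re-inserted into the same solubility model — rather
  than read as thermochemical truth. Passing tests therefore demonstrate
  internal consistency of the workflow, not the accuracy of
  correlation-derived sublimation pressures for real solids.

Sequential re-application of the one-shot z > 2 rule to model-inconsistent
data can trim additional points (the scale shrinks after each removal);
the pipeline deliberately does not iterate.

## Synthetic data

The generator emulates the two penicillin studies: 3 isotherms ×
6 pressures (N = 18, 313.15–333.15 K) and 3 × 8 (N = 24, 314.85–334.85 K)
over 100–350 bar, Schmitt–Reid forward route, Clausius–Clapeyron
sublimation models (Aₛ = 26.2, Bₛ = 85.3 kJ/mol; Aₛ = 12.8,
Bₛ = 41.9 kJ/mol), solid molar volumes 226.1 and 243.2 cm³/mol (the older
213 cm³/mol group-contribution value for penicillin V is shipped as an
alternative). Covolumes b₂ are set at the reported 1.98×10⁻⁴ and
2.72×10⁻⁴ m³/mol. The attraction parameters (13.0 and 12.0 Pa·m⁶/mol²)
were chosen once so the simulated mole fractions span the 10⁻⁶–10⁻⁴
window typical of drug solids in CO₂; reported a₂ values in the
10⁻⁴ range cannot be literal Pa·m⁶/mol² — at that magnitude the
attraction term is negligible against the b₂ repulsion, φ₂ ≫ 1, and
solubilities would sit near 10⁻¹⁸ — so their unit is treated as
unresolved and only their covolume scale is reused.

Noise is mean-one lognormal with configurable coefficient of variation
(default 0.08, typical of static-method solubility scatter) —
multiplicative because y₂ spans decades and the fit metric is relative.
Constructed outliers multiply chosen grid points; the standard setting
perturbs the two lowest-density states — (323.15 K, 100 bar) up ×5 and
(333.15 K, 100 bar) down ×5 — which the consistency check then flags
exactly, noiseless and across noise seeds. What the generator does *not*
emulate: temperature-dependent measurement bias, pressure-correlated
errors, co-solute impurities, and the real systems' unknown true
(a₂, b₂); recovery tests therefore validate the estimation machinery, not
the published parameter values.

## Numerical conventions

SI units internally (Pa, K, m³/mol, J/mol); bar only at I/O boundaries.
R = 8.314462618 J/(mol·K) everywhere. Cubic-root residual tolerance
10⁻¹² relative; near-duplicate analytic roots are collapsed at 10⁻⁹
relative spacing. Fixed-point solubility tolerance 10⁻¹⁰ relative.
Rank-deficient regression designs raise an input error rather than
returning a pseudo-inverse fit. Degenerate ideal-gas parameters
(a = b = 0) short-circuit to φ = 1.

## Known limitations

* Binary systems only; no cosolvents, no liquid-phase equilibria, no
  melting-point/fusion solid-fugacity routes.
* No temperature dependence in the Schmitt–Reid (a₂, b₂).
* The density-correlation sublimation estimate carries the solvation bias
  described above; its AARD improvement claims should be read per-system.
* Published per-system AARD tables for the real penicillin datasets cannot
  be reproduced because the underlying measurements were never printed;
  the package reproduces their *structure* and validates by closed-loop
  synthetic recovery instead.
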