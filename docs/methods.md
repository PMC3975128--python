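# Methods

## The model

Telomeres in a cycling, telomerase-positive cell population are tracked by
their length x (bp), treated as continuous, and by their conformational
state:

- **U** — open (uncapped, unfolded), the only state telomerase can bind;
- **B** — telomerase-bound, elongating at the processivity rate ρ (nt/s),
  which acts as an advection speed in length space;
- **G** — G-quadruplex folded (fold/unfold rates k_f, k_u), inaccessible to
  telomerase;
- **C** — G-quadruplex locked by a stabilising ligand (RHPS4; binding k_s,
  dissociation k_d per molecule).

Telomeres leave the cycling pool by t-loop formation from U at the
length-dependent rate k_c(x) = δ / (1 + exp((α − x)/β)) — long telomeres
loop readily, short ones hardly at all — and from C at rate k_r.  Free
telomerase (T₀ molecules) and free drug (R₀ molecules) are conserved;
throughout the steady-state machinery they are approximated by their totals
(valid when the bound pools are small, i.e. k_on ≪ k_off, k_s ≪ k_d).

Two system closures are provided:

1. **Open system** (one replication): telomeres enter at rate k_e with a
   prescribed length density p(x).  At steady state the four densities
   reduce to one linear first-order ODE for B(x); U, G, C follow
   algebraically.  The exit density is p̂ ∝ k_c U + k_r C.  Iterating
   exit → (shift down by the per-replication loss μ) → next input gives the
   discrete-generation dynamics.
2. **Closed system** (many replications): the exit flux is recycled μ bp
   shorter, giving a linear advance-delay equation for U(x).  Expanding the
   shift operators to first order in μ and ρ/k_off (quasicontinuum
   approximation) yields the closed form
   U(x) = A e^{λx} sech^{βδ/(c₀c_T)}((x − α)/(2β)) with
   c₀ = μ/2 + ρ/k_off, c_T = k_on T₀ ρ/(μ k_off),
   c_R = k_f k_s k_r R₀ / (k_u k_d + k_r(k_u + k_s R₀)), and
   λ = (2c_T − 2c_R − δ)/(2c₀c_T).

U is normalisable exactly when c_R < c_T < c_R + δ.  Rearranged, this gives
the feasibility window: below the telomerase floor T̃_min(R₀) telomeres
erode without bound, above the ceiling T_max(R₀) they lengthen without
bound.  The R₀ → ∞ limits T∞_min = μ k_off k_f/(ρ k_on) and
T∞_max = μ k_off(δ + k_f)/(ρ k_on) are evaluated analytically.  Because
δ ≪ k_f at the default parameters, there is no telomerase level that
survives arbitrarily large drug doses.

## Parameters

Defaults describe telomerase-positive HeLa cells (units in the
`ParameterSet` docstring): k_on = 2.6e-7, k_off = 2.2e-4, ρ = 6.287e-2,
k_f = 1.6e-2, k_u = 3.8e-3, K = 1.4e-5, k_s = 1e-7, k_d = 7.1e-3,
k_e = 1.5e-2, k_r = 5e-6, δ = 5e-5, α = 1775, β = 300, μ = 45, L₀ = 3440,
σ₀ = 800.  The nM ↔ molecules bridge uses N_A = 6.022e23 and a HeLa nuclear
volume of 6.9e-13 l, so 1 nM ≈ 415.5 molecules per nucleus; the exact
product is used (no rounding to 415).  The tabulated k_d differs from
k_s/K by 0.6%; `ParameterSet.from_K` derives k_d = k_s/K exactly, and an
explicitly supplied k_d is accepted silently within 1% of that ratio.

Internally R₀ and T₀ are real-valued molecule counts (the equations are
continuum ODEs); integer molecule statements appear only in the feasibility
report, where lower bounds are ceiled and upper bounds floored (giving the
drug-free window 1 ≤ T₀ ≤ 30 at the defaults).

## Numerics

- **Open-model ODE.** B′ = m(x)B + σ(x)p(x) with m(x) ≤ 0 everywhere, so
  the equation is integrated left → right from B(x_min) = 0 with an exact
  per-cell integrating-factor (exponential) step, coefficients evaluated at
  cell midpoints.  This is second-order in practice (the balance residual
  drops ~4× per dx halving) and unconditionally stable.  Default grid:
  x ∈ [−2000, 30000] bp, dx = 5 bp.
- **Analytic cross-check.** With the capping sigmoid replaced by a sharp
  step δ·H(x − α) (midpoint value δ/2 at x = α) and Gaussian input, B is
  exponential × error function piecewise; the free constants follow from
  the Gaussian integral against an exponential plus continuity at α, using
  erfc for tail stability.  The numeric solver reproduces it to relative
  L2 ~ 1e-5.
- **Generation timing.** The initial Gaussian (mean L₀) is read as the
  *already shortened* input of generation 0; the μ-shift (linear
  interpolation; exact when μ/dx is integral) is applied between
  subsequent generations.  This timing reproduces the published
  generation-30 means to ≤ 0.13% for all six (T₀, R₀) combinations; the
  alternative (shift before the first solve, `shift_initial=True`) lands
  0.9–1.9% low on every one of them.  Each generation's exit density is
  renormalised (the balance residual, ~1e-7, would otherwise compound).
- **Closed-model moments.** Exit moments are computed by grid quadrature of
  the closed form; by default the right edge of the domain is doubled until
  mean and SD move < 0.1% so near-critical slow tails are captured rather
  than silently truncated.  Caveat: the published moment table for the
  near-critical cell T₀ = 30, R₀ = 0 (tail decay length ≈ 33 kb) was
  evidently computed on a domain ending at 25,000 bp — truncating there
  reproduces both of its printed moments to 4 significant figures, while
  the converged values are ~3× larger.  The reproduction tests therefore
  use the reconstructed 25-kb domain; library defaults do not.
- **Delay-equation oracle.** The exact (pre-expansion) steady state is
  discretised with central differences and an interpolated μ-advance and
  solved as a least-squares null vector under ∫U = 1.  It agrees with the
  long-time limit of the time-dependent closed solver to relative L2 ≈ 0.02.
  The first-order quasicontinuum solution differs from it by relative
  L2 ≈ 0.16–0.23 at the default parameters: the left flank of U steepens on
  the scale c₀ = μ/2 + ρ/k_off itself, so (ρ/k_off)·d(ln U)/dx is order one
  and the truncated expansion shifts the mode by ~100 bp.  The closed form
  is therefore a shape approximation whose *moments* match the published
  values, not a pointwise-accurate solution.
- **Transient solver.** Explicit method of lines; first-order upwind for
  the advection; sub-stepping keeps both ρ·dt/dx and (fastest rate)·dt
  below 0.5.  T(t), R(t) are eliminated algebraically through the
  conservation laws.  Total telomere number in the closed system is
  conserved to ~1e-6 per 2e5 s when μ is a multiple of dx (interpolation of
  the advance term otherwise adds O(dx²) quadrature drift).

## Synthetic data

`generate_fixture` draws seeded gamma samples (shape L²/σ², scale σ²/L)
emulating the HT Q-FISH HeLa histogram (n = 495 nuclei, mean 3440 bp,
SD 800 bp, 500-bp bins).  It emulates only the fitted length distribution:
no measurement noise, probe-calibration error, per-nucleus aggregation or
plate effects.  A green test against it establishes that the generator and
the input-distribution code agree, not that the model fits raw microscopy
data.

## Known limitations

- The T ≈ T₀ approximation is poor for the open system at the default
  k_e = 1.5e-2 (the steady bound pool holds ~half of T₀ = 25); the
  steady-state solvers follow the published treatment and use T₀
  regardless.  The transient solver keeps exact conservation and is the
  tool for probing that regime.
- Negative lengths are in-domain by construction; their (reported) mass is
  interpreted as non-functional telomeres.  No senescence/apoptosis rules,
  no per-cell stochasticity, no POT1 or other shelterin players.
- Closed-form mean exit length: the drug-free expression is valid for
  T₀ > 0 and L > α only.  Its short-telomere dwell term evaluates to
  6.13 nt at the default inputs (pinned as a regression value); it is small
  against the ~37 nt telomerase term, but an order of magnitude larger than
  the value quoted alongside the original formula.
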