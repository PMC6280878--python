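# Methods

## The cellular automaton

The cornea is a square lattice of sites (i, j), 0 ≤ i, j ≤ R, spacing
h = 1/R (one cell diameter), with the limbus at i = 0 and the TAF source
at i = R.  Time is discrete, t = Kτ.  All quantities are dimensionless
(space scaled by the limbus–source distance, time by the TAF diffusion
scale).  The TAF field is prescribed and linear, c_i = i·h, the
quasi-steady profile of a diffusion-dominated source; it is not consumed
or updated.

Agents are tip cells (TCs, at most one per site) and stalk cells (ECs;
unbounded integer counts per site in Model 1, at most one cell of either
species per site in Model 2).  Initially R/2 TCs sit at alternating sites
of column 0 and there are no ECs.

Each discrete step has two phases under a random sequential update:

1. **Motility.** N̄ selections (N̄ = TC count at the step start) are drawn
   uniformly *with replacement* from the currently-alive TCs.  A selected
   TC moves with probability P_m, choosing a von Neumann direction with
   probabilities (1 ± k Δc)/4 built from central differences of the TAF
   field (transverse components exactly 1/4 for the linear field).
   Off-lattice targets abort the move.  A vacant target receives the TC
   and one EC is deposited at the vacated site.  A TC-occupied target
   triggers tip-to-tip anastomosis with probability a_n (both TCs removed,
   ECs at both sites) and exclusion otherwise.  In Model 2 an EC-occupied
   target triggers tip-to-sprout anastomosis with probability a_e (the
   TC is removed, depositing an EC at its origin) unless the target EC
   belongs to the TC's own trail (self-loop: the move is aborted without
   consuming an anastomosis draw); with probability 1 − a_e the move is
   excluded.
2. **Branching.** The TC count is re-read and that many selections are
   drawn the same way.  A selected TC at (i, j) branches with probability
   P_b = P_p·c_i, replacing itself with daughters at (i, j±1), and only if
   *both* transverse neighbours are vacant (no TC; in Model 2 also no EC).
   Branching at j ∈ {0, R} is blocked and never creates ECs.  Daughters
   start with empty trails.

If the sampling pool empties mid-phase (every TC annihilated), the
remaining selections of that phase are skipped without consuming random
draws.

**Randomness.** One MT19937 stream per realization, consumed in a fixed
order (selection, gate, direction, resolution); realization m of an
ensemble uses seed `base_seed + m`.  The pure-Python reference engine and
the numba kernel consume the identical stream, so they are bit-identical —
an equivalence the test suite asserts on both models.  The kernel
represents Model 2 trails as an EC-owner grid; this is exact because in
Model 2 an EC site has a unique depositor for the lifetime of a run
(ECs are never removed and no TC can subsequently occupy an EC site).

Two readings of the update rule were genuinely open and were fixed as
follows: selections are with replacement (this matches the per-capita
rates of the mean-field equations, and a killed TC leaves the pool
immediately); branching requires both daughter sites vacant, never placing
a single daughter (the squared vacancy factor in the continuum branching
term implies two independent vacancy requirements); daughters do not
inherit the parent's trail (the simplest reading of "its own sprout").

## Averaging

Site occupancies are averaged over M realizations, and column averages
carry the 1/(M(R+1)) normalization over realizations and the transverse
direction.  Masses are trapezoidal integrals over x ∈ [0, 1] (the rule is
exact for the linear integrands used in the worked checks; any fixed
second-order rule would do).  Averaged Model 2 profiles satisfy
N + E ≤ 1 by construction, since no microstate violates occupancy caps.

## Continuum models

The mean-field PDEs (see README for the equations) are solved by the
method of lines on the R+1 CA column centres, so CA column averages seed
the PDE without interpolation at t_IC = τ·K_IC (default 0.2; the
discontinuous K = 0 initial condition is never given to the PDE).

* **Spatial discretization.** Second-order centred differences on nodal
  products, with ghost nodes encoding the no-flux condition
  D N_x − χ N (1 − (1 − a_n) N) c_x = 0 at x = 0, 1 to second order.  The
  chemotactic bracket is evaluated in the algebraically equivalent form
  (1 − N − B a_e E)(N c_x)_x − (1 − a_n) N N_x c_x.  This form was chosen
  deliberately: its a_n = 0 and a_n = 1 specializations coincide *exactly*
  (to rounding) with the discretizations of the two published limiting
  equations (the Burgers-like 1 − 2N form and the 1 − N pre-multiplied
  form), so the reduction identities can be asserted to machine precision
  rather than to O(h²).
* **Branching clamp.** The source λ c N (1 − N − B E)² uses the positive
  part of the vacancy factor and is zeroed wherever N ≥ 1 (Model 1) or
  N + E ≥ 1 (Model 2), which keeps the models well-posed at maximum
  density.
* **Time integration.** `scipy.integrate.solve_ivp` with RK45 at
  rtol 1e-6 / atol 1e-8.  At the default coefficients (D = 1e-3,
  h = 1/200) the semi-discrete system is non-stiff — the fastest scales
  are the reaction rate μ = 160 and the diffusion eigenvalue ≈ 4D/h² =
  160 over a time range of 1.8 — so an explicit pair is both accurate and
  roughly an order of magnitude cheaper per solve than BDF, which matters
  because a calibration performs ~500 solves.  BDF with a banded Jacobian
  sparsity pattern is the automatic fallback.
* **Diagnostics.** Each solution records a mass-balance defect (the
  spatial integral of dN/dt at the output times), a cheap audit of the
  discrete conservation structure.

The cell Péclet number at default parameters is χh/D = 2, so the centred
advection stencil is at its comfort limit; solutions seeded from averaged
(smooth) CA profiles show no oscillations, and the density caps hold to
about 1e-4 in the aggressive branching regimes exercised by the tests.

`meanfield_lattice_iterate` iterates the column-averaged difference
equations themselves (pre-Taylor): in-movement with vacancy factor
(1 − N − B a_e E), departures with factor 1 − (1 − a_n)·N_target (EC
blocking absent, since the mean-field closure is derived at a_e = 1),
per-departure EC deposition, tip-to-tip conversion of residents, and
branching with the squared vacancy factor; boundary in/out contributions
are dropped at i = 0, R, mirroring the CA's aborted boundary moves.
Taylor expansion of this update reproduces the PDEs exactly (the package's
internal consistency check), and the iterate converges to `solve_pde`
output at first order in τ when τ is refined at fixed (D, χ, μ, λ) via
P_m = μτ, P_p = λτ — the only refinement path consistent with the
coefficient map, since D = μh²/4 ties D, μ and h together.

## The linear comparator

The baseline snail-trail model is linear in N in its diffusive,
chemotactic and branching terms, with quadratic anastomosis sinks:

```
N_t = D_bc N_xx − χ_bc (N c_x)_x + λ_bc c N − β_n N² − β_e N E
E_t = μ N [+ 2 β_n N²]
```

Its five transport/reaction coefficients are all estimated by fitting; the
EC production rate is fixed to the mapped μ.  The +2β_n N² EC source (two
tips convert per tip-to-tip event) is on by default and toggleable.  This
comparator is reconstructed from the modified model's published
description — five fitted parameters, linear transport and branching,
EC evolution μN — rather than transcribed from its original closed-form
statement, and any quantitative claim resting on its exact form should be
read with that caveat.  Its boundary condition is the linear no-flux flux
D_bc N_x = χ_bc N c_x.

## Calibration

Per species, RMSE = sqrt(mean over fit times (default t = 0.4 … 2.0) and
grid nodes of the squared mismatch); the objective is rmse_N + rmse_E with
equal weights (exposed as `species_weighting`).  The search is
deterministic: a 21-point-per-axis grid scan over the boxed domain for one
or two free parameters, followed by a bounded Nelder–Mead polish
(xatol 1e-5, iteration cap 500).  A full grid is impractical for the
five-parameter comparator, so it uses a deterministic multi-start
Nelder–Mead from the mapped coefficients, the box mid-point and a
low-corner start instead.  Fitting bounds default to λ̃ ∈ [0, P_p/τ]
(the mapped rate is the natural upper bound: correlations slow effective
branching), ã_n ∈ [0, 1], and ã_e ∈ [1e-3, 1] (the half-open lower bound
floored).  The published ± companions of fitted values are interpreted as
across-ensemble repeat variability; `repeat_uncertainty` (default five
repeats on disjoint seed blocks) computes them, and the acceptance script
reports the five-repeat mean per scenario.

Self-consistency is enforced by an inverse-crime test (fitting
PDE-generated data recovers the generating parameters to 1e-3) and by the
low-branching regime (P_p = 1e-3), where the directly mapped PDE already
matches the averaged CA and fitting is unnecessary.

## What the synthetic data does and does not show

The CA itself is the data generator; there is no external data.  The
generator's defaults are the study conditions throughout: R = 200,
h = 1/200, P_m = 1, k = 100, τ = 1/160, K_IC = 32 (macroscale D = 1e-3,
χ = 0.4, μ = 160, t_IC = 0.2), ensembles of M = 200 realizations
(M = 50 in the scaled-down test-suite runs), branching probabilities
P_p ∈ {1e-3, 1e-2, 4e-2, 1e-1} depending on regime.  Passing tests
demonstrate internal consistency of the discrete-to-continuum chain and
reproduction of the benchmark fitted values; they say nothing about real
corneal vasculature, where the TAF field is dynamic, branching is
mediated by signalling rather than a linear concentration response, and
vessels are three-dimensional.

Known limitations: the single-species mean-field closure degrades when
branching/anastomosis rates are large relative to motility (that failure
is the very reason the calibration stage exists); strong EC volume
exclusion (a_e well below 0.1) produces long immobilized-TC tails that
neither continuum model captures; and the comparator model's exact
published form is reconstructed rather than transcribed.

## Numerical sizes used by the shipped checks

The test suite runs the full benchmark at M = 50 (tolerances sized from
the measured across-ensemble repeat scatter at that M: sd ≈ 0.05 for a
lambda-only fit, ≈ 0.02/0.008 for the joint fit), the exclusion-limit
check at 10⁴ single-walker realizations on R = 20, and the qualitative
regime checks at M = 50.  The acceptance script uses the full M = 200
protocol with five repeat fits per scenario.
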