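# Methods

## Model

Three boundedly rational populations — hospitals, third-party
investigators, local governments — repeatedly play a two-strategy game
each and update by payoff comparison.  The state `(x, y, z)` collects
the frequencies of compliant operation, true investigation and strict
supervision.  Payoffs come from an 8-cell matrix over sixteen
non-negative monetary parameters; the ordering assumptions are

* compliance costs more than fraud (`Ch1 > Ch2`), a true investigation
  more than a false one (`Ct1 > Ct2`), supervision is costly (`Cg > 0`);
* fraud pays the hospital more (`Ih2 > Ih1`), collusion pays the
  investigator more (`It2 > It1`, the margin being the bribe), and
  compliant operation yields the larger social benefit (`Ig1 > Ig2`);
* rewards are smaller than the corresponding costs (`Ah < Ch1`,
  `Ag < Cg`), so no player is paid into profitability.

Validation is two-tier: the *core* tier checks exactly these orderings,
the *strict* tier additionally requires `Ph, Pt, Pg > 0` and
`It2 > It1` strictly, because the threshold formulas divide by them.
Degenerate explorations (e.g. a zero fine) remain possible under core
validation.

The replicator equations are `dx/dt = x(1-x)G`, `dy/dt = y(1-y)J`,
`dz/dt = z(z-1)H` with `G = E11-E12`, `J = E21-E22`, `H = E32-E31`
(note the sign convention on H: supervision spreads where `H < 0`).

## Two dynamics modes and the symbolic audit

The payoff matrix is the single source of truth: expected payoffs are
always probability-weighted from it.  The closed-form equations printed
in the study this model originates from, however, contain two
discrepancies relative to their own matrix, and the package keeps both
routes alive rather than guessing the authors' intent:

* the printed third-party factor carries an extra bilinear term; the
  two vector fields differ by exactly `y(1-y)·x·z·(It1-It2)`
  (`mode_residual` proves this with sympy).  The `published` mode
  (default) integrates the printed equations — the stability table and
  all three scenario endpoints are only reproduced in this mode; the
  `matrix` mode integrates the derived field.  The divergence is
  substantive: at the scenario-3 parameters the corner (1,0,1) has
  third-party eigenvalue `Ct2-Ct1+Pt = +0.2` under matrix dynamics and
  is then *not* an ESS.
* the printed three-term expansion of the government's
  strict-supervision expected payoff omits the undetected-fraud cell;
  the omission equals `(1-x)(1-y)(Ig2-Cg+Ph+Pt+Ag)` exactly
  (`strict_payoff_residual`).  It is treated as typographical because
  the printed government *replicator equation* is matrix-consistent.

One consequence worth knowing: the published `J` is **not** monotone in
`z` wherever `x(It2-It1) > Pt` (its extra term overturns the fine
effect); the matrix-derived `J` is monotone (`dJ/dz = Pt`).

## Stationary points and stability

Setting all three rates to zero yields fifteen candidates: the eight
cube corners, one candidate per face (the two factor equations that
survive on the face are affine in one free coordinate each and solve in
closed form), and one interior candidate.  For the interior, `J = 0`
and `G = 0` give rational `x(z)` and `y(z)`; substitution into the
bilinear `H` and clearing denominators leaves a quadratic in `z`,
solved exactly (`numpy.roots`).  Candidates outside the cube are
flagged `in_domain=False`, degenerate solves are reported as undefined
with a reason — the census always has fifteen entries.  Mixed
candidates are enumerated but never classified: an asymptotically
stable state of a multi-population replicator system must be a
pure-strategy profile, so classification is restricted to corners.

At a corner the Jacobian is diagonal; eigenvalues are returned in the
row order of the study's stability table (a per-corner permutation of
the diagonal) so numeric output aligns with the table entry-for-entry.
Classification uses `tol = 1e-9` on eigenvalue signs; any eigenvalue
within `±tol` of zero yields `indeterminate` rather than a guessed
class, because the first Lyapunov method is inconclusive there.

The table-note conditions A/B/C are implemented as printed, but note
they are *necessary*, not sufficient, for E4 and E6: E4 additionally
needs `Cg < Ag+Pg+Ph+Pt` (not-A), and E6 needs
`Pt < Ct1-Ct2+It2-It1` together with `Ah+Ph > Ch1-Ch2+Ih2-Ih1`.  The
test suite asserts the exact characterizations; only `E1 ⇔ A` is a true
biconditional.

## Threshold geometry

Each player's indifference surface (`G=0`, `J=0`, `H=0`) is hyperbolic
on its unit square.  The region measures are reported two ways:

* **triangle** — the study's construction from the axis intercepts,
  `S = ½·L1·L2`, clipped into [0,1] and flagged when clipping occurred.
  Intercepts can exceed 1 (scenario 1 gives `A1C1 = 2`), and the
  government numerator `Ag-Cg+Pg+Ph+Pt` can be negative, in which case
  the curve misses the unit square entirely and the supervision basin
  is empty: the triangle area is defined as 0 there (the naive product
  of two negative intercepts would be spuriously positive).
* **integral** — midpoint quadrature of the exact factor sub-level set
  on a 512×512 grid; the grid error is far below the 1e-3 tolerance
  used in comparisons.  This is the reference when the triangle is
  clipped.

Sensitivity signs differentiate the closed-form segment lengths and
(unclipped) triangle measures symbolically and cross-check every value
against a central finite difference; for an empty basin the local
sensitivity is reported as zero.  One nuance: the bribe income `It2`
raises the segment `A2B2` but its effect on the *product* measure
`Vt2 = ½·A2B2·A2C2` can cancel exactly (it does at the scenario-1
values), so the sign claims are made at segment level.

## Numerical integration

`scipy.integrate.solve_ivp` with RK45, `rtol = 1e-8`, `atol = 1e-10`,
dense output at 201 evenly spaced times, default horizon `T = 50`
(the study plots 10–20 time units; the longer horizon makes endpoint
assertions robust without changing them).  The right-hand side is
evaluated at the state clamped into the cube — a no-op on the exact
solution (the cube is invariant) that prevents adaptive overshoot past
a face from feeding the anti-restoring polynomial continuation outside
[0,1]; stored states are clamped likewise.  Halving the tolerances
moves preset endpoints by less than 1e-6.

Convergence detection: a trajectory is settled when, over the last 10%
of its time span, the rate norm stays below `2·tol` and the state moves
less than `tol` (default `tol = 1e-3`).

**Boundary absorption.**  In float arithmetic a strategy frequency
decays to (numerical) zero in finite time, after which the trajectory
lives on an invariant boundary face.  A corner that is a saddle of the
full dynamics can be attracting *within* such a face, so converged
trajectories occasionally land on saddles whose escape directions have
been absorbed (observed in roughly 1–2% of random-parameter
trajectories; longer horizons absorb more, not fewer).  This is a
property of the dynamics, not an integrator defect.  The asymptotic
consistency of the classification is therefore tested two ways: settled
trajectories must never land on unstable corners and may land on a
saddle only along its numerically absorbed stable set (every escape
rate `λ·δ` below the detector resolution); and, directly, each corner
is displaced 0.01 into the interior — ESS corners must re-absorb the
perturbation, corners with a clearly positive eigenvalue must expel it
at some point of the trajectory (maximum excursion, because boundary
heteroclinic cycles can revisit a corner's neighbourhood).

## Scenario presets and the sampler

The three presets are the study's printed parameter sets; all start at
(0.8, 0.5, 0.2) and converge to (0,0,0), (0,0,1) and (1,0,1)
respectively under the published dynamics.  Property tests draw random
parameter sets by seeded rejection sampling — costs and incomes uniform
on (0, 10], rewards and fines on (0, 5], kept when the strict ordering
constraints (and optionally condition A, B or C) hold.  The ranges
bracket the printed scenario values (all lie in (0, 10]); the sampler
is deterministic per seed.

What the synthetic conditions do *not* emulate: real supervision
systems have heterogeneous hospitals, information asymmetry, budget
dynamics and a patient population — none are modelled, so passing tests
certify the game-theoretic machinery, not empirical calibration.

## Problem sizes

Test and acceptance runs use: 1000 random parameter sets for the
algebraic property suites, 200 sets × 5 interior starts (1000
trajectories, T = 50) for the dynamic suites, 50 sets × 8 corners for
the perturbation certification, a 512² quadrature grid, and 2–3-point
parameter sweeps per direction claim.

## Known limitations

* No stochastic (finite-population) dynamics, no time-varying
  parameters, no fourth player (patients), no reward mechanism for the
  third party — with the given assumptions the third party never
  stabilizes on true investigation (`y → 0` in every scenario).
* Mixed equilibria are enumerated but not classified; no
  center-manifold analysis at indeterminate corners; no
  basin-of-attraction computation beyond the empirical checks above.
* The triangle region measures inherit the study's straight-boundary
  approximation; use the integral method when intercepts approach or
  exceed 1.
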