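# fraudgame

A tested simulator and stability analyzer for a **tripartite evolutionary
game of healthcare-fraud supervision**: a hospital that chooses between
compliant and illegal (fraudulent) operation, a for-profit third-party
investigator that either investigates truthfully or colludes with the
hospital and files a false report, and a local government that either
supervises strictly or not at all, all coupled through a
reward-and-punishment mechanism (hospital reward `Ah`, hospital fine `Ph`,
third-party fine `Pt`, superior-government reward `Ag` and fine `Pg`).

The package is aimed at health-policy modellers who want to ask *which
instrument settings make compliance, honest investigation and supervision
evolutionarily stable* — and to get the answer with auditable algebra
rather than a one-off script.

## The model

Each player follows replicator dynamics over its mixed strategy
`(x, y, z)` = (P(compliant), P(true investigation), P(strict
supervision)):

```
dx/dt = x(1-x) G(y,z),   G = E11 - E12
dy/dt = y(1-y) J(x,z),   J = E21 - E22
dz/dt = z(z-1) H(x,y),   H = E32 - E31
```

where `Eij` are expected payoffs derived by probability-weighting an
8-cell payoff matrix over the sixteen non-negative parameters (costs
`Ch1, Ch2, Ct1, Ct2, Cg`; incomes `Ih1, Ih2, It1, It2, Ig1, Ig2`;
instruments `Ah, Ph, Pt, Ag, Pg`).  The unit cube is invariant; the eight
corners are stationary, and at a corner the Jacobian is diagonal, so
eigenvalues are closed-form and the first Lyapunov method classifies each
corner as ESS / saddle / unstable.  Only three corners can ever be ESS:

| corner | interpretation | stability condition |
|---|---|---|
| `E1 (0,0,0)` | fraud, collusion, no supervision | A: `Cg > Ag+Pg+Ph+Pt` |
| `E4 (0,0,1)` | supervised fraud | B: `Pt < Ct1-Ct2+It2-It1` and `Ah+Ph < Ch1-Ch2+Ih2-Ih1` (plus not-A) |
| `E6 (1,0,1)` | deterred fraud | C: `Ah+Cg < Ag+Pt` (plus complementary signs) |

The replicator field is provided in two symbolically audited forms
(`published` — the closed-form equations of the originating study, the
default — and `matrix`, derived from the payoff matrix; they differ by
exactly `y(1-y)·x·z·(It1-It2)` in the third-party equation, see
`fraudgame.replicator.mode_residual`).

## Worked example

Classify the equilibria of scenario preset 3 (strong hospital fine
`Ph=4.5`, generous superior reward `Ag=4.9`):

```
$ fraudgame stability --scenario 3
point  lambda1  lambda2  lambda3    class  condA  condB  condC
   E1     -2.0     -1.5      8.6   saddle  False  False   True
   ...
   E6     -0.5     -0.3     -3.1      ESS  False  False   True
   ...
conditions: A=False B=False C=True
ESS set: {E6}
```

All three eigenvalues at `E6 (1,0,1)` are negative — compliant operation
under strict supervision is the unique ESS, because condition C holds
(the supervision cost plus the hospital reward, `0.6+5=5.6`, is less
than the superior reward plus the third-party fine, `4.9+1.2=6.1`).
Integrating scenario 1 (costly supervision, weak fines) instead drives
everything to zero:

```
$ fraudgame simulate --scenario 1 --out traj1.csv
final state: x=0.000000 y=0.000000 z=0.000000
wrote 201 rows to traj1.csv
```

i.e. from the initial state (0.8, 0.5, 0.2) the hospital ends up
operating illegally, the third party colluding and the government
disengaged.  Sweeping the hospital fine in scenario 3 shows the deterrent
working faster as it grows — the time for compliance to cross 90% drops
from 1.18 to 0.64 time units:

```
$ fraudgame sweep --scenario 3 --vary Ph --values 4.5,5.0,5.5 --metric "time-to:x>0.9"
 Ph  valid  x_final      y_final  z_final   metric note
4.5   True      1.0 4.682938e-08      1.0 1.177708 None
5.0   True      1.0 3.935327e-08      1.0 0.838641 None
5.5   True      1.0 3.389777e-08      1.0 0.642066 None
```

The same analyses are available as library calls
(`fraudgame.run_scenario`, `fraudgame.stability_report`,
`fraudgame.threshold_geometry`, `fraudgame.parameter_sweep`) and accept
custom parameter files (`--params file.yaml` with exactly the sixteen
symbol keys).

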