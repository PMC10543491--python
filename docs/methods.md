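# Methods

## The model

`fraudgame` analyses an asymmetric 2×2 evolutionary game between a
population of doctors and a population of patients settling health-insurance
claims. Each side chooses *fraud* or *non-fraud*; `x` and `y` denote the
population frequencies of fraud among doctors and patients. Seventeen
constants parameterise the stage game:

| symbol | meaning | baseline |
|---|---|---|
| `K0`, `K1` | doctor payoff, honest / fraudulent (`K1 > K0`) | 2, 8 |
| `N0`, `N1` | patient payoff, honest / fraudulent (`N1 > N0`) | 2, 5 |
| `C1`, `C2` | fraud cost, doctor / patient | 3, 2 |
| `f`, `g` | moral-hazard coefficients (fraction of the counterpart's honest payoff extracted under information asymmetry), in (0, 1) | 0.8, 0.6 |
| `P1`, `P2` | insurer penalty on fraudulent doctor / patient | 5, 3 |
| `R1`, `R2` | insurer reward to honest doctor / patient | 5, 3 |
| `beta1`, `beta2` | risk coefficients: a fraudulent doctor carries risk `beta1*K1`, a patient `beta2*N1`, in (0, 1) | 0.5, 0.5 |
| `H` | bribe paid by the patient to the doctor under collusion | 2 |
| `M` | collusion surplus, split `alpha : 1-alpha` | 25 |
| `alpha` | doctor's share of the surplus, in (0, 1) | 0.5 |

The payoff matrix assigns honest-honest `(K0, N0)`; a lone fraudulent
doctor gets `-C1 + f*N0 + K1 - P1 - beta1*K1` while the honest patient gets
`N0 + R2 - f*N0` (reward, minus the extracted share); symmetrically for a
lone fraudulent patient; and under collusion the doctor gets
`-C1 + H + alpha*M + K1 - beta1*K1 - P1`, the patient
`-C2 - H + (1-alpha)*M + N1 - beta2*N1 - P2`. The bribe `H` enters the
patient's collusion payoff with a **minus** sign — the patient pays it —
which is what makes the bribery sweep non-monotone. Rewards are granted
only when the counterpart defects (the honest-honest cell is bare
`K0`/`N0`); the package implements this asymmetry as given and does not
second-guess it.

Two-population replicator dynamics drive the frequencies: each strategy
grows in proportion to its payoff advantage over its own population's
average. Expanding the expected utilities gives the planar cubic system

    dx/dt = x (1 - x) (a1 + b1 y)
    dy/dt = y (1 - y) (a2 + b2 x)

with `a1 = -C1 + f N0 + K1 - P1 - beta1 K1 - K0`,
`b1 = H + alpha M - R1 + g K0 - f N0`,
`a2 = -C2 + g K0 + N1 - P2 - beta2 N1 - N0`,
`b2 = -H + (1-alpha) M - R2 - g K0 + f N0`. Note the patient bracket
depends on the **doctor** frequency `x` (each side reacts to the other
population's mix, not its own); the package computes the field both from
this bracket form and, independently, from averaged payoff-matrix rows, and
its tests hold the two routes to 1e-10 agreement.

## Equilibria and regimes

The four corners are always fixed points; an interior point
`(x*, y*) = (A2/B2, A1/B1)` exists when both coordinates lie strictly in
(0, 1), where `A1 = -a1`, `B1 = b1`, `A2 = -a2`, `B2 = b2`. Stability uses
the planar determinant/trace criterion on the analytic Jacobian: det > 0
with trace < 0 is asymptotically stable (the game's ESS), det > 0 with
trace > 0 unstable, det < 0 a saddle, and det > 0 with zero trace a saddle
by convention. Sign tests use tolerance 1e-9; boundary hits are labelled
`indeterminate` (points) or `other` (regimes) rather than forced into a
class.

Three regimes follow from the order structure of (A1, B1, A2, B2):

* **case 1** (`A2 > B2 > 0`, `A1 > B1 > 0`): `x*, y* > 1`, four fixed
  points, unique ESS at the honest corner E(0,0).
* **case 2** (`A1 < 0`, `A2 < 0`, `B1, B2 > 0`): `x*, y* < 0`, unique ESS
  at the collusion corner K(1,1).
* **case 3** (`0 < A2 < B2`, `0 < A1 < B1`): bistable — E and K are both
  stable, the off-diagonal corners unstable, and P(x*, y*) is an interior
  saddle (its Jacobian has zero diagonal, so det < 0 and trace = 0
  identically).

**Attractor prediction (area rule).** In the bistable regime the long-run
outcome is predicted by comparing the area of the quadrilateral
S(0,1)-E(0,0)-N(1,0)-P(x*,y*) — shoelace value `(x* + y*)/2` — with its
complement: the corner bordering the larger region wins, ties (within
1e-9) are `undetermined`. The classical statement covers only saddles with
both coordinates on the same side of 1/2; comparing `(x* + y*)/2` with 1/2
extends it continuously and reduces to the classical statement in those
sub-cases. The rule is a straight-edge proxy for a curved separatrix: on
random bistable parameter sets the (1,1)-basin fraction measured on a
21×21 grid deviates from `1 - (x* + y*)/2` by ~0.07 in the median and up
to ~0.19 in the tail, while tracking it tightly in rank order (Spearman
ρ ≈ 0.97 over 50 samples). The package therefore asserts the ±0.1
numerical band only at the baseline (observed error ≈ 0.03) and the rank
correlation across samples; where the rule is decisive (area at least 0.05
from the tie) it agrees with simulation from (0.5, 0.5) in ≥ 95% of random
bistable samples.

## Numerical integration

The field is a smooth cubic on the invariant unit square, so a fixed-step
classical RK4 is used: `dt = 0.01` (time units of the replicator clock),
`max_steps = 100,000`, corner-convergence tolerance 1e-3 (Euclidean),
interior-stall velocity threshold 1e-10. States are clamped to the square
after each step; a clamp larger than 1e-9 raises a step-size error rather
than silently projecting, since it signals the step is too coarse for the
local stiffness. Halving `dt` changes the terminal corner on none of 100
random bistable samples. Trajectories started exactly at the interior
saddle report `interior-stall` at the first step.

Terminal frequencies are resolved only to the convergence tolerance, so
monotonicity checks on terminal values allow slack of twice that tolerance;
this is measurement resolution, not a loosened claim.

Basin maps integrate an n×n grid of starts placed strictly inside the
square (the boundary is a fixed line and would bias fractions), batch-
vectorised with converged points frozen. Default grid n = 21.

## Sweep experiments

Nine built-in one-parameter sweeps vary, against the full baseline, the
fraud costs C1 ∈ {3..7} and C2 ∈ {2..4}, moral hazard f ∈ {0.8..0.0} and
g ∈ {0.6..0.0}, penalties P1 ∈ {5..7} and P2 ∈ {3..7}, rewards
R1 ∈ {5..9} and R2 ∈ {3..7}, and the bribe H ∈ {2..6}. All start from
(0.5, 0.5) — the maximally uninformative mix, since the model itself
does not pin an initial state — and integrate one common run per value,
recording both coordinates. "Terminal fraud frequency" is the relevant
coordinate at convergence. The moral-hazard endpoint 0 lies on the
boundary of the open (0, 1) domain; the built-in specs relax the bound to
[0, 1) locally, while user-supplied configurations must opt in explicitly
(`allow_boundary` / `--allow-boundary`).

Expected qualitative behaviour, all reproduced by the test suite: terminal
fraud falls (weakly) in costs, penalties and rewards and rises in moral
hazard; among penalty values reaching honesty, convergence step counts
shrink as the penalty grows; and the bribery sweep reverses — collusion at
H = 2, 3 but honesty by H = 6, because the bribe transfers surplus from
patient to doctor, moving the saddle's coordinates in opposite directions
(`x*` strictly up, `y*` strictly down in H).

## Scenario generation

`scenarios` makes every other module testable without external data. The
baseline is the reference bistable parameter set. Random regimes come from
rejection sampling over uniform boxes bracketing the baseline (`K0, N0 ~
U(1,5)`; `K1, N1` as offsets `U(1,10)` above them, so fraud-pays-more holds
by construction; costs/penalties/rewards `U(0,10)`; `H ~ U(0,8)`; `M ~
U(5,40)`; unit-interval coefficients `U(0.05, 0.95)`), keeping the
distribution exactly uniform on each regime's feasible region. Acceptance
rates under the default box are roughly 7% (case 1), 0.2% (case 2, the
binding constraint being `A1, A2 < 0` with `B1, B2 > 0`), and 10%
(case 3); an exhausted attempt budget raises a feasibility error reporting
the observed rate. A single seeded generator stream per call makes draws
reproducible; the seed is carried in the sample metadata.

What the generator does **not** emulate: real claims data, empirical
parameter calibration, heterogeneous agents, or noise in payoffs. Passing
tests therefore demonstrate internal consistency of the game-theoretic
analysis across its parameter regimes, not predictive validity for any
actual insurance system.

## Problem sizes and test budget

The suite samples 200 parameter sets per regime once per session and
reuses them; the heavier invariants run at 1,000 random (parameter, state)
pairs for the field-equivalence oracle, 100 samples for dt-halving and for
prediction-vs-simulation agreement, 50 samples at grid 21 for the
basin/area rank correlation, and 200 samples per regime for the
stability-census cross-validation (100 in the per-criterion acceptance
tests). The full suite runs in well under a minute on one core.

## Known limitations

* Strictly the 2×2 two-population game: no third player (insurer as a
  strategic agent), no n-strategy or finite-population (Moran) variants,
  and no stochastic dynamics.
* Absolute time axes are not meaningful: the replicator clock is only
  defined up to the payoff scale, so step counts support orderings
  ("penalties shorten the road to honesty"), not durations.
* The area rule is a heuristic basin-share proxy; see its accuracy
  envelope above.
* Case boundaries (measure-zero equalities in the regime inequalities) are
  reported as `other`/`indeterminate`; no center-manifold analysis is
  attempted at degenerate points.
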