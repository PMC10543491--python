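# fraudgame

Evolutionary-game analysis of doctor–patient health-insurance fraud.

Health-insurance fraud — over-prescription, exaggerated claims, and
outright doctor–patient collusion — is shaped by incentives: fraud costs,
insurer penalties and rewards, moral hazard under information asymmetry,
and bribes that enable collusion. `fraudgame` models the interaction as an
asymmetric 2×2 evolutionary game between a population of doctors and a
population of patients and asks which incentive levers drive the system
toward honesty. It is aimed at health-policy modellers and at anyone who
wants a compact, fully tested reference implementation of two-population
replicator dynamics with stability and basin analysis.

## The model

Doctors play *fraud* with frequency `x`, patients with frequency `y`.
Seventeen constants set the stage-game payoffs (honest payoffs `K0, N0`;
fraudulent payoffs `K1 > K0`, `N1 > N0`; fraud costs `C1, C2`; moral-hazard
coefficients `f, g`; penalties `P1, P2`; rewards `R1, R2`; risk
coefficients `β1, β2`; bribe `H`; collusion surplus `M` split `α : 1−α`).
Frequencies evolve under replicator dynamics

    dx/dt = x(1−x)[U₁₁ − U₁₂],   dy/dt = y(1−y)[U₂₁ − U₂₂],

where `U₁₁ − U₁₂` is the doctor's expected payoff gain from fraud against
the current patient mix (and symmetrically for patients). The package
provides:

* **model core** — validated parameter sets, the payoff matrix, expected
  utilities, and the replicator vector field;
* **equilibria** — the four corner fixed points plus the interior point
  `(x*, y*)`, analytic Jacobians, determinant/trace stability labels
  (ESS / unstable / saddle), classification of the parameter regime
  (honesty-dominant, fraud-dominant, or bistable), and a
  quadrilateral-area rule predicting the long-run corner in the bistable
  regime;
* **dynamics** — fixed-step RK4 integration with corner-convergence
  detection and basin-of-attraction maps over grids of initial conditions;
* **sweeps** — nine built-in one-parameter experiments (costs, moral
  hazard, penalties, rewards, bribery);
* **scenarios** — the reference baseline parameter set and seeded
  rejection sampling of parameter sets from each regime.

See `docs/methods.md` for the full model account, numerical choices and
limitations.

## Worked example

```python
import fraudgame as fg

p = fg.baseline_params()
print("regime:", fg.classify_case(p).case_id)
ie = fg.interior_equilibrium(p)
print(f"interior saddle: x* = {ie.x_star:.4f}, y* = {ie.y_star:.4f}")
for r in fg.classify_equilibria(p):
    print(f"  {r.point}: det = {r.det:+.2f}, trace = {r.trace:+.2f} -> {r.label}")
pred = fg.predict_attractor(p)
print(f"area rule: S(PSEN) = {pred.area_PSEN:.4f} -> predicted corner {pred.corner}")
traj = fg.integrate(p, fg.StrategyState(0.5, 0.5))
print(f"simulation from (0.5, 0.5): {traj.status} at {traj.corner} after {traj.steps} steps")
basins = fg.basin_map(p, 21)
print(f"fraud-basin fraction (21x21 grid): {basins.fractions[(1.0, 1.0)]:.3f}")
```

prints

```text
regime: case3
interior saddle: x* = 0.4177, y* = 0.4835
  (0.0, 0.0): det = +14.52, trace = -7.70 -> ESS
  (0.0, 1.0): det = +15.51, trace = +8.00 -> unstable
  (1.0, 0.0): det = +20.24, trace = +9.00 -> unstable
  (1.0, 1.0): det = +21.62, trace = -9.30 -> ESS
  (0.4177215189873417, 0.4835164835164836): det = -4.37, trace = +0.00 -> saddle
area rule: S(PSEN) = 0.4506 -> predicted corner (1.0, 1.0)
simulation from (0.5, 0.5): converged at (1.0, 1.0) after 239 steps
fraud-basin fraction (21x21 grid): 0.580
```

Read: at the baseline incentives the system is **bistable** — both the
honest corner (0,0) and the collusion corner (1,1) are evolutionarily
stable, separated by an interior saddle at (0.418, 0.484). Because the
saddle sits below the centre of the square, the collusion basin is the
larger one (area-rule share 0.549; measured grid share 0.580), so a
population starting from an even strategy mix drifts into full
doctor–patient collusion. Raising the doctor's fraud cost from 3 to 7
(`p.replace(C1=7.0)`) moves the saddle up and flips the same start to the
honest corner.

A CLI mirrors the library:

```sh
fraudgame classify                      # regime + equilibria (baseline)
fraudgame simulate params.yaml --x0 0.4 --y0 0.6 --traj-out traj.csv
fraudgame basins params.yaml --grid 21 --out basins.csv
fraudgame sweep --figure bribery --out sweep.csv --plot sweep.png
fraudgame scenario --case 3 --seed 7 --n 10 --out scenarios.jsonl
```

Parameter files are flat YAML/JSON mappings keyed by the symbol names
above (`K0: 2`, `C1: 3`, …).

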