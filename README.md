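# mastsync

Analysis toolkit for **masting synchrony**: the population-wide, intermittent
seed production of perennial trees. Most masting species show irregular
(oak-type) or strict two-year alternate-bearing (citrus-type) cycles; some
populations instead lock into a dominant **period-3** cycle — one heavy crop
year followed by two lean years, synchronised across the whole stand.
`mastsync` provides the model and the statistics needed to detect, quantify
and explain that behaviour:

* a simulator for the **globally coupled resource budget model (GCM-RBM)**
  of pollen-coupled trees, with individual and common environmental noise;
* **Hilbert-phase** analysis and on/off-year flagging of ensemble
  seed-production series (survey classes or simulated crops);
* the **period-composition statistic** FP(Q) and the **in-phase fraction**
  F_IN for short ecological records;
* a **border-collision bifurcation** toolkit for the reduced one-dimensional
  map: iterated maps, tangent-bifurcation location, period-window scans,
  attractor-density diagrams and β–R_C parameter studies;
* a synthetic ordinal **survey generator** so the full analysis stack is
  testable without (rarely deposited) raw field tables.

## The model

Each tree stores reserves S(t) and gains a surplus P_S every year. Once
S + P_S exceeds a threshold L_T the excess is spent on flowering,

    C_f(t) = S(t) + P_S − L_T          (0 below threshold),

and a proportional amount on pollination/fruiting, C_a = R_C · C_f · Y,
where the cost ratio R_C is the central control parameter. The pollen
availability of tree i couples it to the rest of the stand,

    Y_i(t) = [ Σ_{j≠i} C_f^j(t) / ((N−1) P_0) ]^β,

so an out-of-phase tree sets no seed (C_S = C_f · Y). Noise enters the
surplus multiplicatively, P_S = P_0 (1 + e_C σ(t)) (1 + e_I δ_i(t)), with a
common draw σ and individual draws δ_i per year.

When the stand is synchronised the dynamics reduce to a piecewise-smooth
scalar map

    f(S) = S + P_0                                    if S + P_0 ≤ L_T
         = L_T − R_C (S + P_0 − L_T)^{β+1} / P_0^β     otherwise,

whose kink at S = L_T − P_0 makes every bifurcation a *border-collision*
event: as R_C grows the attractor period increases by one near each integer
R_C (period adding), and the dominant period-3 window opens through a
tangent bifurcation of the third iterate, f³.

Statistics: a period-Q motif is an on-year, Q−1 off-years, then an on-year;
FP(Q) is the normalised motif count per tree, averaged over the stand.
On-years are flagged either by amplitude (above the tree's temporal mean) or
by Hilbert phase (|θ| < π/2); the two rules agree on model output. F_IN is
the fraction of tree pairs whose year-on-year crop changes share sign, and
the Kuramoto order parameter r measures per-year phase coherence.

## Worked example

```python
import numpy as np
from mastsync import (ModelParams, simulate, hilbert_phase, on_flags_phase,
                      fraction_period_population, in_phase_fraction,
                      order_parameter)

params = ModelParams(R_C=2.0, beta=6.0, e_I=0.2, N=106, T_record=15, seed=0)
traj = simulate(params)                      # 106 trees, 15 recorded years

phases = hilbert_phase(traj.C_S)             # wrapped phases in (-pi, pi]
flags  = on_flags_phase(phases)              # on/off-year flags
fp     = fraction_period_population(flags)   # FP(Q) for Q = 2..6
sync   = in_phase_fraction(traj.C_S)
r, _   = order_parameter(phases.theta[:, -1])

print("population FP(Q):", {q: round(v, 3) for q, v in zip(fp.Q_range, fp.population)})
print("FP(3)/FP(2) =", round(fp[3] / fp[2], 2))
print("F_IN =", round(sync.F_IN, 3))
print("final-year order parameter r =", round(r, 3))
```

Output:

```
population FP(Q): {2: 0.259, 3: 0.717, 4: 0.0, 5: 0.057, 6: 0.005}
FP(3)/FP(2) = 2.77
F_IN = 0.982
final-year order parameter r = 0.96
```

Period-3 motifs occupy ~72% of the flag trains and period-2 slips ~26%, the
stand is almost perfectly in phase (F_IN ≈ 0.98), and the final year is
highly coherent (r ≈ 0.96): a noisy period-3 dominant synchronised state.

The same pipeline runs from the shell:

```
mastsync simulate --rc 2.0 --beta 6.0 --ei 0.2 --seed 0 --out crops.csv
mastsync analyze --input crops.csv --stats-out stats.json --figure-out panels.png
mastsync bifurcate --task window --period 3 --beta 6 --rc-min 1.55 --rc-max 2.0 --out edge.csv
mastsync synth --out survey.csv          # synthetic ordinal survey ensemble
mastsync sweep --out sweep.csv           # beta x R_C parameter study
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's numeric anchors from
scratch — the period-3 window edge of the reduced map (1e-4 resolution
scan), the near-tangency points of the third iterate just below the window,
the border derivatives and the first flip of the uncoupled map, and the
seed-averaged period composition, class-histogram mass and synchrony
extremes of the noisy ensemble simulation — and writes them to a JSON file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`; deterministic map anchors ignore it.
See `docs/methods.md` for the model assumptions, parameter conventions and
numerical choices behind these computations.
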