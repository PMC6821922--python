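# Methods

## Model

The resource budget model (RBM) treats a tree as a reservoir: every year it
adds a photosynthetic surplus `P_S` to its reserve `S`; once `S + P_S`
exceeds the threshold `L_T` the whole excess `C_f = S + P_S − L_T` is spent
on flowering, plus `C_a = R_C · C_f · Y` on pollination and fruiting. The
reserve after a reproductive year is `S + P_S − C_f − C_a`; it may be
negative after a heavy crop (no floor is applied — the update rule imposes
none, and a deficit year simply lengthens the recovery).

Pollen coupling makes fruiting depend on the rest of the stand: for tree i,

    Y_i = [ Σ_{j≠i} C_f^j / ((N−1) P_0) ]^β .

The self term is excluded (outcross pollen only); in a fully synchronised
stand both conventions coincide. Seed production is `C_S = C_f · Y`, the
observable a survey scores. With β = 0 the trees decouple (`Y ≡ 1`).

Noise enters the surplus multiplicatively,

    P_S^i(t) = P_0 (1 + e_C σ(t)) (1 + e_I δ_i(t)),

with one common standard-normal draw σ per year (a Moran-effect channel)
and one individual draw δ_i per tree-year (heterogeneity). `P_S` is not
clamped: a very rare large negative draw can make it negative, which the
threshold branch absorbs (`C_f` is clamped at zero). Draw order is fixed —
common first, then individuals in tree order — from one seeded generator,
so runs are bitwise reproducible.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `P_0` | annual surplus (resource units) | 10 | scale-setting |
| `L_T` | flowering threshold (resource units) | 100 | scale-setting |
| `R_C` | fruiting/flowering cost ratio (–) | 2.0 | slope at the uncoupled fixed point; the bifurcation parameter |
| `beta` | pollen-coupling exponent (–) | 6.0 | ≥ ~1 gives strong synchronisation; 6 puts the period-3 window at R_C ∈ [1.6172, 2.0] |
| `e_I`, `e_C` | individual / common noise (–) | 0 | 0.2 reproduces survey-like disturbance |
| `N` | stand size | 106 | survey-sized ensemble |
| `T_transient` | discarded years | 1000 | ample for the noisy steady state |
| `T_record` | recorded years | 15 | a typical survey span |

Initial reserves are drawn uniformly on `[0, L_T]`, one draw per tree (the
stationary statistics do not depend on this choice; synchronised and random
starts were checked to give the same ensemble behaviour).

## Reduced map and border-collision structure

A synchronised stand obeys the scalar map

    f(S) = S + P_0                                     (S + P_0 ≤ L_T)
         = L_T − R_C (S + P_0 − L_T)^{β+1} / P_0^β      (otherwise).

`f` is continuous with a kink at the border `S = L_T − P_0`: the left
derivative is 1 for every β; the right derivative is −R_C for β = 0 and 0
for β > 0. Bifurcations therefore happen when an orbit point collides with
the border (border-collision), producing a period-adding cascade: the
attractor period near integer `R_C = Q` is Q + 1. At exactly `R_C = 2` the
noise-free attractor is the border cycle {80, 90, 100}, with one orbit
point exactly on the border — which is why the noisy statistics at that
parameter are so sensitive to slip events.

The period-3 window opens through a tangent (saddle-node) bifurcation of
the third iterate `f³`. Numerically (β = 6, P_0 = 10, L_T = 100):

* scanning `R_C` at 1e-4 resolution, the first grid point whose attractor
  has period 3 is **1.6172** (the window edge);
* the tangent bifurcation itself sits at `R* = 1.6171511` (bisection on the
  signed minimum of `f³(S) − S`), where the newborn 3-cycle is
  {84.4800, 94.4800, 99.9414};
* at the window-edge grid point 1.6172 the stable 3-cycle is
  {84.45325, 94.45325, 99.94383};
* just below the window (1.6171) the third iterate shows three
  *near*-tangencies — local minimisers of |f³(S) − S| that do not cross the
  diagonal — at {84.4799, 94.4799, 99.9415}.

The smallest and middle points of any such triple lie on the accumulation
branch and differ by exactly `P_0`: `f` maps the smallest to the middle by
pure accumulation. This identity is used as a consistency check in the
acceptance tests (it also pins down a digit transposition in the published
reference triple: a printed pair differing by 10.0009 cannot both be orbit
points).

### Numerical choices

* **Transients.** Deterministic scans use 2·10⁵ iterations before period
  detection: near a tangent bifurcation convergence onto the newborn cycle
  is only algebraically fast, and the default keeps the 1e-4-resolution
  window scan correct at its edge.
* **Period detection.** Smallest q with `|x(t+q) − x(t)| < 1e-6` over a
  60-sample post-transient record; noisy runs are summarised by FP(Q)
  instead (strict recurrence is meaningless under noise).
* **Scan initial condition.** `S₀ = 50` (half-full pool). It is generic for
  every scan used here; integer-arithmetic coincidences (e.g. landing
  exactly on the unstable border cycle of the β = 0 map at R_C = 3) are
  avoided in tests by perturbing S₀.
* **Tangency search.** Dense grid (2·10⁵ points) for local minima of
  `|fⁿ(S) − S|` with residual below 1, refined by bracketed golden-section
  minimisation (xtol 1e-9); sign change across the bracket tags a genuine
  crossing. Fixed points of divisor iterates (the map's own unstable fixed
  point appears in f³) are filtered when locating the tangent bifurcation.
* **Derivatives at the border.** One-sided finite differences; the left
  branch is exactly linear so a unit step is exact, the right quotient at
  h = 1e-6 is `−R_C h^β / P_0^β` (zero to ~1e-42 for β = 6).

## Phase and period statistics

* **Hilbert phase.** Each tree's series is mean-centred and transformed to
  the discrete analytic signal over the full record — no padding,
  detrending or tapering. Short-record edge effects are accepted as part of
  the method. A clean period-3 cycle visits the three fundamental phases 0
  (on-year), 2π/3 (first off-year) and −2π/3 (second off-year). Constant
  series have no phase: they are masked invalid (phase 0 by convention)
  with a warning.
* **On/off flags.** Amplitude rule: strictly above the tree's temporal
  mean. Phase rule: |θ| < π/2 strictly. Boundaries and ties resolve to
  "off". The two rules agree exactly (agreement 1.0) on model output across
  the default β–R_C grid at e_I ∈ {0, 0.2}; the acceptance suite asserts
  this and would surface any disagreeing cell.
* **FP(Q).** Motif count (on, Q−1 offs, on) scaled by
  `Q / ((T−1) − (T−1) mod Q)` and clipped to [0, 1]. The off-run check
  covers t+1 … t+Q−1; a variant that starts at t+2 (admitting on-on
  adjacencies, matching one printed form of the definition but not its
  verbal description) is available as `strict_printed_product` for
  comparison. Population reducer: mean (median and mode available).
* **F_IN.** Pairs are in phase when their yearly increments share sign;
  both-zero increments count as in phase, a single zero as out of phase.
  Implemented in O(NT) by sign counting; an O(N²T) literal pair loop is the
  test oracle. For *independent* trees the expected pair fraction is
  exactly 1/2 once self-pairs are excluded, with finite-ensemble standard
  error √2/(2N); the uncoupled-stand bound F_IN ≤ 0.5 is therefore asserted
  with a 3σ allowance, derived before any measurement.
* **Order parameter.** `r e^{iψ} = mean(e^{iθ_i})`; r = 1 is perfect
  coherence, r ~ 1/√N an incoherent stand.
* **Population phase.** Ordinary median of the wrapped phases per year —
  deliberately not a circular median, adequate for tightly synchronised
  ensembles away from the ±π seam.

## State classification and parameter studies

Sweeps over β × R_C classify each cell from (F_IN, FP):
state I — desynchronised (F_IN < 0.9); state II — synchronised, period-2
dominant; state III — synchronised with some period ≥ 3 exceeding FP(2).
The 0.9 threshold is configurable; the transition is empirically sharp so
its exact value is uncritical. Default sweep ranges R_C ∈ [0.5, 4],
β ∈ [0, 8] (40×40) contain all three states and the period-2/3/4 windows;
the grid, replicate count and seeds are recorded in the scan metadata
because they are conventions, not measurements.

## Synthetic survey generator

The generator emulates the *statistical* structure of an ordinal masting
survey: ten crop classes, dominant on/off/off cycling anchored to a common
clock, per-tree initial phase jitter, per-cycle period-2 slips (which shift
the tree's clock permanently, as real slips do), ~70% of scores in the two
lowest classes (two lean years in three, plus a 10% crop-failure chance in
on-years), and a desynchronised episode in which each tree's clock is
scrambled by a random 0–2 year shift inside a ±2-year window. The window is
needed because the Hilbert phase at a year is estimated from the
oscillation around it: one scrambled year cannot decohere the estimate,
whereas the five-year window collapses the order parameter to its
incoherent floor of order 1/√N. Off-year scores are drawn once per year and
shared by all off trees, so the perfectly clean configuration has F_IN
exactly 1.

What a green test on this fixture establishes: the analysis stack
(phases → flags → FP/F_IN/r) recovers period-3 dominance, class-histogram
shape and a coherence collapse from data with the survey's format and
summary statistics. What it does not establish: anything about real
biology — the generator is not fitted to any species, its class bands are
equal-width by assumption, and its slip/jitter processes are convenient
idealisations.

## Known limitations and honest discrepancies

* The noisy-ensemble period composition at R_C = 2, β = 6, e_I = 0.2 is
  strongly realisation-dependent: 15-year windows fall into a bimodal
  mixture of clean mixed 3–2 realisations (FP(3) ≈ 0.72–0.75) and
  period-2-trapped epochs (FP(3) ≈ 0.25–0.5). The seed-ensemble mean of
  FP(3) is ≈ 0.47, while a single representative clean realisation gives
  ≈ 0.73. The acceptance suite asserts the published single-run reference
  value against the ensemble mean and keeps the resulting failure visible
  rather than selecting seeds; the companion FP(2) (≈ 0.25) and
  lowest-two-class mass (≈ 69%) do match their reference values under seed
  averaging. The sensitivity traces to the R_C = 2 border cycle sitting
  exactly on the flowering threshold.
* Strict period detection is undefined under noise; all noisy claims are
  made through FP/F_IN statistics.
* The reduced map describes only the fully synchronised stand; partially
  clustered noise-free states are not treated analytically, only through
  the full simulation.
* No spatially explicit coupling: the stand is a global mean field. No
  Lyapunov exponents or analytic continuation of bifurcation curves.
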