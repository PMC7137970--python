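# Methods

## Model

Two cell compartments are tracked as density fields over a continuous
state space of cell-cycle progression `p` and accumulated damage `a`:

* **Stem cells** `S(t, p, a)` (mitotic cells, including progenitors) on
  `[0, p*] x [0, a*]`. They progress through the cycle at speed `V_p`,
  accumulate damage at speed `v_a`, divide when `p` reaches `p*`, and are
  removed when `a` reaches the lethal threshold `a*`.
* **TD cells** `T(t, p, a)` (post-mitotic, terminally differentiated) on
  `[0, ∞) x [0, a_c]` with constant speeds `u_p`, `u_a`; they never
  divide and die at `a_c`.

Both fields obey hyperbolic conservation laws

    ∂S/∂t + ∂(V_p S)/∂p + ∂(v_a S)/∂a = 0,
    ∂T/∂t + ∂(u_p T)/∂p + ∂(u_a T)/∂a = 0.

Division is a boundary process. The flux of mothers through `p = p*` is
redistributed at `p = 0` according to the division type — symmetric
renewal (probability `δ1`, two stem daughters), symmetric
differentiation (`δ2`, two TD daughters) or asymmetric division (`δ3`,
one of each) — and the mother's damage `a'` is split between daughters
by point-mass kernels: fractions `(α1, α2)` between stem daughters,
`(β1, β2)` between TD daughters, `(γ1, γ2)` between the stem and TD
daughter of an asymmetric division. The kernels conserve cell number
(2, 2, 1, 1) and the total damage of each division.

### Feedback regimes

Signalling molecules are treated at quasi-steady state: a secreted
factor degraded in proportion to a population `P` has equilibrium
`1/(1 + (kP)^m)` (a Hill function, recomputed from the current
populations once per time step). Three regimes:

* **none** — constant basal rates `v_p`, `δ_i⁰`; the analytically
  tractable model.
* **td_only** — long-range inhibition by the TD population:
  `δ_i = δ_i⁰/(1 + (k_iT P_T)^mT)` for `i = 1, 2`, and
  `V_p = v_p/(1 + (k_vT P_T)^mT)`.
* **td_stem** — additional autocrine inhibition by the stem population
  and damage-dependent sigmoids:
  `V_p = v_p f(a)/(1 + (k_vT P_T)^mS + (k_vS P_S)^mS)`,
  `δ1 = δ1⁰ g(a)/(1 + (k_1T P_T)^mS + (k_1S P_S)^mS)`,
  `δ2 = δ2⁰/(1 + (k_2T P_T)^mS + (k_2S P_S)^mS)`, with
  `f(a) = a1 + b1/(1 + e^{-k1a(a - a10)})` and `g` analogous. With the
  default constants both sigmoids decrease from ≈1.1 to 0.4 with
  midpoint 0.75: heavily damaged cells cycle slower and renew less.

`δ3` is always the complement `1 − δ1 − δ2`; a configuration for which
`δ1 + δ2` could exceed 1 is rejected as an error rather than clamped
(with the default constants `δ1 + δ2 ≤ 0.9·1.1 < 1` always). The
sigmoids multiply the whole Hill quotient — they act as damage-dependent
modifiers of the maximal speed and renewal fraction. The stem-side Hill
exponent `mS` applies to both the TD and the stem term of the
`td_stem` denominators; `mT` is used in `td_only` mode.

### Default parameters

| symbol | meaning | default |
|---|---|---|
| `p*`, `a*`, `a_c` | cycle threshold, stem and TD lethal damage | 1, 1, 1 |
| `v_p`, `v_a` | stem cycle speed, stem damage accumulation | 0.2, 0.06 |
| `u_p`, `u_a` | TD cycle speed, TD damage accumulation | 0.02, 0.02 |
| `δ⁰` | basal division fractions | (0.6, 0.3, 0.1) |
| `k1T, k2T, kvT`; `mT` | TD regulation constants; Hill exponent | 1e-8, 0.5e-8, 0.5e-8; 2 |
| `k1S, k2S, kvS`; `mS` | stem regulation constants; Hill exponent | 1e-7, 0.25e-7, 0.5e-7; 2 |
| `a1=a2, b1=b2, k1a=k2a, a10=a20` | sigmoid constants | 1.1, −0.7, 20, 0.75 |

Feedback-free analyses (phase diagrams, limit-band checks) use
`v_a = 0.1` unless noted. Regulation constants are per cell, so the
regulated steady states sit near `P ~ 1/k ~ 1e8` cells.

## Analytic results encoded

* **Self-renewal fraction** `f_r = (2δ1 + δ3)/2`: expected stem
  daughters per division over two; geometric growth at `2 f_r` per
  cycle when nothing dies.
* **Limit damage band**: with constant rates, end-of-cycle damage of
  every lineage is attracted to `[Δ/(1−ω1), Δ/(1−ω2)]`, where
  `Δ = v_a p*/v_p` is the damage gained per cycle and `ω1 ≤ ω2` are the
  extreme stem-side inheritance fractions among `α1, α2, γ1`.
* **Classification**: extinction if `f_r < 1/2` or the whole band is
  lethal; blow-up (`f_r > 1/2`) or conservation (`f_r = 1/2`) if the
  whole band is sub-lethal; in the intermediate regime
  (`γ1 ≤ α1 < α2`, threshold inside the band) a sufficient extinction
  condition is `(2 f_r)^n − δ1^n < 1` with `n` the minimal number of
  consecutive heavy-daughter renewals that overshoot the threshold,
  found by direct scan (cap 10⁴; the scan's right side converges
  geometrically, so the cap is never the binding constraint). A
  threshold exactly at the band's upper edge yields `n = None`
  (definitively no finite `n`). The blow-up/conservation clauses also
  require initial mass on surviving trajectories; `classify` takes that
  as an explicit flag instead of assuming it.

## Numerics

* **Scheme**: dimensionally split first-order upwind finite volume on
  uniform cell-centred grids (progression sweep, then damage sweep).
  All velocities are non-negative, so upwinding is one-sided, the split
  scheme is conservative, and positivity is preserved under the
  per-direction CFL bound `dt ≤ safety·min(Δp/V_p^max, Δa/v_a, …)`
  (default safety 0.9). First order was chosen because positivity and
  exact conservation matter more here than order of accuracy; the
  scheme is verified against closed-form growth laws and the cohort
  oracle.
* **Division remapping**: the mother out-flux through `p = p*` is
  deposited at the kernel atoms (`α_i a'`, `γ1 a'` into newborn stem;
  `β_i a'`, `γ2 a'` into newborn TD) by particle-in-cell linear
  deposition: each point mass is split between the two bracketing cell
  centres so that count and first damage moment are both exact. At the
  extreme cells, where no bracketing pair exists, the whole mass goes to
  the boundary cell (count still exact). Deposition is linear in the
  mother flux, so it is precomputed as a matrix bank per (rule, grid).
  Two-cell deposition rather than nearest-cell rounding keeps the limit
  damage band from being pinned to the grid. TD newborns whose target
  damage is already at or past `a_c` (possible only when `a_c < a*`)
  are routed directly to the death tally, never clipped inward.
* **TD axis truncation**: the TD progression axis is cut at
  `p_max_T = 1.25 u_p a_c/u_a`; every TD cell dies before progressing
  that far, so the decay-at-infinity condition is honoured exactly (the
  residual escape flux is tracked and is zero to rounding).
* **Synchronized grids**: when `v_a p*/(v_p a*)` is a small rational,
  `synchronized_grid` picks cell counts and `dt` with Courant number
  exactly 1 in both directions; upwind advection then degenerates to an
  exact one-cell shift and the solver reproduces the branching-map
  oracle to machine precision. Long feedback-free classification runs
  use these grids so that extinction/blow-up verdicts are not polluted
  by numerical diffusion. On such grids a delta-like founding cohort
  occupies a single moving progression column, so end-of-cycle
  quantities are sampled at the step when that column is the last one.
* **Bookkeeping**: every step satisfies
  `ΔP = (births − mothers − deaths − escape)·dt` per compartment to
  rounding; `simulate` accumulates all tallies and the test suite
  asserts the identity end-to-end.
* **Death rates**: `r = (boundary out-flux at the lethal damage)/P`,
  with the boundary density approximated by the last damage cell.
  Empty compartments report NaN (undefined), not an exception.
* **Steady-state detection**: steady when the trailing-window
  (default 10 cycle times) relative variation of both populations is
  below 1e-5. Sustained oscillation: trailing peak-to-trough amplitude
  above 2% of the mean — well above solver ripple at default grids,
  well below visible population oscillations. Overshoot: maximum of
  `P_T` over the trailing-window mean.
* **Initial condition** (default): a smoothly tapered block on
  `p < 0.5 p*`, `a < 0.25 a*` scaled to `P_S(0) = 1e6`, no TD cells — a
  small, low-damage founding population; fully overridable. Delta-like
  cohorts (single cell) are used for oracle comparisons.
  Classification runs use extinction floor `1e-3 P_S(0)` and blow-up
  ceiling `1e6 P_S(0)`.

## The cohort oracle

With constant rates a synchronized founding cohort never
desynchronizes, so the stem population is exactly a finite set of
damage atoms evolving under an affine branching map (age by `Δ`, kill
at `a*`, spawn at `α1 a`, `α2 a`, `γ1 a`). This is an independent,
brute-force realization of the same dynamics used to validate the PDE
solver; it is exact but its atom count grows like 3^generations (merge
tolerance 1e-12, cap 10⁶ atoms), so it is a short-horizon tool.
Feedback regimes are out of its scope by design.

## Experiment defaults and problem sizes

* Segregation sweeps: `α1 ∈ {0.1, 0.3, 0.5}`, `γ1 ∈ {0.1, …, 0.9}`,
  `β1 = 0.5` (β sensitivity checked separately at `β1 ∈ {0.1, 0.3, 0.5}`),
  stem grid 128×128, TD grid 64×64, horizon 2500 time units with early
  stop on steadiness. These grids resolve the steady populations to the
  few-tenths-of-a-percent level while keeping a full sweep at
  desk-scale runtime.
* Phase diagrams: 100 division-fraction pairs sampled uniformly on
  `0 < δ1 + δ3 ≤ 1`, `2δ1 + δ3 ≥ 1` (default seed 191848; the region
  `2δ1 + δ3 < 1` is provably extinct and skipped), classified on
  synchronized grids over a 300-cycle horizon with floor/ceiling early
  exits and a trailing-trend fallback.
* Oracle comparisons: grids 32², 64², 128² with CFL 0.9; populations
  compared at mid-cycle times, where the whole (numerically smeared)
  cohort has completed the same number of divisions — sampling at the
  division instant itself would measure the jump discontinuity, not
  solver error.

## What the defaults do and do not show

The default conditions are idealized: uniform founding cohorts, exactly
constant speeds, deterministic segregation fractions and noiseless
feedback. Passing tests demonstrate internal consistency of solver,
oracle and theory under these conditions; they do not calibrate the
model to any measured tissue, and absolute population sizes are set by
the regulation constants, not by data.

A useful sanity identity: at any population steady state the TD death
rate equals `u_a/(a_c − mean TD birth damage)` — every TD cell born at
damage `a_b` lives exactly `(a_c − a_b)/u_a` — so with the default
`u_a = 0.02` the rate is of order 1e-2 per unit time, and its spread
across segregation rules (about 1.6x between the extreme rules) is set
entirely by where the rules place the TD birth damages. The absolute
scale is proportional to `u_a`.

## Known limitations

* First-order accuracy; no flux limiting or adaptive meshing.
* General (non-point-mass) transition kernels are not implemented; the
  remapper keeps them behind one operation so they could be added.
* The oracle covers only constant-rate regimes.
* Oscillatory regimes never satisfy the steadiness criterion; sweeps
  report trailing-window means plus oscillation metrics for them.
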