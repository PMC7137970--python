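"""Computational experiments: phase diagrams, segregation sweeps, feedback comparisons.

These drive the solver across parameter grids and reduce each run to
summary statistics: steady populations and death rates, realized
division fractions, oscillation/overshoot metrics, and the low-damage
mass fraction of the end-of-cycle damage distribution.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import FeedbackConfig, ModelParams, SegregationRule
from .theory import classify
from .transport_solver import (
    Grid,
    GridSpec,
    Trace,
    damage_marginal_at_division,
    detect_steady_state,
    make_grid,
    simulate,
    synchronized_grid,
)

__all__ = [
    "sample_delta_pairs",
    "classify_by_simulation",
    "phase_diagram",
    "proposition_concordance",
    "segregation_sweep",
    "oscillation_metrics",
    "fitness_comparison",
    "low_damage_fraction",
    "marginal_interquantile_width",
]

#: default division-pair sample size and seed for phase diagrams
PHASE_PAIRS = 100
PHASE_SEED = 191848
#: relative trailing amplitude above which oscillation counts as sustained
OSCILLATION_THRESHOLD = 0.02

_NO_FEEDBACK = FeedbackConfig(mode="none")


def sample_delta_pairs(n_pairs: int, seed: int = PHASE_SEED) -> np.ndarray:
    """Uniform (delta1, delta3) pairs over the triangle
    ``0 < delta1 + delta3 <= 1`` and ``2 delta1 + delta3 >= 1`` (rejection sampling).

    The second constraint excludes the region where extinction follows
    for any other parameters (subcritical renewal).
    """
    rng = np.random.default_rng(seed)
    out = np.empty((n_pairs, 2))
    got = 0
    while got < n_pairs:
        cand = rng.random((4 * (n_pairs - got) + 16, 2))
        d1, d3 = cand[:, 0], cand[:, 1]
        keep = (d1 + d3 > 0) & (d1 + d3 <= 1.0) & (2 * d1 + d3 >= 1.0)
        take = cand[keep][: n_pairs - got]
        out[got : got + take.shape[0]] = take
        got += take.shape[0]
    return out


def classify_by_simulation(
    params: ModelParams,
    rule: SegregationRule,
    deltas: Sequence[float],
    n_p_min: int = 12,
    t_end_cycles: float = 300.0,
    trailing_generations: int = 20,
    floor_frac: float = 1e-3,
    ceiling_frac: float = 1e6,
) -> str:
    """Empirical long-term verdict (``"extinct"`` / ``"non_extinct"``) of a
    feedback-free configuration.

    Runs the solver on a synchronized grid (exact advection; the only
    discretization left is the division deposition) from a delta-like
    low-damage founding cohort, stopping at the extinction floor or
    blow-up ceiling; if neither is hit, the verdict is the sign of the
    trailing population trend over the last ``trailing_generations``
    cycles (a flat trend — the conserved case — counts as non-extinct).
    """
    d1, d2, d3 = (float(x) for x in deltas)
    p = replace(params, delta0=(d1, d2, d3))
    grid, dt = synchronized_grid(p, n_p_min=n_p_min, n_p_T=8, n_a_T=8)
    cycle = p.cycle_time
    trace = simulate(
        p,
        rule,
        _NO_FEEDBACK,
        grid,
        init={"kind": "delta", "a0": 0.0, "total": 1.0},
        t_end=t_end_cycles * cycle,
        record_every=cycle,
        dt=dt,
        floor=floor_frac,
        ceiling=ceiling_frac,
        stop_on_steady=False,
    )
    if trace.termination == "extinct":
        return "extinct"
    if trace.termination == "blowup":
        return "non_extinct"
    P = trace.P_S
    k = min(trailing_generations, P.size - 1)
    if P[-1] <= 0:
        return "extinct"
    factor = P[-1] / P[-1 - k]
    return "non_extinct" if factor >= 1.0 - 1e-9 else "extinct"


def phase_diagram(
    params: ModelParams,
    rule: SegregationRule,
    n_pairs: int = PHASE_PAIRS,
    seed: int = PHASE_SEED,
    **classify_kwargs,
) -> pd.DataFrame:
    """Classify sampled (delta1, delta3) division pairs by simulation and by theory.

    Returns one row per pair with the simulated label
    (``extinct`` / ``non_extinct``), the analytic verdict and its firing
    clause.  A fixed seed makes the sample shareable across parameter
    variants, so survival regions can be compared pointwise.
    """
    pairs = sample_delta_pairs(n_pairs, seed=seed)
    rows = []
    for d1, d3 in pairs:
        d2 = 1.0 - d1 - d3
        verdict = classify(params, rule, (d1, d2, d3))
        sim = classify_by_simulation(params, rule, (d1, d2, d3), **classify_kwargs)
        rows.append(
            {
                "delta1": d1,
                "delta3": d3,
                "sim_class": sim,
                "theory_verdict": verdict.verdict,
                "theory_reason": verdict.reason,
            }
        )
    return pd.DataFrame(rows)


def proposition_concordance(
    params: ModelParams,
    n_configs: int = 100,
    seed: int = PHASE_SEED,
    **classify_kwargs,
) -> pd.DataFrame:
    """Compare analytic verdicts with simulated outcomes on random
    feedback-free configurations where a definitive proposition fires.

    Random division triples (uniform on the simplex) and segregation
    rules are drawn until ``n_configs`` of them are classified as
    ``extinct`` (subcritical renewal / lethal band), ``conserved`` or
    ``blowup_or_survival``; each is then simulated and the empirical
    label recorded.  Extinct must match ``extinct``; the other two are
    non-extinct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    while len(rows) < n_configs:
        d = rng.dirichlet((1.0, 1.0, 1.0))
        a1 = rng.uniform(0.05, 0.5)
        g1 = rng.uniform(0.05, 0.95)
        rule = SegregationRule(alpha1=a1, gamma1=g1)
        verdict = classify(params, rule, d)
        if verdict.verdict not in ("extinct", "conserved", "blowup_or_survival"):
            continue
        sim = classify_by_simulation(params, rule, d, **classify_kwargs)
        expected = "extinct" if verdict.verdict == "extinct" else "non_extinct"
        rows.append(
            {
                "delta1": d[0],
                "delta2": d[1],
                "delta3": d[2],
                "alpha1": a1,
                "gamma1": g1,
                "theory_verdict": verdict.verdict,
                "expected": expected,
                "sim_class": sim,
                "agree": sim == expected,
            }
        )
    return pd.DataFrame(rows)


def oscillation_metrics(
    trace: Trace, trailing_window: Optional[float] = None, threshold: float = OSCILLATION_THRESHOLD
) -> Tuple[float, bool, float]:
    """Overshoot ratio, sustained-oscillation flag and trailing relative amplitude.

    ``overshoot = max P_T / mean P_T over the trailing window``; the
    oscillation is sustained when the trailing peak-to-trough amplitude
    relative to the mean exceeds ``threshold`` (default 2%, well above
    solver ripple and well below visible population oscillations).
    ``trailing_window`` defaults to the last quarter of the trace.
    """
    t, PT = trace.times, trace.P_T
    if trailing_window is None:
        trailing_window = 0.25 * (t[-1] - t[0])
    m = t >= t[-1] - trailing_window
    late = PT[m]
    mean = float(late.mean())
    if mean <= 0:
        return math.nan, False, math.nan
    amplitude = float(late.max() - late.min()) / mean
    overshoot = float(PT.max()) / mean
    return overshoot, amplitude > threshold, amplitude


def low_damage_fraction(marginal: np.ndarray, a_centers: np.ndarray, da: float, cutoff: float) -> float:
    """Mass fraction of a damage marginal below ``cutoff`` (midpoint rule)."""
    total = float(marginal.sum()) * da
    if total <= 0:
        return math.nan
    return float(marginal[a_centers < cutoff].sum()) * da / total


def marginal_interquantile_width(
    marginal: np.ndarray, a_centers: np.ndarray, da: float, lo: float = 0.1, hi: float = 0.9
) -> float:
    """Width of the central quantile range of a damage marginal."""
    mass = marginal * da
    total = mass.sum()
    if total <= 0:
        return math.nan
    cdf = np.cumsum(mass) / total
    return float(np.interp(hi, cdf, a_centers) - np.interp(lo, cdf, a_centers))


def _run_to_steady(
    params: ModelParams,
    rule: SegregationRule,
    fb: FeedbackConfig,
    grid: Grid,
    t_end: float,
    trailing_window: float,
):
    trace = simulate(
        params,
        rule,
        fb,
        grid,
        t_end=t_end,
        record_every=1.0,
        floor=1.0,
        ceiling=1e30,
        stop_on_steady=True,
    )
    steady = trace.termination == "steady"
    if steady:
        vals = trace.steady
    else:
        _, vals = detect_steady_state(trace, rel_tol=math.inf, window=trailing_window)
    return trace, steady, vals


def segregation_sweep(
    params: ModelParams,
    mode: str,
    alpha1_list: Sequence[float] = (0.1, 0.3, 0.5),
    beta1_list: Sequence[float] = (0.5,),
    gamma1_list: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    grid: Optional[Grid] = None,
    fb: Optional[FeedbackConfig] = None,
    t_end: float = 2500.0,
    trailing_window: float = 100.0,
    damage_cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Run the solver to (quasi-)steady state over a segregation-rule grid.

    One row per (alpha1, beta1, gamma1): steady or trailing-window mean
    populations, their ratio, death rates, realized division fractions,
    oscillation metrics, and the low-damage mass fraction of the
    end-of-cycle damage marginal.  Non-steady runs are flagged and
    summarized by their trailing window instead.
    """
    if fb is None:
        fb = FeedbackConfig(mode=mode)
    elif fb.mode != mode:
        fb = replace(fb, mode=mode)
    if grid is None:
        grid = make_grid(params, GridSpec())
    if damage_cutoff is None:
        damage_cutoff = fb.a10
    rows = []
    for a1 in alpha1_list:
        for b1 in beta1_list:
            for g1 in gamma1_list:
                rule = SegregationRule(alpha1=a1, beta1=b1, gamma1=g1)
                trace, steady, vals = _run_to_steady(
                    params, rule, fb, grid, t_end, trailing_window
                )
                overshoot, sustained, amplitude = oscillation_metrics(
                    trace, trailing_window=trailing_window
                )
                marginal, ok = damage_marginal_at_division(trace.final_state, grid)
                frac = (
                    low_damage_fraction(marginal, grid.a_centers_S, grid.da_S, damage_cutoff)
                    if ok
                    else math.nan
                )
                width = (
                    marginal_interquantile_width(marginal, grid.a_centers_S, grid.da_S)
                    if ok
                    else math.nan
                )
                rows.append(
                    {
                        "alpha1": a1,
                        "beta1": b1,
                        "gamma1": g1,
                        "mode": mode,
                        "steady": steady,
                        "termination": trace.termination,
                        "P_S": vals.get("P_S", math.nan),
                        "P_T": vals.get("P_T", math.nan),
                        "ratio_T_S": vals.get("P_T", math.nan) / vals.get("P_S", math.nan),
                        "r_S": vals.get("r_S", math.nan),
                        "r_T": vals.get("r_T", math.nan),
                        "delta1": vals.get("delta1", math.nan),
                        "delta2": vals.get("delta2", math.nan),
                        "delta3": vals.get("delta3", math.nan),
                        "overshoot": overshoot,
                        "sustained_oscillation": sustained,
                        "oscillation_amplitude": amplitude,
                        "low_damage_fraction": frac,
                        "marginal_iqw": width,
                    }
                )
    return pd.DataFrame(rows)


def fitness_comparison(
    params: ModelParams,
    rule: SegregationRule,
    grid: Optional[Grid] = None,
    cutoff: Optional[float] = None,
    t_end: float = 2500.0,
    trailing_window: float = 100.0,
) -> dict:
    """Low-damage mass fractions of the steady end-of-cycle damage marginal,
    TD-only feedback versus TD+stem feedback, at a fixed segregation rule."""
    if grid is None:
        grid = make_grid(params, GridSpec())
    out = {}
    for mode in ("td_only", "td_stem"):
        fb = FeedbackConfig(mode=mode)
        if cutoff is None:
            cutoff = fb.a10
        trace, steady, _ = _run_to_steady(params, rule, fb, grid, t_end, trailing_window)
        marginal, ok = damage_marginal_at_division(trace.final_state, grid)
        out[mode] = (
            low_damage_fraction(marginal, grid.a_centers_S, grid.da_S, cutoff)
            if ok
            else math.nan
        )
        out[f"{mode}_steady"] = steady
    out["difference"] = out["td_stem"] - out["td_only"]
    out["cutoff"] = cutoff
    return out
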