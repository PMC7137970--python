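"""Conservative finite-volume integration of the two-compartment transport system.

The stem density ``S(t, p, a)`` obeys a hyperbolic conservation law with
uni-directional velocities (``V_p`` in cycle progression, ``v_a`` in
damage); likewise the TD density ``T`` with speeds ``u_p``, ``u_a``.
Both are discretized on uniform cell-centred grids and advanced with a
dimensionally split first-order upwind scheme:

1. progression sweep — upwind fluxes in ``p``; the outflux through
   ``p = p_star`` is the mother flux, remapped by the division kernels
   into the ``p = 0`` influxes of both compartments;
2. damage sweep — upwind fluxes in ``a`` with zero inflow at ``a = 0``;
   the outflux through ``a = a_star`` (stem) or ``a = a_c`` (TD) is
   accumulated as death flux and never re-enters.

The split scheme is conservative and positivity-preserving under the
per-direction CFL bound, and every step satisfies the exact bookkeeping
identity ``dP = (births - mothers consumed - deaths) dt`` per
compartment.  When the time step is chosen so that the Courant number
is exactly 1 in both directions (see :func:`synchronized_grid`),
upwinding degenerates to an exact one-cell shift and the only numerical
error left is the division deposition — useful for long feedback-free
classification runs.

Feedback quantities (populations, division fractions, cycle speed) are
recomputed once per step from the current state: the quasi-steady-state
treatment of the signalling molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .division_kernels import DivisionRemapper
from .model_core import (
    FeedbackConfig,
    ModelParams,
    SegregationRule,
    cycle_speed,
    division_fractions,
    max_cycle_speed,
    sigmoid_f,
    sigmoid_g,
)

__all__ = [
    "GridSpec",
    "Grid",
    "make_grid",
    "synchronized_grid",
    "PopulationState",
    "Trace",
    "default_initial_state",
    "delta_initial_state",
    "cfl_dt",
    "step",
    "death_rates",
    "simulate",
    "detect_steady_state",
    "damage_marginal_at_division",
]

#: default extinction floor / blow-up ceiling, relative to the initial population
EXTINCTION_FLOOR_FRAC = 1e-3
BLOWUP_CEILING_FRAC = 1e6
#: default steady-state detector settings: relative tolerance and window in cycle times
STEADY_REL_TOL = 1e-5
STEADY_WINDOW_CYCLES = 10.0


@dataclass(frozen=True)
class GridSpec:
    """Cell counts for the stem and TD domains.

    The stem domain is ``[0, p_star] x [0, a_star]``; the TD domain is
    ``[0, p_max_T] x [0, a_c]`` with the progression axis truncated at
    ``p_max_T`` (default ``1.25 u_p a_c / u_a``, beyond the progression
    any TD cell can reach before dying, so no mass is lost).
    """

    n_p_S: int = 128
    n_a_S: int = 128
    n_p_T: int = 64
    n_a_T: int = 64
    p_max_T: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("n_p_S", "n_a_S", "n_p_T", "n_a_T"):
            if getattr(self, name) < 8:
                raise ValueError(f"{name} must be at least 8 cells")


@dataclass(frozen=True)
class Grid:
    """Realized geometry: cell widths and centre coordinates for both domains."""

    spec: GridSpec
    dp_S: float
    da_S: float
    dp_T: float
    da_T: float
    p_centers_S: np.ndarray
    a_centers_S: np.ndarray
    p_centers_T: np.ndarray
    a_centers_T: np.ndarray
    p_max_T: float


def make_grid(params: ModelParams, spec: GridSpec = GridSpec()) -> Grid:
    """Build grid geometry for a parameter set; validates the TD truncation."""
    p_max_T = spec.p_max_T
    escape_p = params.u_p * params.a_c / params.u_a
    if p_max_T is None:
        p_max_T = 1.25 * escape_p
    elif p_max_T < escape_p - 1e-12:
        raise ValueError(
            f"p_max_T={p_max_T} is below u_p*a_c/u_a={escape_p}; TD cells could outlive the axis"
        )
    dp_S = params.p_star / spec.n_p_S
    da_S = params.a_star / spec.n_a_S
    dp_T = p_max_T / spec.n_p_T
    da_T = params.a_c / spec.n_a_T
    mk = lambda d, n: (np.arange(n) + 0.5) * d
    return Grid(
        spec=spec,
        dp_S=dp_S,
        da_S=da_S,
        dp_T=dp_T,
        da_T=da_T,
        p_centers_S=mk(dp_S, spec.n_p_S),
        a_centers_S=mk(da_S, spec.n_a_S),
        p_centers_T=mk(dp_T, spec.n_p_T),
        a_centers_T=mk(da_T, spec.n_a_T),
        p_max_T=p_max_T,
    )


def synchronized_grid(
    params: ModelParams,
    n_p_min: int = 24,
    n_p_T: int = 16,
    n_a_T: int = 16,
    max_denominator: int = 64,
):
    """Stem grid and time step with Courant number exactly 1 in both directions.

    Requires the ratio ``v_a p_star / (v_p a_star)`` to be (close to) a
    small rational ``num/den``; then ``n_p_S = k num``, ``n_a_S = k den``
    and ``dt = dp_S / v_p = da_S / v_a`` make upwind advection an exact
    one-cell shift.  Returns ``(grid, dt)``.
    """
    r = Fraction(params.v_a * params.p_star / (params.v_p * params.a_star)).limit_denominator(
        max_denominator
    )
    if abs(float(r) - params.v_a * params.p_star / (params.v_p * params.a_star)) > 1e-12:
        raise ValueError("speed ratio is not a small rational; no synchronized grid exists")
    num, den = r.numerator, r.denominator
    k = max(1, math.ceil(n_p_min / num), math.ceil(8 / num), math.ceil(8 / den))
    spec = GridSpec(n_p_S=k * num, n_a_S=k * den, n_p_T=n_p_T, n_a_T=n_a_T)
    grid = make_grid(params, spec)
    dt = grid.dp_S / params.v_p
    assert abs(dt * params.v_a - grid.da_S) < 1e-14
    return grid, dt


@dataclass
class PopulationState:
    """Discretized density fields and the clock.

    ``S`` has shape ``(n_p_S, n_a_S)`` and ``T`` ``(n_p_T, n_a_T)``, in
    cells per unit progression per unit damage.
    """

    S: np.ndarray
    T: np.ndarray
    t: float = 0.0

    def populations(self, grid: Grid):
        """Midpoint-rule population integrals ``(P_S, P_T)``."""
        P_S = float(self.S.sum()) * grid.dp_S * grid.da_S
        P_T = float(self.T.sum()) * grid.dp_T * grid.da_T
        return P_S, P_T


def default_initial_state(
    params: ModelParams, grid: Grid, total: float = 1e6
) -> PopulationState:
    """Small low-damage founding population: a smoothly tapered block on
    ``p < 0.5 p_star``, ``a < 0.25 a_star``, scaled to ``P_S = total``; no TD cells."""

    def taper(x: np.ndarray, cutoff: float) -> np.ndarray:
        y = x / cutoff
        out = np.where(y <= 0.8, 1.0, 0.5 * (1.0 + np.cos(np.pi * (y - 0.8) / 0.2)))
        out[y >= 1.0] = 0.0
        return out

    shape = taper(grid.p_centers_S, 0.5 * params.p_star)[:, None] * taper(
        grid.a_centers_S, 0.25 * params.a_star
    )[None, :]
    mass = shape.sum() * grid.dp_S * grid.da_S
    S = shape * (total / mass)
    T = np.zeros((grid.spec.n_p_T, grid.spec.n_a_T))
    return PopulationState(S=S, T=T, t=0.0)


def delta_initial_state(
    params: ModelParams, grid: Grid, a0: float = 0.0, p0: float = 0.0, total: float = 1.0
) -> PopulationState:
    """Delta-like founding cohort: all mass in the single cell nearest ``(p0, a0)``."""
    ip = int(np.clip(p0 / grid.dp_S, 0, grid.spec.n_p_S - 1))
    ia = int(np.clip(a0 / grid.da_S, 0, grid.spec.n_a_S - 1))
    S = np.zeros((grid.spec.n_p_S, grid.spec.n_a_S))
    S[ip, ia] = total / (grid.dp_S * grid.da_S)
    T = np.zeros((grid.spec.n_p_T, grid.spec.n_a_T))
    return PopulationState(S=S, T=T, t=0.0)


def cfl_dt(params: ModelParams, fb: FeedbackConfig, grid: Grid, safety: float = 0.9) -> float:
    """Largest stable time step under the per-direction CFL bound, times ``safety``."""
    vmax = max_cycle_speed(params, fb)
    return safety * min(
        grid.dp_S / vmax,
        grid.da_S / params.v_a,
        grid.dp_T / params.u_p,
        grid.da_T / params.u_a,
    )


class _StepWorkspace:
    """Per-run cached quantities: deposit operator and damage-grid profiles."""

    def __init__(self, params: ModelParams, rule: SegregationRule, fb: FeedbackConfig, grid: Grid):
        self.remapper = DivisionRemapper(
            rule,
            grid.a_centers_S,
            grid.da_S,
            grid.a_centers_T,
            grid.da_T,
            params.a_c,
            a_star=params.a_star,
        )
        self.fb = fb
        if fb.mode == "td_stem":
            self.f_arr = sigmoid_f(grid.a_centers_S, fb)
            self.g_arr = sigmoid_g(grid.a_centers_S, fb)
        else:
            self.f_arr = None
            self.g_arr = None

    def rates(self, PT: float, PS: float, params: ModelParams):
        """Cycle speed (scalar or per-damage array) and division-fraction triple."""
        fb = self.fb
        d10, d20, _ = params.delta0
        if fb.mode == "none":
            return params.v_p, (d10, d20, 1.0 - d10 - d20)
        if fb.mode == "td_only":
            vp = params.v_p / (1.0 + (fb.kvT * PT) ** fb.mT)
            d1 = d10 / (1.0 + (fb.k1T * PT) ** fb.mT)
            d2 = d20 / (1.0 + (fb.k2T * PT) ** fb.mT)
            return vp, (d1, d2, 1.0 - d1 - d2)
        hv = 1.0 + (fb.kvT * PT) ** fb.mS + (fb.kvS * PS) ** fb.mS
        h1 = 1.0 + (fb.k1T * PT) ** fb.mS + (fb.k1S * PS) ** fb.mS
        h2 = 1.0 + (fb.k2T * PT) ** fb.mS + (fb.k2S * PS) ** fb.mS
        vp = params.v_p * self.f_arr / hv
        d1 = d10 * self.g_arr / h1
        d2 = d20 / h2
        return vp, (d1, d2, 1.0 - d1 - d2)


def _check_cfl(params, fb, grid, dt, vmax):
    bound = min(
        grid.dp_S / vmax,
        grid.da_S / params.v_a,
        grid.dp_T / params.u_p,
        grid.da_T / params.u_a,
    )
    if dt > bound * (1.0 + 1e-9):
        raise ValueError(f"CFL violation: dt={dt} exceeds stable bound {bound}")


def step(
    state: PopulationState,
    params: ModelParams,
    rule: SegregationRule,
    fb: FeedbackConfig,
    grid: Grid,
    dt: float,
    workspace: Optional[_StepWorkspace] = None,
):
    """Advance one time step; returns ``(new_state, diagnostics)``.

    Diagnostics is a dict with the per-step fluxes (births, mothers
    consumed, deaths, TD escape through the truncated axis), realized
    division fractions (mother-flux weighted), and the pre-step
    populations.  The bookkeeping identity
    ``P_new - P_old = (births - mothers - deaths - escape) * dt``
    holds to rounding in each compartment.
    """
    ws = workspace or _StepWorkspace(params, rule, fb, grid)
    P_S = float(state.S.sum()) * grid.dp_S * grid.da_S
    P_T = float(state.T.sum()) * grid.dp_T * grid.da_T
    vp, deltas = ws.rates(P_T, P_S, params)
    vmax = float(np.max(vp))
    _check_cfl(params, fb, grid, dt, vmax)

    S = state.S
    # --- stem progression sweep ---
    Fp = S * vp  # vp scalar or (n_a,) broadcast over p rows
    mother_flux = Fp[-1]
    outcome = ws.remapper(mother_flux, deltas)
    S_new = S.copy()
    S_new[1:] += (dt / grid.dp_S) * (Fp[:-1] - Fp[1:])
    S_new[0] += (dt / grid.dp_S) * (outcome.newborn_S_influx - Fp[0])
    # --- stem damage sweep ---
    Fa = params.v_a * S_new
    death_S_flux = float(Fa[:, -1].sum()) * grid.dp_S
    S_new[:, 1:] += (dt / grid.da_S) * (Fa[:, :-1] - Fa[:, 1:])
    S_new[:, 0] -= (dt / grid.da_S) * Fa[:, 0]

    T = state.T
    # --- TD progression sweep ---
    Gp = params.u_p * T
    escape_flux = float(Gp[-1].sum()) * grid.da_T
    T_new = T.copy()
    T_new[1:] += (dt / grid.dp_T) * (Gp[:-1] - Gp[1:])
    T_new[0] += (dt / grid.dp_T) * (outcome.newborn_T_influx - Gp[0])
    # --- TD damage sweep ---
    Ga = params.u_a * T_new
    death_T_flux = float(Ga[:, -1].sum()) * grid.dp_T + outcome.overflow_T_deaths
    T_new[:, 1:] += (dt / grid.da_T) * (Ga[:, :-1] - Ga[:, 1:])
    T_new[:, 0] -= (dt / grid.da_T) * Ga[:, 0]

    if S_new.min() < -1e-12 * max(S_new.max(), 1.0) or T_new.min() < -1e-12 * max(
        T_new.max(), 1.0
    ):
        raise RuntimeError(
            "negative density after step; the split upwind scheme is positivity-"
            "preserving under CFL, so this indicates a configuration or solver bug"
        )
    np.clip(S_new, 0.0, None, out=S_new)
    np.clip(T_new, 0.0, None, out=T_new)

    mothers = outcome.mothers_consumed
    if mothers > 0:
        F = mother_flux * grid.da_S
        d_real = tuple(float(np.sum(np.broadcast_to(d, F.shape) * F)) / mothers for d in deltas)
    else:
        d_real = (math.nan, math.nan, math.nan)

    diag = {
        "P_S": P_S,
        "P_T": P_T,
        "mothers": mothers,
        "births_S": outcome.newborn_S_count,
        "births_T": outcome.newborn_T_count - outcome.overflow_T_deaths,
        "deaths_S": death_S_flux,
        "deaths_T": death_T_flux,
        "overflow_T": outcome.overflow_T_deaths,
        "escape_T": escape_flux,
        "delta_realized": d_real,
        "v_p_max": vmax,
    }
    return PopulationState(S=S_new, T=T_new, t=state.t + dt), diag


def death_rates(state: PopulationState, params: ModelParams, grid: Grid):
    """Instantaneous per-capita death rates ``(r_S, r_T)`` from the lethal boundary flux.

    ``r_S = v_a integral S(t, p, a_star) dp / P_S`` (boundary density
    approximated by the last damage cell), and analogously for TD cells.
    Returns ``nan`` for an empty compartment (undefined rate).
    """
    P_S, P_T = state.populations(grid)
    r_S = (
        params.v_a * float(state.S[:, -1].sum()) * grid.dp_S / P_S if P_S > 0 else math.nan
    )
    r_T = (
        params.u_a * float(state.T[:, -1].sum()) * grid.dp_T / P_T if P_T > 0 else math.nan
    )
    return r_S, r_T


@dataclass
class Trace:
    """Recorded time series of a run plus termination metadata."""

    times: np.ndarray
    P_S: np.ndarray
    P_T: np.ndarray
    r_S: np.ndarray
    r_T: np.ndarray
    delta1: np.ndarray
    delta2: np.ndarray
    delta3: np.ndarray
    termination: str
    steady: Optional[dict]
    final_state: Optional[PopulationState]
    cum_births_S: float = 0.0
    cum_deaths_S: float = 0.0
    cum_mothers: float = 0.0
    cum_births_T: float = 0.0
    cum_deaths_T: float = 0.0
    cum_escape_T: float = 0.0
    marginals: Optional[dict] = None  # time -> end-of-cycle damage marginal

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "P_S": self.P_S,
                "P_T": self.P_T,
                "r_S": self.r_S,
                "r_T": self.r_T,
                "delta1": self.delta1,
                "delta2": self.delta2,
                "delta3": self.delta3,
            }
        )


def detect_steady_state(
    trace: Trace,
    rel_tol: float = STEADY_REL_TOL,
    window: Optional[float] = None,
    cycle_time: Optional[float] = None,
):
    """Trailing-window steadiness verdict on the recorded populations.

    Steady iff the max relative variation of both ``P_S`` and ``P_T``
    over the trailing ``window`` time units is below ``rel_tol``.
    Returns ``(steady: bool, values: dict)`` where values are window
    averages of populations, death rates and division fractions.
    """
    if window is None:
        window = STEADY_WINDOW_CYCLES * (cycle_time if cycle_time is not None else 1.0)
    t = trace.times
    if t.size < 2:
        return False, {}
    mask = t >= t[-1] - window
    if mask.sum() < 2:
        return False, {}
    vals = {}
    steady = True
    for name in ("P_S", "P_T"):
        x = getattr(trace, name)[mask]
        mean = float(x.mean())
        if mean <= 0:
            steady = False
        else:
            steady = steady and float(x.max() - x.min()) / mean < rel_tol
        vals[name] = mean
    for name in ("r_S", "r_T", "delta1", "delta2", "delta3"):
        x = getattr(trace, name)[mask]
        vals[name] = float(np.nanmean(x)) if np.any(np.isfinite(x)) else math.nan
    return steady, vals


def damage_marginal_at_division(state: PopulationState, grid: Grid):
    """End-of-cycle damage marginal: the last-``p`` slice of S, normalized to integrate to 1.

    Returns ``(marginal, nonempty)``; an empty slice yields the zero
    vector with ``nonempty=False``.
    """
    slice_ = state.S[-1, :]
    total = float(slice_.sum()) * grid.da_S
    if total <= 0:
        return np.zeros_like(slice_), False
    return slice_ / total, True


def simulate(
    params: ModelParams,
    rule: SegregationRule,
    fb: FeedbackConfig,
    grid: Grid,
    init=None,
    t_end: float = 2000.0,
    record_every: float = 0.5,
    dt: Optional[float] = None,
    safety: float = 0.9,
    floor: Optional[float] = None,
    ceiling: Optional[float] = None,
    stop_on_steady: bool = True,
    steady_rel_tol: float = STEADY_REL_TOL,
    steady_window: Optional[float] = None,
    record_marginals: bool = False,
) -> Trace:
    """Time-march the system and record a :class:`Trace`.

    ``init`` may be a :class:`PopulationState`, a dict
    (``{"kind": "default", "total": ...}`` or
    ``{"kind": "delta", "a0": ..., "p0": ..., "total": ...}``), or None
    for the default founding population.  The run stops at ``t_end``, on
    steady-state detection (populations flat within ``steady_rel_tol``
    over ``steady_window``, default 10 cycle times), on extinction
    (``P_S`` below ``floor``, default 1e-3 of the initial population) or
    on blow-up (above ``ceiling``, default 1e6 of it).
    """
    if init is None:
        init = {"kind": "default"}
    if isinstance(init, dict):
        kind = init.get("kind", "default")
        if kind == "default":
            state = default_initial_state(params, grid, total=init.get("total", 1e6))
        elif kind == "delta":
            state = delta_initial_state(
                params,
                grid,
                a0=init.get("a0", 0.0),
                p0=init.get("p0", 0.0),
                total=init.get("total", 1.0),
            )
        else:
            raise ValueError(f"unknown initial-condition kind {kind!r}")
    else:
        state = init

    if dt is None:
        dt = cfl_dt(params, fb, grid, safety=safety)
    P_S0, _ = state.populations(grid)
    if floor is None:
        floor = EXTINCTION_FLOOR_FRAC * P_S0
    if ceiling is None:
        ceiling = BLOWUP_CEILING_FRAC * P_S0
    cycle = params.cycle_time
    if steady_window is None:
        steady_window = STEADY_WINDOW_CYCLES * cycle

    ws = _StepWorkspace(params, rule, fb, grid)
    n_steps = int(math.ceil(t_end / dt))
    rec_stride = max(1, int(round(record_every / dt)))
    check_stride = max(rec_stride, int(round(0.5 * steady_window / dt)))

    rows = {k: [] for k in ("t", "P_S", "P_T", "r_S", "r_T", "d1", "d2", "d3")}
    cum = dict.fromkeys(("births_S", "deaths_S", "mothers", "births_T", "deaths_T", "escape_T"), 0.0)
    marginals = {} if record_marginals else None
    termination = "t_end"
    steady_vals: Optional[dict] = None

    def record(st, diag):
        P_S_now = float(st.S.sum()) * grid.dp_S * grid.da_S
        P_T_now = float(st.T.sum()) * grid.dp_T * grid.da_T
        rows["t"].append(st.t)
        rows["P_S"].append(P_S_now)
        rows["P_T"].append(P_T_now)
        rows["r_S"].append(diag["deaths_S"] / P_S_now if P_S_now > 0 else math.nan)
        rows["r_T"].append(diag["deaths_T"] / P_T_now if P_T_now > 0 else math.nan)
        d1, d2, d3 = diag["delta_realized"]
        rows["d1"].append(d1)
        rows["d2"].append(d2)
        rows["d3"].append(d3)
        return P_S_now

    def build_trace(final_state):
        return Trace(
            times=np.asarray(rows["t"]),
            P_S=np.asarray(rows["P_S"]),
            P_T=np.asarray(rows["P_T"]),
            r_S=np.asarray(rows["r_S"]),
            r_T=np.asarray(rows["r_T"]),
            delta1=np.asarray(rows["d1"]),
            delta2=np.asarray(rows["d2"]),
            delta3=np.asarray(rows["d3"]),
            termination=termination,
            steady=steady_vals,
            final_state=final_state,
            cum_births_S=cum["births_S"],
            cum_deaths_S=cum["deaths_S"],
            cum_mothers=cum["mothers"],
            cum_births_T=cum["births_T"],
            cum_deaths_T=cum["deaths_T"],
            cum_escape_T=cum["escape_T"],
            marginals=marginals,
        )

    for istep in range(n_steps):
        state, diag = step(state, params, rule, fb, grid, dt, workspace=ws)
        if not np.isfinite(diag["P_S"]):
            raise RuntimeError(f"non-finite state at t={state.t}; aborting")
        for key, dkey in (
            ("births_S", "births_S"),
            ("deaths_S", "deaths_S"),
            ("mothers", "mothers"),
            ("births_T", "births_T"),
            ("deaths_T", "deaths_T"),
            ("escape_T", "escape_T"),
        ):
            cum[key] += diag[dkey] * dt
        if istep % rec_stride == 0 or istep == n_steps - 1:
            P_S_now = record(state, diag)
            if marginals is not None:
                m, ok = damage_marginal_at_division(state, grid)
                if ok:
                    marginals[state.t] = m
            if P_S_now < floor:
                termination = "extinct"
                return build_trace(state)
            if P_S_now > ceiling:
                termination = "blowup"
                return build_trace(state)
        if stop_on_steady and istep > 0 and istep % check_stride == 0:
            probe = build_trace(None)
            is_steady, vals = detect_steady_state(
                probe, rel_tol=steady_rel_tol, window=steady_window
            )
            if is_steady and state.t >= 2 * steady_window:
                termination = "steady"
                steady_vals = vals
                return build_trace(state)
    probe = build_trace(None)
    is_steady, vals = detect_steady_state(probe, rel_tol=steady_rel_tol, window=steady_window)
    if is_steady:
        termination = "steady"
        steady_vals = vals
    trace = build_trace(state)
    trace.termination = termination
    trace.steady = steady_vals
    return trace
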