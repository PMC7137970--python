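"""Domain types and pointwise rate/feedback functions.

The model tracks two cell compartments on a (cycle progression ``p``,
damage ``a``) state space: mitotic stem cells that divide when ``p``
reaches ``p_star`` and die when ``a`` reaches ``a_star``, and post-mitotic
terminally differentiated (TD) cells that never divide and die at
``a_c``.  Division produces two stem daughters (probability ``delta1``),
two TD daughters (``delta2``) or one of each (``delta3``), with the
mother's damage split between daughters according to a
:class:`SegregationRule`.

Feedback regulation enters through the quasi-steady state of a secreted
signal, a Hill function of the regulating population, which scales the
cycle-progression speed and the symmetric division fractions.  Three
regimes are supported:

``none``
    constant basal rates (the analytically tractable model);
``td_only``
    long-range inhibition by the TD population only;
``td_stem``
    additional autocrine inhibition by the stem population and
    damage-dependent sigmoid modifiers ``f(a)`` (slows cycling of
    damaged cells) and ``g(a)`` (suppresses self-renewal of damaged
    cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "FEEDBACK_MODES",
    "ModelParams",
    "SegregationRule",
    "FeedbackConfig",
    "hill_signal",
    "sigmoid_f",
    "sigmoid_g",
    "division_fractions",
    "cycle_speed",
]

FEEDBACK_MODES = ("none", "td_only", "td_stem")


class ConfigurationError(ValueError):
    """A parameter combination violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, lethal thresholds and basal division fractions.

    Units: ``p`` is measured in progression units (a full cycle is
    ``p_star``), ``a`` in damage units, speeds in (progression or
    damage)/time.  Defaults are the baseline parameter set used
    throughout: cell cycle threshold 1, lethal thresholds 1, stem cycle
    speed 0.2, stem damage accumulation 0.06, TD speeds 0.02, basal
    division fractions (0.6, 0.3, 0.1).
    """

    p_star: float = 1.0
    a_star: float = 1.0
    a_c: float = 1.0
    v_p: float = 0.2
    v_a: float = 0.06
    u_p: float = 0.02
    u_a: float = 0.02
    delta0: Tuple[float, float, float] = (0.6, 0.3, 0.1)

    def __post_init__(self) -> None:
        for name in ("p_star", "a_star", "a_c", "v_p", "v_a", "u_p", "u_a"):
            _require(getattr(self, name) > 0, f"{name} must be strictly positive")
        d = self.delta0
        _require(len(d) == 3, "delta0 must be a triple")
        _require(all(0.0 <= x <= 1.0 for x in d), "each basal fraction must lie in [0, 1]")
        _require(abs(sum(d) - 1.0) < 1e-12, "basal division fractions must sum to 1")
        object.__setattr__(self, "delta0", tuple(float(x) for x in d))

    @property
    def cycle_time(self) -> float:
        """Duration of one cell cycle at maximal speed, ``p_star / v_p``."""
        return self.p_star / self.v_p

    @property
    def damage_gain_per_cycle(self) -> float:
        """Damage accumulated over one unimpeded cycle, ``v_a * p_star / v_p``."""
        return self.v_a * self.p_star / self.v_p


@dataclass(frozen=True)
class SegregationRule:
    """Damage-partition fractions applied at division.

    ``alpha1``/``alpha2`` split the mother's damage between the two stem
    daughters of a symmetric renewal, ``beta1``/``beta2`` between the two
    TD daughters of a symmetric differentiation, and ``gamma1`` is the
    fraction retained by the stem daughter in an asymmetric division
    (the TD daughter receives ``gamma2``).  Convention: the first
    fraction of each symmetric pair is the smaller one.
    """

    alpha1: float = 0.3
    beta1: float = 0.5
    gamma1: float = 0.1

    def __post_init__(self) -> None:
        _require(0.0 < self.alpha1 <= 0.5, "alpha1 must lie in (0, 0.5] (alpha1 <= alpha2)")
        _require(0.0 < self.beta1 <= 0.5, "beta1 must lie in (0, 0.5] (beta1 <= beta2)")
        _require(0.0 < self.gamma1 < 1.0, "gamma1 must lie in (0, 1)")

    @property
    def alpha2(self) -> float:
        return 1.0 - self.alpha1

    @property
    def beta2(self) -> float:
        return 1.0 - self.beta1

    @property
    def gamma2(self) -> float:
        return 1.0 - self.gamma1

    @property
    def omega1(self) -> float:
        """Smallest stem-side inheritance fraction, min(alpha1, alpha2, gamma1)."""
        return min(self.alpha1, self.alpha2, self.gamma1)

    @property
    def omega2(self) -> float:
        """Largest stem-side inheritance fraction, max(alpha1, alpha2, gamma1)."""
        return max(self.alpha1, self.alpha2, self.gamma1)


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback mode and its Hill/sigmoid constants.

    Regulation constants have units 1/population; Hill exponents are
    dimensionless.  Defaults are the baseline feedback parameter set:
    TD regulation constants of order 1e-8, stem regulation constants of
    order 1e-7, Hill exponents 2, and sigmoids decreasing from ~1.1 to
    0.4 with midpoint 0.75 and stiffness 20.
    """

    mode: str = "none"
    # TD-population regulation (long-range feedback)
    k1T: float = 1e-8
    k2T: float = 0.5e-8
    kvT: float = 0.5e-8
    mT: float = 2.0
    # stem-population regulation (autocrine feedback)
    k1S: float = 1e-7
    k2S: float = 0.25e-7
    kvS: float = 0.5e-7
    mS: float = 2.0
    # sigmoid f(a): damage slows cycle progression
    a1: float = 1.1
    b1: float = -0.7
    k1a: float = 20.0
    a10: float = 0.75
    # sigmoid g(a): damage suppresses self-renewal
    a2: float = 1.1
    b2: float = -0.7
    k2a: float = 20.0
    a20: float = 0.75

    def __post_init__(self) -> None:
        _require(self.mode in FEEDBACK_MODES, f"mode must be one of {FEEDBACK_MODES}")
        for name in ("k1T", "k2T", "kvT", "k1S", "k2S", "kvS"):
            _require(getattr(self, name) >= 0, f"{name} must be non-negative")
        _require(self.mT >= 1 and self.mS >= 1, "Hill exponents must be >= 1")


def hill_signal(P, k: float, m: float):
    """Quasi-steady feedback signal ``1 / (1 + (k P)^m)``.

    This is the equilibrium of a secreted signalling molecule whose
    degradation grows with the population ``P``; it equals 1 in the
    absence of cells and decreases monotonically to 0 as ``P`` grows.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("population must be non-negative")
    if k < 0:
        raise ValueError("regulation constant must be non-negative")
    if m < 1:
        raise ValueError("Hill exponent must be >= 1")
    out = 1.0 / (1.0 + (k * P) ** m)
    return float(out) if out.ndim == 0 else out


def sigmoid_f(a, fb: FeedbackConfig):
    """Damage-dependent cycle-speed modifier ``a1 + b1/(1 + exp(-k1a (a - a10)))``."""
    a = np.asarray(a, dtype=float)
    out = fb.a1 + fb.b1 / (1.0 + np.exp(-fb.k1a * (a - fb.a10)))
    return float(out) if out.ndim == 0 else out


def sigmoid_g(a, fb: FeedbackConfig):
    """Damage-dependent self-renewal modifier ``a2 + b2/(1 + exp(-k2a (a - a20)))``."""
    a = np.asarray(a, dtype=float)
    out = fb.a2 + fb.b2 / (1.0 + np.exp(-fb.k2a * (a - fb.a20)))
    return float(out) if out.ndim == 0 else out


def division_fractions(PT, PS, a, params: ModelParams, fb: FeedbackConfig):
    """Division-type probabilities (delta1, delta2, delta3) of a mother with damage ``a``.

    * ``none``: the basal triple.
    * ``td_only``: ``delta_i = delta_i0 / (1 + (k_iT P_T)^mT)`` for i = 1, 2;
      independent of the stem population and of damage.
    * ``td_stem``: ``delta1 = delta1_0 g(a) / (1 + (k1T P_T)^mS + (k1S P_S)^mS)``
      and ``delta2 = delta2_0 / (1 + (k2T P_T)^mS + (k2S P_S)^mS)``.

    ``delta3`` is always the complement ``1 - delta1 - delta2``.  Returns
    scalars for scalar input, or arrays broadcast against ``a``.
    """
    PT = float(PT)
    PS = float(PS)
    if PT < 0 or PS < 0:
        raise ValueError("populations must be non-negative")
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("damage must be non-negative")
    d10, d20, _ = params.delta0
    if fb.mode == "none":
        d1 = np.broadcast_to(d10, a_arr.shape).astype(float).copy()
        d2 = np.broadcast_to(d20, a_arr.shape).astype(float).copy()
    elif fb.mode == "td_only":
        h1 = 1.0 + (fb.k1T * PT) ** fb.mT
        h2 = 1.0 + (fb.k2T * PT) ** fb.mT
        d1 = np.broadcast_to(d10 / h1, a_arr.shape).astype(float).copy()
        d2 = np.broadcast_to(d20 / h2, a_arr.shape).astype(float).copy()
    elif fb.mode == "td_stem":
        h1 = 1.0 + (fb.k1T * PT) ** fb.mS + (fb.k1S * PS) ** fb.mS
        h2 = 1.0 + (fb.k2T * PT) ** fb.mS + (fb.k2S * PS) ** fb.mS
        d1 = d10 * sigmoid_g(a_arr, fb) / h1
        d1 = np.asarray(d1, dtype=float)
        d2 = np.broadcast_to(d20 / h2, a_arr.shape).astype(float).copy()
    else:  # pragma: no cover - guarded by FeedbackConfig
        raise ConfigurationError(f"unknown feedback mode {fb.mode!r}")
    if np.any(d1 + d2 > 1.0 + 1e-12):
        raise ConfigurationError(
            "delta1 + delta2 exceeds 1; the sigmoid g and basal fractions are "
            "incompatible (complement delta3 would be negative)"
        )
    d3 = 1.0 - d1 - d2
    if a_arr.ndim == 0:
        return float(d1), float(d2), float(d3)
    return d1, d2, d3


def cycle_speed(PT, PS, a, params: ModelParams, fb: FeedbackConfig):
    """Stem cycle-progression speed ``V_p`` under the configured feedback.

    * ``none``: the constant ``v_p``.
    * ``td_only``: ``v_p / (1 + (kvT P_T)^mT)``.
    * ``td_stem``: ``v_p f(a) / (1 + (kvT P_T)^mS + (kvS P_S)^mS)``.
    """
    PT = float(PT)
    PS = float(PS)
    if PT < 0 or PS < 0:
        raise ValueError("populations must be non-negative")
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < 0):
        raise ValueError("damage must be non-negative")
    if fb.mode == "none":
        out = np.broadcast_to(params.v_p, a_arr.shape).astype(float).copy()
    elif fb.mode == "td_only":
        out = np.broadcast_to(
            params.v_p / (1.0 + (fb.kvT * PT) ** fb.mT), a_arr.shape
        ).astype(float).copy()
    elif fb.mode == "td_stem":
        h = 1.0 + (fb.kvT * PT) ** fb.mS + (fb.kvS * PS) ** fb.mS
        out = np.asarray(params.v_p * sigmoid_f(a_arr, fb) / h, dtype=float)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown feedback mode {fb.mode!r}")
    if a_arr.ndim == 0:
        return float(out)
    return out


def max_cycle_speed(params: ModelParams, fb: FeedbackConfig) -> float:
    """Upper bound on ``V_p`` over all populations and damages (for CFL)."""
    if fb.mode == "td_stem":
        # f is monotone; its supremum over a >= 0 is at a = 0 (b1 < 0) or a -> inf
        f_sup = max(sigmoid_f(0.0, fb), fb.a1 + fb.b1, fb.a1)
        return params.v_p * max(f_sup, 1.0)
    return params.v_p
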