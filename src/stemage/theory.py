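"""Closed-form long-term results for the feedback-free model.

With constant speeds and division fractions, the end-of-cycle damage of
every stem lineage is attracted into a *limit damage band* determined by
the segregation rule, and the population grows or shrinks geometrically
at rate set by the *self-renewal fraction* ``f_r = (2 delta1 + delta3)/2``
(expected stem daughters per division, halved).  Three regimes follow:

* extinction when ``f_r < 1/2`` or the whole band is lethal;
* blow-up (``f_r > 1/2``) or conservation (``f_r = 1/2``) when the whole
  band is sub-lethal;
* an intermediate regime when the lethal threshold cuts through the
  band, where a sufficient extinction condition involves the minimal
  number ``n`` of consecutive symmetric renewals that push a lineage
  over the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

from .model_core import ModelParams, SegregationRule

__all__ = [
    "LongTermClass",
    "self_renewal_fraction",
    "limit_damage_band",
    "eq37_n",
    "classify",
]

#: verdicts a classification can return
VERDICTS = (
    "extinct",
    "conserved",
    "blowup_or_survival",
    "extinct_if_condition",
    "undetermined",
)

_M_CAP = 10_000  # scan cap for the intermediate-regime integer n


@dataclass(frozen=True)
class LongTermClass:
    """Outcome of the analytic classification.

    ``verdict`` is one of :data:`VERDICTS`; ``reason`` names the clause
    that fired; ``n`` is the intermediate-regime integer when applicable.
    """

    verdict: str
    reason: str
    n: Optional[int] = None


class RegimeError(ValueError):
    """The intermediate-regime assumptions do not hold."""


def self_renewal_fraction(delta1: float, delta2: float, delta3: float) -> float:
    """Expected stem daughters per division over 2: ``(2 delta1 + delta3) / 2``."""
    if not (min(delta1, delta2, delta3) >= 0 and abs(delta1 + delta2 + delta3 - 1.0) < 1e-9):
        raise ValueError("division fractions must be a probability triple summing to 1")
    return (2.0 * delta1 + delta3) / 2.0


def limit_damage_band(params: ModelParams, rule: SegregationRule) -> Tuple[float, float]:
    """End-of-cycle limit damage band ``[Delta/(1-omega1), Delta/(1-omega2)]``.

    ``Delta = v_a p_star / v_p`` is the damage gained over one cycle and
    ``omega1 <= omega2`` are the extreme stem-side inheritance fractions.
    Every surviving lineage's end-of-cycle damage is eventually trapped
    in this interval (in damage units; divide by ``v_a`` for the
    time-unit form compared against ``a_star / v_a``).
    """
    w1, w2 = rule.omega1, rule.omega2
    if w2 >= 1.0:
        raise ValueError("degenerate retention: max inheritance fraction must be < 1")
    delta = params.damage_gain_per_cycle
    return (delta / (1.0 - w1), delta / (1.0 - w2))


def eq37_n(params: ModelParams, rule: SegregationRule, m_cap: int = _M_CAP) -> Optional[int]:
    """Minimal ``m >= 1`` with ``a*/v_a < p*/(v_p (1-alpha2)) - (p*/v_p)(1/(1-alpha2) - 1/(1-gamma1)) alpha2^m``.

    This is the smallest number of consecutive symmetric renewals (along
    the heavier daughter) after which a lineage entering from the
    asymmetric-retention fixed point exceeds the lethal threshold.
    Returns ``None`` when no finite ``m`` works, which is definitive
    because the right-hand side increases to ``p*/(v_p (1-alpha2))``.

    Raises :class:`RegimeError` unless the intermediate-regime
    assumptions hold: ``gamma1 <= alpha1 < alpha2`` and
    ``p*/(v_p (1-alpha1)) < a*/v_a < p*/(v_p (1-alpha2))``.
    """
    a1, a2, g1 = rule.alpha1, rule.alpha2, rule.gamma1
    if not g1 <= a1:
        raise RegimeError("requires gamma1 <= alpha1 (asymmetric retention below symmetric split)")
    if not a1 < a2:
        raise RegimeError("requires alpha1 < alpha2 (strictly asymmetric renewal split)")
    tau = params.p_star / params.v_p
    thresh = params.a_star / params.v_a
    if not tau / (1.0 - a1) < thresh:
        raise RegimeError("requires p*/(v_p (1-alpha1)) < a*/v_a (lighter-daughter lineage survives)")
    limit = tau / (1.0 - a2)
    if thresh > limit * (1.0 + 1e-12):
        raise RegimeError("requires a*/v_a < p*/(v_p (1-alpha2)) (heavier-daughter limit is lethal)")
    coef = tau * (1.0 / (1.0 - a2) - 1.0 / (1.0 - g1))
    if thresh >= limit:  # RHS never exceeds its limit: no finite m works, definitively
        return None
    for m in range(1, m_cap + 1):
        if thresh < limit - coef * a2**m:
            return m
    return None


def classify(
    params: ModelParams,
    rule: SegregationRule,
    deltas: Sequence[float],
    initial_mass_in_surviving_region: bool = True,
) -> LongTermClass:
    """Apply the long-term propositions in order and report the first that fires.

    ``initial_mass_in_surviving_region`` asserts the hypothesis that the
    initial density puts positive mass on trajectories that reach
    division before dying; the blow-up/conservation clauses require it.
    """
    d1, d2, d3 = (float(x) for x in deltas)
    fr = self_renewal_fraction(d1, d2, d3)
    lo, hi = limit_damage_band(params, rule)
    a_star = params.a_star

    if fr < 0.5 - 1e-12:
        return LongTermClass("extinct", "subcritical renewal: f_r < 1/2")
    if lo > a_star:
        return LongTermClass("extinct", "limit damage band entirely above the lethal threshold")

    if hi < a_star:
        if not initial_mass_in_surviving_region:
            return LongTermClass(
                "undetermined", "sub-lethal band but no initial mass in the surviving region"
            )
        if fr > 0.5 + 1e-12:
            return LongTermClass(
                "blowup_or_survival", "sub-lethal band with supercritical renewal f_r > 1/2"
            )
        return LongTermClass("conserved", "sub-lethal band with critical renewal f_r = 1/2")

    # lethal threshold inside the band: intermediate regime
    try:
        n = eq37_n(params, rule)
    except RegimeError as exc:
        return LongTermClass("undetermined", f"intermediate regime assumptions fail: {exc}")
    if fr <= 0.5 + 1e-12:
        # f_r = 1/2 inside the band is not covered by any clause
        return LongTermClass("undetermined", "critical renewal inside the band")
    if n is not None and (2.0 * fr) ** n - d1**n < 1.0:
        return LongTermClass(
            "extinct_if_condition", "intermediate regime with (2 f_r)^n - delta1^n < 1", n=n
        )
    return LongTermClass("undetermined", "intermediate regime, sufficient condition not met", n=n)
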