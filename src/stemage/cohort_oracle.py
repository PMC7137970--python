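"""Exact generation-by-generation branching map for the feedback-free model.

With constant speeds a synchronized founding cohort (all cells at
``p = 0``) stays synchronized forever: every surviving cell divides at
multiples of the cycle time ``p_star / v_p``, gaining exactly
``Delta = v_a p_star / v_p`` damage per cycle.  The stem population is
then fully described by a finite set of damage atoms with weights, and
one generation is an exact affine branching map on those atoms:

* an atom at birth damage ``a0`` reaches ``a1 = a0 + Delta`` at division;
* if ``a1 >= a_star`` the lineage dies before dividing;
* otherwise it spawns stem atoms at ``alpha1 a1``, ``alpha2 a1`` (weight
  ``delta1 w`` each) and ``gamma1 a1`` (weight ``delta3 w``), and produces
  ``(2 delta2 + delta3) w`` TD cells.

This map is used as an independent oracle for the transport solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import ModelParams, SegregationRule

__all__ = ["CohortEnsemble", "advance_generation", "oracle_population_curve"]

MERGE_TOL = 1e-12  # absolute tolerance for merging equal damage atoms
ATOM_CAP = 1_000_000


@dataclass
class CohortEnsemble:
    """Damage atoms (birth damage, weight) of the current stem generation."""

    damages: np.ndarray
    weights: np.ndarray
    generation: int = 0
    td_produced: List[float] = field(default_factory=list)
    deaths: List[float] = field(default_factory=list)

    @classmethod
    def from_atoms(cls, atoms: Sequence[Tuple[float, float]]) -> "CohortEnsemble":
        d = np.array([a for a, _ in atoms], dtype=float)
        w = np.array([w for _, w in atoms], dtype=float)
        if np.any(w < 0) or np.any(d < 0):
            raise ValueError("atom damages and weights must be non-negative")
        return cls(damages=d, weights=w)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def _merge(damages: np.ndarray, weights: np.ndarray, tol: float = MERGE_TOL):
    """Merge atoms whose damage values agree within ``tol`` (sorted grouping)."""
    if damages.size == 0:
        return damages, weights
    order = np.argsort(damages)
    d, w = damages[order], weights[order]
    new_group = np.empty(d.size, dtype=bool)
    new_group[0] = True
    np.greater(np.diff(d), tol, out=new_group[1:])
    gid = np.cumsum(new_group) - 1
    n = gid[-1] + 1
    dm = np.zeros(n)
    wm = np.zeros(n)
    np.add.at(wm, gid, w)
    # representative damage: first member of each group (all within tol)
    dm[gid[new_group]] = d[new_group]
    return dm, wm


def advance_generation(
    ens: CohortEnsemble,
    params: ModelParams,
    rule: SegregationRule,
    deltas: Sequence[float],
) -> CohortEnsemble:
    """One cycle of the branching map: age, kill, divide, merge."""
    d1, d2, d3 = (float(x) for x in deltas)
    delta = params.damage_gain_per_cycle
    a_end = ens.damages + delta
    dead = a_end >= params.a_star
    died = float(ens.weights[dead].sum())
    a_live = a_end[~dead]
    w_live = ens.weights[~dead]

    child_d = np.concatenate([rule.alpha1 * a_live, rule.alpha2 * a_live, rule.gamma1 * a_live])
    child_w = np.concatenate([d1 * w_live, d1 * w_live, d3 * w_live])
    keep = child_w > 0.0
    child_d, child_w = _merge(child_d[keep], child_w[keep])
    if child_d.size > ATOM_CAP:
        raise RuntimeError(
            f"atom count {child_d.size} exceeds cap {ATOM_CAP}; coarsen the merge tolerance"
        )
    td = (2.0 * d2 + d3) * float(w_live.sum())
    return CohortEnsemble(
        damages=child_d,
        weights=child_w,
        generation=ens.generation + 1,
        td_produced=ens.td_produced + [td],
        deaths=ens.deaths + [died],
    )


def oracle_population_curve(
    init_atoms: Sequence[Tuple[float, float]],
    params: ModelParams,
    rule: SegregationRule,
    deltas: Sequence[float],
    n_gen: int,
) -> pd.DataFrame:
    """Iterate the branching map; return per-generation stem weight and TD production.

    The returned frame has one row per generation ``0..n_gen`` with
    columns ``generation``, ``stem_weight`` (stem cohort weight at the
    start of the generation), ``td_produced`` and ``deaths`` (events
    during the preceding cycle; zero for generation 0).
    """
    ens = CohortEnsemble.from_atoms(init_atoms)
    stem = [ens.total_weight]
    for _ in range(n_gen):
        ens = advance_generation(ens, params, rule, deltas)
        stem.append(ens.total_weight)
    return pd.DataFrame(
        {
            "generation": np.arange(n_gen + 1),
            "stem_weight": stem,
            "td_produced": [0.0] + ens.td_produced,
            "deaths": [0.0] + ens.deaths,
        }
    )
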