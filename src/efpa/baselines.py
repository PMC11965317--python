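"""Comparison methods: reaction expression, resistance scoring (Compass-),
and the original power-decay flux potential analysis.

All three scores are oriented so that higher means more predicted flux
capacity and normalized against the same hypothetical super condition used
by the enhanced method, so they are directly comparable:

* ``reaction_expression_score`` — the ROI's own relative expression; no
  network integration at all.
* ``compass_minus`` — whole-network resistance: first find the unweighted
  flux optimum v* of the ROI, then minimize the penalty-weighted total flux
  needed to sustain a fraction f of v*.  The score is the super-condition
  resistance divided by the condition's resistance (low expression anywhere
  on the required routes raises resistance and lowers the score).  No
  distance decay, no cell pooling.
* ``compass_with_decay`` — same two-stage LP but with the stage-2 weights
  scaled by the original power decay over naive distances.
* ``original_fpa`` — the flux-potential LP with power decay over naive
  distances (shared code path with the enhanced method).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    DecaySpec,
    EfpaConfig,
    _LpProblem,
    decay,
    run_efpa,
    weights,
)
from .distance import build_reaction_graph, compute_distance_map
from .expression import ReactionExpression, penalties as make_penalties
from .model_io import MetabolicNetwork, directed_id, split_reversible

__all__ = [
    "CompassConfig",
    "reaction_expression_score",
    "compass_minus",
    "compass_with_decay",
    "original_fpa",
    "run_compass",
]

DEFAULT_OPTIMUM_FRACTION = 0.95  # Compass's published default


class CompassConfig:
    def __init__(
        self,
        optimum_fraction: float = DEFAULT_OPTIMUM_FRACTION,
        decay_order: float = 0.0,
        eps: float = 1e-3,
        upper_bound_default: float = 1000.0,
        tolerance: float = 1e-9,
    ):
        if not 0 < optimum_fraction <= 1:
            raise ValueError("optimum fraction must lie in (0, 1]")
        self.optimum_fraction = optimum_fraction
        self.decay_order = decay_order
        self.eps = eps
        self.upper_bound_default = upper_bound_default
        self.tolerance = tolerance


def reaction_expression_score(rel: ReactionExpression, roi: str) -> pd.Series:
    """The ROI's own relative expression per condition; NaN when missing."""
    if roi not in rel.values.index:
        raise KeyError(f"unknown reaction {roi!r}")
    row = rel.values.loc[roi]
    if rel.status[roi] == "missing":
        return pd.Series(np.nan, index=row.index)
    return row.copy()


def _resistance(
    problem: _LpProblem,
    did: str,
    stage2_weights: np.ndarray,
    cfg: CompassConfig,
) -> tuple[float, str]:
    """Two-stage LP: max v_roi, then min weighted total flux at >= f * v*."""
    res1 = problem.maximize(did, None, 0.0)
    if res1.status != 0:
        return math.nan, "stage1_failed"
    v_star = -res1.fun
    if v_star <= cfg.tolerance:
        return math.nan, "blocked"
    res2 = problem.minimize(
        stage2_weights, (did, cfg.optimum_fraction * v_star)
    )
    if res2.status != 0:
        return math.nan, "stage2_failed"
    return res2.fun, "optimal"


def compass_minus(
    net: MetabolicNetwork,
    rel: ReactionExpression,
    roi: str,
    direction: str = "fwd",
    cfg: CompassConfig | None = None,
) -> pd.DataFrame:
    """Per-condition resistance-based score in [0, 1] for one ROI direction.

    score = resistance(super condition) / resistance(condition), clipped to
    [0, 1]; a blocked ROI (v* ~ 0) scores 0 with a flag.
    """
    cfg = cfg or CompassConfig()
    return _compass(net, rel, roi, direction, cfg)


def compass_with_decay(
    net: MetabolicNetwork,
    rel: ReactionExpression,
    roi: str,
    direction: str = "fwd",
    order: float = 2.5,
    cfg: CompassConfig | None = None,
) -> pd.DataFrame:
    """Resistance scoring with the original power decay (default order 2.5)
    applied over naive distances in the stage-2 objective.  Order 0 reduces
    to ``compass_minus``."""
    cfg = cfg or CompassConfig()
    cfg.decay_order = order
    return _compass(net, rel, roi, direction, cfg)


def _compass(net, rel, roi, direction, cfg: CompassConfig) -> pd.DataFrame:
    dnet = split_reversible(net)
    problem = _LpProblem(dnet, cfg.upper_bound_default)
    did = directed_id(roi, direction)
    if did not in problem.index:
        raise KeyError(f"no directed reaction {did!r}")
    pen = make_penalties(rel, cfg.eps)
    super_pen = pd.Series(
        np.where(rel.status != "missing", 1.0, 0.0), index=rel.values.index
    )

    if cfg.decay_order > 0:
        graph = build_reaction_graph(dnet)
        dm = compute_distance_map(graph, did)
        spec = DecaySpec(family="power", n=cfg.decay_order)
        decay_vec = pd.Series(
            {d: decay(dist, spec) for d, dist in dm.naive.items()}
        )
    else:
        decay_vec = pd.Series(1.0, index=problem.ids)

    def stage2_vector(col: pd.Series) -> np.ndarray:
        w = []
        for d in problem.ids:
            base = d.rsplit("[", 1)[0]
            w.append(decay_vec.get(d, 0.0) * float(col.get(base, 0.0)))
        return np.asarray(w)

    r_super, st_super = _resistance(problem, did, stage2_vector(super_pen), cfg)
    records = []
    for cond in rel.conditions:
        r_cond, st = _resistance(problem, did, stage2_vector(pen[cond]), cfg)
        if st == "blocked" or st_super == "blocked":
            score, status = 0.0, "blocked"
        elif not (math.isfinite(r_cond) and math.isfinite(r_super)):
            score, status = math.nan, "failed"
        elif r_cond <= cfg.tolerance:
            # no resistance anywhere (all weights 0): parity with super
            score, status = 1.0, "zero_resistance"
        else:
            score = min(max(r_super / r_cond, 0.0), 1.0)
            status = "optimal"
        records.append(
            {"roi": roi, "direction": direction, "condition": cond,
             "score": score, "resistance": r_cond,
             "resistance_super": r_super, "status": status}
        )
    return pd.DataFrame.from_records(records)


def run_compass(
    net: MetabolicNetwork,
    rel: ReactionExpression,
    rois: list[str],
    direction: str = "fwd",
    cfg: CompassConfig | None = None,
) -> pd.DataFrame:
    frames = [
        _compass(net, rel, roi, direction, cfg or CompassConfig())
        for roi in rois
    ]
    return pd.concat(frames, ignore_index=True)


def original_fpa(
    net: MetabolicNetwork,
    rel: ReactionExpression,
    rois: list[str] | None = None,
    order: float = 1.5,
    metric: str = "naive",
    **kwargs,
) -> pd.DataFrame:
    """Power-decay flux potential over naive distances (order 0 integrates
    the whole network).  ``metric='weighted'`` gives the hybrid that keeps
    the power decay but measures distance with metabolite-degree weights."""
    cfg = EfpaConfig(
        decay=DecaySpec(family="power", n=order), metric=metric, **kwargs
    )
    return run_efpa(net, rel, rois=rois, cfg=cfg)
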