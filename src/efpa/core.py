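"""The flux-potential LP and its distance-decayed, expression-weighted form.

For a reaction of interest (ROI) and one condition, the flux potential FP is
the optimum of

    max  v_roi
    s.t. S v = 0                  (steady state, split non-negative fluxes)
         0 <= v <= ub
         sum_j w_j v_j <= A       (flux allowance)

where w_j = decay(d_j) * penalty_j couples each reaction's expression
penalty (reciprocal relative expression) to its network distance d_j from
the ROI.  Poorly expressed reactions near the ROI eat into the allowance A
and depress FP; distant reactions are discounted by the decay and can carry
flux freely.  FP is normalized by the FP of a hypothetical super condition
in which every measured reaction sits at its observed expression maximum
(all penalties 1), giving the dimensionless relative flux potential
rFP in [0, 1].  rFP is invariant to the value of A.

Decay families:

    power(n):          (1 + d) ** -n            (the original formulation)
    hard_boundary(b):  1 if d <= b else 0
    exponential(b):    1 if d <= b else 2 ** -(d - b)

The standard configuration is exponential decay with boundary b = 6 over
the metabolite-degree-weighted distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .distance import DistanceMap, build_reaction_graph, compute_distance_map
from .expression import ReactionExpression, penalties as make_penalties, DEFAULT_EPS
from .model_io import (
    DirectedNetwork,
    MetabolicNetwork,
    directed_id,
    split_reversible,
)

__all__ = [
    "DecaySpec",
    "EfpaConfig",
    "decay",
    "weights",
    "flux_potential",
    "relative_fp",
    "run_efpa",
    "STANDARD_DECAY",
]

STATUS_OK = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_CLAMPED = "clamped"
STATUS_FAILED = "failed"


@dataclass(frozen=True)
class DecaySpec:
    """Distance-decay family and parameters.

    ``family`` is ``power`` (order ``n``), ``hard_boundary`` or
    ``exponential`` (boundary ``b``).
    """

    family: str = "exponential"
    n: float = 0.0
    b: float = 6.0

    def __post_init__(self):
        if self.family not in ("power", "hard_boundary", "exponential"):
            raise ValueError(f"unknown decay family {self.family!r}")
        if self.n < 0 or self.b < 0:
            raise ValueError("decay parameters must be non-negative")


STANDARD_DECAY = DecaySpec(family="exponential", b=6.0)


@dataclass(frozen=True)
class EfpaConfig:
    """Solver-facing knobs.  rFP is invariant to ``allowance``; the default
    upper bound of 1000 flux a.u. is deliberately slack."""

    allowance: float = 1.0
    decay: DecaySpec = field(default_factory=lambda: STANDARD_DECAY)
    metric: str = "weighted"  # naive | weighted
    eps: float = DEFAULT_EPS
    upper_bound_default: float = 1000.0
    tolerance: float = 1e-9

    def __post_init__(self):
        if self.allowance <= 0:
            raise ValueError("flux allowance must be positive")
        if self.metric not in ("naive", "weighted"):
            raise ValueError(f"unknown distance metric {self.metric!r}")


def decay(d: float, spec: DecaySpec) -> float:
    """Decay factor in [0, 1] for a reaction at distance ``d`` from the ROI."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    if math.isinf(d):
        return 0.0
    if spec.family == "power":
        return (1.0 + d) ** (-spec.n)
    if spec.family == "hard_boundary":
        return 1.0 if d <= spec.b else 0.0
    # exponential beyond the boundary
    return 1.0 if d <= spec.b else 2.0 ** (-(d - spec.b))


def weights(
    penalty_col: pd.Series,
    distmap: DistanceMap,
    spec: DecaySpec,
    metric: str = "weighted",
) -> pd.Series:
    """Per-directed-reaction LP weights: decay(d_j) * penalty of the base.

    ``penalty_col`` is indexed by base reaction id (both directions of a
    base share its penalty); the result is indexed by directed ids present
    in the distance map.  The ROI itself sits at d = 0 and keeps its full
    penalty.
    """
    dists = distmap.weighted if metric == "weighted" else distmap.naive
    out = {}
    for did, d in dists.items():
        base = did.rsplit("[", 1)[0]
        pen = float(penalty_col.get(base, 0.0))
        out[did] = decay(d, spec) * pen
    return pd.Series(out)


class _LpProblem:
    """Cached sparse steady-state system for one directed network."""

    def __init__(self, dnet: DirectedNetwork, ub_default: float = 1000.0):
        self.dnet = dnet
        self.ids = dnet.ids
        self.index = {rid: j for j, rid in enumerate(self.ids)}
        met_index = {m.id: i for i, m in enumerate(dnet.metabolites)}
        rows, cols, vals = [], [], []
        for j, r in enumerate(dnet.reactions):
            for m, c in r.stoichiometry.items():
                rows.append(met_index[m])
                cols.append(j)
                vals.append(c)
        self.S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_index), len(self.ids))
        )
        self.ub = np.array(
            [min(r.upper_bound, ub_default) if r.upper_bound > 0 else 0.0
             for r in dnet.reactions]
        )

    def maximize(self, objective_id: str, w: np.ndarray | None, allowance: float):
        j = self.index[objective_id]
        c = np.zeros(len(self.ids))
        c[j] = -1.0
        A_ub = b_ub = None
        if w is not None:
            A_ub = sparse.csr_matrix(w.reshape(1, -1))
            b_ub = np.array([allowance])
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(np.zeros(len(self.ids)), self.ub)),
            method="highs",
        )
        return res

    def minimize(self, objective: np.ndarray, extra_lb: tuple[str, float] | None):
        """min objective . v subject to S v = 0, bounds, and optionally
        v_k >= value for one reaction (used by the resistance baselines)."""
        A_ub = b_ub = None
        if extra_lb is not None:
            rid, val = extra_lb
            row = np.zeros(len(self.ids))
            row[self.index[rid]] = -1.0
            A_ub = sparse.csr_matrix(row.reshape(1, -1))
            b_ub = np.array([-val])
        res = linprog(
            objective, A_ub=A_ub, b_ub=b_ub, A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(np.zeros(len(self.ids)), self.ub)),
            method="highs",
        )
        return res


def flux_potential(
    problem: _LpProblem,
    roi: str,
    w: pd.Series,
    cfg: EfpaConfig,
) -> tuple[float, str]:
    """Solve one flux-potential LP; returns (FP, status).

    Infeasibility reports FP = 0.  An objective at its (slack) variable
    bound — possible when every weight along an unbounded route is 0 — is
    flagged as clamped rather than treated as a finite optimum.
    """
    wv = w.reindex(problem.ids).fillna(0.0).to_numpy()
    if (wv < 0).any():
        raise ValueError("weights must be non-negative")
    res = problem.maximize(roi, wv, cfg.allowance)
    if res.status == 2:
        return 0.0, STATUS_INFEASIBLE
    if res.status != 0:
        return 0.0, STATUS_FAILED
    fp = -res.fun
    jub = problem.ub[problem.index[roi]]
    status = STATUS_CLAMPED if fp >= jub - 1e-6 else STATUS_OK
    return fp, status


def relative_fp(fp: float, fp_super: float, tolerance: float = 1e-9) -> float:
    """rFP = FP / FP_super; NaN (undefined) when the super condition itself
    carries no flux."""
    if fp < 0 or fp_super < 0:
        raise ValueError("flux potentials must be non-negative")
    if fp_super <= tolerance:
        return float("nan")
    return fp / fp_super


def run_efpa(
    net: MetabolicNetwork,
    rel: ReactionExpression,
    rois: list[str] | None = None,
    cfg: EfpaConfig | None = None,
    penalty_override: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Batch eFPA: one LP per ROI direction per condition plus one
    super-condition LP (all measured penalties 1).

    ``rois`` are base reaction ids; a reversible ROI yields a result for
    each direction, reported separately.  Returns a tidy frame with columns
    roi, direction, condition, FP, FP_super, rFP, status.  Per-ROI failures
    are recorded in ``status`` and the batch continues.
    """
    cfg = cfg or EfpaConfig()
    dnet = split_reversible(net)
    graph = build_reaction_graph(dnet)
    problem = _LpProblem(dnet, cfg.upper_bound_default)
    pen = (
        penalty_override
        if penalty_override is not None
        else make_penalties(rel, cfg.eps)
    )
    super_pen = pd.Series(
        np.where(rel.status != "missing", 1.0, 0.0), index=rel.values.index
    )
    if rois is None:
        rois = [r.id for r in net.reactions if not r.is_boundary]

    records = []
    for base in rois:
        r = net.reaction(base)
        directions = []
        if max(r.upper_bound, 0) > 0 or r.lower_bound >= 0:
            directions.append("fwd")
        if r.lower_bound < 0:
            directions.append("rev")
        for direction in directions:
            did = directed_id(base, direction)
            if did not in problem.index:
                continue
            try:
                dm = compute_distance_map(graph, did)
                w_super = weights(super_pen, dm, cfg.decay, cfg.metric)
                fp_super, st_super = flux_potential(problem, did, w_super, cfg)
                for cond in rel.conditions:
                    w_c = weights(pen[cond], dm, cfg.decay, cfg.metric)
                    fp, st = flux_potential(problem, did, w_c, cfg)
                    records.append(
                        {
                            "roi": base,
                            "direction": direction,
                            "condition": cond,
                            "FP": fp,
                            "FP_super": fp_super,
                            "rFP": relative_fp(fp, fp_super, cfg.tolerance),
                            "status": st if st_super == STATUS_OK else st_super,
                        }
                    )
            except Exception as exc:  # keep the batch alive
                records.append(
                    {
                        "roi": base, "direction": direction, "condition": None,
                        "FP": np.nan, "FP_super": np.nan, "rFP": np.nan,
                        "status": f"{STATUS_FAILED}: {exc}",
                    }
                )
    return pd.DataFrame.from_records(records)


def rfp_matrix(result: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy run_efpa result to (roi, direction) x condition rFP."""
    return result.pivot_table(
        index=["roi", "direction"], columns="condition", values="rFP",
        dropna=False,
    )
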