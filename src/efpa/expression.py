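"""Mapping gene expression to reaction-level relative expression and penalties.

Gene levels (unscaled, non-negative) are collapsed to one value per reaction
via its GPR rule: isozymes (OR) add, complex subunits (AND) take the minimum.
Each reaction row is then rescaled by its own across-condition maximum to a
relative expression in [0, 1], whose reciprocal gives the flux penalty used
by the LP-based integration.

A measured/unmeasured distinction is carried end-to-end: a zero is data, an
absent measurement is not.  Reactions whose GPR genes are entirely unmeasured
(or that have no GPR) are *missing* and receive penalty 0, i.e. their flux is
unconstrained by expression — this is what permits gap-filling predictions
for reactions without expression data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import GprTree, MetabolicNetwork

__all__ = [
    "ReactionExpression",
    "growth_adjust_flux",
    "unscale_log2",
    "reaction_raw_expression",
    "map_to_reactions",
    "normalize_relative",
    "penalties",
    "DEFAULT_EPS",
]

DEFAULT_EPS = 1e-3  # caps penalties at 1000; keeps dropout zeros finite

COMPLETE = "complete"
PARTIAL = "partial"
MISSING = "missing"


@dataclass
class ReactionExpression:
    """Reaction-by-condition relative expression in [0, 1].

    ``values`` rows for reactions with status ``missing`` are all-NaN.
    ``status`` maps each reaction to complete/partial/missing measurement.
    """

    values: pd.DataFrame
    status: pd.Series

    def __post_init__(self) -> None:
        self.status = self.status.reindex(self.values.index)

    @property
    def conditions(self) -> pd.Index:
        return self.values.columns

    def measured_ids(self) -> list[str]:
        return list(self.values.index[self.status != MISSING])


def growth_adjust_flux(
    raw_flux: pd.DataFrame, growth_rate: pd.Series
) -> pd.DataFrame:
    """Divide each condition's fluxes by that condition's growth rate.

    Removes the common growth-rate scaling of flux so that residual
    variation across conditions is comparable with relative expression.
    """
    growth_rate = growth_rate.reindex(raw_flux.columns)
    bad = growth_rate.index[~(growth_rate > 0)]
    if len(bad):
        raise ValueError(
            f"non-positive growth rate for condition(s): {list(bad)}"
        )
    return raw_flux.div(growth_rate, axis=1)


def unscale_log2(log2_values):
    """Invert a log2 transform: out = 2**in."""
    arr = np.asarray(log2_values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("log2 values must be finite")
    out = np.exp2(arr)
    if isinstance(log2_values, (pd.DataFrame, pd.Series)):
        return type(log2_values)(
            out, index=log2_values.index,
            **({"columns": log2_values.columns}
               if isinstance(log2_values, pd.DataFrame) else {}),
        )
    return out


def reaction_raw_expression(
    gpr: GprTree | None,
    levels: dict[str, float],
    measured: dict[str, bool] | None = None,
) -> tuple[float, str]:
    """Collapse gene levels to one reaction-level value with min/sum semantics.

    AND -> min of children (a complex is limited by its scarcest subunit);
    OR -> sum of children (isozymes add capacity).  Unmeasured genes are
    excluded from OR sums; an AND over a mix of measured and unmeasured
    children uses the measured minimum but the result is flagged *partial*.
    A node with all children unmeasured — or an empty GPR — is *missing*.

    Returns ``(value, status)`` with value NaN when status is ``missing``.
    """
    if measured is None:
        measured = {}

    def is_measured(g: str) -> bool:
        return measured.get(g, g in levels)

    def ev(node: GprTree) -> tuple[float | None, bool]:
        # -> (value or None when unmeasured, any_unmeasured_below)
        if node.op == "gene":
            if not is_measured(node.gene):
                return None, True
            v = float(levels.get(node.gene, 0.0))
            if v < 0:
                raise ValueError(f"negative level for gene {node.gene}")
            return v, False
        vals, partial = [], False
        for c in node.children:
            v, p = ev(c)
            partial = partial or p
            if v is not None:
                vals.append(v)
        if not vals:
            return None, True
        return (min(vals) if node.op == "and" else sum(vals)), partial

    if gpr is None:
        return float("nan"), MISSING
    value, partial = ev(gpr)
    if value is None:
        return float("nan"), MISSING
    return value, (PARTIAL if partial else COMPLETE)


def map_to_reactions(
    net: MetabolicNetwork,
    gene_levels: pd.DataFrame,
    measured: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-condition GPR collapse for every reaction of a network.

    ``gene_levels`` is genes x conditions (unscaled, non-negative);
    ``measured`` an optional boolean mask of the same shape (default: a gene
    is measured iff present in ``gene_levels``).  Returns the raw
    reaction-by-condition matrix and the per-reaction status series.
    """
    if (np.asarray(gene_levels, dtype=float) < 0).any():
        raise ValueError("gene levels must be non-negative")
    conds = gene_levels.columns
    raw = pd.DataFrame(np.nan, index=net.reaction_ids, columns=conds)
    status = pd.Series(MISSING, index=net.reaction_ids, dtype=object)
    for r in net.reactions:
        if r.gpr is None:
            continue
        worst = COMPLETE
        for c in conds:
            levels = gene_levels[c].to_dict()
            meas = None
            if measured is not None:
                meas = measured[c].to_dict()
            else:
                meas = {g: g in gene_levels.index for g in r.gpr.genes()}
            v, st = reaction_raw_expression(r.gpr, levels, meas)
            raw.loc[r.id, c] = v
            if st == MISSING:
                worst = MISSING
            elif st == PARTIAL and worst == COMPLETE:
                worst = PARTIAL
        status[r.id] = worst
    return raw, status


def normalize_relative(
    raw: pd.DataFrame, status: pd.Series | None = None
) -> ReactionExpression:
    """Rescale each measured reaction row by its own across-condition max.

    Rows whose raw values are all zero (fully dropped-out reactions) keep
    relative expression 0 everywhere; their status stays as given — zeros
    are data, not absence.
    """
    if status is None:
        status = pd.Series(
            np.where(raw.notna().all(axis=1), COMPLETE, MISSING),
            index=raw.index, dtype=object,
        )
    values = raw.copy().astype(float)
    row_max = values.max(axis=1)
    scalable = (row_max > 0) & (status != MISSING)
    values.loc[scalable] = values.loc[scalable].div(row_max[scalable], axis=0)
    values.loc[status == MISSING] = np.nan
    # all-zero measured rows stay at 0
    return ReactionExpression(values=values, status=status)


def penalties(
    rel: ReactionExpression, eps: float = DEFAULT_EPS
) -> pd.DataFrame:
    """Reciprocal penalties: 1 where a reaction is at its observed maximum,
    up to 1/eps where expression is zero; 0 (no penalty) where no expression
    data exists at all.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    vals = rel.values.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < -1e-12 or np.nanmax(vals, initial=1.0) > 1 + 1e-9:
        raise ValueError("relative expression must lie in [0, 1]")
    pen = 1.0 / np.maximum(vals, eps)
    out = pd.DataFrame(pen, index=rel.values.index, columns=rel.values.columns)
    out.loc[rel.status == MISSING] = 0.0
    return out


def reaction_expression_from_genes(
    net: MetabolicNetwork,
    gene_levels: pd.DataFrame,
    measured: pd.DataFrame | None = None,
) -> ReactionExpression:
    """Full gene-to-reaction pipeline: GPR collapse then row-max scaling."""
    raw, status = map_to_reactions(net, gene_levels, measured)
    return normalize_relative(raw, status)


def read_expression_tsv(path, measured_path=None):
    """Expression TSV: first column gene id, remaining columns conditions."""
    levels = pd.read_csv(path, sep="\t", index_col=0)
    measured = None
    if measured_path is not None:
        measured = pd.read_csv(measured_path, sep="\t", index_col=0).astype(bool)
    return levels, measured
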