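"""Statistical layer: flux-expression correlation with BH-FDR, pathway
coexpression, cross-informing rate, label-permutation testing, and the
tissue / cell-type enrichment scores used to read out flux predictions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "pearson_fdr",
    "pathway_coexpression",
    "cross_informing_rate",
    "permute_labels",
    "permutation_pvalue",
    "delta_rfp",
    "celltype_enrichment",
]

FDR_ALPHA = 0.05


def pearson_fdr(
    x_table: pd.DataFrame,
    y_table: pd.DataFrame,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Row-wise Pearson correlation between two aligned tables with BH-FDR.

    Rows (reactions) present in both tables are paired over shared columns
    (conditions); each row needs >= 3 paired finite observations.  The BH
    family is exactly the set of testable rows: constant or too-short rows
    are excluded and flagged, not silently given q = 1.  A row is
    significant when q <= alpha and PCC > 0.
    """
    shared_rows = x_table.index.intersection(y_table.index)
    shared_cols = x_table.columns.intersection(y_table.columns)
    records = []
    for rid in shared_rows:
        x = x_table.loc[rid, shared_cols].astype(float)
        y = y_table.loc[rid, shared_cols].astype(float)
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < 3 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            records.append(
                {"reaction": rid, "pcc": np.nan, "p": np.nan, "n": n,
                 "tested": False}
            )
            continue
        r, p = sps.pearsonr(x[ok], y[ok])
        records.append(
            {"reaction": rid, "pcc": r, "p": p, "n": n, "tested": True}
        )
    out = pd.DataFrame.from_records(records).set_index("reaction")
    out["q"] = np.nan
    tested = out.index[out["tested"]]
    if len(tested):
        out.loc[tested, "q"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    out["significant"] = (out["q"] <= alpha) & (out["pcc"] > 0)
    return out


def pathway_coexpression(
    rel_values: pd.DataFrame, pathway: list[str]
) -> tuple[float, pd.Series]:
    """Coexpression strength of a pathway and its expression profile.

    strength = median of all pairwise Pearson correlations among member
    rows with data; profile = per-condition median of member relative
    expressions.  Requires at least two members with data.
    """
    members = [r for r in pathway if r in rel_values.index]
    sub = rel_values.loc[members].dropna(how="all")
    if len(sub) < 2:
        return float("nan"), pd.Series(np.nan, index=rel_values.columns)
    pccs = []
    for a, b in itertools.combinations(sub.index, 2):
        x, y = sub.loc[a], sub.loc[b]
        ok = x.notna() & y.notna()
        if ok.sum() >= 3 and x[ok].nunique() > 1 and y[ok].nunique() > 1:
            pccs.append(sps.pearsonr(x[ok], y[ok])[0])
    strength = float(np.median(pccs)) if pccs else float("nan")
    return strength, sub.median(axis=0)


def cross_informing_rate(
    pairs: pd.DataFrame,
    n_bins: int = 8,
    alpha: float = FDR_ALPHA,
) -> pd.DataFrame:
    """Fraction of significantly correlated reaction pairs per bridging-
    metabolite-degree bin.

    ``pairs`` needs columns ``degree``, ``pcc``, ``q``.  Pairs are grouped
    into equal-count degree bins; each non-empty bin reports its mean
    degree (x) and the proportion of pairs with q <= alpha and PCC > 0 (y).
    """
    required = {"degree", "pcc", "q"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    df = pairs.dropna(subset=["degree", "q"]).copy()
    df["informed"] = (df["q"] <= alpha) & (df["pcc"] > 0)
    n_bins = min(n_bins, max(df["degree"].nunique(), 1))
    df["bin"] = pd.qcut(df["degree"].rank(method="first"), n_bins, labels=False)
    rows = []
    for b, grp in df.groupby("bin"):
        rows.append(
            {"bin": int(b), "mean_degree": grp["degree"].mean(),
             "rate": grp["informed"].mean(), "n_pairs": len(grp)}
        )
    return pd.DataFrame(rows)


def permute_labels(
    rel_values: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """One row-label shuffle of a reaction-by-condition matrix: the value
    rows stay intact, the reaction labels are reassigned."""
    perm = rng.permutation(len(rel_values))
    return pd.DataFrame(
        rel_values.to_numpy(),
        index=rel_values.index[perm],
        columns=rel_values.columns,
    )


def permutation_pvalue(
    statistic,
    rel_values: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Empirical p for an observed statistic under reaction-label shuffles.

    ``statistic`` maps a reaction-by-condition matrix to a scalar (e.g. the
    number of reactions predicted).  The pseudo-count form
    p = (1 + #{perm >= observed}) / (1 + n_perm) is used, so p is never 0.
    Returns (p, observed, null_distribution).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = float(statistic(rel_values))
    null = np.array(
        [float(statistic(permute_labels(rel_values, rng)))
         for _ in range(n_perm)]
    )
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return p, observed, null


def delta_rfp(
    rfp: pd.DataFrame, threshold: float = 0.2
) -> pd.DataFrame:
    """Group-enrichment scores for a reaction-by-group rFP table.

    Each value is centered by its row median (undefined rFPs excluded from
    the median); a group is enriched at delta >= +threshold and depleted at
    <= -threshold.  Returned frame has the same shape with the deltas.
    """
    med = rfp.median(axis=1, skipna=True)
    return rfp.sub(med, axis=0)


def enrichment_flags(delta: pd.DataFrame, threshold: float = 0.2) -> pd.DataFrame:
    flags = pd.DataFrame("", index=delta.index, columns=delta.columns)
    flags[delta >= threshold] = "enriched"
    flags[delta <= -threshold] = "depleted"
    return flags


@dataclass
class CellTypeEnrichment:
    table: pd.DataFrame  # per cell type: median, rank, fc, p, enriched


def celltype_enrichment(
    scores: pd.Series,
    labels: pd.Series,
    fc_threshold: float = 1.2,
    p_threshold: float = 1e-10,
) -> pd.DataFrame:
    """Cell-type enrichment of one reaction's per-cell scores.

    For each cell type: FC = median(type) / median(others) and a two-sided
    Wilcoxon rank-sum p versus the others, where "others" always excludes
    the top-ranked cell type by median (or the second-ranked when the
    tested type is itself on top) so that one dominant, highly metabolic
    type cannot mask enrichment elsewhere.  Ties from single-cell zeros are
    handled with the tie-corrected normal approximation.  Enriched when
    FC > fc_threshold and p < p_threshold.
    """
    labels = labels.reindex(scores.index)
    types = labels.dropna().unique().tolist()
    if len(types) < 2:
        raise ValueError("need at least two cell types")
    medians = scores.groupby(labels).median().sort_values(ascending=False)
    ranks = pd.Series(
        np.arange(1, len(medians) + 1), index=medians.index
    )
    records = []
    for t in types:
        excluded = medians.index[0] if t != medians.index[0] else medians.index[1]
        own = scores[labels == t]
        others = scores[(labels != t) & (labels != excluded) & labels.notna()]
        if len(own) < 2 or len(others) < 2:
            raise ValueError(f"cell type {t!r} needs >= 2 cells and others")
        med_others = others.median()
        fc = own.median() / med_others if med_others > 0 else np.nan
        p = sps.mannwhitneyu(
            own, others, alternative="two-sided", method="asymptotic"
        ).pvalue
        records.append(
            {"cell_type": t, "median": own.median(), "rank": int(ranks[t]),
             "excluded": excluded, "fc": fc, "p": p,
             "enriched": bool(fc > fc_threshold and p < p_threshold)
             if np.isfinite(fc) else False}
        )
    return pd.DataFrame.from_records(records).set_index("cell_type")
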