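"""Background-corrected gene-set enrichment and temporal profiling.

Over-representation is a one-sided Fisher exact test (equivalently the
hypergeometric upper tail) against a user-supplied background universe —
in the motivating study all protein-coding genes detected in the tissue —
with Benjamini-Hochberg correction across sets. Temporal profiles express,
per gene set, the number of DEGs significant at each timepoint as a
percentage of the set's collapsed 24-h DEG membership.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("methyltide")


def fisher_enrichment(
    query: list[str] | set,
    collection: dict[str, list[str]],
    universe: list[str] | set,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher enrichment per gene set.

    Query genes outside the universe are dropped with a warning; set
    members outside the universe are trimmed before testing (background
    correction). p equals the hypergeometric survival P(X >= overlap).
    BH-adjusted across the collection.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("%d query gene(s) outside the universe dropped", len(outside))
        query &= universe
    n_u, n_q = len(universe), len(query)
    rows = []
    for name, genes in collection.items():
        genes_in = set(genes) & universe
        k = len(genes_in & query)
        n_set = len(genes_in)
        # hypergeometric upper tail == one-sided Fisher on the 2x2 table
        p = float(stats.hypergeom.sf(k - 1, n_u, n_set, n_q))
        a, b = k, n_set - k
        c, d = n_q - k, n_u - n_set - (n_q - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((name, k, n_set, n_q, odds, p,
                     ",".join(sorted(genes_in & query))))
    res = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "query_size",
                       "odds_ratio", "pvalue", "genes"],
    )
    if len(res):
        res["padj"] = multipletests(res["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        res["padj"] = pd.Series(dtype=float)
    return res.sort_values("pvalue", kind="mergesort").reset_index(drop=True)


def temporal_profile(
    membership: pd.DataFrame,
    gene_set: list[str],
    collapsed: set,
    timepoints: list[str],
    direction: str | None = None,
) -> pd.DataFrame | None:
    """Per-timepoint DEG proportion of a gene set's collapsed response.

    proportion(t) = 100 * |set ∩ DEGs(t)| / |set ∩ collapsed|. The peak
    timepoint is the argmax (earliest on ties). Returns None (with a
    warning) when the set has no collapsed DEGs.

    ``membership`` is the collapsed-DEG membership table (gene, timepoint,
    direction); ``direction`` optionally restricts to up or down calls.
    """
    mem = membership if direction is None else membership[membership["direction"] == direction]
    set_genes = set(gene_set)
    denom_genes = set_genes & set(collapsed)
    if not denom_genes:
        logger.warning("gene set has no collapsed DEGs; profile undefined, skipped")
        return None
    denom = len(denom_genes)
    rows = []
    for tp in timepoints:
        tp_genes = set(mem.loc[mem["timepoint"] == tp, "gene"])
        n = len(denom_genes & tp_genes)
        rows.append((tp, n, denom, 100.0 * n / denom))
    prof = pd.DataFrame(rows, columns=["timepoint", "n_deg", "set_collapsed_n", "proportion"])
    peak_i = int(prof["proportion"].to_numpy().argmax())  # argmax -> earliest on ties
    prof.attrs["peak_timepoint"] = prof.loc[peak_i, "timepoint"]
    return prof


def format_proportion(p: float, style: str = "summary") -> str:
    """Render a temporal proportion: one decimal in tables, nearest
    integer percent in summaries."""
    if style == "table":
        return f"{p:.1f}"
    return f"{p:.0f}%"


def trajectory_summary(
    de_tables: dict[str, pd.DataFrame], gene_set: list[str],
) -> tuple[pd.Series, pd.DataFrame]:
    """Mean log2FC per timepoint over set members, plus per-gene curves.

    Returns ``(mean_curve, per_gene)`` where per_gene is genes x timepoints.
    """
    tps = list(de_tables)
    curves = {}
    for tp in tps:
        t = de_tables[tp].set_index("gene")["log2FC"]
        curves[tp] = t.reindex([g for g in gene_set if g in t.index])
    per_gene = pd.DataFrame(curves)
    mean_curve = per_gene.mean(axis=0)
    mean_curve.name = "mean_log2FC"
    return mean_curve, per_gene


def overlap_sets(list_a: list[str], list_b: list[str]) -> dict[str, list[str]]:
    """Exact partition of two deduplicated gene lists (Venn-style).

    Returns intersection, a_only, b_only (sorted) with |a| = |a∩b| + |a-only|.
    """
    a, b = set(list_a), set(list_b)
    return {
        "intersection": sorted(a & b),
        "a_only": sorted(a - b),
        "b_only": sorted(b - a),
    }
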