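"""RRBS differential methylation: pooling, Fisher testing, peak export.

Samples are pooled into their groups to maximize coverage, sites are kept
only when every group reaches a minimum pooled read depth (default 10 reads
per base, covered in at least one sample per group), and regions (promoters
or CpG islands) are tested with a two-sided Fisher exact test on pooled
counts. Significant regions become "methylation peaks" — intervals treated
like transcription-factor binding peaks by the integration stage.

Multiple testing uses Benjamini–Hochberg by default; the correction is a
configurable hook (``fdr_method``) accepting any statsmodels method name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import write_bed

logger = logging.getLogger("methyltide")


def pool_and_filter(
    tables: dict[str, pd.DataFrame],
    groups: pd.DataFrame,
    min_reads: int = 10,
    min_samples_per_group: int = 1,
) -> dict[str, pd.DataFrame]:
    """Pool per-sample CpG counts into groups and apply coverage filters.

    A site survives only if, in EVERY group, its pooled coverage is at
    least ``min_reads`` and it is covered (>0 reads) in at least
    ``min_samples_per_group`` samples. Sites absent from any group are
    dropped. Pooled counts are exact sums over samples.

    Parameters
    ----------
    tables : mapping of sample_id -> site table (chrom, pos, count_M, count_U)
    groups : DataFrame with sample_id, group columns; every sample in
        exactly one group.

    Returns
    -------
    dict of group -> pooled site table (chrom, pos, count_M, count_U, percent)
    restricted to the common surviving sites, identically ordered.
    """
    assign = groups.set_index("sample_id")["group"]
    if assign.index.duplicated().any():
        raise ValueError("a sample is assigned to more than one group")
    group_names = list(dict.fromkeys(assign))
    for g in group_names:
        if (assign == g).sum() == 0:
            raise ValueError(f"group {g!r} has zero samples")

    pooled: dict[str, pd.DataFrame] = {}
    covered_ok: dict[str, pd.Index] = {}
    for g in group_names:
        samples = assign.index[assign == g]
        frames = []
        for s in samples:
            if s not in tables:
                raise ValueError(f"sample {s!r} has no table")
            t = tables[s]
            frames.append(t[["chrom", "pos", "count_M", "count_U"]])
        cat = pd.concat(frames, keys=range(len(frames)))
        agg = cat.groupby(["chrom", "pos"], sort=True).agg(
            count_M=("count_M", "sum"),
            count_U=("count_U", "sum"),
        )
        ncov = (
            cat.assign(covered=(cat["count_M"] + cat["count_U"] > 0).astype(int))
            .groupby(["chrom", "pos"], sort=True)["covered"]
            .sum()
        )
        keep = (agg["count_M"] + agg["count_U"] >= min_reads) & (
            ncov >= min_samples_per_group
        )
        pooled[g] = agg
        covered_ok[g] = agg.index[keep]

    common = covered_ok[group_names[0]]
    for g in group_names[1:]:
        common = common.intersection(covered_ok[g])
    out = {}
    for g in group_names:
        t = pooled[g].loc[common].reset_index()
        cov = t["count_M"] + t["count_U"]
        t["percent"] = np.where(cov > 0, 100.0 * t["count_M"] / cov.replace(0, 1), np.nan)
        out[g] = t
    return out


def test_site(pooled_a: tuple[int, int], pooled_b: tuple[int, int]) -> tuple[float, float]:
    """Two-sided Fisher exact test on one CpG site (or pooled region).

    Parameters are (methylated, unmethylated) pooled counts per group.
    Returns ``(p_value, meth_diff)`` where meth_diff is the percentage-point
    difference group B − group A. Symmetric under group swap up to the sign
    of meth_diff.
    """
    ma, ua = pooled_a
    mb, ub = pooled_b
    if ma + ua == 0 or mb + ub == 0:
        raise ValueError("zero total coverage in a group; filter before testing")
    _, p = stats.fisher_exact([[ma, ua], [mb, ub]], alternative="two-sided")
    diff = 100.0 * (mb / (mb + ub) - ma / (ma + ua))
    return float(p), float(diff)


def _fisher_two_sided_vec(ma, ua, mb, ub):
    """Vectorized two-sided Fisher exact p-values for many 2x2 tables.

    Uses the standard "probability at most that of the observed table"
    definition via the hypergeometric pmf, identical to
    scipy.stats.fisher_exact(two-sided) up to floating tolerance.
    """
    ma = np.asarray(ma, dtype=np.int64)
    ua = np.asarray(ua, dtype=np.int64)
    mb = np.asarray(mb, dtype=np.int64)
    ub = np.asarray(ub, dtype=np.int64)
    from scipy.special import gammaln

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.ones(len(ma))
    for i in range(len(ma)):
        n_tot = ma[i] + ua[i] + mb[i] + ub[i]
        k_m = ma[i] + mb[i]  # methylated margin
        n_a = ma[i] + ua[i]  # group A margin
        lo = max(0, k_m - (n_tot - n_a))
        hi = min(k_m, n_a)
        support = np.arange(lo, hi + 1)
        logpmf = logC(n_a, support) + logC(n_tot - n_a, k_m - support) - logC(n_tot, k_m)
        pmf = np.exp(logpmf)
        p_obs = pmf[ma[i] - lo]
        out[i] = min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    return out


def aggregate_regions(
    pooled: dict[str, pd.DataFrame], regions: pd.DataFrame
) -> pd.DataFrame:
    """Sum surviving CpGs inside each region per group and test once per region.

    ``regions`` is a BED-style frame (chrom, start, end 0-based half-open,
    and a name column used as region_id; optional gene column is carried
    through). Regions with zero surviving CpGs are omitted. Each CpG is
    counted in every region containing it; adjacent non-overlapping
    regions therefore partition sites exactly.
    """
    if len(pooled) != 2:
        raise ValueError("region testing is defined for exactly two groups")
    if "name" not in regions.columns:
        regions = regions.copy()
        regions["name"] = [f"region_{i}" for i in range(len(regions))]
    if regions["name"].duplicated().any():
        dup = regions.loc[regions["name"].duplicated(), "name"].tolist()[:5]
        raise ValueError(f"duplicated region ids: {dup}")
    if (regions["end"] <= regions["start"]).any():
        raise ValueError("degenerate region (end <= start)")

    (ga, ta), (gb, tb) = pooled.items()
    sites = ta[["chrom", "pos"]].copy()
    sites["ma"] = ta["count_M"].to_numpy()
    sites["ua"] = ta["count_U"].to_numpy()
    sites["mb"] = tb["count_M"].to_numpy()
    sites["ub"] = tb["count_U"].to_numpy()

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in regions.groupby("chrom"):
        tree = IntervalTree()
        for i, r in sub.iterrows():
            tree.addi(int(r["start"]), int(r["end"]), i)
        trees[chrom] = tree

    acc: dict[int, list[int]] = {}
    for chrom, sub in sites.groupby("chrom"):
        tree = trees.get(chrom)
        if tree is None:
            continue
        pos0 = sub["pos"].to_numpy() - 1  # 1-based position -> 0-based coordinate
        for row_i, p0 in zip(sub.index, pos0):
            for iv in tree.at(p0):
                acc.setdefault(iv.data, []).append(row_i)

    rows = []
    for reg_i, site_rows in sorted(acc.items()):
        block = sites.loc[site_rows]
        ma, ua = int(block["ma"].sum()), int(block["ua"].sum())
        mb, ub = int(block["mb"].sum()), int(block["ub"].sum())
        if ma + ua == 0 or mb + ub == 0:
            continue
        r = regions.loc[reg_i]
        rows.append(
            (r["chrom"], int(r["start"]), int(r["end"]), r["name"],
             r.get("gene_id", ""), ma, ua, mb, ub, len(site_rows))
        )
    res = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "region_id", "gene_id",
                 "m_a", "u_a", "m_b", "u_b", "n_cpg"],
    )
    if len(res):
        res["p_value"] = _fisher_two_sided_vec(res["m_a"], res["u_a"], res["m_b"], res["u_b"])
        pa = res["m_a"] / (res["m_a"] + res["u_a"])
        pb = res["m_b"] / (res["m_b"] + res["u_b"])
        res["meth_diff"] = 100.0 * (pb - pa)
    else:
        res["p_value"] = pd.Series(dtype=float)
        res["meth_diff"] = pd.Series(dtype=float)
    return res


def call_dmrs_to_peaks(
    region_results: pd.DataFrame,
    q_thresh: float = 0.05,
    diff_thresh: float = 25.0,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """FDR-correct region tests and export significant DMRs as peaks.

    Peaks are regions with q < ``q_thresh`` and |meth_diff| >=
    ``diff_thresh`` percentage points, tagged hypo (negative diff, group B
    lower) or hyper.
    """
    if region_results.empty:
        raise ValueError("no region results to call peaks from")
    res = region_results.copy()
    res["q_value"] = multipletests(res["p_value"].to_numpy(), method=fdr_method)[1]
    sig = (res["q_value"] < q_thresh) & (res["meth_diff"].abs() >= diff_thresh)
    peaks = res.loc[sig].copy()
    peaks["direction"] = np.where(peaks["meth_diff"] < 0, "hypo", "hyper")
    return peaks.reset_index(drop=True)


def peaks_to_bed(peaks: pd.DataFrame, path: str | Path, direction: str | None = None) -> None:
    """Write peaks as BED6 (name=region_id, score=|meth_diff|, strand='.')."""
    sel = peaks if direction is None else peaks[peaks["direction"] == direction]
    bed = pd.DataFrame(
        {
            "chrom": sel["chrom"],
            "start": sel["start"],
            "end": sel["end"],
            "name": sel["region_id"],
            "score": sel["meth_diff"].abs().round(3),
            "strand": ".",
        }
    )
    write_bed(bed, path)


def promoters_from_tss(
    tss: pd.DataFrame, upstream: int = 1000, downstream: int = 1000
) -> pd.DataFrame:
    """Strand-aware promoter windows (BED half-open) around TSSs.

    ``tss`` needs chrom, tss (0-based coordinate), strand, gene_id. For a
    plus-strand gene the window is [tss-upstream, tss+downstream); minus
    strand is mirrored.
    """
    plus = tss["strand"] != "-"
    start = np.where(plus, tss["tss"] - upstream, tss["tss"] - downstream)
    end = np.where(plus, tss["tss"] + downstream, tss["tss"] + upstream)
    return pd.DataFrame(
        {
            "chrom": tss["chrom"],
            "start": np.maximum(start, 0).astype(int),
            "end": end.astype(int),
            "name": tss["gene_id"],
            "gene_id": tss["gene_id"],
        }
    )


@dataclass
class PeakSet:
    """Called methylation peaks plus the full region-level test table."""

    peaks: pd.DataFrame
    regions: pd.DataFrame

    def by_direction(self, direction: str) -> pd.DataFrame:
        return self.peaks[self.peaks["direction"] == direction]


class DifferentialMethylation(BaseEstimator):
    """Pooled-Fisher DMR caller, sklearn-style.

    Parameters
    ----------
    min_reads : minimum pooled coverage per group per site (default 10).
    min_samples_per_group : minimum samples covering a site per group.
    q_thresh, diff_thresh : peak-calling thresholds (BH q and percentage
        points of methylation difference).
    fdr_method : statsmodels multiple-testing method name.

    Attributes (after ``fit``)
    --------------------------
    pooled_ : dict of group -> filtered pooled site table
    regions_ : per-region Fisher results
    peaks_ : significant peaks with direction
    """

    def __init__(self, min_reads: int = 10, min_samples_per_group: int = 1,
                 q_thresh: float = 0.05, diff_thresh: float = 25.0,
                 fdr_method: str = "fdr_bh"):
        self.min_reads = min_reads
        self.min_samples_per_group = min_samples_per_group
        self.q_thresh = q_thresh
        self.diff_thresh = diff_thresh
        self.fdr_method = fdr_method

    def fit(self, tables: dict[str, pd.DataFrame], groups: pd.DataFrame,
            regions: pd.DataFrame):
        self.pooled_ = pool_and_filter(
            tables, groups, self.min_reads, self.min_samples_per_group
        )
        self.regions_ = aggregate_regions(self.pooled_, regions)
        if self.regions_.empty:
            logger.warning("no region survived coverage filtering; empty peak set")
            self.peaks_ = self.regions_.assign(q_value=[], direction=[])
        else:
            self.peaks_ = call_dmrs_to_peaks(
                self.regions_, self.q_thresh, self.diff_thresh, self.fdr_method
            )
        self.peak_set_ = PeakSet(peaks=self.peaks_, regions=self.regions_)
        return self
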