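"""Time-course transcriptome analytics.

Normalization is DESeq2-style median-of-ratios. Differential expression is
a deliberately simple negative-binomial Wald test with method-of-moments
dispersion — a documented stand-in, not a DESeq2 clone (no shrinkage, no
outlier refitting); externally produced DE tables can be ingested from TSV
instead via :func:`read_de_table`. Downstream: per-timepoint DEG tables are
collapsed into 24-h up/down lists, trajectories are z-scored and
hierarchically clustered, and fiber-type composition is interpolated from
the MYH7/(MYH1+MYH2) transcript ratio against a histology reference curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("methyltide")


# -- normalization ------------------------------------------------------------

def normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors.

    Reference genes are those with nonzero counts in every sample; the
    size factor of a sample is the median over reference genes of
    count / geometric mean across samples. Rescaling one sample's library
    by c rescales the size factors so that only relative expression is
    preserved (the geometric-mean reference itself moves by c^(1/n));
    normalized matrices are therefore equal up to one global constant.

    Returns ``(size_factors, normalized)``.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    mat = counts.to_numpy(dtype=float)
    ref = (mat > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no gene expressed in all samples; cannot normalize")
    log_geo = np.log(mat[ref]).mean(axis=1)
    ratios = np.log(mat[ref]) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    size_factors = pd.Series(sf, index=counts.columns, name="size_factor")
    normalized = counts / sf
    return size_factors, normalized


# -- differential expression --------------------------------------------------

DE_COLUMNS = ["gene", "timepoint", "baseMean", "log2FC", "se", "stat", "pvalue", "padj"]


def _moment_dispersion(norm_a: np.ndarray, norm_b: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion by pooled method of moments, floored at 1e-8.

    For each group, alpha_hat = (s^2 - m) / m^2 on normalized counts; the
    two estimates are combined weighted by degrees of freedom.
    """
    out = np.zeros(norm_a.shape[0])
    w = 0.0
    for mat in (norm_a, norm_b):
        m = mat.mean(axis=1)
        s2 = mat.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - m) / np.where(m > 0, m, 1.0) ** 2
        a = np.where(np.isfinite(a), a, 0.0)
        dof = mat.shape[1] - 1
        out = out + dof * a
        w += dof
    return np.maximum(out / w, 1e-8)


def differential_expression(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    timepoint: str,
    reference: str = "Pre",
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    paired: bool = False,
) -> pd.DataFrame:
    """NB Wald differential expression of one timepoint versus the reference.

    Normalized group means give log2FC (with pseudocount); the Wald
    statistic divides log2FC by a delta-method standard error from the NB
    variance mu + alpha*mu^2 with per-gene moment dispersion. BH adjusts
    p-values across genes within the contrast. Genes with zero counts
    everywhere are removed first.

    ``paired=True`` subtracts each subject's mean log-normalized value
    before computing group means (subject mean-centering), a simple
    surrogate for a paired design.
    """
    samples_a = metadata.loc[metadata["timepoint"] == reference, "sample"].tolist()
    samples_b = metadata.loc[metadata["timepoint"] == timepoint, "sample"].tolist()
    if len(samples_a) < 3 or len(samples_b) < 3:
        raise ValueError("each group needs >= 3 samples")
    sub = counts[samples_a + samples_b]
    keep = sub.sum(axis=1) > 0
    sub = sub.loc[keep]
    sf, norm = normalize(sub)
    na, nb = norm[samples_a].to_numpy(), norm[samples_b].to_numpy()

    if paired:
        meta = metadata.set_index("sample")
        subj_a = meta.loc[samples_a, "subject"].to_numpy()
        subj_b = meta.loc[samples_b, "subject"].to_numpy()
        both = np.intersect1d(subj_a, subj_b)
        la = np.log2(na + pseudocount)
        lb = np.log2(nb + pseudocount)
        for s in both:
            ma = la[:, subj_a == s].mean(axis=1)
            mb = lb[:, subj_b == s].mean(axis=1)
            off = (ma + mb) / 2
            la[:, subj_a == s] -= off[:, None]
            lb[:, subj_b == s] -= off[:, None]
        # recenter back onto the count scale for moment estimation
        na = np.exp2(la + np.log2(na + pseudocount).mean()) - pseudocount
        nb = np.exp2(lb + np.log2(nb + pseudocount).mean()) - pseudocount
        na = np.maximum(na, 0.0)
        nb = np.maximum(nb, 0.0)

    ma, mb = na.mean(axis=1), nb.mean(axis=1)
    log2fc = np.log2(mb + pseudocount) - np.log2(ma + pseudocount)
    disp = _moment_dispersion(na, nb)
    var_a = ma + disp * ma**2
    var_b = mb + disp * mb**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(
            var_a / (len(samples_a) * (ma + pseudocount) ** 2)
            + var_b / (len(samples_b) * (mb + pseudocount) ** 2)
        ) / np.log(2)
    se = np.where(se > 0, se, np.inf)
    z = log2fc / se
    df = len(samples_a) + len(samples_b) - 2
    pvalue = 2.0 * stats.t.sf(np.abs(z), df=df)
    padj = multipletests(pvalue, method="fdr_bh")[1]
    res = pd.DataFrame(
        {
            "gene": sub.index,
            "timepoint": timepoint,
            "baseMean": (ma + mb) / 2,
            "log2FC": log2fc,
            "se": se,
            "stat": z,
            "pvalue": pvalue,
            "padj": padj,
        }
    ).reset_index(drop=True)
    res["direction"] = np.where(res["log2FC"] > 0, "up", "down")
    return res


def read_de_table(path, timepoint: str | None = None) -> pd.DataFrame:
    """Ingest an externally produced DE table (gene, log2FC, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2FC", "pvalue", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    if timepoint is not None and "timepoint" not in df.columns:
        df["timepoint"] = timepoint
    df["direction"] = np.where(df["log2FC"] > 0, "up", "down")
    return df


class NBWaldDE(BaseEstimator):
    """Per-timepoint NB Wald differential expression, sklearn-style.

    ``fit(counts, metadata)`` runs every post-reference timepoint contrast
    and stores ``results_`` (dict timepoint -> DE table).
    """

    def __init__(self, reference: str = "Pre", alpha: float = 0.05,
                 pseudocount: float = 0.5, paired: bool = False):
        self.reference = reference
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.paired = paired

    def fit(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        tps = [t for t in metadata["timepoint"].unique() if t != self.reference]
        self.results_ = {
            tp: differential_expression(
                counts, metadata, tp, self.reference, self.alpha,
                self.pseudocount, self.paired,
            )
            for tp in tps
        }
        return self


# -- collapsing ---------------------------------------------------------------

@dataclass
class CollapsedDEGLists:
    """Union of per-timepoint DEG calls across the recovery period."""

    up: set
    down: set
    membership: pd.DataFrame  # gene, timepoint, direction for each significant call

    @property
    def multi_timepoint(self) -> set:
        n = self.membership.groupby("gene")["timepoint"].nunique()
        return set(n[n >= 2].index)

    @property
    def biphasic(self) -> set:
        return self.up & self.down


def collapse_degs(de_tables: dict[str, pd.DataFrame], alpha: float = 0.05) -> CollapsedDEGLists:
    """Collapse per-timepoint DEG calls into 24-h up/down lists.

    A gene enters the up list if significantly upregulated (padj < alpha,
    log2FC > 0) at >= 1 timepoint; down analogous. A gene significant in
    opposite directions at different timepoints appears in both lists
    (biphasic). Idempotent and order-independent in its inputs.
    """
    rows = []
    for tp in sorted(de_tables):
        t = de_tables[tp]
        sig = t[(t["padj"] < alpha) & (t["log2FC"] != 0)]
        for _, r in sig.iterrows():
            rows.append((r["gene"], tp, "up" if r["log2FC"] > 0 else "down"))
    membership = pd.DataFrame(rows, columns=["gene", "timepoint", "direction"])
    up = set(membership.loc[membership["direction"] == "up", "gene"])
    down = set(membership.loc[membership["direction"] == "down", "gene"])
    return CollapsedDEGLists(up=up, down=down, membership=membership)


# -- trajectory clustering ----------------------------------------------------

def zscore_trajectories(
    normalized: pd.DataFrame, metadata: pd.DataFrame, genes: list[str],
    timepoints: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene z-scores over timepoint means. Zero-variance genes are
    excluded with a warning."""
    if timepoints is None:
        timepoints = list(dict.fromkeys(metadata["timepoint"]))
    means = pd.DataFrame(index=normalized.index)
    for tp in timepoints:
        cols = metadata.loc[metadata["timepoint"] == tp, "sample"]
        means[tp] = normalized[cols].mean(axis=1)
    sel = means.loc[[g for g in genes if g in means.index]]
    sd = sel.std(axis=1, ddof=0)
    const = sd == 0
    if const.any():
        logger.warning("excluding %d constant-expression gene(s) from clustering",
                       int(const.sum()))
        sel = sel.loc[~const]
        sd = sd[~const]
    return sel.sub(sel.mean(axis=1), axis=0).div(sd, axis=0)


class TrajectoryClusterer(BaseEstimator):
    """Euclidean agglomerative clustering of z-scored expression trajectories."""

    def __init__(self, n_clusters: int = 4, linkage: str = "average"):
        self.n_clusters = n_clusters
        self.linkage = linkage

    def fit(self, normalized: pd.DataFrame, metadata: pd.DataFrame,
            genes: list[str], timepoints: list[str] | None = None):
        z = zscore_trajectories(normalized, metadata, genes, timepoints)
        if self.n_clusters > len(z):
            raise ValueError(
                f"n_clusters={self.n_clusters} > {len(z)} usable genes"
            )
        model = AgglomerativeClustering(
            n_clusters=self.n_clusters, linkage=self.linkage, metric="euclidean"
        )
        labels = model.fit_predict(z.to_numpy())
        self.zscores_ = z
        self.labels_ = pd.Series(labels, index=z.index, name="cluster")
        return self


def cluster_trajectories(
    normalized: pd.DataFrame, metadata: pd.DataFrame, genes: list[str],
    n_clusters: int, linkage: str = "average",
) -> pd.Series:
    return TrajectoryClusterer(n_clusters, linkage).fit(
        normalized, metadata, genes
    ).labels_


# -- fiber type ---------------------------------------------------------------

def myh_ratio(counts: pd.Series | pd.DataFrame) -> float | pd.Series:
    """MYH7 / (MYH1 + MYH2) from normalized counts (rows = genes)."""
    for g in ("MYH7", "MYH1", "MYH2"):
        if g not in counts.index:
            raise ValueError(f"missing MYH gene in counts: {g}")
    denom = counts.loc["MYH1"] + counts.loc["MYH2"]
    if np.any(np.asarray(denom) <= 0):
        raise ValueError("MYH1 + MYH2 must be > 0 to form the ratio")
    return counts.loc["MYH7"] / denom


class FiberTypeCurve(BaseEstimator, RegressorMixin):
    """Standard curve interpolating % Type-I fiber area from the MYH ratio.

    ``fit`` takes a reference table with columns type1_pct, MYH7, MYH1,
    MYH2 (one row per reference individual with histology), performs an
    OLS fit of %Type-I area on MYH7/(MYH1+MYH2), and stores slope_,
    intercept_, pearson_r_, n_. ``predict`` interpolates new samples along
    the fitted line, clamped to [0, 100]%.
    """

    def fit(self, reference: pd.DataFrame, y=None):
        required = {"type1_pct", "MYH7", "MYH1", "MYH2"}
        missing = required - set(reference.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if len(reference) < 3:
            raise ValueError("need >= 3 reference individuals")
        denom = reference["MYH1"] + reference["MYH2"]
        bad = reference.index[denom <= 0].tolist()
        if bad:
            raise ValueError(f"MYH1 + MYH2 <= 0 for reference rows: {bad}")
        ratio = (reference["MYH7"] / denom).to_numpy(dtype=float)
        pct = reference["type1_pct"].to_numpy(dtype=float)
        if np.ptp(ratio) == 0:
            raise ValueError("MYH ratio has zero variance in the reference")
        fitres = stats.linregress(ratio, pct)
        self.slope_ = float(fitres.slope)
        self.intercept_ = float(fitres.intercept)
        self.pearson_r_ = float(fitres.rvalue)
        self.p_value_ = float(fitres.pvalue)
        self.n_ = len(reference)
        return self

    def predict(self, ratio) -> np.ndarray:
        if not hasattr(self, "slope_"):
            raise ValueError("curve is not fitted")
        ratio = np.asarray(ratio, dtype=float)
        raw = self.intercept_ + self.slope_ * ratio
        clipped = (raw < 0) | (raw > 100)
        if np.any(clipped):
            logger.warning("%d fiber-type estimate(s) clamped to [0, 100]%%",
                           int(np.sum(clipped)))
        return np.clip(raw, 0.0, 100.0)

    def predict_from_counts(self, counts: pd.DataFrame) -> pd.Series:
        """Estimate %Type-I for each sample column of a normalized count table."""
        r = myh_ratio(counts)
        vals = self.predict(np.atleast_1d(np.asarray(r, dtype=float)))
        if np.isscalar(r) or getattr(r, "ndim", 0) == 0:
            return pd.Series(vals, index=["sample"], name="type1_pct")
        return pd.Series(vals, index=r.index, name="type1_pct")


def fit_fiber_curve(reference: pd.DataFrame) -> FiberTypeCurve:
    return FiberTypeCurve().fit(reference)


def estimate_fiber_type(curve: FiberTypeCurve, counts: pd.DataFrame) -> pd.Series:
    return curve.predict_from_counts(counts)
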