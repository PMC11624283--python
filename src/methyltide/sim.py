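"""Synthetic study generator with planted ground truth.

Emulates a paired multi-timepoint resistance-exercise transcriptome study
(Pre plus four recovery timepoints, ~8 subjects) together with a two-condition
RRBS methylome in which a subset of differentially expressed genes carry a
hypomethylated CpG island near their TSS. Every downstream stage of the
pipeline can therefore be tested against known truth without any external
download.

The generator is deterministic: the same :class:`SyntheticDesign` (including
its seed) yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("methyltide")

#: trajectory archetypes; log2FC multiplier applied per post-Pre timepoint
ARCHETYPES = {
    "early": (1.0, 1.0, 0.0, 0.0),
    "late": (0.0, 0.0, 1.0, 1.0),
    "sustained": (1.0, 1.0, 1.0, 1.0),
    "biphasic": (1.0, 1.0, 0.0, -1.0),  # up early, down late
}

DEFAULT_TIMEPOINTS = ("Pre", "30min", "3h", "8h", "24h")


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of the simulated study.

    Defaults describe the reference scenario used throughout the test
    suite: 4000 genes, 10% planted DEGs of which 37.5% (150 genes) also
    carry a hypomethylated promoter island, a 40-point methylation shift,
    log2FC 1.5 effects, mean RRBS coverage 50x and 8 paired subjects.
    """

    n_genes: int = 4000
    chrom_length: int = 400_000_000
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_subjects: int = 8
    nb_dispersion: float = 0.05
    baseline_mean_log: float = float(np.log(200.0))
    baseline_sd_log: float = 1.0
    subject_sd_log: float = 0.15
    planted_deg_fraction: float = 0.10
    planted_coupling_fraction: float = 0.375
    effect_log2fc: float = 1.5
    meth_shift: float = 40.0
    coverage_mean: float = 50.0
    cpgs_per_island: tuple[int, int] = (10, 30)
    island_width: tuple[int, int] = (200, 1500)
    uncoupled_island_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_subjects < 1 or self.chrom_length < 1:
            raise ValueError("counts must be >= 1")
        for name in ("planted_deg_fraction", "planted_coupling_fraction",
                     "uncoupled_island_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(set(self.timepoints)) != len(self.timepoints):
            raise ValueError("timepoints must be unique")
        if len(self.timepoints) < 2:
            raise ValueError("need Pre plus >= 1 post timepoint")
        if self.nb_dispersion <= 0 or self.coverage_mean <= 0:
            raise ValueError("nb_dispersion and coverage_mean must be positive")
        for name in ("n_genes", "chrom_length", "n_subjects", "seed"):
            if not float(getattr(self, name)).is_integer():
                raise ValueError(f"{name} must be an integer")

    def with_seed(self, seed: int) -> "SyntheticDesign":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Planted truth: per-gene DEG status/trajectories and per-island DMRs."""

    genes: pd.DataFrame  # gene_id, is_deg, archetype, sign, is_coupled, lfc_<tp>...
    islands: pd.DataFrame  # island_id, gene_id, category, direction, p_a, p_b

    @property
    def coupled_genes(self) -> list[str]:
        return self.genes.loc[self.genes["is_coupled"], "gene_id"].tolist()

    def deg_genes(self, timepoint: str, direction: str = "up") -> list[str]:
        lfc = self.genes[f"lfc_{timepoint}"]
        mask = lfc > 0 if direction == "up" else lfc < 0
        return self.genes.loc[mask, "gene_id"].tolist()


# -- annotation ---------------------------------------------------------------

#: minimum slot width per gene; placement is infeasible below this
_MIN_SLOT = 2000


def generate_annotation(design: SyntheticDesign) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Place genes and CpG islands on one synthetic chromosome.

    Genes occupy the first 80% of the chromosome in fixed slots with a
    jittered TSS, guaranteeing distinct, ordered TSSs. Coupled genes get a
    CpG island whose midpoint is within 50 kb of their TSS; a fraction of
    other genes get an uncoupled island (no methylation shift); and at
    least 10% of islands are placed in the gene-free tail of the
    chromosome, more than 100 kb from every TSS, as negative controls.

    Returns ``(genes, islands, truth)``.
    """
    rng = np.random.default_rng(design.seed)
    gene_region = int(0.8 * design.chrom_length)
    slot = gene_region // design.n_genes
    if slot < _MIN_SLOT:
        raise ValueError(
            f"cannot place {design.n_genes} genes on a {design.chrom_length} bp "
            f"chromosome: slot width {slot} < {_MIN_SLOT}"
        )
    jitter = rng.uniform(0.1, 0.9, size=design.n_genes)
    tss = (np.arange(design.n_genes) * slot + (jitter * slot)).astype(np.int64)
    strand = rng.choice(["+", "-"], size=design.n_genes)
    gene_ids = [f"G{i:05d}" for i in range(design.n_genes)]
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": "chrS", "tss": tss, "strand": strand}
    )

    # planted truth -----------------------------------------------------
    n_deg = int(round(design.planted_deg_fraction * design.n_genes))
    n_coupled = int(round(design.planted_coupling_fraction * n_deg))
    deg_idx = rng.choice(design.n_genes, size=n_deg, replace=False)
    archetype = rng.choice(list(ARCHETYPES), size=n_deg)
    sign = rng.choice([1.0, -1.0], size=n_deg)
    coupled_pos = rng.choice(n_deg, size=n_coupled, replace=False)
    # coupled genes model the hypomethylation->upregulation axis: force an
    # archetype with a positive effect at the early recovery timepoints
    archetype[coupled_pos] = rng.choice(["early", "sustained"], size=n_coupled)
    sign[coupled_pos] = 1.0

    post_tps = design.timepoints[1:]
    truth_genes = pd.DataFrame({"gene_id": gene_ids})
    truth_genes["is_deg"] = False
    truth_genes.loc[deg_idx, "is_deg"] = True
    truth_genes["archetype"] = "none"
    truth_genes.loc[deg_idx, "archetype"] = archetype
    truth_genes["sign"] = 0.0
    truth_genes.loc[deg_idx, "sign"] = sign
    truth_genes["is_coupled"] = False
    truth_genes.loc[deg_idx[coupled_pos], "is_coupled"] = True
    for j, tp in enumerate(post_tps):
        lfc = np.zeros(design.n_genes)
        for k, idx in enumerate(deg_idx):
            mult = ARCHETYPES[archetype[k]][min(j, 3)]
            lfc[idx] = sign[k] * mult * design.effect_log2fc
        truth_genes[f"lfc_{tp}"] = lfc
    for tp in design.timepoints[:1]:
        truth_genes[f"lfc_{tp}"] = 0.0

    # islands ------------------------------------------------------------
    rows = []
    widths = design.island_width
    coupled_ids = truth_genes.loc[truth_genes["is_coupled"]].index.to_numpy()
    for idx in coupled_ids:
        w = int(rng.integers(widths[0], widths[1] + 1))
        center = int(tss[idx] + rng.integers(-50_000, 50_001))
        center = max(center, w // 2 + 1)
        rows.append((f"isl_c{idx:05d}", gene_ids[idx], "coupled", "hypo",
                     center - w // 2, center + w - w // 2))
    n_unc = int(round(design.uncoupled_island_fraction * design.n_genes))
    unc_pool = np.setdiff1d(np.arange(design.n_genes), coupled_ids)
    unc_idx = rng.choice(unc_pool, size=min(n_unc, len(unc_pool)), replace=False)
    for idx in unc_idx:
        w = int(rng.integers(widths[0], widths[1] + 1))
        center = int(tss[idx] + rng.integers(-50_000, 50_001))
        center = max(center, w // 2 + 1)
        rows.append((f"isl_u{idx:05d}", gene_ids[idx], "uncoupled", "none",
                     center - w // 2, center + w - w // 2))
    n_pos = len(rows)
    n_neg = max(1, int(np.ceil(0.1 * max(n_pos, 1) / 0.9)))
    neg_lo = gene_region + 150_000  # > 100 kb past the last possible TSS
    if neg_lo + 200_000 > design.chrom_length:
        raise ValueError("chrom_length leaves no room for negative-control islands")
    for i in range(n_neg):
        w = int(rng.integers(widths[0], widths[1] + 1))
        center = int(rng.integers(neg_lo, design.chrom_length - w))
        rows.append((f"isl_n{i:05d}", "", "negative", "none",
                     center - w // 2, center + w - w // 2))

    islands = pd.DataFrame(
        rows, columns=["island_id", "gene_id", "category", "direction", "start", "end"]
    )
    islands.insert(1, "chrom", "chrS")
    islands["n_cpg"] = rng.integers(
        design.cpgs_per_island[0], design.cpgs_per_island[1] + 1, size=len(islands)
    )
    # baseline methylation: coupled islands start high so a hypo shift is visible
    p_a = rng.uniform(0.1, 0.9, size=len(islands))
    coupled_mask = (islands["category"] == "coupled").to_numpy()
    p_a[coupled_mask] = rng.uniform(0.55, 0.9, size=int(coupled_mask.sum()))
    p_b = p_a.copy()
    shift = design.meth_shift / 100.0
    p_b[coupled_mask] = p_a[coupled_mask] - shift
    clipped = (p_b < 0) | (p_b > 1)
    if clipped.any():
        logger.warning("meth_shift pushed %d island(s) outside [0,1]; clamped",
                       int(clipped.sum()))
        p_b = np.clip(p_b, 0.0, 1.0)
    islands["p_a"] = p_a
    islands["p_b"] = p_b

    truth = GroundTruth(genes=truth_genes, islands=islands.copy())
    return genes, islands, truth


# -- methylome ----------------------------------------------------------------

def generate_methylome(
    islands: pd.DataFrame,
    design: SyntheticDesign,
    conditions: tuple[str, str] = ("pre", "post"),
    n_samples: int | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate per-sample per-CpG RRBS counts for two conditions.

    CpG positions are drawn once per island and shared across samples.
    Per CpG and sample, coverage ~ Poisson(coverage_mean) and the
    methylated count ~ Binomial(coverage, p) where p is the island's
    condition-specific methylation level. Zero-coverage CpGs are emitted
    with 0/0 counts (they are filtered downstream).

    Returns ``(tables, groups)`` where ``tables`` maps sample_id to a
    MethylSiteTable DataFrame and ``groups`` assigns samples to conditions.
    """
    rng = np.random.default_rng(design.seed + 1)
    n_samples = design.n_subjects if n_samples is None else n_samples

    pos_list, island_of = [], []
    for i, isl in islands.iterrows():
        lo, hi = int(isl["start"]) + 1, int(isl["end"])  # 1-based inclusive
        n = min(int(isl["n_cpg"]), hi - lo + 1)
        pts = np.sort(rng.choice(np.arange(lo, hi + 1), size=n, replace=False))
        pos_list.append(pts)
        island_of.append(np.full(n, i))
    pos = np.concatenate(pos_list)
    island_idx = np.concatenate(island_of)
    p_by_cond = {
        conditions[0]: islands["p_a"].to_numpy()[island_idx],
        conditions[1]: islands["p_b"].to_numpy()[island_idx],
    }

    tables: dict[str, pd.DataFrame] = {}
    group_rows = []
    for cond in conditions:
        p = p_by_cond[cond]
        for s in range(n_samples):
            sample_id = f"{cond}_s{s + 1}"
            cov = rng.poisson(design.coverage_mean, size=len(pos))
            m = rng.binomial(cov, p)
            tables[sample_id] = pd.DataFrame(
                {
                    "chrom": islands["chrom"].iloc[0],
                    "pos": pos,
                    "count_M": m,
                    "count_U": cov - m,
                }
            )
            group_rows.append((sample_id, cond))
    groups = pd.DataFrame(group_rows, columns=["sample_id", "group"])
    return tables, groups


# -- counts -------------------------------------------------------------------

def generate_counts(
    truth: GroundTruth, design: SyntheticDesign
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a paired NB count matrix over all timepoints.

    Per-gene baselines are lognormal; each subject carries a lognormal
    multiplier shared across its timepoints (the paired-biopsy structure);
    planted log2 fold changes from the ground truth shift the NB mean at
    post timepoints. Counts are NB(mean, dispersion) via the gamma-Poisson
    mixture.

    Returns ``(counts, metadata)``: counts is genes x samples with gene_id
    index; metadata has sample, subject, timepoint columns.
    """
    if design.n_subjects < 3:
        raise ValueError("n_subjects must be >= 3")
    rng = np.random.default_rng(design.seed + 2)
    n_genes = design.n_genes
    base = rng.lognormal(design.baseline_mean_log, design.baseline_sd_log, size=n_genes)
    subj = rng.lognormal(0.0, design.subject_sd_log, size=design.n_subjects)

    lfc = np.column_stack(
        [truth.genes[f"lfc_{tp}"].to_numpy() for tp in design.timepoints]
    )  # genes x timepoints
    cols, data = [], []
    alpha = design.nb_dispersion
    meta_rows = []
    for j, tp in enumerate(design.timepoints):
        mu_t = base * np.exp2(lfc[:, j])
        for s in range(design.n_subjects):
            mu = mu_t * subj[s]
            lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
            counts = rng.poisson(lam)
            cols.append(f"S{s + 1}_{tp}")
            data.append(counts)
            meta_rows.append((f"S{s + 1}_{tp}", f"S{s + 1}", tp))
    counts = pd.DataFrame(
        np.column_stack(data), index=truth.genes["gene_id"], columns=cols
    )
    counts.index.name = "gene_id"
    metadata = pd.DataFrame(meta_rows, columns=["sample", "subject", "timepoint"])
    return counts, metadata


# -- gene sets ----------------------------------------------------------------

def generate_gene_sets(
    universe: list[str],
    deg_genes: list[str],
    n_sets: int = 20,
    size_range: tuple[int, int] = (20, 100),
    planted_set_fraction: float = 0.5,
    planted_deg_share: float = 0.9,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Build a GMT-style collection with planted DEG-enriched sets.

    Planted sets draw ``planted_deg_share`` of their members from the DEG
    list and the rest from the remaining universe; null sets are uniform
    draws from the whole universe.
    """
    rng = np.random.default_rng(seed)
    if size_range[1] > len(universe):
        raise ValueError("set size exceeds universe size")
    universe = list(dict.fromkeys(universe))
    deg = [g for g in deg_genes if g in set(universe)]
    non_deg = [g for g in universe if g not in set(deg)]
    n_planted = int(round(planted_set_fraction * n_sets))
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if i < n_planted and deg:
            k = min(int(round(planted_deg_share * size)), len(deg))
            members = list(rng.choice(deg, size=k, replace=False))
            pool = non_deg if len(non_deg) >= size - k else universe
            members += list(rng.choice(pool, size=size - k, replace=False))
            name = f"planted_set_{i:03d}"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            name = f"null_set_{i:03d}"
        sets[name] = sorted(set(members))
    return sets
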