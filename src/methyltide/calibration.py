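"""Null-calibration and power studies for the pipeline's test statistics.

These helpers run the package's own stages on synthetic data in regimes
where the truth is known exactly — no planted coupling (KS), no planted
effects (DE type-I error), or a fixed planted effect (DE power) — so that
the empirical operating characteristics can be measured. They are used by
the test suite and the acceptance script, and are available to users who
want to recalibrate after changing thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integrate import ks_target_test, regulatory_potential
from .meth import DifferentialMethylation
from .sim import GroundTruth, SyntheticDesign, generate_annotation, generate_counts, generate_methylome
from .txn import differential_expression

#: compact genome used for per-replicate null studies; dense shifted islands
#: keep the regulatory-potential score distribution effectively continuous
NULL_KS_DESIGN = dict(
    n_genes=300,
    chrom_length=30_000_000,
    planted_deg_fraction=1.0,
    planted_coupling_fraction=0.75,
    cpgs_per_island=(8, 12),
)


def ks_null_replicate(seed: int, n_group: int = 30, n_samples: int = 2) -> float:
    """One null replicate of the up-vs-background KS test.

    DMRs are planted as usual, but the tested 'upregulated' gene set is
    drawn uniformly at random, independent of peak placement — i.e. no
    DMR-DEG coupling. Returns the one-tailed KS p-value; under this null
    the rejection rate at 0.05 should sit near 0.05.
    """
    design = SyntheticDesign(seed=int(seed), **NULL_KS_DESIGN)
    genes, islands, _ = generate_annotation(design)
    tables, groups = generate_methylome(islands, design, n_samples=n_samples)
    dm = DifferentialMethylation().fit(
        tables, groups, islands.rename(columns={"island_id": "name"})
    )
    tss = genes[["gene_id", "chrom", "tss", "strand"]]
    scores = regulatory_potential(tss, dm.peaks_)
    rng = np.random.default_rng(int(seed) + 10_000)
    ids = genes["gene_id"].to_numpy()
    group = rng.choice(ids, size=n_group, replace=False)
    background = np.setdiff1d(ids, group)
    return ks_target_test(scores, list(group), list(background)).p_value


def ks_null_rejection_rate(n_runs: int = 500, seed: int = 0, alpha: float = 0.05) -> float:
    ps = [ks_null_replicate(seed * n_runs + i) for i in range(n_runs)]
    return float(np.mean(np.asarray(ps) < alpha))


def _two_point_truth(n_genes: int, lfc: np.ndarray) -> GroundTruth:
    genes = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(n_genes)],
            "is_deg": lfc != 0,
            "archetype": np.where(lfc != 0, "sustained", "none"),
            "sign": np.sign(lfc),
            "is_coupled": False,
            "lfc_Pre": 0.0,
            "lfc_post": lfc,
        }
    )
    return GroundTruth(genes=genes, islands=pd.DataFrame())


def de_null_pvalues(
    n_genes: int = 2000, n_subjects: int = 8, baseline: float = 500.0,
    dispersion: float = 0.05, seed: int = 0,
) -> np.ndarray:
    """Raw DE p-values under the global null (no planted effects)."""
    design = SyntheticDesign(
        n_genes=n_genes, chrom_length=max(3000 * n_genes + 1_000_000, 4_000_000),
        timepoints=("Pre", "post"), n_subjects=n_subjects,
        nb_dispersion=dispersion, baseline_mean_log=float(np.log(baseline)),
        planted_deg_fraction=0.0, planted_coupling_fraction=0.0, seed=int(seed),
    )
    truth = _two_point_truth(n_genes, np.zeros(n_genes))
    counts, metadata = generate_counts(truth, design)
    res = differential_expression(counts, metadata, "post")
    return res["pvalue"].to_numpy()


def de_power(
    log2fc: float = 3.0, n_planted: int = 100, n_genes: int = 2000,
    n_subjects: int = 8, baseline: float = 500.0, dispersion: float = 0.05,
    seed: int = 0, n_runs: int = 1,
) -> float:
    """Fraction of planted genes detected at BH-adjusted p < 0.05."""
    hits = total = 0
    for r in range(n_runs):
        rng = np.random.default_rng(seed + 20_000 + r)
        lfc = np.zeros(n_genes)
        planted = rng.choice(n_genes, size=n_planted, replace=False)
        lfc[planted] = log2fc
        design = SyntheticDesign(
            n_genes=n_genes, chrom_length=max(3000 * n_genes + 1_000_000, 4_000_000),
            timepoints=("Pre", "post"), n_subjects=n_subjects,
            nb_dispersion=dispersion, baseline_mean_log=float(np.log(baseline)),
            planted_deg_fraction=0.0, planted_coupling_fraction=0.0,
            seed=int(seed) + r,
        )
        truth = _two_point_truth(n_genes, lfc)
        counts, metadata = generate_counts(truth, design)
        res = differential_expression(counts, metadata, "post").set_index("gene")
        ids = [f"G{i:05d}" for i in planted]
        hits += int((res.loc[res.index.intersection(ids), "padj"] < 0.05).sum())
        total += n_planted
    return hits / total


def planted_recovery_run(seed: int, de_timepoint: str = "3h") -> dict:
    """One full pipeline run at the reference planted-coupling conditions.

    Returns the up-vs-background KS p-value and the fraction of planted
    coupled genes among the top-500 regulatory-potential genes.
    """
    from .integrate import BetaIntegrator

    design = SyntheticDesign(seed=int(seed))
    genes, islands, truth = generate_annotation(design)
    tables, groups = generate_methylome(islands, design)
    dm = DifferentialMethylation().fit(
        tables, groups, islands.rename(columns={"island_id": "name"})
    )
    counts, metadata = generate_counts(truth, design)
    de = differential_expression(counts, metadata, de_timepoint)
    tss = genes[["gene_id", "chrom", "tss", "strand"]]
    beta = BetaIntegrator(direction_mode="combined").fit(tss, dm.peaks_, de)
    result = beta.results_["combined"]
    top500 = set(
        result.scores.sort_values("score", ascending=False, kind="mergesort")
        .head(500)["gene_id"]
    )
    planted = set(truth.coupled_genes)
    return {
        "ks_up_p": result.ks["up"].p_value if "up" in result.ks else float("nan"),
        "top500_recovery": len(top500 & planted) / len(planted),
        "n_peaks": len(dm.peaks_),
        "n_up_degs": result.ks["up"].n_group if "up" in result.ks else 0,
    }
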