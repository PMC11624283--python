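"""End-to-end pipeline: simulate -> methylation peaks -> DE -> integration -> enrichment.

A single config dict (typically loaded from YAML) drives every stage;
the resolved config and a run manifest (package version, seed, parameter
hash) are echoed into the output directory so a rerun with the same config
reproduces byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrich import fisher_enrichment, temporal_profile
from .integrate import BetaIntegrator
from .io import write_bed, write_coverage, write_gmt, write_tsv
from .meth import DifferentialMethylation, peaks_to_bed
from .sim import (SyntheticDesign, generate_annotation, generate_counts,
                  generate_gene_sets, generate_methylome)
from .txn import NBWaldDE, collapse_degs, normalize

logger = logging.getLogger("methyltide")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "sim": {},  # SyntheticDesign field overrides
    "meth": {"min_reads": 10, "min_samples_per_group": 1,
             "q_thresh": 0.05, "diff_thresh": 25.0},
    "de": {"alpha": 0.05, "reference": "Pre", "paired": False},
    "integrate": {"window": 100_000, "df_cutoff": 0.05, "c_cutoff": 0.05,
                  "da_top": 500, "de_timepoint": "3h"},
    "enrich": {"n_sets": 20, "planted_set_fraction": 0.5},
}


def resolve_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    config = config or {}
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    for k, v in config.items():
        if isinstance(v, dict):
            known = set()
            if k == "sim":
                known = {f.name for f in dataclasses.fields(SyntheticDesign)}
            else:
                known = set(cfg[k])
            bad = set(v) - known
            if bad:
                raise ValueError(f"unknown key(s) in config section {k!r}: {sorted(bad)}")
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: dict | None = None, out_dir: str | Path = "methyltide_run") -> dict:
    """Run every stage on synthetic data and write all artifacts.

    Returns a dict of in-memory results keyed by stage. Stage failures
    raise with the failing stage named.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    results: dict = {"config": cfg}
    stage = "sim"
    try:
        design = SyntheticDesign(**{"seed": cfg["seed"], **cfg["sim"]})
        genes, islands, truth = generate_annotation(design)
        tables, groups = generate_methylome(islands, design)
        counts, metadata = generate_counts(truth, design)
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        write_tsv(genes, sim_dir / "genes.tsv")
        write_bed(islands.assign(name=islands["island_id"]), sim_dir / "islands.bed")
        write_tsv(truth.genes, sim_dir / "truth_genes.tsv")
        write_tsv(counts.reset_index(), sim_dir / "counts.tsv")
        write_tsv(metadata, sim_dir / "metadata.tsv")
        write_tsv(groups, sim_dir / "meth_groups.tsv")
        cov_dir = sim_dir / "coverage"
        cov_dir.mkdir(exist_ok=True)
        for sid, t in tables.items():
            write_coverage(t, cov_dir / f"{sid}.cov")
        results[stage] = {"design": design, "genes": genes, "islands": islands,
                          "truth": truth, "counts": counts, "metadata": metadata}

        stage = "meth"
        dm = DifferentialMethylation(**cfg["meth"]).fit(
            tables, groups, islands.rename(columns={"island_id": "name"})
        )
        meth_dir = out / "meth"
        meth_dir.mkdir(exist_ok=True)
        write_tsv(dm.regions_, meth_dir / "region_results.tsv")
        peaks_to_bed(dm.peaks_, meth_dir / "peaks_all.bed")
        for d in ("hypo", "hyper"):
            peaks_to_bed(dm.peaks_, meth_dir / f"peaks_{d}.bed", direction=d)
        results[stage] = {"model": dm, "peaks": dm.peaks_}

        stage = "txn"
        de = NBWaldDE(reference=cfg["de"]["reference"], alpha=cfg["de"]["alpha"],
                      paired=cfg["de"]["paired"]).fit(counts, metadata)
        collapsed = collapse_degs(de.results_, alpha=cfg["de"]["alpha"])
        txn_dir = out / "txn"
        txn_dir.mkdir(exist_ok=True)
        for tp, tab in de.results_.items():
            write_tsv(tab, txn_dir / f"de_{tp}.tsv")
        write_tsv(collapsed.membership, txn_dir / "collapsed_membership.tsv")
        pd.DataFrame({"gene": sorted(collapsed.up)}).to_csv(
            txn_dir / "collapsed_up.tsv", sep="\t", index=False)
        pd.DataFrame({"gene": sorted(collapsed.down)}).to_csv(
            txn_dir / "collapsed_down.tsv", sep="\t", index=False)
        results[stage] = {"de": de.results_, "collapsed": collapsed}

        stage = "integrate"
        tp = cfg["integrate"]["de_timepoint"]
        if tp not in de.results_:
            raise ValueError(f"integration timepoint {tp!r} has no DE table")
        tss = genes[["gene_id", "chrom", "tss", "strand"]]
        beta = BetaIntegrator(
            window=cfg["integrate"]["window"], df_cutoff=cfg["integrate"]["df_cutoff"],
            c_cutoff=cfg["integrate"]["c_cutoff"], da_top=cfg["integrate"]["da_top"],
        ).fit(tss, dm.peaks_, de.results_[tp])
        int_dir = out / "integrate"
        int_dir.mkdir(exist_ok=True)
        summary_lines = []
        for mode, r in beta.results_.items():
            write_tsv(r.scores, int_dir / f"scores_{mode}.tsv")
            for grp, t in r.targets.items():
                write_tsv(t, int_dir / f"targets_{mode}_{grp}.tsv")
            summary_lines.append(r.summary())
        (int_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
        results[stage] = {"model": beta}

        stage = "enrich"
        universe = counts.index.tolist()
        deg_up = sorted(collapsed.up)
        sets = generate_gene_sets(
            universe, deg_up, n_sets=cfg["enrich"]["n_sets"],
            planted_set_fraction=cfg["enrich"]["planted_set_fraction"],
            seed=cfg["seed"] + 3,
        )
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        write_gmt(sets, enr_dir / "gene_sets.gmt")
        enr = fisher_enrichment(deg_up, sets, universe)
        write_tsv(enr, enr_dir / "enrichment_up.tsv")
        tps = [t for t in design.timepoints if t != cfg["de"]["reference"]]
        profiles = []
        for name, members in sets.items():
            prof = temporal_profile(collapsed.membership, members, collapsed.up,
                                    tps, direction="up")
            if prof is not None:
                prof.insert(0, "set", name)
                profiles.append(prof)
        if profiles:
            write_tsv(pd.concat(profiles, ignore_index=True),
                      enr_dir / "temporal_profiles.tsv")
        results[stage] = {"enrichment": enr, "sets": sets}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "methyltide",
        "version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "stages": ["sim", "meth", "txn", "integrate", "enrich"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results
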