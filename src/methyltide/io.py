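"""File formats and coordinate conventions.

Everything genomic in this package lives in one of two coordinate systems:

* Bismark coverage files: 1-based, inclusive, start == end == CpG position.
* BED: 0-based, half-open.

Conversions between the two are centralized here so no other module does
coordinate arithmetic on file columns.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

logger = logging.getLogger("methyltide")

COVERAGE_COLUMNS = ["chrom", "start", "end", "percent", "count_M", "count_U"]


def pos_to_bed(pos: int) -> tuple[int, int]:
    """1-based CpG position -> 0-based half-open BED interval of width 1."""
    return pos - 1, pos


def bed_to_pos(start: int) -> int:
    """0-based BED start -> 1-based position."""
    return start + 1


def read_coverage(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a Bismark-dialect coverage file into a per-CpG site table.

    The file has six tab-separated columns: chrom, start, end, percent
    methylation, methylated count, unmethylated count. Coordinates are
    1-based. The percent column is redundant with the counts and is
    recomputed on read; a contradiction is logged as a warning, the counts
    win.

    Returns a DataFrame with columns chrom, pos, count_M, count_U, percent
    (NaN where coverage is zero) and, if given, sample_id.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=COVERAGE_COLUMNS,
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=COVERAGE_COLUMNS)
    if df.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 tab-separated columns, got {df.shape[1]}")
    for col in ("start", "end", "count_M", "count_U"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            lines = (bad.index + 1).tolist()[:10]
            raise ValueError(f"{path}: malformed numeric field '{col}' at line(s) {lines}")
        df[col] = df[col].astype(int)
    if (df["count_M"] < 0).any() or (df["count_U"] < 0).any():
        lines = (df.index[(df["count_M"] < 0) | (df["count_U"] < 0)] + 1).tolist()[:10]
        raise ValueError(f"{path}: negative counts at line(s) {lines}")

    cov = df["count_M"] + df["count_U"]
    percent = pd.Series(float("nan"), index=df.index)
    nz = cov > 0
    percent[nz] = 100.0 * df.loc[nz, "count_M"] / cov[nz]
    stated = pd.to_numeric(df["percent"], errors="coerce")
    mismatch = nz & stated.notna() & ((stated - percent).abs() > 0.51)
    if mismatch.any():
        logger.warning(
            "%s: percent column contradicts counts at %d line(s) (e.g. line %d); "
            "counts take precedence", path, int(mismatch.sum()), int(mismatch.idxmax()) + 1,
        )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"],
            "count_M": df["count_M"],
            "count_U": df["count_U"],
            "percent": percent,
        }
    )
    if sample_id is not None:
        out["sample_id"] = sample_id
    return out


def write_coverage(sites: pd.DataFrame, path: str | Path) -> None:
    """Write a site table (chrom, pos, count_M, count_U) as Bismark coverage text."""
    cov = sites["count_M"] + sites["count_U"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        percent = (100.0 * sites["count_M"] / cov).fillna(0.0)
    out = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"],
            "percent": percent.round(6),
            "count_M": sites["count_M"],
            "count_U": sites["count_U"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 (0-based half-open). Returns chrom, start, end and,
    when present, name, score, strand."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED needs >= 3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"][:ncol]
    df.columns = names + [f"extra_{i}" for i in range(ncol - len(names))]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: degenerate BED intervals (end <= start)")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ...

    Duplicate genes within a set are removed with a warning; order of first
    occurrence is preserved.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: GMT needs name, description, >=1 gene")
            name, genes = parts[0], parts[2:]
            dedup = list(dict.fromkeys(g for g in genes if g))
            if len(dedup) < len([g for g in genes if g]):
                logger.warning("%s: set %r contains duplicate genes; deduplicated", path, name)
            if name in sets:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            sets[name] = dedup
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
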