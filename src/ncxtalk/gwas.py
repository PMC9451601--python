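"""Per-trait GWAS summary-statistic filtering, FDR selection, and trait intersection.

A trait is represented by one or more summary-statistic tables (one per
source file, Neale-lab-style columns). Each file is independently cleaned
(MAF >= 0.001 by default), Benjamini–Hochberg adjusted, and thresholded at
adj. p < alpha; per-trait significant sets are combined across files
(union by default) and the two traits are intersected to give the shared
significant SNPs that seed the LD graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataValidationError, PipelineStateError

logger = logging.getLogger(__name__)

#: canonical column name -> default header in the input TSV
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant": "variant",
    "rsid": "rsid",
    "chrom": "chr",
    "pos": "pos",
    "maf": "minor_AF",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
}

_MANDATORY = ("variant", "maf", "beta", "se", "pval")
_CANONICAL = ["variant_id", "rsid", "chrom", "pos", "maf", "beta", "se", "pval"]


@dataclass
class TraitDataset:
    """One trait's GWAS evidence: a label plus one table per source file."""

    trait_label: str
    files: list[pd.DataFrame] = field(default_factory=list)
    combine_policy: str = "union"


def load_gwas_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read one summary-statistic TSV into canonical columns.

    Rows whose mandatory fields (variant, maf, beta, se, pval) do not parse
    are dropped and counted in the log. Variant identity is normalized to
    the rsid when present, else the raw variant string (chrom:pos:ref:alt);
    duplicate ids keep the smallest p-value.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.empty:
        logger.warning("GWAS table %s is empty", path)
        return pd.DataFrame(columns=_CANONICAL)
    for key in _MANDATORY:
        if cmap[key] not in raw.columns:
            raise ConfigurationError(
                f"GWAS table {path} lacks mandatory column "
                f"{cmap[key]!r} (mapped from {key!r})"
            )

    df = pd.DataFrame(index=raw.index)
    df["variant"] = raw[cmap["variant"]].astype(str)
    df["rsid"] = raw[cmap["rsid"]] if cmap["rsid"] in raw.columns else None
    for key in ("maf", "beta", "se", "pval"):
        df[key] = pd.to_numeric(raw[cmap[key]], errors="coerce")

    # chrom/pos from explicit columns, else parsed from chrom:pos:ref:alt
    if cmap["chrom"] in raw.columns:
        df["chrom"] = raw[cmap["chrom"]].astype(str)
    else:
        df["chrom"] = df["variant"].str.split(":").str[0]
    if cmap["pos"] in raw.columns:
        df["pos"] = pd.to_numeric(raw[cmap["pos"]], errors="coerce")
    else:
        parts = df["variant"].str.split(":")
        df["pos"] = pd.to_numeric(
            parts.str[1].where(parts.str.len() >= 2), errors="coerce"
        )

    ok = df[["maf", "beta", "se", "pval"]].notna().all(axis=1)
    ok &= df["pval"].gt(0) & df["pval"].le(1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with unparseable fields", path, n_dropped)
    df = df[ok].copy()

    has_rsid = df["rsid"].notna() & df["rsid"].astype(str).str.len().gt(0)
    df["variant_id"] = df["variant"].where(~has_rsid, df["rsid"])
    df = df.sort_values("pval", kind="mergesort")
    n_dup = int(df.duplicated("variant_id").sum())
    if n_dup:
        logger.info("%s: %d duplicated variant ids, kept smallest p", path, n_dup)
    df = df.drop_duplicates("variant_id", keep="first").sort_index()
    df.attrs["n_dropped"] = n_dropped
    return df[_CANONICAL].reset_index(drop=True)


def filter_low_confidence(records: pd.DataFrame, maf_threshold: float = 0.001) -> pd.DataFrame:
    """Remove low-confidence variants with maf < maf_threshold (boundary kept)."""
    if maf_threshold < 0:
        raise ConfigurationError(f"maf_threshold must be >= 0, got {maf_threshold}")
    return records[records["maf"] >= maf_threshold].reset_index(drop=True)


def adjust_pvalues_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, aligned to input order."""
    arr = np.asarray(pvals, dtype=float)
    bad = np.flatnonzero(~((arr > 0) & (arr <= 1)))
    if bad.size:
        raise DataValidationError(
            f"p-value outside (0, 1] at index {int(bad[0])}: {arr[bad[0]]}"
        )
    if arr.size == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def add_adjusted_pvalues(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an adj_pval column from :func:`adjust_pvalues_bh`."""
    out = records.copy()
    out["adj_pval"] = adjust_pvalues_bh(out["pval"].to_numpy())
    return out


def select_significant(records: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Variant ids with adj. p strictly below alpha."""
    if "adj_pval" not in records.columns:
        raise PipelineStateError("adj_pval absent: run adjustment first")
    sel = records.loc[records["adj_pval"] < alpha, "variant_id"]
    return set(sel.astype(str))


def combine_trait_files(
    dataset: TraitDataset,
    alpha: float = 0.05,
    maf_threshold: float = 0.001,
) -> set[str]:
    """Per-file filter + BH + select, combined across files per policy.

    Policies: ``union`` (significant in >= 1 file, the default),
    ``intersection`` (significant in every file), ``single`` (first file).
    """
    if not dataset.files:
        raise ConfigurationError(f"trait {dataset.trait_label}: no files")
    policy = dataset.combine_policy
    if policy not in ("union", "intersection", "single"):
        raise ConfigurationError(f"unknown combine policy {policy!r}")
    per_file = []
    for df in dataset.files if policy != "single" else dataset.files[:1]:
        cleaned = add_adjusted_pvalues(filter_low_confidence(df, maf_threshold))
        per_file.append(select_significant(cleaned, alpha))
    logger.info(
        "trait %s: combining %d files by %s", dataset.trait_label, len(per_file), policy
    )
    if policy == "intersection":
        return set.intersection(*per_file)
    return set.union(*per_file)


def intersect_traits(ids_a: Iterable[str], ids_b: Iterable[str]) -> list[str]:
    """Shared significant variant ids, sorted lexicographically."""
    return sorted(set(ids_a) & set(ids_b))
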