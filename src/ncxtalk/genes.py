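"""Signature-to-gene mapping, the minimum-SNP filter, and gene reports.

SNP -> gene assignment comes from an annotation table rather than a live
genome query, so the stage is testable offline; a SNP annotated to several
overlapping genes contributes to each of them. Genes supported by at least
3 signature SNPs (default) are reported; the protein-coding subset defines
the first layer of the downstream tripartite network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataValidationError, NcxtalkError
from .ld import Signature

logger = logging.getLogger(__name__)

GENE_CLASSES = ("protein_coding", "lncRNA", "pseudogene", "other")

ANNOTATION_COLUMNS = ["variant_id", "gene_symbol", "gene_class", "chrom"]


@dataclass
class GeneMapping:
    """SNPs and signatures supporting one gene."""

    snps: set[str] = field(default_factory=set)
    signature_ids: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class GeneSignatureSummary:
    gene_symbol: str
    gene_class: str
    chrom: str
    signature_ids: frozenset[str]
    snp_count: int


def load_annotation(path) -> pd.DataFrame:
    """Read a SNP->gene annotation TSV; unknown classes map to 'other'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"annotation table {path} lacks columns {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    unknown = ~df["gene_class"].isin(GENE_CLASSES)
    if unknown.any():
        logger.warning(
            "%d annotation rows with unknown gene_class mapped to 'other'",
            int(unknown.sum()),
        )
        df.loc[unknown, "gene_class"] = "other"
    return df.drop_duplicates(["variant_id", "gene_symbol"]).reset_index(drop=True)


def map_signatures_to_genes(
    signatures: Sequence[Signature], annotation: pd.DataFrame
) -> dict[str, GeneMapping]:
    """Aggregate signature SNPs per gene via the annotation table.

    A gene's signature set contains every signature contributing at least
    one annotated SNP. Signature SNPs with no annotation row are counted
    and logged.
    """
    if annotation.empty:
        logger.warning("annotation table is empty: no genes mapped")
        return {}
    snp_to_genes: dict[str, list[str]] = {}
    for row in annotation.itertuples(index=False):
        snp_to_genes.setdefault(str(row.variant_id), []).append(str(row.gene_symbol))
    gene_map: dict[str, GeneMapping] = {}
    unannotated: set[str] = set()
    for sig in signatures:
        for snp in sig.members:
            genes = snp_to_genes.get(snp)
            if not genes:
                unannotated.add(snp)
                continue
            for gene in genes:
                entry = gene_map.setdefault(gene, GeneMapping())
                entry.snps.add(snp)
                entry.signature_ids.add(sig.signature_id)
    if unannotated:
        logger.info("%d signature SNPs carry no annotation", len(unannotated))
    return gene_map


def filter_genes_min_snps(
    gene_map: Mapping[str, GeneMapping], min_snps: int = 3
) -> dict[str, GeneMapping]:
    """Keep genes supported by at least ``min_snps`` signature SNPs."""
    if min_snps < 1:
        raise ConfigurationError(f"min_snps must be >= 1, got {min_snps}")
    return {g: m for g, m in gene_map.items() if len(m.snps) >= min_snps}


def summarize_genes(
    gene_map: Mapping[str, GeneMapping], annotation: pd.DataFrame
) -> list[GeneSignatureSummary]:
    """One row per gene with class, chromosome, signatures, and SNP count.

    Deterministic order: chromosome, then gene symbol. A gene annotated to
    two chromosomes is a data error and is reported by name.
    """
    meta = annotation.drop_duplicates(["gene_symbol", "gene_class", "chrom"])
    rows: list[GeneSignatureSummary] = []
    for gene, mapping in gene_map.items():
        info = meta[meta["gene_symbol"] == gene]
        chroms = sorted(info["chrom"].unique())
        if len(chroms) != 1:
            raise DataValidationError(
                f"gene {gene} has conflicting chromosome annotations: {chroms}"
            )
        classes = sorted(info["gene_class"].unique())
        rows.append(
            GeneSignatureSummary(
                gene_symbol=gene,
                gene_class=classes[0],
                chrom=chroms[0],
                signature_ids=frozenset(mapping.signature_ids),
                snp_count=len(mapping.snps),
            )
        )
    return sorted(rows, key=lambda r: (r.chrom, r.gene_symbol))


def summaries_frame(summaries: Sequence[GeneSignatureSummary]) -> pd.DataFrame:
    rows = [
        {
            "gene_symbol": s.gene_symbol,
            "gene_class": s.gene_class,
            "chrom": s.chrom,
            "signatures": ";".join(sorted(s.signature_ids)),
            "snp_count": s.snp_count,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["gene_symbol", "gene_class", "chrom", "signatures", "snp_count"]
    )


def select_protein_set(summaries: Sequence[GeneSignatureSummary]) -> list[str]:
    """Protein-coding gene symbols, sorted; the tripartite network's first layer."""
    proteins = sorted(s.gene_symbol for s in summaries if s.gene_class == "protein_coding")
    if not proteins:
        raise NcxtalkError("no protein-coding genes survive: downstream stages undefined")
    return proteins


def disease_association_report(
    genes: Iterable[str], records: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene disease rows with PMID support; absent genes get 'no evidence'."""
    rows = []
    for gene in sorted(set(genes)):
        hits = records[records["gene_symbol"] == gene] if not records.empty else records
        if hits is None or len(hits) == 0:
            rows.append({"gene_symbol": gene, "disease": "no evidence", "n_pmids": 0})
            continue
        for rec in hits.itertuples(index=False):
            rows.append(
                {
                    "gene_symbol": gene,
                    "disease": str(rec.disease),
                    "n_pmids": int(rec.n_pmids),
                }
            )
    return pd.DataFrame(rows, columns=["gene_symbol", "disease", "n_pmids"])
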