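"""Curated reference tables for the diabetes–Alzheimer cross-talk analysis.

The package ships small transcribed reference tables under ``data/``:

* ``shared_snps.tsv`` — the curated list of shared significant
  SNPs with chromosome labels (117 rsIDs: 43 on chromosome 19, 74 on
  chromosome 6);
* ``gene_signatures.tsv`` — gene symbols with class, chromosome,
  and the SNP signatures (A–F) supporting them;
* ``gene_disease.tsv`` — per-gene disease associations with PMID
  support counts;
* ``protein_mirna_evidence.tsv`` — the 49-cell protein–miRNA evidence matrix
  (codes a=starBase, b=miRWalk, c=TargetScan, d=miRanda via starBase,
  e=miRmap, f=microT);
* ``mirna_lncrna_evidence.tsv`` — the full miRNA–lncRNA evidence matrix
  including cells supported by starBase only (codes S=starBase, L=LncBase).

These tables are data, not computations: the GWAS downloads, LD service
queries, and interaction-database queries that produced them are outside
the package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .ld import Signature
from .networks import InteractionRecord, load_interactions


def _data_path(name: str):
    return resources.files("ncxtalk.data").joinpath(name)


@dataclass(frozen=True)
class ReferenceTables:
    """Bundle of the transcribed reference tables."""

    shared_snps: pd.DataFrame
    gene_signatures: pd.DataFrame
    gene_disease: pd.DataFrame
    pm_records: tuple[InteractionRecord, ...]
    ml_records: tuple[InteractionRecord, ...]

    @property
    def protein_set(self) -> list[str]:
        coding = self.gene_signatures.query("gene_class == 'protein_coding'")
        return sorted(coding["gene_symbol"])


def reference_tables() -> ReferenceTables:
    """Load the versioned reference tables shipped with the package."""
    shared = pd.read_csv(_data_path("shared_snps.tsv"), sep="\t", dtype={"chrom": str})
    genes = pd.read_csv(_data_path("gene_signatures.tsv"), sep="\t", dtype={"chrom": str})
    disease = pd.read_csv(_data_path("gene_disease.tsv"), sep="\t")
    pm = tuple(load_interactions(_data_path("protein_mirna_evidence.tsv")))
    ml = tuple(load_interactions(_data_path("mirna_lncrna_evidence.tsv")))
    return ReferenceTables(shared, genes, disease, pm, ml)


def synthetic_signature_bridge() -> tuple[list[Signature], pd.DataFrame]:
    """SYNTHETIC deterministic SNP-level bridge between the shared-SNP list
    and the gene table.

    The SNP-resolution assignment of shared SNPs to signatures and genes
    is not part of the curated tables, so this bridge is a constructed stand-in: it
    allocates the curated rsIDs to six signatures (A–F) over four
    components and to the ten genes of ``gene_signatures.tsv`` so
    that every documented constraint holds — each gene's signature set
    matches the gene table (e.g. HLA-DQA1 from D, E, F), every reported
    gene has at least 3 SNPs, APOE has the fewest SNPs and HLA-DRB1 the
    most, rs6857 annotates AC011481.2, and ten chromosome-6 SNPs belong to
    no signature. Densities are nominal (1.0) because the underlying LD
    edges are likewise unavailable.

    Returns the signature list and an annotation table
    (variant_id, gene_symbol, gene_class, chrom).
    """
    fx = reference_tables()
    ids = list(fx.shared_snps["rsid"])
    chr19, chr6 = ids[:43], ids[43:]

    comp1 = chr19[:12]
    comp2 = chr19[12:]
    comp3 = chr6[:20]
    comp4 = chr6[20:]

    sig_members = {
        "A": comp1,  # whole first component
        "B": comp2,  # whole second component: every chr19 SNP is covered
        "C": comp3,  # whole third component
        "D": comp4[:24],
        "E": comp4[12:36],
        "F": comp4[22:44],
    }
    component_of = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 3, "F": 3}
    signatures = [
        Signature(
            signature_id=label,
            component_id=component_of[label],
            members=frozenset(members),
            density=1.0,
        )
        for label, members in sig_members.items()
    ]

    b, c, d = sig_members["B"], sig_members["C"], sig_members["D"]
    e, f = sig_members["E"], sig_members["F"]
    d_only = [s for s in d if s not in e and s not in f]
    f_only = [s for s in f if s not in d and s not in e]
    def_core = [s for s in d if s in e]  # D∩E; tail overlaps F
    gene_snps = {
        "NECTIN2": comp1[:8],
        "APOE": b[:3],
        # AC011481.2 takes 4 SNPs including rs6857 (index 17 -> comp2[4] -> b[4])
        "AC011481.2": b[3:7],
        "TOMM40": b[6:12],
        "APOC1": b[12:16],
        "AL662844.2": c[:4],
        "HLA-C": c[4:9],
        "HLA-DRB1": def_core[:10],
        "HLA-DQA1": def_core[8:12],  # last two lie in D∩E∩F
        "TSBP1-AS1": d_only[:2] + f_only[:2],
    }
    meta = fx.gene_signatures.set_index("gene_symbol")
    rows = [
        {
            "variant_id": snp,
            "gene_symbol": gene,
            "gene_class": meta.loc[gene, "gene_class"],
            "chrom": meta.loc[gene, "chrom"],
        }
        for gene, snps in gene_snps.items()
        for snp in snps
    ]
    annotation = pd.DataFrame(rows, columns=["variant_id", "gene_symbol", "gene_class", "chrom"])
    return signatures, annotation


def write_fixture_bundle(outdir) -> "Path":
    """Write a runnable input bundle from the curated tables.

    Produces signatures.tsv (from the synthetic SNP-level bridge),
    annotation.tsv, interactions_pm.tsv / interactions_ml.tsv,
    gene_disease.tsv, and a config.yaml with ``start_stage: signatures``
    (the GWAS and LD inputs behind the curated tables are not
    redistributable, so the pipeline starts at the signature stage).
    Returns the config path.
    """
    import yaml

    from .ld import signatures_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signatures, annotation = synthetic_signature_bridge()
    signatures_frame(signatures).to_csv(outdir / "signatures.tsv", sep="\t", index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    for src, dst in (
        ("protein_mirna_evidence.tsv", "interactions_pm.tsv"),
        ("mirna_lncrna_evidence.tsv", "interactions_ml.tsv"),
        ("gene_disease.tsv", "gene_disease.tsv"),
        ("shared_snps.tsv", "shared_snps.tsv"),
    ):
        (outdir / dst).write_text(_data_path(src).read_text())
    config = {
        "out_dir": str(outdir / "results"),
        "start_stage": "signatures",
        "signature_table": str(outdir / "signatures.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "interactions_pm": str(outdir / "interactions_pm.tsv"),
        "interactions_ml": str(outdir / "interactions_ml.tsv"),
        "gene_disease": str(outdir / "gene_disease.tsv"),
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return config_path
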