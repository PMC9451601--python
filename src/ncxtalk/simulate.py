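"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

The generator emits summary-level tables directly — two-trait GWAS
summary statistics with planted shared signals, an LD pair table with
planted dense blocks, a SNP→gene annotation, and hub-structured
interaction tables with corroborating-evidence codes — because the
pipeline, like the analysis it reimplements, consumes summaries rather
than genotypes. Ground truth (planted shared ids, block map, satellite
SNPs, genes that must survive the ≥3-SNP filter, hub selections, and
kept-edge sets under the validation rule) is emitted alongside so every
stage can be checked against what was planted.

Default study conditions: 5000 variants per trait with 127 planted shared
signals split over four LD blocks on two chromosomes (20+23 on "19",
40+37 on "6") plus 7 satellite SNPs with no qualifying LD partner;
planted raw p-values at most 1e-8 (conservative, below alpha/m); 2% of
null variants below the MAF floor; intra-block edge probability 0.95
against 0.02 between blocks, with in-block D' in [0.8, 1] and out-of-block
D' in [0, 0.6]; 15 hub miRNAs whose degree multiset ties at rank 10 (so
top-10 selection extends to 15) and 11 hub lncRNAs tying to 11; each edge
carries its primary evidence code plus each corroborating code
independently with probability 0.8.

All randomness flows through one ``numpy.random.default_rng(seed)``;
identical (seed, config) gives byte-identical TSVs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

GWAS_HEADER = ["variant", "rsid", "chr", "pos", "minor_AF", "beta", "se", "pval"]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_snps_per_trait: int = 5000
    n_shared_true: int = 127
    n_trait_specific: int = 50
    signal_p_max: float = 1e-8
    maf_low_fraction: float = 0.02
    block_sizes: tuple[int, ...] = (20, 23, 40, 37)
    block_chroms: tuple[str, ...] = ("19", "19", "6", "6")
    n_satellites: int = 7
    intra_block_edge_prob: float = 0.95
    inter_block_edge_prob: float = 0.02
    dprime_in_block: tuple[float, float] = (0.8, 1.0)
    dprime_out_block: tuple[float, float] = (0.0, 0.6)
    genes_per_block: int = 3
    gene_snp_counts: tuple[int, ...] = (4, 3, 2)  # per-block genes; last fails the >=3 filter
    n_mirnas: int = 60
    n_lncrnas: int = 80
    mirna_hub_degrees: tuple[int, ...] = (6, 6, 5, 5, 4, 4, 4, 3, 3, 3, 3, 3, 3, 3, 3)
    lncrna_hub_degrees: tuple[int, ...] = (12, 11, 10, 9, 8, 7, 6, 5, 4, 3, 3)
    evidence_corroboration_prob: float = 0.8

    def validate(self) -> None:
        probs = (
            self.maf_low_fraction,
            self.intra_block_edge_prob,
            self.inter_block_edge_prob,
            self.evidence_corroboration_prob,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if sum(self.block_sizes) + self.n_satellites > self.n_shared_true:
            raise ConfigurationError("block sizes plus satellites exceed n_shared_true")
        if self.n_shared_true + 2 * self.n_trait_specific > self.n_snps_per_trait:
            raise ConfigurationError("planted signals exceed n_snps_per_trait")
        if len(self.block_sizes) != len(self.block_chroms):
            raise ConfigurationError("block_sizes and block_chroms lengths differ")


def _variant_ids(n: int) -> list[str]:
    return [f"rs{9000000 + i}" for i in range(n)]


def generate_gwas_pair(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two trait tables (Neale-style columns) plus the planted shared-id list.

    Planted shared signals receive raw p <= signal_p_max in both traits;
    each trait additionally gets its own disjoint planted signals so the
    trait intersection is informative. A maf_low_fraction of null variants
    falls below the 0.001 MAF floor.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_snps_per_trait
    ids = _variant_ids(n)
    shared = ids[: config.n_shared_true]

    # chromosome labels: planted ids take their block chromosome
    chroms = np.array([str(c) for c in rng.integers(1, 23, size=n)], dtype=object)
    offset = 0
    for size, chrom in zip(config.block_sizes, config.block_chroms):
        chroms[offset : offset + size] = chrom
        offset += size
    if config.block_chroms:
        chroms[offset : offset + config.n_satellites] = config.block_chroms[-1]

    positions = np.sort(rng.integers(1, 50_000_000, size=n))
    tables = []
    for trait_idx in range(2):
        lo = config.n_shared_true + trait_idx * config.n_trait_specific
        hi = lo + config.n_trait_specific
        planted = set(range(config.n_shared_true)) | set(range(lo, hi))
        pvals = rng.uniform(0.0, 1.0, size=n)
        pvals = np.clip(pvals, 1e-300, 1.0)
        for i in planted:
            pvals[i] = rng.uniform(0.0, config.signal_p_max) or config.signal_p_max
        maf = rng.uniform(0.01, 0.5, size=n)
        null_idx = np.array(sorted(set(range(n)) - planted))
        n_low = int(round(config.maf_low_fraction * len(null_idx)))
        low_idx = rng.choice(null_idx, size=n_low, replace=False)
        maf[low_idx] = rng.uniform(0.0, 0.0009, size=n_low)
        beta = rng.normal(0.0, 0.05, size=n)
        se = np.abs(rng.normal(0.02, 0.005, size=n)) + 1e-4
        tables.append(
            pd.DataFrame(
                {
                    "variant": [f"{c}:{p}:A:G" for c, p in zip(chroms, positions)],
                    "rsid": ids,
                    "chr": chroms,
                    "pos": positions,
                    "minor_AF": np.round(maf, 6),
                    "beta": np.round(beta, 6),
                    "se": np.round(se, 6),
                    "pval": pvals,
                }
            )
        )
    return tables[0], tables[1], shared


def generate_ld_blocks(
    config: SimulationConfig,
    snps: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, int], list[str]]:
    """LD pair table over the planted shared SNPs, plus the block map.

    Intra-block pairs pass both edge thresholds with probability
    intra_block_edge_prob (a spanning path per block always passes, so each
    block is one connected component); inter-block and satellite pairs draw
    D' below 0.7 and so never form edges.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    block_map: dict[str, int] = {}
    blocks: list[list[str]] = []
    offset = 0
    for b, size in enumerate(config.block_sizes):
        members = snps[offset : offset + size]
        for snp in members:
            block_map[snp] = b
        blocks.append(members)
        offset += size
    satellites = snps[offset : offset + config.n_satellites]

    lo_in, hi_in = config.dprime_in_block
    lo_out, hi_out = config.dprime_out_block
    rows = []
    for b, members in enumerate(blocks):
        chrom = config.block_chroms[b]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                on_path = j == i + 1
                if on_path or rng.uniform() < config.intra_block_edge_prob:
                    dprime = rng.uniform(max(lo_in, 0.701), hi_in)
                    pval = rng.uniform(1e-12, 1e-6)
                else:
                    dprime = rng.uniform(lo_out, hi_out)
                    pval = rng.uniform(1e-3, 1.0)
                rows.append((members[i], members[j], chrom, dprime, 1.0 - dprime / 2, pval))
        # inter-block pairs on the same chromosome: present but sub-threshold
        for b2 in range(b + 1, len(blocks)):
            if config.block_chroms[b2] != chrom:
                continue
            for a in members:
                for c in blocks[b2]:
                    if rng.uniform() < config.inter_block_edge_prob:
                        rows.append(
                            (a, c, chrom, rng.uniform(lo_out, hi_out), 0.1, rng.uniform(0.001, 1.0))
                        )
    for sat in satellites:
        partner = blocks[-1][int(rng.integers(0, len(blocks[-1])))]
        rows.append(
            (sat, partner, config.block_chroms[-1], rng.uniform(0.0, 0.6), 0.1, rng.uniform(0.5, 1.0))
        )
    ld = pd.DataFrame(rows, columns=["snp_a", "snp_b", "chrom", "dprime", "r2", "pval"])
    ld["dprime"] = ld["dprime"].round(6)
    ld["r2"] = ld["r2"].round(6)
    return ld, block_map, satellites


def generate_annotation(
    config: SimulationConfig, block_map: dict[str, int]
) -> tuple[pd.DataFrame, dict]:
    """SNP→gene annotation over the planted blocks, plus gene ground truth.

    Each block hosts ``genes_per_block`` genes taking consecutive member
    SNPs with counts from ``gene_snp_counts``; classes cycle
    protein_coding/protein_coding/protein_coding/lncRNA so the surviving
    set mixes coding and non-coding genes. Truth lists the genes that must
    survive the >=3-SNP filter and the protein subset.
    """
    class_cycle = ("protein_coding", "protein_coding", "protein_coding", "lncRNA")
    blocks: dict[int, list[str]] = {}
    for snp, b in block_map.items():
        blocks.setdefault(b, []).append(snp)
    # preserve planting order (ids are generated in order)
    for b in blocks:
        blocks[b].sort(key=lambda s: int(s[2:]))

    rows = []
    surviving, proteins = [], []
    for b in sorted(blocks):
        members = blocks[b]
        chrom = config.block_chroms[b]
        start = 0
        for g in range(config.genes_per_block):
            count = config.gene_snp_counts[g % len(config.gene_snp_counts)]
            snps = members[start : start + count]
            start += count
            gene = f"GENE_B{b}_{g}"
            gene_class = class_cycle[(config.genes_per_block * b + g) % len(class_cycle)]
            for snp in snps:
                rows.append((snp, gene, gene_class, chrom))
            if len(snps) >= 3:
                surviving.append(gene)
                if gene_class == "protein_coding":
                    proteins.append(gene)
    annotation = pd.DataFrame(rows, columns=["variant_id", "gene_symbol", "gene_class", "chrom"])
    truth = {"surviving_genes": sorted(surviving), "protein_set": sorted(proteins)}
    return annotation, truth


def generate_interaction_tables(
    config: SimulationConfig,
    proteins: list[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Hub-structured protein–miRNA and miRNA–lncRNA interaction tables.

    Hub regulators receive planted degrees whose multiset ties at rank 10;
    non-hubs stay below the tie cutoff. Each edge carries the layer's
    primary evidence code plus each corroborating code independently with
    probability evidence_corroboration_prob. Truth records the hub lists
    and the edges that must survive validation.
    """
    if not proteins:
        raise ConfigurationError("protein list must be non-empty")
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 2)
    hub_deg = list(config.mirna_hub_degrees)
    if max(hub_deg) > len(proteins):
        raise ConfigurationError("mirna hub degree exceeds number of proteins")
    mirnas = [f"hsa-miR-{7000 + i}" for i in range(config.n_mirnas)]
    hubs_m = mirnas[: len(hub_deg)]
    pm_rows, pm_kept = [], []
    for idx, m in enumerate(mirnas):
        if idx < len(hub_deg):
            deg = hub_deg[idx]
        else:
            deg = int(rng.integers(1, min(3, len(proteins)) ))
        targets = list(rng.choice(proteins, size=deg, replace=False))
        for t in sorted(targets):
            codes = ["a"] + [
                c for c in "bcdef" if rng.uniform() < config.evidence_corroboration_prob
            ]
            pm_rows.append((m, t, "protein_mirna", ",".join(codes)))
            if len(codes) > 1:
                pm_kept.append([m, t])

    lnc_deg = list(config.lncrna_hub_degrees)
    if max(lnc_deg) > len(hubs_m):
        raise ConfigurationError("lncrna hub degree exceeds number of hub miRNAs")
    lncrnas = [f"LNC{i:04d}" for i in range(config.n_lncrnas)]
    ml_rows, ml_kept = [], []
    for idx, l in enumerate(lncrnas):
        if idx < len(lnc_deg):
            deg = lnc_deg[idx]
        else:
            deg = int(rng.integers(1, 3))
        targets = list(rng.choice(hubs_m, size=deg, replace=False))
        for t in sorted(targets):
            codes = ["S"] + (
                ["L"] if rng.uniform() < config.evidence_corroboration_prob else []
            )
            ml_rows.append((l, t, "mirna_lncrna", ",".join(codes)))
            if len(codes) > 1:
                ml_kept.append([l, t])

    pm = pd.DataFrame(pm_rows, columns=["regulator", "target", "layer", "evidence"])
    ml = pd.DataFrame(ml_rows, columns=["regulator", "target", "layer", "evidence"])
    truth = {
        "hub_mirnas": sorted(hubs_m),
        "hub_lncrnas": sorted(lncrnas[: len(lnc_deg)]),
        "pm_kept_edges": sorted(pm_kept),
        "ml_kept_edges": sorted(ml_kept),
    }
    return pm, ml, truth


def write_bundle(config: SimulationConfig, outdir) -> dict:
    """Write the full synthetic input bundle plus ``truth.json``.

    Files: gwas_a.tsv, gwas_b.tsv, ld_pairs.tsv, annotation.tsv,
    interactions_pm.tsv, interactions_ml.tsv, truth.json. Deterministic
    under (seed, config).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    gwas_a, gwas_b, shared = generate_gwas_pair(config, rng)
    ld, block_map, satellites = generate_ld_blocks(config, shared, rng)
    annotation, gene_truth = generate_annotation(config, block_map)
    pm, ml, net_truth = generate_interaction_tables(config, gene_truth["protein_set"], rng)

    gwas_a.to_csv(outdir / "gwas_a.tsv", sep="\t", index=False)
    gwas_b.to_csv(outdir / "gwas_b.tsv", sep="\t", index=False)
    ld.to_csv(outdir / "ld_pairs.tsv", sep="\t", index=False)
    annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
    pm.to_csv(outdir / "interactions_pm.tsv", sep="\t", index=False)
    ml.to_csv(outdir / "interactions_ml.tsv", sep="\t", index=False)

    truth = {
        "config": asdict(config),
        "planted_shared": shared,
        "block_map": block_map,
        "satellites": satellites,
        **gene_truth,
        **net_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
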