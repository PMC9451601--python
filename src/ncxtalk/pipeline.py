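"""Stage orchestration: deterministic artifacts, manifests, and run-all.

Stages: gwas-select -> ld-graph -> signatures -> map-genes -> networks ->
validate -> score. Each stage reads the artifacts of its upstream stage
from the output directory (or the configured input tables), writes its
outputs under ``<out_dir>/<stage>/`` together with a manifest (parameters,
input/output content hashes, record counts), and is byte-identical on
rerun with identical inputs. Bundles that start from curated signature
tables rather than raw GWAS files set ``start_stage: signatures``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genes as genes_mod
from . import gwas as gwas_mod
from . import ld as ld_mod
from . import networks as net_mod
from . import scoring as score_mod
from .errors import ConfigurationError, MissingArtifactError

logger = logging.getLogger(__name__)

STAGES = ("gwas-select", "ld-graph", "signatures", "map-genes", "networks", "validate", "score")


@dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds; defaults follow the study design."""

    out_dir: str = "results"
    gwas_a: list[str] = field(default_factory=list)
    gwas_b: list[str] = field(default_factory=list)
    ld_pairs: str | None = None
    annotation: str | None = None
    interactions_pm: str | None = None
    interactions_ml: str | None = None
    gene_disease: str | None = None
    signature_table: str | None = None  # used when start_stage == "signatures"
    start_stage: str = "gwas-select"
    maf_threshold: float = 0.001
    alpha: float = 0.05
    combine_policy: str = "union"
    dprime_threshold: float = 0.7
    ld_p_threshold: float = 1e-4
    min_fraction: float = 0.2
    density_threshold: float = 0.8
    min_size_rounding: str = "ceil"
    min_snps_per_gene: int = 3
    top_k: int = 10
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (0 <= self.maf_threshold <= 0.5, "maf_threshold in [0, 0.5]"),
            (0 < self.alpha < 1, "alpha in (0, 1)"),
            (0 <= self.dprime_threshold <= 1, "dprime_threshold in [0, 1]"),
            (0 < self.ld_p_threshold <= 1, "ld_p_threshold in (0, 1]"),
            (0 < self.min_fraction <= 1, "min_fraction in (0, 1]"),
            (0 < self.density_threshold <= 1, "density_threshold in (0, 1]"),
            (self.min_snps_per_gene >= 1, "min_snps_per_gene >= 1"),
            (self.top_k >= 1, "top_k >= 1"),
            (self.combine_policy in ("union", "intersection", "single"), "combine_policy"),
            (self.min_size_rounding in ("ceil", "floor", "round"), "min_size_rounding"),
            (self.start_stage in STAGES, "start_stage"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigurationError(f"invalid config: {name}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_dir(config: PipelineConfig, stage: str) -> Path:
    d = Path(config.out_dir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(path, stage: str, producer: str) -> Path:
    if path is None or not Path(path).exists():
        raise MissingArtifactError(
            f"stage {stage!r} requires {path!r}; run stage {producer!r} or supply it"
        )
    return Path(path)


def _write_manifest(stage_dir: Path, params: dict, inputs: list[Path], counts: dict) -> None:
    outputs = sorted(
        p for p in stage_dir.iterdir() if p.name != "manifest.json" and p.is_file()
    )
    manifest = {
        "parameters": params,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
        "counts": counts,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def stage_gwas_select(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "gwas-select")
    inputs = [
        _require(p, "gwas-select", "(input)") for p in [*config.gwas_a, *config.gwas_b]
    ]
    if not config.gwas_a or not config.gwas_b:
        raise MissingArtifactError("stage 'gwas-select' requires gwas_a and gwas_b tables")
    selected = {}
    chrom_of: dict[str, str] = {}
    for label, paths in (("A", config.gwas_a), ("B", config.gwas_b)):
        tables = [gwas_mod.load_gwas_table(p) for p in paths]
        for t in tables:
            chrom_of.update(zip(t["variant_id"], t["chrom"].astype(str)))
        dataset = gwas_mod.TraitDataset(label, tables, config.combine_policy)
        ids = gwas_mod.combine_trait_files(dataset, config.alpha, config.maf_threshold)
        selected[label] = ids
        pd.DataFrame(sorted(ids), columns=["variant_id"]).to_csv(
            stage_dir / f"significant_{label}.tsv", sep="\t", index=False
        )
    shared = gwas_mod.intersect_traits(selected["A"], selected["B"])
    pd.DataFrame(
        {"variant_id": shared, "chrom": [chrom_of.get(v, "") for v in shared]}
    ).to_csv(stage_dir / "shared_snps.tsv", sep="\t", index=False)
    counts = {
        "significant_A": len(selected["A"]),
        "significant_B": len(selected["B"]),
        "shared": len(shared),
    }
    _write_manifest(
        stage_dir,
        {
            "maf_threshold": config.maf_threshold,
            "alpha": config.alpha,
            "combine_policy": config.combine_policy,
        },
        inputs,
        counts,
    )
    return counts


def _load_shared(config: PipelineConfig) -> dict[str, str]:
    path = _require(
        Path(config.out_dir) / "gwas-select" / "shared_snps.tsv", "ld-graph", "gwas-select"
    )
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["variant_id"], df["chrom"]))


def stage_ld_graph(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "ld-graph")
    ld_path = _require(config.ld_pairs, "ld-graph", "(input)")
    snps = _load_shared(config)
    graph = ld_mod.build_snp_graph(
        snps, ld_mod.load_ld_table(ld_path), config.dprime_threshold, config.ld_p_threshold
    )
    comps = ld_mod.connected_components(graph)
    ld_mod.export_graph(graph, [], stage_dir / "snp_graph")
    pd.DataFrame(
        [
            {"component_id": i, "size": len(c), "members": ";".join(sorted(c))}
            for i, c in enumerate(comps)
        ]
    ).to_csv(stage_dir / "components.tsv", sep="\t", index=False)
    counts = {
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "components": len(comps),
    }
    _write_manifest(
        stage_dir,
        {"dprime_threshold": config.dprime_threshold, "ld_p_threshold": config.ld_p_threshold},
        [ld_path],
        counts,
    )
    return counts


def stage_signatures(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "signatures")
    if config.start_stage == "signatures":
        # curated signature table supplied directly
        sig_path = _require(config.signature_table, "signatures", "(input)")
        df = pd.read_csv(sig_path, sep="\t", dtype={"signature_id": str})
        df.to_csv(stage_dir / "signatures.tsv", sep="\t", index=False)
        _write_manifest(stage_dir, {"source": "curated"}, [sig_path], {"signatures": len(df)})
        return {"signatures": len(df)}
    ld_path = _require(config.ld_pairs, "signatures", "(input)")
    snps = _load_shared(config)
    graph = ld_mod.build_snp_graph(
        snps, ld_mod.load_ld_table(ld_path), config.dprime_threshold, config.ld_p_threshold
    )
    comps = ld_mod.connected_components(graph)
    sigs = ld_mod.extract_signatures(
        comps, graph, config.min_fraction, config.density_threshold, config.min_size_rounding
    )
    ld_mod.signatures_frame(sigs).to_csv(stage_dir / "signatures.tsv", sep="\t", index=False)
    unassigned = sorted(
        snp for i, comp in enumerate(comps)
        for snp in ld_mod.unassigned_snps(comp, [s for s in sigs if s.component_id == i])
    )
    pd.DataFrame(unassigned, columns=["variant_id"]).to_csv(
        stage_dir / "unassigned.tsv", sep="\t", index=False
    )
    ld_mod.export_graph(graph, sigs, stage_dir / "snp_graph")
    counts = {"signatures": len(sigs), "unassigned": len(unassigned)}
    _write_manifest(
        stage_dir,
        {
            "min_fraction": config.min_fraction,
            "density_threshold": config.density_threshold,
            "rounding": config.min_size_rounding,
        },
        [ld_path],
        counts,
    )
    return counts


def _load_signatures(config: PipelineConfig) -> list[ld_mod.Signature]:
    path = _require(
        Path(config.out_dir) / "signatures" / "signatures.tsv", "map-genes", "signatures"
    )
    df = pd.read_csv(path, sep="\t", dtype={"signature_id": str})
    return [
        ld_mod.Signature(
            signature_id=str(r.signature_id),
            component_id=int(r.component_id),
            members=frozenset(str(r.members).split(";")),
            density=float(getattr(r, "density", 1.0)),
        )
        for r in df.itertuples(index=False)
    ]


def stage_map_genes(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "map-genes")
    ann_path = _require(config.annotation, "map-genes", "(input)")
    sigs = _load_signatures(config)
    annotation = genes_mod.load_annotation(ann_path)
    gene_map = genes_mod.filter_genes_min_snps(
        genes_mod.map_signatures_to_genes(sigs, annotation), config.min_snps_per_gene
    )
    summaries = genes_mod.summarize_genes(gene_map, annotation)
    genes_mod.summaries_frame(summaries).to_csv(
        stage_dir / "genes.tsv", sep="\t", index=False
    )
    proteins = genes_mod.select_protein_set(summaries)
    pd.DataFrame(proteins, columns=["gene_symbol"]).to_csv(
        stage_dir / "proteins.tsv", sep="\t", index=False
    )
    if config.gene_disease:
        records = pd.read_csv(config.gene_disease, sep="\t")
        genes_mod.disease_association_report(proteins, records).to_csv(
            stage_dir / "gene_disease.tsv", sep="\t", index=False
        )
    counts = {"genes": len(summaries), "proteins": len(proteins)}
    _write_manifest(
        stage_dir, {"min_snps_per_gene": config.min_snps_per_gene}, [ann_path], counts
    )
    return counts


def _load_proteins(config: PipelineConfig) -> list[str]:
    path = _require(
        Path(config.out_dir) / "map-genes" / "proteins.tsv", "networks", "map-genes"
    )
    return list(pd.read_csv(path, sep="\t", dtype=str)["gene_symbol"])


def stage_networks(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "networks")
    pm_path = _require(config.interactions_pm, "networks", "(input)")
    ml_path = _require(config.interactions_ml, "networks", "(input)")
    proteins = _load_proteins(config)

    pm_records = net_mod.load_interactions(pm_path, "protein_mirna")
    pm_net = net_mod.build_bipartite(pm_records, proteins, "protein_mirna")
    m_degrees = net_mod.degree_table(pm_net, "right")
    selected_m = net_mod.top_degree_with_ties(m_degrees, config.top_k)
    net_mod.degrees_frame(m_degrees).to_csv(stage_dir / "mirna_degrees.tsv", sep="\t", index=False)
    pd.DataFrame(selected_m, columns=["mirna"]).to_csv(
        stage_dir / "selected_mirnas.tsv", sep="\t", index=False
    )

    ml_records = net_mod.load_interactions(ml_path, "mirna_lncrna")
    ml_net = net_mod.build_bipartite(ml_records, selected_m, "mirna_lncrna")
    l_degrees = net_mod.degree_table(ml_net, "right")
    selected_l = net_mod.top_degree_with_ties(l_degrees, config.top_k)
    net_mod.degrees_frame(l_degrees).to_csv(stage_dir / "lncrna_degrees.tsv", sep="\t", index=False)
    pd.DataFrame(selected_l, columns=["lncrna"]).to_csv(
        stage_dir / "selected_lncrnas.tsv", sep="\t", index=False
    )
    counts = {
        "mirnas_in_network": len(pm_net.right_nodes),
        "selected_mirnas": len(selected_m),
        "lncrnas_in_network": len(ml_net.right_nodes),
        "selected_lncrnas": len(selected_l),
    }
    _write_manifest(stage_dir, {"top_k": config.top_k}, [pm_path, ml_path], counts)
    return counts


def _load_selection(config: PipelineConfig, name: str, column: str) -> list[str]:
    path = _require(
        Path(config.out_dir) / "networks" / name, "validate", "networks"
    )
    return list(pd.read_csv(path, sep="\t", dtype=str)[column])


def stage_validate(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "validate")
    pm_path = _require(config.interactions_pm, "validate", "(input)")
    ml_path = _require(config.interactions_ml, "validate", "(input)")
    proteins = set(_load_proteins(config))
    selected_m = set(_load_selection(config, "selected_mirnas.tsv", "mirna"))
    selected_l = set(_load_selection(config, "selected_lncrnas.tsv", "lncrna"))

    pm_kept = net_mod.validate_edges(
        [
            r
            for r in net_mod.load_interactions(pm_path, "protein_mirna")
            if r.target in proteins and r.regulator in selected_m
        ]
    )
    ml_kept = net_mod.validate_edges(
        [
            r
            for r in net_mod.load_interactions(ml_path, "mirna_lncrna")
            if r.target in selected_m and r.regulator in selected_l
        ]
    )
    for name, kept in (("kept_pm.tsv", pm_kept), ("kept_ml.tsv", ml_kept)):
        pd.DataFrame(
            [
                {
                    "regulator": r.regulator,
                    "target": r.target,
                    "layer": r.layer,
                    "evidence": ",".join(sorted(r.evidence)),
                }
                for r in sorted(kept, key=lambda r: (r.regulator, r.target))
            ],
            columns=["regulator", "target", "layer", "evidence"],
        ).to_csv(stage_dir / name, sep="\t", index=False)
    counts = {"pm_kept": len(pm_kept), "ml_kept": len(ml_kept)}
    _write_manifest(stage_dir, {}, [pm_path, ml_path], counts)
    return counts


def stage_score(config: PipelineConfig) -> dict:
    stage_dir = _stage_dir(config, "score")
    val_dir = Path(config.out_dir) / "validate"
    pm_path = _require(val_dir / "kept_pm.tsv", "score", "validate")
    ml_path = _require(val_dir / "kept_ml.tsv", "score", "validate")
    proteins = _load_proteins(config)
    selected_m = _load_selection(config, "selected_mirnas.tsv", "mirna")
    selected_l = _load_selection(config, "selected_lncrnas.tsv", "lncrna")
    network = score_mod.assemble_tripartite(
        net_mod.load_interactions(pm_path),
        net_mod.load_interactions(ml_path),
        proteins,
        selected_m,
        selected_l,
    )
    rows = score_mod.rank_and_flag(network)
    score_mod.export_results(rows, network, stage_dir)
    counts = score_mod.network_summary(network)
    _write_manifest(stage_dir, {}, [pm_path, ml_path], counts)
    return counts


_STAGE_FUNCS = {
    "gwas-select": stage_gwas_select,
    "ld-graph": stage_ld_graph,
    "signatures": stage_signatures,
    "map-genes": stage_map_genes,
    "networks": stage_networks,
    "validate": stage_validate,
    "score": stage_score,
}


def run_stage(stage_name: str, config: PipelineConfig) -> dict:
    """Run one named stage and return its count summary."""
    if stage_name not in _STAGE_FUNCS:
        raise ConfigurationError(f"unknown stage {stage_name!r}; one of {STAGES}")
    config.validate()
    logger.info("running stage %s", stage_name)
    return _STAGE_FUNCS[stage_name](config)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage from ``config.start_stage`` onward; consolidated summary."""
    config.validate()
    start = STAGES.index(config.start_stage)
    summary: dict[str, dict] = {}
    for stage in STAGES[start:]:
        summary[stage] = run_stage(stage, config)
    out = Path(config.out_dir) / "run_summary.json"
    with open(out, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
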