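"""Bipartite regulatory networks, hub selection, and evidence validation.

Two layers are built from interaction tables: protein–miRNA (regulator =
miRNA, target = protein) and miRNA–lncRNA (regulator = lncRNA, target =
miRNA). The top-10-by-degree regulators are selected with tie extension
(every node tied with the 10th-ranked degree is kept, so more than 10 may
be chosen). Edges originate from a primary database and are kept only when
corroborated by at least one further database: codes b/c/d/e/f
(miRWalk, TargetScan, miRanda-via-starBase, miRmap, microT) against primary
code a (starBase) for protein–miRNA, and code L (LncBase) against primary
code S (starBase) for miRNA–lncRNA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, DataValidationError

logger = logging.getLogger(__name__)

LAYERS = ("protein_mirna", "mirna_lncrna")

#: per-layer originating database code and corroborating codes
PRIMARY_CODE = {"protein_mirna": "a", "mirna_lncrna": "S"}
VALIDATION_CODES = {
    "protein_mirna": frozenset("bcdef"),
    "mirna_lncrna": frozenset("L"),
}


@dataclass(frozen=True)
class InteractionRecord:
    """A directed regulatory edge with its database-evidence codes."""

    regulator: str
    target: str
    layer: str
    evidence: frozenset[str]


@dataclass(frozen=True)
class BipartiteNetwork:
    left_nodes: frozenset[str]
    right_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]


_MIR_PATTERN = re.compile(r"^(hsa-)?(mir|let)", re.IGNORECASE)


def normalize_mirna(name: str) -> str:
    """Canonical miRNA name: 'hsa-' prefix, 'miR'/'let' casing, rest lowered."""
    name = name.strip()
    if not _MIR_PATTERN.match(name):
        return name
    lowered = name.lower()
    if not lowered.startswith("hsa-"):
        lowered = "hsa-" + lowered
    return lowered.replace("mir", "miR", 1).replace("hsa-let", "hsa-let", 1)


def load_interactions(path, layer: str | None = None) -> list[InteractionRecord]:
    """Read an interaction TSV (regulator, target, layer, evidence comma-joined)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("regulator", "target", "layer", "evidence"):
        if col not in df.columns:
            raise ConfigurationError(f"interaction table {path} lacks column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        if layer is not None and row.layer != layer:
            continue
        if row.layer not in LAYERS:
            raise DataValidationError(f"unknown interaction layer {row.layer!r}")
        regulator, target = str(row.regulator), str(row.target)
        if row.layer == "protein_mirna":
            regulator = normalize_mirna(regulator)
        else:
            target = normalize_mirna(target)
        codes = frozenset(c.strip() for c in str(row.evidence).split(",") if c.strip())
        if not codes:
            raise DataValidationError(
                f"interaction {regulator} -> {target} has empty evidence"
            )
        records.append(InteractionRecord(regulator, target, str(row.layer), codes))
    return records


def build_bipartite(
    records: Sequence[InteractionRecord], left_ids: Iterable[str], layer: str
) -> BipartiteNetwork:
    """Bipartite network with ``left_ids`` as targets and regulators on the right.

    Records of other layers or targeting unknown left nodes are skipped
    with a warning; duplicate pairs collapse to one edge.
    """
    left = frozenset(left_ids)
    edges: set[tuple[str, str]] = set()
    n_skipped = 0
    for rec in records:
        if rec.layer != layer:
            continue
        if rec.target not in left:
            n_skipped += 1
            continue
        edges.add((rec.target, rec.regulator))
    if n_skipped:
        logger.warning("skipped %d records targeting unknown left nodes", n_skipped)
    right = frozenset(r for _, r in edges)
    return BipartiteNetwork(left, right, frozenset(edges))


def degree_table(network: BipartiteNetwork, side: str) -> dict[str, int]:
    """Degree per node on one side; zero-degree nodes included."""
    if side == "left":
        nodes, idx = network.left_nodes, 0
    elif side == "right":
        nodes, idx = network.right_nodes, 1
    else:
        raise ConfigurationError(f"side must be 'left' or 'right', got {side!r}")
    degrees = {n: 0 for n in nodes}
    for edge in network.edges:
        degrees[edge[idx]] += 1
    return degrees


def top_degree_with_ties(degrees: Mapping[str, int], k: int = 10) -> list[str]:
    """Nodes with degree >= the k-th largest degree (cutoff ties all kept).

    Ordered by descending degree, then node id. May return more than k
    nodes; returns all nodes (with a warning) when fewer than k exist.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    ranked = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    if len(ranked) <= k:
        if len(ranked) < k:
            logger.warning("only %d nodes available for top-%d selection", len(ranked), k)
        return [node for node, _ in ranked]
    cutoff = ranked[k - 1][1]
    return [node for node, deg in ranked if deg >= cutoff]


def validate_edges(
    records: Sequence[InteractionRecord],
    primary_code: str | None = None,
    validation_codes: frozenset[str] | None = None,
) -> list[InteractionRecord]:
    """Keep records corroborated by at least one database beyond the primary.

    Defaults per layer come from :data:`PRIMARY_CODE` and
    :data:`VALIDATION_CODES`. A record lacking its primary code indicates an
    inconsistent source table and raises.
    """
    kept = []
    for rec in records:
        primary = primary_code if primary_code is not None else PRIMARY_CODE[rec.layer]
        codes = (
            validation_codes
            if validation_codes is not None
            else VALIDATION_CODES[rec.layer]
        )
        if primary not in rec.evidence:
            raise DataValidationError(
                f"interaction {rec.regulator} -> {rec.target} lacks primary "
                f"evidence code {primary!r}"
            )
        if rec.evidence & codes:
            kept.append(rec)
    return kept


def induced_subnetwork(network: BipartiteNetwork, keep_right: Iterable[str]) -> BipartiteNetwork:
    """Restrict the right side; the left side is unchanged."""
    keep = frozenset(keep_right)
    edges = frozenset(e for e in network.edges if e[1] in keep)
    return BipartiteNetwork(network.left_nodes, keep & network.right_nodes, edges)


def degrees_frame(degrees: Mapping[str, int]) -> pd.DataFrame:
    rows = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    return pd.DataFrame(rows, columns=["node", "degree"])
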