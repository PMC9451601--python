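"""Tripartite network assembly and miRNA/lncRNA biomarker scoring.

With P the protein layer (N_P = |P|), a miRNA's score is the fraction of
proteins it regulates, S(m) = |{p : (p, m) in pm_edges}| / N_P, and a
lncRNA's score is the sum of the scores of the miRNAs it regulates,
S(l) = sum_{m : (m, l) in ml_edges} S(m). Scores are computed in exact
rational arithmetic (denominator N_P), so ranking and the identity
sum_m S(m) = |pm_edges| / N_P are tolerance-free; decimals are rendered at
4 places for reports. Entities are flagged significant when their score
strictly exceeds the mean of their kind; miRNAs additionally when the
score strictly exceeds 1/2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import DataValidationError
from .networks import InteractionRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TripartiteNetwork:
    """Protein / miRNA / lncRNA layers with inter-layer edges only."""

    proteins: frozenset[str]
    mirnas: frozenset[str]
    lncrnas: frozenset[str]
    pm_edges: frozenset[tuple[str, str]]  # (protein, miRNA)
    ml_edges: frozenset[tuple[str, str]]  # (miRNA, lncRNA)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)


@dataclass(frozen=True)
class ScoreRow:
    entity: str
    kind: str  # "miRNA" | "lncRNA"
    neighbor_count: int
    score: Fraction
    above_average: bool
    above_half: bool | None  # miRNA only


def assemble_tripartite(
    pm_records: Sequence[InteractionRecord],
    ml_records: Sequence[InteractionRecord],
    proteins: Iterable[str],
    mirnas: Iterable[str],
    lncrnas: Iterable[str],
) -> TripartiteNetwork:
    """Assemble the validated tripartite network.

    All selected nodes are retained even with zero validated edges in one
    layer; edges referencing unselected nodes are dropped with a warning.
    """
    p, m, l = frozenset(proteins), frozenset(mirnas), frozenset(lncrnas)
    if not p:
        raise DataValidationError("tripartite network requires a non-empty protein layer")
    pm, ml = set(), set()
    n_dropped = 0
    for rec in pm_records:
        if rec.target in p and rec.regulator in m:
            pm.add((rec.target, rec.regulator))
        else:
            n_dropped += 1
    for rec in ml_records:
        if rec.target in m and rec.regulator in l:
            ml.add((rec.target, rec.regulator))
        else:
            n_dropped += 1
    if n_dropped:
        logger.warning("dropped %d edges referencing unselected nodes", n_dropped)
    return TripartiteNetwork(p, m, l, frozenset(pm), frozenset(ml))


def score_mirna(network: TripartiteNetwork, m: str) -> Fraction:
    """Protein-partner count over N_P, as an exact rational."""
    if m not in network.mirnas:
        raise KeyError(f"miRNA {m!r} not in the tripartite network")
    n_partners = sum(1 for p, mm in network.pm_edges if mm == m)
    return Fraction(n_partners, network.n_proteins)


def score_lncrna(network: TripartiteNetwork, l: str) -> Fraction:
    """Sum of the scores of the miRNAs regulated by lncRNA ``l``."""
    if l not in network.lncrnas:
        raise KeyError(f"lncRNA {l!r} not in the tripartite network")
    partners = [m for m, ll in network.ml_edges if ll == l]
    return sum((score_mirna(network, m) for m in partners), Fraction(0))


def rank_and_flag(network: TripartiteNetwork) -> list[ScoreRow]:
    """Score all ncRNAs, sort within kind by descending score, and flag.

    ``above_average`` is strict (> mean of the kind); ``above_half`` (miRNA
    only) is strict (> 1/2). Ties order lexicographically.
    """
    rows: list[ScoreRow] = []
    for kind, entities, score_fn, edge_idx in (
        ("miRNA", network.mirnas, score_mirna, 1),
        ("lncRNA", network.lncrnas, score_lncrna, 1),
    ):
        scored = {e: score_fn(network, e) for e in entities}
        if not scored:
            continue
        mean = sum(scored.values(), Fraction(0)) / len(scored)
        edges = network.pm_edges if kind == "miRNA" else network.ml_edges
        for entity in sorted(entities, key=lambda e: (-scored[e], e)):
            n_neigh = sum(1 for edge in edges if edge[edge_idx] == entity)
            rows.append(
                ScoreRow(
                    entity=entity,
                    kind=kind,
                    neighbor_count=n_neigh,
                    score=scored[entity],
                    above_average=scored[entity] > mean,
                    above_half=(scored[entity] > Fraction(1, 2)) if kind == "miRNA" else None,
                )
            )
    return rows


def scores_frame(rows: Sequence[ScoreRow]) -> pd.DataFrame:
    """Tabular score view with exact fraction and 4-place decimal."""
    data = [
        {
            "entity": r.entity,
            "kind": r.kind,
            "neighbor_count": r.neighbor_count,
            "score_fraction": f"{r.score.numerator}/{r.score.denominator}",
            "score_decimal": round(float(r.score), 4),
            "above_average": r.above_average,
            "above_half": "" if r.above_half is None else r.above_half,
        }
        for r in rows
    ]
    return pd.DataFrame(
        data,
        columns=[
            "entity",
            "kind",
            "neighbor_count",
            "score_fraction",
            "score_decimal",
            "above_average",
            "above_half",
        ],
    )


def network_summary(network: TripartiteNetwork) -> dict:
    return {
        "n_proteins": len(network.proteins),
        "n_mirnas": len(network.mirnas),
        "n_lncrnas": len(network.lncrnas),
        "pm_edge_count": len(network.pm_edges),
        "ml_edge_count": len(network.ml_edges),
    }


def export_results(rows: Sequence[ScoreRow], network: TripartiteNetwork, outdir) -> None:
    """Write the score TSV, a layered GraphML, and a JSON run summary."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scores_frame(rows).to_csv(outdir / "scores.tsv", sep="\t", index=False)

    graph = nx.Graph()
    for layer, nodes in (
        ("protein", network.proteins),
        ("miRNA", network.mirnas),
        ("lncRNA", network.lncrnas),
    ):
        for node in sorted(nodes):
            graph.add_node(node, layer=layer)
    for p, m in sorted(network.pm_edges):
        graph.add_edge(p, m)
    for m, l in sorted(network.ml_edges):
        graph.add_edge(m, l)
    nx.write_graphml(graph, outdir / "tripartite.graphml")

    with open(outdir / "summary.json", "w") as fh:
        json.dump(network_summary(network), fh, indent=2, sort_keys=True)
        fh.write("\n")
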