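"""LD-threshold SNP graph and dense-subgraph (quasi-clique) signatures.

Edges join same-chromosome SNP pairs with D' strictly above 0.7 and an LD
test p-value strictly below 1e-4. Within each connected component we
enumerate inclusion-maximal vertex sets whose induced edge density
2|E(S)| / (|S|(|S|-1)) meets a threshold (default 0.8) and whose size is at
least a fraction (default 20%) of the component; those vertex sets are the
SNP signatures. A SNP may belong to several overlapping signatures, or to
none.

Enumeration is exact (exhaustive over subsets) for components with at most
``exhaustive_limit`` nodes, and clique-seeded greedy expansion above that:
a deterministic, bounded set of maximal-clique seeds (plus one
degeneracy-peeling core per component) is grown by repeatedly adding the
neighbouring node with the most links into the current set — the node that
maximizes the resulting density — while the density stays above threshold;
results are deduplicated to inclusion-maximal sets. Both routes are
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, islice
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

LD_COLUMNS = ["snp_a", "snp_b", "chrom", "dprime", "r2", "pval"]


@dataclass(frozen=True)
class Signature:
    """A dense SNP subgraph within one connected component."""

    signature_id: str
    component_id: int
    members: frozenset[str]
    density: float

    @property
    def size(self) -> int:
        return len(self.members)


def load_ld_table(path) -> pd.DataFrame:
    """Read an LD pair TSV (snp_a, snp_b, chrom, dprime, r2, pval)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str, "chrom": str})
    missing = [c for c in LD_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"LD table {path} lacks columns {missing}")
    return df[LD_COLUMNS]


def build_snp_graph(
    snps: Mapping[str, str],
    ld_pairs: pd.DataFrame,
    dprime_threshold: float = 0.7,
    p_threshold: float = 1e-4,
) -> nx.Graph:
    """SNP graph over ``snps`` (id -> chromosome label).

    An edge is added iff D' > dprime_threshold (strict), p < p_threshold
    (strict), and both endpoints sit on the same chromosome. Pairs naming
    unknown SNPs or spanning chromosomes are rejected with a warning.
    """
    graph = nx.Graph()
    for snp in sorted(snps):
        graph.add_node(snp, chrom=str(snps[snp]))
    n_rejected = 0
    for row in ld_pairs.itertuples(index=False):
        a, b = str(row.snp_a), str(row.snp_b)
        if a not in graph or b not in graph or a == b:
            n_rejected += 1
            continue
        if graph.nodes[a]["chrom"] != graph.nodes[b]["chrom"]:
            n_rejected += 1
            continue
        if row.dprime > dprime_threshold and row.pval < p_threshold:
            graph.add_edge(a, b, dprime=float(row.dprime), pval=float(row.pval))
    if n_rejected:
        logger.warning("rejected %d LD pairs (unknown node or cross-chromosome)", n_rejected)
    return graph


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Components ordered by descending size, then smallest member id."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def density(graph: nx.Graph, members: Iterable[str]) -> float:
    """Induced edge density 2|E(S)| / (|S|(|S|-1)); 1.0 for singletons."""
    members = set(members)
    n = len(members)
    if n < 2:
        return 1.0
    m = graph.subgraph(members).number_of_edges()
    return 2.0 * m / (n * (n - 1))


def _maximal_only(sets: list[frozenset[str]]) -> list[frozenset[str]]:
    """Keep inclusion-maximal sets; input need not be ordered."""
    ordered = sorted(sets, key=lambda s: (-len(s), tuple(sorted(s))))
    kept: list[frozenset[str]] = []
    for cand in ordered:
        if not any(cand < k for k in kept):
            if cand not in kept:
                kept.append(cand)
    return kept


def enumerate_dense_subgraphs(
    component: nx.Graph,
    density_threshold: float,
    min_size: int,
    exhaustive_limit: int = 15,
    max_seeds: int = 64,
) -> list[frozenset[str]]:
    """Inclusion-maximal vertex sets with density >= threshold and size >= min_size.

    Returned in deterministic order: descending size, then lexicographic.
    Components smaller than ``min_size`` yield an empty list. Above
    ``exhaustive_limit`` nodes the search is heuristic: at most
    ``max_seeds`` maximal cliques (dense graphs have exponentially many)
    plus a degeneracy-peeling core are expanded greedily.
    """
    if min_size < 2:
        raise ConfigurationError(f"min_size must be >= 2, got {min_size}")
    if not 0 < density_threshold <= 1:
        raise ConfigurationError(
            f"density_threshold must be in (0, 1], got {density_threshold}"
        )
    nodes = sorted(component.nodes)
    if len(nodes) < min_size:
        return []
    if len(nodes) <= exhaustive_limit:
        qualifying = [
            frozenset(sub)
            for size in range(min_size, len(nodes) + 1)
            for sub in combinations(nodes, size)
            if density(component, sub) >= density_threshold
        ]
        return _maximal_only(qualifying)

    seeds = [set(c) for c in islice(nx.find_cliques(component), max_seeds)]
    core = _peel_core(component, density_threshold, min_size)
    if core:
        seeds.append(set(core))
    candidates: set[frozenset[str]] = set()
    for seed in seeds:
        grown = _greedy_expand(component, seed, density_threshold)
        if len(grown) >= min_size and density(component, grown) >= density_threshold:
            candidates.add(frozenset(grown))
    return _maximal_only(list(candidates))


def _peel_core(graph: nx.Graph, threshold: float, min_size: int) -> frozenset[str] | None:
    """Largest qualifying set found by iteratively peeling the min-degree node."""
    remaining = set(graph.nodes)
    degree = {n: graph.degree(n) for n in remaining}
    best: frozenset[str] | None = None
    while len(remaining) >= min_size:
        if best is None and density(graph, remaining) >= threshold:
            best = frozenset(remaining)  # first (largest) qualifying set
        victim = min(remaining, key=lambda n: (degree[n], n))
        remaining.discard(victim)
        for nbr in graph.neighbors(victim):
            if nbr in remaining:
                degree[nbr] -= 1
    return best


def _greedy_expand(graph: nx.Graph, seed: set[str], threshold: float) -> set[str]:
    """Grow a seed by the neighbour with most links into it while density >= threshold.

    Adding the max-links neighbour is exactly the density-maximizing step;
    link counts are maintained incrementally so each step costs O(degree).
    Ties break lexicographically.
    """
    current = set(seed)
    links: dict[str, int] = {}
    for member in current:
        for nbr in graph.neighbors(member):
            if nbr not in current:
                links[nbr] = links.get(nbr, 0) + 1
    n_edges = graph.subgraph(current).number_of_edges()
    while links:
        best = min(links, key=lambda n: (-links[n], n))
        s = len(current)
        new_density = 2.0 * (n_edges + links[best]) / ((s + 1) * s)
        if new_density < threshold:
            return current
        n_edges += links.pop(best)
        current.add(best)
        for nbr in graph.neighbors(best):
            if nbr not in current:
                links[nbr] = links.get(nbr, 0) + 1
    return current


def _labels() -> Iterable[str]:
    """A, B, ..., Z, AA, AB, ... deterministic signature labels."""
    import itertools
    import string

    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def min_signature_size(
    component_size: int, min_fraction: float = 0.2, rounding: str = "ceil"
) -> int:
    """Smallest admissible signature size for a component (never below 2)."""
    raw = min_fraction * component_size
    if rounding == "ceil":
        value = math.ceil(raw)
    elif rounding == "floor":
        value = math.floor(raw)
    elif rounding == "round":
        value = round(raw)
    else:
        raise ConfigurationError(f"unknown rounding {rounding!r}")
    return max(2, int(value))


def extract_signatures(
    components: Sequence[set[str]],
    graph: nx.Graph,
    min_fraction: float = 0.2,
    density_threshold: float = 0.8,
    rounding: str = "ceil",
    exhaustive_limit: int = 15,
) -> list[Signature]:
    """Dense-subgraph signatures per component, labelled A, B, C, ...

    Labels follow component order, then descending subgraph size, then
    lexicographic smallest member — fully deterministic.
    """
    out: list[Signature] = []
    labels = _labels()
    for comp_id, comp in enumerate(components):
        sub = graph.subgraph(comp)
        min_size = min_signature_size(len(comp), min_fraction, rounding)
        if len(comp) < min_size:
            continue
        for members in enumerate_dense_subgraphs(
            sub, density_threshold, min_size, exhaustive_limit
        ):
            out.append(
                Signature(
                    signature_id=next(labels),
                    component_id=comp_id,
                    members=members,
                    density=density(graph, members),
                )
            )
    return out


def unassigned_snps(component: Iterable[str], signatures: Sequence[Signature]) -> set[str]:
    """Component members that belong to no signature."""
    covered: set[str] = set()
    for sig in signatures:
        covered |= sig.members
    return set(component) - covered


def signatures_frame(signatures: Sequence[Signature]) -> pd.DataFrame:
    """Tabular view (signature_id, component_id, size, density, members)."""
    rows = [
        {
            "signature_id": s.signature_id,
            "component_id": s.component_id,
            "size": s.size,
            "density": round(s.density, 6),
            "members": ";".join(sorted(s.members)),
        }
        for s in signatures
    ]
    return pd.DataFrame(rows, columns=["signature_id", "component_id", "size", "density", "members"])


def export_graph(graph: nx.Graph, signatures: Sequence[Signature], basepath) -> None:
    """Write GraphML plus an edge-list TSV, byte-stable across runs.

    Node attributes carry the chromosome and semicolon-joined signature
    labels; nodes and edges are inserted in sorted order so the output is
    reproducible for identical inputs.
    """
    basepath = str(basepath)
    membership: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for sig in signatures:
        for node in sig.members:
            membership[node].append(sig.signature_id)
    ordered = nx.Graph()
    for node in sorted(graph.nodes):
        ordered.add_node(
            node,
            chrom=str(graph.nodes[node].get("chrom", "")),
            signatures=";".join(sorted(membership[node])),
        )
    edge_rows = []
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        data = graph.edges[a, b]
        ordered.add_edge(a, b, **data)
        edge_rows.append(
            {
                "snp_a": a,
                "snp_b": b,
                "dprime": data.get("dprime", ""),
                "pval": data.get("pval", ""),
            }
        )
    nx.write_graphml(ordered, basepath + ".graphml")
    pd.DataFrame(edge_rows, columns=["snp_a", "snp_b", "dprime", "pval"]).to_csv(
        basepath + ".edges.tsv", sep="\t", index=False
    )
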