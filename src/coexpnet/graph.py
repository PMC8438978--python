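"""Directed network topology: main component, greedy-modularity modules,
degree/betweenness centrality, and k-th order neighborhoods."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data import DETable, SampleSheet
from .inference import EdgeList
from .preprocess import ResponseCriteria, count_responsive_chemicals


def build_graph(el: EdgeList) -> nx.DiGraph:
    """Directed weighted graph over all edge endpoints."""
    if len(el) == 0:
        raise ValueError("empty edge list")
    g = nx.DiGraph()
    for row in el.edges.itertuples(index=False):
        g.add_edge(row.regulator, row.target, weight=float(row.weight))
    return g


def main_component(net: nx.DiGraph) -> nx.DiGraph:
    """Largest weakly connected component; size ties broken by the
    lexicographically smallest member node id."""
    comps = sorted(
        nx.weakly_connected_components(net),
        key=lambda c: (-len(c), min(c)),
    )
    return net.subgraph(comps[0]).copy()


@dataclass
class ModulePartition:
    """Gene -> module id; ids 1..K ordered by non-increasing module size.

    Genes in communities smaller than ``min_size`` are unassigned (absent
    from ``membership``).
    """

    membership: dict[str, int]
    min_size: int

    def module_ids(self) -> list[int]:
        return sorted(set(self.membership.values()))

    def genes_of(self, module_id: int) -> list[str]:
        return sorted(g for g, m in self.membership.items() if m == module_id)

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for m in self.membership.values():
            out[m] = out.get(m, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.membership), "module": list(self.membership.values())}
        ).sort_values(["module", "gene"], ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, min_size: int = 12) -> "ModulePartition":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["gene"], df["module"].astype(int))), min_size=min_size)


def _undirected_simplification(net: nx.DiGraph) -> nx.Graph:
    """Collapse reciprocal edges, summing weights."""
    und = nx.Graph()
    und.add_nodes_from(net.nodes)
    for u, v, d in net.edges(data=True):
        w = d.get("weight", 1.0)
        if und.has_edge(u, v):
            und[u][v]["weight"] += w
        else:
            und.add_edge(u, v, weight=w)
    return und


def detect_modules(
    net: nx.DiGraph, min_size: int = 12, seed: int = 0, resolution: float = 1.0
) -> ModulePartition:
    """Greedy modularity (Clauset–Newman–Moore) communities on the
    undirected, weight-summed simplification of the network.

    Communities below ``min_size`` are left unassigned; surviving modules
    are renumbered 1..K by descending size (ties by smallest member id).
    ``resolution`` < 1 counteracts fragmentation on small sparse networks
    (greedy modularity's resolution limit); 1.0 matches the classic
    agglomeration.
    """
    und = _undirected_simplification(net)
    communities = nx.community.greedy_modularity_communities(
        und, weight="weight", resolution=resolution
    )
    kept = [c for c in communities if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    membership = {g: i for i, c in enumerate(kept, start=1) for g in sorted(c)}
    return ModulePartition(membership, min_size=min_size)


def centrality(net: nx.DiGraph, partition: ModulePartition | None = None) -> pd.DataFrame:
    """Per-gene degree / indegree / outdegree / betweenness table.

    Betweenness is directed shortest-path betweenness with unweighted path
    lengths, normalized by (n-1)(n-2) so values lie in [0, 1].
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    btw = nx.betweenness_centrality(net, normalized=True, weight=None)
    rows = []
    for g in net.nodes:
        indeg = net.in_degree(g)
        outdeg = net.out_degree(g)
        rows.append(
            {
                "gene": g,
                "betweenness": btw[g],
                "degree": indeg + outdeg,
                "indegree": indeg,
                "outdegree": outdeg,
                "module": partition.membership.get(g) if partition else None,
            }
        )
    return pd.DataFrame(rows).sort_values("gene", ignore_index=True)


def top_central(tab: pd.DataFrame, by: str = "degree", n: int = 20) -> pd.DataFrame:
    """Top-n genes by a centrality column; ties broken by gene id."""
    if by not in ("degree", "betweenness"):
        raise ValueError("by must be 'degree' or 'betweenness'")
    if n > len(tab):
        raise ValueError("n exceeds the number of genes")
    ranked = tab.sort_values(
        [by, "gene"], ascending=[False, True], kind="stable", ignore_index=True
    )
    return ranked.head(n)


@dataclass
class Subnetwork:
    seed_gene: str
    order: int
    shells: dict[str, int]  # gene -> 0 (seed), 1, or 2
    subgraph: nx.DiGraph

    @property
    def nodes(self) -> list[str]:
        return list(self.subgraph.nodes)

    def shell_genes(self, shell: int) -> set[str]:
        return {g for g, s in self.shells.items() if s == shell}

    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.shells), "shell": list(self.shells.values())}
        ).sort_values(["shell", "gene"], ignore_index=True)


def neighborhood(net: nx.DiGraph, gene: str, order: int = 1) -> Subnetwork:
    """Direction-blind k-th order neighborhood of a seed gene (k = 1 or 2)."""
    if gene not in net:
        raise KeyError(f"gene not in network: {gene}")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    und = net.to_undirected(as_view=True)
    shells = {gene: 0}
    frontier = {gene}
    for shell in range(1, order + 1):
        nxt = set()
        for g in frontier:
            nxt.update(und.neighbors(g))
        nxt -= set(shells)
        for g in sorted(nxt):
            shells[g] = shell
        frontier = nxt
    sub = net.subgraph(shells).copy()
    return Subnetwork(seed_gene=gene, order=order, shells=shells, subgraph=sub)


def module_response_profile(
    part: ModulePartition,
    det: DETable,
    sheet: SampleSheet,
    class_filter: list[str] | None,
    crit: ResponseCriteria,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chemical-response overlay: per-gene counts and per-module summaries.

    Returns ``(gene_counts, module_summary)`` where the summary gives the
    mean and max response count per module, sorted by mean descending — the
    flagging order for class-associated modules.
    """
    det_genes = set(det.genes)
    gene_rows = []
    for g, m in part.membership.items():
        if g not in det_genes:
            continue
        cnt = count_responsive_chemicals(det, g, class_filter, crit, sheet=sheet)
        gene_rows.append({"gene": g, "module": m, "n_responsive": cnt})
    gene_counts = pd.DataFrame(gene_rows, columns=["gene", "module", "n_responsive"])
    if gene_counts.empty:
        summary = pd.DataFrame(columns=["module", "n_genes", "mean", "max"])
    else:
        summary = (
            gene_counts.groupby("module")["n_responsive"]
            .agg(n_genes="size", mean="mean", max="max")
            .reset_index()
            .sort_values(["mean", "module"], ascending=[False, True], ignore_index=True)
        )
    return gene_counts, summary
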