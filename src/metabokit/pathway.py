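"""Metabolite-set / pathway analysis: hypergeometric over-representation,
topology-based node importance and pathway impact, and the integrated
gene + metabolite mode.

A pathway's *impact* is the summed relative topological importance
(betweenness or out-degree centrality, normalized to sum to 1 within the
pathway) of the nodes present in the hit list, so it lies in [0, 1].

In the integrated mode, gene and metabolite hits are typed by namespace
prefix (``G:`` for genes, ``C:`` for compounds in the toy libraries); the
combined mode pools both hit lists over the pooled universe, while the
single-omics modes restrict sets, universe and hits to one id type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .univariate import adjust_bh

GENE_PREFIX = "G:"
METABOLITE_PREFIX = "C:"


@dataclass
class PathwayLibrary:
    """Named member sets plus optional directed graphs for topology."""

    sets: dict                      # name -> list of member ids
    graphs: dict = field(default_factory=dict)   # name -> nx.DiGraph
    universe: list | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {name!r}")
            g = self.graphs.get(name)
            if g is not None:
                extra = set(g.nodes) - set(members)
                if extra:
                    raise ValueError(
                        f"graph nodes not in set {name!r}: {sorted(extra)}")
        if self.universe is None:
            self.universe = sorted({m for s in self.sets.values() for m in s})

    def subset_by_type(self, prefix: str) -> "PathwayLibrary":
        """Restrict sets, graphs and universe to one id namespace."""
        sets = {}
        graphs = {}
        for name, members in self.sets.items():
            kept = [m for m in members if str(m).startswith(prefix)]
            if not kept:
                continue
            sets[name] = kept
            g = self.graphs.get(name)
            if g is not None:
                graphs[name] = g.subgraph(kept).copy()
        return PathwayLibrary(
            sets=sets, graphs=graphs,
            universe=[u for u in self.universe if str(u).startswith(prefix)])


@dataclass
class EnrichmentRow:
    pathway: str
    set_size: int
    n_hits: int
    expected_hits: float
    p_value: float
    fdr: float
    impact: float = 0.0
    mode: str = "metabolites_only"


def rows_to_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(hits, lib: PathwayLibrary, universe=None, mode: str = "metabolites_only",
        impacts: dict | None = None) -> list[EnrichmentRow]:
    """Right-tail hypergeometric over-representation test per pathway set.

    With population size N = |universe|, K set members in the universe,
    n mapped hits and k hits in the set, p = P(X >= k).  Hits outside the
    universe are dropped (reported via the returned rows' bookkeeping is not
    needed; a warning list is available on request through
    :func:`ora_with_report`).
    """
    rows, _ = ora_with_report(hits, lib, universe=universe, mode=mode,
                              impacts=impacts)
    return rows


def ora_with_report(hits, lib: PathwayLibrary, universe=None,
                    mode: str = "metabolites_only",
                    impacts: dict | None = None):
    universe = list(lib.universe if universe is None else universe)
    uni = set(universe)
    hits = list(dict.fromkeys(hits))        # dedupe, keep order
    dropped = [h for h in hits if h not in uni]
    mapped = [h for h in hits if h in uni]
    report = {"n_hits_input": len(hits), "n_hits_mapped": len(mapped),
              "dropped": dropped, "warnings": []}
    if not mapped:
        report["warnings"].append("empty mapped hit list; all p-values are 1")
    n_total = len(uni)
    n_draw = len(mapped)
    hit_set = set(mapped)
    names = sorted(lib.sets)
    p_values = []
    rows = []
    for name in names:
        members = set(lib.sets[name]) & uni
        k_obs = len(members & hit_set)
        k_set = len(members)
        if n_draw == 0 or k_set == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k_obs - 1, n_total, k_set, n_draw))
        expected = n_draw * k_set / n_total if n_total else 0.0
        impact = float(impacts.get(name, 0.0)) if impacts else 0.0
        rows.append(EnrichmentRow(pathway=name, set_size=k_set, n_hits=k_obs,
                                  expected_hits=expected, p_value=min(p, 1.0),
                                  fdr=np.nan, impact=impact, mode=mode))
        p_values.append(min(p, 1.0))
    if rows:
        fdr = adjust_bh(np.array(p_values))
        for row, f in zip(rows, fdr):
            row.fdr = float(f)
    return rows, report


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

def topology_importance(graph: nx.DiGraph, measure: str = "rel_betweenness") -> dict:
    """Relative node importance within one pathway graph, summing to 1.

    ``rel_betweenness`` uses raw (unnormalized) shortest-path betweenness;
    ``out_degree`` uses out-degree.  Graphs whose raw centralities are all
    zero (e.g. no edges) fall back to uniform importance.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if measure == "rel_betweenness":
        raw = nx.betweenness_centrality(graph, normalized=False)
    elif measure == "out_degree":
        raw = dict(graph.out_degree())
    else:
        raise ValueError(f"unknown measure {measure!r}")
    total = float(sum(raw.values()))
    n = graph.number_of_nodes()
    if total <= 0:
        return {v: 1.0 / n for v in graph.nodes}
    return {v: raw[v] / total for v in graph.nodes}


def pathway_impact(hits, graph: nx.DiGraph, measure: str = "rel_betweenness") -> float:
    """Summed relative importance of the hit nodes; in [0, 1]."""
    imp = topology_importance(graph, measure=measure)
    return float(sum(imp.get(h, 0.0) for h in set(hits)))


def library_impacts(hits, lib: PathwayLibrary,
                    measure: str = "rel_betweenness") -> dict:
    """Pathway impact for every pathway in a library that has a graph."""
    return {name: pathway_impact(hits, g, measure=measure)
            for name, g in lib.graphs.items()}


# ---------------------------------------------------------------------------
# Integrated gene + metabolite analysis
# ---------------------------------------------------------------------------

def integrated_analysis(gene_hits, metabolite_hits, lib: PathwayLibrary,
                        mode: str = "combined",
                        measure: str = "rel_betweenness") -> list[EnrichmentRow]:
    """Joint pathway analysis of gene and metabolite hit lists.

    ``combined`` pools both lists over the pooled universe; ``genes_only`` /
    ``metabolites_only`` restrict library sets, universe and hits to that id
    type, reproducing plain single-omics ORA on the restricted inputs.
    """
    if mode == "combined":
        sub = lib
        hits = list(gene_hits) + list(metabolite_hits)
    elif mode == "genes_only":
        sub = lib.subset_by_type(GENE_PREFIX)
        if not sub.sets:
            raise ValueError("library contains no gene ids")
        hits = list(gene_hits)
    elif mode == "metabolites_only":
        sub = lib.subset_by_type(METABOLITE_PREFIX)
        if not sub.sets:
            raise ValueError("library contains no metabolite ids")
        hits = list(metabolite_hits)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    impacts = library_impacts(hits, sub, measure=measure)
    return ora(hits, sub, mode=mode, impacts=impacts)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """GMT set file: name <tab> description <tab> member ids."""
    sets = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [m for m in parts[2:] if m]
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description] + list(sets[name])) + "\n")


def read_edge_list(path) -> dict:
    """Edge-list TSV (pathway, source, target) -> directed graphs."""
    graphs: dict[str, nx.DiGraph] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[0].lower() == "pathway":
                continue
            name, src, dst = parts
            graphs.setdefault(name, nx.DiGraph()).add_edge(src, dst)
    return graphs


def write_edge_list(graphs: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway\tsource\ttarget\n")
        for name in sorted(graphs):
            for src, dst in sorted(graphs[name].edges):
                fh.write(f"{name}\t{src}\t{dst}\n")


def load_pathway_library(gmt_path, edges_path=None, universe=None) -> PathwayLibrary:
    sets = read_gmt(gmt_path)
    graphs = read_edge_list(edges_path) if edges_path else {}
    return PathwayLibrary(sets=sets, graphs=graphs, universe=universe)
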