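"""Deterministic synthetic-data generators.

Every generator is a pure function of its spec and seed, so each module can
be exercised without downloading any reference data.  Concentration tables
use a log-normal baseline — metabolite concentrations are positive and
right-skewed — with group effects applied as standardized shifts on the log
scale, so ``effect_size`` is directly the Cohen-d separation of the log
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import DataTable
from .pathway import GENE_PREFIX, METABOLITE_PREFIX, PathwayLibrary


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic two-group concentration table."""

    n_per_group: int = 20
    n_features: int = 200
    n_informative: int = 20
    effect_size: float = 1.0
    missing_rate: float = 0.0
    pi0: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must not exceed n_features")
        for name in ("missing_rate", "pi0"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def make_two_group(spec: FixtureSpec) -> DataTable:
    """Two-group table: log-normal baseline, first ``n_informative``
    features shifted by ``effect_size`` log-scale SDs in group B, values
    missing completely at random at ``missing_rate``."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_per_group, spec.n_features
    base_mean = rng.normal(loc=3.0, scale=0.5, size=m)   # log-concentration
    z = rng.normal(size=(2 * n, m)) + base_mean
    z[n:, :spec.n_informative] += spec.effect_size
    values = np.exp(z)
    if spec.missing_rate > 0:
        mask = rng.random(size=values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    features = [f"M{j + 1:04d}" for j in range(m)]
    frame = pd.DataFrame(values, index=samples, columns=features)
    group = pd.Series(["A"] * n + ["B"] * n, index=samples, name="Label")
    dt = DataTable(values=frame, group=group)
    dt.log.append({"op": "fixture", "kind": "two_group", "spec": vars(spec).copy()})
    return dt


def make_power_pilot(spec: FixtureSpec) -> DataTable:
    """Pilot table for power analysis: a fraction ``1 - pi0`` of features
    carry the effect, the rest are null."""
    n_inf = int(round((1 - spec.pi0) * spec.n_features))
    sub = FixtureSpec(n_per_group=spec.n_per_group, n_features=spec.n_features,
                      n_informative=n_inf, effect_size=spec.effect_size,
                      missing_rate=spec.missing_rate, pi0=spec.pi0,
                      seed=spec.seed)
    return make_two_group(sub)


def _random_connected_digraph(nodes, rng) -> nx.DiGraph:
    """Random spanning tree (weakly connecting) plus a few extra edges."""
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    order = list(nodes)
    rng.shuffle(order)
    for i in range(1, len(order)):
        j = int(rng.integers(0, i))
        if rng.random() < 0.5:
            g.add_edge(order[j], order[i])
        else:
            g.add_edge(order[i], order[j])
    n_extra = max(1, len(order) // 3)
    for _ in range(n_extra):
        a, b = rng.choice(len(order), size=2, replace=False)
        g.add_edge(order[int(a)], order[int(b)])
    return g


def make_pathway_library(n_pathways: int = 10, size_range=(5, 15),
                         planted: str | None = "planted_pathway",
                         gene_fraction: float = 0.5,
                         universe_size: int = 300,
                         seed: int = 0) -> PathwayLibrary:
    """Random pathway library over a synthetic mixed gene/metabolite
    universe, each pathway carrying a connected directed graph.

    The optional planted pathway is built from reserved universe members so
    hit lists sampled from it (see :func:`make_multiomics_lists`) hit no
    other pathway by construction.
    """
    lo, hi = size_range
    if lo < 3:
        raise ValueError("minimum pathway size is 3")
    rng = np.random.default_rng(seed)
    n_genes = int(universe_size * gene_fraction)
    universe = [f"{GENE_PREFIX}{i + 1:04d}" for i in range(n_genes)]
    universe += [f"{METABOLITE_PREFIX}{i + 1:04d}"
                 for i in range(universe_size - n_genes)]
    sets, graphs = {}, {}
    pool = list(universe)
    if planted:
        size = int(rng.integers(lo, hi + 1))
        genes = [u for u in pool if u.startswith(GENE_PREFIX)][:size // 2 + 1]
        mets = [u for u in pool if u.startswith(METABOLITE_PREFIX)][:size - len(genes)]
        members = genes + mets
        sets[planted] = members
        graphs[planted] = _random_connected_digraph(members, rng)
        pool = [u for u in pool if u not in set(members)]
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = [pool[j] for j in rng.choice(len(pool), size=size,
                                               replace=False)]
        name = f"pathway_{i + 1:02d}"
        sets[name] = members
        graphs[name] = _random_connected_digraph(members, rng)
    return PathwayLibrary(sets=sets, graphs=graphs, universe=universe)


def make_multiomics_lists(lib: PathwayLibrary, planted: str,
                          gene_frac: float = 1.0, met_frac: float = 1.0,
                          noise: int = 0, seed: int = 0):
    """Gene and metabolite hit lists enriched for one planted pathway."""
    if planted not in lib.sets:
        raise ValueError(f"pathway {planted!r} not in library")
    rng = np.random.default_rng(seed)
    members = lib.sets[planted]
    genes = [m for m in members if str(m).startswith(GENE_PREFIX)]
    mets = [m for m in members if str(m).startswith(METABOLITE_PREFIX)]
    n_g = int(round(gene_frac * len(genes)))
    n_m = int(round(met_frac * len(mets)))
    if n_g > len(genes) or n_m > len(mets):
        raise ValueError("requested fractions exceed availability")
    gene_hits = [genes[i] for i in rng.choice(len(genes), size=n_g,
                                              replace=False)] if n_g else []
    met_hits = [mets[i] for i in rng.choice(len(mets), size=n_m,
                                            replace=False)] if n_m else []
    off = [u for u in lib.universe if u not in set(members)]
    off_g = [u for u in off if str(u).startswith(GENE_PREFIX)]
    off_m = [u for u in off if str(u).startswith(METABOLITE_PREFIX)]
    if noise:
        gene_hits += [off_g[i] for i in rng.choice(len(off_g), size=noise,
                                                   replace=False)]
        met_hits += [off_m[i] for i in rng.choice(len(off_m), size=noise,
                                                  replace=False)]
    return sorted(gene_hits), sorted(met_hits)


def write_two_group_csv(spec: FixtureSpec, path) -> None:
    """Write a fixture table in the samples-in-rows CSV layout accepted by
    the reader; byte-identical for identical specs."""
    make_two_group(spec).to_csv(path)
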