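"""Median-joining networks of Y-STR haplotypes.

The median-joining construction embeds all sampled haplotypes in a network
that contains every minimum spanning tree and augments it with inferred
"median vectors" — unsampled intermediate haplotypes (per-locus medians of
node triples) — whenever adding one reduces the total connection cost.
Distances are single-step mutation counts, i.e. the L1 distance between
integer repeat-count vectors.

Preprocessing follows the standard conventions for STR networks:
microvariant repeat numbers are rounded to the nearest integer, the
constitutively duplicated DYS385 a/b locus is excluded (its copies cannot be
assigned), and haplotypes with missing data are dropped with an auditable
manifest.  Identical haplotypes collapse to one node whose size is the
number of males carrying it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from ystrkit.datamodel import HaplotypeTable, round_half_away

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReducedHaplotypes:
    """Collapsed integer haplotypes ready for network construction."""

    loci: tuple[str, ...]
    haplotypes: tuple[tuple[int, ...], ...]  # distinct, lexicographically sorted
    sizes: tuple[int, ...]
    annotations: tuple[str, ...]  # majority annotation per haplotype ("" if none)
    excluded_ids: tuple[str, ...]  # rows dropped for missing data


def prepare_network_input(
    table: HaplotypeTable, annotate_col: str | None = None
) -> ReducedHaplotypes:
    """Reduce a haplotype table to distinct integer haplotypes.

    Drops multi-copy loci, rounds microvariants half away from zero,
    excludes rows with missing data at the remaining loci (manifest in
    ``excluded_ids``), and collapses identical haplotypes with size counts.
    """
    loci = tuple(l for l in table.panel.loci if l not in table.panel.multi_copy)
    X, kept = table.integer_matrix(loci)
    excluded = tuple(
        table.sample_ids[i] for i in range(len(table)) if i not in set(kept)
    )
    if excluded:
        logger.info("prepare_network_input: excluded %d incomplete rows", len(excluded))
    ann_src = (
        [str(table.metadata.at[i, annotate_col]) for i in kept]
        if annotate_col is not None and annotate_col in table.metadata.columns
        else [""] * len(kept)
    )
    groups: dict[tuple[int, ...], list[int]] = {}
    for j in range(X.shape[0]):
        groups.setdefault(tuple(int(v) for v in X[j]), []).append(j)
    if len(groups) < 2:
        raise ValueError("fewer than 2 distinct haplotypes remain after reduction")
    haps = tuple(sorted(groups))
    sizes = tuple(len(groups[h]) for h in haps)
    anns = []
    for h in haps:
        labels = [ann_src[j] for j in groups[h] if ann_src[j]]
        anns.append(max(set(labels), key=labels.count) if labels else "")
    return ReducedHaplotypes(loci, haps, sizes, tuple(anns), excluded)


def step_distance(x, y, weights=None) -> int:
    """Weighted single-step mutation distance sum_l w_l |x_l - y_l|."""
    x = tuple(x)
    y = tuple(y)
    if len(x) != len(y):
        raise ValueError("haplotype vectors differ in length")
    w = weights if weights is not None else (1,) * len(x)
    return int(sum(wi * abs(a - b) for wi, a, b in zip(w, x, y)))


@dataclass
class HaplotypeNetwork:
    """A median-joining network as a networkx graph.

    Node keys are haplotype tuples; node attributes: ``kind``
    (``sampled`` / ``median_vector``), ``size``, ``annotation``.  Edge
    attribute ``weight`` is the mutational step count between endpoints.
    """

    graph: nx.Graph
    loci: tuple[str, ...]
    epsilon: int = 0
    n_medians: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        self.n_medians = sum(
            1 for _, d in self.graph.nodes(data=True) if d["kind"] == "median_vector"
        )

    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def _mst_edges(nodes: list[tuple[int, ...]]) -> tuple[int, list[tuple[int, int, int]]]:
    """Deterministic Kruskal MST over haplotype tuples.

    Edges sorted by (weight, endpoints lexicographic) — the stated tie-break
    — so the returned tree and cost are bit-reproducible.  Returns
    (total cost, edge list as index pairs).
    """
    n = len(nodes)
    edges = sorted(
        (step_distance(nodes[i], nodes[j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    cost = 0
    tree = []
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            cost += w
            tree.append((i, j, w))
    return cost, tree


def _minimax_matrix(nodes: list[tuple[int, ...]]) -> np.ndarray:
    """minimax[i,j] = the largest edge on the MST path i..j (the cost at
    which i and j become connected)."""
    n = len(nodes)
    _, tree = _mst_edges(nodes)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i, j, w in tree:
        adj[i].append((j, w))
        adj[j].append((i, w))
    mm = np.zeros((n, n), dtype=np.int64)
    for src in range(n):
        stack = [(src, 0)]
        seen = {src}
        while stack:
            u, path_max = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    mm[src, v] = max(path_max, w)
                    stack.append((v, max(path_max, w)))
    return mm


def _msn_edges(nodes: list[tuple[int, ...]], epsilon: int) -> list[tuple[int, int, int]]:
    """epsilon-relaxed minimum spanning network: keep every link whose cost
    is within ``epsilon`` of the minimal cost at which its endpoints'
    components connect (epsilon=0 gives the union of all MSTs)."""
    mm = _minimax_matrix(nodes)
    out = []
    for i, j in itertools.combinations(range(len(nodes)), 2):
        d = step_distance(nodes[i], nodes[j])
        if d <= mm[i, j] + epsilon:
            out.append((i, j, d))
    return out


def median_joining(reduced: ReducedHaplotypes, epsilon: int = 0) -> HaplotypeNetwork:
    """Build the median-joining network of the reduced haplotypes.

    Iterates: (1) form the epsilon-relaxed minimum spanning network over the
    current node set; (2) for every triple connected within it, compute the
    per-locus median vector; (3) greedily add the new median that most
    reduces the minimum connection cost (ties broken lexicographically) and
    re-iterate; (4) at fixpoint, prune median vectors whose removal leaves
    the connection cost unchanged.  Sampled haplotypes are never removed.
    The cost is a non-negative integer strictly decreasing at each accepted
    median, so the construction terminates.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be a non-negative integer")
    sampled = list(reduced.haplotypes)
    nodes = list(sampled)
    cost, _ = _mst_edges(nodes)
    while True:
        msn = _msn_edges(nodes, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _w in msn:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[tuple[int, ...]] = set()
        for u in range(len(nodes)):
            for v, w in itertools.combinations(sorted(adj[u]), 2):
                m = tuple(
                    int(np.median([nodes[u][k], nodes[v][k], nodes[w][k]]))
                    for k in range(len(reduced.loci))
                )
                if m not in set(nodes):
                    candidates.add(m)
        best: tuple[int, tuple[int, ...]] | None = None
        for m in sorted(candidates):
            c2, _ = _mst_edges(nodes + [m])
            if c2 < cost and (best is None or c2 < best[0]):
                best = (c2, m)
        if best is None:
            break
        cost = best[0]
        nodes.append(best[1])

    # prune median vectors that no longer pay for themselves
    changed = True
    while changed:
        changed = False
        for m in sorted(n for n in nodes if n not in set(sampled)):
            trial = [n for n in nodes if n != m]
            c2, _ = _mst_edges(trial)
            if c2 <= cost:
                nodes = trial
                cost = c2
                changed = True
                break

    size_by_hap = dict(zip(reduced.haplotypes, reduced.sizes))
    ann_by_hap = dict(zip(reduced.haplotypes, reduced.annotations))
    g = nx.Graph()
    for h in nodes:
        if h in size_by_hap:
            g.add_node(h, kind="sampled", size=size_by_hap[h], annotation=ann_by_hap[h])
        else:
            g.add_node(h, kind="median_vector", size=0, annotation="")
    for i, j, w in _msn_edges(nodes, epsilon):
        g.add_edge(nodes[i], nodes[j], weight=w)
    return HaplotypeNetwork(g, reduced.loci, epsilon)


# ---------------------------------------------------------------------------
# export


def export_network(net: HaplotypeNetwork, path: str | Path, format: str = "graphml") -> Path:
    """Write the network as GraphML or DOT (haplotypes serialised as
    comma-joined repeat counts in the ``haplotype`` node attribute)."""
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for h, d in net.graph.nodes(data=True):
            g.add_node(",".join(map(str, h)), **d)
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(",".join(map(str, u)), ",".join(map(str, v)), weight=int(d["weight"]))
        g.graph["loci"] = ",".join(net.loci)
        g.graph["epsilon"] = net.epsilon
        nx.write_graphml(g, path)
        return path
    if format == "dot":
        lines = ["graph mj_network {"]
        for h, d in net.graph.nodes(data=True):
            key = ",".join(map(str, h))
            shape = "circle" if d["kind"] == "sampled" else "point"
            label = d["annotation"] or key
            lines.append(
                f'  "{key}" [kind="{d["kind"]}", size={d["size"]}, label="{label}", shape={shape}];'
            )
        for u, v, d in net.graph.edges(data=True):
            lines.append(
                f'  "{",".join(map(str, u))}" -- "{",".join(map(str, v))}" [weight={int(d["weight"])}, label="{int(d["weight"])}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ValueError(f"unsupported network format {format!r}")


def import_network(path: str | Path) -> HaplotypeNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    g0 = nx.read_graphml(path)
    g = nx.Graph()
    for key, d in g0.nodes(data=True):
        h = tuple(int(v) for v in str(key).split(","))
        g.add_node(
            h,
            kind=d["kind"],
            size=int(d["size"]),
            annotation=d.get("annotation", ""),
        )
    for u, v, d in g0.edges(data=True):
        g.add_edge(
            tuple(int(x) for x in str(u).split(",")),
            tuple(int(x) for x in str(v).split(",")),
            weight=int(d["weight"]),
        )
    loci = tuple(g0.graph.get("loci", "").split(",")) if g0.graph.get("loci") else ()
    return HaplotypeNetwork(g, loci, int(g0.graph.get("epsilon", 0)))
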