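"""Weighted median-joining haplotype networks.

Characters are mixed: numeric multistate STR loci (distance = weighted
absolute repeat difference) and binary SNPs (weighted mismatch, weight 99).
The construction iterates: (1) epsilon-relaxed minimum spanning network over
the current node set; (2) quasi-medians (component-wise median for STRs,
majority for SNPs) of mutually connected triplets; (3) greedy addition of
medians that strictly reduce the minimum-spanning cost, to a fixed point;
(4) removal of median vectors that no longer shorten the network.  All tie
breaks are lexicographic on node vectors, making the result independent of
input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .dataset import PopulationDataset
from .panel import SNP_NETWORK_WEIGHT


@dataclass(frozen=True)
class CharacterSet:
    """Shared metadata for haplotype character vectors."""

    names: tuple[str, ...]
    weights: tuple[float, ...]
    is_snp: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.weights) == len(self.is_snp)):
            raise ValueError("character metadata lengths differ")
        for w, snp in zip(self.weights, self.is_snp):
            if snp and w != SNP_NETWORK_WEIGHT:
                raise ValueError("SNP characters must carry weight 99")
            if not snp and not (1 <= w <= 5):
                raise ValueError("STR weights must lie in [1, 5]")

    @property
    def n(self) -> int:
        return len(self.names)


Vector = tuple[float, ...]


def weighted_distance(a: Vector, b: Vector, chars: CharacterSet) -> float:
    """Weighted distance: sum w*|repeat diff| (STR) + w*[state differs] (SNP)."""
    if len(a) != len(chars.names) or len(b) != len(chars.names):
        raise ValueError("vector length does not match character set")
    total = 0.0
    for x, y, w, snp in zip(a, b, chars.weights, chars.is_snp):
        if snp:
            total += w * (x != y)
        else:
            total += w * abs(x - y)
    return total


def step_distance(a: Vector, b: Vector, chars: CharacterSet) -> float:
    """Unweighted mutational steps between two vectors."""
    total = 0.0
    for x, y, snp in zip(a, b, chars.is_snp):
        total += (x != y) if snp else abs(x - y)
    return total


@dataclass
class HaplotypeNetwork:
    chars: CharacterSet
    graph: nx.Graph  # nodes keyed by vector tuple
    observed: dict[Vector, int]  # vector -> multiplicity
    composition: dict[Vector, dict[str, int]]
    epsilon: float

    @property
    def medians(self) -> list[Vector]:
        return sorted(v for v in self.graph.nodes if v not in self.observed)

    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def node_labels(self) -> dict[Vector, str]:
        labels = {}
        for i, v in enumerate(sorted(self.observed), 1):
            labels[v] = f"H{i}"
        for i, v in enumerate(self.medians, 1):
            labels[v] = f"mv{i}"
        return labels


def _mst_cost(nodes: Sequence[Vector], chars: CharacterSet) -> float:
    """Minimum spanning cost of the complete weighted graph on ``nodes``."""
    n = len(nodes)
    if n <= 1:
        return 0.0
    in_tree = [False] * n
    dist = [float("inf")] * n
    dist[0] = 0.0
    cost = 0.0
    for _ in range(n):
        j = min(
            (i for i in range(n) if not in_tree[i]),
            key=lambda i: (dist[i], nodes[i]),
        )
        in_tree[j] = True
        cost += dist[j]
        for i in range(n):
            if not in_tree[i]:
                d = weighted_distance(nodes[j], nodes[i], chars)
                if d < dist[i]:
                    dist[i] = d
    return cost


def _msn_edges(nodes: Sequence[Vector], chars: CharacterSet, epsilon: float) -> list[tuple[int, int, float]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u, v) belongs to the network iff its weight is within epsilon of
    the bottleneck (minimax) path weight between u and v, i.e. of the
    connection threshold at which u and v first join one component.
    """
    n = len(nodes)
    if n <= 1:
        return []
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = weighted_distance(nodes[i], nodes[j], chars)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=d[i, j])
    mst = nx.minimum_spanning_tree(g, weight="weight")
    # bottleneck distances from max edge on MST paths
    bottleneck = np.zeros((n, n))
    for src in range(n):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in mst.neighbors(u):
                if v not in seen:
                    seen[v] = max(seen[u], mst[u][v]["weight"])
                    stack.append(v)
        for v, b in seen.items():
            bottleneck[src, v] = b
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= bottleneck[i, j] + epsilon + 1e-12:
                edges.append((i, j, d[i, j]))
    return edges


def quasi_median(a: Vector, b: Vector, c: Vector, chars: CharacterSet) -> Vector:
    """Component-wise quasi-median: numeric median (STR), majority (SNP)."""
    out = []
    for x, y, z, snp in zip(a, b, c, chars.is_snp):
        if snp:
            out.append(x if (x == y or x == z) else y)
        else:
            out.append(sorted((x, y, z))[1])
    return tuple(out)


def build_mj_network(
    classes: Sequence[tuple[Vector, int]] | Sequence[Vector],
    chars: CharacterSet,
    epsilon: float = 0.0,
    composition: dict[Vector, dict[str, int]] | None = None,
    max_iter: int = 100,
) -> HaplotypeNetwork:
    """Median-joining network over merged haplotype classes.

    ``classes`` is either a list of vectors or of (vector, multiplicity)
    pairs; duplicate vectors must already be merged.
    """
    if not classes:
        raise ValueError("need at least one haplotype class")
    if isinstance(classes[0][0], (tuple, list)):
        observed = {tuple(float(x) for x in v): int(m) for v, m in classes}  # type: ignore[misc]
    else:
        observed = {tuple(float(x) for x in v): 1 for v in classes}  # type: ignore[arg-type]
    if len(observed) != len(classes):
        raise ValueError("duplicate vectors must be merged into classes beforehand")

    nodes: list[Vector] = sorted(observed)
    node_set = set(nodes)

    for _ in range(max_iter):
        edges = _msn_edges(nodes, chars, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _w in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[Vector] = set()
        for i in range(len(nodes)):
            for j in adj[i]:
                if j <= i:
                    continue
                for k in adj[i] & adj[j]:
                    if k <= j:
                        continue
                    m = quasi_median(nodes[i], nodes[j], nodes[k], chars)
                    if m not in node_set:
                        candidates.add(m)
        if not candidates:
            break
        base_cost = _mst_cost(nodes, chars)
        best: tuple[float, Vector] | None = None
        for m in sorted(candidates):
            cost = _mst_cost(nodes + [m], chars)
            gain = base_cost - cost
            if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                best = (gain, m)
        if best is None:
            break
        nodes.append(best[1])
        node_set.add(best[1])
        nodes.sort()

    # cleanup: drop medians that no longer shorten the minimum spanning cost
    changed = True
    while changed:
        changed = False
        for m in sorted(node_set - set(observed)):
            rest = [v for v in nodes if v != m]
            if _mst_cost(rest, chars) <= _mst_cost(nodes, chars) + 1e-12:
                nodes = rest
                node_set.discard(m)
                changed = True

    edges = _msn_edges(nodes, chars, epsilon)
    g = nx.Graph()
    for v in nodes:
        g.add_node(v, observed=v in observed, multiplicity=observed.get(v, 0))
    for i, j, w in edges:
        a, b = nodes[i], nodes[j]
        changes = [
            chars.names[c]
            for c in range(chars.n)
            if a[c] != b[c]
        ]
        g.add_edge(a, b, length=w, steps=step_distance(a, b, chars), changes=changes)
    comp = composition or {}
    return HaplotypeNetwork(
        chars=chars, graph=g, observed=observed,
        composition={v: comp.get(v, {}) for v in observed}, epsilon=epsilon,
    )


def star_contraction(
    classes: Sequence[tuple[Vector, int]],
    chars: CharacterSet,
    delta: float,
) -> list[tuple[Vector, int]]:
    """Optional pre-processing: merge leaf classes within ``delta`` of a hub.

    Iteratively folds each class into its nearest strictly-more-frequent
    neighbour when the weighted distance is <= delta, accumulating
    multiplicity.  Used to simplify large star-like data before network
    construction; off by default.
    """
    merged = {tuple(v): int(m) for v, m in classes}
    changed = True
    while changed:
        changed = False
        for v in sorted(merged, key=lambda x: (merged[x], x)):
            hubs = [
                u for u in merged
                if u != v and merged[u] > merged[v]
                and weighted_distance(u, v, chars) <= delta
            ]
            if hubs:
                hub = min(hubs, key=lambda u: (weighted_distance(u, v, chars), u))
                merged[hub] += merged.pop(v)
                changed = True
                break
    return sorted(merged.items())


def haplotype_classes(
    ds: PopulationDataset,
    snp_states: dict[str, dict[str, int]] | None = None,
    by: str = "ethnicity",
) -> tuple[list[tuple[Vector, int]], CharacterSet, dict[Vector, dict[str, int]]]:
    """Merge a dataset into haplotype classes over single-copy STRs (+ SNPs).

    ``snp_states`` maps sample_id -> {snp_name: 0/1}.  Returns (classes,
    character set, per-class population composition).
    """
    loci = ds.panel.single_copy
    weights = [float(ds.panel[l].network_weight) for l in loci]
    snp_names: list[str] = []
    if snp_states:
        seen: set[str] = set()
        for states in snp_states.values():
            seen.update(states)
        snp_names = sorted(seen)
    chars = CharacterSet(
        names=tuple(loci) + tuple(snp_names),
        weights=tuple(weights) + tuple(float(SNP_NETWORK_WEIGHT) for _ in snp_names),
        is_snp=tuple(False for _ in loci) + tuple(True for _ in snp_names),
    )
    counts: dict[Vector, int] = {}
    comp: dict[Vector, dict[str, int]] = {}
    for s in ds.samples:
        vals = [s.haplotype.single_value(l) for l in loci]
        if any(v is None for v in vals):
            continue
        if snp_names:
            states = (snp_states or {}).get(s.sample_id, {})
            vals += [float(states.get(n, 0)) for n in snp_names]
        v = tuple(float(x) for x in vals)  # type: ignore[arg-type]
        counts[v] = counts.get(v, 0) + 1
        comp.setdefault(v, {})
        g = getattr(s, by)
        comp[v][g] = comp[v].get(g, 0) + 1
    return sorted(counts.items()), chars, comp


def export_network(net: HaplotypeNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as graphml, dot, or an edge TSV.

    Nodes carry multiplicity and per-population composition ("Han:3;Hui:1");
    edges carry weighted length and the changed characters.
    """
    path = Path(path)
    labels = net.node_labels()

    def comp_str(v: Vector) -> str:
        comp = net.composition.get(v, {})
        return ";".join(f"{k}:{n}" for k, n in sorted(comp.items()))

    if fmt == "edge_tsv":
        with path.open("w") as fh:
            fh.write("source\ttarget\tlength\tsteps\tchanges\tsource_mult\ttarget_mult\n")
            for a, b, d in sorted(net.graph.edges(data=True), key=lambda e: (labels[e[0]], labels[e[1]])):
                fh.write(
                    f"{labels[a]}\t{labels[b]}\t{d['length']:g}\t{d['steps']:g}\t"
                    f"{','.join(d['changes'])}\t{net.observed.get(a, 0)}\t{net.observed.get(b, 0)}\n"
                )
        return
    h = nx.Graph()
    for v in net.graph.nodes:
        h.add_node(
            labels[v],
            multiplicity=net.observed.get(v, 0),
            observed=v in net.observed,
            composition=comp_str(v),
        )
    for a, b, d in net.graph.edges(data=True):
        h.add_edge(labels[a], labels[b], length=float(d["length"]), changes=",".join(d["changes"]))
    if fmt == "graphml":
        nx.write_graphml(h, path)
    elif fmt == "dot":
        with path.open("w") as fh:
            fh.write("graph haplotypes {\n")
            for n, d in sorted(h.nodes(data=True)):
                shape = "circle" if d["observed"] else "point"
                fh.write(f'  "{n}" [shape={shape}, label="{n} ({d["multiplicity"]})", comment="{d["composition"]}"];\n')
            for a, b, d in sorted(h.edges(data=True)):
                fh.write(f'  "{a}" -- "{b}" [label="{d["length"]:g}"];\n')
            fh.write("}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
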