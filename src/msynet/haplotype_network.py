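"""Haplotype collapsing, median-joining networks, and haplogroup partitioning.

Samples with identical allele vectors collapse to one haplotype node. The
median-joining construction (Bandelt's algorithm on binary characters)
iterates between building the epsilon-relaxed minimum-spanning network over
the current vector set and inserting per-site majority ("median") vectors of
connected triples whenever they shorten the network, then prunes median
vectors that no longer contribute. On homoplasy-free (infinite-sites) data
the result is the unique perfect phylogeny: a tree whose path lengths equal
Hamming distances.

A brute-force Steiner oracle (:func:`network_oracle`) enumerates subsets of
the median closure and is intended for tests only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, Site

# ---------------------------------------------------------------------------
# Types


@dataclass
class HaplotypeTable:
    """Distinct binary haplotypes with their member samples."""

    ids: list[str]
    vectors: np.ndarray  # (n_hap, n_sites) uint8, over segregating sites only
    members: list[tuple[str, ...]]
    sites: list[Site]
    n_constant_dropped: int = 0

    @property
    def n_haplotypes(self) -> int:
        return len(self.ids)

    def multiplicity(self, i: int) -> int:
        return len(self.members[i])


@dataclass
class HaploNetwork:
    """Observed haplotypes plus inferred median vectors, with mutation-labeled edges."""

    graph: nx.Graph  # node attrs: vector(int), is_median, members, multiplicity
    sites: list[Site]

    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if not d["is_median"]]

    def medians(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["is_median"]]

    def node_of_sample(self, sample_id: str) -> str:
        for n, d in self.graph.nodes(data=True):
            if sample_id in d["members"]:
                return n
        raise KeyError(f"sample {sample_id!r} not on any node")

    def total_length(self) -> int:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))

    def path_length(self, u: str, v: str) -> int:
        return int(nx.shortest_path_length(self.graph, u, v, weight="length"))


@dataclass
class HaplogroupPartition:
    labels: dict[str, str]
    split_edge: tuple[str, str]
    split_length: int


# ---------------------------------------------------------------------------
# Collapse


def collapse_haplotypes(matrix: GenotypeMatrix) -> HaplotypeTable:
    """Merge identical sample rows into haplotypes; drop constant columns.

    Constant columns cannot separate haplotypes; their count is logged on
    the table so diversity denominators can remain the full sequence length.
    """
    if matrix.n_samples == 0:
        raise ValueError("empty genotype matrix")
    if (matrix.calls == MISSING).any():
        raise ValueError("matrix contains MISSING cells; impute first")
    calls = matrix.calls.astype(np.uint8)
    variable = calls.min(axis=0) != calls.max(axis=0)
    dropped = int((~variable).sum())
    core = calls[:, variable]
    sites = [s for s, v in zip(matrix.sites, variable) if v]

    seen: dict[bytes, int] = {}
    vectors: list[np.ndarray] = []
    members: list[list[str]] = []
    for i, sample in enumerate(matrix.samples):
        key = core[i].tobytes()
        if key in seen:
            members[seen[key]].append(sample)
        else:
            seen[key] = len(vectors)
            vectors.append(core[i])
            members.append([sample])
    ids = [f"H{i + 1}" for i in range(len(vectors))]
    return HaplotypeTable(
        ids=ids,
        vectors=np.array(vectors, dtype=np.uint8).reshape(len(vectors), core.shape[1]),
        members=[tuple(m) for m in members],
        sites=sites,
        n_constant_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Bit-vector helpers (haplotypes as Python int bitmasks for speed)


def _to_bits(vectors: np.ndarray) -> list[int]:
    return [
        int.from_bytes(np.packbits(row, bitorder="little").tobytes(), "little")
        for row in vectors
    ]


def _from_bits(bits: int, n_sites: int) -> np.ndarray:
    raw = bits.to_bytes((n_sites + 7) // 8 or 1, "little")
    return np.unpackbits(np.frombuffer(raw, dtype=np.uint8), bitorder="little")[:n_sites]


def _ham(a: int, b: int) -> int:
    return (a ^ b).bit_count()


def _median(a: int, b: int, c: int) -> int:
    return (a & b) | (a & c) | (b & c)


def _mst_length(vecs: list[int]) -> int:
    """Total weight of a minimum spanning tree over Hamming distances (Prim)."""
    n = len(vecs)
    if n <= 1:
        return 0
    best = [_ham(vecs[0], vecs[j]) for j in range(n)]
    used = [False] * n
    used[0] = True
    total = 0
    for _ in range(n - 1):
        j = min((j for j in range(n) if not used[j]), key=lambda j: (best[j], j))
        total += best[j]
        used[j] = True
        for k in range(n):
            if not used[k]:
                d = _ham(vecs[j], vecs[k])
                if d < best[k]:
                    best[k] = d
    return total


class _DSU:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, x: int) -> int:
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.p[self.find(a)] = self.find(b)


def _msn_edges(vecs: list[int], epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Edges (i, j, weight) of the epsilon-relaxed minimum spanning network.

    An edge joins two vectors iff its weight is within ``epsilon`` of the
    smallest weight that would connect their components (union-of-MSTs for
    epsilon = 0).
    """
    n = len(vecs)
    edges = sorted(
        (_ham(vecs[i], vecs[j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    )
    dsu = _DSU(n)
    out: list[tuple[int, int, int]] = []
    pending: list[tuple[int, int, int]] = []  # unions delayed by epsilon
    for w, group in itertools.groupby(edges, key=lambda e: e[0]):
        while pending and pending[0][0] <= w - epsilon - 1:
            _, i, j = pending.pop(0)
            dsu.union(i, j)
        batch = list(group)
        for _, i, j in batch:
            if dsu.find(i) != dsu.find(j):
                out.append((i, j, w))
        pending.extend(batch)
    return out


# ---------------------------------------------------------------------------
# Median joining


def median_joining(ht: HaplotypeTable, epsilon: int = 0, max_medians: int = 256) -> HaploNetwork:
    """Build the median-joining network over the observed haplotypes.

    Candidate medians come from triples connected in the current
    minimum-spanning network; a single best length-reducing candidate is
    inserted per round (ties to the lexicographically smallest vector, for
    determinism). Obsolete medians — those whose removal leaves the spanning
    length unchanged — are pruned before the final network is assembled.
    """
    n_sites = len(ht.sites)
    observed = _to_bits(ht.vectors)
    if len(set(observed)) != len(observed):
        raise ValueError("haplotype vectors must be pairwise distinct")
    current = list(observed)

    while True:
        if len(current) - len(observed) >= max_medians:
            raise RuntimeError(f"exceeded {max_medians} median vectors; data too reticulate")
        edges = _msn_edges(current, epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(current))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[int] = set()
        present = set(current)
        for v, nb in adj.items():
            for u, w in itertools.combinations(sorted(nb), 2):
                m = _median(current[u], current[v], current[w])
                if m not in present:
                    candidates.add(m)
        if not candidates:
            break
        base = _mst_length(current)
        best_m, best_red = None, 0
        for m in sorted(candidates):
            red = base - _mst_length(current + [m])
            if red > best_red:
                best_m, best_red = m, red
        if best_m is None:
            break
        current.append(best_m)

    # prune medians that no longer shorten the network
    total = _mst_length(current)
    changed = True
    while changed:
        changed = False
        for m in sorted(v for v in current if v not in set(observed)):
            trial = [v for v in current if v != m]
            if _mst_length(trial) == total:
                current = trial
                changed = True
                break

    return _assemble(ht, observed, current, n_sites, epsilon)


def _assemble(
    ht: HaplotypeTable,
    observed: list[int],
    final: list[int],
    n_sites: int,
    epsilon: int,
) -> HaploNetwork:
    g = nx.Graph()
    names: dict[int, str] = {}
    for i, bits in enumerate(observed):
        names[bits] = ht.ids[i]
        g.add_node(
            ht.ids[i],
            vector=bits,
            is_median=False,
            members=ht.members[i],
            multiplicity=len(ht.members[i]),
        )
    mv = 0
    for bits in final:
        if bits not in names:
            mv += 1
            names[bits] = f"mv{mv}"
            g.add_node(names[bits], vector=bits, is_median=True, members=(), multiplicity=0)
    for i, j, w in _msn_edges(final, epsilon):
        u, v = final[i], final[j]
        diff = u ^ v
        site_idx = tuple(k for k in range(n_sites) if diff >> k & 1)
        g.add_edge(names[u], names[v], length=w, sites=site_idx)
    return HaploNetwork(graph=g, sites=list(ht.sites))


# ---------------------------------------------------------------------------
# Exhaustive oracle (tests only)


def median_closure(vectors: list[int], limit: int = 4096) -> set[int]:
    """Close a vector set under triple-wise majority."""
    closed = set(vectors)
    while True:
        new: set[int] = set()
        for a, b, c in itertools.combinations(sorted(closed), 3):
            m = _median(a, b, c)
            if m not in closed:
                new.add(m)
        if not new:
            return closed
        closed |= new
        if len(closed) > limit:
            raise RuntimeError(f"median closure exceeds {limit} vectors")


def network_oracle(ht: HaplotypeTable, max_extra: int = 18) -> HaploNetwork:
    """Minimum-length spanning network by exhaustive enumeration.

    Enumerates every subset of the non-observed median-closure vectors and
    returns a minimum spanning network over the best augmented set. Intended
    as an independent test oracle; refuses large instances.
    """
    if ht.n_haplotypes > 12 or len(ht.sites) > 64:
        raise ValueError("oracle limited to <= 12 haplotypes and <= 64 sites")
    observed = _to_bits(ht.vectors)
    extras = sorted(median_closure(observed) - set(observed))
    if len(extras) > max_extra:
        raise ValueError(f"{len(extras)} candidate medians exceed the oracle limit {max_extra}")
    best_set, best_len = list(observed), _mst_length(observed)
    for r in range(1, len(extras) + 1):
        for combo in itertools.combinations(extras, r):
            vecs = observed + list(combo)
            ln = _mst_length(vecs)
            if ln < best_len:
                best_set, best_len = vecs, ln
    return _assemble(ht, observed, best_set, len(ht.sites), epsilon=0)


# ---------------------------------------------------------------------------
# Haplogroups


def assign_haplogroups(net: HaploNetwork, seeds: dict[str, str]) -> HaplogroupPartition:
    """Partition the network by cutting the longest edge between unlike seeds.

    ``seeds`` maps node ids to haplogroup labels (at least two distinct
    labels on two nodes). The single longest edge lying on a path between
    differently-labeled seeds is removed and labels propagate within the
    resulting components. Ties among longest edges are an error listing the
    candidates, as is any cut that fails to separate the labels.
    """
    if len(seeds) < 2 or len(set(seeds.values())) < 2:
        raise ValueError("need seed labels on >= 2 nodes with >= 2 distinct labels")
    g = net.graph
    for node in seeds:
        if node not in g:
            raise KeyError(f"seed node {node!r} not in network")

    path_edges: set[tuple[str, str]] = set()
    for u, v in itertools.combinations(sorted(seeds), 2):
        if seeds[u] == seeds[v]:
            continue
        path = nx.shortest_path(g, u, v, weight="length")
        for a, b in zip(path, path[1:]):
            path_edges.add((min(a, b), max(a, b)))
    longest = max(g.edges[e]["length"] for e in path_edges)
    top = sorted(e for e in path_edges if g.edges[e]["length"] == longest)
    if len(top) != 1:
        raise ValueError(
            f"tie among longest candidate split edges (length {longest}): {top}; "
            "manual resolution required"
        )
    split = top[0]
    cut = g.copy()
    cut.remove_edge(*split)
    labels: dict[str, str] = {}
    for comp in nx.connected_components(cut):
        comp_labels = {seeds[n] for n in comp if n in seeds}
        if len(comp_labels) > 1:
            raise ValueError(f"cut does not separate labels {comp_labels}")
        if comp_labels:
            lab = comp_labels.pop()
            for n in comp:
                labels[n] = lab
    return HaplogroupPartition(
        labels=labels, split_edge=split, split_length=int(g.edges[split]["length"])
    )


# ---------------------------------------------------------------------------
# Export


def network_tables(net: HaploNetwork, labels: dict[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nodes and edges tables for on-disk export."""
    nodes = pd.DataFrame(
        [
            {
                "node": n,
                "multiplicity": d["multiplicity"],
                "members": ",".join(d["members"]),
                "is_median": int(d["is_median"]),
                "haplogroup": (labels or {}).get(n, ""),
                "vector": "".join(
                    str(b) for b in _from_bits(d["vector"], len(net.sites))
                ),
            }
            for n, d in sorted(net.graph.nodes(data=True))
        ]
    )
    edges = pd.DataFrame(
        [
            {
                "u": min(u, v),
                "v": max(u, v),
                "length": d["length"],
                "sites": ";".join(net.sites[k].label() for k in d["sites"]),
            }
            for u, v, d in net.graph.edges(data=True)
        ]
    ).sort_values(["u", "v"], ignore_index=True) if net.graph.number_of_edges() else pd.DataFrame(
        columns=["u", "v", "length", "sites"]
    )
    return nodes, edges


def network_from_tables(nodes: pd.DataFrame, edges: pd.DataFrame) -> HaploNetwork:
    """Rebuild a network from exported tables (vectors as 0/1 strings).

    Edge site labels are parsed back into :class:`Site` objects; topology,
    lengths, vectors and multiplicities round-trip exactly.
    """
    g = nx.Graph()
    n_sites = len(str(nodes.iloc[0]["vector"])) if len(nodes) else 0
    for _, r in nodes.iterrows():
        vec = str(r["vector"])
        bits = int(vec[::-1], 2) if vec else 0
        raw = "" if pd.isna(r["members"]) else str(r["members"])
        members = tuple(raw.split(",")) if raw else ()
        g.add_node(
            r["node"],
            vector=bits,
            is_median=bool(int(r["is_median"])),
            members=members,
            multiplicity=int(r["multiplicity"]),
        )
    site_index: dict[str, int] = {}
    sites: list[Site] = []
    pending = []
    for _, r in edges.iterrows():
        raw = "" if pd.isna(r["sites"]) else str(r["sites"])
        idx = []
        for lbl in filter(None, raw.split(";")):
            if lbl not in site_index:
                site_index[lbl] = len(sites)
                sites.append(Site.from_label(lbl))
            idx.append(site_index[lbl])
        pending.append((r["u"], r["v"], int(r["length"]), tuple(idx)))
    for u, v, length, idx in pending:
        g.add_edge(u, v, length=length, sites=idx)
    if len(sites) < n_sites:
        sites += [Site("pad", i + 1) for i in range(n_sites - len(sites))]
    return HaploNetwork(graph=g, sites=sites)


def to_dot(net: HaploNetwork, labels: dict[str, str] | None = None) -> str:
    """GraphViz DOT export (node size by multiplicity, edge label = length)."""
    lines = ["graph msy_network {", "  node [shape=circle];"]
    for n, d in sorted(net.graph.nodes(data=True)):
        if d["is_median"]:
            lines.append(f'  "{n}" [shape=point, label=""];')
        else:
            attr = f'label="{n}\\n{",".join(d["members"])}"'
            hg = (labels or {}).get(n)
            if hg:
                attr += f', group="{hg}"'
            lines.append(f'  "{n}" [{attr}];')
    for u, v, d in sorted(net.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label="{d["length"]}"];')
    lines.append("}")
    return "\n".join(lines)
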