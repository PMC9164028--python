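"""Network module detection by node-similarity agglomeration.

Two genes are topologically similar when they share many network
neighbours relative to their connectivity:

    s_ij = (h_ij + a_ij) / (c_i + c_j - h_ij - a_ij)

where h_ij counts shared neighbours, a_ij is 1 if i and j are adjacent
(else 0), and c_i, c_j are the node degrees. s is in [0, 1]: 1 for an
isolated edge or an adjacent pair in a triangle, 0 for nodes with no
topological overlap.

Modules are grown by average-linkage agglomerative clustering on s:
starting from singletons, the pair of edge-connected clusters with the
highest mean pairwise node similarity is merged, repeatedly, while that
mean stays at or above the cutoff. Restricting merges to edge-connected
cluster pairs keeps every module a connected subgraph, matching the
biological reading of a module as a co-regulated gene group. Clusters
reaching the minimum size become modules; the rest are unassigned.
Ties are broken by the lexicographically smallest cluster pair, so the
partition is deterministic and independent of edge-list row order.

Similarities are computed on demand from adjacency sets; no dense
gene-by-gene similarity matrix is ever materialized.
"""

from __future__ import annotations

from itertools import product

from .errors import CoexnetError
from .io import CoexpressionNetwork, ModulePartition

__all__ = ["node_similarity", "identify_modules"]


def node_similarity(net: CoexpressionNetwork, i: str, j: str) -> float:
    """Shared-neighbour similarity of two distinct network genes, in [0, 1]."""
    if i == j:
        raise CoexnetError("node similarity is undefined for i == j")
    if i not in net.nodes or j not in net.nodes:
        raise CoexnetError(f"gene {i!r} or {j!r} not in network")
    ni, nj = net.neighbors(i), net.neighbors(j)
    h = len(ni & nj)
    a = 1 if j in ni else 0
    num = h + a
    if num == 0:
        return 0.0
    return num / (len(ni) + len(nj) - h - a)


def identify_modules(
    net: CoexpressionNetwork,
    similarity_cutoff: float = 0.5,
    min_module_size: int = 3,
) -> ModulePartition:
    """Agglomerate network genes into modules.

    Parameters
    ----------
    net
        Non-empty co-expression network.
    similarity_cutoff
        Minimum average pairwise node similarity for a merge, in (0, 1].
        A cutoff above 1 vacuously prevents all merges.
    min_module_size
        Clusters smaller than this end up unassigned.
    """
    if net.n_edges == 0:
        raise CoexnetError("cannot detect modules in an empty network")
    if similarity_cutoff <= 0:
        raise CoexnetError("similarity_cutoff must be > 0")

    nodes = sorted(net.nodes)
    # cluster id = lexicographic minimum member (stable under merging)
    clusters: dict[str, set[str]] = {g: {g} for g in nodes}
    cadj: dict[str, set[str]] = {g: set() for g in nodes}  # edge-connected ids
    for a, b, *_ in net.edges():
        cadj[a].add(b)
        cadj[b].add(a)

    sim_cache: dict[tuple[str, str], float] = {}

    def node_sim(u: str, v: str) -> float:
        key = (u, v) if u < v else (v, u)
        if key not in sim_cache:
            sim_cache[key] = node_similarity(net, u, v)
        return sim_cache[key]

    def avg_sim(ca: str, cb: str) -> float:
        A, B = clusters[ca], clusters[cb]
        total = sum(node_sim(u, v) for u, v in product(A, B))
        return total / (len(A) * len(B))

    while True:
        best = None  # (avg, pair tie key, id_a, id_b)
        for ca in sorted(clusters):
            for cb in sorted(cadj[ca]):
                if cb <= ca:
                    continue
                avg = avg_sim(ca, cb)
                tie = (ca, cb)  # ids are min members, already sorted
                if best is None or avg > best[0] or (avg == best[0] and tie < best[1]):
                    best = (avg, tie, ca, cb)
        if best is None or best[0] < similarity_cutoff:
            break
        _, _, ca, cb = best
        clusters[ca] |= clusters.pop(cb)
        new_adj = (cadj.pop(ca) | cadj.pop(cb)) - {ca, cb}
        cadj[ca] = new_adj
        for other in new_adj:
            cadj[other].discard(cb)
            cadj[other].add(ca)
        # keep the id = min member invariant (ca < cb so ca is still min)

    modules = sorted(
        (frozenset(c) for c in clusters.values() if len(c) >= min_module_size),
        key=min,
    )
    assigned = set().union(*modules) if modules else set()
    unassigned = set(nodes) - assigned
    return ModulePartition(list(modules), unassigned)
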