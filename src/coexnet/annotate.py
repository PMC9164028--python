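"""Guilt-by-association function annotation and its evaluation.

An unknown gene (typically a lncRNA) is annotated by "voting" among
functionally characterized genes it is associated with — either its
direct network neighbours or the other members of its module. For a
target with n annotated associates, of which k carry a term present in
M of the N background genes, the enrichment p-value is the
hypergeometric upper tail

    p = 1 - sum_{i=0}^{k-1} C(M, i) C(N-M, n-i) / C(N, n).

Benjamini-Hochberg FDR control is applied jointly across every
(target, term) test of a run; both raw and adjusted values are reported.
By default the background N is the set of genes that are both in the
network and annotated, which avoids inflating M with genes that can
never be neighbours; ``background="annotation"`` uses all annotated
genes instead.

Random walk with restart (RWR) offers score-based prioritization: with
W the column-normalized adjacency of the network and p0 the seed
distribution, iterate

    p_k = alpha * p0 + (1 - alpha) * W @ p_{k-1}

to convergence; the stationary scores rank every gene's proximity to
the seeds and sum to one.

``evaluate_accuracy`` quantifies how trustworthy the transfer is on a
given dataset: each annotated gene's labels are hidden in turn and the
method is asked to recover them; accuracy is compared against the same
procedure on a degree-preserving shuffled network, which destroys the
co-expression signal while keeping every node's connectivity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import CoexnetError
from .io import AnnotationMap, CoexpressionNetwork, ModulePartition
from .modules import identify_modules
from .network import bh_fdr

logger = logging.getLogger("coexnet")

__all__ = [
    "EnrichmentRecord",
    "NodeScoreVector",
    "AccuracyReport",
    "hypergeom_pvalue",
    "annotate_by_neighbors",
    "annotate_by_module",
    "rwr",
    "shuffle_network",
    "evaluate_accuracy",
]


@dataclass
class EnrichmentRecord:
    """One (target gene, term) enrichment test.

    k of the target's n annotated associates carry the term, which is
    present in M of the N background genes.
    """

    gene: str
    term: str
    k: int
    n: int
    M: int
    N: int
    pvalue: float
    fdr: float | None = None


@dataclass
class NodeScoreVector:
    """Per-gene relevance scores from network propagation; sums to 1."""

    scores: dict[str, float]

    def top(self, k: int) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]


@dataclass
class AccuracyReport:
    """Leave-one-out annotation accuracy, real network vs shuffled control."""

    accuracy: float
    control_accuracy: float
    difference: float
    n_evaluated: int
    n_hits: int
    n_no_annotated_neighbors: int
    control_n_evaluated: int
    control_n_hits: int
    mode: str


def hypergeom_pvalue(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability of >= k successes.

    Drawing n genes from a background of N containing M term carriers,
    the probability of seeing k or more carriers. k = 0 returns 1.
    Evaluated via the survival function in log space for stability.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(n, M)):
        raise CoexnetError(
            f"invalid hypergeometric bounds N={N}, M={M}, n={n}, k={k}"
        )
    if k == 0:
        return 1.0
    lgN = _lchoose(N, n)
    log_terms = [
        _lchoose(M, i) + _lchoose(N - M, n - i) - lgN
        for i in range(k, min(n, M) + 1)
    ]
    hi = max(log_terms)
    return float(min(1.0, math.exp(hi) * math.fsum(math.exp(t - hi) for t in log_terms)))


def _lchoose(a: int, b: int) -> float:
    """log C(a, b); -inf when the coefficient is zero (b < 0 or b > a)."""
    if b < 0 or b > a:
        return -math.inf
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def _enrich(
    neighbor_sets: dict[str, set[str]],
    ann: AnnotationMap,
    background: set[str],
    max_fdr: float,
) -> list[EnrichmentRecord]:
    """Hypergeometric tests for every (target, term) with joint BH-FDR."""
    N = len(background)
    records: list[EnrichmentRecord] = []
    for gene in sorted(neighbor_sets):
        annotated = {
            g for g in neighbor_sets[gene] if g in background and ann.terms_of(g)
        }
        n = len(annotated)
        if n == 0:
            continue
        terms = sorted({t for g in annotated for t in ann.terms_of(g)})
        for term in terms:
            carriers = ann.genes_of(term) & background
            M = len(carriers)
            k = len(annotated & carriers)
            records.append(
                EnrichmentRecord(
                    gene, term, k, n, M, N, hypergeom_pvalue(N, M, n, k)
                )
            )
    if not records:
        return []
    adj = bh_fdr([r.pvalue for r in records])
    for r, q in zip(records, adj):
        r.fdr = float(q)
    out = [r for r in records if r.fdr <= max_fdr]
    out.sort(key=lambda r: (r.gene, r.pvalue, r.term))
    return out


def _background(universe: set[str], ann: AnnotationMap, background: str) -> set[str]:
    if background == "network":
        return {g for g in universe if ann.terms_of(g)}
    if background == "annotation":
        return ann.genes
    raise CoexnetError(f"unknown background {background!r}")


def annotate_by_neighbors(
    net: CoexpressionNetwork,
    ann: AnnotationMap,
    targets,
    max_fdr: float = 0.05,
    background: str = "network",
) -> list[EnrichmentRecord]:
    """Annotate targets from the terms of their direct network neighbours.

    Targets absent from the network are skipped with a warning. Records
    with FDR <= *max_fdr* are returned sorted by (gene, p-value).
    """
    nodes = net.nodes
    neighbor_sets = {}
    for gene in targets:
        if gene not in nodes:
            logger.warning("target %r not in network; skipped", gene)
            continue
        neighbor_sets[gene] = net.neighbors(gene)
    bg = _background(nodes, ann, background)
    return _enrich(neighbor_sets, ann, bg, max_fdr)


def annotate_by_module(
    partition: ModulePartition,
    ann: AnnotationMap,
    targets,
    max_fdr: float = 0.05,
    background: str = "network",
) -> list[EnrichmentRecord]:
    """Annotate targets from the other members of their module.

    Unassigned targets receive no records. Same arithmetic and FDR
    handling as :func:`annotate_by_neighbors`.
    """
    universe = partition.assigned | partition.unassigned
    neighbor_sets = {}
    for gene in targets:
        if gene not in universe:
            logger.warning("target %r not in partition; skipped", gene)
            continue
        idx = partition.module_of(gene)
        if idx is None:
            continue
        neighbor_sets[gene] = set(partition.modules[idx]) - {gene}
    bg = _background(universe, ann, background)
    return _enrich(neighbor_sets, ann, bg, max_fdr)


def rwr(
    net: CoexpressionNetwork,
    seeds,
    alpha: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 1000,
    weighted: bool = False,
) -> NodeScoreVector:
    """Random walk with restart from seed genes.

    Parameters
    ----------
    seeds
        Gene set (uniform restart) or gene -> weight mapping (normalized).
    alpha
        Restart probability in (0, 1]; alpha = 1 returns the seed
        distribution itself.
    weighted
        Use |correlation|-weighted columns instead of the unweighted
        adjacency.

    The walk matrix W is the column-normalized adjacency; a zero-degree
    column teleports back to the seed distribution (logged). Iteration
    stops once the L1 change drops below *tol*; the result sums to 1.
    """
    if not (0 < alpha <= 1):
        raise CoexnetError("alpha must be in (0, 1]")
    nodes = sorted(net.nodes)
    if not nodes:
        raise CoexnetError("RWR requires a non-empty network")
    index = {g: i for i, g in enumerate(nodes)}

    if isinstance(seeds, dict):
        seed_items = sorted(seeds.items())
        if not seed_items:
            raise CoexnetError("seed set is empty")
        missing = [g for g, _ in seed_items if g not in index]
        if missing:
            raise CoexnetError(f"seed gene(s) not in network: {missing}")
        p0 = np.zeros(len(nodes))
        for g, w in seed_items:
            if w < 0:
                raise CoexnetError("seed weights must be non-negative")
            p0[index[g]] = w
        if p0.sum() == 0:
            raise CoexnetError("seed weights sum to zero")
    else:
        seed_list = sorted(set(seeds))
        if not seed_list:
            raise CoexnetError("seed set is empty")
        missing = [g for g in seed_list if g not in index]
        if missing:
            raise CoexnetError(f"seed gene(s) not in network: {missing}")
        p0 = np.zeros(len(nodes))
        p0[[index[g] for g in seed_list]] = 1.0
    p0 /= p0.sum()

    A = np.zeros((len(nodes), len(nodes)))
    for a, b, w, _p, _f in net.edges():
        val = abs(w) if weighted else 1.0
        A[index[a], index[b]] = val
        A[index[b], index[a]] = val
    col = A.sum(axis=0)
    dangling = col == 0
    if dangling.any():
        logger.info("%d zero-degree column(s) teleport to the seeds", dangling.sum())
    W = A / np.where(dangling, 1.0, col)  # dangling columns are all-zero already

    p = p0.copy()
    for _ in range(max_iter):
        spill = p[dangling].sum()  # mass on dangling nodes restarts
        p_new = alpha * p0 + (1 - alpha) * (W @ p + spill * p0)
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    # alpha*1 + (1-alpha)*1 with a column-stochastic walk: mass stays 1
    return NodeScoreVector({g: float(p[index[g]]) for g in nodes})


def shuffle_network(
    net: CoexpressionNetwork,
    seed: int,
    n_swaps_per_edge: int = 10,
) -> CoexpressionNetwork:
    """Degree-preserving randomization by double-edge swaps.

    Picks two edges (a, b), (c, d) and rewires them to (a, d), (c, b),
    rejecting swaps that would create self-edges or duplicate edges; the
    degree sequence is left exactly intact. Runs until
    ``n_swaps_per_edge * n_edges`` successful swaps or an attempt cap.
    If no legal swap exists (e.g. a triangle), the input is returned
    unchanged with a warning. Deterministic for a given seed.
    """
    if net.n_edges < 2:
        raise CoexnetError("shuffling requires >= 2 edges")
    rng = np.random.default_rng(seed)
    edges = [(a, b) for a, b, *_ in net.edges()]
    weights = {(a, b): w for a, b, w, _p, _f in net.edges()}
    edge_set = set(edges)
    target = n_swaps_per_edge * len(edges)
    max_attempts = 100 * target
    done = 0
    for _ in range(max_attempts):
        if done >= target:
            break
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):  # also try the crossed pairing
            c, d = d, c
        if a == d or c == b or a == c or b == d:
            continue
        new1 = (a, d) if a < d else (d, a)
        new2 = (c, b) if c < b else (b, c)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        w1, w2 = weights.pop(edges[i]), weights.pop(edges[j])
        edges[i], edges[j] = new1, new2
        edge_set.update((new1, new2))
        weights[new1], weights[new2] = w1, w2
        done += 1
    if done == 0:
        logger.warning("no legal double-edge swap exists; network unchanged")
        return net
    out = CoexpressionNetwork()
    for (a, b) in edges:
        out.add_edge(a, b, weights[(a, b)])
    return out


def _loo_accuracy(
    net: CoexpressionNetwork,
    ann: AnnotationMap,
    max_fdr: float,
    mode: str,
    background: str,
) -> tuple[int, int, int]:
    """(hits, evaluated, skipped-for-no-annotated-neighbors) over LOO."""
    if mode == "module":
        partition = identify_modules(net)
    hits = evaluated = skipped = 0
    for gene in sorted(net.nodes):
        true_terms = ann.terms_of(gene)
        if not true_terms:
            continue
        hidden = ann.without_gene(gene)
        if mode == "neighbors":
            records = annotate_by_neighbors(
                net, hidden, {gene}, max_fdr=max_fdr, background=background
            )
            has_annotated = any(hidden.terms_of(g) for g in net.neighbors(gene))
        elif mode == "module":
            records = annotate_by_module(
                partition, hidden, {gene}, max_fdr=max_fdr, background=background
            )
            idx = partition.module_of(gene)
            members = partition.modules[idx] - {gene} if idx is not None else set()
            has_annotated = any(hidden.terms_of(g) for g in members)
        else:
            raise CoexnetError(f"unknown mode {mode!r}")
        if not has_annotated:
            skipped += 1
            continue
        evaluated += 1
        if any(r.term in true_terms for r in records):
            hits += 1
    return hits, evaluated, skipped


def evaluate_accuracy(
    net: CoexpressionNetwork,
    ann: AnnotationMap,
    max_fdr: float = 0.05,
    mode: str = "neighbors",
    control_seed: int = 0,
    background: str = "network",
) -> AccuracyReport:
    """Leave-one-out annotation accuracy vs a shuffled-network control.

    Each annotated network gene's labels are hidden in turn; a prediction
    counts as a hit when any true term appears among its FDR-passing
    records. Genes with no annotated associates are excluded from the
    denominator and reported separately. The identical procedure runs on
    a degree-preserving shuffle of the network; a real-minus-control gap
    indicates genuine co-expression signal rather than degree artefacts.
    """
    if not ann.genes:
        raise CoexnetError("annotation map is empty")
    hits, evaluated, skipped = _loo_accuracy(net, ann, max_fdr, mode, background)
    if evaluated == 0:
        raise CoexnetError("no annotated gene with annotated associates to evaluate")
    shuffled = shuffle_network(net, control_seed)
    c_hits, c_eval, _c_skip = _loo_accuracy(shuffled, ann, max_fdr, mode, background)
    accuracy = hits / evaluated
    control = c_hits / c_eval if c_eval else 0.0
    return AccuracyReport(
        accuracy=accuracy,
        control_accuracy=control,
        difference=accuracy - control,
        n_evaluated=evaluated,
        n_hits=hits,
        n_no_annotated_neighbors=skipped,
        control_n_evaluated=c_eval,
        control_n_hits=c_hits,
        mode=mode,
    )
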