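"""Co-expression network construction, merging and summary statistics.

An edge links two genes whose expression profiles correlate across
samples. Correlation is plain Pearson

    rho = sum_i (x_i - xbar)(y_i - ybar) /
          sqrt(sum_i (x_i - xbar)^2 * sum_i (y_i - ybar)^2)

or Spearman (the same statistic on average ranks), used directly without
soft thresholding — the simplest, most transparent construction. Spearman
is the default: it is robust to outliers and the usual recommendation for
RNA-Seq. Each pair additionally gets a two-sided p-value from the exact
t transform of rho and a Benjamini-Hochberg FDR computed over *all*
evaluated pairs; edges must pass both the |rho| and FDR thresholds
(optionally rho > 0 only, since negative co-expression is often not
biologically meaningful).

All-pairs correlation is computed in row chunks (optionally across a
thread pool) with a deterministic reduction order, so the output is
byte-identical regardless of thread count.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CoexnetError
from .io import CoexpressionNetwork, ExpressionMatrix

logger = logging.getLogger("coexnet")

__all__ = [
    "pearson",
    "spearman",
    "correlation_pvalue",
    "bh_fdr",
    "build_network",
    "merge_networks",
    "network_stats",
    "NetworkStats",
]


def pearson(x, y) -> float:
    """Pearson correlation of two equal-length vectors (n >= 3).

    A constant vector has undefined correlation and raises; at network
    level such genes are skipped rather than aborting the run.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CoexnetError("vectors must be 1-D and of equal length")
    if len(x) < 3:
        raise CoexnetError("correlation requires >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise CoexnetError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def spearman(x, y) -> float:
    """Spearman correlation: Pearson on average ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pearson(stats.rankdata(x), stats.rankdata(y))


def correlation_pvalue(rho: float, n: int) -> float:
    """Two-sided p-value for a correlation of *rho* over *n* observations.

    Uses the exact null transform t = rho * sqrt((n-2) / (1-rho^2)) on
    n-2 degrees of freedom; |rho| = 1 returns 0 by convention.
    """
    if n < 3:
        raise CoexnetError("p-value requires n >= 3")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise CoexnetError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def _chunk_corr(Z: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Correlations of standardized rows [i0, i1) against all rows."""
    return Z[i0:i1] @ Z.T


def build_network(
    m: ExpressionMatrix,
    method: str = "spearman",
    min_abs_rho: float = 0.8,
    max_fdr: float = 0.05,
    positive_only: bool = False,
    threads: int = 1,
) -> CoexpressionNetwork:
    """Evaluate all unordered gene pairs and keep the significant ones.

    An edge is kept iff ``|rho| >= min_abs_rho`` and ``fdr <= max_fdr``
    (and ``rho > 0`` when *positive_only*). The FDR is adjusted over every
    evaluated pair, not just those passing the correlation cut. Genes with
    constant expression are skipped with a logged count. Fewer than 3
    samples is an error; zero surviving edges yields an empty network with
    a warning.
    """
    if m.n_samples < 3:
        raise CoexnetError("network construction requires >= 3 samples")
    if m.n_genes < 2:
        raise CoexnetError("network construction requires >= 2 genes")
    if method not in ("pearson", "spearman"):
        raise CoexnetError(f"unknown correlation method {method!r}")

    X = m.values
    if method == "spearman":
        X = stats.rankdata(X, axis=1, method="average")
    sd = X.std(axis=1)
    keep = sd > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.info("skipping %d constant-expression gene(s)", n_const)
    genes = [g for g, k in zip(m.gene_ids, keep) if k]
    Xk = X[keep]
    ng = len(genes)
    if ng < 2:
        logger.warning("fewer than 2 variable genes; empty network")
        return CoexpressionNetwork()

    Z = Xk - Xk.mean(axis=1, keepdims=True)
    Z /= np.linalg.norm(Z, axis=1, keepdims=True)

    # chunked upper-triangle extraction; chunk order fixes reduction order
    chunk = max(1, min(512, ng))
    bounds = [(i, min(i + chunk, ng)) for i in range(0, ng, chunk)]
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            blocks = list(pool.map(lambda b: _chunk_corr(Z, *b), bounds))
    else:
        blocks = [_chunk_corr(Z, *b) for b in bounds]

    rows_i: list[np.ndarray] = []
    rows_j: list[np.ndarray] = []
    rhos: list[np.ndarray] = []
    for (i0, i1), block in zip(bounds, blocks):
        for local, i in enumerate(range(i0, i1)):
            rho_row = np.clip(block[local, i + 1 :], -1.0, 1.0)
            rows_i.append(np.full(ng - i - 1, i))
            rows_j.append(np.arange(i + 1, ng))
            rhos.append(rho_row)
    ii = np.concatenate(rows_i)
    jj = np.concatenate(rows_j)
    rho = np.concatenate(rhos)

    n = m.n_samples
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    pvals[np.abs(rho) >= 1.0] = 0.0
    fdr = bh_fdr(pvals)

    mask = (np.abs(rho) >= min_abs_rho) & (fdr <= max_fdr)
    if positive_only:
        mask &= rho > 0

    net = CoexpressionNetwork()
    for i, j, r, p, q in zip(
        ii[mask], jj[mask], rho[mask], pvals[mask], fdr[mask]
    ):
        net.add_edge(genes[i], genes[j], float(r), float(p), float(q))
    if net.n_edges == 0:
        logger.warning("no gene pair passed the thresholds; empty network")
    return net


def merge_networks(nets, min_support: int = 1) -> CoexpressionNetwork:
    """Aggregate networks: keep edges supported by >= *min_support* inputs.

    The merged weight is the mean of the weights in the networks containing
    the edge; p-value/FDR are dropped (they are no longer meaningful for an
    aggregated edge). Aggregation across independent datasets improves
    co-expression reliability.
    """
    nets = list(nets)
    if len(nets) < 2:
        raise CoexnetError("merge requires >= 2 networks")
    if not (1 <= min_support <= len(nets)):
        raise CoexnetError(
            f"min_support must be in [1, {len(nets)}], got {min_support}"
        )
    support: dict[tuple[str, str], list[float]] = {}
    for net in nets:
        for a, b, w, _p, _f in net.edges():
            support.setdefault((a, b), []).append(w)
    out = CoexpressionNetwork()
    for (a, b), weights in support.items():
        if len(weights) >= min_support:
            out.add_edge(a, b, float(np.mean(weights)))
    return out


@dataclass
class NetworkStats:
    """Node/edge counts plus the degree distribution.

    ``loglog`` holds ``(log10 degree, log10 frequency)`` pairs for a
    scale-free check: co-expression degree distributions approximately
    follow a power law, a straight line in these coordinates.
    """

    n_nodes: int
    n_edges: int
    degree_hist: dict[int, int]
    loglog: list[tuple[float, float]]


def network_stats(net: CoexpressionNetwork) -> NetworkStats:
    """Summarize a non-empty network's size and degree distribution."""
    if net.n_edges == 0:
        raise CoexnetError("cannot summarize an empty network")
    degrees = [net.degree(g) for g in net.nodes]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    loglog = [
        (float(np.log10(k)), float(np.log10(c)))
        for k, c in sorted(hist.items())
        if k >= 1
    ]
    return NetworkStats(net.n_nodes, net.n_edges, dict(sorted(hist.items())), loglog)
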