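"""Expression-matrix normalization and gene filtering.

Five normalization methods are provided, all per-sample rescalings except
quantile normalization (a value substitution):

* **median** — every sample is scaled so its median equals the mean of
  the per-sample medians (zeros included in the median).
* **quantile** — each sample's sorted values are replaced by the
  across-sample mean at that sort rank; afterwards all samples share the
  same empirical distribution. Ties receive the mean of the rank-mean
  values they span (Bolstad-style).
* **median-of-ratios** — DESeq-style size factors: the median, over genes
  expressed in every sample, of the ratio of a sample's value to the
  gene's across-sample geometric mean.
* **TMM** — trimmed mean of M-values with the published defaults:
  reference sample by upper-quartile proximity, two-sided 30% trim on
  log-ratios and 5% on average intensity, delta-method binomial weights,
  factors recentred to log-mean zero.
* **housekeeping** — samples scaled so the median expression of a given
  housekeeping gene list is equalized across samples.

Low-expression filtering drops genes by mean or variance, either the
lowest fraction (default: a quarter of all genes, by mean) or below an
absolute threshold.
"""

from __future__ import annotations

import numpy as np

from .errors import CoexnetError
from .io import ExpressionMatrix

__all__ = [
    "normalize_median",
    "normalize_quantile",
    "normalize_median_of_ratios",
    "normalize_tmm",
    "normalize_housekeeping",
    "filter_genes",
    "log_transform",
]


def normalize_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample by (mean of all sample medians) / (its own median).

    After normalization every sample has the same median. A sample whose
    median is zero cannot be scaled and is an error.
    """
    medians = np.median(m.values, axis=0)
    zero = np.flatnonzero(medians <= 0)
    if zero.size:
        bad = [m.sample_ids[i] for i in zero]
        raise CoexnetError(f"sample(s) with non-positive median: {bad}")
    factors = medians.mean() / medians
    return m.with_values(m.values * factors)


def normalize_quantile(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: substitute rank means for observed values.

    Requires >= 2 samples. Tied values within a sample receive the mean of
    the reference values at the sort positions the tie spans, so the output
    is invariant to how a stable sort orders equal inputs.
    """
    if m.n_samples < 2:
        raise CoexnetError("quantile normalization requires >= 2 samples")
    X = m.values
    ref = np.sort(X, axis=0).mean(axis=1)  # mean distribution by sort rank
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average the reference values across each tie group
        i = 0
        sorted_vals = col[order]
        while i < len(col):
            k = i
            while k + 1 < len(col) and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                assigned[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return m.with_values(out)


def median_of_ratios_factors(m: ExpressionMatrix) -> np.ndarray:
    """DESeq-style size factors.

    Reference genes are those expressed (> 0) in every sample; the factor
    of sample *j* is the median over reference genes of
    ``value / geometric mean across samples``. Raw medians are only
    defined up to a global constant, so factors are recentred to
    geometric mean 1 — this makes the normalization exactly idempotent.
    """
    X = m.values
    ref_genes = np.all(X > 0, axis=1)
    if not ref_genes.any():
        raise CoexnetError(
            "median-of-ratios: no gene is positive in all samples"
        )
    logs = np.log(X[ref_genes])
    geo = logs.mean(axis=1)  # log geometric means
    log_factors = np.median(logs - geo[:, None], axis=0)
    return np.exp(log_factors - log_factors.mean())


def normalize_median_of_ratios(m: ExpressionMatrix):
    """Divide each sample by its median-of-ratios size factor.

    Returns ``(normalized matrix, size factors)``.
    """
    factors = median_of_ratios_factors(m)
    return m.with_values(m.values / factors), factors


def _tmm_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """TMM scaling factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise CoexnetError("TMM: sample shares no positive gene with reference")
    o, r = obs[pos], ref[pos]
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # delta-method variance of M under binomial sampling
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = len(M)
    loM, hiM = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    loA, hiA = np.floor(n * abs_trim) + 1, n + 1 - (np.floor(n * abs_trim) + 1)
    rM = _rank(M)
    rA = _rank(A)
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any():  # degenerate tiny input: fall back to untrimmed
        keep = np.ones(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    if not np.all(np.isfinite(inv_w)):
        inv_w = np.ones(keep.sum())
    f = np.sum(M[keep] * inv_w) / np.sum(inv_w)
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def tmm_factors(m: ExpressionMatrix) -> np.ndarray:
    """TMM scaling factors, recentred so their log-mean is zero.

    The reference is the sample whose upper quartile of library-size-scaled
    values is closest to the mean upper quartile.
    """
    if m.n_samples < 2:
        raise CoexnetError("TMM requires >= 2 samples")
    X = m.values
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise CoexnetError("TMM: sample with zero library size")
    f75 = np.quantile(X / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_factor(X[:, j], X[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(m.n_samples)
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def normalize_tmm(m: ExpressionMatrix):
    """Divide counts by (library size x TMM factor).

    Returns ``(normalized matrix, scaling factors)``. The normalized values
    are on a per-library scale (they sum to ~1/factor per sample); within-
    sample ratios are preserved exactly.
    """
    factors = tmm_factors(m)
    lib = m.values.sum(axis=0)
    return m.with_values(m.values / (lib * factors)), factors


def normalize_housekeeping(m: ExpressionMatrix, hk_genes) -> ExpressionMatrix:
    """Equalize the median of housekeeping-gene expression across samples.

    Sample *j* is scaled by ``mean over samples of HK medians / HK median
    of sample j``. All requested housekeeping genes absent from the matrix
    is an error naming the missing IDs.
    """
    present = [g for g in hk_genes if g in m._gene_index]
    if not present:
        raise CoexnetError(
            f"no housekeeping gene found in matrix; missing: {list(hk_genes)}"
        )
    idx = [m._gene_index[g] for g in present]
    hk_medians = np.median(m.values[idx], axis=0)
    if np.any(hk_medians <= 0):
        bad = [m.sample_ids[i] for i in np.flatnonzero(hk_medians <= 0)]
        raise CoexnetError(f"housekeeping median non-positive in sample(s) {bad}")
    factors = hk_medians.mean() / hk_medians
    return m.with_values(m.values * factors)


def filter_genes(
    m: ExpressionMatrix,
    statistic: str = "mean",
    mode: str = "fraction",
    value: float = 0.25,
) -> ExpressionMatrix:
    """Drop low-expression genes by mean or variance.

    ``mode="fraction"`` removes the lowest ``floor(value * n_genes)`` genes
    by the statistic (ties broken stably by input order); the default — a
    quarter of all genes by mean — is the usual empirical choice for
    de-noising co-expression input. ``mode="threshold"`` keeps genes with
    statistic >= value. Removing every gene is an error.
    """
    if statistic not in ("mean", "variance"):
        raise CoexnetError(f"unknown statistic {statistic!r}")
    stat = (
        m.values.mean(axis=1) if statistic == "mean" else m.values.var(axis=1, ddof=0)
    )
    if mode == "fraction":
        if not (0 <= value < 1):
            raise CoexnetError("fraction must be in [0, 1)")
        n_drop = int(np.floor(value * m.n_genes))
        order = np.argsort(stat, kind="stable")  # ascending; stable tie rule
        drop = set(order[:n_drop].tolist())
        keep = [g for i, g in enumerate(m.gene_ids) if i not in drop]
    elif mode == "threshold":
        keep = [g for g, s in zip(m.gene_ids, stat) if s >= value]
    else:
        raise CoexnetError(f"unknown filter mode {mode!r}")
    if not keep:
        raise CoexnetError("filtering removed every gene")
    return m.subset_genes(keep)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entry-wise ``log2(value + pseudocount)``; pseudocount must be > 0."""
    if pseudocount <= 0:
        raise CoexnetError("pseudocount must be > 0")
    return m.with_values(np.log2(m.values + pseudocount))
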