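"""Synthetic expression data with planted co-expression modules.

The generator emulates the one feature the pipeline actually exploits:
groups of genes sharing a latent expression program. Each block b gets a
latent profile z_b ~ N(0, 1) across samples, and gene g in the block is

    x_g = a * z_b + noise_sd * eps_g,   a = noise_sd * sqrt(r / (1 - r))

so the expected within-block Pearson correlation is exactly the target r
while cross-block correlations are 0 in expectation. The matrix is then
shifted by its global minimum — a correlation-preserving translation —
to satisfy the non-negativity of expression values. A count mode
exponentiates values (2^x) to produce skewed, strictly positive data for
exercising the normalization methods.

Gaussian latent factors rather than negative-binomial counts: the
pipeline is rank/correlation based, so these fixtures exercise every
code path; they make no attempt to mimic a real study's sequencing depth
or dispersion.
"""

from __future__ import annotations

import numpy as np

from .errors import CoexnetError
from .io import AnnotationMap, ExpressionMatrix

__all__ = ["make_block_matrix", "make_annotation"]


def make_block_matrix(
    n_blocks: int = 3,
    genes_per_block: int = 10,
    n_samples: int = 20,
    within_rho: float = 0.9,
    noise_sd: float = 1.0,
    seed: int = 0,
    count_mode: bool = False,
):
    """Generate a block-correlated expression matrix with known modules.

    Returns ``(ExpressionMatrix, labels)`` where *labels* maps each gene
    ID to its 1-based block index. Gene IDs are ``b<block>_g<index>``,
    zero-padded so lexicographic and generation order agree.

    Raises if the target correlation is infeasible (needs
    0 < within_rho < 1 and noise_sd > 0) or n_samples < 4.
    """
    if n_samples < 4:
        raise CoexnetError("need >= 4 samples")
    if not (0 < within_rho < 1):
        raise CoexnetError("within_rho must be in (0, 1)")
    if noise_sd <= 0:
        raise CoexnetError(
            f"within_rho={within_rho} infeasible with noise_sd={noise_sd}"
        )
    rng = np.random.default_rng(seed)
    a = noise_sd * np.sqrt(within_rho / (1.0 - within_rho))
    gene_ids: list[str] = []
    labels: dict[str, int] = {}
    rows = []
    for b in range(1, n_blocks + 1):
        z = rng.standard_normal(n_samples)
        for g in range(1, genes_per_block + 1):
            gid = f"b{b:02d}_g{g:03d}"
            gene_ids.append(gid)
            labels[gid] = b
            rows.append(a * z + noise_sd * rng.standard_normal(n_samples))
    X = np.array(rows)
    if count_mode:
        X = np.exp2(X)
    else:
        X = X - X.min()  # translation: preserves all correlations
    sample_ids = [f"s{j:03d}" for j in range(1, n_samples + 1)]
    return ExpressionMatrix(gene_ids, sample_ids, X), labels


def make_annotation(
    labels: dict[str, int],
    coverage_fraction: float = 1.0,
    seed: int = 0,
) -> AnnotationMap:
    """Annotate a random fraction of each block with its block term.

    Term ``T<block>`` is assigned to ``floor(coverage_fraction * size)``
    genes of each block, sampled without replacement; reproducible for a
    given seed.
    """
    if not (0 < coverage_fraction <= 1):
        raise CoexnetError("coverage_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    by_block: dict[int, list[str]] = {}
    for gene in sorted(labels):
        by_block.setdefault(labels[gene], []).append(gene)
    ann = AnnotationMap()
    for block in sorted(by_block):
        genes = by_block[block]
        n_pick = int(np.floor(coverage_fraction * len(genes)))
        picked = rng.choice(genes, size=n_pick, replace=False)
        for g in sorted(picked):
            ann.add(g, f"T{block}")
    return ann
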