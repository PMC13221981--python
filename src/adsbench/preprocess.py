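"""Normalization and dimensionality reduction ahead of correction and distances.

Library-size differences are removed with median-of-ratios size factors (the
scheme popularised by DESeq-style differential-expression tools): the
reference expression of each gene is its geometric mean across samples,
restricted to genes observed in every sample, and a sample's factor is the
median of its count-to-reference ratios.  Counts are divided column-wise by
the factors, then log2-transformed with a pseudocount.  An exact
variance-stabilizing transformation is deliberately not replicated; see the
methods note for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix

__all__ = ["SizeFactors", "size_factor_normalize", "log_transform", "pca_reduce"]


@dataclass
class SizeFactors:
    """Positive per-sample scaling factors; equal columns get equal factors."""

    factors: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or not np.all(np.isfinite(self.factors)):
            raise ValueError("size factors must be positive and finite")


def size_factor_normalize(
    counts: ExpressionMatrix,
) -> tuple[ExpressionMatrix, SizeFactors]:
    """Median-of-ratios normalization.

    For each gene with strictly positive counts in all samples, compute the
    geometric mean across samples; sample *j*'s factor is the median over
    those reference genes of ``count[g, j] / geomean[g]``.  Returns the counts
    divided column-wise by the factors (kind ``normalized``) and the factors.

    Raises if no gene is positive in every sample.
    """
    if counts.kind != "counts":
        raise ValueError(f"expected kind='counts', got {counts.kind!r}")
    vals = counts.values
    reference = np.all(vals > 0, axis=1)
    if not np.any(reference):
        raise ValueError("no gene has all-positive counts; cannot form the "
                         "median-of-ratios reference set")
    logref = np.log(vals[reference])
    geomean = np.exp(logref.mean(axis=1))
    ratios = vals[reference] / geomean[:, None]
    factors = np.median(ratios, axis=0)
    if np.any(factors <= 0):
        raise ValueError("non-positive size factor encountered")
    normalized = counts.with_values(vals / factors[None, :], kind="normalized")
    return normalized, SizeFactors(factors, counts.sample_ids.copy())


def log_transform(normalized: ExpressionMatrix,
                  pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entrywise ``log2(value + pseudocount)``; returns kind ``logcounts``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if np.any(normalized.values < 0):
        raise ValueError("log transform requires non-negative entries")
    return normalized.with_values(
        np.log2(normalized.values + pseudocount), kind="logcounts")


def pca_reduce(X: ExpressionMatrix, n_components: int) -> ExpressionMatrix:
    """Project samples onto the top principal components of gene-centered data.

    Genes are centered (not scaled); components are ordered by decreasing
    explained variance.  The sign of each component is fixed so that its
    largest-magnitude gene loading is positive, making the output
    deterministic.  Rows of the result are components (kind ``embedding``).
    """
    n_components = int(n_components)
    rank_bound = min(X.n_genes, X.n_samples)
    if not 1 <= n_components <= rank_bound:
        raise ValueError(
            f"n_components must be in [1, {rank_bound}], got {n_components}")
    centered = X.values - X.values.mean(axis=1, keepdims=True)
    # SVD of genes x samples: U holds gene loadings, S*Vt the sample scores.
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    scores = (S * flip)[:, None] * Vt
    comp_ids = np.array([f"PC{i + 1}" for i in range(n_components)], dtype=object)
    return ExpressionMatrix(scores, comp_ids, X.sample_ids.copy(), kind="embedding")
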