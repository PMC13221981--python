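"""Variance models: generating technical-replicate-like perturbations of a
dataset so metric scatter within one dilution level can be assessed.

Two schemes are provided.  Dirichlet-multinomial resampling redraws each
sample's counts from a multinomial whose probabilities are Dirichlet-drawn
with the observed counts as concentration parameters — library sizes are
preserved exactly and observed zeros stay structural zeros.  Gene
bootstrapping resamples genes (rows) with replacement, leaving samples and
their labels untouched.
"""

from __future__ import annotations

import numpy as np

from .data_model import ExpressionMatrix

__all__ = ["dirichlet_multinomial_resample", "bootstrap_genes"]


def dirichlet_multinomial_resample(counts: ExpressionMatrix, seed: int,
                                   pseudocount: float = 0.0) -> ExpressionMatrix:
    """Redraw every sample column from a Dirichlet-multinomial.

    Column *j* with library size ``n_j`` is replaced by
    ``x_j ~ Multinomial(n_j, theta)`` with
    ``theta ~ Dirichlet(counts[:, j])`` restricted to genes with positive
    count (zero-count genes keep probability exactly 0 unless a positive
    ``pseudocount`` is added for sparse single-cell inputs).  Column totals
    are preserved exactly; output is reproducible given ``seed``.
    """
    if counts.kind != "counts":
        raise ValueError(f"expected kind='counts', got {counts.kind!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = counts.values.astype(np.int64)
    totals = vals.sum(axis=0)
    if np.any(totals <= 0):
        bad = list(counts.sample_ids[totals <= 0][:5])
        raise ValueError(f"all-zero column(s): {bad}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(vals)
    for j in range(vals.shape[1]):
        alpha = vals[:, j].astype(float) + pseudocount
        support = np.flatnonzero(alpha > 0)
        theta = rng.dirichlet(alpha[support])
        out[support, j] = rng.multinomial(totals[j], theta)
    return counts.with_values(out, kind="counts")


def bootstrap_genes(X: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Resample genes (rows) with replacement to the original row count.

    Samples and therefore all per-sample annotations are untouched.  Gene ids
    are suffixed with their occurrence index so identifiers stay unique.
    """
    if X.n_genes < 1:
        raise ValueError("empty matrix")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, X.n_genes, size=X.n_genes)
    seen: dict[int, int] = {}
    new_ids = []
    for r in rows:
        c = seen.get(r, 0)
        seen[r] = c + 1
        base = X.gene_ids[r]
        new_ids.append(base if c == 0 else f"{base}.b{c}")
    return ExpressionMatrix(X.values[rows], np.asarray(new_ids, dtype=object),
                            X.sample_ids.copy(), X.kind)
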