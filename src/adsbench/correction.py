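"""Location-scale batch-effect estimation and removal.

The model: for gene *g*, batch *i*, sample *j*,

    Y[g,i,j] = alpha[g] + (X beta)[g] + gamma[i,g] + delta[i,g] * eps[i,j,g]

where ``alpha`` is baseline log-expression, ``beta`` the additive biological
group effects (design matrix X), ``gamma`` an additive per-batch shift and
``delta`` a positive per-batch residual-scale multiplier.  ``fit_ls_model``
estimates all four by gene-wise least squares; ``correct_batch`` inverts the
model:

    Z = (Y - alpha - X beta - gamma) / delta + alpha + X beta

Identifiability: gamma is constrained to batch-size-weighted zero mean per
gene, and the first biological group in sorted label order is the beta
reference level.

``embedding_correct`` is the embedding-space counterpart used on the
single-cell path: it translates every batch's centroid onto the global
centroid in PCA space, leaving within-batch geometry untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, SampleAnnotations

__all__ = ["BatchModelFit", "fit_ls_model", "correct_batch", "embedding_correct"]

DELTA_FLOOR = 1e-6


@dataclass
class BatchModelFit:
    """Per-gene estimates of the location-scale batch model.

    ``beta_hat`` has one column per biological group in sorted label order;
    the first (reference) column is identically zero.  ``gamma_hat`` and
    ``delta_hat`` have one row per batch in sorted label order.
    """

    alpha_hat: np.ndarray          # (G,)
    beta_hat: np.ndarray           # (G, n_groups), reference column 0
    gamma_hat: np.ndarray          # (n_batches, G)
    delta_hat: np.ndarray          # (n_batches, G), positive
    batches: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.delta_hat <= 0):
            raise ValueError("delta_hat must be positive everywhere")


def _design(ann: SampleAnnotations,
            batches: list[str], groups: list[str]) -> np.ndarray:
    """Design matrix [intercept | group dummies | constrained batch contrasts].

    Batch columns encode gamma_1..gamma_{B-1}; gamma_B is determined by the
    batch-size-weighted zero-mean constraint, so the contrast for batch i is
    1{batch=i} - (n_i/n_B) * 1{batch=B}.
    """
    n = ann.n_samples
    batch_idx = np.array([batches.index(b) for b in ann.batch])
    group_idx = np.array([groups.index(g) for g in ann.group])
    n_b = np.bincount(batch_idx, minlength=len(batches))
    cols = [np.ones(n)]
    for k in range(1, len(groups)):
        cols.append((group_idx == k).astype(float))
    B = len(batches)
    last = (batch_idx == B - 1).astype(float)
    for i in range(B - 1):
        cols.append((batch_idx == i).astype(float) - (n_b[i] / n_b[B - 1]) * last)
    return np.column_stack(cols)


def fit_ls_model(Y: ExpressionMatrix, ann: SampleAnnotations,
                 delta_floor: float = DELTA_FLOOR,
                 eb_shrinkage: bool = False) -> BatchModelFit:
    """Gene-wise least-squares fit of the location-scale batch model.

    ``delta_hat[i, g]`` is the standard deviation of gene *g*'s batch-*i*
    residuals divided by the pooled residual standard deviation; genes with
    zero pooled residual variance get delta 1.  Every batch must contain at
    least two samples and batch must not be confounded with the biological
    grouping (full-rank design).

    ``eb_shrinkage`` applies a light empirical-Bayes moderation of the batch
    parameters across genes (normal prior on gamma, moment-matched squeeze of
    delta**2 toward 1); default off.
    """
    if Y.kind not in ("logcounts", "normalized", "embedding"):
        raise ValueError("fit_ls_model expects transformed data, not raw counts")
    if list(Y.sample_ids) != list(ann.sample_ids):
        raise ValueError("matrix and annotations are not aligned")
    batches, groups = ann.batch_levels, ann.group_levels
    batch_idx = np.array([batches.index(b) for b in ann.batch])
    n_b = np.bincount(batch_idx, minlength=len(batches))
    if np.any(n_b < 2):
        small = [batches[i] for i in np.flatnonzero(n_b < 2)]
        raise ValueError(f"every batch needs >=2 samples; too small: {small}")
    X = _design(ann, batches, groups)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch and group factors are confounded "
                         "(design matrix is rank deficient)")
    G, n = Y.n_genes, Y.n_samples
    K, B = len(groups), len(batches)
    coef, *_ = np.linalg.lstsq(X, Y.values.T, rcond=None)   # (p, G)
    alpha = coef[0]
    beta = np.zeros((G, K))
    beta[:, 1:] = coef[1:K].T
    gamma = np.zeros((B, G))
    gamma[: B - 1] = coef[K:]
    gamma[B - 1] = -(n_b[: B - 1] @ gamma[: B - 1]) / n_b[B - 1]

    resid = Y.values.T - X @ coef                            # (n, G)
    batch_var = np.empty((B, G))
    for i in range(B):
        batch_var[i] = resid[batch_idx == i].var(axis=0, ddof=1)
    pooled_var = ((n_b - 1)[:, None] * batch_var).sum(axis=0) / (n - B)
    # a numerically-zero pooled variance (noiseless gene) means the scale is
    # unidentified; relative threshold guards against lstsq round-off
    scale = max(float(np.mean(Y.values ** 2)), 1.0)
    zero_var = pooled_var <= 1e-20 * scale
    pooled_sd = np.sqrt(np.where(zero_var, 1.0, pooled_var))
    delta = np.sqrt(np.maximum(batch_var, 0.0)) / pooled_sd
    delta[:, zero_var] = 1.0
    delta = np.maximum(delta, delta_floor)

    if eb_shrinkage:
        gamma, delta = _eb_moderate(gamma, delta, pooled_var, n_b)
        delta = np.maximum(delta, delta_floor)
    return BatchModelFit(alpha, beta, gamma, delta,
                         batches=batches, groups=groups,
                         gene_ids=Y.gene_ids.copy())


def _eb_moderate(gamma: np.ndarray, delta: np.ndarray,
                 pooled_var: np.ndarray, n_b: np.ndarray):
    """Shrink batch parameters across genes (simplified parametric EB).

    gamma: posterior-mean squeeze toward the cross-gene batch mean under a
    normal prior whose variance is the cross-gene spread of the estimates.
    delta**2: precision-weighted squeeze toward its cross-gene mean.
    """
    B, G = gamma.shape
    g_out = gamma.copy()
    d_out = delta.copy()
    for i in range(B):
        prior_mean = gamma[i].mean()
        prior_var = max(gamma[i].var(ddof=1), 1e-12)
        noise_var = pooled_var / n_b[i]
        w = prior_var / (prior_var + noise_var)
        g_out[i] = w * gamma[i] + (1 - w) * prior_mean
        d2 = delta[i] ** 2
        target = d2.mean()
        # effective prior weight ~ a handful of pseudo-genes
        m = max(n_b[i] - 1, 1)
        d_out[i] = np.sqrt((m * d2 + 2.0 * target) / (m + 2.0))
    # restore the weighted zero-mean constraint per gene
    g_out -= (n_b[:, None] * g_out).sum(axis=0) / n_b.sum()
    return g_out, d_out


def _fitted_bio(fit: BatchModelFit, ann: SampleAnnotations) -> np.ndarray:
    """alpha + X beta for every (gene, sample), shape (G, n)."""
    group_idx = np.array([fit.groups.index(g) for g in ann.group])
    return fit.alpha_hat[:, None] + fit.beta_hat[:, group_idx]


def correct_batch(Y: ExpressionMatrix, fit: BatchModelFit,
                  ann: SampleAnnotations) -> ExpressionMatrix:
    """Remove fitted batch shifts and rescale residuals to the pooled scale.

    Applies ``Z = (Y - alpha - X beta - gamma) / delta + alpha + X beta``
    per gene/sample; output keeps Y's shape and kind.
    """
    if list(Y.sample_ids) != list(ann.sample_ids):
        raise ValueError("matrix and annotations are not aligned")
    if fit.alpha_hat.shape[0] != Y.n_genes:
        raise ValueError("fit was computed on a different gene set")
    unknown_b = set(ann.batch) - set(fit.batches)
    unknown_g = set(ann.group) - set(fit.groups)
    if unknown_b or unknown_g:
        raise ValueError(f"labels absent from fit: {unknown_b | unknown_g}")
    batch_idx = np.array([fit.batches.index(b) for b in ann.batch])
    bio = _fitted_bio(fit, ann)                         # (G, n)
    gamma = fit.gamma_hat[batch_idx].T                  # (G, n)
    delta = fit.delta_hat[batch_idx].T                  # (G, n)
    if np.any(delta <= 0):
        raise ValueError("non-positive delta in fit")
    Z = (Y.values - bio - gamma) / delta + bio
    return Y.with_values(Z)


def embedding_correct(E: ExpressionMatrix,
                      ann: SampleAnnotations) -> ExpressionMatrix:
    """Batch-centroid matching in embedding space.

    Per component, each batch's centroid is translated onto the global
    centroid; within-batch dispersion and pairwise distances are unchanged.
    """
    if E.kind != "embedding":
        raise ValueError("embedding_correct expects kind='embedding'")
    if list(E.sample_ids) != list(ann.sample_ids):
        raise ValueError("matrix and annotations are not aligned")
    batches = ann.batch_levels
    if len(batches) < 2:
        raise ValueError("need >=2 batches to correct")
    vals = E.values.copy()
    global_centroid = vals.mean(axis=1, keepdims=True)
    for b in batches:
        mask = ann.batch == b
        vals[:, mask] += global_centroid - vals[:, mask].mean(axis=1, keepdims=True)
    return E.with_values(vals)
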