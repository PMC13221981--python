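"""Artificial dilution series: interpolating between uncorrected and
corrected data (batch axis), or between full and removed biological signal.

The batch-axis series is the convex combination

    ADS_p(Y, Z) = (1 - p) * Y + p * Z,

where ``Y`` is uncorrected and ``Z`` batch-corrected data, so ``p`` is the
fraction of batch effect removed.  The biological axis instead shrinks each
gene's group-mean deviations toward the grand mean by a fraction ``q``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix, SampleAnnotations

__all__ = ["ADSSeries", "ads_mix", "build_batch_ads", "build_bio_ads",
           "dilute_bio_signal"]


@dataclass
class ADSSeries:
    """An ordered ladder of datasets at increasing mixing fractions.

    ``levels`` are the mixing fractions, strictly increasing from 0 to 1.
    For the batch axis, level ``p`` is the fraction of batch effect removed;
    the amount of batch noise therefore *decreases* along ``levels``.
    ``noise_order`` gives the dataset indices sorted from least to most noisy
    (batch axis: fully corrected first; bio axis: undiluted first), which is
    the rank order used for scoring.
    """

    levels: np.ndarray
    datasets: list[ExpressionMatrix]
    axis: str = "batch_effect"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        if self.axis not in ("batch_effect", "bio_signal"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if len(self.levels) != len(self.datasets):
            raise ValueError("levels and datasets must match in length")
        if len(self.levels) < 2:
            raise ValueError("a series needs at least two levels")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if self.levels[0] != 0.0 or self.levels[-1] != 1.0:
            raise ValueError("levels must start at 0 and end at 1")
        shape = self.datasets[0].values.shape
        ids = (list(self.datasets[0].gene_ids), list(self.datasets[0].sample_ids))
        for d in self.datasets[1:]:
            if d.values.shape != shape or (list(d.gene_ids), list(d.sample_ids)) != ids:
                raise ValueError("all series members must share shape and ids")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def noise_order(self) -> np.ndarray:
        """Dataset indices ordered from least noise to most noise."""
        if self.axis == "batch_effect":
            return np.arange(self.n_levels)[::-1]   # p=1 (corrected) first
        return np.arange(self.n_levels)             # q=0 (full signal) first


def ads_mix(Y: ExpressionMatrix, Z: ExpressionMatrix,
            p: float) -> ExpressionMatrix:
    """Entrywise convex combination ``(1-p)*Y + p*Z``.

    Endpoints are returned bit-exactly (a copy of Y at p=0, of Z at p=1).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if Y.values.shape != Z.values.shape:
        raise ValueError("Y and Z differ in shape")
    if (list(Y.gene_ids) != list(Z.gene_ids)
            or list(Y.sample_ids) != list(Z.sample_ids)):
        raise ValueError("Y and Z differ in identifiers")
    if Y.kind != Z.kind:
        raise ValueError(f"kind mismatch: {Y.kind!r} vs {Z.kind!r}")
    if p == 0.0:
        return Y.copy()
    if p == 1.0:
        return Z.copy()
    return Y.with_values((1.0 - p) * Y.values + p * Z.values)


def build_batch_ads(Y: ExpressionMatrix, Z: ExpressionMatrix,
                    n_levels: int = 11) -> ADSSeries:
    """Series of ``n_levels`` equally spaced mixes from uncorrected (p=0) to
    fully corrected (p=1)."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels = np.arange(n_levels) / (n_levels - 1)
    levels[-1] = 1.0
    datasets = [ads_mix(Y, Z, p) for p in levels]
    return ADSSeries(levels, datasets, axis="batch_effect")


def dilute_bio_signal(X: ExpressionMatrix, ann: SampleAnnotations,
                      q: float) -> ExpressionMatrix:
    """Shrink per-gene biological group means toward the grand mean.

    For each gene, every sample of group *k* has ``q * (mean_k - grand_mean)``
    subtracted, where the grand mean is the unweighted per-gene mean over all
    samples.  ``q=0`` leaves X unchanged; ``q=1`` equalizes all per-gene group
    means.  Within-group centered values are preserved exactly.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    if list(X.sample_ids) != list(ann.sample_ids):
        raise ValueError("matrix and annotations are not aligned")
    groups = ann.group_levels
    if len(groups) < 2:
        raise ValueError("need >=2 biological groups")
    if q == 0.0:
        return X.copy()
    vals = X.values.copy()
    grand = X.values.mean(axis=1, keepdims=True)
    for g in groups:
        mask = ann.group == g
        group_mean = X.values[:, mask].mean(axis=1, keepdims=True)
        vals[:, mask] -= q * (group_mean - grand)
    return X.with_values(vals)


def build_bio_ads(X: ExpressionMatrix, ann: SampleAnnotations,
                  n_levels: int = 11) -> ADSSeries:
    """Series of ``n_levels`` dilutions from full signal (q=0) to fully mixed
    groups (q=1), applied to batch-corrected data."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    levels = np.arange(n_levels) / (n_levels - 1)
    levels[-1] = 1.0
    datasets = [dilute_bio_signal(X, ann, q) for q in levels]
    return ADSSeries(levels, datasets, axis="bio_signal")
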