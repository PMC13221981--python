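"""Synthetic RNA-seq count generator with known batch and biological effects.

The generator runs the location-scale batch model forward: per-gene baseline
log2-expression alpha, additive biological group shifts beta, additive batch
shifts gamma and multiplicative batch residual scales delta.  The log-scale
signal ``mu = alpha + beta[group] + gamma[batch]`` receives Gaussian
log-noise whose spread is multiplied by the batch's delta, and counts are
drawn negative-binomially around ``2**(mu + noise)``.  Ground-truth
parameter arrays are returned next to the data so estimators can be tested
for recovery.

Default parameter values are meant to look like a moderately deep bulk
RNA-seq experiment with a clearly detectable batch effect: baseline log2
means around 6 (i.e. typical counts in the tens to hundreds), biological and
batch shifts of about one log2 unit, batch scale factors within ~25% of one,
and mild negative-binomial overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, SampleAnnotations

__all__ = ["SyntheticConfig", "GroundTruth", "generate_synthetic_counts",
           "make_fixture"]


@dataclass
class SyntheticConfig:
    """Parameters of the forward model.

    ``batch_assignment``/``group_assignment`` may be explicit label vectors
    or ``"balanced"``, which cycles samples through batches and, within the
    batch cycle, through groups so the batch-by-group cross-tabulation has no
    empty cell (requires ``n_samples`` divisible by
    ``n_batches * n_groups`` for exact balance; any remainder keeps cycling).

    ``bio_shift_sd`` is the spread (log2 units) of group effects over
    genes; ``batch_shift_sd`` the spread of additive batch shifts;
    ``batch_scale_range`` an interval around 1 for multiplicative residual
    scales; ``noise_log_sd`` the baseline log2 residual spread that delta
    multiplies; ``dispersion`` the negative-binomial overdispersion
    (variance = m + dispersion * m**2); ``frac_affected_genes`` the fraction
    of genes that carry batch effects.
    """

    n_genes: int = 500
    n_samples: int = 60
    n_batches: int = 2
    n_groups: int = 2
    batch_assignment: object = "balanced"
    group_assignment: object = "balanced"
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.5
    bio_shift_sd: float = 1.0
    batch_shift_sd: float = 1.0
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_log_sd: float = 0.4
    dispersion: float = 0.05
    frac_affected_genes: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need >=1 gene and >=2 samples")
        if self.n_batches < 2 or self.n_groups < 2:
            raise ValueError("need >=2 batches and >=2 groups")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ValueError("batch_scale_range must be within (0, inf)")
        if not 0.0 <= self.frac_affected_genes <= 1.0:
            raise ValueError("frac_affected_genes must be in [0, 1]")
        for name in ("baseline_log_sd", "bio_shift_sd", "batch_shift_sd",
                     "noise_log_sd", "dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """True parameter arrays behind a generated dataset."""

    alpha: np.ndarray           # (G,)
    beta: np.ndarray            # (G, n_groups), reference column 0
    gamma: np.ndarray           # (n_batches, G), batch-size-weighted zero mean
    delta: np.ndarray           # (n_batches, G)
    affected: np.ndarray        # (G,) bool, genes carrying batch effects


def _assignments(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    n, B, K = config.n_samples, config.n_batches, config.n_groups
    if isinstance(config.batch_assignment, str) and config.batch_assignment == "balanced":
        batch_idx = np.arange(n) % B
    else:
        labels = np.asarray(config.batch_assignment)
        levels = sorted(set(map(str, labels)))
        batch_idx = np.array([levels.index(str(x)) for x in labels])
    if isinstance(config.group_assignment, str) and config.group_assignment == "balanced":
        group_idx = (np.arange(n) // B) % K
    else:
        labels = np.asarray(config.group_assignment)
        levels = sorted(set(map(str, labels)))
        group_idx = np.array([levels.index(str(x)) for x in labels])
    if len(batch_idx) != n or len(group_idx) != n:
        raise ValueError("assignment vectors must have length n_samples")
    cross = np.zeros((B, K), dtype=int)
    np.add.at(cross, (batch_idx, group_idx), 1)
    if (isinstance(config.batch_assignment, str)
            and isinstance(config.group_assignment, str)
            and np.any(cross == 0)):
        raise ValueError("balanced assignment produced an empty batch x group "
                         "cell; increase n_samples")
    return batch_idx, group_idx


def generate_synthetic_counts(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SampleAnnotations, GroundTruth]:
    """Draw a count matrix, annotations and ground truth from the model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, n = config.n_genes, config.n_samples
    B, K = config.n_batches, config.n_groups
    batch_idx, group_idx = _assignments(config)
    n_b = np.bincount(batch_idx, minlength=B).astype(float)

    alpha = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)
    beta = np.zeros((G, K))
    beta[:, 1:] = rng.normal(0.0, config.bio_shift_sd, (G, K - 1))
    affected = rng.random(G) < config.frac_affected_genes

    gamma = rng.normal(0.0, config.batch_shift_sd, (B, G))
    gamma[:, ~affected] = 0.0
    # identifiability: batch-size-weighted zero mean per gene
    gamma -= (n_b[:, None] * gamma).sum(axis=0) / n_b.sum()
    gamma[:, ~affected] = 0.0

    lo, hi = config.batch_scale_range
    delta = rng.uniform(lo, hi, (B, G))
    delta[:, ~affected] = 1.0

    mu = alpha[:, None] + beta[:, group_idx] + gamma[:, :].T[:, batch_idx]
    eps = rng.normal(0.0, 1.0, (G, n))
    log_signal = mu + config.noise_log_sd * delta.T[:, batch_idx] * eps
    mean = np.power(2.0, log_signal)
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)

    gene_ids = np.array([f"gene{g + 1}" for g in range(G)], dtype=object)
    sample_ids = np.array([f"sample{j + 1}" for j in range(n)], dtype=object)
    matrix = ExpressionMatrix(counts.astype(float), gene_ids, sample_ids,
                              kind="counts")
    ann = SampleAnnotations(
        sample_ids.copy(),
        np.array([f"batch{i + 1}" for i in batch_idx], dtype=object),
        np.array([f"group{k + 1}" for k in group_idx], dtype=object),
    )
    truth = GroundTruth(alpha, beta, gamma, delta, affected)
    return matrix, ann, truth


_FIXTURES = {
    # strong, clearly detectable batch and biological effects at each scale
    "tiny": SyntheticConfig(n_genes=50, n_samples=24, n_batches=2, n_groups=2,
                            bio_shift_sd=1.5, batch_shift_sd=1.5,
                            batch_scale_range=(0.8, 1.25), seed=11),
    "small": SyntheticConfig(n_genes=500, n_samples=60, n_batches=2, n_groups=3,
                             bio_shift_sd=1.5, batch_shift_sd=1.5,
                             batch_scale_range=(0.8, 1.25), seed=12),
    "medium": SyntheticConfig(n_genes=2000, n_samples=300, n_batches=2,
                              n_groups=3, bio_shift_sd=1.5, batch_shift_sd=1.5,
                              batch_scale_range=(0.8, 1.25), seed=13),
}


def make_fixture(scale: str = "tiny"):
    """Canned deterministic datasets: ``tiny`` (50 genes x 24 samples, 2x2),
    ``small`` (500 x 60, 2 batches x 3 groups), ``medium`` (2000 x 300,
    2 batches x 3 groups)."""
    if scale not in _FIXTURES:
        raise KeyError(f"unknown scale {scale!r}; choose from {list(_FIXTURES)}")
    import copy
    return generate_synthetic_counts(copy.deepcopy(_FIXTURES[scale]))
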