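"""Cluster-mixing metrics on labeled expression data.

All metrics quantify how strongly a labeling (batch or biological group)
separates samples.  Most operate on the pairwise Pearson-correlation distance
matrix ``D[i,j] = 1 - rho(x_i, x_j)``; two (Davies-Bouldin, guided-PCA delta)
also need the expression/embedding matrix itself.

Each metric declares a fixed direction: ``higher_means_more_separation`` or
``lower_means_more_separation``.  ``evaluate_all`` runs a metric set against
batch labels, biological labels, and reports the batch/bio ratio, which is
how a dilution-series benchmark consumes them.

Registry names: ``f``, ``f_scaled``, ``db``, ``knn``, ``mindist``,
``kldist``, ``gpca``, ``kbet``, ``cms``.  The neighbourhood tests ``kbet``
and ``cms`` are batch-only by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import DistanceMatrix, ExpressionMatrix, SampleAnnotations

__all__ = [
    "MetricResult", "pearson_distance_matrix", "f_score", "f_score_scaled",
    "davies_bouldin", "knn_proportion", "min_distance", "kl_dist",
    "gpca_delta", "kbet_rejection_rate", "cell_mix_score", "evaluate_all",
    "METRIC_DIRECTIONS", "BATCH_ONLY_METRICS",
]

HIGHER = "higher_means_more_separation"
LOWER = "lower_means_more_separation"

METRIC_DIRECTIONS = {
    "f": HIGHER,
    "f_scaled": HIGHER,
    "db": LOWER,
    "knn": HIGHER,
    "mindist": HIGHER,
    "kldist": HIGHER,
    "gpca": HIGHER,
    "kbet": HIGHER,
    "cms": LOWER,
}

# neighbourhood composition tests are defined against batch labels only
BATCH_ONLY_METRICS = frozenset({"kbet", "cms"})

KLD_EPS = 1e-12


@dataclass
class MetricResult:
    """One metric evaluation: name, which labeling (bio/batch/ratio), value,
    and the metric's fixed direction.  ``note`` flags undefined values."""

    metric_name: str
    signal: str
    value: float
    direction: str
    note: str | None = None


# ---------------------------------------------------------------------------
# distance backbone
# ---------------------------------------------------------------------------

def pearson_distance_matrix(X: ExpressionMatrix) -> DistanceMatrix:
    """Pairwise sample distances ``1 - Pearson correlation``, in [0, 2]."""
    if X.n_samples < 2:
        raise ValueError("need >=2 samples for a distance matrix")
    vals = X.values
    sd = vals.std(axis=0)
    if np.any(sd == 0):
        bad = list(X.sample_ids[sd == 0][:5])
        raise ValueError(f"constant sample column(s), correlation undefined: {bad}")
    corr = np.corrcoef(vals, rowvar=False)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D, X.sample_ids.copy())


def _labels_to_clusters(labels: np.ndarray) -> dict[str, np.ndarray]:
    labels = np.asarray(labels)
    return {lab: np.flatnonzero(labels == lab) for lab in sorted(set(map(str, labels)))}


def _check_distance(D: DistanceMatrix | np.ndarray) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    return np.asarray(D, dtype=float)


# ---------------------------------------------------------------------------
# pairwise-distance metrics
# ---------------------------------------------------------------------------

def f_score(D: DistanceMatrix, labels: np.ndarray) -> float:
    """ANOVA-style ratio: sum of between-cluster pairwise distances over the
    sum of within-cluster pairwise distances (each unordered pair once).

    Higher values mean stronger cluster separation.
    """
    Dv = _check_distance(D)
    labels = np.asarray([str(x) for x in labels])
    clusters = _labels_to_clusters(labels)
    if len(clusters) < 2:
        raise ValueError("f_score needs >=2 clusters")
    for lab, idx in clusters.items():
        if len(idx) < 2:
            raise ValueError(f"cluster {lab!r} has <2 members")
    n = Dv.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    within = Dv[iu[same], ju[same]].sum()
    between = Dv[iu[~same], ju[~same]].sum()
    if within == 0:
        raise ValueError("zero within-cluster distance sum")
    return float(between / within)


def _row_quantiles(Dv: np.ndarray, p: float) -> np.ndarray:
    """p-quantile of each row of D excluding the diagonal entry."""
    n = Dv.shape[0]
    out = np.empty(n)
    for i in range(n):
        row = np.delete(Dv[i], i)
        out[i] = np.quantile(row, p)
    return out


def f_score_scaled(D: DistanceMatrix, labels: np.ndarray,
                   quantile_p: float = 0.5) -> float:
    """F ratio with per-sample quantile scaling.

    Each pair (i, j) contributes ``D[i,j]/Q_i + D[i,j]/Q_j`` (the ordered-pair
    sum), where Q_i is the ``quantile_p`` quantile of sample i's off-diagonal
    distances; this keeps the statistic symmetric in the samples and hence
    invariant to relabeling.  Compensates for unequal cluster size/spread."""
    if not 0.0 < quantile_p <= 1.0:
        raise ValueError("quantile_p must be in (0, 1]")
    Dv = _check_distance(D)
    labels = np.asarray([str(x) for x in labels])
    clusters = _labels_to_clusters(labels)
    if len(clusters) < 2:
        raise ValueError("f_score_scaled needs >=2 clusters")
    for lab, idx in clusters.items():
        if len(idx) < 2:
            raise ValueError(f"cluster {lab!r} has <2 members")
    Q = _row_quantiles(Dv, quantile_p)
    if np.any(Q == 0):
        raise ValueError("zero row quantile; cannot scale")
    n = Dv.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    terms = Dv[iu, ju] * (1.0 / Q[iu] + 1.0 / Q[ju])
    same = labels[iu] == labels[ju]
    within = terms[same].sum()
    between = terms[~same].sum()
    if within == 0:
        raise ValueError("zero within-cluster scaled distance sum")
    return float(between / within)


def _pearson_dist_vec(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("constant vector, correlation undefined")
    return float(1.0 - (a @ b) / (na * nb))


def davies_bouldin(X: ExpressionMatrix, labels: np.ndarray,
                   D: DistanceMatrix | None = None) -> float:
    """Davies-Bouldin index with Pearson distances.

    S_i is the mean Pearson distance of cluster-i samples to the cluster
    centroid (arithmetic mean of member columns in expression space); M_ij is
    the mean Pearson distance over all cross-cluster sample pairs.  The index
    is ``mean_i max_{j != i} (S_i + S_j) / M_ij``; lower values mean stronger
    separation."""
    labels = np.asarray([str(x) for x in labels])
    clusters = _labels_to_clusters(labels)
    names = list(clusters)
    if len(names) < 2:
        raise ValueError("davies_bouldin needs >=2 clusters")
    Dv = (D.values if isinstance(D, DistanceMatrix)
          else pearson_distance_matrix(X).values)
    S = {}
    for lab, idx in clusters.items():
        centroid = X.values[:, idx].mean(axis=1)
        S[lab] = float(np.mean([_pearson_dist_vec(X.values[:, j], centroid)
                                for j in idx]))
    ratios = np.zeros((len(names), len(names)))
    for a, la in enumerate(names):
        for b, lb in enumerate(names):
            if b <= a:
                continue
            M = Dv[np.ix_(clusters[la], clusters[lb])].mean()
            if M == 0:
                raise ValueError(f"zero between-cluster distance for "
                                 f"({la!r}, {lb!r})")
            ratios[a, b] = ratios[b, a] = (S[la] + S[lb]) / M
    per_cluster_max = ratios.max(axis=1)
    return float(per_cluster_max.mean())


def _knn_indices(Dv: np.ndarray, k: int) -> np.ndarray:
    """k nearest neighbours of each sample (self excluded), distance ties
    broken by ascending sample index (stable sort)."""
    n = Dv.shape[0]
    work = Dv.copy()
    np.fill_diagonal(work, np.inf)
    order = np.argsort(work, axis=1, kind="stable")
    return order[:, :k]


def knn_proportion(D: DistanceMatrix, labels: np.ndarray,
                   k: int | str = "auto") -> float:
    """Mean same-label fraction among each sample's k nearest neighbours,
    averaged per cluster then over clusters (unweighted).

    ``k='auto'`` uses the mean cluster size of the evaluated labeling,
    rounded half-up.  Higher values mean stronger separation."""
    Dv = _check_distance(D)
    labels = np.asarray([str(x) for x in labels])
    clusters = _labels_to_clusters(labels)
    n = Dv.shape[0]
    if k == "auto":
        k = int(math.floor(n / len(clusters) + 0.5))
        k = min(k, n - 1)
    k = int(k)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nn = _knn_indices(Dv, k)
    same = labels[nn] == labels[:, None]
    frac = same.mean(axis=1)
    return float(np.mean([frac[idx].mean() for idx in clusters.values()]))


def min_distance(D: DistanceMatrix, labels: np.ndarray) -> float:
    """Mean over unordered cluster pairs of the minimum cross-cluster
    pairwise distance.  Higher values mean stronger separation."""
    Dv = _check_distance(D)
    labels = np.asarray([str(x) for x in labels])
    clusters = _labels_to_clusters(labels)
    names = list(clusters)
    if len(names) < 2:
        raise ValueError("min_distance needs >=2 clusters")
    minima = [Dv[np.ix_(clusters[a], clusters[b])].min()
              for i, a in enumerate(names) for b in names[i + 1:]]
    return float(np.mean(minima))


def _kde_on_grid(d: np.ndarray, grid: np.ndarray,
                 bandwidth_rule: str) -> np.ndarray:
    """Gaussian KDE of distances evaluated on a grid, robust to degenerate
    (constant) samples, floored and renormalized."""
    d = np.asarray(d, dtype=float)
    if np.ptp(d) > 0:
        kde = stats.gaussian_kde(d, bw_method=bandwidth_rule)
        dens = kde(grid)
    else:
        # all distances identical: narrow Gaussian bump at the common value
        span = max(grid[-1] - grid[0], 1e-6)
        bw = 1e-3 * span
        dens = np.exp(-0.5 * ((grid - d[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
    dens = np.maximum(dens, KLD_EPS)
    dens /= np.trapezoid(dens, grid)
    return dens


def kl_dist(D: DistanceMatrix, labels: np.ndarray, grid_size: int = 512,
            bandwidth_rule: str = "scott") -> float:
    """Mean symmetrized Kullback-Leibler divergence between the estimated
    densities of within-group pairwise distances, over unordered group pairs.

    Densities are Gaussian KDEs on a shared grid spanning all observed
    within-group distances, floored at a small epsilon; the divergence is
    integrated numerically.  Higher values mean stronger separation."""
    Dv = _check_distance(D)
    labels = np.asarray([str(x) for x in labels])
    clusters = _labels_to_clusters(labels)
    names = list(clusters)
    if len(names) < 2:
        raise ValueError("kl_dist needs >=2 groups")
    within = {}
    for lab, idx in clusters.items():
        if len(idx) < 2:
            raise ValueError(f"group {lab!r} has <2 members")
        sub = Dv[np.ix_(idx, idx)]
        within[lab] = sub[np.triu_indices(len(idx), k=1)]
    all_d = np.concatenate(list(within.values()))
    lo, hi = all_d.min(), all_d.max()
    pad = 0.1 * max(hi - lo, 1e-3)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = {lab: _kde_on_grid(d, grid, bandwidth_rule)
            for lab, d in within.items()}
    divs = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p, q = dens[a], dens[b]
            kl_pq = np.trapezoid(p * np.log(p / q), grid)
            kl_qp = np.trapezoid(q * np.log(q / p), grid)
            divs.append(0.5 * kl_pq + 0.5 * kl_qp)
    return float(max(np.mean(divs), 0.0))


# ---------------------------------------------------------------------------
# PCA-based metric
# ---------------------------------------------------------------------------

def gpca_delta(X: ExpressionMatrix, batch: np.ndarray) -> float:
    """Guided-PCA delta: share of the leading variance explained by batch.

    Unguided: variance of sample scores on the first principal component of
    the gene-centered data.  Guided: samples are projected on the first
    singular direction of the batch-mean matrix (per-batch centroids of the
    centered data).  delta = guided variance / unguided variance, clipped to
    [0, 1].  Higher values mean stronger batch separation."""
    batch = np.asarray([str(x) for x in batch])
    clusters = _labels_to_clusters(batch)
    if len(clusters) < 2:
        raise ValueError("gpca_delta needs >=2 batches")
    for lab, idx in clusters.items():
        if len(idx) < 2:
            raise ValueError(f"batch {lab!r} has <2 samples")
    centered = X.values - X.values.mean(axis=1, keepdims=True)
    # unguided leading direction
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    scores_unguided = centered.T @ U[:, 0]
    var_unguided = scores_unguided.var(ddof=1)
    if var_unguided == 0:
        raise ValueError("data has zero variance")
    batch_means = np.column_stack(
        [centered[:, idx].mean(axis=1) for idx in clusters.values()])
    Ug, Sg, Vgt = np.linalg.svd(batch_means, full_matrices=False)
    scores_guided = centered.T @ Ug[:, 0]
    var_guided = scores_guided.var(ddof=1)
    return float(np.clip(var_guided / var_unguided, 0.0, 1.0))


# ---------------------------------------------------------------------------
# neighbourhood composition tests (batch-only)
# ---------------------------------------------------------------------------

def kbet_rejection_rate(D: DistanceMatrix, batch: np.ndarray, k: int,
                        alpha: float = 0.05, n_neighborhoods: int = 100,
                        seed: int = 0) -> float:
    """Chi-square neighbourhood-composition test rejection rate.

    For each of ``n_neighborhoods`` anchors drawn without replacement, the
    anchor plus its k nearest neighbours form a neighbourhood; its batch-label
    counts are tested (Pearson chi-square, dof = #batches - 1, no continuity
    correction) against expected counts ``(k+1) * global batch frequency``.
    The score is the fraction of neighbourhoods with p < alpha.  Higher values
    mean stronger batch separation (poor mixing)."""
    Dv = _check_distance(D)
    batch = np.asarray([str(x) for x in batch])
    n = Dv.shape[0]
    levels = sorted(set(batch))
    B = len(levels)
    if B < 2:
        raise ValueError("kbet needs >=2 batches")
    if not (B <= k < n):
        raise ValueError(f"k must satisfy {B} <= k < {n}, got {k}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    freqs = np.array([(batch == b).mean() for b in levels])
    if np.any(freqs == 0):
        raise ValueError("a batch has zero frequency")
    rng = np.random.default_rng(seed)
    n_nb = min(n_neighborhoods, n)
    anchors = rng.choice(n, size=n_nb, replace=False)
    nn = _knn_indices(Dv, k)
    expected = (k + 1) * freqs
    level_index = {b: i for i, b in enumerate(levels)}
    batch_codes = np.array([level_index[b] for b in batch])
    rejections = 0
    for a in anchors:
        members = np.concatenate(([a], nn[a]))
        counts = np.bincount(batch_codes[members], minlength=B)
        stat = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(stat, df=B - 1)
        if p < alpha:
            rejections += 1
    return rejections / n_nb


def cell_mix_score(D: DistanceMatrix, batch: np.ndarray, k: int) -> float:
    """Cell-mixing score: mean over samples of a rank-test p-value comparing
    batch-specific neighbour-distance distributions.

    Per sample, its k nearest neighbours' distances are partitioned by
    neighbour batch; batches represented by >=2 neighbours are compared with
    two-sided Mann-Whitney tests (pairwise-averaged p-values when more than
    two batches qualify).  A sample whose neighbourhood holds fewer than two
    such batches contributes 1.  Low values mean strong batch structure, so
    the direction is lower_means_more_separation."""
    Dv = _check_distance(D)
    batch = np.asarray([str(x) for x in batch])
    n = Dv.shape[0]
    if len(set(batch)) < 2:
        raise ValueError("cell_mix_score needs >=2 batches")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    nn = _knn_indices(Dv, k)
    scores = np.empty(n)
    for i in range(n):
        neigh = nn[i]
        dists = Dv[i, neigh]
        by_batch = {}
        for b, d in zip(batch[neigh], dists):
            by_batch.setdefault(b, []).append(d)
        samples = [np.asarray(v) for v in by_batch.values() if len(v) >= 2]
        if len(samples) < 2:
            scores[i] = 1.0
            continue
        pvals = []
        for a in range(len(samples)):
            for b in range(a + 1, len(samples)):
                if (np.all(samples[a] == samples[a][0])
                        and np.all(samples[b] == samples[b][0])
                        and samples[a][0] == samples[b][0]):
                    pvals.append(1.0)
                    continue
                res = stats.mannwhitneyu(samples[a], samples[b],
                                         alternative="two-sided")
                pvals.append(res.pvalue)
        scores[i] = float(np.mean(pvals))
    return float(scores.mean())


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _compute_metric(name: str, X: ExpressionMatrix, D: DistanceMatrix,
                    labels: np.ndarray, params: dict) -> float:
    if name == "f":
        return f_score(D, labels)
    if name == "f_scaled":
        return f_score_scaled(D, labels, params.get("quantile_p", 0.5))
    if name == "db":
        return davies_bouldin(X, labels, D=D)
    if name == "knn":
        return knn_proportion(D, labels, params.get("k", "auto"))
    if name == "mindist":
        return min_distance(D, labels)
    if name == "kldist":
        return kl_dist(D, labels, params.get("grid_size", 512),
                       params.get("bandwidth_rule", "scott"))
    if name == "gpca":
        return gpca_delta(X, labels)
    if name == "kbet":
        n = D.n_samples
        B = len(set(map(str, labels)))
        default_k = int(np.clip(round(0.1 * n), B, n - 1))
        return kbet_rejection_rate(
            D, labels,
            k=params.get("k", default_k),
            alpha=params.get("alpha", 0.05),
            n_neighborhoods=params.get("n_neighborhoods", min(100, n)),
            seed=params.get("seed", 0))
    if name == "cms":
        n = D.n_samples
        default_k = int(np.clip(round(0.1 * n), 4, n - 1))
        return cell_mix_score(D, labels, k=params.get("k", default_k))
    raise KeyError(f"unknown metric {name!r}; known: {sorted(METRIC_DIRECTIONS)}")


def evaluate_all(X: ExpressionMatrix, ann: SampleAnnotations,
                 metric_set: list[str] | tuple[str, ...] = ("f", "db", "knn", "mindist"),
                 params: dict | None = None) -> list[MetricResult]:
    """Evaluate metrics against batch labels, biological labels, and their
    ratio.

    Each metric is computed once with batch labels (``signal='batch'``), once
    with group labels (``signal='bio'``), and their ratio batch/bio is
    reported (``signal='ratio'``).  Batch-only metrics (kbet, cms) report
    only the batch signal.  ``params`` maps metric name to a kwargs dict.
    A zero bio value yields a ratio flagged undefined instead of a crash.
    """
    params = params or {}
    unknown = [m for m in metric_set if m not in METRIC_DIRECTIONS]
    if unknown:
        raise KeyError(f"unknown metric(s) {unknown}; known: "
                       f"{sorted(METRIC_DIRECTIONS)}")
    results: list[MetricResult] = []
    if not metric_set:
        return results
    D = pearson_distance_matrix(X)
    for name in metric_set:
        mp = params.get(name, {})
        direction = METRIC_DIRECTIONS[name]
        batch_val = _compute_metric(name, X, D, ann.batch, mp)
        results.append(MetricResult(name, "batch", float(batch_val), direction))
        if name in BATCH_ONLY_METRICS:
            continue
        bio_val = _compute_metric(name, X, D, ann.group, mp)
        results.append(MetricResult(name, "bio", float(bio_val), direction))
        if bio_val == 0:
            results.append(MetricResult(name, "ratio", float("nan"), direction,
                                        note="undefined: bio value is 0"))
        else:
            results.append(MetricResult(name, "ratio",
                                        float(batch_val / bio_val), direction))
    return results
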