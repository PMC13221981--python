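"""End-to-end dilution-series benchmark of evaluation metrics.

Pipeline (batch axis, Dirichlet-multinomial variance model), per iteration:
resample counts -> size-factor normalize -> log2 -> (optional PCA) -> fit the
batch corrector -> build the dilution series between uncorrected and
corrected data -> evaluate every metric at every level against batch labels,
biological labels and their ratio.  The gene-bootstrap variance model instead
corrects once, builds the series once, and perturbs each level's gene set per
iteration.  The biological axis dilutes group means of the corrected data.

Each (metric, signal) stream is scored by Spearman rank correlation between
the pooled metric values and the noise rank of the levels (rank 1 = least
noisy: fully corrected / undiluted).  Alongside the raw rho an *oriented*
rho is reported — rho multiplied by the sign the metric is expected to show
given its direction — so an ideally behaved metric scores +1 on every
signal it is oriented for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .ads import ADSSeries, build_batch_ads, build_bio_ads
from .correction import correct_batch, embedding_correct, fit_ls_model
from .data_model import ExpressionMatrix, SampleAnnotations
from .metrics import BATCH_ONLY_METRICS, METRIC_DIRECTIONS, evaluate_all
from .preprocess import log_transform, pca_reduce, size_factor_normalize
from .resampling import bootstrap_genes, dirichlet_multinomial_resample

__all__ = ["BenchmarkConfig", "BenchmarkResult", "run_benchmark",
           "spearman_score", "minmax_standardize", "expected_sign", "summarize"]


@dataclass
class BenchmarkConfig:
    """Knobs of one benchmark run; every field has a usable default."""

    corrector: str = "location_scale"       # or "embedding_centroid"
    variance_model: str = "dirichlet_multinomial"   # or "gene_bootstrap"
    metrics: tuple[str, ...] = ("f", "db", "knn", "mindist", "kldist", "gpca")
    n_iter: int = 50
    n_levels: int = 11
    ads_axis: str = "batch_effect"          # or "bio_signal"
    seed: int = 0
    pseudocount: float = 1.0
    n_components: int = 50
    pca_sample_threshold: int = 500
    eb_shrinkage: bool = False
    resample_pseudocount: float = 0.0
    invert_ratio: bool = False
    metric_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.corrector not in ("location_scale", "embedding_centroid"):
            raise ValueError(f"unknown corrector {self.corrector!r}")
        if self.variance_model not in ("dirichlet_multinomial", "gene_bootstrap"):
            raise ValueError(f"unknown variance model {self.variance_model!r}")
        if self.ads_axis not in ("batch_effect", "bio_signal"):
            raise ValueError(f"unknown ads_axis {self.ads_axis!r}")
        if self.n_iter < 1 or self.n_levels < 2:
            raise ValueError("n_iter must be >=1 and n_levels >=2")
        unknown = [m for m in self.metrics if m not in METRIC_DIRECTIONS]
        if unknown:
            raise ValueError(f"unknown metric(s): {unknown}")

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        extra = set(d) - known
        if extra:
            raise KeyError(f"unknown config key(s): {sorted(extra)}")
        d = dict(d)
        if "metrics" in d and not isinstance(d["metrics"], (list, tuple)):
            d["metrics"] = [s.strip() for s in str(d["metrics"]).split(",")]
        if "metrics" in d:
            d["metrics"] = tuple(d["metrics"])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class BenchmarkResult:
    """Long table of metric values plus per-(metric, signal) Spearman scores.

    ``values`` columns: metric, signal, level (mixing fraction), noise_rank
    (1 = least noisy), iteration, value, direction.  ``scores`` columns:
    metric, signal, rho, oriented_rho, n.
    """

    values: pd.DataFrame
    scores: pd.DataFrame
    config: dict
    axis: str


def expected_sign(metric: str, signal: str, axis: str,
                  invert_ratio: bool = False) -> float:
    """Sign the metric is expected to show against increasing noise rank.

    A separation-type metric (direction 'higher means more separation')
    should increase with batch noise on the batch signal and decrease on the
    bio signal; an inversely oriented metric (e.g. Davies-Bouldin) flips
    those signs.  On the bio-dilution axis the batch signal has no expected
    trend (sign 0).  The ratio follows the literal batch/bio definition.
    """
    sep = 1.0 if METRIC_DIRECTIONS[metric] == "higher_means_more_separation" else -1.0
    if axis == "batch_effect":
        signs = {"batch": sep, "bio": -sep, "ratio": sep}
    else:
        signs = {"batch": 0.0, "bio": -sep, "ratio": sep}
    s = signs[signal]
    if signal == "ratio" and invert_ratio:
        s = -s
    return s


def spearman_score(values: np.ndarray, ranks: np.ndarray) -> float:
    """Spearman rho between pooled metric values and level ranks (average-rank
    tie handling).  Returns NaN when the values are constant."""
    values = np.asarray(values, dtype=float)
    ranks = np.asarray(ranks, dtype=float)
    if len(np.unique(ranks)) < 2:
        raise ValueError("need >=2 distinct levels")
    ok = np.isfinite(values)
    if ok.sum() < 2 or len(np.unique(values[ok])) < 2:
        return float("nan")
    rho = stats.spearmanr(values[ok], ranks[ok]).statistic
    return float(rho)


def minmax_standardize(series: np.ndarray) -> np.ndarray:
    """Map a per-level series onto [0, 1] by its global min and max.

    A constant series maps to all 0.5 (with a warning) so plots stay drawable.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    lo, hi = np.nanmin(series), np.nanmax(series)
    if hi == lo:
        warnings.warn("constant series in min-max standardization; mapping "
                      "to 0.5", UserWarning, stacklevel=2)
        return np.full_like(series, 0.5)
    return (series - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# pipeline pieces
# ---------------------------------------------------------------------------

def _process_counts(counts: ExpressionMatrix,
                    config: BenchmarkConfig) -> ExpressionMatrix:
    normalized, _ = size_factor_normalize(counts)
    return log_transform(normalized, config.pseudocount)


def _maybe_reduce(X: ExpressionMatrix, config: BenchmarkConfig) -> ExpressionMatrix:
    """PCA for distance computation on large sample counts (location-scale
    path only; the embedding corrector already lives in PCA space)."""
    if X.kind == "embedding":
        return X
    if X.n_samples > config.pca_sample_threshold:
        k = min(config.n_components, X.n_genes, X.n_samples)
        return pca_reduce(X, k)
    return X


def _corrected_pair(Y: ExpressionMatrix, ann: SampleAnnotations,
                    config: BenchmarkConfig
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """(uncorrected, corrected) pair in the space the corrector works in."""
    if config.corrector == "embedding_centroid":
        k = min(config.n_components, Y.n_genes, Y.n_samples)
        E = pca_reduce(Y, k)
        return E, embedding_correct(E, ann)
    fit = fit_ls_model(Y, ann, eb_shrinkage=config.eb_shrinkage)
    return Y, correct_batch(Y, fit, ann)


def _series_for_axis(Y: ExpressionMatrix, ann: SampleAnnotations,
                     config: BenchmarkConfig) -> ADSSeries:
    base, corrected = _corrected_pair(Y, ann, config)
    if config.ads_axis == "batch_effect":
        return build_batch_ads(base, corrected, config.n_levels)
    return build_bio_ads(corrected, ann, config.n_levels)


def _evaluate_series(series: ADSSeries, ann: SampleAnnotations,
                     config: BenchmarkConfig, iteration: int,
                     rows: list, perturb=None) -> None:
    noise_rank_of = {idx: r + 1 for r, idx in enumerate(series.noise_order)}
    for idx, (level, ds) in enumerate(zip(series.levels, series.datasets)):
        if perturb is not None:
            ds = perturb(ds, idx)
        ds = _maybe_reduce(ds, config)
        for res in evaluate_all(ds, ann, config.metrics, config.metric_params):
            rows.append({
                "metric": res.metric_name, "signal": res.signal,
                "level": float(level), "noise_rank": noise_rank_of[idx],
                "iteration": iteration, "value": res.value,
                "direction": res.direction,
            })


def run_benchmark(counts: ExpressionMatrix, ann: SampleAnnotations,
                  config: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Run the full dilution-series benchmark on a count matrix.

    Requires aligned annotations with >=2 batches and >=2 biological groups.
    Deterministic for a fixed config (iteration *i* derives its randomness
    from ``config.seed + i``).
    """
    config = config or BenchmarkConfig()
    config.validate()
    ann.validate_for_benchmark()
    if list(counts.sample_ids) != list(ann.sample_ids):
        raise ValueError("counts and annotations are not aligned; call align()")
    rows: list[dict] = []

    if config.variance_model == "dirichlet_multinomial":
        for it in range(config.n_iter):
            seed_i = config.seed + it
            resampled = dirichlet_multinomial_resample(
                counts, seed_i, pseudocount=config.resample_pseudocount)
            Y = _process_counts(resampled, config)
            series = _series_for_axis(Y, ann, config)
            cfg_i = _with_metric_seed(config, seed_i)
            _evaluate_series(series, ann, cfg_i, it, rows)
    else:  # gene_bootstrap: correct once, perturb gene sets per iteration
        Y = _process_counts(counts, config)
        if config.corrector == "embedding_centroid":
            raise ValueError("gene bootstrap operates on genes and cannot "
                             "follow an embedding-space corrector")
        zero_rows = np.mean(np.all(counts.values == 0, axis=1))
        if zero_rows > 0.5:
            warnings.warn("more than 50% all-zero gene rows: gene bootstrap "
                          "is unsuitable for sparse single-cell data",
                          UserWarning, stacklevel=2)
        series = _series_for_axis(Y, ann, config)
        for it in range(config.n_iter):
            def perturb(ds, idx, _it=it):
                return bootstrap_genes(ds, config.seed + _it * config.n_levels + idx)
            cfg_i = _with_metric_seed(config, config.seed + it)
            _evaluate_series(series, ann, cfg_i, it, rows, perturb=perturb)

    values = pd.DataFrame(rows)
    scores = _score(values, config)
    return BenchmarkResult(values=values, scores=scores,
                           config=asdict(config), axis=config.ads_axis)


def _with_metric_seed(config: BenchmarkConfig, seed: int) -> BenchmarkConfig:
    """Copy of config whose kbet neighbourhood sampling uses this seed."""
    mp = {k: dict(v) for k, v in config.metric_params.items()}
    mp.setdefault("kbet", {}).setdefault("seed", seed)
    out = BenchmarkConfig(**{**asdict(config), "metric_params": mp})
    return out


def _score(values: pd.DataFrame, config: BenchmarkConfig) -> pd.DataFrame:
    rows = []
    for (metric, signal), grp in values.groupby(["metric", "signal"], sort=False):
        rho = spearman_score(grp["value"].to_numpy(),
                             grp["noise_rank"].to_numpy())
        sign = expected_sign(metric, signal, config.ads_axis,
                             config.invert_ratio)
        oriented = rho * sign if np.isfinite(rho) else float("nan")
        rows.append({"metric": metric, "signal": signal, "rho": rho,
                     "oriented_rho": oriented, "n": len(grp)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def summarize(result: BenchmarkResult, out_dir=None, plots: bool = False) -> dict:
    """Build (and optionally write) the result tables.

    Returns a dict of DataFrames: ``long`` (every evaluation),
    ``level_summary`` (median/min/max per metric x signal x level),
    ``spearman`` (metrics x signals rho table), ``oriented_spearman``,
    and ``mean_rank`` (metrics ranked per signal by oriented rho, then
    averaged).  With ``out_dir`` the tables are written as TSV; with
    ``plots=True`` one boxplot figure per metric is saved there too.
    """
    if result.values.empty:
        raise ValueError("empty benchmark result")
    long = result.values.copy()
    level_summary = (
        long.groupby(["metric", "signal", "noise_rank", "level"])["value"]
        .agg(["median", "min", "max"]).reset_index()
        .sort_values(["metric", "signal", "noise_rank"]).reset_index(drop=True)
    )
    spearman = result.scores.pivot(index="metric", columns="signal",
                                   values="rho")
    oriented = result.scores.pivot(index="metric", columns="signal",
                                   values="oriented_rho")
    metric_order = [m for m in result.config["metrics"]
                    if m in spearman.index]
    spearman = spearman.loc[metric_order]
    oriented = oriented.loc[metric_order]
    ranks = oriented.rank(axis=0, ascending=False, na_option="keep")
    mean_rank = ranks.mean(axis=1, skipna=True).to_frame("mean_rank")
    tables = {"long": long, "level_summary": level_summary,
              "spearman": spearman.reset_index(),
              "oriented_spearman": oriented.reset_index(),
              "mean_rank": mean_rank.reset_index()}
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        float_fmt = "%.10g"
        for name, df in tables.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format=float_fmt)
        if plots:
            _boxplots(long, out)
    return tables


def _boxplots(long: pd.DataFrame, out_dir) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric, mgrp in long.groupby("metric"):
        signals = [s for s in ("bio", "batch", "ratio")
                   if s in set(mgrp["signal"])]
        fig, axes = plt.subplots(1, len(signals),
                                 figsize=(4 * len(signals), 3.2), squeeze=False)
        for ax, signal in zip(axes[0], signals):
            sgrp = mgrp[mgrp["signal"] == signal]
            ranks = sorted(sgrp["noise_rank"].unique())
            data = [sgrp.loc[sgrp["noise_rank"] == r, "value"].to_numpy()
                    for r in ranks]
            finite = [d[np.isfinite(d)] for d in data]
            ax.boxplot(finite, tick_labels=[str(r) for r in ranks])
            ax.set_title(f"{metric} / {signal}")
            ax.set_xlabel("noise rank")
        fig.tight_layout()
        fig.savefig(f"{out_dir}/boxplot_{metric}.png", dpi=110)
        plt.close(fig)
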