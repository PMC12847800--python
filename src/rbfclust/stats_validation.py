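"""Statistical comparison workflow: per-fold metrics, tests, and Holm correction.

The t statistic uses the unpooled form
``t = (mean1 - mean2) / sqrt(s1^2/n1 + s2^2/n2)`` with Welch-Satterthwaite
degrees of freedom. One-way ANOVA, Pearson chi-square independence, and the
Holm-Bonferroni step-down correction are implemented from their standard
decompositions, with tail probabilities taken from scipy distributions.

The 5-fold stability protocol clusters each fold's complementary training
subset and scores partitions with internal indices plus pairwise NMI on the
points shared between training subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps

from . import validity
from .hybrid_rbf import RBFParams, fit
from .kmer_features import StandardizedMatrix

__all__ = [
    "FoldMetrics",
    "ComparisonReport",
    "welch_t",
    "anova_f",
    "chi_square_independence",
    "holm_bonferroni",
    "crossval_stability",
    "compare_algorithms",
    "make_baselines",
]

_INTERNAL_METRICS = ("silhouette", "ch", "db")


@dataclass
class FoldMetrics:
    algorithm: str
    fold: int
    metrics: Dict[str, float]


@dataclass
class ComparisonReport:
    t_stats: Dict[Tuple[str, str, str], Tuple[float, float, float]]
    anova: Dict[str, Tuple[float, float]]
    p_adjusted: Dict[str, float]
    reject: Dict[str, bool]
    fold_metrics: List[FoldMetrics] = field(default_factory=list)
    chi_square: tuple = None

    def to_dict(self) -> dict:
        return {
            "t_tests": [
                {"pair": list(k[:2]), "metric": k[2], "t": v[0], "p": v[1], "df": v[2]}
                for k, v in self.t_stats.items()
            ],
            "anova": [{"metric": m, "F": v[0], "p": v[1]} for m, v in self.anova.items()],
            "p_adjusted": dict(self.p_adjusted),
            "reject": dict(self.reject),
            "fold_metrics": [
                {"algorithm": f.algorithm, "fold": f.fold, "metrics": f.metrics}
                for f in self.fold_metrics
            ],
        }


def welch_t(x1: Sequence[float], x2: Sequence[float]) -> Tuple[float, float, float]:
    """Unpooled two-sample t with Welch-Satterthwaite df; returns (t, df, p)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    v1 = x1.var(ddof=1)
    v2 = x2.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("degenerate samples: both variances are zero")
    se2 = v1 / n1 + v2 / n2
    t = (x1.mean() - x2.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_f(groups: Sequence[Sequence[float]]) -> Tuple[float, float, float, float]:
    """One-way ANOVA; returns (F, df1, df2, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = all_x.size - len(groups)
    if ssw == 0.0:
        raise ValueError("zero within-group variance")
    f = (ssb / df1) / (ssw / df2)
    p = sps.f.sf(f, df1, df2)
    return float(f), float(df1), float(df2), float(p)


def chi_square_independence(table) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column marginal")
    expected = np.outer(rows, cols) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def holm_bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Step-down Holm correction; returns (adjusted p, reject) in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    # step-down: running max of (m - rank) * p_(rank), capped at 1
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= alpha
    return adjusted, reject


def _internal_metrics(x: np.ndarray, labels: np.ndarray) -> Dict[str, float]:
    if np.unique(labels).size < 2:
        warnings.warn("fewer than 2 clusters; internal metrics undefined", stacklevel=2)
        return {m: float("nan") for m in _INTERNAL_METRICS}
    mean_s, _ = validity.silhouette(x, labels)
    return {
        "silhouette": mean_s,
        "ch": validity.calinski_harabasz(x, labels),
        "db": validity.davies_bouldin(x, labels),
    }


def _fold_indices(n: int, n_folds: int, seed: int) -> List[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def crossval_stability(
    z: Union[StandardizedMatrix, np.ndarray],
    params: RBFParams,
    n_folds: int = 5,
    seed: int = 0,
) -> Tuple[List[FoldMetrics], dict]:
    """Cluster each fold's complementary training subset; summarize stability.

    Returns per-fold internal metrics plus a summary with per-metric mean/sd
    and the mean pairwise NMI between fold partitions restricted to points
    shared by both training subsets.
    """
    x = z.z if isinstance(z, StandardizedMatrix) else np.asarray(z, dtype=float)
    n = x.shape[0]
    if n < 2 * n_folds:
        raise ValueError("need n >= 2 * n_folds")
    folds = _fold_indices(n, n_folds, seed)
    fold_metrics: List[FoldMetrics] = []
    fold_labels: List[dict] = []  # global index -> label, per fold
    for f, held_out in enumerate(folds, start=1):
        train = np.setdiff1d(np.arange(n), held_out)
        try:
            result = fit(x[train], params)
        except ValueError as exc:
            warnings.warn(f"fold {f}: clustering failed ({exc}); recorded as missing")
            fold_metrics.append(
                FoldMetrics("hybrid", f, {m: float("nan") for m in _INTERNAL_METRICS})
            )
            fold_labels.append({})
            continue
        fold_metrics.append(FoldMetrics("hybrid", f, _internal_metrics(x[train], result.final_labels)))
        fold_labels.append({int(g): int(l) for g, l in zip(train, result.final_labels)})

    pairwise = []
    for a in range(n_folds):
        for b in range(a + 1, n_folds):
            shared = sorted(set(fold_labels[a]) & set(fold_labels[b]))
            if len(shared) >= 2:
                la = [fold_labels[a][i] for i in shared]
                lb = [fold_labels[b][i] for i in shared]
                pairwise.append(validity.nmi(la, lb))
    summary = {
        "metric_mean": {
            m: float(np.nanmean([fm.metrics[m] for fm in fold_metrics]))
            for m in _INTERNAL_METRICS
        },
        "metric_sd": {
            m: float(np.nanstd([fm.metrics[m] for fm in fold_metrics], ddof=1))
            for m in _INTERNAL_METRICS
        },
        "mean_pairwise_nmi": float(np.mean(pairwise)) if pairwise else float("nan"),
    }
    return fold_metrics, summary


def make_baselines(n_clusters: int = 3, seed: int = 0) -> Dict[str, Callable]:
    """Thin adapters around established baseline clusterers (labels = f(X))."""
    from sklearn.cluster import DBSCAN, AgglomerativeClustering, KMeans, SpectralClustering
    from sklearn.mixture import GaussianMixture

    return {
        "kmeans": lambda X: KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit_predict(X),
        "hierarchical": lambda X: AgglomerativeClustering(n_clusters=n_clusters).fit_predict(X),
        "dbscan": lambda X: DBSCAN().fit_predict(X),
        "spectral": lambda X: SpectralClustering(
            n_clusters=n_clusters, random_state=seed, assign_labels="discretize"
        ).fit_predict(X),
        "gmm": lambda X: GaussianMixture(
            n_components=n_clusters, random_state=seed
        ).fit_predict(X),
    }


def compare_algorithms(
    z: Union[StandardizedMatrix, np.ndarray],
    algorithms: Mapping[str, Callable],
    params: RBFParams = None,
    n_folds: int = 5,
    seed: int = 0,
    reference: str = "hybrid",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Per-fold metrics for every algorithm, Welch t vs the reference, ANOVA
    across all algorithms, and joint Holm adjustment of every raw p-value.

    ``algorithms`` maps name -> callable(features) -> labels. If the
    reference name is absent it is added as the hybrid RBF pipeline using
    ``params``. Identical samples (e.g. two copies of one deterministic
    algorithm) are reported as t = 0, p = 1 rather than an error.
    """
    if params is None:
        params = RBFParams()
    x = z.z if isinstance(z, StandardizedMatrix) else np.asarray(z, dtype=float)
    algorithms = dict(algorithms)
    if reference not in algorithms:
        algorithms[reference] = lambda X: fit(X, params).final_labels
    if len(algorithms) < 2:
        raise ValueError("need at least 2 algorithms")
    n = x.shape[0]
    folds = _fold_indices(n, n_folds, seed)

    fold_metrics: List[FoldMetrics] = []
    samples: Dict[str, Dict[str, list]] = {
        name: {m: [] for m in _INTERNAL_METRICS} for name in algorithms
    }
    for f, held_out in enumerate(folds, start=1):
        train = np.setdiff1d(np.arange(n), held_out)
        for name, proc in algorithms.items():
            labels = np.asarray(proc(x[train]))
            metrics = _internal_metrics(x[train], labels)
            fold_metrics.append(FoldMetrics(name, f, metrics))
            for m in _INTERNAL_METRICS:
                samples[name][m].append(metrics[m])

    t_stats: Dict[Tuple[str, str, str], Tuple[float, float, float]] = {}
    raw_p: Dict[str, float] = {}
    for name in algorithms:
        if name == reference:
            continue
        for m in _INTERNAL_METRICS:
            s_ref = np.asarray(samples[reference][m])
            s_alt = np.asarray(samples[name][m])
            ok = np.isfinite(s_ref) & np.isfinite(s_alt)
            if ok.sum() < 2:
                continue
            a, b = s_ref[ok], s_alt[ok]
            if np.array_equal(a, b):
                t, df, p = 0.0, float(ok.sum() * 2 - 2), 1.0
            else:
                try:
                    t, df, p = welch_t(a, b)
                except ValueError:
                    t, df, p = 0.0, float(ok.sum() * 2 - 2), 1.0
            t_stats[(reference, name, m)] = (t, p, df)
            raw_p[f"t:{reference}-vs-{name}:{m}"] = p

    anova: Dict[str, Tuple[float, float]] = {}
    for m in _INTERNAL_METRICS:
        groups = [
            np.asarray(samples[name][m])[np.isfinite(samples[name][m])]
            for name in algorithms
        ]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        try:
            fstat, _, _, p = anova_f(groups)
        except ValueError:
            continue
        anova[m] = (fstat, p)
        raw_p[f"anova:{m}"] = p

    ids = list(raw_p)
    adjusted, reject = holm_bonferroni([raw_p[i] for i in ids], alpha=alpha)
    return ComparisonReport(
        t_stats=t_stats,
        anova=anova,
        p_adjusted={i: float(a) for i, a in zip(ids, adjusted)},
        reject={i: bool(r) for i, r in zip(ids, reject)},
        fold_metrics=fold_metrics,
    )
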