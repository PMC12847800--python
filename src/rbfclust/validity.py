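"""Internal and external cluster validity indices.

All indices are computed directly from their defining formulas on Euclidean
distances:

* silhouette: ``s(i) = (b(i) - a(i)) / max(a(i), b(i))`` with the
  convention ``s(i) = 0`` for singleton clusters;
* Calinski-Harabasz: ``CH = (Tr(B_k) / Tr(W_k)) * (N - k) / (k - 1)``;
* Davies-Bouldin: ``DB = (1/k) sum_i max_{j != i} (s_i + s_j) / d(c_i, c_j)``
  with ``s_i`` the mean distance of cluster-i points to their centroid;
* NMI: ``I(A; B)`` normalized by the arithmetic (default) or geometric mean
  of the two label entropies, natural logarithms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ValidityReport",
    "silhouette",
    "calinski_harabasz",
    "davies_bouldin",
    "nmi",
    "evaluate_all",
]


@dataclass
class ValidityReport:
    silhouette_mean: float
    silhouette_per_point: np.ndarray
    calinski_harabasz: float
    davies_bouldin: float
    nmi: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "silhouette_mean": self.silhouette_mean,
            "calinski_harabasz": self.calinski_harabasz,
            "davies_bouldin": self.davies_bouldin,
        }
        if self.nmi is not None:
            d["nmi"] = self.nmi
        return d


def _check_features_labels(x, labels):
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    labels = np.asarray(labels)
    if x.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must have the same length")
    return x, labels


def silhouette(x, labels) -> Tuple[float, np.ndarray]:
    """Mean and per-point silhouette coefficients."""
    x, labels = _check_features_labels(x, labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for k=1")
    d = cdist(x, x)
    n = x.shape[0]
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = d[i, own[own != i]].mean()
        b = min(d[i, members[c]].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean()), s


def calinski_harabasz(x, labels) -> float:
    """Ratio of between- to within-cluster scatter traces, scaled by (N-k)/(k-1)."""
    x, labels = _check_features_labels(x, labels)
    uniq = np.unique(labels)
    n, k = x.shape[0], uniq.size
    if not (2 <= k <= n - 1):
        raise ValueError("calinski_harabasz requires 2 <= k <= N - 1")
    grand = x.mean(axis=0)
    tr_b = 0.0
    tr_w = 0.0
    for c in uniq:
        pts = x[labels == c]
        centroid = pts.mean(axis=0)
        tr_b += pts.shape[0] * float(((centroid - grand) ** 2).sum())
        tr_w += float(((pts - centroid) ** 2).sum())
    if tr_w == 0.0:
        warnings.warn("zero within-cluster scatter; CH is infinite", stacklevel=2)
        return float("inf")
    return (tr_b / tr_w) * (n - k) / (k - 1)


def davies_bouldin(x, labels) -> float:
    """Average worst-case (s_i + s_j) / d(c_i, c_j) cluster similarity."""
    x, labels = _check_features_labels(x, labels)
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("davies_bouldin requires k >= 2")
    centroids = np.vstack([x[labels == c].mean(axis=0) for c in uniq])
    spread = np.array(
        [cdist(x[labels == c], centroids[[j]]).mean() for j, c in enumerate(uniq)]
    )
    dc = cdist(centroids, centroids)
    total = 0.0
    for i in range(k):
        ratios = []
        for j in range(k):
            if j == i:
                continue
            if dc[i, j] == 0:
                raise ValueError(
                    f"coincident centroids for clusters {uniq[i]!r} and {uniq[j]!r}"
                )
            ratios.append((spread[i] + spread[j]) / dc[i, j])
        total += max(ratios)
    return total / k


def nmi(labels_a, labels_b, average: str = "arithmetic") -> float:
    """Normalized mutual information between two labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if a.size == 0:
        raise ValueError("labelings must be non-empty")
    if average not in {"arithmetic", "geometric"}:
        raise ValueError("average must be 'arithmetic' or 'geometric'")
    n = a.size
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((ua.size, ub.size))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha = -np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa)))
    hb = -np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb)))
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])))
    if ha == 0.0 and hb == 0.0:
        return 1.0  # both constant: identical partitions up to relabeling
    if ha == 0.0 or hb == 0.0:
        return 0.0
    denom = 0.5 * (ha + hb) if average == "arithmetic" else float(np.sqrt(ha * hb))
    return float(np.clip(mi / denom, 0.0, 1.0))


def evaluate_all(x, labels, truth=None, nmi_average: str = "arithmetic") -> ValidityReport:
    """Compute every index at once; NMI only when reference labels are given."""
    mean_s, per_point = silhouette(x, labels)
    return ValidityReport(
        silhouette_mean=mean_s,
        silhouette_per_point=per_point,
        calinski_harabasz=calinski_harabasz(x, labels),
        davies_bouldin=davies_bouldin(x, labels),
        nmi=None if truth is None else nmi(labels, truth, average=nmi_average),
    )
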