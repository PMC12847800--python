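"""Two-phase density/kernel clustering on a Gaussian RBF affinity graph.

The method is deterministic and parameterized by ``RBFParams``:

Phase 1 (subcluster detection)
    A Gaussian kernel ``W[i, j] = exp(-d(x_i, x_j)^2 / (2 sigma^2))`` turns
    pairwise Euclidean distances into affinities. Each point's normalized
    density ``rho_norm[i] = sum_{j != i} W[i, j] / (n - 1)`` measures how
    strongly its neighborhood supports it; points with
    ``rho_norm < p1 - p3`` are set aside in the isolated set S. Remaining
    points are scanned in descending density order; each unprocessed point
    seeds a subcluster together with every unprocessed, non-isolated
    neighbor whose kernel weight is at least ``tau_link``.

Phase 2 (merging and final assignment)
    Subcluster pairs whose cross-pair mean kernel weight reaches
    ``tau_merge`` are linked; final clusters are the connected components of
    this link graph (a single pass, order-independent). Isolated points are
    then absorbed by the cluster with maximal mean kernel weight to them.

The kernel width ``sigma`` is ``p2`` times the grand mean over points of the
mean Euclidean distance to each point's ``n_sigma_neighbors`` nearest
neighbors, so ``p2 = 1`` reproduces the average-5-nearest-neighbor
initialization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .kmer_features import StandardizedMatrix

__all__ = [
    "RBFParams",
    "AffinityState",
    "SubClusterState",
    "ClusteringResult",
    "compute_sigma",
    "build_affinity",
    "detect_subclusters",
    "merge_subclusters",
    "assign_isolated",
    "fit",
]

#: kernel weight of two points exactly one sigma apart
TAU_LINK_DEFAULT = math.exp(-0.5)


@dataclass(frozen=True)
class RBFParams:
    """Algorithm parameters.

    Parameters
    ----------
    p1 : float
        Density threshold in (0, 1].
    p2 : float
        Spread multiplier (> 0) applied to the mean nearest-neighbor
        distance when deriving the kernel width sigma.
    p3 : float
        Resolution modifier (>= 0); the isolation cutoff is ``p1 - p3``.
    n_sigma_neighbors : int
        Number of nearest neighbors used for the sigma initialization.
    tau_link : float
        Minimum kernel weight for a point to join a seed's subcluster.
    tau_merge : float
        Minimum cross-pair connectivity for two subclusters to merge.
    merge_linkage : str
        ``"mean"`` (default) uses the mean cross-pair weight as the
        connectivity statistic; ``"max"`` uses the single strongest link.
    """

    p1: float = 0.15
    p2: float = 1.0
    p3: float = 0.05
    n_sigma_neighbors: int = 5
    tau_link: float = TAU_LINK_DEFAULT
    tau_merge: float = 0.2
    merge_linkage: str = "mean"

    def __post_init__(self) -> None:
        if not (0 < self.p1 <= 1):
            raise ValueError("p1 must lie in (0, 1]")
        if self.p2 <= 0:
            raise ValueError("p2 must be > 0")
        if self.p3 < 0:
            raise ValueError("p3 must be >= 0")
        if self.n_sigma_neighbors < 1:
            raise ValueError("n_sigma_neighbors must be >= 1")
        if not (0 < self.tau_link < 1) or not (0 < self.tau_merge < 1):
            raise ValueError("tau_link and tau_merge must lie in (0, 1)")
        if self.merge_linkage not in {"mean", "max"}:
            raise ValueError("merge_linkage must be 'mean' or 'max'")
        if self.tau_merge >= self.tau_link:
            warnings.warn(
                "tau_merge >= tau_link: merging is no stricter than linking",
                stacklevel=2,
            )


@dataclass
class AffinityState:
    """Symmetric kernel weight matrix with per-point densities."""

    w: np.ndarray  # (n, n), symmetric, unit diagonal
    sigma: float
    rho_raw: np.ndarray  # sum_{j != i} w[i, j]
    rho_norm: np.ndarray  # rho_raw / (n - 1), in [0, 1]

    @property
    def n(self) -> int:
        return self.w.shape[0]


@dataclass
class SubClusterState:
    """Phase-1 output: subcluster labels plus the isolated set S."""

    labels: np.ndarray  # 0 = isolated/unassigned, 1..t = subcluster id
    isolated: list  # ordered point indices in S
    subclusters: list  # list of index lists, subclusters[i] has label i + 1
    t: int


@dataclass
class ClusteringResult:
    """Final hard partition with merge/isolation provenance."""

    final_labels: np.ndarray  # 1..K once complete (0 for isolated pre-assignment)
    n_clusters: int
    merge_log: list  # one sorted list of subcluster ids per final cluster
    isolated_assignments: dict  # isolated index -> final cluster id
    params_used: RBFParams
    sigma: float


def _as_array(z: Union[StandardizedMatrix, np.ndarray]) -> np.ndarray:
    x = z.z if isinstance(z, StandardizedMatrix) else np.asarray(z, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def compute_sigma(z: Union[StandardizedMatrix, np.ndarray], params: RBFParams) -> float:
    """Kernel width: p2 times the grand mean of mean k-nearest-neighbor distances."""
    x = _as_array(z)
    n = x.shape[0]
    k = params.n_sigma_neighbors
    if n < k + 1:
        raise ValueError(f"need at least n_sigma_neighbors + 1 = {k + 1} points, got {n}")
    d = squareform(pdist(x))
    # drop self-distance, take the k smallest of the remaining n - 1
    d_sorted = np.sort(d, axis=1)[:, 1 : k + 1]
    sigma = params.p2 * float(d_sorted.mean())
    if sigma <= 0:
        raise ValueError("degenerate data: all pairwise distances are zero")
    return sigma


def build_affinity(z: Union[StandardizedMatrix, np.ndarray], sigma: float) -> AffinityState:
    """Gaussian kernel affinity matrix and normalized densities."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = _as_array(z)
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    n = x.shape[0]
    d2 = squareform(pdist(x, metric="sqeuclidean"))
    w = np.exp(-d2 / (2.0 * sigma**2))
    np.fill_diagonal(w, 1.0)
    rho_raw = w.sum(axis=1) - 1.0
    rho_norm = rho_raw / max(n - 1, 1)
    return AffinityState(w=w, sigma=float(sigma), rho_raw=rho_raw, rho_norm=rho_norm)


def detect_subclusters(aff: AffinityState, params: RBFParams) -> SubClusterState:
    """Phase 1: isolate low-density points, then grow subclusters from dense seeds.

    Points with ``rho_norm < p1 - p3`` go to S. The rest are processed in
    descending ``rho_norm`` order (ties broken by lower index): each
    unprocessed point seeds a new subcluster containing itself plus all
    unprocessed, non-isolated points j with ``w[i, j] >= tau_link``. A seed
    with no qualifying neighbor forms a singleton subcluster.
    """
    n = aff.n
    cutoff = params.p1 - params.p3
    if cutoff <= 0:
        warnings.warn("p1 - p3 <= 0: no point can be isolated", stacklevel=2)
    iso_mask = aff.rho_norm < cutoff
    isolated = list(np.flatnonzero(iso_mask))

    labels = np.zeros(n, dtype=int)
    processed = iso_mask.copy()
    # descending density, ties -> lower index first
    order = np.lexsort((np.arange(n), -aff.rho_norm))
    subclusters = []
    t = 0
    for i in order:
        if processed[i]:
            continue
        members = np.flatnonzero(~processed & (aff.w[i] >= params.tau_link))
        members = np.union1d(members, [i])
        t += 1
        labels[members] = t
        processed[members] = True
        subclusters.append(list(members))
    return SubClusterState(labels=labels, isolated=isolated, subclusters=subclusters, t=t)


def _connectivity(w: np.ndarray, a: list, b: list, linkage: str) -> float:
    block = w[np.ix_(a, b)]
    return float(block.max() if linkage == "max" else block.mean())


def merge_subclusters(
    state: SubClusterState, aff: AffinityState, params: RBFParams
) -> ClusteringResult:
    """Phase 2: link subclusters with connectivity >= tau_merge, take components.

    Connectivity C(a, b) is the mean (or max, per ``merge_linkage``) kernel
    weight over all cross pairs. Final clusters are connected components of
    the link graph; they are numbered 1..K by their smallest member point
    index. Isolated points keep label 0 until :func:`assign_isolated`.
    """
    t = state.t
    n = aff.n
    final = np.zeros(n, dtype=int)
    if t == 0:
        return ClusteringResult(
            final_labels=final,
            n_clusters=0,
            merge_log=[],
            isolated_assignments={},
            params_used=params,
            sigma=aff.sigma,
        )
    adj = np.zeros((t, t), dtype=bool)
    for a in range(t):
        for b in range(a + 1, t):
            c = _connectivity(aff.w, state.subclusters[a], state.subclusters[b], params.merge_linkage)
            if c >= params.tau_merge:
                adj[a, b] = adj[b, a] = True
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    # order components by smallest member point index
    comp_min = [
        min(min(state.subclusters[sc]) for sc in range(t) if comp[sc] == c)
        for c in range(n_comp)
    ]
    comp_order = np.argsort(comp_min, kind="stable")
    comp_rank = {int(c): r + 1 for r, c in enumerate(comp_order)}

    merge_log = []
    for c in comp_order:
        members_sc = sorted(sc + 1 for sc in range(t) if comp[sc] == c)
        merge_log.append(members_sc)
    for sc in range(t):
        final[state.subclusters[sc]] = comp_rank[int(comp[sc])]
    return ClusteringResult(
        final_labels=final,
        n_clusters=n_comp,
        merge_log=merge_log,
        isolated_assignments={},
        params_used=params,
        sigma=aff.sigma,
    )


def assign_isolated(
    result: ClusteringResult, state: SubClusterState, aff: AffinityState
) -> ClusteringResult:
    """Absorb each isolated point into the cluster with maximal mean kernel weight.

    Ties go to the lowest cluster label. Raises if there is no cluster to
    absorb the points into.
    """
    if state.isolated and result.n_clusters == 0:
        raise ValueError("no clusters to absorb isolated points")
    labels = result.final_labels.copy()
    assignments = dict(result.isolated_assignments)
    members_by_cluster = [
        np.flatnonzero(result.final_labels == c) for c in range(1, result.n_clusters + 1)
    ]
    for i in state.isolated:
        means = np.array([aff.w[i, m].mean() for m in members_by_cluster])
        best = int(np.argmax(means)) + 1  # argmax returns first max -> lowest label
        labels[i] = best
        assignments[int(i)] = best
    return ClusteringResult(
        final_labels=labels,
        n_clusters=result.n_clusters,
        merge_log=result.merge_log,
        isolated_assignments=assignments,
        params_used=result.params_used,
        sigma=result.sigma,
    )


def fit(
    z: Union[StandardizedMatrix, np.ndarray], params: RBFParams = None
) -> ClusteringResult:
    """Run the full pipeline: sigma, affinity, Phase 1, Phase 2, final assignment.

    Deterministic: no randomness anywhere in the algorithm.
    """
    if params is None:
        params = RBFParams()
    x = _as_array(z)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 points")
    sigma = compute_sigma(x, params)
    aff = build_affinity(x, sigma)
    state = detect_subclusters(aff, params)
    result = merge_subclusters(state, aff, params)
    return assign_isolated(result, state, aff)
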