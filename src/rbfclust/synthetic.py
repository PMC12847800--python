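"""Planted-cluster data generators for sequences and feature-space blobs.

Sequence mode draws one i.i.d.-uniform ACGT ancestor per cluster (redrawing
until all ancestor pairs are at least ``between_divergence`` apart in
normalized Hamming distance), then derives each member by independent
per-base substitution at ``within_mut_rate`` (to a uniformly random
different base). Outliers are fresh uniform sequences with truth label 0.
The mutation model is substitution-only, keeping the expected pairwise
Hamming distance between cluster mates analytically checkable:
``L * (2 p (1 - p) + p^2 * 2/3)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .io_sequences import SequenceRecord, SequenceSet

__all__ = ["PlantedDesign", "generate_planted_sequences", "generate_feature_blobs"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedDesign:
    n_clusters: int = 3
    per_cluster: int = 20
    seq_length: int = 2000
    within_mut_rate: float = 0.01
    between_divergence: float = 0.20
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.per_cluster < 1:
            raise ValueError("n_clusters and per_cluster must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if not (0 <= self.within_mut_rate <= 1) or not (0 <= self.between_divergence <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_outliers < 0:
            raise ValueError("n_outliers must be >= 0")
        if self.within_mut_rate >= self.between_divergence:
            warnings.warn(
                "within_mut_rate >= between_divergence: design may not be separable",
                stacklevel=2,
            )


def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    child = ancestor.copy()
    mask = rng.random(child.size) < rate
    # shift by 1..3 mod 4 -> always a different base, uniform over the other 3
    child[mask] = (child[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return child


def _draw_ancestors(design: PlantedDesign, rng: np.random.Generator) -> np.ndarray:
    anc = rng.integers(0, 4, size=(design.n_clusters, design.seq_length))
    for _ in range(100):
        bad = False
        for a in range(design.n_clusters):
            for b in range(a + 1, design.n_clusters):
                if np.mean(anc[a] != anc[b]) < design.between_divergence:
                    anc[b] = rng.integers(0, 4, size=design.seq_length)
                    bad = True
        if not bad:
            return anc
    raise RuntimeError(
        f"could not achieve between_divergence={design.between_divergence} "
        "after 100 redraw attempts (unattainable divergence?)"
    )


def generate_planted_sequences(design: PlantedDesign) -> Tuple[SequenceSet, np.ndarray]:
    """Return (SequenceSet, truth labels); cluster labels 1..C, outliers 0."""
    rng = np.random.default_rng(design.seed)
    ancestors = _draw_ancestors(design, rng)
    records = []
    labels = []
    for c in range(design.n_clusters):
        for g in range(design.per_cluster):
            child = _mutate(ancestors[c], design.within_mut_rate, rng)
            records.append(
                SequenceRecord(
                    gene_symbol=f"C{c + 1}G{g + 1:03d}",
                    accession=f"SYN{c + 1:02d}{g + 1:04d}",
                    sequence="".join(_BASES[child]),
                )
            )
            labels.append(c + 1)
    for o in range(design.n_outliers):
        seq = rng.integers(0, 4, size=design.seq_length)
        records.append(
            SequenceRecord(
                gene_symbol=f"OUT{o + 1:03d}",
                accession=f"SYNOUT{o + 1:04d}",
                sequence="".join(_BASES[seq]),
            )
        )
        labels.append(0)
    return (
        SequenceSet(records=records, provenance=f"planted(seed={design.seed})"),
        np.asarray(labels, dtype=int),
    )


def generate_feature_blobs(
    n_clusters: int,
    per_cluster: int,
    dims: int = 2,
    center_spread: float = 10.0,
    within_sd: float = 0.5,
    n_outliers: int = 0,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian blobs around uniform cube centers; outliers uniform, label 0."""
    if center_spread <= 0 or within_sd < 0:
        raise ValueError("center_spread must be > 0 and within_sd >= 0")
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, center_spread, size=(n_clusters, dims))
    rows = []
    labels = []
    for c in range(n_clusters):
        rows.append(centers[c] + rng.normal(0, within_sd, size=(per_cluster, dims)))
        labels.extend([c + 1] * per_cluster)
    if n_outliers:
        rows.append(rng.uniform(0, center_spread, size=(n_outliers, dims)))
        labels.extend([0] * n_outliers)
    return np.vstack(rows), np.asarray(labels, dtype=int)
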