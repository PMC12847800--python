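"""k-mer counting and per-column Z-score standardization.

Sequences of arbitrary length are mapped into a fixed-size feature space by
counting overlapping k-length windows (step 1). Windows containing any
character outside {A, C, G, T} are skipped entirely. Counts are then
standardized column-wise, ``Z[i, j] = (M[i, j] - mu_j) / sigma_j``, using the
population (divide-by-n) standard deviation; zero-variance columns are
dropped.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .io_sequences import SequenceSet

__all__ = ["KmerCountMatrix", "StandardizedMatrix", "count_kmers", "standardize"]

_VALID = frozenset("ACGT")


@dataclass
class KmerCountMatrix:
    """n x m nonnegative integer matrix of k-mer counts with its vocabulary."""

    counts: np.ndarray  # (n, m) int
    vocabulary: list  # m k-mer strings, ordered
    k: int

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    def to_csv(self, path: Union[str, Path]) -> None:
        header = ",".join(self.vocabulary)
        np.savetxt(path, self.counts, fmt="%d", delimiter=",", header=header, comments="")

    def to_mtx(self, path: Union[str, Path], vocab_path: Union[str, Path] = None) -> None:
        mmwrite(str(path), csr_matrix(self.counts))
        if vocab_path is not None:
            Path(vocab_path).write_text("\n".join(self.vocabulary) + "\n")


@dataclass
class StandardizedMatrix:
    """Z-scored feature matrix with the statistics used to produce it."""

    z: np.ndarray  # (n, m')
    column_means: np.ndarray
    column_sds: np.ndarray
    kept_columns: np.ndarray  # indices into the source vocabulary

    @property
    def n(self) -> int:
        return self.z.shape[0]

    def to_csv(self, path: Union[str, Path]) -> None:
        np.savetxt(path, self.z, delimiter=",")


def _kmer_counter(sequence: str, k: int) -> Counter:
    # Windows overlapping a non-ACGT character contribute nothing.
    c = Counter()
    for i in range(len(sequence) - k + 1):
        w = sequence[i : i + k]
        if _VALID.issuperset(w):
            c[w] += 1
    return c


def count_kmers(s: SequenceSet, k: int = 5, full_vocabulary: bool = False) -> KmerCountMatrix:
    """Count overlapping k-mers per record.

    Parameters
    ----------
    s : SequenceSet
        Input sequences; row order follows record order.
    k : int
        Window length, default 5.
    full_vocabulary : bool
        If True, columns span the full 4^k grid; otherwise the sorted union
        of observed k-mers.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    per_record = []
    for rec in s.records:
        if rec.length < k:
            warnings.warn(
                f"sequence {rec.gene_symbol!r} shorter than k={k}; all-zero row",
                stacklevel=2,
            )
        per_record.append(_kmer_counter(rec.sequence, k))
    if full_vocabulary:
        vocabulary = ["".join(p) for p in itertools.product("ACGT", repeat=k)]
    else:
        vocabulary = sorted(set().union(*per_record)) if per_record else []
    index = {kmer: j for j, kmer in enumerate(vocabulary)}
    counts = np.zeros((len(per_record), len(vocabulary)), dtype=np.int64)
    for i, c in enumerate(per_record):
        for kmer, v in c.items():
            counts[i, index[kmer]] = v
    return KmerCountMatrix(counts=counts, vocabulary=vocabulary, k=k)


def standardize(mc: Union[KmerCountMatrix, np.ndarray]) -> StandardizedMatrix:
    """Column-wise Z-scoring with population sd; zero-variance columns dropped."""
    x = mc.counts if isinstance(mc, KmerCountMatrix) else np.asarray(mc)
    x = x.astype(float)
    if x.shape[0] < 2:
        raise ValueError("standardize requires at least 2 rows")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # ddof=0, population
    kept = np.flatnonzero(sd > 0)
    z = (x[:, kept] - mu[kept]) / sd[kept]
    return StandardizedMatrix(
        z=z, column_means=mu[kept], column_sds=sd[kept], kept_columns=kept
    )
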