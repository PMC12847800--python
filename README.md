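# rbfclust

Hybrid RBF-network clustering of nucleotide sequences via k-mer profiles.

Sequences are quality-filtered, converted to standardized k-mer count
vectors, and clustered by a deterministic two-phase procedure on a Gaussian
kernel affinity graph: Phase 1 isolates low-density points and grows
subclusters from dense seeds; Phase 2 merges strongly connected subclusters
into final clusters and reassigns the isolated points. The package also
ships the internal/external validity indices (silhouette,
Calinski–Harabasz, Davies–Bouldin, NMI), a statistical comparison workflow
(Welch t, one-way ANOVA, chi-square, Holm–Bonferroni, k-fold stability),
and planted-cluster simulators so everything is testable offline.

## Modules

| module | contents |
| --- | --- |
| `rbfclust.io_sequences` | FASTA/CSV ingestion, dedup, length/N-content quality filter |
| `rbfclust.kmer_features` | k-mer counting (default k=5) and per-column Z-scoring |
| `rbfclust.hybrid_rbf` | the two-phase clustering algorithm (`fit` and its stages) |
| `rbfclust.validity` | silhouette, CH, DB, NMI |
| `rbfclust.stats_validation` | Welch t, ANOVA, chi-square, Holm correction, cross-validation stability, algorithm comparison |
| `rbfclust.synthetic` | planted-cluster sequence and feature-blob generators |

## Quick start

```python
from rbfclust import read_fasta, deduplicate, filter_quality, count_kmers, standardize, fit, RBFParams

seqs = filter_quality(deduplicate(read_fasta("genes.fasta")), min_length=1000)
z = standardize(count_kmers(seqs, k=5))
result = fit(z, RBFParams(p1=0.15, p2=1.0, p3=0.05))
print(result.n_clusters, result.final_labels)
```

## CLI

```bash
# simulate planted sequences, then cluster them
echo '{"n_clusters": 3, "per_cluster": 20, "seq_length": 2000, "seed": 1}' > design.json
rbfclust simulate --mode sequences --config design.json --out simdir
rbfclust cluster --fasta simdir/sequences.fasta --k 5 --p1 0.15 --p2 1.0 --p3 0.05 --out clustdir

# validity metrics and algorithm comparison on a feature CSV
rbfclust evaluate --features features.csv --labels clustdir/labels.csv --out report.json
rbfclust compare --features features.csv --algorithms hybrid,kmeans,gmm --folds 5 --seed 42 --out cmp.json
```

## Key parameters

- `p1` (density threshold, default 0.15) and `p3` (resolution modifier,
  default 0.05): points with normalized kernel density below `p1 - p3`
  are provisionally isolated.
- `p2` (spread multiplier, default 1.0): the kernel width sigma equals
  `p2` times the average Euclidean distance to each point's five nearest
  neighbors.
- `tau_link` (default `exp(-1/2)`, i.e. within one sigma): minimum kernel
  weight for joining a subcluster seed.
- `tau_merge` (default 0.2): minimum mean cross-pair weight for merging
  two subclusters.
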