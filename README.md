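# icastab

Stabilized independent component analysis (ICA) of transcriptomic
matrices, with stability-based component ranking, data-driven selection
of the number of components (the Maximally Stable Transcriptome
Dimension, MSTD) and cross-dataset reproducibility analysis.

## The problem

ICA factorizes a log-scale expression matrix as **X ≈ AS**: the rows of
**S** are *metagenes* (gene weight vectors of statistically independent
expression programs — cell cycle, immune infiltration, stromal content,
technical batches, …) and the columns of **A** are the matching sample
loadings.  Unlike PCA, ICA solutions are local optima of a non-convex
contrast, so different random initializations give different components,
and the components carry no natural order.  Worse, the method needs the
number of components *M* up front, and both under-decomposition (fused
signals) and extreme over-decomposition (unstable, fragmented signals)
hurt interpretability.

`icastab` addresses both issues with a reproducibility-first protocol:

1. **Stabilization** — fastICA (pow3 contrast, symmetric decorrelation)
   is run *K* times from different seeded rotations on the same
   PCA-whitened data.  The pooled *K·M* components are clustered with
   average-linkage agglomerative clustering under the dissimilarity
   1 − |r| (Pearson correlation of gene-space weights).  Each cluster
   *C_k* gets a stability index

   *I_q(C_k) = (1/|C_k|²) Σ_{i,j∈C_k} |r_ij| −
   (1/(|C_k| Σ_{l≠k}|C_l|)) Σ_{i∈C_k} Σ_{j∉C_k} |r_ij|*,

   which is 1 for a perfectly reproducible component.  Clusters are
   summarized by their centrotype, oriented so the heaviest weight tail
   is positive, and ranked by descending stability.
2. **MSTD** — the scan over orders M overlays all stability profiles as
   (rank, I_q) points; two-line clustering (k-lines, total least
   squares) separates the uniformly-stable regime from the mode of
   low-stability components, and the intersection of the two lines is
   the advised decomposition order.
3. **Comparison** — metagenes from different decompositions or datasets
   are matched by |Pearson r| over common genes; reciprocal best
   matches above |r| > 0.3 form an undirected reproducibility graph.
   A component's *reproducibility score* is the sum of its reciprocal
   edge correlations (bounded by the number of other datasets).
   Components conserved, split or lost in higher-order decompositions
   are classified, components driven by 1–3 genes are detected from
   the multiplicative gap structure of their weight tails
   (W^top = 3.0, G^max = 1.5), and top-contributing genes
   (weight > 5.0) are annotated against GMT gene sets (Jaccard index,
   BH-corrected hypergeometric tests).

## Worked example

```python
import icastab

# synthetic 2000-gene x 200-sample study with 10 planted programs
data = icastab.generate_factor_data(icastab.GeneratorConfig(seed=0))

res = icastab.StabilizedICA(data.X).fit(n_components=10, n_runs=20, seed=0)
print(res.summary())
```

```
Stabilized ICA decomposition
  order M:              10
  runs K:               20  (converged: 20)
  seed:                 0
  explained variance:   0.5237
  avg stability S(M):   1.0000

  component  stability
  IC1          1.0000
  IC2          1.0000
  IC3          1.0000
  IC4          1.0000
  IC5          1.0000
  IC6          1.0000
  IC7          1.0000
  IC8          1.0000
  IC9          1.0000
  IC10         1.0000
```

The ten components are perfectly reproducible across the 20 restarts
(all I_q = 1.00 at this precision), and the 10-dimensional subspace
carries 52% of the variance — the rest is measurement noise.  Every
planted metagene is matched by a component with |r| > 0.9
(`tests/test_acceptance.py`).

Selecting the order instead of assuming it:

```python
scan = icastab.DimensionScan(data.X, grid=range(2, 31)).fit(n_runs=20, seed=0)
print(scan.mstd, scan.baselines)          # -> 13 {'kaiser': 10, 'broken_stick': 10}
scan.plot()                               # grey profiles + fitted lines + MSTD marker
```

The two-line intersection lands at 13, close to the planted dimension
10; on this clean synthetic model the PCA baselines agree (on real
transcriptomes the Kaiser rule is known to run far higher).

The same workflow from the shell:

```bash
icastab simulate --genes 2000 --samples 200 --sources 10 --seed 1 --out sim/
icastab scan --data sim/expression.tsv --grid 2:30 --runs 20 --seed 1 --out scan.json
icastab mstd --scan scan.json --out mstd.json --plot profiles.png
icastab decompose --data sim/expression.tsv --m 10 --runs 20 --seed 1 --out dec/sim
```

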