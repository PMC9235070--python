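# scheter

Quantifying intra-tumoral transcriptomic heterogeneity in single-cell
RNA-seq data, and organizing genes into cluster hierarchies that can be
compared across cancer types and validated in bulk cohorts.

`scheter` is aimed at computational biologists working with tumor
single-cell expression matrices (genes × cells, depth-normalized, with
dropout) plus patient labels. It provides:

* **Heterogeneity statistics** — the average **NSV fraction** (per tumor,
  the fraction of cells with negative silhouette value
  `s(i) = (b(i) − a(i)) / max(a(i), b(i))`, with tumors as clusters and
  distances between per-cell z-scores) and **p_diff**
  `= P(X > Y + ε) − P(X < Y − ε)`, the margin-ε deviation between the
  intra-tumoral (X) and inter-tumoral (Y) cell-cell correlation
  distributions, estimated by rejection sampling from kernel density
  estimates. p_diff lives in [−1, 1] and, unlike rank-test p-values, does
  not collapse with the enormous pair counts of single-cell data. A
  per-tumor KDE entropy baseline (bits, gene-independence assumption) is
  included for comparison.
* **Gene-cluster hierarchies** — consensus k-means partitions for
  k = 1..12, tied into a DAG by the inheritance rule
  `|c_i ∩ c_j| ≥ 0.15·|c_j|` between consecutive levels, reduced by
  collapsing stumps (chains of single-parent/single-child clusters), and
  annotated with p_diff, NSV and density.
* **Enrichment** — hypergeometric gene-set tests with BH-FDR control and a
  unique-enrichment procedure that walks the hierarchy to the single
  deepest cluster a gene set's signal belongs to.
* **Cross-dataset alignment** — matching of hierarchy paths between
  datasets by cluster overlap (Jaccard > 0.2, or 0.1–0.2 with mutual
  top-ten rank), NMF decomposition of subgraph–edge membership matrices,
  clique merging of components into **meta gene clusters**, and a
  Hamming-distance consensus over randomized trials.
* **Bulk validation & subtyping** — expression-coherence and per-gene Cox
  coefficient p_diff scores against bulk expression/survival cohorts, a
  one-sided KS random-walk enrichment of meta clusters, PAM50-style marker
  panel extension, and correlation-based per-cell/per-patient subtype
  prediction.
* **Synthetic data generators** for all of the above, used throughout the
  test suite.

## Worked example

The bundled tumor-mixture simulation draws 500 cells (10 genes, 5
orthogonal population centroids, Gaussian noise σ) and allocates them to 5
tumors either purely (case 1) or fully mixed (case 3):

```python
from scheter import MixtureSimConfig, heterogeneity_report, simulate_mixture

for case in (1, 3):
    m = simulate_mixture(MixtureSimConfig(case=case, sigma=0.05, seed=0))
    rep = heterogeneity_report(m, n_samples=30_000, seed=0, with_entropy=True)
    print(f"case {case}: avg_nsv={rep.avg_nsv:.3f}  p_diff={rep.p_diff:.3f}  "
          f"entropy={rep.avg_entropy:.2f} bits")
```

```
case 1: avg_nsv=0.000  p_diff=1.000  entropy=-22.33 bits
case 3: avg_nsv=0.606  p_diff=-0.013  entropy=-14.06 bits
```

Pure tumors (case 1) are perfectly homogeneous: no cell sits closer to a
foreign tumor (NSV 0) and intra-tumoral correlations dominate inter-tumoral
ones by more than the ε = 0.05 margin (p_diff ≈ 1). Fully mixed tumors are
statistically identical to each other: p_diff ≈ 0, while almost two thirds
of the cells have negative silhouettes and the per-tumor entropy rises by
≈ 8 bits as every gene's marginal becomes bimodal.

The same statistics, hierarchy construction, alignment and validation are
available from the command line:

```bash
scheter simulate --case 3 --sigma 0.05 --seed 0 -o toy/
scheter heterogeneity --matrix toy/matrix.tsv --labels toy/labels.tsv --entropy
scheter hierarchy --matrix X.tsv --labels L.tsv --kmax 12 --reduce -o hier.json
scheter align --hierarchies h1.json --hierarchies h2.json --trials 100 -o meta.tsv
```

See `docs/methods.md` for the statistical conventions, defaults, and the
design of the synthetic benchmarks.

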