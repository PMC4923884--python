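# modulenet

Gene networks from expression data alone, adaptively partitioned into
functional modules — with the survival and classification harness needed to
evaluate whether the modules carry clinical signal.

## The problem

Most network analyses of cancer cohorts wire genes together using curated
interaction databases, which cannot reflect cancer-specific rewiring. An
alternative is to infer the network directly from the cohort's expression
matrix: model the P genes as a multivariate Gaussian and estimate the
precision (inverse covariance) matrix Θ = Σ⁻¹, whose zero pattern encodes
conditional independence. Because P usually exceeds the number of samples N,
the empirical covariance S is singular and Θ is estimated by the graphical
lasso, maximizing the L1-penalized log-likelihood

    log det Θ − tr(SΘ) − ρ‖Θ‖₁

An edge joins genes i and j exactly when Θ̂ᵢⱼ ≠ 0. The resulting networks are
scale-free-like: a few hub genes with many neighbors, many low-degree genes.

The package's core algorithm then partitions the network into modules:

1. Take the k = 20 highest-degree genes as **hubs**; each hub plus its direct
   neighbors is an **initialized module** Uᵢ.
2. Every maximal collection of ≥ 2 pairwise-disjoint initialized modules is a
   **seed module set** S.
3. For each seed set, merge every remaining initialized module into the
   current module with the largest overlap |r ∩ s| (the target is updated
   after every merge), giving a candidate partition C = {c₁, …, c_α}.
4. Score each candidate by the **average overlap**
   E = Σ_{a<b} |c_a ∩ c_b| / C(α, 2); the partition(s) with minimal E — the
   best-separated modules — win.

The penalty ρ is chosen by scanning 0, 0.1, …, 1.0 and keeping the smallest
value (densest network) whose network admits at least one seed set.

Module quality is evaluated two ways: unsupervised — hierarchical clustering
of patients on module genes into two groups, compared by the log-rank test
and benchmarked against random same-size gene sets — and supervised —
repeated (100×) re-sampling classification with an SVM on an SVM-RFE-selected
30-gene signature, scored by SEN, SPC, ACC and Matthews correlation (MCC).

## Worked example

```python
from modulenet import (make_model, sample_expression, penalty_scan,
                       partition_network)

# 30 genes, two planted hub modules (degree 8), 5 background edges
model = make_model(p=30, n_hubs=2, hub_degree=8, background_edges=5, seed=7)
mat, ann, labels = sample_expression(model, n_per_class=1000, seed=7)

scan = penalty_scan(mat, k=2)
print(scan.selected_rho, scan.network.n_edges)
best = partition_network(scan.network, k=2).best[0]
print([len(m) for m in best.modules], best.avg_overlap)
```

prints

```
0.1 26
[9, 9] 0.0
```

meaning: the scan kept ρ = 0.1 (the densest partitionable network, 26 edges —
the 21 true edges plus a few spurious ones), and the partition recovered two
disjoint 9-gene modules (average overlap E = 0) that coincide exactly with
the planted hub modules.

The same objects drive the evaluation harness:

```python
from modulenet import resample_evaluate
module = sorted(model.module_genes(0))
report = resample_evaluate(mat.subset_genes(module), risk_labels, reps=100, seed=7)
print(report.averages)   # mean SEN/SPC/ACC/MCC over the re-sampling runs
```

A command-line interface mirrors the library
(`modulenet simulate | degs | network | partition | evaluate | run`); `run`
executes the whole pipeline from a JSON config and writes a manifest plus all
artifacts (risk labels, DEG table, penalty-scan report, edge list, GraphML,
module GMT, merge log, E table, resampling reports).

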