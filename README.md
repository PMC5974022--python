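# fmnet

Integrated 16S-amplicon + NMR-metabolomics network analysis for case-control
microbiome studies, built around the workflow used to characterize gut
dysbiosis, bacterial translocation and hepatic encephalopathy (HE) in liver
cirrhosis.

`fmnet` is for microbiome/metabolomics researchers who have (a) an OTU or
taxon count table, (b) 1-D ¹H-NMR spectra or a bucket matrix, and (c) a
clinical table with group labels and a binary outcome, and who want the full
"functional metagenomics" treatment:

1. **Abundance preprocessing** — rarefaction to the least-rich sample,
   relative abundances, a mean-relative-abundance ≥ 0.5% feature filter,
   α-diversity (observed taxa, Shannon H = −Σ pᵢ ln pᵢ), β-dissimilarity
   (Yue & Clayton θ and Bray-Curtis), and PCoA ordination.
2. **NMR preprocessing** — rolling-ball baseline removal, spectral alignment,
   0.02-ppm bucketing with exclusion windows, total-integral normalization to
   1000, and probabilistic quotient normalization (PQN) for dilution.
3. **Functional metagenomic networks (FMNs)** — all-pairs Pearson correlation
   over the merged taxon + metabolite features; edges where |r| > 0.7
   (strict), signed *synergistic* (r > 0) or *competitive* (r < 0);
   functional metagenomic communities (FMCs) by Louvain modularity
   maximization (resolution 1, |r| weights, best of seeded restarts);
   keystone features ranked by unnormalized betweenness centrality; and the
   descriptor record (nodes, edges, syn/com ratio, density
   2E/(N(N−1)), modularity) used to compare cohorts.
4. **Clinical cross-correlation** — feature × clinical-parameter Pearson
   matrices with matrix-wide Benjamini–Hochberg FDR stars (q ≤ 0.05), plus
   Mann-Whitney U / Kruskal-Wallis group tests.
5. **Consensus HE risk ranking** — on mean-centred unit-variance features,
   four models of the binary outcome: per-feature logistic regression (β),
   stability-selection randomized lasso (selection frequency ∈ [0, 1]),
   elastic-net logistic regression, and an SGD logistic-loss classifier;
   odds ratios via the base-2 transform **OR = 2^β** and risk change
   (OR − 1)·100%.

A fully parameterized synthetic-cohort generator with planted ground truth
(correlation blocks, keystone bridges, NMR dilution factors, a logistic HE
label model) makes every stage testable end to end.

## Worked example

```python
from fmnet import synthetic_data as syn, evaluation as ev, fmn_network as net

spec = syn.SyntheticCohortSpec(seed=1, **ev.RECOVERY_COHORT)   # 35 + 14 samples
network, partition, planted, R = ev.run_cohort_network(spec)
summary = net.network_summary(network, partition, keystone_k=5)
print(summary.n_nodes, summary.n_edges, summary.density, summary.modularity)
print([(k["id"], round(k["betweenness"], 1)) for k in summary.keystone_features])
print(planted.keystone_ids)
```

prints

```
107 234 0.041 0.473
[('met_13', 240.0), ('met_01', 26.7), ('met_03', 26.7), ('met_05', 26.7), ('met_07', 26.7)]
['met_13']
```

The cohort plants two correlated feature blocks bridged by one keystone
metabolite (`met_13`). After the full pipeline — rarefaction, filtering, PQN,
correlation thresholding at |r| > 0.7, Louvain partitioning — the planted
keystone has by far the highest betweenness (240 vs 27 for block-interior
features): it is the node shortest paths between the two communities must
cross, which is exactly what the keystone ranking is designed to surface.
The many low-degree nodes are unstructured background taxa/buckets that stay
isolated, so the density (0.041) is low while modularity (0.47) is high.

The same pipeline runs from the shell:

```bash
fmnet simulate --seed 1 --out cohort/
fmnet run-all --config cohort/config.yaml
```

which writes diversity tables, distance matrices, PCoA coordinates, the
normalized bucket matrix, per-cohort GraphML networks with summary JSON,
the FDR-starred cross-correlation table, the HE risk report, and a manifest
recording every seed and a config hash (reruns are byte-identical).

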