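# tascore

Target addiction scoring for cell-based drug sensitivity screens.

Phenotype-based drug testing measures how strongly a panel of compounds
inhibits the growth of a cell sample — a cancer cell line or patient-derived
primary cells — but it does not by itself say *which protein the sample
depends on*. Because most inhibitors are polypharmacological (they hit
several kinases or other targets at once), the target signal can be
deconvoluted computationally: every compound "votes" for each of its known
targets with its observed response. `tascore` implements this deconvolution
and the statistical machinery around it, end to end, for anyone running
viability screens on cell panels or patient cohorts.

## The model

For sample *s* and target *t*, the **target addiction score** is the mean
observed drug response over the *n<sub>t</sub>* compounds known to hit *t*:

```
TAS(s, t) = (1 / n_t) * Σ_{c : t ∈ targets(c)} DR(s, c)
```

where DR is any per-compound response metric. The package provides three:

* **DSS** (drug sensitivity score): each dilution series is fitted with a
  log-logistic inhibition curve `y(x) = Rmax / (1 + 10^(s(m−x)))` with
  `x = log10(conc nM)`, top asymptote `Rmax` (%), slope `s` and
  `m = log10(IC50)`. The fitted curve is integrated (in closed form) above a
  minimal activity threshold `Amin` over the tested window and normalised so
  that a curve pinned at 100% inhibition scores 100.
* **AUC**: normalised trapezoidal area of the observed responses.
* **pIC50**: −log10 of the fitted IC50 in molar units.

The compound → target map is assembled from heterogeneous evidence with
field-standard retention rules: confidence-scored database edges
(experimental > 10 and combined > 500, or experimental < 10 and
combined ≥ 900, with a relaxed ≥ 300 rule for a configurable compound list),
a ≤ 35 nM potency cutoff for bioactivity-based edges, and exclusion of
metabolism gene families (CYP\*, ABC\*).

On top of the TAS matrix the package offers: cosangle (uncentered
correlation) distances and Ward clustering with feature-bootstrap cluster
support weighted by dendrogram height (0.1–1); congruence testing between
distance matrices (Kendall's W with permutation p, Mantel test); projection
of new samples onto a reference clustering with an empirical similarity
p-value; and cohort statistics (Wilcoxon rank-sum biomarker stratification,
Spearman co-addiction discovery with Bonferroni correction and
shared-inhibitor annotation). A synthetic-screen generator with planted
addiction structure makes the whole pipeline testable without external data.

## Worked example

```python
import tascore as tc

cfg = tc.SimulationConfig(n_samples=12, n_compounds=16, n_targets=12,
                          n_clusters=3, noise_sd=3.0, seed=11)
series, truth, network = tc.simulate_screen(cfg)
responses = tc.build_response_matrix(series, "DSS", tc.DSSConfig(amin=10.0))
tas = tc.compute_tas(responses, network)

print("network:", len(network.compounds), "compounds x", len(network.targets), "targets")
print(tc.rank_targets(tas, "S001").head(3).to_string(index=False))

tree = tc.ward_cluster(tc.cosangle_distance(tas.data))
labels = tc.cut_clusters(tree, 3)
from sklearn.metrics import adjusted_rand_score
print("ARI vs planted clusters:",
      adjusted_rand_score(truth.cluster_labels[labels.index], labels))

result = tc.compare_groups(tas.data[cfg.resolved_biomarker_target],
                           truth.biomarker_labels)
print(f"biomarker separation: p = {result.p_value:.3g} ({result.method})")
```

Output:

```
network: 16 compounds x 12 targets
target_id       tas  missing
     T009 30.993388    False
     T004 29.662852    False
     T005 28.947512    False
ARI vs planted clusters: 1.0
biomarker separation: p = 0.00216 (exact)
```

The ranked table lists the targets sample `S001` is most addicted to (mean
DSS over their inhibitors). The clustering cut at the planted k recovers the
three simulated sub-populations exactly (adjusted Rand index 1.0), and the
samples carrying the planted biomarker addiction separate from the negative
ones in the rank-sum test.

The same stages are available from the shell:

```sh
tascore simulate --seed 1 --out screen/
tascore fit --input screen/dose_response.tsv --metric dss --amin 10 --out resp.tsv
tascore tas --responses resp.tsv --network screen/network_edges.tsv --out tas.tsv
tascore cluster --input tas.tsv --distance cosangle --k 3 --nboot 1000 --seed 1 --out clust/
tascore run --out full_run/        # entire pipeline in one go
```

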