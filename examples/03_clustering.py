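"""Splicing-based clustering, label enrichment, and the cell-type
variance partition.

Samples are clustered on the most variable splice events (Ward linkage);
cluster-histology association is tested one-vs-rest with Fisher exact
odds ratios; and each event's PSI is regressed on marker-derived
cell-type scores to ask how much variance mere cellular composition
explains.
"""

from sklearn.metrics import adjusted_rand_score

from spliceburden import (SimConfig, celltype_scores, cluster_enrichment,
                          cluster_samples, psi_variance_explained,
                          simulate_cohort, top_variable_events)

cohort = simulate_cohort(SimConfig(n_samples=150, n_events={"SE": 5000},
                                   seed=3))
top = top_variable_events(cohort.psi, k=5000)
sub = cohort.psi.subset_events(top)
res = cluster_samples(sub, k=10)
ari = adjusted_rand_score(cohort.truth.clusters.loc[res.assignments.index],
                          res.assignments)
print(f"clusters: {res.k} (Ward/Euclidean); ARI vs planted truth = {ari:.2f}")

hist = cohort.manifest.set_index("sample_id")["histology"]
enr = cluster_enrichment(res.assignments, hist)
best = enr.sort_values("p").head(3)
print("top cluster-histology enrichments (odds ratio, BH-adjusted p):")
for r in best.itertuples():
    print(f"  cluster {r.cluster} ~ {r.label}: OR = {r.odds_ratio:.1f}, "
          f"adj p = {r.adj_p:.2g}")

scores = celltype_scores(cohort.tpm, cohort.marker_sets)
ve = psi_variance_explained(sub, scores)
frac = ve["bin"].value_counts(normalize=True)
print("PSI variance explained by cell-type composition:")
for b in ("<30%", "30-50%", ">50%"):
    print(f"  R^2 {b}: {frac.get(b, 0.0):.1%} of events")
# Most events falling in the <30% bin means the clusters reflect
# tumor-intrinsic splicing programs, not just cellular composition.
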