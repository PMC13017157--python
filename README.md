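# spliceburden

Cohort-scale analysis of alternative splicing in tumor RNA-seq, built
for settings — such as pediatric CNS tumors — where matched normal
tissue is unavailable and each tumor must be compared against the cohort
itself.

Starting from rMATS-style per-sample event tables (inclusion/skipping
junction counts for SE, A5SS, A3SS, RI and MXE events), the package:

1. assembles a PSI matrix with a junction-read coverage filter
   (PSI = (IJC/L_inc) / (IJC/L_inc + SJC/L_skip), cells with
   IJC + SJC < 10 masked);
2. calls **single-sample differential splicing** against cohort
   statistics: sample *i* is differential for event *j* when
   |z_ij| = |PSI_ij − μ_j|/σ_j > 2 and |ΔPSI_ij| > 0.2, and summarises
   recurrence (events called in ≥ 2 tumors) and histology specificity;
3. computes the **Splicing Burden Index** — SBI_i = (# differential
   calls in sample i) / (# evaluable events in sample i) — with
   quartile groups (high ≥ Q3, low ≤ Q1) and its associations: TMB
   correlation with hypermutant exclusion, and splicing-factor
   differential expression between burden groups (rank-sum on
   log2(TPM+1), Benjamini–Hochberg);
4. clusters samples hierarchically (Ward/Euclidean, k = 10) on the top
   5000 most variable events, tests cluster–histology enrichment
   (Fisher exact odds ratios with Haldane correction) and partitions
   per-event PSI variance into marker-derived cell-type scores (OLS R²,
   binned at 30%/50%);
5. **prioritizes** recurrent events by projecting each variable region
   through transcript models onto protein coordinates
   (aa = ⌊CDS offset/3⌋ + 1, strand-aware) and applying an ordered
   filter cascade: protein-feature impact → kinase → splicing kinase →
   median TPM > 10 → called in > 10 tumors → retained-intron exclusion;
6. fits **outcome models**: Cox proportional hazards with cluster,
   resection, age, SBI and SBI×cluster interactions (Efron ties,
   declared reference levels), Kaplan–Meier stratification with
   log-rank tests, and an ordered age-group trend test for oncofetal
   splicing patterns.

Because real patient cohorts of this kind are access-restricted, the
package ships a first-class synthetic-cohort generator
(`spliceburden.simulate`) that emits the complete input surface — rMATS
tables, clinical manifest, TPM matrix, toy GTF with protein features,
gene lists — with planted ground truth (outlier cells, cluster labels,
cell-type fractions, a candidate splicing-kinase exon, survival
coefficients), so every stage is testable end to end.

## Worked example

```python
from spliceburden import (SimConfig, simulate_cohort, cohort_event_stats,
                          call_differential, recurrence, compute_sbi,
                          assign_sbi_groups)

cohort = simulate_cohort(SimConfig(n_samples=120, n_events={"SE": 5000},
                                   frac_cluster_informative=0.0, seed=2))
stats = cohort_event_stats(cohort.psi)
calls = call_differential(cohort.psi, stats)      # z > |2|, dPSI > 0.2
rec = recurrence(calls, min_recurrence=2)
sbi = assign_sbi_groups(compute_sbi(calls, cohort.psi, stats))
print(len(calls), len(rec), f"{sbi['sbi'].median():.4f}")
```

prints (seed 2):

```
16118 4161 0.0285
```

— 16,118 (sample, event) differential calls, 4,161 recurrent events,
and a median SBI of 0.0285: the median tumor has 2.85% of its evaluable
splice events in a differential state, the package's headline
per-sample burden readout. The scripts under `examples/` walk one
capability each (simulation, differential + burden, clustering,
prioritization, survival, full pipeline) and print what every number
means; `examples/04_prioritize.py` ends with the cascade's survivor
audit and the single planted splicing-kinase candidate.

A thin CLI mirrors the library:

```bash
splice-burden simulate --out cohort/ --seed 7
splice-burden run --config cfg.yaml
splice-burden call-differential --psi psi.tsv --coverage cov.tsv --out calls.tsv
```

## Layout

- `src/spliceburden/` — library (`rmats_io`, `differential`, `burden`,
  `clustering`, `annotation` + `prioritize`, `outcomes`, `simulate`,
  `pipeline`, `benchmarks`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — unit, property and cohort-scale recovery tests
- `docs/methods.md` — models, defaults, numerical choices, limitations
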