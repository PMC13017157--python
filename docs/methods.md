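# Methods

`spliceburden` implements a cohort-referenced analysis of alternative
splicing in tumor RNA-seq: per-sample differential splice calling
without matched normals, a sample-level burden statistic, splicing-based
cohort structure, protein-level functional prioritization of recurrent
events, and outcome models. This note records the models, the defaults
and why they are what they are, the numerical choices, and what the
synthetic cohort does and does not emulate.

## PSI and the cohort matrix

Splice events follow the rMATS dialect: five event classes (SE, A5SS,
A3SS, RI, MXE), genomic intervals half-open with 0-based starts, and
per-sample inclusion/skipping junction counts (IJC/SJC) with effective
form lengths. PSI is length-normalised,

    PSI = (IJC / L_inc) / (IJC / L_inc + SJC / L_skip),

so that the longer read support of the inclusion form does not bias the
estimate. A cell (event x sample) counts as *covered* when
IJC + SJC >= `min_reads` (default 10, applied to the sum; a per-junction
minimum is a stricter reading of the same filter and the parameter is
exposed). Uncovered cells are missing, never zero. Event identity is a
deterministic string key over (type, chromosome, strand, full coordinate
tuple), so identically described events in different files collide by
construction. Matrix serialisation uses fixed 6-decimal formatting so
write -> read -> write is byte-stable.

MXE events are parsed and carried through the matrix (PSI refers to the
first variable exon, as in rMATS) but excluded from protein mapping: with
two variable exons a single gain/loss projection is ill-defined.

## Differential calling and the Splicing Burden Index

For event *j* the cohort statistics are the mean and sample standard
deviation (n-1 denominator) of PSI over covered samples; events with
fewer than `min_cohort_n` (default 10) covered samples or zero variance
are non-evaluable rather than producing infinite z-scores. Sample *i* is
called differential for event *j* when, strictly,

    |PSI_ij - mu_j| / sigma_j > 2   and   |PSI_ij - mu_j| > 0.2.

Both thresholds are applied to magnitudes, so inclusion (dPSI > 0) and
skipping (dPSI < 0) calls are symmetric. The default statistics include
the queried sample ("sample compared to cohort"); a leave-one-out mode
derives per-sample mu/sigma from sufficient statistics to remove
self-inflation. The two modes agree on the decision-relevant range as the
cohort grows — the self-removal perturbation of z scales as z^3/(2n), so
far-tail cells (|z| of 5-6) differ by ~0.2-0.3 at n = 500 while cells
near the threshold differ by < 0.03; the call sets coincide.

A consequence worth knowing: cohort-referenced calling saturates when one
event is aberrant in a large fraction of samples, because those samples
inflate sigma_j. With a 0.4 PSI shift planted in 14 samples, the event is
reliably callable at |z| > 2 in a 200-sample cohort (7% contamination)
but not in a 60-sample one (23%). Analyses that need recurrence above a
fixed tumor count therefore presuppose cohorts of roughly 130+ samples
at these thresholds.

The Splicing Burden Index of a sample is the number of its differential
calls divided by the number of events that are both covered in that
sample and cohort-evaluable. The per-sample denominator (rather than the
global event count) keeps samples with unequal coverage comparable; a
global-denominator mode exists. High/low SBI groups take the cohort
quartiles with boundary ties included: Q3 is the observation at the
ceiling of the 0.75 linear rank and Q1 at the floor of the 0.25 rank, so
a cohort of 4k samples puts exactly k in each extreme group. An
all-constant SBI vector degenerates (Q1 = Q3) and resolves to all-mid
with a warning.

Correlations (e.g. tumor mutation burden vs SBI, splicing-factor
expression vs SBI by cluster) are Pearson or Spearman with BH adjustment
across the rows of one invocation; an exclusion filter drops samples
first (hypermutant cutoff default TMB > 10 mutations/Mb, configurable —
the cutoff is a convention, not an estimate). The high-vs-low SBI
expression comparison is a two-sided Wilcoxon rank-sum per gene on
log2(TPM+1), effect = difference of group means on that scale, BH over
the supplied gene list; a count model was deliberately not used because
the comparison operates on normalised abundances, not raw counts.

## Clustering and the cell-type variance partition

Events covered in >= 75% of samples are ranked by PSI variance and the
top 5000 retained (deterministic tie-break by event key). Remaining
missing cells are imputed with the event median — minor by construction
after the coverage filter — and samples are clustered agglomeratively
with Ward linkage on Euclidean distance, the tree cut at k = 10.
Distance (1 - Pearson) and average linkage are available by flag; a
silhouette k-scan is provided for diagnostics but never auto-applied,
keeping k an explicit analysis choice. Cluster labels are canonicalised
(1..k by first appearance over the sorted sample list) so the partition
is independent of input order.

Cluster-label enrichment is one-vs-rest per (cluster, label): a 2x2
table, two-sided Fisher exact p, BH across all rows, and an odds ratio
with the Haldane-Anscombe 0.5 correction whenever a cell is zero (the
uncorrected OR and an infinity flag are kept alongside).

Cell-type scores are marker-based: per type, the mean across its marker
genes of z-scored log2(TPM+1). This replaces a matrix-decomposition
estimator deliberately: only the *relative* ordering of scores enters the
downstream regression, and mean-of-z is transparent and dependency-free.
Each event's PSI is then regressed (OLS with intercept) on all cell-type
scores over its covered samples; R^2 = 1 - RSS/TSS is binned at
R^2 < 0.30, 0.30 <= R^2 <= 0.50, > 0.50. Events with fewer than
(n_types + 2) covered samples or constant PSI (TSS below 1e-10) are
skipped. Under independence E[R^2] = p/(n-1), which the tests verify.

## Genomic-to-protein projection and the prioritization cascade

No standard defines how a splice event maps to protein coordinates; the
projection here is the package's own contract. A transcript model is an
ordered set of non-overlapping exons plus a CDS span whose spliced length
is a multiple of 3. The query interval is intersected with the CDS
segments, the intersection is read off in spliced-CDS coordinates
(strand-aware; minus-strand transcripts read right-to-left), and 0-based
coding offsets are floored to codons: aa = floor(offset/3) + 1, 1-based
inclusive. Partial codons count as touched. An empty CDS intersection
returns no projection. Retained introns are the one special case: the
intron itself has no CDS overlap, so the projected region is widened by
one base on each side, mapping to the codons flanking the interrupted
junction.

Feature impact: a feature is hit when its amino-acid interval intersects
the projection — except disulfide bonds, which are hit only when a bonded
cysteine itself falls inside the projection (a bond's span crossing the
region without either endpoint does not lose the bond). The predicted
label follows the event's cohort direction class: inclusion -> gain,
skipping -> loss, mixed -> mixed. When a gene has several models, impacts
are computed per model and unioned; no canonical-transcript election is
attempted.

The cascade applies, in order: (1) recurrent differential events in;
(2) >= 1 feature impact; (3) gene in the kinase list; (4) gene in the
splicing-kinase list (default: CLK1-4, FASTK, MARK2, PKN2, PRKDC, SMG1,
SRPK1, SRPK3); (5) cohort median TPM > 10 (median chosen as the cohort
statistic; a per-calling-sample mode exists); (6) called in > 10 tumors
(counted per event, not per gene); (7) drop RI events and RI-like
A5SS/A3SS events, operationalised as a variable region containing an
entire annotated intron of any model of the gene. Survivor counts are
recorded after every stage and are monotone non-increasing; the drop log
names the stage that removed each event.

## Outcome models

Proportional-hazards fits use partial likelihood with Efron tie handling
(Breslow by flag), via lifelines. Categorical covariates are
dummy-expanded against declared reference levels — cluster 1 and
gross/near-total resection by default, both configurable — and
interactions are products with the non-reference dummies (SBI x cluster
being the motivating case). Histology groups under a minimum size can be
collapsed into one level before fitting. Continuous PSI covariates enter
per unit (0 to 1); per-0.1 scaling is a trivial rescale of the reported
log-HR. Non-convergence is flagged on the fit object (with a ridge
fallback for near-collinear designs), never silently dropped; complete
separation raises naming the term. Kaplan-Meier stratification splits a
continuous score at its median (or a given value) and reports the
two-sided log-rank p. The age-trend test for oncofetal behaviour runs
two-sided rank-sum tests on adjacent ordered age groups (BH-adjusted)
plus a Spearman correlation of value against group rank as the single
trend statistic.

## The synthetic cohort

The generator emits the full input surface — per-sample rMATS-style
tables, manifest, TPM matrix, toy GTF + protein features, marker and
kinase lists — from one seeded configuration, with the planted truth
serialised separately so fixtures can never leak it. Per event and
sample: a base inclusion mean m0 ~ U(0.10, 0.90); a configurable fraction
of events carries per-cluster means m0 +/- cluster_dpsi/2 (cluster
signature); outlier cells are planted by shifting the target by
+/- effect_size (default 0.4, clipped to [0.01, 0.99]; infeasible
configurations error before writing). Planting avoids cluster-informative
events so the two kinds of structure never confound, and each sample
draws its own planting rate uniform on (0, 2 x planted_fraction), giving
a true burden ranking for SBI recovery. Realised PSI is
Beta(mc, (1-m)c) with concentration c (default 200, PSI noise sd ~0.035
at m = 0.5). Junction counts invert the length normalisation: total reads
n ~ LogNormal (mean 100), IJC ~ Binomial(n, p) with
p = psi L_i / (psi L_i + (1-psi) L_s), so the length-normalised PSI
estimator recovers the target in expectation — the one subtle part of
emulating rMATS counts, verified by Monte-Carlo calibration tests.

The toy annotation plants one candidate gene (a splicing kinase whose
cassette exon lies inside its kinase-domain feature, median TPM > 10,
skipping planted in 14 tumors) and seven decoys, each constructed to fall
at exactly one cascade stage: no feature overlap, non-kinase, kinase but
not splicing kinase, low expression, low recurrence, a retained intron,
and an RI-like A5SS. Expression couples designated SF genes linearly (in
log2) to the planted burden, marker genes to Dirichlet cell-type
fractions, and survival times are exponential with log-hazard linear in
cluster membership and in the candidate exon's PSI, with independent
exponential censoring (~30%).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: realistic gene models or isoform
complexity, correlated event structure beyond the block cluster
signature, batch and library-preparation effects, coverage that varies
with expression, overdispersed junction counts, non-proportional
hazards, or informative censoring. Recovery results are statements about
the pipeline's correctness under its own model, not about biological
effect sizes.

## Problem sizes and determinism

Default study conditions: 200 samples x ~21,000 events (20,000 SE plus
small numbers of the other classes). Recovery benchmarks run at these
sizes: differential calling over five seed-swept cohorts (sensitivity
>= 0.95, false-call rate <= 0.01 at default thresholds), SBI rank
recovery (Spearman >= 0.9), clustering of the planted 10-cluster
structure at 0.3 separation / ~0.05 within-cluster sd over ten seeds
(ARI >= 0.9), Cox CI coverage over 50 simulations at n = 1000, and a
byte-reproducibility run of the whole pipeline. Everything is driven by
`numpy.random.default_rng` seeds; reruns with the same seed and inputs
are byte-identical, and the pipeline report carries a hash of every
semantically relevant configuration field.
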