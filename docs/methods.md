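# Methods

This note documents the models, defaults and design choices behind
methmark, and what the synthetic study conditions do and do not establish.

## Data model

β values are methylated-signal fractions M/(U + M + offset) with the
standard offset of 100, hence bounded in [0, 1). Matrices are probes ×
samples with NaN as a first-class missing value distinct from 0; every
statistic states its missing policy. Coordinates are 1-based. Multi-gene
probes follow the primary-gene convention: all gene-level maps use the
first listed gene, while per-gene promoter queries scan the full
annotation. "Promoter" is operationalized as region class TSS1500 ∪ TSS200
(within 1500 bp upstream of the TSS), matching 450K manifest semantics.
Inputs are assumed pre-normalized (TCGA-level-3-style); IDAT parsing,
probe-type normalization and batch correction are out of scope.

## Statistical primitives

Standard tests delegate to the reference implementations (scipy paired
*t*, Fisher exact, Pearson; lifelines Kaplan–Meier and log-rank;
scikit-learn ROC AUC with ties counted ½). Two pieces are authored here
because their exact conventions matter downstream and are asserted by
oracle tests:

* **BH step-up FDR** — q(i) = min over j ≥ i of m·p(j)/j, capped at 1,
  returned in input order. The FDR family is always stated per analysis
  (all filtered probes for methylation; all non-zero genes for expression;
  all cis tests together; all trans tests together; the candidate set for
  cascade stage 1). Degenerate records (zero-variance differences,
  constant vectors) are flagged and excluded from the family, never
  silently NaN.
* **Information gain with MDL discretization** — Fayyad–Irani recursive
  entropy partitioning with the MDL stopping rule (the classic
  preprocessing of attribute-ranking tools for continuous features), base-2
  entropies; a fixed-width binning mode is available. An uninformative
  feature accepts no cut and scores exactly 0.

The two-sided Fisher p sums hypergeometric probabilities of tables no more
probable than the observed one (the R convention). Pearson p-values use the
*t* transformation; correlation is pairwise-complete over observed values.

## CIMP subtyping

Informative probes: promoter CpGs with tumor SD > 0.2 and normal mean
β < 0.05 (both thresholds configurable; raising the SD floor can only
shrink the set). Consensus clustering follows the Monti resampling scheme:
250 resamples of 80% of samples, k-means (k-means++, 10 restarts) per
resample, consensus(i,j) = co-clustered / co-sampled, final assignment by
average-linkage hierarchical clustering of 1 − consensus cut at k. All
k-means seeds derive from the master seed through a counter, so the whole
procedure is one-seed deterministic; pairs never co-sampled get consensus 0
with a warning to raise the resample count.

Choosing k is genuinely open. The consensus-CDF areas and their increments
are always reported, but the raw "largest area increment" rule degenerates
(the increment from the first k dominates), so the default selector
minimizes the proportion of ambiguous clustering (PAC: the mass of
consensus entries strictly between 0.1 and 0.9), resolving near-ties
(within 0.01) toward the **largest** crisp k — merging two true clusters
can also be perfectly stable, so ties at low PAC must favor the finer
partition. k can be pinned in configuration, and a delta-area mode is
provided for comparison.

The CIMP call goes to the cluster with the highest mean β over the
selected probes, provided it exceeds the grand mean by a margin (default
0.15; 0 degenerates to plain argmax). The margin is reported with the call
so the decision is auditable. Cluster–covariate association uses 2×2
Fisher tests (in-cluster vs out × level vs not) per covariate level;
survival contrasts (all patients or a single stage) use Kaplan–Meier plus
the log-rank test.

## Differential analysis

Probes with **more than** 10% missing values (strict) are removed; the
rest are imputed probe-wise by k-nearest neighbors (k = 10): a missing
cell becomes the mean, at that sample, of the k nearest probes by
Euclidean distance. Neighbor candidates are fully observed probes, and for
large matrices the candidate pool is subsampled (seeded, default 2000) so
the distance computation stays linear in probe count — the same
large-matrix strategy as the classic microarray KNN imputers. Observed
cells are never altered; imputed values are clipped to [0, 1]. Imputation
runs on the combined paired tumor+normal matrix before testing.

Differential methylation: per-probe paired *t* on patient-matched β, BH
across all tested probes, calls requiring FDR < 0.05 **and** |Δβ| > 0.2
(both strict). Differential expression runs on log2(CPM + 0.5) with
median-of-ratios library scaling, per-gene paired *t*, and the FDR < 0.05,
|log2FC| > 1 gates; the call labels are DE-high / DE-low. This transparent
normal-theory route was chosen over a negative-binomial framework so every
step is directly checkable by hand and by simulation; with 15–50 pairs and
moderate dispersion its power and error control are verified against the
generator's planted truth. Gene methylation status (DM-high / DM-low /
both) requires at least one called promoter probe of the primary gene.
Context summaries report hyper/hypo counts and fractions by stratum
(promoter, CGI, promoter∩CGI, whole genome), CGI relation, and signed
distance-to-TSS bins.

## cis / trans regulation

Expression enters as log2 normalized CPM so r is scale-stable. Cis: one
record per promoter probe against its primary gene over patient-matched
tumor samples (≥ 3 required); trans: the full probe × DE-gene grid with
self pairs excluded by default (they are the cis question; a flag restores
them). "Correlation coefficient greater than 0.3" is read as |r| > 0.3
with the sign recorded separately, since both negative and positive
classes are reported. Gene classes aggregate probe records (negative /
positive / both / none) and fractions are computable over arbitrary gene
subsets (all, DE, DM, DM∩DE).

## The specificity cascade

Stage 0 takes hyper-called promoter probes whose primary gene is DE-low.
Stage 1 requires the hypermethylation to replicate in the full unpaired
cohorts; the test is a Wilcoxon rank-sum with BH within the candidate set
plus the Δmean > 0.2 hyper-direction gate (rank-sum because β is bounded
and skewed; a Welch-t mode exists, and the choice is stamped into the
audit). Stage 2 removes probes at least as methylated in blood as in
tumors and additionally caps the blood mean at 0.1 by default, so
survivors are genuinely unmethylated in healthy people; the cap can be
disabled for the comparison-only rule. Stage 3 removes any probe whose
mean β exceeds 0.1 in the tumor **or** normal samples of **any** other
cancer type. Stage means use observed values only; a probe with no
observed value in a required cohort (including one removed by the
missingness filter there) fails that stage — conservative by design.
Ranking is by information gain of tumor-vs-normal labels with a
deterministic probe-id tie-break; the default panel size is 6 and the full
ranking is always kept in the audit. Every stage emits its rule, counts
and per-probe measurements, so the cascade narrative is reconstructible
and each stage is a pure function of its declared inputs.

## Diagnostic model

Logistic regression by IRLS on a ridge-penalized likelihood (default
penalty 1e-8 on coefficients, none on the intercept) — small enough not to
shrink estimates, large enough to keep separable panels well-posed.
Convergence requires the largest coefficient step < 1e-8; non-convergence
raises with the iteration trace. β values enter untransformed. The
decision threshold is fixed at 0.5 (single sensitivity/specificity pairs
imply a fixed threshold); the full score vector and AUC are always
reported so other thresholds are recoverable. The training protocol
mirrors the study design: fit on the paired cohort, evaluate on
independent cohorts, and profile cross-cancer specificity as the fraction
of each other-cancer cohort classified positive. The fit is cross-checked
in tests against an independent regularized-logistic implementation.

## Synthetic study conditions

The generator draws β from Beta(mean·c, (1−mean)·c) per genomic-context
stratum — promoter-CGI probes centered at 0.03, body and open-sea probes
at 0.70, concentration 30 (SD ≈ 0.03 at the low mode). The unmethylated
promoter mode is placed at 0.03 so that the normal-mean < 0.05 selection
rule has the discriminating power it has on real normal tissue, where
unmethylated promoters sit near β ≈ 0.02–0.05. Default cohort sizes mirror
the reference study's ratios at roughly quarter scale (100 tumors, 30
paired normals, 50 blood donors, 10 other cancers × 40 tumor + 20 normal)
so the full pipeline runs in seconds; planted classes are 500 hyper and
1500 hypo probes at Δβ = 0.4, 6 specific markers, 20 pan-cancer decoys
(elevated to β ≈ 0.5 in 3–6 other cancer types, sometimes their normals),
20 blood-high decoys (β ≈ 0.5 in blood), and 20 paired-only artifacts
(shifted only in the paired patients' tumors — the stage-1 failure mode).
Markers and decoys all sit in promoters of planted DE-low genes, so the
cascade, not the plant, must tell them apart.

The CIMP structure has two layers: 300 variably methylated promoter probes
that are hypermethylated (+0.5) in a random 40% of each tumor's probes —
these carry the SD > 0.2 signal that real subtype-defining CpGs carry —
and a patient layer in which 5% of patients shift **all** promoter-CGI
probes by +0.4. cis-regulated genes get an intermediate-methylation driver
probe (mean 0.3, extra tumor variance) in both tumor and normal so they are
neither DM nor DE by construction; expression counts are gamma-Poisson
(dispersion 0.1) around log2 means of ≈ 9 ± 1, with −4 log2 units per unit
β for negative cis genes and ±2 log2FC for DE genes. Survival is
exponential (baseline hazard 1/1000 per day) with the CIMP hazard
multiplied by 3, uniform censoring calibrated to a 20% rate, and
cluster-enriched covariates. Missingness is MCAR at 1%.

A separate `structure_seed` decouples *which* probes/genes/patients carry
planted effects from the noise draws, so an independent validation cohort
(same biology, new samples) can be generated — the synthetic analog of an
independent dataset.

What the generator does **not** emulate: co-methylation blocks and other
probe–probe correlation, tumor purity and copy-number confounding, batch
effects, probe-type (I/II) chemistry, and non-MCAR missingness. Passing
recovery tests therefore show the pipeline's logic is correct under its
stated assumptions, not that real-data effect sizes or error rates will
match; on real cohorts the cascade's counts and the model's accuracy are
data properties, not package guarantees.

## Problem sizes and tolerances in the test suite

The recovery and calibration checks run at the default conditions above:
20 replicates for end-to-end marker recovery (≥ 95% must recover the panel
exactly), 20 no-effect replicates for FDR control (mean false-discovery
proportion within 2 Monte-Carlo SE of the 0.05 level), 50-pair bundles for
power (≥ 0.99 at Δβ = 0.4), 100/200 replicates for log-rank power and null
uniformity, and exhaustive 2×2 enumeration up to table total 40 for the
Fisher oracle. Unit tests run on a ~2000-probe scaled configuration.
Imputed consensus matrices, panels and reports are asserted bit-identical
under a fixed seed.

## Known limitations

* The DE route is normal-theory on log CPM; for very low counts or few
  pairs a count-model framework would be more powerful.
* Trans-regulation reports the correlation grid and per-probe sign
  summaries only; no planted trans structure ships in the default
  conditions (the hub-recovery behavior is exercised with constructed
  data in the tests).
* PAC-based k selection assumes at least one candidate k yields a crisp
  consensus; on structureless data it will still return some k — inspect
  the reported PAC values before trusting a subtype call.
* Cross-cancer specificity fills missing panel-probe values with cohort
  means at prediction time; cohorts missing a panel probe entirely are an
  error rather than an imputation target.
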