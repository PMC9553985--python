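# Methods

This note documents the models, statistics, numerical choices, and the
synthetic-data design behind `tcrscope`, and what the package's benchmarks do
and do not establish about real repertoire data.

## 1. Scope and data model

The package analyses three kinds of input: (i) bulk TCRβ clonotype tables
(CDR3β amino-acid sequence, V/J gene call, read count) in simple, AIRR-C
rearrangement, or ImmunoSEQ-style dialects; (ii) epitope-labeled CDR3β
training sets (VDJdb-style TSV); (iii) a single-cell layer given as a
genes×cells count matrix plus a cell table linking cells to clusters and
clonotypes. Frequencies in input files are always discarded and recomputed
from read counts, so dialect-specific rounding cannot propagate.

Clonotype identity is configurable: `(cdr3aa, v_gene)` is the default key for
sharing, pooling and pre/post matching, and the CDR3β amino-acid sequence
alone is the key for classifier scoring (specificity is a property of the
receptor sequence, not of the V-gene annotation). Whether a nucleotide- or
amino-acid-level key is the "right" join for a given assay is data-dependent;
both keys are first-class.

QC follows the standard functionality rule: a clonotype is kept when its CDR3
is ≥5 residues over the 20-letter alphabet with no stop (`*`) or frameshift
(`_`, `#`) marks; ImmunoSEQ frame/productive columns are honored when
present. The filter is idempotent and re-normalizes frequencies.

## 2. Diversity and sharing

Shannon H = −Σ pᵢ ln pᵢ (nats), Simpson dominance Σ pᵢ² (the diversity form
1 − Σp² is exposed as a derived field), and clonality 1 − H/ln(richness) —
the normalized-Shannon definition, 0 for a perfectly even repertoire and → 1
under single-clone dominance. Richness < 2 leaves clonality undefined rather
than silently 0. Public sharing is exact key intersection with a
Jaccard-style fraction; the pairwise matrix carries own-richness on the
diagonal. Subsampling to fixed depth is multivariate-hypergeometric (reads
without replacement), the unbiased way to compare diversity across depths.

## 3. Motif convergence

GLIPH-style motif discovery is deliberately replaced by a transparent
statistic: all contiguous k-mers (default k=3) of the CDR3 interior after
trimming 3 residues from each end (near-germline termini carry little
epitope-specific information). For each k-mer present in the target, a
one-sided Fisher exact test on TCR presence/absence (a TCR contributes at
most once per motif, keeping the 2×2 margins honest) against a reference
repertoire, BH-corrected; retained motifs need adjusted p < 0.05 and fold ≥ 2
(fold uses a 0.5 pseudocount). Ranks follow the number of carrying target
TCRs, ties broken lexicographically so output is deterministic. Convergence
between two repertoires is the Spearman correlation of shared-motif ranks;
rho is the reported statistic and rho² is carried in the method string, since
"rank correlation" figures in the field are sometimes annotated with a
squared coefficient.

## 4. The specificity classifier

**Encoding.** Residues map to d-dimensional vectors (default d = 8) from the
eigendecomposition of BLOSUM62 restricted to the 20 standard residues, each
component scaled by √|λ| with a fixed sign convention, so Euclidean distance
between residue vectors approximates substitution dissimilarity. A CDR3 is
split at its midpoint into left/right halves aligned into `max_len` = 22
slots with zero-coded center gaps. No terminal trimming is applied for the
classifier (trim = 0): the motif module owns trimming.

**Model.** Laplace-approximate Gaussian-process classification with an RBF
kernel over the encoded vectors (scikit-learn's implementation). The kernel
length-scale defaults to the median pairwise Euclidean distance of (up to
500) training encodings — a deterministic, data-adaptive heuristic.
Marginal-likelihood optimization of the hyperparameters is available
(`optimize_hyperparams=True`) but off by default: with a single shared
length-scale the fit is insensitive to it, and the fixed heuristic keeps
20-fold cross-validation fast and bitwise reproducible. If the GP fit fails
numerically, a ridge-regularized kernel-logistic model over the same RBF
kernel is used with an identical external contract; the fitted attribute
`method_` records which route ran. Kernel matrices exposed for inspection
carry a 1e-6 diagonal jitter.

**Training sets.** Positives pooled across subjects; the background is an
equal-size draw (seeded, without replacement) from a background pool disjoint
from the positives. Background pools for training and for threshold
calibration are disjoint draws, so calibration is not optimistically biased
by sequences the model has seen.

**Cross-validation.** `scheme="auto"` uses leave-one-out below 100 positives
and 20-fold stratified CV otherwise; leave-one-subject-out holds out one
subject's positives per fold (backgrounds are assigned pseudo-subjects
round-robin in seeded order so folds stay roughly balanced). Out-of-fold
scores are pooled into one ROC/PR report; AUROC is the trapezoid of the ROC
curve and is tested against exhaustive concordant-pair counting (ties ½),
average precision is the PR summary. Evaluation is at 1:1 class balance by
construction of the training set.

**Calibration and panels.** The threshold is the smallest t with
fraction(background > t) ≤ target FPR (default 5%); positive calls use strict
inequality, the conservative choice at score ties. Degenerate constant score
distributions trigger a warning and t = max score. Panel groups use the union
rule; clones positive in more than one group are labeled `both` and counted
in each group's frequency (the union rule is silent on overlaps; counting in
each group is the documented choice). The panel-level FPR on known negatives
is the fraction flagged by any group member — for five well-separated motifs
it lands near the independence closed form 1 − 0.95⁵ ≈ 0.226.

## 5. Cohort analyses

The biomarker for a sample is the summed read frequency of clones carrying a
group label (`target_frequency`); the unique-clonotype fraction is also
computed (`target_clone_fraction`) since "abundance" admits both readings,
with summed frequency the default. Cohort separation is a single-feature
logistic regression (ridge 1e-6 only — one covariate leaves nothing to tune)
in stratified 10-fold CV; the out-of-fold scores are pooled into one AUROC
computed by exhaustive pair counting. Note a subtlety: per-fold AUROCs are
exactly invariant under monotone transforms of the biomarker, the pooled
AUROC only approximately so, because fold-specific calibration maps differ.

Age matching is greedy nearest-age without replacement, `ratio` controls per
case within a caliper, ties broken by a seeded shuffle; it fails loudly,
naming the first unmatched case. The dominant-clone flag is per-clone — any
single labeled clone above 1% of reads — not a group sum, matching the notion
of a *dominating clonotype*. Survival uses the Kaplan–Meier product-limit
estimator and the two-sided log-rank test (lifelines); multivariable
proportional-hazards modeling is out of scope.

## 6. Clonal dynamics

Expansion between a pre/post sample pair: per clone, a two-sided Fisher exact
test on [(count_pre, rest_pre), (count_post, rest_post)] using raw read
depths; clones absent from one sample enter with count 0. BH correction runs
within the sample pair (the per-patient counting unit), and "expanded"
additionally requires post-frequency > pre-frequency — significant
contractions are never expansions. Clones with fewer than `min_total` = 2
reads across both timepoints are excluded by default: a singleton can never
reach significance and only inflates the BH family (set `min_total=0` for
strict literalism). Replacement: the replacing set is post-sample clones
absent from pre; its summed post frequency equals 1 − persisting frequency
*exactly* (the complement is computed, not re-summed), with clonality of the
replacing set and an optional per-specificity breakdown.

## 7. Single-cell layer

Counts are log-normalized per cell to a 10,000 scale, v = ln(1 + 10⁴·c/total);
normalizing an already log-normalized layer is a state error. Clustering is
an *input* (a cluster column), never computed here — this keeps the module
usable with the generator's ground-truth clusters or any external clustering.
Cells without a recovered TCR are excluded from specificity tests.

Cluster enrichment of a specificity label: one-sided Fisher per cluster, BH
across clusters. Differential expression: per-gene Welch t-test (unequal
variances — the safer default when only "t-test" is specified) on lognorm
values, Bonferroni across genes, log2 fold change of group means with a 1e-9
pseudocount; zero-variance genes report p = 1. The paired pre/post exhaustion
comparison computes, per patient, the fraction of group-labeled cells in the
exhausted cluster at each timepoint and applies the two-sided Wilcoxon
signed-rank test — the paired analogue of the rank-sum test (a "paired
Mann–Whitney" has no standard definition; the signed-rank reading is used
without asserting equivalence to any other convention). Exact null up to 20
informative pairs, zero differences dropped.

Ligand–receptor interactions: for ordered clusters (A, B), both with ≥ 50
cells (the larger subsampled to the smaller, seeded — cell-number
normalization across phenotypes), the score of a (ligand, receptor) pair is
½(mean ligand expression in A + mean receptor expression in B); the null
re-assigns the pooled cells to A/B `n_perm` = 1000 times and
p = (1 + #{null ≥ observed})/(n_perm + 1), never zero. Pairs with either mean
exactly 0 are reported non-expressed without a p-value. Only simple
gene–gene pairs are supported; a 20-pair default list with
inhibitory/stimulatory classes (including LGALS9–HAVCR2, PVR–TIGIT, PVR–CD96)
ships as package data. Comparing two result tables yields per-partner
log2((n_sig_a + 1)/(n_sig_b + 1)).

## 8. Synthetic data: what it emulates, what it does not

Every generator is a pure function of its config including the seed
(run-twice byte equality), and every generated CDR3 passes QC (C + interior +
F, 20-letter alphabet, length 8–20).

Defaults, chosen once as the package's study conditions: clone weights
lognormal(μ=0, σ=2) — heavy-tailed enough to produce the rare dominant clones
visible in real repertoires without fitting any dataset; depth 10⁴ reads over
500 clones; uniform amino-acid composition (no claim of biological realism —
a composition vector is a config field); motif planting at the CDR3 center by
default, since antigen-contact residues concentrate at the loop apex, with a
uniform-interior policy available. Epitope-specific sets plant one k-mer with
a configurable probability and assign subjects round-robin so
leave-one-subject-out is exercisable.

Cohort samples draw background sequences that *exclude* the planted motif, so
the injected clones carry exactly the labeled mass; per-sample targets are
jittered ±8% (inside the ±10% construction tolerance), which gives null
cohorts genuine between-sample variation instead of a degenerate constant.
Longitudinal pairs multiply `n_expanded` chosen clone weights by `fold`,
renormalize, optionally add novel clones carrying `replacing_fraction` of
post mass, and resample both timepoints multinomially; expansions are planted
only in clones with baseline frequency ≥ 5/depth — smaller clones are
statistically undetectable at the study depth, so planting them would measure
the generator, not the test. The expansion-recovery benchmark runs with
`replacing_fraction=0`: novel clones are genuinely up-significant and belong
to the replacement truth, not the expansion truth. Single-cell counts are
gamma-Poisson (negative binomial) with dispersion 0.5 and cluster-specific
means; enrichment plants labels at odds `o` against a 5% baseline, DE entries
multiply a gene's cluster mean by exp(shift), ligand–receptor entries set the
two genes' means in the two clusters.

What passing benchmarks on these data shows: the statistics recover planted
effects at realistic depths and control their nominal error rates under the
generators' nulls. What it does not show: performance under V(D)J
recombination biases, sequencing error, UMI artifacts, batch effects,
HLA-restricted training-set composition, or real clone-size dynamics — none
of which the generators model. Classifier AUROCs on planted-motif data are a
sanity floor, not an estimate of accuracy on tetramer-sorted repertoires.

## 9. Numerical and testing choices

Exact rank tests switch to tie-corrected normal approximations past
enumeration limits (Mann–Whitney beyond n₁·n₂ = 400 or with ties; signed-rank
beyond 20 informative pairs); all-tied inputs return p = 1 by convention
rather than erroring. Fisher p-values across the package are checked in the
test suite against an independent full-enumeration hypergeometric oracle
(exact integer binomials) to 1e-10. BH adjustment is validated against
textbook step-up enumeration on all short p-vectors. Benchmark problem sizes
in the test suite (500-positive training sets, 10⁴-read pairs, 10–20 seeds
per null ensemble, 600-cell single-cell sets) were chosen as the smallest
sizes at which the measured properties are stable across seeds.
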