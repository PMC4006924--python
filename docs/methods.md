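# Methods

This note documents the statistical procedures sepsiskit implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known
limitations.

## The analysis problem

Two experimental sepsis models (a surgical cecal ligation and puncture,
"model A", and an intraperitoneal cecal slurry, "model B") are profiled
on expression arrays at three timepoints (2 h, 1 d, 3 d) alongside
healthy controls. The questions the pipeline answers are: which genes
respond; whether the two models' responses are the same, at each
timepoint and overall; whether the transcriptome identifies the sample
source; how far each septic sample has moved from the healthy state as
a single scalar; and which gene sets are over-represented or
directionally activated. All statistics operate on an
already-normalized log2 expression matrix; normalization itself
(e.g. RMA from raw array files) is out of scope.

## Gene selection

**CV filter.** Per probe, CV = sd/mean with sd the n−1 sample standard
deviation. The default scale is linear (values anti-logged as 2^x)
because on log2-normalized data, where typical values are 4–14 with
sub-unit spread, a CV > 0.5 cut would retain essentially nothing; on
the linear scale it retains the broadly varying minority a heat map is
built from. A log2-scale option exists for sensitivity analysis.
Probes are kept when CV is *strictly* greater than the threshold.

**F-test.** Per probe, a one-way ANOVA across either the three classes
(control / model A / model B pooling timepoints — the default) or
control plus every (model, timepoint) cell. The pooled grouping is the
natural omnibus test, but it loses power against transient effects that
change sign over time (they cancel in the pooled group mean), so the
per-cell grouping is used for the per-model "sepsis responsive"
selections. The cutoff is a raw p < 0.001 with no multiple-testing
correction — this is deliberate fidelity to the analysis style the
pipeline reproduces; a Benjamini–Hochberg FDR column is emitted
alongside for users who want it. Probes with zero within-group
variance get p = 0 with a warning (a perfectly separated probe is
maximally significant). The implementation is a vectorized sums-of-
squares computation with `scipy.stats.f.sf` for the tail; it is
cross-checked against `scipy.stats.f_oneway` in the tests, and the
permutation-LOOCV stage relies on its speed.

**Probe→gene collapsing.** A gene counts as selected if at least one
of its probe sets is selected; unannotated probes are retained for
probe-level statistics and skipped in gene-level accounting.

**Fold changes.** d = mean(group) − mean(control) on the log2 scale;
the signed fold is 2^d for d ≥ 0 and −2^(−d) otherwise, so |fold| ≥ 1
always and sign(fold) = sign(d). Correlations are computed on d, not on
folds.

## Class prediction

Nearest centroid on per-probe standardized values (training mean/sd;
constant probes get sd 1 so they contribute nothing), standardized
Euclidean distance, ties to the lexicographically first class. The
classifier is deliberately parameter-free. Leave-one-out
cross-validation re-runs the F-test selection inside each fold by
default so the selection step cannot see the held-out sample; a flag
reproduces the optimistic select-once variant. If no probe passes the
selector in a fold, all probes are used for that fold (logged), which
keeps the procedure total on null data.

The permutation null permutes class labels over the whole cohort
(controls included) and repeats the complete LOOCV per permutation.
The p-value is the add-one estimate (1 + #{null ≤ observed})/(B + 1),
never zero, exact under exchangeability. Samples are sorted by id
internally before any computation, so results are invariant to input
column order; B defaults to 1,000 (resolving p < 0.01 comfortably) and
the RNG seed is mandatory.

Two properties of this estimator are worth knowing. First, the null
LOOCV rate for k balanced classes sits slightly *above* (k−1)/k
because the held-out sample is removed from its own class centroid;
tests therefore check a window around 2/3 rather than the population
value. Second, the LOOCV rate is discrete (support ≈ n+1 values), so
under the null the add-one p is conservative (super-uniform) — ties
between observed and permuted rates inflate p. The uniformity check
accordingly bounds the Kolmogorov–Smirnov distance at 0.15 and the
mean p in [0.40, 0.65] rather than asserting exact uniformity, which
no implementation using this p-value formula could deliver.

## Concordance between models

Per timepoint, Pearson r (with the two-sided t-transform p) between
the two models' mean log2 change vectors over a common probe universe.
The universe defaults to the **union** of the two models' significant
sets: an intersection would drop model-unique responders, and since
those are exactly where the models disagree, it would bias r upward.
The intersection rule is available and both choices are recorded in the
report. The maximum-change summary takes, per probe and model, the
largest-|d| change across timepoints with sign retained (ties go to the
earliest timepoint) and correlates the two resulting vectors; with one
timepoint it reduces to that timepoint's r.

## Distance from reference (DFR)

D = Σᵢ (eᵢ − Mᵢ)²/Vᵢ over a probe universe, with Mᵢ and Vᵢ the control
group's mean and unbiased (n−1) variance, and the reported score is
ln D. The squared, variance-normalized form is the one that makes the
score a distance: non-negative, additive over disjoint probe subsets,
and invariant to jointly rescaling (e, M, √V). The log of the *sum*
(not a sum of logs, which is undefined for negative differences) keeps
the metric in single digits for thousands of probes. An
absolute-deviation variant Σ|e−M|/√V is available behind a flag for
sensitivity analysis.

Under the null — a sample drawn from the control population, reference
estimated from n controls — each term is (1 + 1/n) times an F(1, n−1)
variable, so E[D/G] = (1 + 1/n)(n−1)/(n−3), ≈ 1.414 at n = 10. This is
the calibration target of the tests and acceptance script. The score
universe defaults to each model's own significant probe set (so each
model is measured on the genes *it* perturbs); a shared-universe option
supports comparison on equal footing. Probes with zero control variance
are excluded with a logged list; at least 3 controls are required;
D = 0 is reported as degenerate rather than ln 0.

## Gene-set statistics

Over-representation is a two-sided Fisher exact test on the 2×2 table
(in set × significant) against a universe defaulting to all annotated
genes on the matrix, reported as −log10 p (0.05 ↦ 1.3). The two-sided
p sums all hypergeometric tables with probability ≤ the observed
table's — the convention that is deterministic and checkable by full
enumeration.

The activation score implements the simple published form of the
directional z-statistic: over set members whose observed |signed fold|
passes the inclusion threshold (default 2-fold, matching the
conventional inclusion rule for pathway scoring),
Z = (N_consistent − N_inconsistent)/√N, Z = 0 when nothing qualifies,
|Z| ≥ 2 flagged significant (under a random-sign null,
P(|Z| ≥ 2) ≈ 4.6%). Probe-level changes collapse to genes by taking
each gene's largest-|d| probe, the same convention as the max-change
correlation. This reproduces the documented statistic's behaviour
without any proprietary pathway knowledge base; pathway *content* is
always user-supplied.

## Synthetic data generator

The generator emulates the structure the analysis assumes: per-probe
baselines uniform on [4, 14] log2 units (the typical normalized
microarray range — wide enough to exercise the CV filter's scale
choice); Gaussian noise on the log2 scale (default sd 0.3, the scale of
replicate scatter on normalized arrays); a DE fraction (default 0.2)
whose probes get effects drawn per timepoint from a bivariate normal
across the two models with sd `effect_sd` (default 1.0 ≈ 2-fold) and
correlation ρ_t — the dial the concordance analysis recovers, with
defaults 0.6 / 0.4 / −0.3 mirroring the early-agreement-to-inversion
pattern the analysis is designed to detect. Non-DE probes have exactly
zero effect (a sharp null, making type-I calibration exact). Genes get
alternating 1 and 2 probe sets so probe and gene counts differ.
Group sizes default to 6 controls and 4 samples per (model, timepoint)
cell — a typical small-animal cohort; the source design's group sizes
are not published, so this is a configurable convention. An optional
`de_fraction_b` makes model B perturb a superset (or subset) of probes,
expressing breadth asymmetries such as one model inducing ~3× the DE
gene count of the other; the shared block keeps the ρ_t correlation
structure and surplus probes respond in one model only.

Deliberately not emulated: raw-array (CEL-level) artefacts and
normalization, batch effects, probe-level correlation within genes
beyond shared effects, heavy-tailed noise, and cell-composition
(leukocyte differential) shifts. Effects are drawn independently
across timepoints, so the generator has no within-gene temporal
autocorrelation; one consequence is that the max-change correlation of
synthetic data sits well below the per-timepoint maximum (each probe's
maxima often occur at different timepoints in the two models),
whereas real kinetics with persistent effects would push it toward the
per-timepoint values. Passing tests therefore demonstrate statistical
correctness of the machinery, not that real arrays satisfy these
distributional assumptions.

## Numerical and design choices

- Identical design + seed ⇒ bit-identical datasets; the pipeline
  manifest records a SHA-256 config hash and the seed, and a rerun of
  `run_pipeline` is byte-identical.
- Hierarchical ordering for heat maps: average linkage on 1 − Pearson
  distance, rows and columns independently; constant rows (undefined
  correlation) are placed last with a warning; ties resolve to input
  order, so the ordering is deterministic. This is a documented default
  for export, not a claim about any particular published figure.
- ρ = ±1 is generated exactly (Cholesky construction), not via a
  near-singular covariance.
- Zero-variance cases are handled explicitly everywhere they can
  occur: CV (linear-scale mean is positive, log2 zero-mean probes are
  excluded with a warning), F-test (p = 0 + warning), DFR reference
  (probe excluded + logged), clustering (row placed last).
- Validation is total: a loaded dataset satisfies all type invariants
  or loading raises an error naming the offending identifiers.

## Problem sizes

The test suite and acceptance script run on deliberately compact
instances chosen to make each statistical check sharp: 10,000 probes
for null calibration (binomial interval around 0.001), 5,000 DE probes
for correlation recovery (sampling error ≈ 0.014, well inside the
±0.05 check), 1,000 null draws for the DFR scale (Monte-Carlo error
≈ 0.5%), 100 replicates for the DFR ordering and permutation-p
uniformity checks, and B = 999 permutations where the floor p-value
1/(B+1) = 0.001 is asserted.

## Known limitations

- The F-test assumes equal within-group variances and normal errors;
  it is applied probe-wise with no moderation (no empirical-Bayes
  shrinkage), matching the legacy analysis style rather than modern
  practice (limma/DESeq-style moderation is out of scope).
- The raw p < 0.001 cutoff controls nothing family-wise; the FDR
  column is advisory only.
- The DFR null expectation requires n ≥ 4 controls (the (n−3)
  denominator) and is exact only when the scored probes are not
  selected using the same samples being scored; selecting probes on
  septic-vs-control contrasts leaves control scores essentially null
  but makes septic scores conditional on selection.
- The activation Z ignores gene-gene correlation; its null is exact
  only for independent member genes.
- With very small cohorts the permutation p's discreteness dominates:
  at B permutations only B+1 p-values are attainable.
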