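# Methods

This note documents the statistical models, defaults and numerical
choices behind `mirsig`, and what the synthetic cohorts do and do not
establish about real plasma data.

## Data model

A **Cq matrix** holds qPCR quantification cycles, assays × samples, each
value in (0, 40]; cycle 40 is the instrument's censoring limit and
undetected reactions are stored as missing (`NA`). One cycle corresponds
to one doubling of template, so Cq differences are log2 abundance
differences with reversed sign. The **sample sheet** assigns each sample
one of five histology strata — healthy, hyperplastic polyp, adenoma,
CRC, metastatic CRC — and the binary cancer flag is derived as
{CRC, metastatic CRC}; most statistics operate on that two-group
contrast.

## Quality control

**Hemolysis.** Red-cell lysis floods plasma with erythrocyte miR-451a
while miR-23a-3p is comparatively unaffected, so the screen computes
ΔCq = Cq(miR-23a-3p) − Cq(miR-451a) per sample and flags hemolysis when
ΔCq > 7 strictly. The delta is invariant to per-sample loading offsets.
The orientation (23a minus 451a) is the one under which contamination
*raises* the delta; both assay names and the cut-off are arguments. A
sample in which either assay is undetected is reported `indeterminate`
rather than silently passed. We read "positive if > 7" as
positive-for-hemolysis (sample excluded); the opposite reading would
make the screen useless, but the choice is recorded here because the
phrasing in the field is ambiguous.

**Detection filter.** An assay is retained iff it is detected in at
least 95% (`min_rate`) of the samples of the cancer *or* of the
non-cancer super-group — the filter intentionally uses the two
super-groups, not the five strata, so a marker expressed only in cancer
survives. No imputation happens at this stage.

## Normalization

Livak 2^−ΔΔCt on the cycle scale:

* *global mode* (array cards): the per-sample reference is the
  arithmetic mean Cq over retained assays — equivalently the geometric
  mean of the linear quantities — making outputs invariant to additive
  per-sample Cq shifts (loading/input differences);
* *endogenous mode* (single assays): the reference is the mean Cq of a
  small stable set, default miR-423-5p + miR-361-5p, which must be
  detected in every sample (hard error otherwise: a missing reference is
  not recoverable).

The calibrator is the mean ΔCt over the control samples; the default
control group is the healthy stratum (configurable to all non-cancer),
so output is log2 fold difference relative to the average healthy
subject. Undetected target cells are imputed at the censoring limit
Cq = 40 with a warning — after the detection filter this touches at most
5% of cells in one group, and imputing at the limit is the conservative
(lowest-abundance) choice. The count of imputed cells is reported so a
user can judge the impact.

**Quantile normalization** maps every column onto the across-sample mean
of sorted columns. Ties share the mean of their rank quantiles, which
makes the transform deterministic and exactly idempotent (tested to
machine precision). It requires a complete matrix; run it after Livak
normalization. Whether a downstream threshold was calibrated on
quantile-normalized or plain Livak values matters, which is why
signature models carry a `scale` tag.

## Reference-gene selection (geNorm)

Candidates are abundant, fully detected assays (mean Cq < 20, strict).
On linear relative quantities, the stability of candidate *j* is
M_j = mean over partners *k* of sd_samples(log2(q_j/q_k)), using the
n−1 sample standard deviation. The least stable candidate is excluded
and M recomputed until two remain; M ties break lexicographically by
assay name so runs are reproducible. geNorm is run on linear quantities
2^−ΔCt (its published definition); M and V are invariant to
per-candidate rescaling, so the choice of calibrator does not affect
the ranking. The pairwise variation V(n/n+1) is the sd across samples
of log2(NF_n/NF_{n+1}), NF_n being the geometric mean of the *n* most
stable candidates; the conventional V < 0.15 guide is reported, never
enforced. The published study's own values (pair stability 0.23,
V = 0.065) derive from raw plasma data that is not public; they are
context, not test targets.

## Marker screening

**Random-variance moderated t.** Per-assay pooled variances s² (df =
n₁+n₀−2) are modeled with an inverse-gamma prior: precisions 1/σ² ~
Gamma(shape *a*, scale *b*), under which s²·a·b ~ F(df, 2a). (*a*, *b*)
are fitted by maximizing the exact F-likelihood across the panel
(Nelder–Mead on log-parameters from four starting shapes, start scale
matched to the mean observed variance; zero variances are floored at
the smallest positive float so the likelihood stays finite). Each assay
then uses the posterior-precision variance

    s̃² = (df·s² + 2/b) / (df + 2a),

a t statistic with s̃² in the denominator, and df + 2a degrees of
freedom — the borrowing that makes five-per-group screens workable.
With no prior the test is exactly the classical pooled t (tested to
1e−10 against an independent implementation). P-values are two-sided;
selection uses raw p < 0.05 plus |FC| ≥ 1.5 with the signed fold-change
convention FC = ±2^|Δ| (so |FC| ≥ 1 always); Benjamini–Hochberg
q-values are emitted for information only, matching screening-stage
practice where the fold-change filter, not FDR control, guards against
noise. The homogeneous limit behaves correctly: with identical observed
variances the fitted prior concentrates and every moderated variance
equals the common value.

**Clustering.** Heatmap orderings come from complete-linkage
agglomeration on 1 − Pearson correlation, computed for both assays and
samples; a zero-variance item is a hard error naming the item, since
its correlation is undefined.

## Signatures

**Published four-miRNA score.** A fixed linear functional of
log2-normalized expression with weights (1.037, 0.9, 0.247, 0.903) for
(let-7e-5p, miR-106a-5p, miR-28-3p, miR-542-5p), no intercept, and a
strict `score > threshold` cancer call at 1.024 (TLDA scale), 2.442
(single-assay scale) or — with all weights 1 — 19.14 (external
RNA-seq-style matrices). These models are frozen constants: the
elimination path that produced the weights is not recoverable from
public data, so they are applied, never re-fitted. Marker-name matching
is case-insensitive and tolerant of the `hsa-` prefix (external
matrices vary), but a missing marker is an error, never imputed.

**SVM-RFE.** New signatures are trained with a linear soft-margin SVM
(C = 1, features standardized within the training data — defaults
chosen to match common array-tool behavior; both are arguments) over
candidate markers, eliminating the feature with the smallest squared
weight one at a time. Apparent accuracy is resubstitution accuracy at
each requested size; LOOCV accuracy re-runs the entire elimination path
inside every fold, so the cross-validated estimate is free of
feature-selection bias — the gap between the two is itself informative
and both are reported. A fold that loses one class entirely counts as a
miss. Threshold calibration scans midpoints between adjacent sorted
unique scores plus an all-positive and an all-negative cut, maximizing
overall accuracy; ties prefer higher specificity (a screening test
should not over-call cancer), then the lowest threshold.

## Evaluation

Proportion CIs use the continuity-corrected Wilson score interval, the
convention of the Vassarstats calculator used in clinical reporting; at
0 or n successes the corresponding bound is exactly 0 or 1. Percentages
are rounded half-up to one decimal for report parity, with raw
proportions retained. A metric whose denominator is zero is reported as
undefined, not as 0. AUC is the tie-aware Mann–Whitney probability
(equal to the trapezoidal area under the empirical ROC; verified
against brute-force pair counting), with a Hanley–McNeil standard-error
CI clipped to [0, 1]. The planning formula
n = N·s²·t² / ((N−1)·e² + s²·t²) is evaluated as printed, returning
both the real value and its ceiling.

## Synthetic cohorts

The generator draws one baseline Cq per assay from N(26, 3²) — mid-range
plasma abundance on a 381-assay panel — and adds per-sample technical
noise of sd 0.5 cycles, typical qPCR replicate variability. Planted
cancer markers (default 6, named after well-known up-regulated plasma
miRNAs) have their Cq lowered by `effect_log2` cycles (default 1.5) in
cancer samples; stable endogenous-like assays (default 2, named
miR-423-5p/miR-361-5p) sit near Cq 18 with sd 0.1 so they pass the
reference-candidate prefilter; the hemolysis pair is always present at
realistic levels (miR-23a ≈ 20, miR-451a ≈ 17, delta ≈ 3). Values
beyond 40 cycles are censored to missing. Hemolysis injection lowers
miR-451a to ΔCq = 7 + U(0.5, 3), strictly violating the rule. All
randomness flows from one `numpy` generator seed; identical seeds give
bit-identical output.

What the simulations do **not** emulate: correlated miRNA co-regulation,
batch/plate effects, amplification-efficiency differences between
assays (no Pfaffl correction is implemented), heavy-tailed or
sample-quality-dependent noise, and group-dependent detection dropout
beyond what the mean shift induces. Passing recovery tests therefore
demonstrates that the chain is implemented correctly and has the
expected power under idealized qPCR noise — not that the published
signature will transfer to any particular real cohort.

## Test problem sizes

The statistical acceptance checks use: a 1000-assay null panel (12 vs
12) for type-I error against a 99% binomial band; 2000 simulated
variances (df 22) for hyperparameter recovery within 15%; 50 label
permutations of a 40-sample planted design for the chance-level LOOCV
check (99% t-interval — LOOCV under a balanced null is known to sit
slightly below the majority rate, which the interval accommodates
honestly); and 100 seeded cohorts at effect 1.5 log2, 20 per stratum,
for the ≥5-of-6 marker-recovery rate (≥90% of seeds). These sizes make
the Monte-Carlo error comfortably smaller than the margins they check.

## Known limitations

* Efficiency-corrected quantification (standard curves, Pfaffl) is out
  of scope; the 2^−ΔΔCt model assumes ~100% amplification efficiency.
* The RVM fit assumes exchangeable variances across assays; gross
  violations (e.g. a bimodal variance landscape) would miscalibrate the
  moderation, though the classical fallback (`hyper=None`) always
  remains.
* `calibrate_threshold` optimizes accuracy only; cost-sensitive
  thresholds (weighting sensitivity over specificity) are not
  implemented.
* External matrices are consumed as-is: no cross-platform
  renormalization is attempted beyond the equal-weight score scale.
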