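# Methods

## The model

The package assumes the standard master-regulator-analysis premise: the
mRNA levels of a transcription regulator's target genes carry information
about the regulator's activity, so a regulator's per-sample activity can be
estimated by enrichment of its **regulon** — the set of targets assigned by
network inference, each with a mode of regulation (activated/repressed) and
a confidence weight — in that sample's expression signature. A **master
regulator** is a TR whose activity is significantly differential between
two phenotype classes and survives a consensus across four independent
inference-plus-scoring pipelines:

| pipeline     | network engine | activity / test                         |
|--------------|----------------|-----------------------------------------|
| BOOST_GSEA   | boosting       | two-group weighted-KS GSEA (NES, perm p) |
| BOOST_GSVA   | boosting       | kernel-CDF KS score → moderated t        |
| BOOST_AREA   | boosting       | analytic rank NES → moderated t          |
| MI_AREA      | MI + DPI       | analytic rank NES → moderated t          |

Intersecting the four per-cohort MR sets trades recall for precision; the
cross-cohort rules then ask for recurrence (all cohorts or a ≥ 50%
fraction, rounding up, so "4 of 8" and "2 of 4" both follow from 0.5),
and the quadrant rule labels an MR phenotype-specific only when its median
activity is strictly positive in one class and strictly negative in the
other. Ties/zero medians map to no vote: the quadrant semantics require
strictly opposite signs. A pooled-median filter (> 0 over all samples of
the class, cohorts concatenated, missing cohorts contributing zeros)
guards the final lists; an MR qualifying for both lists is dropped.

## Phenotype labeling

Cohorts are labeled by consensus clustering over the z-scored 20-gene
immune-activation signature (chemokine, Th1/IFN-γ, cytotoxic and
immune-regulatory transcripts): B = 100 subsamples of 80% of samples,
Ward-linkage hierarchical clustering on Euclidean distance, cut at k = 3;
the consensus matrix entry is the co-clustering frequency among
co-samplings. The final partition cuts a Ward tree on 1 − consensus, and
clusters are ordered by mean signature z-score (top → HIGH, bottom → LOW,
ties broken toward the larger cluster). Ward/Euclidean was chosen for the
inner kernel because it is deterministic given the data; samples are
processed in a canonical (sorted-identifier) order so labels are invariant
to input sample order. Labels are also invariant to any uniform affine
rescaling of the signature genes because of the initial z-scoring.

## Network inference

**Boosting engine.** For each target gene, a least-squares gradient-boosted
ensemble of depth ≤ 2 trees (300 rounds, shrinkage 0.05, 90% row bagging
and 30% regulator subsampling per round; LightGBM backend, single-thread
deterministic mode) predicts the z-scored target row from all candidate
regulator rows (excluding the target itself). The importance of regulator
t for target g is the total squared-error reduction (gain) of splits on t.
Edges are kept when the gain exceeds `null_margin` (default 2.0) times the
maximum gain obtained on a target-permuted copy of the same fit, then
thresholded at 0.33 of the per-target maximum (weights are the max-rescaled
gains) and capped at the top 25 regulators per target. The margin matters:
for a pure-noise target, the real and permuted fits draw their maximum
gains from the same distribution, so a bare "beat the null maximum" rule
keeps a spurious top edge about half the time; measured on noise targets,
the max-gain ratio's 95th percentile is ≈ 1.9, so a margin of 2 empties
≈ 95% of noise targets while true-regulator gains at realistic sample
sizes sit far above it. The minimum leaf size adapts to the cohort
(max(2, min(20, n/5))) so small matrices can still split.

**MI engine.** Rows are discretized into equal-frequency bins
(⌈√N⌉, capped at 10; tied values share a bin); the edge weight is the
plug-in mutual information in bits with the Miller–Madow correction
MI + (Kx + Ky − Kxy − 1)/(2N ln 2). Significance is a permutation
keep-threshold: the edge survives when its MI exceeds the 95th percentile
of MI under row permutation (200 permutations). Because that null depends
only on the two rows' bin-count profiles, thresholds are cached per
profile pair — exact, and orders of magnitude faster on continuous data
where all rows share one profile. DPI pruning then removes, in every
triangle, the edge whose weight is ≤ (1 − ε) · min of the other two
(ε = 0.15, classic tolerance), evaluated against pre-pruning weights.

**Regulon construction.** TRs with fewer than 10 targets are dropped (the
quality-control floor; re-applied after signing). Modes come from the sign
of the Spearman correlation between TR and target rows — Spearman rather
than Pearson for robustness to monotone distortion — and the confidence
multiplies the per-TR max-rescaled network weight by |ρ| so both evidence
sources matter. Targets with zero or undefined correlation are dropped.

## Activity scoring

Single-sample signatures are cohort z-scores (genes with zero variance
excluded). For the analytic engine the z-scores are rank-mapped per sample
to normal quantiles Φ⁻¹(rank/(G+1)) so that
NES = Σ wᵢmᵢqᵢ / √Σwᵢ² is standard normal under an independent-null
signature, giving the closed-form two-sided p = 2Φ(−|NES|). Measured over
10 000 random signatures (G = 1000, regulon size 25) the empirical null
mean is ≈ 0.001 and the variance ≈ 0.97 — slightly below 1 because the
finite quantile grid has variance < 1; the deficit shrinks as G grows.

The GSVA-style engine scores each gene by a Gaussian-kernel CDF across
samples (bandwidth sd/4, floored at 1e-6), ranks genes per sample by
decreasing score, uses the rank statistic r = |G/2 − rank| with τ = 1, and
runs a weighted-KS walk per mode-set (inside steps r^τ normalized within
the set, outside steps 1/(G − |set|)); the statistic is the signed sum
max(walk⁺) + min(walk⁻), and the regulon score is the positive-set score
minus the negative-set score. The signed-sum ("max.diff-style") statistic
was preferred to the max deviation because it is antisymmetric under mode
swap, which the consensus semantics rely on.

Two-group GSEA ranks genes by the fold-change signature (mean HIGH − mean
LOW); a signed regulon enters as its target set on a mode-adjusted
signature (target values multiplied by their mode — the alternative of
splitting pos/neg sets and subtracting ES scores is implemented in the
GSVA engine). ES is the maximum-absolute signed deviation of the weighted
walk (|s|^p hit steps, p = 1). All ranking ties break by stable gene-id
order so results are machine-independent; at an exact ±ES tie the positive
branch is reported. The permutation null draws same-size gene sets; NES is
ES over the mean |ES| of same-sign nulls and p uses add-one smoothing.
Null ES values are computed by a position-based closed form of the walk's
extrema (extremes occur only just after a hit or just before the next),
vectorized over permutations and verified exhaustively against the
explicit running sum.

### Gene-permutation vs phenotype-permutation GSEA nulls

Gene permutation treats genes as the exchangeable unit. Regulon targets
are co-regulated by construction — that is the premise of the whole
method — so under the *population* null (no group effect) the chance
between-group fluctuation of a TR's activity coherently shifts all of its
targets and inflates |ES| relative to the gene-permutation null: on null
benchmarks the GSEA pipeline's realized false-discovery proportion is
≈ 0.75–0.85 rather than the nominal 0.05. A phenotype-label permutation
null (`fgsea_label_scores`, `PipelineConfig(gsea_null="label")`) is exact
under group exchangeability and measured calibrated (FDP ≈ 0–0.05), but
the rank-based ES discards the magnitude of the separation, so its power
against genuine shifts collapses when many co-regulated sets compete —
planted effects that the moderated-t pipelines detect at p < 1e-6 reach
only p ≈ 0.03–0.2 under the label null and rarely survive the FDR step.
No weighted-KS variant can have both properties on such data. The package
default follows the cited tool's convention (gene permutation, powerful,
nominally-scaled NES); users who need calibrated GSEA error rates under
the population null should select the label null and expect reduced
power, or rely on the three moderated-t pipelines, which are calibrated
(measured FDP ≤ 0.10) because they model per-TR activity variance across
samples.

## Differential analysis

The moderated t shrinks per-TR pooled variances toward a prior fitted by
the method of moments on log variances (digamma/trigamma identities for
the log-chi-square mean and variance; the trigamma inverse by Newton
iteration). The posterior is s̃² = (d₀s₀² + d s²)/(d₀ + d) and the t
statistic has d₀ + d degrees of freedom; it agrees with the reference
empirical-Bayes implementation to ≈ 1e-4 relative on random matrices
(cross-checked in the suite). When the moment fit is degenerate (the
excess variance of log s² is non-positive, e.g. rows with identical
scatter), the implementation falls back to the ordinary pooled t with a
warning. A TR with zero within-group variance and zero effect gets p = 1.
MEDIUM samples are excluded from all differential stages. BH adjustment
delegates to the standard step-up implementation and is oracle-tested
against the definition.

## Synthetic data

The generator plants a signed network (regulon sizes uniform on 20–50 by
default — a realistic regulon scale; weights uniform on (0.5, 1];
modes −1 with probability 0.3), latent TR activities a_t ~ N(±δ/2, 1)
with the sign of the shift set by the TR's favored group (δ = 2 by
default, half the differential TRs favoring each phenotype so both
quadrants are exercised), TR expression as a noisy copy of activity
(sd 0.25, making correlation-based signing well-posed), and target rows as
Σ mode·weight·activity plus N(0, σ²) noise (σ = 0.5). Twenty filler genes
named after the immune-signature transcripts are shifted upward (by 2) in
the HIGH group so the labeling stage can recover the planted groups.
Multi-cohort benchmarks share a configurable core of differential TRs
(identical directions) across independently drawn networks, with the
remaining differential TRs private to single cohorts. The linear-Gaussian
choice keeps closed-form expectations for tests; it does not model
library-size effects, count noise, or heavy-tailed real distributions, so
passing recovery tests demonstrate the machinery under the model's own
premise, not performance on real sequencing data.

Default study sizes used by the test suite and the acceptance script —
4 cohorts × 120 samples with 100 TRs and 1000 targets for the end-to-end
consensus benchmark, 50 TRs × 500 targets × 200 samples for network
recovery, and 20 replicate null cohorts for calibration — were chosen as
the smallest scales at which the statistical properties under test are
stable.

## Numerical conventions and edge cases

- Quantile normalization maps each column's ranks onto the row-wise mean
  of the sorted columns; tied values share the mean of the reference
  values they span (deterministic and permutation-invariant). With ties
  the collapse changes the column's value multiset, so exact idempotence
  holds on tie-free columns only.
- Duplicate gene rows are collapsed by mean with a warning; duplicate
  sample headers are an error. Gene identifiers match case-sensitively,
  with no alias resolution.
- Regulators for a target that is itself a TR exclude only that TR.
- An MR absent from a held-out cohort (gene or < 3 expressed regulon
  targets) gets activity 0 and a flag, following the zero-activity
  convention for non-TR cohorts; projection significance is a one-sided
  Wilcoxon rank-sum in the direction of the MR's label (nonparametric,
  matching the median-based specificity claims), BH-adjusted per cohort.
- Over-representation analysis intersects every set with the background
  before testing and reports the upper-tail hypergeometric p, k/K ratio
  and member genes.

## Known limitations

- No tumor-purity or other covariate adjustment in the differential model
  (single-factor two-class design only).
- No pleiotropy/shadow correction in the rank-based activity engine.
- Gene-permutation GSEA p-values are nominal, not calibrated, under
  co-regulated regulons (see above).
- No survival analysis; no probe-level microarray handling (inputs are
  assumed collapsed to gene symbols and normalized).
- The boosting engine's hyperparameters approximate regularized boosting
  at desk scale; they are configurable but not tuned per dataset.
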