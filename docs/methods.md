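# Methods

## Design and data model

The package targets a paired two-tissue expression study: the same subjects
(default 8 control + 9 treated) contribute one heart and one PBMC array, on
a platform of ~22.5k probes of which ~40% measure genuinely expressed
transcripts. All statistics are computed per tissue on a shared expressed
gene set; the cross-tissue step only intersects and compares per-tissue
results — there is no paired-sample or mixed model across tissues, matching
the analysis the package reimplements.

## Preprocessing

1. **log2 transform.** Raw intensities must be strictly positive; a
   nonpositive cell raises (no silent flooring), since raw bead summaries
   without background subtraction are positive by construction.
2. **Expressed/background call.** A probe is expressed iff its average log2
   intensity over *all* arrays is strictly greater than the threshold
   (default 7.2; a probe exactly at threshold is background). In the
   default joint analysis the average pools both tissues' arrays, giving one
   shared expressed set; single-tissue entry points classify on that
   tissue's arrays. `threshold="auto"` puts the cut at the antimode between
   the two largest density modes of the average-intensity distribution and
   refuses unimodal data. Whether classification should precede or follow
   normalization is ambiguous in this pipeline family; the default
   classifies on un-normalized averages (the order the steps are usually
   listed in), and `classify_after_normalization=True` gives the other
   order. Since median subtraction shifts all probes of an array equally,
   the choice only matters when arrays have very different offsets.
3. **Median-of-background normalization.** Each array's median over
   not-expressed probes is subtracted from every value of that array. This
   makes the background class a negative-control anchor (its per-array
   median is exactly 0 afterwards; the operation is idempotent).
4. **Replicate merge.** Duplicate arrays of a subject are averaged on the
   log2 scale; per-pair Pearson correlations are reported. Replicates of
   one subject in different treatment groups are a metadata error.
5. **Probe collapse.** Unmapped probes are dropped; a gene with several
   probes keeps exactly the probe with the largest average normalized
   intensity (ties toward the smallest probe id), with provenance recorded.

## Moderated test and calibration

The random-variance model places a gamma prior on gene-wise precision,
1/σ² ~ Gamma(shape a, scale b), equivalently an inverse-gamma prior on σ².
The marginal law of the pooled sample variance is then a·b·s² ~ F(ν, 2a),
and (a, b) are fit by maximizing this marginal likelihood over
(log a, log b) with Nelder–Mead from a moment start (a₀ = 2,
b₀ = 1/mean s²). Identical s² values make the likelihood unbounded in a;
this degenerate case raises rather than returning an arbitrary point. The
fit uses expressed genes only: background probes have a different variance
structure and serve purely as a p-value reference set.

The moderated variance s̃² = (ν·s² + 2/b)/(ν + 2a) interpolates between s²
and the precision-implied prior point 1/(ab); the t statistic is referred
to Student's t with ν + 2a df. As a → 0 with 1/b → 0 the ordinary pooled
t-test is recovered (verified against an independent implementation).

**Empirical null.** Background probes run through the same fitted test give
a reference p-value set; each expressed gene's p becomes
(#{null p ≤ p} + 1)/(m_null + 1). The add-one rule keeps p strictly
positive (needed downstream by the log in Fisher's combination). This
corrects miscalibration of the parametric null — e.g. the mild
anticonservatism induced by shrinking background-probe variances toward an
expressed-gene prior — at the cost of a granularity of 1/(m_null + 1).

**π₀.** Under the null the count of p-values above t falls on a line of
slope π₀·m through (1, 0) when plotted against 1 − t. The slope is fit by
OLS through the origin using the observed p-values above λ = 0.5 as
plotting points, clipped to [0, 1]. The estimator inherits the classic
upward bias of tail-based π₀ estimates: any signal mass above λ inflates
the slope, so heavy-tailed alternatives push π̂₀ up by roughly their
exceedance probability. With the generator's default well-separated
effects this bias is 1–3 percentage points.

**q-values and calls.** Storey step-down q₍ᵢ₎ = min_{j≥i} π₀·m·p₍ⱼ₎/j
(exact vs brute-force enumeration on small instances). Calls use strict
gates: up ⇔ q < 0.05 ∧ log2FC > 1, down ⇔ q < 0.05 ∧ log2FC < −1. Both the
FDR and the fold-change gate apply to both tissues by default
(configurable), and all boundary comparisons are strict.

## Cross-tissue concordance

SDRG = genes with non-ns calls in both tissues; by default direction
agreement is required and discordant genes are reported separately (the
partition total = up-both + down-both + discordant always holds). The
summary reports the Pearson correlation of paired log2FC, quadrant counts
and mean |log2FC| per tissue, so a "down-regulation stronger in tissue X"
statement is directly assertable.

## GO enrichment

Terms need more than four expressed annotated genes (strict; ≥ 5). The
term statistic is Fisher's combination X² = −2Σln pᵢ of the member genes'
*calibrated* p-values against χ² with 2k df — the canonical instantiation
of an "overall probability that the set is unaffected". Fisher assumes
independent member p-values; correlated co-expression makes it liberal,
which is acceptable for ranking but means absolute term FDRs should be
read cautiously. BH runs within each GO aspect separately because results
are reported per aspect. Note the method tests "every member unaffected":
when most genes genuinely respond, most terms are significant — that is
correct behaviour, not inflation. No annotation propagation along the GO
graph is performed.

## qPCR

Replicate wells are averaged on the Ct scale; per sample
ΔCt = Ct_target − Ct_housekeeping (default housekeeping "18S"); group
ΔCt is the mean over samples (not the ΔCt of group means), ΔΔCt =
ΔCt_treated − ΔCt_control, fold change 2^−ΔΔCt. Label swap negates ΔΔCt
exactly and inverts the fold; adding a constant to one sample's target and
housekeeping Ct leaves ΔCt unchanged. No amplification-efficiency
correction is applied.

## Synthetic-data generator

Defaults are the study conditions the package targets: 22,523 probes,
40.6% expressed, 8 vs 9 subjects per tissue with the same subjects in both
tissues, 7 subjects with duplicate arrays, 80% of expressed genes affected,
90% of effects negative, and gene precisions from Gamma(a = 2, scale
b = 10) (mean σ² = 0.1, a realistic log2-scale residual). Expressed gene
means are uniform on (8, 12) against background N(5, 0.5), reproducing the
clear bimodality that motivates a fixed intensity cutoff. Effect magnitudes
are |N(1.5, 0.5)| with a Bernoulli(0.9) sign flip; nothing in the original
report constrains this distribution, so it is a free parameter chosen once
to give well-separated effects, not an estimate of real data. Cross-tissue
sharing: a gene is shared-affected (identical signed effect in both
tissues) with probability `affected_fraction·shared_fraction`
(shared_fraction default 0.6, chosen once to match the observed overlap of
the two tissues' significant sets) and tissue-specific affected with the
complementary share, keeping the marginal affected fraction equal in both
tissues.

Noise is split so that both spec'd behaviours hold exactly: the per-gene
total array variance σ² is drawn from the prior and divided into a
biological share (1 − ρ) carried by the subject and a measurement share
ρ = 0.05 re-drawn per array. Duplicate arrays therefore share the
subject's true expression and re-draw only measurement noise, while the
marginal per-array variance is exactly σ² — so pooled sample variances
follow the F marginal exactly (verified by Kolmogorov–Smirnov at
n ≥ 2000 genes). All draws flow through named per-(tissue, stage) child
streams of the master seed: regeneration is bit-identical and enlarging
one stage does not perturb another.

What the generator does *not* emulate: probe sequence effects,
hybridization chemistry, spatial artifacts, batch structure, correlated
co-expression between genes, and heavier-tailed intensity noise. Passing
tests therefore demonstrate correctness of the statistical machinery under
its own assumptions, not robustness to real-array pathologies.

qPCR tables are generated by inverting the true log2 effect onto the Ct
scale (treated Ct = baseline − effect) with per-well Gaussian noise, so the
noiseless table reproduces 2^effect exactly and noisy tables recover it in
Monte-Carlo mean.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script run at 12,500 probes
(~5,000 expressed + ~7,500 background), 50 seeds for the false-discovery
check and 20 for prevalence recovery — large enough that binomial noise is
well below the tolerances, small enough for quick desk runs. Tolerances:
normalization medians checked at 1e-9; optimizer verified against a dense
100×100 grid over (log a, log b); q-values against exhaustive step-down
enumeration; the empirical-null add-one estimator guarantees p ∈ (0, 1].
Tie handling: q-values are computed on a stable sort (ties are
q-constant by the step-down minimum); probe-collapse ties go to the
smallest probe id; all threshold comparisons are strict.

## Known limitations

- π₀ tail estimator biased upward under weak, dense alternatives (see
  above); λ is configurable but 0.5 is the default.
- Fisher combination ignores inter-gene correlation.
- The background-probe empirical null assumes background probes'
  statistics are exchangeable with null expressed genes' after the
  moderated fit — adequate here, but a strong variance mismatch between
  classes would propagate into calibration.
- No covariates, batch terms, or paired modeling across tissues.
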