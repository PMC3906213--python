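# Methods

`twinmeth` implements a differential DNA-methylation analysis for
disease-discordant monozygotic (MZ) twin cohorts measured on two-channel
Infinium-style arrays, together with a ground-truthed cohort simulator so
that every stage can be validated without access to raw array data.

## The analysis model

### Measurement model

Each probe *g* on each sample *i* yields a methylated intensity
M<sub>gi</sub>, an unmethylated intensity U<sub>gi</sub> and a detection
p-value. The methylation fraction is the plain ratio

> β<sub>gi</sub> = M<sub>gi</sub> / (M<sub>gi</sub> + U<sub>gi</sub>) ∈ [0, 1],

with no offset constant. When M + U = 0 the fraction is undefined; the
entry is flagged and the probe is routed to the filter report rather than
imputed — the QC filter, not imputation, is the missingness mechanism.

### Probe QC

Two rules, applied in a fixed order so the reported counts are
unambiguous:

1. **Detection**: a probe is removed if its detection p-value exceeds the
   threshold (default 0.05, strictly `>`) in *any* sample.
2. **Blacklist**: remaining probes flagged as non-specific or unreliable
   in the manifest are removed.

A `FilterReport` accounts for every input probe exactly once (first
matching rule) and must reconcile with the retained matrix dimensions at
all times; a violation raises.

### Normalization

Quantile normalization is applied to the methylated and unmethylated
signal layers **separately**, before β is computed (signals, not β
values, are normalized). Every column is mapped onto the mean of the
sorted columns; ties within a column receive the mean of the reference
values their rank positions span. On ties-free input the column-wise
empirical distributions are exactly identical afterwards, and the
operation is idempotent. With heavy, column-specific ties the mean-of-span
rule makes the tied column's distribution deviate slightly from the
reference, so exact idempotence is only guaranteed when ties occupy the
same ranks in every column (e.g. exactly duplicated measurements); this
is a documented limitation of the tie rule, not of the implementation.

### Variance-stabilizing transform (VST)

β values are heteroskedastically measured: the array compresses variation
near 0 and 1, and the marginal distribution across probes is strongly
bimodal. Statistical tests therefore run on a transformed scale while
effect sizes (Δβ) are always reported on the β scale. Two strategies are
provided behind one interface; both are strictly monotone, invertible on
their reference range, and serializable so new data can be transformed
consistently:

* **`variance` (default)** — `EmpiricalVarianceVST`: a genuine
  variance-stabilizing map. Per-probe across-sample standard deviations
  are pooled into quantile bins of the probe mean, giving a robust
  (bin-median) spread profile s(β); the transform is
  T(β) = ∫₀^β du / s(u), centred at the pooled median. Where the scale
  compresses (low spread) the transform stretches; where the noise
  profile is flat the map is essentially affine and per-probe
  t-statistics are untouched.
* **`probit`** — `EmpiricalNormalVST`: the standard-normal quantile of
  the pooled empirical CDF (midrank convention, so the pooled median maps
  exactly to 0 and an empirical CDF value of 0.975 maps to ≈1.96).

The probit strategy flattens the across-probe *marginal* rather than the
sampling variance. On sharply bimodal data its derivative collapses in
the sparse valley between the modes, so a homogeneous β-scale effect that
spans the valley becomes heterogeneous across pairs on the transformed
scale and loses testing power — measurable as a drop in planted-effect
recovery. That is why `variance` is the default; `probit` remains
available and fully tested for pipelines that want a
distribution-flattening transform.

### Within-pair analysis

For a chosen design (ASD-discordant, one of the three trait-discordant
groups, or all discordant pairs combined) the per-pair difference

> Δβ<sub>gk</sub> = β(affected twin) − β(unaffected twin)

is formed on both scales. Per probe, a one-sample t-test of the
transformed differences against zero (equivalent to a paired t-test)
gives the significance; the mean Δβ on the β scale gives the magnitude.
Probes whose differences have zero variance cannot support a t-test and
are excluded with a logged count.

### Between-group analysis

Welch (unequal-variance) two-sample t-tests on the transformed values
compare e.g. ASD cases against unrelated controls, or sporadic (affected
member of a discordant pair) against familial (concordant-pair) cases.
Welch is used because the designs have unequal group sizes and no reason
to assume equal variances. These mixed-sex group comparisons are
restricted to autosomal probes by default, since X/Y probes would
otherwise reflect sex, not phenotype. Within-pair analyses keep the sex
chromosomes: twins are sex-matched.

### Combined ranking

Lists are ranked by significance and magnitude together: probes receive a
p-rank (ascending p) and a magnitude rank (descending |mean Δβ|), average
ranks on ties; the combined score is the **rank sum** (a rank-product
option is exposed). Final order is ascending score, ties broken by
smaller p, then by probe id, so ranks are unique and reproducible. The
rank sum is monotone in both ingredients and invariant to any strictly
monotone rescaling of p or |Δβ|. A Bonferroni flag (p < 0.05/number of
probes tested) annotates records but never truncates lists. Note that
0.05/N for the probe counts involved here is of order 2×10⁻⁶.

### Family-private screen

Complex phenotypes can carry family-specific epigenetic changes that
average away across pairs. Per discordant pair, every probe with
|Δβ| ≥ 0.15 (inclusive boundary, exact comparison) is reported, annotated
with the other pairs that exceed the threshold at the same probe with the
same sign.

### Distribution skew

The per-probe average |Δβ| distributions of the discordant and the
unaffected-concordant pairs are compared with a two-sample
Kolmogorov–Smirnov test (two-sided, asymptotic p). An excess of probes
with large average differences in the discordant group shifts its
distribution right. The two samples share the probe set, which makes
them positively dependent and the KS test conservative — acceptable for a
screen whose null behaviour is verified by simulation. For the top-k
ranked probes of the discordant design the mean within-pair |Δβ| in each
group is also reported (top-hit specificity).

### Cross-design overlap

For the top-k probes of every ranked list, the table of their ranks in
all other designs is produced, plus the Spearman correlation between full
combined-score vectors for each design pair.

### Trait correlation

Per probe, Pearson's product–moment correlation between β and a
quantitative trait score (total or one of the three subscales), pooling
individuals. Correlations run on the β scale — the scale on which
methylation-versus-score scatter is read — and the choice is switchable.
Pair non-independence is acknowledged but not modelled; the output log
carries a note that p-values pool individuals. The leave-pairs-out
sensitivity analysis recomputes r and p with chosen twin pairs removed
and reports both side by side. "Extreme pair" detection is
operationalized (the original identification was ad hoc) as: both members
score above a cutoff (default 25 of 31) *and* both lie beyond `mad_k`
(default 3) robust MAD-deviations from the cohort median at ≥
`min_probes` (default 5) of the listed probes.

## The simulator

The generator produces the cohort structure the analyses assume: 50 MZ
pairs (100 samples) by default — 6 ASD-discordant, 5 ASD-concordant, 9/9/8
discordant for the social/RRBI/communication trait domains (32 discordant
pairs in total), 13 unaffected-concordant — over 27,578 probes.

* **β first, intensities derived.** Probe means come from a
  two-component Gaussian mixture on the β scale (defaults: modes 0.15 and
  0.80, spreads 0.06/0.07, weights 0.60/0.40 — a promoter-heavy bimodal
  marginal). Twin pairs share a baseline (pair deviation sd 0.03); members
  add independent noise (sd 0.02). The within-pair noise default was
  chosen so null probes show small average |Δβ| relative to the planted
  effect scale (0.03–0.10) while keeping within-pair correlations near 1.
  Everything is clipped to [0, 1]. Total signal is log-normal
  (median 2000, log-sd 0.35) and split as (βS, (1−β)S), so β is exactly
  recoverable; raw signal levels are otherwise arbitrary.
* **Planted effects are additive on the β scale** (effects are reported
  as Δβ), applied to the affected members of the target design, a single
  pair (family-private; the same probe may recur in several pairs), or —
  for trait loci — constructed so the realised Pearson correlation with
  the integer trait score equals the target exactly in-sample
  (orthogonalised residuals), up to clipping, which the mid-range
  centring of trait loci avoids.
* **Trait scores** are integers from a 31-item instrument (subscales
  12/7/12, at-risk cutoff ≥15): a group-structured latent Gaussian
  (affected domains high, shared pair component) is pushed through the
  normal CDF and scaled to the item count. When the extreme-pair
  mechanism is on, the first ASD-concordant pair is set to the configured
  extreme total (default 29) and shifted by +0.30 at the configured
  probes; the extreme pair is by construction the cohort's unique
  phenotype outlier.
* **Artifacts**: detection failures (p drawn above 0.05) at a per-cell
  rate of 4.3×10⁻⁴ (≈4% of probes failing in at least one of 100
  samples); a blacklist scaled from 2,923/27,578 when not set explicitly;
  SNP-driven trimodal probes with pair-shared genotypes under
  Hardy–Weinberg (modes 0, ½, 1 within ±0.1); ~3.5% X/Y probes. Planted
  probes never receive artifacts, so ground truth stays recoverable.
* All randomness flows from one seed through named sub-streams; outputs
  are byte-identical across runs for a fixed configuration.

### What the simulator does not emulate

Infinium I/II chemistry differences, dye bias, background, batch/chip
effects, genomic autocorrelation between neighbouring CpGs, realistic
blood cell-composition variation, or β-dependent measurement noise
(within-pair noise is homoskedastic by default). Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to array artefacts the model omits.

## Numerical choices

* Detection threshold comparison is strictly `>`; family-screen threshold
  is inclusive `≥` with exact floating-point comparison (no epsilon).
* Quantile-normalization ties: mean of spanned reference values; stable
  sorts everywhere, so results are order-independent.
* VST references: the probit strategy stores the pooled ECDF (midrank);
  the variance strategy stores a 2001-point integral grid; both
  serialize to a reference table written next to the outputs.
* Degenerate inputs raise rather than guess: constant β for a VST fit,
  constant trait vectors, all probes removed by QC, pairs without a
  unique affected member.
* Identical groups in the Welch test yield t=0, p=1 by continuity;
  zero-variance probes are excluded from ranking with a logged count.
* Genomic export is BED 0-based half-open ((position−1, position));
  internal positions stay 1-based. The genome build of positions is
  treated as opaque metadata.

## Test problem sizes

The suite validates calibration and recovery at sizes chosen to make the
checks sharp while keeping the default run quick: null calibration and
planted-effect recovery use 23,000-probe cohorts with 6 discordant pairs
(type-I error within [0.04, 0.06]; 100-seed KS null rejection ≤5%;
20-probe Δβ=0.08 plantings recovered into the top-50 at ≥90% over 20
seeds); trait-correlation recovery uses 500 probes × 100 samples over 50
seeds. The acceptance script runs the full 27,578-probe, 50-pair study.
The null KS comparison uses equal group sizes (6 vs 6 pairs): with
unequal pair counts the per-probe mean |Δβ| distributions differ under
the null purely through averaging (variance ∝ 1/n_pairs), which is not
the alternative the screen targets.

## Known limitations

* Correlation p-values ignore twin clustering (anticonservative for
  strongly pair-clustered probes); a mixed-model treatment is out of
  scope.
* Single-CpG resolution only: no region-level merging of neighbouring
  probes, no FDR machinery beyond the Bonferroni annotation.
* The family screen's recurrence annotation is descriptive; it attaches
  no significance measure to cross-family sharing.
* Exact idempotence of quantile normalization under heavy
  column-specific ties (see above).
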