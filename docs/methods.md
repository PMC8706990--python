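# Methods

This note documents the statistical models behind each `secretodiff`
module, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical conventions that make
results reproducible.

## Cytokine membrane arrays

A membrane carries each analyte as duplicate antibody spots plus positive
(POS) and negative (NEG) control spots.  Quantification is

    normalized(a) = (mean(duplicate spots of a) − mean(NEG)) / (mean(POS) − mean(NEG))

so POS spots map to 1 and the NEG background to 0, which removes exposure
and scanner-gain differences between membranes (the statistics are exactly
invariant to multiplying all raw intensities by a constant).  Normalized
means are clipped below at a **floor of 0.01**: chemiluminescent blots
have a small dynamic range, values at or below background are not
distinguishable, and the floor keeps log fold changes finite.
Quantification fails loudly when mean(POS) ≤ mean(NEG).

Differential metrics per analyte, treated vs control membranes: means x̄ₜ
and x̄꜀ (floored), differential intensity x̄ₜ − x̄꜀, fold change
FC = x̄ₜ/x̄꜀, relative fold change FC − 1, log₂FC, and a two-tailed
two-sample Student *t* (pooled variance by default, Welch by flag).  The
p-value is reported NA when either condition has fewer than two replicates
or both have zero variance — which happens systematically for analytes
pinned at the floor in both conditions.

The **hit count** is the number of enabled criteria an analyte satisfies.
The default set — p < 0.05, |Δ| ≥ 0.05, |FC − 1| ≥ 0.20, |log₂FC| ≥ 0.32,
max(FC, 1/FC) ≥ 1.25 — is a convention of this package: thresholds of this
kind are rarely reported alongside published hit columns, so the defaults
are deliberately ordinary values and every threshold is configurable or
disableable.  No claim is made that any particular published hit column is
regenerated by these defaults.  Candidate ranking sorts by hit count, then
|log₂FC|, then analyte name — the final lexicographic key exists purely to
make output deterministic.

### Reconstruction tolerances for 4-decimal tables

Given a published summary (treated mean, differential intensity, fold
metrics, all at 4 decimals) the fold columns can be recomputed from the
first two.  Rounding both inputs to 4 dp bounds the reconstruction error
of the relative fold change well below 10⁻³, but the log₂FC error scales
with 1/(intensity·ln 2): for a treated mean of ~0.02 a ±5·10⁻⁵ input
rounding alone can move log₂FC by ~3.5·10⁻³.  The test suite therefore
asserts the identity-style checks (relative FC vs 2^log₂FC − 1, and
differential vs I − I/2^log₂FC) at 2·10⁻³, where rounding propagation is
benign, and documents that direct log₂FC reconstruction can exceed that
band for the smallest intensities.

## Label-free proteomic differential abundance

Input is a protein × replicate abundance table (two groups) with a
unique-peptide count and a high-confidence identification flag per
protein.  Definitions:

- **Quantified**: at least one valid (non-missing) abundance in each
  group.  This reproduces the identified > quantified distinction of
  typical label-free reports without depending on any vendor pipeline's
  internals.
- **Abundance ratio**: mean(treated)/mean(control) over valid values.
- **Ratio variability**: 100 · sd/mean of the ratios tᵢ/cⱼ over all
  treated × control replicate pairs.  Commercial software reports an
  "abundance ratio variability" whose exact formula is not public; the
  cross-pair CV is the closest documented analogue and is stated here as
  such.
- **ANOVA p**: plain one-way ANOVA on log₂ abundances.  With two groups
  this is exactly the squared pooled *t* (F = t²), which the suite checks.
- **q-value**: Benjamini–Hochberg step-up across the quantified proteins.

The cascade applies, in order: identification (high confidence, ≥ 1 unique
peptide) → quantification → q < 0.05 → variability < 30% →
max(r, 1/r) > 1.5 (both gates strict, the fold-change gate symmetric in
up/down).  Stage counts are monotone non-increasing by construction and
up + down = selected.  Note that the variability gate removes genuinely
differential proteins too: with a replicate CV of ~15% the cross-pair CV
concentrates near 21% with enough sampling spread that roughly a tenth of
true positives exceed 30% — the cascade trades sensitivity for
reliability, which is its purpose.

PCA log₂-transforms abundances, imputes missing values with the
protein-wise minimum (or drops incomplete proteins by flag — minimum
imputation is the common label-free convention since missingness is
abundance-dependent), mean-centers proteins and decomposes by SVD.  Each
component's sign is fixed so its largest-|loading| protein is positive,
making output deterministic.

## miRNA count differential expression

**TMM factors.** The reference sample is the one whose 75th-percentile
count fraction is closest to the mean of those.  For sample j vs the
reference, over features positive in both: M = log₂(p_j/p_r),
A = ½·log₂(p_j·p_r) with p = count/library size; the extreme 30% of M and
5% of A (each side, rank-based) are trimmed; the factor is 2 to the
weighted mean of the surviving M with inverse asymptotic (binomial)
variance weights; factors are rescaled to geometric mean 1 (product 1).
M, A and the trim are proportion-based and hence exactly invariant to
per-sample rescaling; the binomial weights retain a depth dependence, so
rescaled matrices reproduce factors to within a fraction of a percent
rather than exactly.  The implementation matches the R reference to ~10⁻⁷
on test matrices.

**voom.** log₂CPM = log₂((count + 0.5)/(lib·factor + 1) · 10⁶).  A
per-feature two-group fit yields residual standard deviations; the lowess
trend (span 0.5, 2 robustness iterations) of √sd on mean log₂ count,
interpolated at each observation's fitted log₂ count, gives precision
weights trend⁻⁴.  The weight–abundance relationship is only monotone where
Poisson noise contributes: with a common NB dispersion φ the variance of a
log count approaches φ at high counts and the trend flattens — the
property test therefore uses shallow libraries so low-count features
exist.

**Moderated t.** Weighted least squares per feature gives logFC (treated −
control), unscaled variance v_g = 1/Σw_t + 1/Σw_c and residual variance
s²_g on d = n − 2 df.  The prior (d₀, s₀²) is estimated by moment matching
on z = log s²: E[z] and Var[z] under the scaled-F model involve digamma
and trigamma of d/2; the trigamma equation is inverted by bisection to
10⁻⁸.  When the observed spread of z does not exceed pure chi-square
sampling, d₀ = ∞ and s₀² is the arithmetic mean of the s²_g — so equal
observed variances collapse the moderated t exactly to the ordinary pooled
t, and the opposite limit (d₀ → ∞ with a common prior) is a z-test against
s₀².  Posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d); t̃ = logFC/√(s̃²v);
p two-tailed from t with d₀ + d df.

The reporting filter keeps |logFC| > log₂ 1.5 and **raw** p < 0.05 (both
strict); adjusted p-values are always reported alongside but do not gate
this table, since the filter mirrors how small secretome miRNA panels are
conventionally reported.  Under the default null generator the moderated-t
type-I rate at p < 0.05 is calibrated (measured ≈ 0.050 over 20 000
simulated null features in the acceptance script).

## Gene-set statistics

**ORA**: one-sided hypergeometric tail P(overlap ≥ observed) with the
query required to be a subset of the universe and sets intersected with
it; BH across sets.  Exhaustive enumeration for small universes is the
test oracle.

**Preranked enrichment**: the list is ordered by decreasing metric with
ties broken by identifier.  Walking the list, members add
|metric|^w / Σ|metric_hits|^w (w = 1 by default; w = 0 gives the classic
unweighted KS statistic, invariant under monotone metric transforms) and
non-members subtract 1/(N − N_h); ES is the extreme of the running sum,
the leading edge the members at or before it (after it, for negative ES).
The null redraws each set's members uniformly from the ranked identifiers
(**gene-label permutation** — the natural null when the input is already a
preranked statistic; sample permutation would require the underlying
replicate data).  Nominal p uses same-sign nulls with add-one smoothing,
(1 + #{|null| ≥ |ES|})/(1 + #same-sign) — valid by construction, floored
at ~1/#same-sign, hence `n_perm` ≥ 100 enforced and 1000 the default.
NES = ES / mean|same-sign null ES|; FDR compares the null and observed NES
tails sign-stratified, clipped to [0, 1]; sets with FDR < 0.05 are flagged
enriched.

## Survival and drug association

The signature score is the unweighted mean expression of the available
signature genes (missing genes logged, not fatal).  The **median split**
sends scores strictly above the median to "high" and everything else to
"low": ties cannot be split and a deterministic rule beats a random one;
assigning them low matches the common survival-plotter convention.
Constant scores abort.

Arms are compared with the product-limit estimator, the two-sample
log-rank test (1 df, two-sided) and a univariate Cox PH fit on the arm
indicator with **Efron tie handling** (better than Breslow under moderate
ties, the standard default), CI = exp(β ± 1.96·SE).  These are standard
fits and are delegated to `lifelines`; the test suite checks the log-rank
against a hand 2×2-table computation and Cox against planted-parameter
recovery.  Note the planted hazard coefficient in the simulator is per
standard deviation of the continuous score; the dichotomized arm contrast
estimates a larger quantity (the mean |z| gap between arms is ≈ 1.6 SD),
so parameter-recovery checks use the continuous-covariate fit
(`cox_univariate`) and the arm-based HR is reported as what it is.

Drug association: per gene × drug, OLS of response on expression across
cell lines (≥ 3 required), F = (R²/(1 − R²))(n − 2) with p from F(1, n−2)
— identical to the squared slope *t* — and a significance flag at
p < 0.01.  Zero-variance predictors yield NaN and are never significant.
Under a null panel the flag rate is calibrated (measured ≈ 0.010 over
5000 genes).

## Synthetic data

Each generator plants known truth and is bit-reproducible under a fixed
seed:

- **Proteins**: log-normal abundances; base log₂ level ~ N(20, 2);
  replicate noise σ(log₂) = √ln(1 + cv²)/ln 2 from `noise_cv`; a
  `de_fraction` of proteins get the treated mean shifted by ±U(range)
  log₂ units; unique-peptide counts Poisson(6); 98% high-confidence;
  optional MAR (uniform) or MNAR (rank-weighted toward low abundance)
  missingness, off by default.
- **Membranes**: per-analyte normalized level 2^N(−2, 1.5) capped below
  the POS scale, background 0.05, planted fold changes applied to treated
  membranes, multiplicative log-normal spot noise; with zero noise the
  normalized treated/control ratio equals the planted fold change exactly.
- **miRNA counts**: relative abundances exp N(3, 1.5) normalized to
  proportions, integer library sizes uniform in `library_size_range`,
  counts NB with common dispersion φ (`nb_dispersion`, default 0.1;
  variance μ + φμ²; Poisson when φ ≈ 0).
- **Survival**: hazard h₀·exp(β·z) with z the standardized signature
  mean, exponential event times, independent uniform censoring at the
  configured rate.
- **Cell-line panel**: one planted driver gene per drug; response =
  slope·expression + intercept + N(0, noise); pure noise under the null.

Defaults are the study design where stated (3 replicates per proteomics
group, 2 membranes per condition, an intensity floor of 0.01, 20-line
drug panels) and conventions where not: `noise_cv = 0.15` is a typical
replicate-level CV for label-free secretome intensities, `nb_dispersion
= 0.1` a typical small-RNA biological dispersion, and library sizes of
~10⁶ a typical miRNA-seq depth.  No published replicate-noise value
exists to anchor these, so they are documented choices, fixed once.

What the generators do **not** emulate: raw spectra or peptide-level
rollup, spot segmentation from membrane images, read-level sequencing
artefacts (adapter content, mapping multiplicity), correlated missingness
between replicates, batch structure, non-proportional hazards, and
correlated gene–gene expression in panels.  Passing tests therefore
demonstrate that the statistics are implemented correctly and behave as
designed under their assumed models — not that those models capture every
property of real instrument output.

## Numerical conventions

- BH step-up: computed in one vectorized pass (sorted p·m/rank with a
  reverse cumulative minimum); NaN p-values propagate and do not count
  toward m; p outside [0, 1] is an error.
- All fold-change gates are strict inequalities; symmetric gates use
  max(r, 1/r).
- Trigamma inversion by log-space bisection to 10⁻⁸ relative width.
- lowess trend values are clipped below at 10⁻⁶ before the ⁻4 power; a
  flat-variance input short-circuits to a constant trend.
- PCA orientation: largest-|loading| protein positive per component.
- Ranking ties: lexicographic by identifier, everywhere.
- Cox fits: lifelines defaults (Efron ties, Newton–Raphson).
- Every permutation or simulation consumes an explicit integer seed; the
  acceptance script derives per-stage sub-seeds from a single `--seed`.

## Problem sizes

The simulated checks use 2000 features × 10 seeds for null calibration,
2000 proteins for cascade recovery, 2000 samples for hazard recovery and
5000 genes for regression calibration — sizes at which binomial 99%
confidence bands are a few per mil wide and planted-effect recovery is
stable, while the full suite and the acceptance script each run in
seconds on one core.

## Known limitations

- The hit-count defaults are conventions; published hit columns generally
  cannot be regenerated without the original thresholds.
- The ratio-variability formula is an analogue of, not a match for,
  proprietary label-free pipeline output; absolute cascade counts on real
  exports may differ at the variability stage.
- The voom trend follows the span-0.5 / 2-iteration lowess stated above;
  the R reference uses 3 robustness iterations, so p-values agree to
  ~10⁻³, not machine precision.
- Gene-label permutation undercorrects inter-gene correlation relative to
  sample permutation; FDRs on strongly correlated real panels will be
  anti-conservative, as for any preranked analysis.
- The exponential-hazard simulator cannot probe violations of
  proportional hazards.
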