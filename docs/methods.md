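# Methods

This note documents the statistical models implemented in `ewaskit`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and known limitations.

## Data model

Beta values β = M/(M+U) ∈ [0, 1] are the substrate of every stage;
matrices are probes × samples with `NA` as the on-disk missing token
and NaN internally. Annotation coordinates are 1-based inclusive
(array-manifest convention) and converted to 0-based half-open only
when writing BED. The sample sheet's order is canonical: matrices are
reindexed to it on load, which removes a whole class of silent
misalignment bugs. All downstream computations are pairwise-complete
in the presence of missing values.

## QC

Samples are dropped when strictly more than 5 % of their probes have
detection p > 0.05; probes are dropped when strictly more than 10 % of
samples fail them; surviving individual failed calls are set to
missing. Blacklist masking removes probes flagged for SNP overlap,
cross-hybridization, or sex-chromosome location (flags are an input —
`ewaskit` does not ship a manifest).

Multimodal (genotype-like) probes are flagged by one-dimensional
density clustering of each probe's β values: maximal runs of sorted
values whose consecutive gaps are ≤ ε = 0.05 form clusters (the 1-D
specialization of neighborhood-density clustering); a probe is flagged
when ≥ 2 clusters each hold ≥ 10 % of samples and their medians are
≥ 0.25 apart. The ε, cluster-fraction and separation parameters are
deliberately config-exposed: there is no canonical parameterization
for this filter, and the defaults are chosen to catch the
well-separated 50/50 clusters that polymorphism-driven probes produce
while never flagging a unimodal probe with realistic noise. Probes with
fewer than 5 non-missing values are never flagged.

## Cell deconvolution

Fractions solve the simplex-constrained least-squares problem per
sample. The solver is a primal active-set method on the non-negativity
bounds with the equality constraint handled in each KKT subproblem —
deterministic and exact to machine precision for ≤ a few dozen cell
types, which is why it is preferred here over a generic iterative QP.
The sum-to-one equality (rather than ≤ 1) matches the convention of
reporting proportions. Noiseless mixtures are recovered exactly
whenever the reference has full column rank on the shared probes.

Group comparison gates on Shapiro–Wilk p ≥ 0.05 in *both* groups:
normal → Welch t-test, otherwise Wilcoxon rank-sum. Welch is used
(rather than the pooled-variance t) because it is uniformly safer at
n ≈ 20/group and changes nothing when variances are equal. The Welch
95 % CI of the mean difference is reported for every cell type
regardless of which test ran, and BH-FDR is applied across cell types.

## Clocks and acceleration

A clock is `score = intercept + Σ w_j β_j` over its coefficient file,
optionally transformed by `age = (1+a)·exp(y) − 1` for y < 0 and
`(1+a)·y + a` for y ≥ 0 with adult-age knot a = 20 — the standard
calibration for pan-tissue clocks trained on log-linear age. Missing
clock probes are imputed with the cohort mean β (configurable:
error / mean); fewer than 50 % present is an error. Composite
biomarkers that need non-β inputs are out of scope; the acceleration
machinery is clock-agnostic.

Acceleration is control-anchored: OLS of predicted on chronological age
fitted in controls only, residuals computed for the whole cohort
against that line. Control residuals therefore average exactly zero,
and the case–control residual difference is the acceleration contrast
(Welch t per clock, BH across clocks).

## SEM / epivariations

Fences per probe from controls: [Q1 − k·IQR, Q3 + k·IQR] with k = 3
and linear-interpolation quantiles (the default convention in both
major ecosystems; config-exposed because fences are sensitive to it).
Calls use strict inequalities and skip missing values; probes with
fewer than 8 non-missing control values are skipped.

Two properties of this construction matter at small control n:

- With ~20 controls the estimated fences are noisy, so the per-cell
  exceedance rate under pure Gaussian noise is ≈ 1–2 × 10⁻³, far above
  the ≈ 2.4 × 10⁻⁶ that ideal (large-n) ±4.7σ fences would give. SEM
  burdens in the thousands over array-scale probe counts are therefore
  expected even for perfectly clean samples.
- Controls are *in-sample* for the fences they define, cases are not;
  cases therefore carry systematically higher burden on otherwise
  exchangeable data. The `leave_one_out` option scores each control
  against fences built from the remaining controls, making both groups
  out-of-sample and removing the bias. It is off by default to match
  the plain control-population-range definition.

Burden is modeled as log10(n + 1) — counts are heavy-tailed and
multiplicative effects are the natural alternative — with samples
outside mean ± 3 SD of the transformed burden excluded before an OLS
on group + age + sex + cell fractions (one cell type dropped for
identifiability). Total, hypo and hyper burdens are modeled
separately. Whether the outlier test is applied to raw or transformed
burden is a genuine free choice; the transformed scale is used so a
single heavy-tailed sample cannot drag the fence it is judged by.

An epivariation is called per (gene, sample) when ≥ 3 genomically
consecutive CpGs of the gene are SEM-called in the same direction; the
enrichment p is the binomial upper tail of the gene's SEM count
against the sample's genome-wide SEM rate. The run-length rule and
enrichment test are a reconstruction of common practice in the
epivariation literature — no single canonical definition exists — so
both are config-exposed.

## DMP analysis

Per-probe OLS of β on intercept + group + age + sex + estimated cell
fractions (each covariate toggleable; β-scale modeling is the default
so the coefficient is directly comparable to the Δβ filter, with
M-scale available via `beta_to_m`). Complete-case probes share one
projection matrix; probes with missing values are re-fit on their
complete rows.

Variance moderation follows the classical empirical-Bayes shrinkage
scheme: residual variances are modeled as scaled-inverse-χ² around a
prior (d₀, s₀²) estimated by moment matching on log s² (digamma /
trigamma equations, trigamma inverted by Newton iteration); posterior
variances s̃² = (d₀s₀² + df·s²)/(d₀ + df) give moderated t with
df + d₀ degrees of freedom. Degenerate cases: identical variances →
no shrinkage (d₀ = ∞, s̃² = s², flagged); non-positive excess variance
→ complete pooling to s₀².

Empirical-null correction fits a 3-component Gaussian mixture to the
z-scores (moderated t mapped to z through matched tail probabilities)
by Gibbs sampling with conjugate updates: Dirichlet(1,1,1) on weights,
data-centred normal priors on locations (candidate null at the median,
signal components at median ± 3 robust SD — data-centred so the fit is
equivariant under shifts), inverse-gamma(2, MAD²) on variances. The
null is identified per retained iteration as the largest-weight
component; its posterior-mean location and scale are the bias μ̂ and
inflation σ̂, and adjusted z = (z − μ̂)/σ̂. Defaults 5000 iterations /
2000 burn-in; the seed is recorded in the diagnostics. λ =
median(z²)/0.4549 is reported before and after adjustment.

Tiers follow the two-filter convention: stringent q < 0.001 with
|Δβ| > 0.1; relaxed q < 0.05 with |Δβ| > 0.05, where Δβ is the
pairwise-complete difference of group means — probes below the relaxed
effect filter are labeled `none` regardless of q, since array effects
under 0.05 β are rarely interpretable.

## DMR analysis

The ACF of the association signal is estimated from the data: p → z =
Φ⁻¹(1−p), then per 50-bp distance bin up to 500 bp, the Pearson
correlation over all same-chromosome probe pairs at that distance
(pooled across chromosomes; bins with < 30 pairs are zeroed and
flagged). Each probe's p is smoothed by Stouffer–Liptak over its
± 500 bp window with correlations looked up from the bins: combined
z = Σz/√(ΣᵢⱼCᵢⱼ) (non-PD correlation matrices are repaired by
eigenvalue clipping; out-of-range p are clipped to [1e−300, 1−1e−16]).
Regions seed at smoothed p < 0.01, extend over probes < 0.05 with gaps
≤ 500 bp, and are re-scored on their members' original p-values. The
Šidák exponent uses the total bases covered by tested probes (per
probe, its distance to the next neighbor capped at the max gap) rather
than genome length, so the correction is computable from the inputs
alone. Combination is one-sided on association strength; the sign of
the mean member Δβ is reported separately and mixed-direction regions
are flagged. Window/seed/extension/gap/bin parameters have no
published canonical values and are config-exposed; the defaults follow
conventional usage of sliding-window combined-p DMR callers.

## ORA

Hypergeometric upper tail P(X ≥ k) for the overlap k between the query
genes and each set restricted to the universe, with enrichment ratio
k/(n·K/N) and BH across retained sets (default size window [5, 2000]).
The default universe is all genes annotated on surviving probes —
using the array universe rather than the whole genome avoids inflating
every enrichment. Only over-representation is tested.

## Synthetic cohorts: what they emulate, what they do not

Baseline probe means come from a 3-component beta mixture (modes
≈ 0.1 / 0.5 / 0.9, weights 0.45/0.10/0.45), reproducing the bimodal
marginal density of array β. Within-probe noise is Gaussian on the β
scale, clipped to [0, 1], default SD 0.03 — chosen for test power
(real within-group SDs vary per probe and are not published for this
design); beta-binomial noise, probe-type chemistry, batch/chip
effects and mQTL structure are *not* simulated. Ages are uniform on
[60, 87]; sex is balanced by construction. Cell-mixture probes are
convex combinations of U-shaped-beta reference profiles under
Dirichlet fractions (neutrophil-dominated α by default); clock probes
carry a linear age trend whose inverse defines an exact synthetic
clock; bimodal probes are 50/50 two-cluster mixtures ≥ 0.5 apart.
Injected effects (single-probe Δβ shifts, 5-probe clustered shifts at
50-bp spacing, per-subject Poisson epimutation outliers displaced by
0.4 away from the nearer boundary) are recorded in the `TruthSet`;
missingness and detection failures avoid injected coordinates so the
recorded truth stays observable. Passing recovery tests on these
cohorts demonstrates the statistical machinery is correct at the
study's design size; it does not demonstrate robustness to the
technical structure (batch, probe chemistry, cellular heterogeneity
beyond the simulated mixture) of real arrays.

Problem sizes used in the shipped tests — 50,000-probe cohorts for
recovery and 20-seed null-calibration checks, 100,000 probes for DMP
power and empirical-null recovery — are the package's chosen
simulation scale: large enough for stable λ, ACF and FDR estimates,
small enough to iterate on.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation everywhere (config-exposed for SEM).
- Strict inequalities at all "more than" thresholds and at SEM fences.
- Active-set deconvolution terminates on dual feasibility at 1e−10;
  degenerate references fall back to a clipped least-squares
  projection.
- Probes with fewer than rank+2 complete observations are left NaN in
  DMP fits; single-position DMR regions get footprint 1 bp; empty
  candidate lists and empty epivariation tables propagate as empty
  outputs, not errors.
- The pipeline fans one global seed into per-stage sub-seeds via
  SeedSequence spawn keys, so toggling one stage never changes
  another's randomness.

## Known limitations

- No IDAT parsing or normalization: the pipeline consumes β matrices.
- Reference-based deconvolution only; no reference-free or training
  mode.
- The empirical-null sampler assumes the null is the dominant mixture
  component; it will mis-identify the null if true associations exceed
  roughly a third of probes.
- With ~20 controls, SEM fences are noisy (see above): absolute SEM
  burdens are fence-estimation-dominated, and between-group burden
  contrasts require the leave-one-out option to be unbiased.
- Epivariation definitions vary across the literature; results under
  the shipped rule are not comparable across tools without aligning
  the rule first.
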