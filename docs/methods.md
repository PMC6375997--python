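# Methods

## Statistical model

The unit of measurement is the CpG site. For subject *i* and site *j*, the
input is a pair of read counts (methylated, unmethylated); the methylation
level is `m_ij = 100 · meth / (meth + unmeth)` percent, recomputed from the
counts whenever a file is read (the percent column of a coverage file is
treated as a checksum with 0.05 absolute tolerance, which accommodates
files rounded to one decimal).

Quality control follows the usual RRBS depth logic, with the two rules read
as: (1) a *cell* (subject × site) with fewer than `min_coverage = 10` reads
is unusable; (2) after that mask, a *site* usable in fewer than
`ceil(min_subject_fraction · n_subjects)` subjects (default fraction 0.5,
so 132 of 263) is excluded. The threshold is derived from the cohort size
rather than hard-coded, so the same rule scales to any cohort. The filter
is idempotent and the QC report conserves counts (input = retained +
excluded) by construction. Whether the depth rule should instead apply to a
site-level mean is genuinely ambiguous in the source description; the
per-cell reading is implemented and the alternative can be emulated by
pre-aggregating coverage.

Association is per-site ordinary least squares with BMI percentile as the
outcome and `m_ij / 10` as the exposure, so the reported coefficient is the
BMI-percentile change per 10% methylation — entering the rescaled regressor
directly is numerically identical to rescaling a per-1% coefficient but
keeps every downstream table on the reported scale. Covariates: age
(years), race as a white/other indicator (the cohort's dichotomy), sex as
a male indicator, and assay batch as fixed indicators with the first batch
as reference. Subjects missing the site are dropped for that site
(complete-case per site; no imputation, consistent with coverage-driven
missingness). A site is non-converged — carried in the output but excluded
downstream — when fewer than `k + 2` usable subjects remain, the design is
rank-deficient, or methylation is constant. Two-sided p-values come from
the t distribution with the residual degrees of freedom.

The engine is a hand-written least-squares fit (QR solve, textbook
covariance) rather than a statsmodels call because the suite routinely fits
10⁴–10⁵ site models; statsmodels.OLS is retained in the tests as an
independent oracle and agrees to 1e-10 relative. Sites with no missing
cells share one covariate design, so they are fit in a single vectorized
pass by projecting the outcome and all methylation columns off the
covariates first (Frisch–Waugh–Lovell); the per-site path is only taken for
incomplete sites, and the two paths are tested for exact agreement.

The genomic inflation factor is
`λ = median(F⁻¹_{χ²₁}(1 − p)) / 0.4549364`, i.e. the median association
χ² statistic over the χ²₁ median; λ = 1 exactly when the median p is 0.5.

## Enrichment

The universe is the converged intragenic sites. Intragenic means inside a
gene's annotated span, inclusive at both bounds, with no promoter or flank
extension; a site overlapping several genes belongs to all of them but
counts once in site tallies. Significance for the 2×2 table is strict
`p < 0.05` (a tie at exactly 0.05 is non-significant). The obesity gene set
is the packaged 50-gene fixture (gene–disease reliability score ≥ 0.20);
matching is case-insensitive.

The hypergeometric test is the one-sided upper tail `P(X ≥ k)` including
the observed value, computed as `logsumexp` of `hypergeom.logpmf` over the
tail support — exact at any universe size up to 10⁷ without underflow. The
permutation test re-draws the K obesity-site labels uniformly without
replacement B times (default 10,000) and uses the add-one estimator
`(1 + #{overlap ≥ k}) / (B + 1)`, which has resolution 1/(B+1) and can
never report zero. Site-label resampling is the default unit: its null is
exactly the hypergeometric sampling model, so the two tests converge and
cross-validate. Because CpGs within a gene are correlated, a gene-label
permutation (permute obesity/background labels over genes, recount sites)
is offered as an option; on a one-site-per-gene universe it reduces to the
site unit, which is how it is tested.

## Multiple testing

Two Bonferroni families are reported: genome-wide (α divided by the number
of converged intragenic sites) and within the obesity set (α divided by
the number of obesity-flagged sites). Printed thresholds are formatted to
two significant figures; all comparisons use full precision.
Benjamini–Hochberg q-values are the step-up minima `min_{j≥i} p_(j)·m/j`;
the family size m may exceed the number of supplied p-values, for ranked
tables that list only the smallest members of a family — valid under the
precondition that every unlisted p exceeds the largest listed one. The
top-site table uses the within-set family for both q-values and the
Bonferroni flag.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, at
a configurable scale; the defaults are the study conditions (263 subjects,
20,000 sites at desk scale).

Demographics: age is truncated normal (mean 16.7, SD 2.2, range 12–23;
truncation shrinks the realized SD to ≈ 1.9 — accepted, since the mean and
the covariate role are what matter downstream); sex is Bernoulli(0.559
male), race Bernoulli(0.787 white), batch round-robin over 4 batches.

Genome: one linear pseudo-chromosome partitioned into `n_genes`
equal-length genes (2 kb) separated by equal gaps sized so that a fraction
`frac_intergenic = 0.38` of the genome is intergenic (the intragenic share
of analyzable sites in the motivating study is ≈ 0.62). Obesity genes are
named from the packaged fixture and placed uniformly; genes named in
`effect_sites` are always included. Sites are uniform over the genome,
with one dedicated site per injected effect spread across its gene body.

Methylation: each site has a baseline probability from a three-component
beta mixture — weights 0.45 / 0.45 / 0.10 on Beta(1.5, 15) (low),
Beta(15, 1.5) (high) and Beta(5, 5) (intermediate) — the canonical bimodal
CpG marginal. Subject-level probabilities are Beta-distributed around the
baseline with concentration 40 (15 at effect sites, whose baselines are
drawn uniform on [0.3, 0.7] so the exposure has usable variance). Read
depth is negative binomial with dispersion 2 around a per-site mean that is
lognormal (σ = 0.6) around `coverage_mean = 30`; dispersion = ∞ gives the
Poisson limit. Methylated counts are binomial. With these defaults the
expected sub-10x cell fraction is 0.19 (`missing_target`), and the
realized missingness is checked against the target within ±0.05; the
target is a declared property of the coverage defaults, not an enforced
knob, so changing the coverage parameters without revisiting it will break
that agreement.

Outcome: `BMI = baseline + covariate terms + Σ_e β_e x_e/10 + N(0, noise_sd²)`,
clamped to [0.5, 99.5]. Three choices deserve note:

* `noise_sd = 25` makes the published effect magnitudes detectable at
  n = 263 with per-site SEs around 1.3–1.7, matching the reported scale;
  no variance decomposition exists to take it from.
* The effect term couples to the *measured* methylation percent at
  QC-passing cells (centered on the site's expected level) and to the
  latent probability at unusable cells. This makes the injected per-10%
  coefficient exactly the estimand of the downstream regression — with the
  effect on the latent scale, binomial read noise at ~30x attenuates the
  fitted slope by a factor of 0.4–0.7 and no recovery guarantee could
  hold. Missingness depends only on read depth, never on the outcome, so
  the missingness-bias check retains a true null.
* The clamp censors roughly 5–14% of subjects depending on the outcome SD,
  and censored OLS is attenuated by a few percent. The ±3 SE recovery
  guarantee holds under the default clamp (99.5% of 200 replicates); the
  strict unbiasedness check (mean recovery within ±0.5 of 7.2) is run with
  the clamp inactive, because attenuation under censoring is a property of
  the truncated outcome, not of the estimator.

Default injected effects are 15 sites on 11 obesity genes with per-10%
effects between −4.4 and 8.0, mirroring the precisely estimated entries of
the motivating study's top table (7.2 and 3.8 on SIM1, 4.0 on CPE, −4.4 on
RMST, 3.7 on ADRB3, 7.8–8.0 on GLUL, 4.5 on CYP2E1). That table's extreme
coefficients (≈ ±30–39) belong to near-constant sites whose variance this
generator does not emulate; those genes carry effects of magnitude ~5
instead.

What the generator does *not* emulate: real genome annotation (gene sizes,
CpG islands/shores, chromosome structure), sequence context, cell-type
mixture, spatial correlation between neighbouring CpGs, and informative
missingness. Passing tests therefore demonstrate the correctness and
calibration of the pipeline's inference machinery under its own
assumptions, not robustness to those real-data features. One scale caveat:
with 50 obesity genes among ~1,200, obesity-gene sites are ~4% of the
desk-scale universe versus ~0.3% in the real annotation, so desk-scale
enrichment p-values are less extreme than full-scale ones for the same
injected signal.

## Determinism and numerics

All randomness flows from `numpy.random.default_rng` seeded via
`SeedSequence([seed, stage])`, one independent stream per generation
stage; the same seed yields byte-identical cohort files (checksum-tested).
The permutation test and the pipeline are pure functions of (inputs,
seed). Percent/count consistency tolerance is 0.05 absolute; the
complete-block OLS path flags a site degenerate when its residual exposure
sum of squares falls below `1e-12 · n`; Mann-Whitney uses exact
enumeration when both groups have ≤ 8 subjects and are tie-free, and the
tie-corrected normal approximation otherwise.

## Problem sizes used in the test and acceptance suites

Unit tests run at 8–150 subjects and ≤ 5,000 sites. The calibration checks
use 263 subjects with 10,000 fully observed sites (global null: KS
uniformity, λ ∈ [0.9, 1.1], background significant fraction 0.05 ± 0.01)
and 200 replicates of a single injected 7.2 effect. These sizes were
chosen as the smallest at which the distributional checks are stable; all
thresholds above are stated before the corresponding checks in the suite
and are not tuned to them.
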