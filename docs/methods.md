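# Methods

This note documents the models, conventions and design choices behind
`coastnis`, in the order the pipeline applies them.

## Study design and data model

The unit of analysis is a coastal sampling site.  Each site carries a
response — the proportion of non-indigenous species (NIS) among the species
found there — and candidate drivers in three groups: *vectors* that deliver
propagules (aquaculture, maritime traffic, distance to the nearest port),
*promoters* that ease establishment (substrate artificiality, pollution and
freshwater proximity, algae cover, wave exposure), and *protection*
(restrictions on extractive coastal uses) at three spatial scales: the
site's own tier, a 10-km window, and a ~60-km regional window.

Site tables are ordered; the order is significant because the Durbin-Watson
diagnostic operates on residuals in table order.  Missing cells are
rejected rather than imputed.  Mixed measurement scales (kilometres,
proportions, bounded Likert-style scores) are declared per column in a
sidecar so downstream code can tell them apart.

The packaged survey (`packaged_table1`) has 30 sites: 16 on Moorea and 14
on Vancouver Island.  The east/west assignment of the Vancouver sites —
needed for regional subset re-analysis but not part of the site table — is
shipped as an overridable YAML sidecar (`data/regions.yaml`): the eight
Strait-of-Georgia sites are east, the six outer-coast sites west.  The
site-level diversity cells in the packaged table are survey data; their
underlying raw abundance counts are not available, so those two columns are
treated as inputs, not recomputation targets.

## Scores

**Aquaculture vector (AqV).**  `Σ X·Farm` over farms within a radius
(default 10 km), with species status weight X = 1 (native), 2 (exotic), 3
(listed invader).  Status weights are user input; there is no registry
lookup.  Raw AqV values are normalized across the survey by the
max-anchored map `5·x/max(x)`, chosen over min–max because the vector has a
natural zero that must stay zero (and because the packaged survey's scaled
cells are exactly reproduced by it: one native farm against a survey
maximum of 63 gives 5/63 = 0.0794).

**Weighted protection (PS).**  Coastline geometry is abstracted to 1-D
segment lists; the score only needs lengths, levels and ages.  Levels are
1/2/3/5 — the jump from 3 to 5 encodes how many more extractive uses are
allowed outside full MPAs.  Without duration the score is the
length-weighted mean level (bounded [1, 5], invariant to splitting
segments, monotone in any segment's level).  With duration it is
`Σ level·age·length / window` in standardized protection-years per km.
Duration is measured in decades, so a young MPA system (~1 decade) and an
old one (~3 decades) sit on comparable axes.  For an island whose perimeter
is shorter than the nominal regional window, the perimeter is the window.

## Diversity

Margalef's d = (S−1)/ln N and Simpson's 1−λ.  Simpson defaults to the
small-sample unbiased form 1 − Σn(n−1)/(N(N−1)) (the convention of the
PRIMER-style software used for intertidal surveys); the plugin form
1 − Σp² is available and the two converge at large N.  Note the unbiased
form reaches exactly 1 for an all-singleton sample; the plugin form is
strictly below 1, which is why the synthetic generator uses it for the
bounded `simpson` column.  NIS proportions are reported at both the species
level and the individual level; they answer different questions and are not
interchangeable.

## Statistical layer

* **Correlation screen.**  Pearson r with t = r√((n−2)/(1−r²)) on n−2 df,
  two-sided.  A seeded permutation p (default 9,999 shuffles, add-one
  estimator (b+1)/(m+1)) accompanies the parametric p.  The Bonferroni
  threshold is α/m with m the *declared* family size (12
  response-vs-covariate tests in the default pipeline), not a hard-coded
  constant.
* **MLR.**  OLS via statsmodels; the overall test is the ANOVA-type
  F = (SSR/k)/(SSE/(n−k−1)).  Rank-deficient designs raise an error naming
  the collinear columns; an exact fit reports F = +∞ rather than a spurious
  number.
* **Bivariate GLM.**  Normal family, identity or log link.  Identity
  reproduces OLS exactly.  The log link is fit by IRLS with a guarded
  start (log of the positive-clipped linear fit) so fitted means stay
  positive even when the response touches zero.  Dispersion is
  φ̂ = deviance/(n−2).  The G statistic is the scaled deviance difference
  (D₀−D₁)/φ̂ against the intercept-only model, referred to χ²₁; under the
  identity link G equals the squared slope t.  This estimated-dispersion
  form was chosen over the profiled-likelihood ratio 2(ℓ₁−ℓ₀) = n·ln(D₀/D₁)
  because it is the convention of the desktop statistics packages this
  analysis is meant to be comparable with, and it reproduces their printed
  G values exactly on the packaged survey.
* **Diagnostics.**  Durbin-Watson DW = Σ(eₜ−eₜ₋₁)²/Σeₜ², in [0, 4].  Its
  p-value is computed by seeded permutation of the residual order
  (two-sided on |DW−2|) rather than the normal approximation, which is
  unreliable at n ≈ 30.  Note the finite-n mean of DW for an exchangeable
  sequence is 2(n−1)/n, slightly below 2.  Breusch-Pagan is the n·R² LM
  form on χ²_k; Shapiro-Wilk checks residual normality.

## PCA and outlier screening

PCA is an eigendecomposition of the correlation matrix (so results are
invariant to affine rescaling of columns and the eigenvalues sum to the
number of variables).  Component signs are fixed by making each component's
largest-magnitude loading positive; signs are otherwise arbitrary and are
not a comparison target.  Eigenvalue confidence limits come from a seeded
percentile bootstrap over sites (default 1,000 resamples; degenerate
resamples with a constant column are redrawn).  Caveat: resampled
correlation spectra are over-dispersed, which biases *trailing* eigenvalues
downward — percentile intervals are reliable for the leading, interpreted
components only, and that is where the package asserts them.

Outlier screening formalizes a visual call into a reproducible rule: sort
the variable, find its largest gap, and flag the smaller side when the gap
exceeds `gap_factor` (default 1.5) × IQR of the remaining values; peel and
repeat.  This catches a detached group at either extreme (e.g. two sites
3–10× farther from any port than the rest) while flagging nothing for
evenly spread values.  Fewer than 5 sites: refuse rather than guess.

## Pipeline conventions

The correlation screen runs on *all* sites; outliers are removed only for
the model-fitting stages (the screen's df therefore reflect the full n
while the regressions use n minus the flagged sites).  The diversity
indices are excluded from the global predictor set because they fail the
row-order autocorrelation check against the response on the packaged
survey; the pipeline records that check in its report rather than deciding
silently.  The default predictor set is the 12 remaining covariates.  The
local-protection predictor is the site's printed tier column; a
status-times-age product can be studied through the scoring module's
`include_duration` option.

Regional subsets re-use the global predictor list; columns that are
constant or exactly collinear within a subset are dropped and recorded
(e.g. the regional-scale protection score is constant within Moorea).
Subsets keep all their sites by default — the outlier screen belongs to the
global model — with a config switch to change that.  Every stochastic stage
draws a child seed from the single pipeline seed via `SeedSequence`, so a
report regenerates byte-identically from its provenance block
(`run_from_provenance`).

## Synthetic surveys

The generator emulates the study conditions: 30 sites in three coastal
regions (16 + 8 + 6) differing in protection-level mix, protection age
(~1 decade vs ~3 decades) and farm intensity (concentrated in one region);
a protection mosaic of exponential-length segments tiling each 10-km and
60-km window, scored by the same `weighted_protection` code used for real
data; farm counts Poisson-thinned by local protection and scored by
`aquaculture_vector`; and the response

    nis_prop = clip(β₀ + β_ps·status_local + β_aq·aquaculture
                    + β_sub·substrate + ε),  ε ~ N(0, σ²)

with defaults β₀ = 0.40, β_ps = −0.05 (per protection level),
β_aq = +0.03 (per unit of the 0–5 aquaculture scale), β_sub = +0.01,
σ = 0.04.  The response is modelled linearly on the proportion scale —
matching the analysis machinery — with defaults placed so the linear
predictor stays interior to [0, 1] (clipping is therefore rare and
recorded in the truth record); a logistic response option exists for
robustness studies.  Abundance tables are multinomial samples of ~100
individuals (the survey's design size) from Dirichlet-distributed
communities, each species flagged NIS with probability equal to the site's
generated invasion pressure; the `with_abundances=False` switch skips the
community draws for high-replicate recovery studies.

What passing tests on synthetic data do show: the estimators are unbiased
(< 10% bias on the protection and aquaculture effects over 1,000
replicates), confidence intervals cover at their nominal rate (95% ± 3%),
the type-I error for a null protection effect is controlled (5% ± 2%), and
the full pipeline flags the true drivers with the correct signs in ≥ 95% of
strong-effect replicates.  What they do not show: behaviour under spatial
autocorrelation along the coast, zero-inflated responses piling up at
nis = 0 (common in real surveys), or ecological interactions between
species — none of which the generator emulates.

## Problem sizes and numerical choices

Statistical checks in the test suite use 200–1,000 replicates of 30-site
surveys, permutation counts of 10³–10⁴ and bootstrap counts of 25–1,000
depending on the stage; these sizes make the Monte-Carlo error comfortably
smaller than the asserted tolerances while keeping the suite quick on a
laptop.  Degenerate inputs are handled explicitly rather than numerically:
zero-variance vectors, constant covariates, exact fits (F = +∞), all-zero
rescaling inputs, windows not tiled by their segments, and sub-5-site
outlier screens all raise or return documented values.

## Known limitations

* The two printed diversity columns of the packaged survey cannot be
  recomputed bit-exactly (their raw counts are unpublished); they are
  carried as data.
* The percentile bootstrap's trailing-eigenvalue bias (above).
* The gap rule is univariate; a multivariate outlier (unusual only in
  combination) would pass the screen.
* The permutation Durbin-Watson p has resolution 1/(n_perm+1); extremely
  small p-values saturate at that floor.
* No spatial statistics: sites are treated as exchangeable units, and any
  residual spatial structure shows up only through the order-based
  autocorrelation check.
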