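# coastnis

Do coastal marine protected areas (MPAs) carry fewer non-indigenous species
(NIS)?  `coastnis` is a Python library for answering that question with
site-comparison surveys: it scores invasion *vectors* (aquaculture, maritime
traffic) and coastal *protection* at several spatial scales, summarizes
community samples with diversity indices, and runs a robustness-oriented
statistical pipeline — correlation screening with Bonferroni and permutation
tests, correlation-matrix PCA with bootstrapped eigenvalues, gap-based
outlier removal, multiple linear regression, bivariate normal-family GLMs,
Durbin-Watson / Breusch-Pagan / Shapiro-Wilk diagnostics, and regional
subset re-analysis.

A fully transcribed 30-site survey of two very different Pacific islands —
Moorea (French Polynesia, 16 sites) and Vancouver Island (Canada, 14 sites,
split into a heavily farmed east coast and an outer west coast) — ships with
the package, so the whole analysis is runnable out of the box.  A synthetic
survey generator with known ground truth makes every stage testable and
supports parameter-recovery studies.

## The scores and models at the core

**Aquaculture vector value.**  For cultivated species *i* with status
weight $X_i$ (1 native, 2 exotic, 3 listed invader) and $\mathrm{Farm}_i$
farms within 10 km of a site,

$$\mathrm{AqV} = \sum_i X_i \cdot \mathrm{Farm}_i ,$$

then rescaled across the survey onto 0–5 with zero anchored at zero.

**Weighted protection status.**  A coastal window is a list of segments with
protection level $PL_i \in \{1,2,3,5\}$ (1 = unprotected … 5 = full
MPA/national park), age $t_i$ (decades) and length $km_i$:

$$PS = \frac{\sum_i PL_i \, t_i \, km_i}{\sum_i km_i}$$

(duration optional; without it the score is the length-weighted mean level,
bounded in [1, 5]).

**Diversity.**  Margalef richness $d = (S-1)/\ln N$ and Simpson's index
(unbiased $1-\sum n_i(n_i-1)/N(N-1)$ or plugin $1-\sum p_i^2$).

**Models.**  NIS proportion is regressed on 12 site covariates; the overall
test is $F = (SSR/k)\,/\,(SSE/(n-k-1))$.  Each covariate is also fit alone
as a normal-family GLM (identity or log link) whose $G$ statistic is the
scaled deviance difference against the intercept-only model,
$G = (D_0 - D_1)/\hat\varphi$ with $\hat\varphi = D_1/(n-2)$, referred to
$\chi^2_1$.

## Worked example

```bash
python examples/reproduce_survey_analysis.py
```

prints (abridged):

```
Bonferroni threshold 0.05/12 = 0.0042
significant in the 30-site screen:
  status_local  r = -0.601  P = 0.00045  (perm P = 0.0020)
  aquaculture   r = +0.673  P = 0.00005  (perm P = 0.0020)

diversity indices autocorrelate with NIS in row order (DW = 0.711 richness,
0.762 Simpson) -> kept out of the model

PCA: first four components carry 65.0% of the variance (23.2%, 17.4%, 14.0%, 10.4%)
outliers removed before modeling: V-CB, V-LB -> n = 28

MLR: multiple R = 0.913, R2 = 0.834 (adj 0.702), F = 6.298 (df 12, 15), P = 0.0006
  status_local  b = -0.076  t = -3.909  P = 0.0014
  aquaculture   b = +0.071  t = +3.214  P = 0.0058

regional subsets (local-protection GLM slope, always negative):
  Vancouver W + Moorea   N = 22  slope = -0.0428  G = 14.656  P = 0.00013
  Vancouver E + Moorea   N = 24  slope = -0.0817  G = 17.729  P = 2.5e-05
  Vancouver Island       N = 14  slope = -0.0863  G =  4.608  P = 0.032
  Moorea                 N = 16  slope = -0.0536  G = 15.137  P = 0.0001
```

Reading it: of the 12 candidate drivers only local protection (negative)
and aquaculture (positive) survive the Bonferroni screen; the same two terms
carry the multiple regression after the two port-remote beaches (China
Beach, Long Beach) are excluded; and the protection effect keeps its
negative sign in every regional subset — the pattern is not an artifact of
pooling two very different islands.

Other entry points: `examples/score_a_coastline.py` (the scoring formulas on
a worked 10-km window), `examples/diversity_from_abundances.py` (indices
from a raw abundance table), `examples/synthetic_recovery.py` (bias and
confidence-interval coverage on synthetic surveys with known truth).

## Layout

| module | contents |
|---|---|
| `coastnis.dataset_io` | `SiteRecord` / `StudyDataset`, CSV I/O, packaged survey, regional subsetting |
| `coastnis.scoring` | aquaculture vector, weighted protection, Likert rescaling |
| `coastnis.diversity` | abundance tables, Simpson, Margalef, NIS proportions |
| `coastnis.stats_models` | Pearson + permutation, Bonferroni, MLR, normal GLM, diagnostics |
| `coastnis.pca_outliers` | correlation-matrix PCA with bootstrap, gap-based outlier screen |
| `coastnis.pipeline` | full-study orchestration, regional subsets, reproducible reports |
| `coastnis.synthetic` | two-region survey generator with known ground truth |

Methodological details, parameter defaults and known limitations:
[docs/methods.md](docs/methods.md).
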