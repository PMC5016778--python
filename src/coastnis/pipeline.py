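"""Full-study orchestration: screen → PCA/outliers → models → regional subsets.

Stage order mirrors the study design:

1. **Correlation screen** of the response (NIS proportion) against every
   candidate predictor on *all* sites, with a Bonferroni threshold over the
   declared family.
2. **Diversity screen**: correlations among the diversity measures and the
   Durbin-Watson autocorrelation check of NIS against each diversity index
   (in dataset row order).  Diversity indices are kept out of the global
   predictor set because they fail this autocorrelation check on the survey
   data.
3. **PCA** (correlation option, bootstrapped eigenvalues) over the screen
   variables, and the **gap-based outlier screen** on distance-to-port.
4. **Multiple linear regression** of NIS on the 12 predictors with outliers
   removed, plus per-predictor bivariate GLMs (normal family) and
   diagnostics.
5. **Regional subset re-analysis** with the same predictor list, dropping
   per-subset constant/collinear columns explicitly.

Every stochastic stage (permutation p-values, bootstrap) draws its own
stream from the single pipeline seed, so a report is reproducible from its
provenance block alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .dataset_io import StudyDataset
from .exceptions import ValidationError
from .pca_outliers import PcaResult, flag_outliers, pca_correlation, remove_outliers
from .stats_models import (
    GlmResult,
    MlrResult,
    bonferroni,
    durbin_watson,
    fit_glm_normal,
    fit_mlr,
    fit_ols,
    pearson,
)

#: The 12 global model predictors (diversity indices intentionally absent).
DEFAULT_PREDICTORS = (
    "status_local",
    "status_10km",
    "status_60km",
    "dist_port_km",
    "dist_freshwater",
    "dist_pollution",
    "algae_cover",
    "wave_exposure",
    "traffic",
    "substrate",
    "aquaculture",
    "n_native",
)

#: The four regional subset re-analyses.
DEFAULT_SUBSETS = (
    ("Vancouver W + Moorea", ("VancouverWest", "Moorea")),
    ("Vancouver E + Moorea", ("VancouverEast", "Moorea")),
    ("Vancouver Island", ("VancouverEast", "VancouverWest")),
    ("Moorea", ("Moorea",)),
)


@dataclass
class PipelineConfig:
    response: str = "nis_prop"
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    diversity_columns: tuple[str, ...] = ("richness", "simpson")
    outlier_variable: str = "dist_port_km"
    gap_factor: float = 1.5
    glm_link: str = "identity"
    n_perm: int = 9999
    n_boot: int = 1000
    seed: int = 0
    subsets: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_SUBSETS
    remove_outliers_in_subsets: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["predictors"] = list(self.predictors)
        d["diversity_columns"] = list(self.diversity_columns)
        d["subsets"] = [[label, list(isl)] for label, isl in self.subsets]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        d["predictors"] = tuple(d.get("predictors", DEFAULT_PREDICTORS))
        d["diversity_columns"] = tuple(d.get("diversity_columns", ("richness", "simpson")))
        d["subsets"] = tuple(
            (label, tuple(isl)) for label, isl in d.get("subsets", DEFAULT_SUBSETS)
        )
        return cls(**d)


@dataclass
class SubsetResult:
    label: str
    islands: tuple[str, ...]
    n: int
    dropped_predictors: tuple[str, ...]
    mlr: MlrResult | None
    mlr_skip_reason: str | None
    glm_table: pd.DataFrame


@dataclass
class PipelineReport:
    correlations: pd.DataFrame
    bonferroni_threshold: float
    bonferroni_m: int
    diversity_screen: pd.DataFrame
    pca: PcaResult
    outliers: tuple[str, ...]
    n_modeling: int
    mlr: MlrResult
    glm_table: pd.DataFrame
    subsets: list[SubsetResult]
    provenance: dict

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "bonferroni": {
                "threshold": self.bonferroni_threshold,
                "m": self.bonferroni_m,
            },
            "correlations": self.correlations.to_dict(orient="records"),
            "diversity_screen": self.diversity_screen.to_dict(orient="records"),
            "pca": {
                "variables": list(self.pca.variables),
                "eigenvalues": self.pca.eigenvalues.tolist(),
                "percent_variance": self.pca.percent_variance.tolist(),
                "eigenvalue_ci": None
                if self.pca.eigenvalue_ci is None
                else self.pca.eigenvalue_ci.tolist(),
                "loadings": self.pca.loadings.round(10).to_dict(orient="index"),
            },
            "outliers": list(self.outliers),
            "n_modeling": self.n_modeling,
            "mlr": _mlr_to_dict(self.mlr),
            "glm": self.glm_table.to_dict(orient="records"),
            "subsets": [
                {
                    "label": s.label,
                    "islands": list(s.islands),
                    "n": s.n,
                    "dropped_predictors": list(s.dropped_predictors),
                    "mlr": None if s.mlr is None else _mlr_to_dict(s.mlr),
                    "mlr_skip_reason": s.mlr_skip_reason,
                    "glm": s.glm_table.to_dict(orient="records"),
                }
                for s in self.subsets
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_markdown(self) -> str:
        lines = ["# Analysis report", ""]
        lines.append(
            f"Bonferroni threshold {self.bonferroni_threshold:.4f} "
            f"(m = {self.bonferroni_m})"
        )
        lines.append("")
        lines.append("## Correlation screen (all sites)")
        lines.append(self.correlations.to_markdown(index=False))
        lines.append("")
        lines.append("## Diversity screen")
        lines.append(self.diversity_screen.to_markdown(index=False))
        lines.append("")
        pct = self.pca.percent_variance
        lines.append(
            f"## PCA: first four components carry "
            f"{pct[:4].sum():.1f}% of the variance"
        )
        lines.append(
            f"Outliers removed before modeling: {', '.join(self.outliers) or 'none'}"
            f" (n = {self.n_modeling} sites retained)"
        )
        lines.append("")
        m = self.mlr
        lines.append("## Multiple linear regression")
        lines.append(
            f"multiple R = {m.multiple_r:.3f}, R² = {m.r2:.3f} "
            f"(adj {m.r2_adjusted:.3f}), F = {m.f_stat:.3f} "
            f"(df {m.df1}, {m.df2}), P = {m.p_overall:.4g}"
        )
        coef = pd.DataFrame(
            {
                "coefficient": m.coefficients,
                "SE": m.std_errors,
                "t": m.t_values,
                "P": m.p_values,
            }
        )
        lines.append(coef.to_markdown())
        lines.append("")
        lines.append("## Bivariate GLMs")
        lines.append(self.glm_table.to_markdown(index=False))
        for s in self.subsets:
            lines.append("")
            lines.append(f"## Subset: {s.label} (N = {s.n})")
            if s.dropped_predictors:
                lines.append(f"dropped predictors: {', '.join(s.dropped_predictors)}")
            if s.mlr is not None:
                lines.append(
                    f"MLR F = {s.mlr.f_stat:.3f} (df {s.mlr.df1}, {s.mlr.df2}), "
                    f"P = {s.mlr.p_overall:.4g}"
                )
            else:
                lines.append(f"MLR skipped: {s.mlr_skip_reason}")
            lines.append(s.glm_table.to_markdown(index=False))
        return "\n".join(lines) + "\n"


def _mlr_to_dict(m: MlrResult) -> dict:
    return {
        "response": m.response,
        "predictors": list(m.predictors),
        "coefficients": m.coefficients,
        "std_errors": m.std_errors,
        "t_values": m.t_values,
        "p_values": m.p_values,
        "intercept": m.intercept,
        "multiple_r": m.multiple_r,
        "r2": m.r2,
        "r2_adjusted": m.r2_adjusted,
        "f_stat": m.f_stat,
        "df1": m.df1,
        "df2": m.df2,
        "p_overall": m.p_overall,
        "nobs": m.nobs,
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage child seeds derived from the pipeline seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def screen_correlations(
    dataset: StudyDataset, config: PipelineConfig, seed: int
) -> tuple[pd.DataFrame, float, int]:
    """Response-vs-predictor Pearson screen with Bonferroni over the family."""
    frame = dataset.frame
    m = len(config.predictors)
    rows = []
    for i, var in enumerate(config.predictors):
        res = pearson(
            frame[var],
            frame[config.response],
            n_perm=config.n_perm,
            seed=seed + i,
        )
        rows.append(
            {
                "variable": var,
                "r": res.r,
                "df": res.df,
                "t": res.t_stat,
                "p": res.p_value,
                "p_perm": res.p_permutation,
            }
        )
    bf = bonferroni([row["p"] for row in rows], m=m)
    for row, sig in zip(rows, bf.significant):
        row["significant_after_bonferroni"] = bool(sig)
    return pd.DataFrame(rows), bf.threshold, m


def screen_diversity(
    dataset: StudyDataset, config: PipelineConfig, seed: int
) -> pd.DataFrame:
    """Correlations and row-order autocorrelation checks for the diversity
    indices; failing the Durbin-Watson check is the recorded reason the
    indices stay out of the global predictor set."""
    frame = dataset.frame
    rows = []
    pairs = [
        (config.response, col) for col in config.diversity_columns
    ] + [("richness", "n_native"), ("richness", "simpson"), ("simpson", "n_native")]
    seen = set()
    for a, b in pairs:
        if (a, b) in seen or a not in frame.columns or b not in frame.columns:
            continue
        seen.add((a, b))
        res = pearson(frame[a], frame[b])
        row = {"pair": f"{a}~{b}", "r": res.r, "df": res.df, "p": res.p_value,
               "dw": np.nan, "dw_p": np.nan}
        if a == config.response:
            ols = fit_ols(frame[b], frame[a])
            dw, dw_p = durbin_watson(ols.residuals, n_perm=config.n_perm, seed=seed)
            row["dw"], row["dw_p"] = dw, dw_p
        rows.append(row)
    return pd.DataFrame(rows)


def _glm_table(
    frame: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    link: str,
    n_perm: int,
    seed: int,
) -> pd.DataFrame:
    rows = []
    for i, var in enumerate(predictors):
        x = frame[var].to_numpy(dtype=float)
        y = frame[response].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue  # constant within this (sub)set; nothing to regress on
        glm = fit_glm_normal(x, y, link=link)
        ols = fit_ols(x, y)
        dw, dw_p = (
            durbin_watson(ols.residuals, n_perm=n_perm, seed=seed + i)
            if n_perm > 0
            else (durbin_watson(ols.residuals, n_perm=0)[0], np.nan)
        )
        rows.append(
            {
                "variable": var,
                "link": glm.link,
                "r2": ols.r2,
                "phi": glm.phi,
                "slope": glm.slope,
                "intercept": glm.intercept,
                "G": glm.g_stat,
                "p_slope": glm.p_slope,
                "ols_t": ols.t_values["x"],
                "dw": dw,
                "dw_p": dw_p,
            }
        )
    return pd.DataFrame(rows)


def _drop_unusable_predictors(
    frame: pd.DataFrame, predictors: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Drop constant columns, then any column still linearly dependent on the
    rest.  Returns (kept, dropped)."""
    kept = [p for p in predictors if frame[p].nunique() > 1]
    dropped = [p for p in predictors if p not in kept]
    # peel off exactly-collinear columns one at a time, last listed first
    while len(kept) >= 2:
        n = len(frame)
        design = np.column_stack(
            [np.ones(n)] + [frame[p].to_numpy(dtype=float) for p in kept]
        )
        if np.linalg.matrix_rank(design) == design.shape[1]:
            break
        for p in reversed(kept):
            others = [q for q in kept if q != p]
            d2 = np.column_stack(
                [np.ones(n)] + [frame[q].to_numpy(dtype=float) for q in others]
            )
            beta, *_ = np.linalg.lstsq(d2, frame[p].to_numpy(dtype=float), rcond=None)
            if np.allclose(d2 @ beta, frame[p], atol=1e-10):
                kept.remove(p)
                dropped.append(p)
                break
        else:  # pragma: no cover - rank deficiency without identifiable column
            break
    return kept, dropped


def run_subsets(
    dataset: StudyDataset, config: PipelineConfig | None = None
) -> list[SubsetResult]:
    """Re-fit the MLR and bivariate GLMs in each regional subset.

    The predictor list matches the global model; columns that are constant
    or collinear within a subset are dropped and recorded.  The subsets keep
    all their sites by default (the outlier screen concerns the global
    model); set ``remove_outliers_in_subsets`` to change that.
    """
    config = config or PipelineConfig()
    seeds = _stage_seeds(config.seed, 8)
    results = []
    for j, (label, islands) in enumerate(config.subsets):
        sub = dataset.subset(islands)
        frame = sub.frame
        if config.remove_outliers_in_subsets:
            out = flag_outliers(sub, config.outlier_variable, config.gap_factor)
            sub = remove_outliers(sub, out)
            frame = sub.frame
        kept, dropped = _drop_unusable_predictors(frame, config.predictors)
        mlr = None
        skip = None
        if len(frame) > len(kept) + 1 and kept:
            mlr = fit_mlr(sub, config.response, kept)
        else:
            skip = (
                f"n = {len(frame)} too small for {len(kept)} predictors "
                "(need n > k + 1)"
            )
        glm_tab = _glm_table(
            frame,
            config.response,
            kept,
            config.glm_link,
            config.n_perm,
            seeds[4 + j % 4] + j,
        )
        results.append(
            SubsetResult(
                label=label,
                islands=tuple(islands),
                n=len(frame),
                dropped_predictors=tuple(dropped),
                mlr=mlr,
                mlr_skip_reason=skip,
                glm_table=glm_tab,
            )
        )
    return results


def run_full(
    dataset: StudyDataset, config: PipelineConfig | None = None
) -> PipelineReport:
    """Run the whole analysis on one dataset.  Deterministic given the seed."""
    config = config or PipelineConfig()
    missing = [
        c
        for c in (config.response, *config.predictors)
        if c not in dataset.frame.columns
    ]
    if missing:
        raise ValidationError(f"pipeline: column(s) not in dataset: {missing}")
    seeds = _stage_seeds(config.seed, 4)

    corr, bf_threshold, bf_m = screen_correlations(dataset, config, seeds[0])
    diversity = screen_diversity(dataset, config, seeds[1])

    pca_vars = [config.response, *config.predictors]
    pca = pca_correlation(dataset, pca_vars, n_boot=config.n_boot, seed=seeds[2])

    outliers = flag_outliers(dataset, config.outlier_variable, config.gap_factor)
    modeling = remove_outliers(dataset, outliers)

    mlr = fit_mlr(modeling, config.response, list(config.predictors))
    glm_tab = _glm_table(
        modeling.frame,
        config.response,
        config.predictors,
        config.glm_link,
        config.n_perm,
        seeds[3],
    )
    subsets = run_subsets(dataset, config)

    provenance = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "n_sites_input": len(dataset),
        "outliers_removed": list(outliers),
    }
    return PipelineReport(
        correlations=corr,
        bonferroni_threshold=bf_threshold,
        bonferroni_m=bf_m,
        diversity_screen=diversity,
        pca=pca,
        outliers=tuple(outliers),
        n_modeling=len(modeling),
        mlr=mlr,
        glm_table=glm_tab,
        subsets=subsets,
        provenance=provenance,
    )


def run_from_provenance(dataset: StudyDataset, provenance: Mapping) -> PipelineReport:
    """Re-run the pipeline from a report's provenance block.

    Because every stochastic stage is seeded from the config, the regenerated
    report reproduces all statistics of the original exactly.
    """
    config = PipelineConfig.from_dict(provenance["config"])
    return run_full(dataset, config)
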