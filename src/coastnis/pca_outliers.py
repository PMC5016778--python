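"""Correlation-matrix PCA with bootstrap eigenvalue intervals, and the
gap-based outlier screen used before model fitting.

The PCA standardizes every variable (correlation option), so the component
structure is invariant to affine rescaling of the inputs and the eigenvalues
sum to the number of variables.  Bootstrap confidence limits on the
eigenvalues come from resampling sites with replacement.

The outlier screen formalizes a visual call: a variable whose sorted values
show a large discontinuity (e.g. two sites lying 3–10× farther from the
nearest port than all others) flags the sites beyond the gap.  Flagged sites
are typically excluded from subsequent regression fitting while the initial
correlation screen keeps all sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError


@dataclass(frozen=True)
class PcaResult:
    variables: tuple[str, ...]
    eigenvalues: np.ndarray                 # nonincreasing
    eigenvalue_ci: np.ndarray | None        # (n_components, 2) bootstrap 2.5/97.5%
    percent_variance: np.ndarray            # sums to 100
    loadings: pd.DataFrame                  # variables x components, unit-norm cols
    scores: pd.DataFrame                    # sites x components
    n_boot: int

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _correlation_eigen(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the correlation matrix, sorted descending,
    with the sign of each loading column fixed so its largest-magnitude
    entry is positive."""
    corr = np.corrcoef(X, rowvar=False)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.clip(w, 0.0, None)
    for j in range(v.shape[1]):
        pivot = np.argmax(np.abs(v[:, j]))
        if v[pivot, j] < 0:
            v[:, j] = -v[:, j]
    return w, v


def pca_correlation(
    data,
    variables: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = 0,
) -> PcaResult:
    """PCA on the correlation matrix of the selected variables.

    Parameters
    ----------
    data
        StudyDataset or DataFrame.
    variables
        At least two column names; a constant column is rejected by name.
    n_boot
        Bootstrap replicates (resampling sites with replacement) for the
        2.5%/97.5% eigenvalue limits; 0 disables the bootstrap.
    seed
        Seed for the bootstrap resampler.
    """
    frame = data.frame if hasattr(data, "frame") else data
    variables = list(variables)
    if len(variables) < 2:
        raise ValidationError("PCA needs at least 2 variables")
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValidationError(f"column(s) not in data: {missing}")
    X = frame[variables].to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValidationError(f"PCA needs at least 3 sites, got {n}")
    constant = [v for v in variables if np.ptp(X[:, variables.index(v)]) == 0]
    if constant:
        raise ValidationError(f"constant variable(s): {constant}")

    w, v = _correlation_eigen(X)
    pct = 100.0 * w / w.sum()

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    Z = (X - mu) / sd
    scores = Z @ v

    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, len(variables)))
        got = 0
        attempts = 0
        while got < n_boot:
            attempts += 1
            if attempts > 20 * n_boot:
                raise ValidationError(
                    "bootstrap failed: too many degenerate resamples"
                )
            idx = rng.integers(0, n, size=n)
            Xb = X[idx]
            if np.any(np.ptp(Xb, axis=0) == 0):
                continue  # a constant column makes the correlation undefined
            wb, _ = _correlation_eigen(Xb)
            boot[got] = wb
            got += 1
        ci = np.column_stack(
            [np.percentile(boot, 2.5, axis=0), np.percentile(boot, 97.5, axis=0)]
        )

    comp_names = [f"PC{i + 1}" for i in range(len(w))]
    site_index = (
        frame["site_id"].tolist() if "site_id" in frame.columns else frame.index
    )
    return PcaResult(
        variables=tuple(variables),
        eigenvalues=w,
        eigenvalue_ci=ci,
        percent_variance=pct,
        loadings=pd.DataFrame(v, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=site_index, columns=comp_names),
        n_boot=n_boot,
    )


def flag_outliers(
    data,
    variable: str,
    gap_factor: float = 1.5,
) -> list[str]:
    """Sites beyond a discontinuity in the distribution of one variable.

    The sorted values are scanned for their largest gap; the smaller side of
    the gap is flagged when the gap exceeds ``gap_factor`` × IQR of the
    remaining values.  Peeling repeats until no qualifying gap remains, so a
    detached pair (or small cluster) at either extreme is caught even when
    internal spacing within the pair is large.

    Returns flagged ``site_id`` values in dataset order.  Refuses to flag
    with fewer than 5 sites.
    """
    frame = data.frame if hasattr(data, "frame") else data
    if variable not in frame.columns:
        raise ValidationError(f"column {variable!r} not in data")
    if gap_factor <= 0:
        raise ValidationError("gap_factor must be positive")
    values = frame[variable].to_numpy(dtype=float)
    ids = (
        frame["site_id"].tolist()
        if "site_id" in frame.columns
        else [str(i) for i in frame.index]
    )
    if len(values) < 5:
        raise ValidationError(
            f"refusing to flag outliers with fewer than 5 sites (n={len(values)})"
        )

    active = list(range(len(values)))
    flagged: set[int] = set()
    while len(active) >= 5:
        order = sorted(active, key=lambda i: values[i])
        sorted_vals = [values[i] for i in order]
        gaps = np.diff(sorted_vals)
        if gaps.size == 0 or gaps.max() == 0:
            break
        g = int(np.argmax(gaps))
        low_side, high_side = order[: g + 1], order[g + 1:]
        if len(low_side) == len(high_side):
            break  # no minority side: not an outlying group
        minority, majority = (
            (low_side, high_side)
            if len(low_side) < len(high_side)
            else (high_side, low_side)
        )
        rest = [values[i] for i in majority]
        q1, q3 = np.percentile(rest, [25, 75])
        iqr = q3 - q1
        if iqr <= 0 or gaps[g] <= gap_factor * iqr:
            break
        flagged.update(minority)
        active = majority
    return [ids[i] for i in sorted(flagged)]


def remove_outliers(dataset, site_ids: Sequence[str]):
    """Return a copy of the dataset without the given sites (order kept)."""
    from .dataset_io import StudyDataset

    frame = dataset.frame if hasattr(dataset, "frame") else dataset
    keep = frame[~frame["site_id"].isin(set(site_ids))].copy()
    if hasattr(dataset, "frame"):
        return StudyDataset(keep, dict(dataset.column_metadata))
    return keep
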