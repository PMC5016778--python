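"""Bespoke invasion-vector and coastal-protection scores.

Two site-level scores drive the analysis:

* **Aquaculture vector value (AqV)** — for each cultivated species near a
  site, a status weight (1 native, 2 exotic, 3 globally recognized invader)
  is multiplied by the number of farms of that species within a radius
  (10 km by default) and summed:  ``AqV = Σ_i X_i · Farm_i``.

* **Weighted protection status (PS)** — a stretch of coast is modelled as
  1-D segments, each with a protection level ``PL ∈ {1, 2, 3, 5}`` (5 = full
  marine protected area / national park, 3 = ecological reserve or regulated
  fishery, 2 = lightly regulated, 1 = unprotected), an optional protection
  duration ``t`` and a length in km.  The window score is the length-weighted
  mean ``Σ PL_i · km_i / window`` or, with duration, ``Σ PL_i · t_i · km_i /
  window`` ("standardized protection-years per km").

Raw vector measurements are normalized across the dataset onto a bounded
0–5 (or 1–5) Likert-style scale with :func:`likert_rescale`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .exceptions import CoverageError, ValidationError

#: Status weight of a cultivated species in the aquaculture vector score.
FARM_STATUS_WEIGHTS = {"native": 1, "exotic": 2, "invader": 3}

#: Qualitative protection tier -> numeric level.  The jump from 3 to 5
#: reflects how many more extractive uses are allowed outside full MPAs.
PROTECTION_TIER_LEVELS = {
    "mpa": 5,
    "national_park": 5,
    "ecological_reserve": 3,
    "fisheries_regulated": 3,
    "regulated_fisheries": 2,
    "regional_park": 2,
    "none": 1,
}


@dataclass(frozen=True)
class FarmRecord:
    """An aquaculture installation near a sampling site.

    ``status_weight`` is the species weight X: 1 for a native species, 2 for
    an exotic one, 3 for a recognized invader on the IUCN/ISSG global list
    (user-supplied; no registry lookup is performed).
    """

    species_name: str
    status_weight: int
    n_farms: int = 1
    distance_to_site_km: float = 0.0

    def __post_init__(self) -> None:
        if self.status_weight not in (1, 2, 3):
            raise ValidationError(
                f"farm {self.species_name!r}: status weight must be 1, 2 or 3, "
                f"got {self.status_weight}"
            )
        if self.n_farms < 1:
            raise ValidationError(
                f"farm {self.species_name!r}: n_farms must be >= 1"
            )
        if self.distance_to_site_km < 0:
            raise ValidationError(
                f"farm {self.species_name!r}: distance must be nonnegative"
            )


@dataclass(frozen=True)
class ProtectionSegment:
    """A stretch of coastline with one protection level and age.

    ``duration`` is the age of the protection regime; the package convention
    is decades (a 30-year-old reserve has duration 3), which keeps duration
    and level on comparable magnitudes.
    """

    level: int
    length_km: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3, 5):
            raise ValidationError(
                f"protection level must be one of (1, 2, 3, 5), got {self.level}"
            )
        if self.length_km <= 0:
            raise ValidationError(
                f"segment length must be positive, got {self.length_km}"
            )
        if self.duration < 0:
            raise ValidationError("protection duration must be nonnegative")


def local_protection_status(tier: str) -> int:
    """Map a qualitative protection tier to its numeric level.

    Accepted tiers: ``mpa``/``national_park`` (level 5),
    ``ecological_reserve``/``fisheries_regulated`` (3),
    ``regulated_fisheries``/``regional_park`` (2), ``none`` (1).
    """
    key = tier.strip().lower().replace(" ", "_").replace("/", "_")
    try:
        return PROTECTION_TIER_LEVELS[key]
    except KeyError:
        raise ValidationError(
            f"unknown protection tier {tier!r}; expected one of "
            f"{sorted(PROTECTION_TIER_LEVELS)}"
        ) from None


def aquaculture_vector(
    farms: Iterable[FarmRecord], radius_km: float = 10.0
) -> float:
    """Raw aquaculture vector value AqV = Σ status_weight × n_farms.

    Only farms within ``radius_km`` of the site contribute.  The result is a
    raw score; rescale across sites with :func:`likert_rescale`
    (``anchor_zero=True``) before use as a model covariate.
    """
    if radius_km <= 0:
        raise ValidationError(f"radius_km must be positive, got {radius_km}")
    return float(
        sum(
            f.status_weight * f.n_farms
            for f in farms
            if f.distance_to_site_km <= radius_km
        )
    )


def weighted_protection(
    segments: Sequence[ProtectionSegment],
    window_km: float,
    include_duration: bool = False,
    atol: float = 1e-9,
) -> float:
    """Length-weighted protection score of a coastal window.

    The segments must tile the window exactly (pad unprotected coast with
    level-1, duration-0 segments).  Without duration the score is the
    length-weighted mean protection level, bounded in [1, 5]; with duration
    it is Σ level·duration·length / window, in standardized
    protection-years per km (duration in the declared unit, decades by
    convention).

    For an island whose perimeter is shorter than the nominal window (e.g.
    a 60-km window on a small island), pass the perimeter as ``window_km``.
    """
    if window_km <= 0:
        raise ValidationError(f"window_km must be positive, got {window_km}")
    if not segments:
        raise CoverageError("no segments supplied for the window")
    total = sum(s.length_km for s in segments)
    if not math.isclose(total, window_km, rel_tol=0.0, abs_tol=atol):
        raise CoverageError(
            f"segments cover {total} km but the window is {window_km} km; "
            "pad unprotected coast with level-1 segments"
        )
    if include_duration:
        score = sum(s.level * s.duration * s.length_km for s in segments)
    else:
        score = sum(s.level * s.length_km for s in segments)
    return score / window_km


def likert_rescale(
    raw: Sequence[float],
    lo: float = 0.0,
    hi: float = 5.0,
    anchor_zero: bool = True,
) -> np.ndarray:
    """Rescale raw measurements onto a bounded Likert-style range.

    With ``anchor_zero`` (the convention for vectors that have a natural
    zero, such as farm counts or ship traffic) the map is ``hi · x /
    max(x)``, so absent pressure stays exactly 0.  Without it the map is the
    min–max affine stretch onto [lo, hi], the convention for site
    characteristics measured on open scales.

    A constant all-zero vector is returned as all zeros under
    ``anchor_zero``; any other constant vector has no defined stretch and
    raises :class:`ValidationError`.
    """
    x = np.asarray(raw, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot rescale an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValidationError("raw values must be finite")
    if hi <= lo:
        raise ValidationError(f"need hi > lo, got lo={lo}, hi={hi}")
    xmin, xmax = float(x.min()), float(x.max())
    if anchor_zero:
        if xmin < 0:
            raise ValidationError(
                "anchor_zero rescaling requires nonnegative raw values"
            )
        if xmax == 0.0:
            return np.zeros_like(x)
        return hi * x / xmax
    if xmax == xmin:
        raise ValidationError(
            "constant vector: min-max rescaling is undefined; "
            "use anchor_zero for natural-zero vectors"
        )
    return lo + (hi - lo) * (x - xmin) / (xmax - xmin)
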