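"""Per-site diversity summaries from species abundance tables.

Implements the two biodiversity measures used as survey descriptors —
Margalef's richness index d = (S − 1)/ln N and Simpson's evenness-sensitive
diversity index — plus NIS (non-indigenous species) proportions at both the
species level (NIS species / total species) and the individual level
(NIS individuals / total individuals).

Simpson's index comes in two variants: the plugin form 1 − Σ(n_i/N)² and the
small-sample unbiased form 1 − Σ n_i(n_i − 1)/(N(N − 1)).  The unbiased form
is the default, matching the convention of the diversity software commonly
used for intertidal surveys.  A single-species site scores 0 on both
richness and Simpson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import SchemaError, ValidationError


@dataclass(frozen=True)
class AbundanceEntry:
    species_name: str
    count: int
    is_nis: bool


@dataclass
class AbundanceTable:
    """Species-by-count record for one site, with NIS flags.

    NIS status is an input (assigned upstream from range registries); no
    lookup is performed here.
    """

    site_id: str
    entries: list[AbundanceEntry]

    def __post_init__(self) -> None:
        names = [e.species_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError(
                f"site {self.site_id!r}: duplicated species names"
            )
        for e in self.entries:
            if e.count < 0 or e.count != int(e.count):
                raise ValidationError(
                    f"site {self.site_id!r}, species {e.species_name!r}: "
                    "counts must be nonnegative integers"
                )

    @property
    def counts(self) -> list[int]:
        return [e.count for e in self.entries if e.count > 0]

    @property
    def total_individuals(self) -> int:
        return sum(e.count for e in self.entries)


@dataclass(frozen=True)
class DiversitySummary:
    site_id: str
    s_total: int
    s_nis: int
    nis_species_proportion: float
    nis_individual_proportion: float
    richness_index: float
    simpson: float


def simpson_index(counts: Sequence[int], variant: str = "unbiased") -> float:
    """Simpson's diversity index 1 − λ of a community sample.

    ``unbiased``: 1 − Σ n_i(n_i−1)/(N(N−1)), requires N ≥ 2.
    ``plugin``:   1 − Σ (n_i/N)².
    """
    counts = [int(c) for c in counts if c > 0]
    if not counts:
        raise ValidationError("empty or all-zero abundance vector")
    n_total = sum(counts)
    if variant == "unbiased":
        if n_total < 2:
            raise ValidationError(
                "unbiased Simpson needs at least 2 individuals"
            )
        lam = sum(c * (c - 1) for c in counts) / (n_total * (n_total - 1))
    elif variant == "plugin":
        lam = sum((c / n_total) ** 2 for c in counts)
    else:
        raise ValidationError(
            f"unknown Simpson variant {variant!r}; use 'unbiased' or 'plugin'"
        )
    return 1.0 - lam


def richness_index(s: int, n: int) -> float:
    """Margalef's sample-size-adjusted richness d = (S − 1)/ln N.

    Zero for a single-species site regardless of N.  Requires N ≥ 2 so the
    logarithm is positive.
    """
    if s < 1:
        raise ValidationError(f"species count must be >= 1, got {s}")
    if n < 2:
        raise ValidationError(f"need at least 2 individuals, got {n}")
    if n < s:
        raise ValidationError(f"N={n} individuals cannot host S={s} species")
    return (s - 1) / math.log(n)


def nis_proportions(
    table: AbundanceTable, simpson_variant: str = "unbiased"
) -> DiversitySummary:
    """Full diversity summary of one site's abundance table.

    Species with zero count are ignored.  Proportions are computed at both
    the species level and the individual level; the two generally differ
    (a site can host one very abundant invader among many rare natives).
    """
    present = [e for e in table.entries if e.count > 0]
    if not present:
        raise ValidationError(f"site {table.site_id!r}: no individuals")
    s_total = len(present)
    s_nis = sum(1 for e in present if e.is_nis)
    n_total = sum(e.count for e in present)
    n_nis = sum(e.count for e in present if e.is_nis)
    return DiversitySummary(
        site_id=table.site_id,
        s_total=s_total,
        s_nis=s_nis,
        nis_species_proportion=s_nis / s_total,
        nis_individual_proportion=n_nis / n_total,
        richness_index=richness_index(s_total, n_total) if n_total >= 2 else 0.0,
        simpson=simpson_index([e.count for e in present], simpson_variant)
        if n_total >= 2
        else 0.0,
    )


def read_abundances(path: str | Path) -> list[AbundanceTable]:
    """Read long-format abundance CSV (site_id, species, count, is_nis)."""
    frame = pd.read_csv(path)
    required = {"site_id", "species", "count", "is_nis"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {sorted(missing)}")
    tables = []
    for site_id, grp in frame.groupby("site_id", sort=False):
        entries = [
            AbundanceEntry(str(r.species), int(r.count), bool(r.is_nis))
            for r in grp.itertuples()
        ]
        tables.append(AbundanceTable(str(site_id), entries))
    return tables


def summarize_all(
    tables: Iterable[AbundanceTable], simpson_variant: str = "unbiased"
) -> pd.DataFrame:
    """Diversity summaries for many sites as a DataFrame in input order."""
    rows = [nis_proportions(t, simpson_variant) for t in tables]
    return pd.DataFrame([r.__dict__ for r in rows])
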