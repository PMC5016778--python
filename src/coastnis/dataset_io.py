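"""Study data model and I/O for site-by-variable tables.

The central object is :class:`StudyDataset`, an ordered collection of scored
coastal sampling sites.  Each site carries a protection score at three spatial
scales, distances to putative invasion sources (port, freshwater discharge,
pollution), habitat descriptors on Likert scales, an aquaculture vector score,
and the response variables: proportion of non-indigenous species (NIS),
native species count and two diversity indices.

Row order is preserved everywhere and is statistically meaningful: the
Durbin-Watson autocorrelation diagnostic operates on residuals in dataset
order.

A fully transcribed 30-site survey of two Pacific islands (Moorea, French
Polynesia and Vancouver Island, Canada) ships with the package; see
:func:`packaged_table1`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .exceptions import EmptySubsetError, ParseError, SchemaError, ValidationError

ISLANDS = ("Moorea", "VancouverEast", "VancouverWest")
VANCOUVER = ("VancouverEast", "VancouverWest")

#: Canonical numeric columns, in file order.
NUMERIC_COLUMNS = (
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
    "nis_prop",
    "n_native",
    "richness",
    "simpson",
)

#: Measurement scale declared per column: raw (physical units), likert
#: (bounded ordinal-style score) or proportion (fraction in [0, 1]).
DEFAULT_COLUMN_SCALES: dict[str, str] = {
    "status_local": "likert",
    "status_10km": "raw",
    "status_60km": "raw",
    "dist_port_km": "raw",
    "dist_freshwater": "raw",
    "dist_pollution": "raw",
    "algae_cover": "proportion",
    "wave_exposure": "likert",
    "traffic": "likert",
    "substrate": "likert",
    "aquaculture": "likert",
    "nis_prop": "proportion",
    "n_native": "raw",
    "richness": "raw",
    "simpson": "proportion",
}

#: The four coastal protection tiers in use: full marine protected area /
#: national park (5), ecological reserve or regulated fishery (3), lightly
#: regulated zone such as a regional park (2), unprotected coast (1).
PROTECTION_LEVELS = (1, 2, 3, 5)


@dataclass(frozen=True)
class SiteRecord:
    """One sampled site: scored covariates plus response variables."""

    site_id: str
    island: str
    status_local: float
    status_10km: float
    status_60km: float
    dist_port_km: float
    dist_freshwater: float
    dist_pollution: float
    algae_cover: float
    wave_exposure: float
    traffic: float
    substrate: float
    aquaculture: float
    nis_prop: float
    n_native: int
    richness: float
    simpson: float

    def validate(self) -> None:
        if self.island not in ISLANDS:
            raise ValidationError(
                f"site {self.site_id!r}: unknown island {self.island!r}; "
                f"expected one of {ISLANDS}"
            )
        if self.status_local not in PROTECTION_LEVELS:
            raise ValidationError(
                f"site {self.site_id!r}: status_local must be one of "
                f"{PROTECTION_LEVELS}, got {self.status_local}"
            )
        if not 0.0 <= self.nis_prop <= 1.0:
            raise ValidationError(
                f"site {self.site_id!r}: nis_prop {self.nis_prop} outside [0, 1]"
            )
        if not 0.0 <= self.simpson < 1.0:
            raise ValidationError(
                f"site {self.site_id!r}: simpson {self.simpson} outside [0, 1)"
            )
        if self.n_native < 0 or self.n_native != int(self.n_native):
            raise ValidationError(
                f"site {self.site_id!r}: n_native must be a nonnegative integer"
            )
        for name in ("status_10km", "status_60km", "dist_port_km", "richness"):
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"site {self.site_id!r}: {name} must be nonnegative"
                )


@dataclass
class StudyDataset:
    """Ordered collection of :class:`SiteRecord` with per-column scale metadata.

    The pandas view (:meth:`to_frame`) is the working representation for the
    statistical layers; records exist for validation and item access.
    """

    frame: pd.DataFrame
    column_metadata: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMN_SCALES)
    )

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[SiteRecord]:
        return iter(self.sites)

    def __getitem__(self, site_id: str) -> SiteRecord:
        hit = self.frame[self.frame["site_id"] == site_id]
        if hit.empty:
            raise KeyError(site_id)
        return _record_from_row(hit.iloc[0])

    @property
    def sites(self) -> list[SiteRecord]:
        return [_record_from_row(row) for _, row in self.frame.iterrows()]

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame["site_id"])

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        missing = [c for c in ("site_id", "island", *NUMERIC_COLUMNS)
                   if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"dataset missing required column(s): {missing}")
        if self.frame["site_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["site_id"].duplicated(), "site_id"]
            raise ValidationError(f"duplicated site_id(s): {sorted(set(dupes))}")
        if self.frame[list(NUMERIC_COLUMNS)].isna().any().any():
            bad = self.frame[list(NUMERIC_COLUMNS)].isna().any()
            raise ValidationError(
                "missing values are not accepted (no imputation); offending "
                f"column(s): {list(bad[bad].index)}"
            )
        for record in self.sites:
            record.validate()

    # -- subsetting ---------------------------------------------------------
    def subset(self, islands: Iterable[str]) -> "StudyDataset":
        """Restrict to sites on the given islands/coasts, preserving row order.

        ``islands`` uses the labels ``Moorea``, ``VancouverEast``,
        ``VancouverWest``.  Raises :class:`EmptySubsetError` when nothing
        matches.
        """
        wanted = set(islands)
        unknown = wanted - set(ISLANDS)
        if unknown:
            raise ValidationError(f"unknown island label(s): {sorted(unknown)}")
        sub = self.frame[self.frame["island"].isin(wanted)]
        if sub.empty:
            raise EmptySubsetError(f"no sites match islands {sorted(wanted)}")
        return StudyDataset(sub.copy(), dict(self.column_metadata))

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def _record_from_row(row: pd.Series) -> SiteRecord:
    kwargs = {"site_id": str(row["site_id"]), "island": str(row["island"])}
    for col in NUMERIC_COLUMNS:
        kwargs[col] = int(row[col]) if col == "n_native" else float(row[col])
    return SiteRecord(**kwargs)


def read_dataset(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    region_map: Mapping[str, str] | str | Path | None = None,
    column_metadata: Mapping[str, str] | None = None,
) -> StudyDataset:
    """Read a site-by-variable CSV into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.  Canonical column names are expected
        unless a ``dialect`` mapping is given.
    dialect
        Mapping from file column names to canonical names, for tables
        exported under different headers.
    region_map
        Either a mapping ``site_id -> island`` or a path to a YAML file with
        that mapping.  Required when the file has no ``island`` column;
        when given it also overrides an existing column.
    column_metadata
        Per-column scale declarations; defaults to
        :data:`DEFAULT_COLUMN_SCALES`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    if raw.empty:
        raise SchemaError(f"{path}: header only, no data rows")
    if dialect:
        raw = raw.rename(columns=dict(dialect))

    missing = [c for c in ("site_id", *NUMERIC_COLUMNS) if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")

    if region_map is not None:
        mapping = _load_region_map(region_map)
        unmapped = [s for s in raw["site_id"] if s not in mapping]
        if unmapped:
            raise SchemaError(
                f"{path}: site(s) absent from region map: {unmapped}"
            )
        raw["island"] = [mapping[s] for s in raw["site_id"]]
    elif "island" not in raw.columns:
        raise SchemaError(
            f"{path}: no 'island' column and no region_map supplied"
        )

    parsed = raw[["site_id", "island"]].copy()
    for col in NUMERIC_COLUMNS:
        values = []
        for i, cell in enumerate(raw[col]):
            try:
                values.append(float(cell))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {i + 1}, "
                    f"column {col!r}"
                ) from exc
            if not math.isfinite(values[-1]):
                raise ParseError(
                    f"{path}: non-finite value at row {i + 1}, column {col!r}"
                )
        parsed[col] = values

    meta = dict(column_metadata) if column_metadata else dict(DEFAULT_COLUMN_SCALES)
    return StudyDataset(parsed, meta)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write the dataset back to CSV, preserving row order and full precision.

    ``repr``-precision floats guarantee an exact numeric round trip through
    :func:`read_dataset`.
    """
    cols = ["site_id", "island", *NUMERIC_COLUMNS]
    frame = dataset.frame[cols].copy()
    frame["n_native"] = frame["n_native"].astype(int)
    frame.to_csv(path, index=False, float_format=None)


def _load_region_map(source: Mapping[str, str] | str | Path) -> dict[str, str]:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise SchemaError(f"{source}: region map must be a mapping site_id -> island")
    return {str(k): str(v) for k, v in data.items()}


def packaged_region_map() -> dict[str, str]:
    """The default site -> island/coast assignment shipped with the package.

    Moorea sites are unambiguous.  The east/west split of the 14 Vancouver
    Island sites follows coastal geography: the eight Strait-of-Georgia-side
    sites (Cortes Island through Victoria) are east coast, the six outer-coast
    sites (Sooke through Long Beach) are west coast.  Override by passing your
    own mapping to :func:`read_dataset`.
    """
    with resources.files("coastnis.data").joinpath("regions.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return {str(k): str(v) for k, v in yaml.safe_load(fh).items()}


def packaged_table1() -> StudyDataset:
    """The built-in 30-site survey: 16 Moorea + 14 Vancouver Island sites.

    Values are transcribed at printed precision from the published site
    table; the diversity columns (richness, simpson) are survey data, not
    recomputed here, because the per-site raw abundances behind them are not
    part of the table.
    """
    with resources.as_file(
        resources.files("coastnis.data").joinpath("table1.csv")
    ) as path:
        return read_dataset(path)
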