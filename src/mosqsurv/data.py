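"""Data model and I/O for monthly mosquito trap surveys.

The survey design this package targets is a stratified monthly trap array:
sites spread across land-cover strata, each visited once a month for a
48-hour trap deployment (one deployment = one sampling occasion), with
per-species counts recorded for every deployment.  Four tables describe a
survey:

* a long-format count table (site, month, species, count),
* per-site land-cover covariates (proportions within a 1 km^2 buffer),
* species traits (currently a mangrove-breeding indicator), and
* an island-wide monthly precipitation series.

All tables are plain CSV with a header row; readers validate the schema and
simple invariants, writers emit a deterministic (site, month, species) row
order so that runs are byte-for-byte reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mosqsurv")

STRATA = ("agricultural", "mangrove", "rainforest", "scrub", "urban")

COUNT_COLUMNS = ["site_id", "month_index", "species", "count", "genus_only"]
SITE_COLUMNS = [
    "site_id",
    "stratum",
    "local_agriculture",
    "local_mangrove",
    "local_rainforest",
    "local_urban",
    "local_scrub",
    "mangrove_site",
]
TRAIT_COLUMNS = ["species", "m_trait"]
PRECIP_COLUMNS = ["month_index", "precip_raw"]


class SchemaError(ValueError):
    """A table is missing required columns or has the wrong dtypes."""


class ValidationError(ValueError):
    """A table has the right shape but violates a value constraint."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.astype(str).str.strip().str.lower().isin(["true", "1", "t", "yes"])


@dataclass
class CountTable:
    """Long-format per-deployment counts.

    One row per (site, month, taxon).  ``genus_only`` marks specimens that
    could be assigned only to genus (damaged individuals); these rows are
    excluded from modelling by :func:`filter_genus_only`.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, COUNT_COLUMNS, "count table")
        df = self.frame.loc[:, COUNT_COLUMNS].copy()
        df["site_id"] = df["site_id"].astype(str)
        df["species"] = df["species"].astype(str)
        df["month_index"] = df["month_index"].astype(int)
        df["genus_only"] = _as_bool(df["genus_only"])
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0) | (counts % 1 != 0)]
        if len(bad):
            raise ValidationError(
                f"count table has invalid count at row(s) {list(bad[:5])}: "
                "counts must be non-negative integers"
            )
        df["count"] = counts.astype(int)
        if (df["month_index"] < 0).any():
            bad = df.index[df["month_index"] < 0]
            raise ValidationError(f"negative month_index at row(s) {list(bad[:5])}")
        self.frame = df

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sites(self) -> list[str]:
        return sorted(self.frame["site_id"].unique())

    @property
    def months(self) -> list[int]:
        return sorted(self.frame["month_index"].unique())

    @property
    def species(self) -> list[str]:
        obs = self.frame.loc[~self.frame["genus_only"], "species"]
        return sorted(obs.unique())

    def sorted(self) -> "CountTable":
        df = self.frame.sort_values(["site_id", "month_index", "species"], kind="mergesort")
        return CountTable(df.reset_index(drop=True))


@dataclass
class SiteTable:
    """Per-site land-cover covariates.

    Five local land-cover proportions (within a 1 km^2 buffer) that must sum
    to one, a stratum label (which land cover the site was selected to
    represent) and a ``mangrove_site`` flag marking sites physically located
    inside mangrove habitat.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, SITE_COLUMNS, "site covariate table")
        df = self.frame.loc[:, SITE_COLUMNS].copy()
        df["site_id"] = df["site_id"].astype(str)
        df["stratum"] = df["stratum"].astype(str)
        df["mangrove_site"] = _as_bool(df["mangrove_site"])
        props = df[list(self.proportion_columns)].astype(float)
        if ((props < -1e-9) | (props > 1 + 1e-9)).any().any():
            raise ValidationError("land-cover proportions must lie in [0, 1]")
        sums = props.sum(axis=1)
        off = df.index[(sums < 0.99) | (sums > 1.01)]
        if len(off):
            raise ValidationError(
                f"land-cover proportions must sum to 1; off at row(s) {list(off[:5])}"
            )
        unknown = set(df["stratum"]) - set(STRATA)
        if unknown:
            raise ValidationError(f"unknown stratum label(s): {sorted(unknown)}")
        if (df["mangrove_site"] & (df["stratum"] != "mangrove")).any():
            raise ValidationError("mangrove_site=True requires stratum='mangrove'")
        df[list(self.proportion_columns)] = props
        self.frame = df.sort_values("site_id", kind="mergesort").reset_index(drop=True)

    proportion_columns = (
        "local_agriculture",
        "local_mangrove",
        "local_rainforest",
        "local_urban",
        "local_scrub",
    )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sites(self) -> list[str]:
        return list(self.frame["site_id"])

    def with_anthropogenic(self) -> pd.DataFrame:
        """Frame plus the derived urban + agriculture proportion."""
        df = self.frame.copy()
        df["local_anthropogenic"] = df["local_urban"] + df["local_agriculture"]
        return df


@dataclass
class TraitTable:
    """Species-level traits: currently the mangrove-breeding indicator."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, TRAIT_COLUMNS, "trait table")
        df = self.frame.loc[:, TRAIT_COLUMNS].copy()
        df["species"] = df["species"].astype(str)
        df["m_trait"] = _as_bool(df["m_trait"])
        if df["species"].duplicated().any():
            raise ValidationError("duplicate species in trait table")
        self.frame = df.sort_values("species", kind="mergesort").reset_index(drop=True)

    def m_trait(self, species: str) -> bool:
        row = self.frame.loc[self.frame["species"] == species, "m_trait"]
        if row.empty:
            raise ValidationError(f"species {species!r} has no trait row")
        return bool(row.iloc[0])


@dataclass
class PrecipSeries:
    """Island-wide monthly precipitation, raw (mm) and optionally z-scored."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.frame, PRECIP_COLUMNS, "precipitation table")
        cols = PRECIP_COLUMNS + (["precip_std"] if "precip_std" in self.frame.columns else [])
        df = self.frame.loc[:, cols].copy()
        df["month_index"] = df["month_index"].astype(int)
        df["precip_raw"] = df["precip_raw"].astype(float)
        if (df["precip_raw"] < 0).any():
            raise ValidationError("precip_raw must be non-negative")
        if df["month_index"].duplicated().any():
            raise ValidationError("duplicate month_index in precipitation table")
        self.frame = df.sort_values("month_index", kind="mergesort").reset_index(drop=True)

    @property
    def months(self) -> list[int]:
        return list(self.frame["month_index"])

    def std_lookup(self) -> dict[int, float]:
        if "precip_std" not in self.frame.columns:
            raise ValidationError("precipitation series has not been standardized")
        return dict(zip(self.frame["month_index"], self.frame["precip_std"]))


@dataclass
class DetectionArray:
    """Binary detection histories for the occupancy model.

    ``X[j, k, i]`` is 1 when species slot ``i`` was captured at site ``j``
    during occasion ``k``.  Slots beyond ``n_obs_species`` are augmented
    pseudo-species with all-zero histories; ``occasion_mask[j, k]`` is 0 for
    months a site was not trapped (those cells carry no information and are
    kept at 0).
    """

    X: np.ndarray
    occasion_mask: np.ndarray
    n_obs_species: int
    n_aug: int
    sites: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.occasion_mask = np.asarray(self.occasion_mask, dtype=np.int8)
        if self.X.ndim != 3:
            raise ValidationError("X must be a (site, occasion, species) array")
        J, K, M = self.X.shape
        if self.occasion_mask.shape != (J, K):
            raise ValidationError("occasion_mask shape must match X[:, :, 0]")
        if M != self.n_obs_species + self.n_aug:
            raise ValidationError("species slots must equal n_obs_species + n_aug")
        if not np.isin(self.X, (0, 1)).all():
            raise ValidationError("X must be binary")
        if self.n_aug and self.X[:, :, self.n_obs_species:].any():
            raise ValidationError("augmented slots must have all-zero histories")
        if (self.X * (1 - self.occasion_mask[:, :, None])).any():
            raise ValidationError("detections recorded in unsampled site-months")
        if not self.sites:
            self.sites = [f"site_{j:02d}" for j in range(J)]
        if not self.species:
            self.species = [f"sp_{i:02d}" for i in range(self.n_obs_species)]

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.X.shape[1]

    @property
    def n_slots(self) -> int:
        return self.X.shape[2]


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path) -> CountTable:
    return CountTable(pd.read_csv(path))


def write_count_table(table: CountTable, path) -> None:
    table.sorted().frame.to_csv(path, index=False)


def read_site_table(path) -> SiteTable:
    return SiteTable(pd.read_csv(path))


def write_site_table(sites: SiteTable, path) -> None:
    sites.frame.to_csv(path, index=False)


def read_trait_table(path) -> TraitTable:
    return TraitTable(pd.read_csv(path))


def write_trait_table(traits: TraitTable, path) -> None:
    traits.frame.to_csv(path, index=False)


def read_precip_series(path) -> PrecipSeries:
    return PrecipSeries(pd.read_csv(path))


def write_precip_series(precip: PrecipSeries, path) -> None:
    precip.frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# transforms


def filter_genus_only(table: CountTable) -> CountTable:
    """Drop genus-level records, keeping only species-level identifications.

    Damaged specimens identified only to genus cannot enter species-level
    models; dropping them assumes every species is equally likely to go
    unidentified.  The number of removed records is logged so the exclusion
    is auditable.
    """
    keep = ~table.frame["genus_only"]
    removed = int((~keep).sum())
    logger.info("filter_genus_only: removed %d genus-only record(s)", removed)
    return CountTable(table.frame.loc[keep].reset_index(drop=True))


def counts_to_detections(table: CountTable, n_aug: int) -> DetectionArray:
    """Collapse counts to detection/non-detection histories.

    A species is "detected" at a site-occasion when its count is positive;
    one occasion is one monthly 48-h deployment.  ``n_aug`` all-zero
    pseudo-species slots are appended for the data-augmented occupancy
    model.  Site-months with no record at all are treated as untrapped and
    masked; an explicit zero-count record marks a trapped month with no
    capture.
    """
    if n_aug < 0:
        raise ValueError("n_aug must be non-negative")
    if table.frame["genus_only"].any():
        raise ValidationError(
            "count table still contains genus-only records; apply filter_genus_only first"
        )
    sites = table.sites
    months = table.months
    species = table.species
    site_ix = {s: j for j, s in enumerate(sites)}
    month_ix = {m: k for k, m in enumerate(months)}
    sp_ix = {s: i for i, s in enumerate(species)}

    J, K, n = len(sites), len(months), len(species)
    X = np.zeros((J, K, n + n_aug), dtype=np.int8)
    mask = np.zeros((J, K), dtype=np.int8)
    df = table.frame
    j = df["site_id"].map(site_ix).to_numpy()
    k = df["month_index"].map(month_ix).to_numpy()
    i = df["species"].map(sp_ix).to_numpy()
    mask[j, k] = 1
    det = df["count"].to_numpy() > 0
    X[j[det], k[det], i[det]] = 1
    return DetectionArray(
        X=X, occasion_mask=mask, n_obs_species=n, n_aug=n_aug, sites=sites, species=species
    )


def top_species(table: CountTable, k: int) -> list[str]:
    """The ``k`` most abundant species by total count, ties alphabetical."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.frame.loc[~table.frame["genus_only"]]
    totals = df.groupby("species")["count"].sum()
    ranked = totals.sort_index().sort_values(ascending=False, kind="mergesort")
    if k > len(ranked):
        logger.warning("top_species: k=%d exceeds %d species; returning all", k, len(ranked))
        k = len(ranked)
    return list(ranked.index[:k])


def standardize_precip(precip: PrecipSeries) -> PrecipSeries:
    """Z-score the precipitation series over the sampled months.

    Uses the sample SD (ddof=1) so downstream intercepts are interpretable
    at average precipitation; a two-month series maps to the symmetric pair
    (-1/sqrt(2), +1/sqrt(2)).
    """
    raw = precip.frame["precip_raw"].to_numpy(float)
    if len(raw) < 2:
        raise ValidationError("need at least two months to standardize precipitation")
    sd = raw.std(ddof=1)
    if sd == 0:
        raise ValidationError("precipitation is constant; cannot standardize")
    df = precip.frame.copy()
    df["precip_std"] = (raw - raw.mean()) / sd
    return PrecipSeries(df)


def standardize_covariates(
    precip: PrecipSeries, sites: SiteTable
) -> tuple[PrecipSeries, SiteTable]:
    """Standardize model inputs: z-score precipitation, pass proportions through.

    Land-cover proportions already live on [0, 1] and are left on that scale
    so their coefficients read as the effect of going from 0% to 100% cover.
    """
    return standardize_precip(precip), sites
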