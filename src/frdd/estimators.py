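"""Non-capture-recapture estimators and descriptive survey computations.

Covers the simple population estimators (human:dog ratio, census detection
percentages), transect-count aggregation, land-cover enrichment of
detections, and the buffer-geometry computation of foot-patrol survey
coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiLineString, Polygon
from shapely.ops import unary_union

from ._util import round_half_up, round_half_up_int

logger = logging.getLogger(__name__)

COUNT_METHODS = ("uav", "ground")
LAND_COVERS = ("yards", "roads", "fields_forest")


@dataclass(frozen=True)
class SiteCensus:
    """Door-to-door census totals for one site."""

    site: str
    humans: int
    owned_dogs: int

    def __post_init__(self) -> None:
        if self.humans < 0 or self.owned_dogs < 0:
            raise ValueError("census counts must be non-negative")


@dataclass(frozen=True)
class TransectCountRecord:
    """One site x method x transect dog count."""

    site: str
    method: str
    transect_index: int
    count: int

    def __post_init__(self) -> None:
        if self.method not in COUNT_METHODS:
            raise ValueError(f"method must be one of {COUNT_METHODS}, got {self.method!r}")
        if self.transect_index < 1:
            raise ValueError("transect_index must be >= 1")
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class DetectionRecord:
    """Dogs detected in one land-cover class of a site, with the fraction of
    the site's area that class covers."""

    site: str
    land_cover: str
    count: int
    cover_fraction: float

    def __post_init__(self) -> None:
        if self.land_cover not in LAND_COVERS:
            raise ValueError(
                f"land_cover must be one of {LAND_COVERS}, got {self.land_cover!r}"
            )
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if not (0.0 <= self.cover_fraction <= 1.0):
            raise ValueError("cover_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# simple estimators
# ---------------------------------------------------------------------------

def human_dog_ratio_estimate(humans: int, ratio: float) -> int:
    """Dogs estimated from a human census via a humans-per-dog ratio
    (vaccination-campaign planning convention), rounded half-up."""
    if ratio <= 0:
        raise ValueError(f"humans-per-dog ratio must be positive, got {ratio}")
    if humans < 0:
        raise ValueError("human count must be non-negative")
    return round_half_up_int(humans / ratio)


def detection_percentage(estimate: int, census: int) -> int:
    """Whole-number percentage of the census count an estimate detects."""
    if census <= 0:
        raise ValueError("census count must be positive")
    if estimate < 0:
        raise ValueError("estimate must be non-negative")
    return round_half_up_int(100.0 * estimate / census)


def empirical_human_dog_ratio(humans: int, owned_dogs: int) -> float:
    """Observed humans-per-dog ratio from census data, to one decimal."""
    if owned_dogs <= 0:
        raise ValueError("owned dog count must be positive")
    if humans < 0:
        raise ValueError("human count must be non-negative")
    return round_half_up(humans / owned_dogs, 1)


# ---------------------------------------------------------------------------
# count aggregation and enrichment
# ---------------------------------------------------------------------------

def _records_frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(columns) - set(records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return records.loc[:, list(columns)].copy()
    return pd.DataFrame([vars(r) if hasattr(r, "__dataclass_fields__") else r
                         for r in records], columns=list(columns))


def aggregate_transect_counts(
    records: Iterable[TransectCountRecord] | pd.DataFrame,
) -> pd.Series:
    """Total dogs counted per (site, method).

    Transects absent from the input are simply absent from the sum; a
    duplicated (site, method, transect_index) key is an error.
    """
    df = _records_frame(records, ("site", "method", "transect_index", "count"))
    if df.empty:
        return pd.Series(dtype=int, name="count",
                         index=pd.MultiIndex.from_arrays([[], []], names=("site", "method")))
    if (df["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    dup = df.duplicated(subset=["site", "method", "transect_index"])
    if dup.any():
        keys = df.loc[dup, ["site", "method", "transect_index"]].to_records(index=False)
        raise ValueError(f"duplicate transect records: {list(keys)}")
    return df.groupby(["site", "method"])["count"].sum()


def land_cover_enrichment(
    records: Iterable[DetectionRecord] | pd.DataFrame,
    tolerance: float = 0.02,
) -> pd.DataFrame:
    """Observed detection fraction, cover fraction and their ratio per
    site x land-cover class.

    Enrichment > 1 means dogs were detected in a class more often than its
    share of the site's area; a class with detections but zero mapped cover
    gets ``inf`` and a logged flag.
    """
    df = _records_frame(records, ("site", "land_cover", "count", "cover_fraction"))
    if (df["count"] < 0).any() or (df["cover_fraction"] < 0).any():
        raise ValueError("negative counts or cover fractions")
    out = []
    for site, grp in df.groupby("site"):
        total = grp["count"].sum()
        if total <= 0:
            raise ValueError(f"site {site!r} has no detections to normalise")
        cover_sum = grp["cover_fraction"].sum()
        if cover_sum > 1.0 + tolerance:
            raise ValueError(
                f"site {site!r}: cover fractions sum to {cover_sum:.3f} > 1"
            )
        for _, row in grp.iterrows():
            observed = row["count"] / total
            if row["cover_fraction"] > 0:
                enrich = observed / row["cover_fraction"]
            elif row["count"] > 0:
                enrich = np.inf
                logger.warning(
                    "site %s, %s: detections in a land cover with zero mapped area",
                    site, row["land_cover"],
                )
            else:
                enrich = np.nan
            out.append({
                "site": site,
                "land_cover": row["land_cover"],
                "observed_fraction": observed,
                "cover_fraction": row["cover_fraction"],
                "enrichment": enrich,
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# survey coverage geometry
# ---------------------------------------------------------------------------

def coverage_fraction(
    transects: Sequence[LineString | MultiLineString | Sequence],
    site: Polygon,
    half_width: float,
) -> float:
    """Fraction of the site area within ``half_width`` metres of a transect.

    Transect lines are buffered with round caps and joins, unioned, clipped
    to the site polygon, and the clipped area is divided by the site area.
    Coordinates must already be projected in metres; no CRS handling is
    performed.
    """
    if half_width <= 0:
        raise ValueError(f"half_width must be positive, got {half_width}")
    if not isinstance(site, Polygon):
        site = Polygon(site)
    if not site.is_valid:
        raise ValueError("site polygon is invalid (e.g. self-intersecting)")
    if site.area <= 0:
        raise ValueError("site polygon has zero area")
    if site.area < 1e4:
        # a 1 km^2 study site has area 1e6; values this small suggest
        # unprojected (degree) coordinates
        logger.warning(
            "site area %.3g m^2 is implausibly small; are coordinates projected "
            "in metres?", site.area,
        )
    lines = [
        geom if isinstance(geom, (LineString, MultiLineString)) else LineString(geom)
        for geom in transects
    ]
    if not lines:
        return 0.0
    buffered = unary_union([ln.buffer(half_width) for ln in lines])
    covered = buffered.intersection(site).area
    return min(covered / site.area, 1.0)
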