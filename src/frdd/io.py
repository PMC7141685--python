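"""Reading and writing the survey file formats.

All tabular inputs are UTF-8 comma-separated files with a header row;
counts must parse as non-negative integers. Site configuration is YAML,
transect geometry is GeoJSON in projected metre coordinates, and reports
are JSON with a ``schema_version`` field.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml
from shapely.geometry import shape

from .estimators import SiteCensus
from .model import CRObservations
from .priors import ROAMING_CATEGORIES, MarkingSummary

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

QUESTIONNAIRE_COLUMNS = (
    "household_id", "site", "roaming_category",
    "est_owned", "est_community", "est_ownerless",
)
COUNTS_COLUMNS = ("site", "transect_index", "marked_count", "unmarked_count")
CENSUS_COLUMNS = ("site", "humans", "owned_dogs")


class SchemaError(ValueError):
    """A required column is missing or a file is structurally unusable."""


class RowError(ValueError):
    """A row holds a value that cannot be validated."""


@dataclass(frozen=True)
class SiteConfig:
    """Survey-design numbers for one site, read from YAML."""

    site: str
    n_collared: int  # Mc
    n_lost: int  # Ml
    n_transects: int  # T
    coverage_min: float
    coverage_max: float
    encounter_min: float
    encounter_max: float
    record_min: float
    record_max: float
    owned_cap: int = 1000

    @property
    def marking(self) -> MarkingSummary:
        return MarkingSummary(self.n_collared, self.n_lost, self.n_transects)


_SITE_YAML_KEYS = {
    "site": "site",
    "Mc": "n_collared",
    "Ml": "n_lost",
    "T": "n_transects",
    "coverage_min": "coverage_min",
    "coverage_max": "coverage_max",
    "encounter_min": "encounter_min",
    "encounter_max": "encounter_max",
    "record_min": "record_min",
    "record_max": "record_max",
    "owned_cap": "owned_cap",
}


def read_site_config(path: str | Path) -> SiteConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"site config {path} is not a YAML mapping")
    unknown = set(raw) - set(_SITE_YAML_KEYS)
    if unknown:
        raise SchemaError(f"site config {path}: unknown keys {sorted(unknown)}")
    missing = {k for k in _SITE_YAML_KEYS if k != "owned_cap"} - set(raw)
    if missing:
        raise SchemaError(f"site config {path}: missing keys {sorted(missing)}")
    kwargs = {_SITE_YAML_KEYS[k]: v for k, v in raw.items()}
    return SiteConfig(**kwargs)


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _as_count(value: Any, column: str, row: int) -> int:
    try:
        f = float(value)
        n = int(f)
    except (TypeError, ValueError):
        raise RowError(f"row {row}: {column}={value!r} is not an integer") from None
    if n != f:
        raise RowError(f"row {row}: {column}={value!r} is not an integer")
    if n < 0:
        raise RowError(f"row {row}: {column}={n} is negative")
    return n


def read_questionnaire(path: str | Path, lenient: bool = False) -> pd.DataFrame:
    """Read and validate owner-interview records.

    Returns a DataFrame with the questionnaire columns plus ``row`` (the
    1-based data row in the file, for error reporting). In strict mode the
    first malformed row raises :class:`RowError`; in lenient mode malformed
    rows are dropped, logged, and listed in ``df.attrs['rejected_rows']``.
    """
    df = pd.read_csv(path)
    _require_columns(df, QUESTIONNAIRE_COLUMNS, path)
    records, rejected = [], []
    for idx, raw in df.iterrows():
        row_no = int(idx) + 1
        try:
            category = str(raw["roaming_category"])
            if category not in ROAMING_CATEGORIES:
                raise RowError(
                    f"row {row_no}: roaming_category={category!r} not in "
                    f"{ROAMING_CATEGORIES}"
                )
            rec = {
                "household_id": str(raw["household_id"]),
                "site": str(raw["site"]),
                "roaming_category": category,
                "est_owned": _as_count(raw["est_owned"], "est_owned", row_no),
                "est_community": _as_count(raw["est_community"], "est_community", row_no),
                "est_ownerless": _as_count(raw["est_ownerless"], "est_ownerless", row_no),
                "row": row_no,
            }
        except RowError as exc:
            if not lenient:
                raise
            logger.warning("%s: rejected %s", path, exc)
            rejected.append(row_no)
            continue
        records.append(rec)
    out = pd.DataFrame(records, columns=list(QUESTIONNAIRE_COLUMNS) + ["row"])
    out.attrs["rejected_rows"] = rejected
    if rejected:
        logger.info("%s: %d row(s) rejected in lenient mode", path, len(rejected))
    return out


def write_questionnaire(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(QUESTIONNAIRE_COLUMNS)].to_csv(path, index=False)


def read_transect_counts(path: str | Path) -> pd.DataFrame:
    """Read per-transect marked/unmarked counts (one row per site x transect)."""
    df = pd.read_csv(path)
    _require_columns(df, COUNTS_COLUMNS, path)
    for idx, raw in df.iterrows():
        row_no = int(idx) + 1
        for col in ("transect_index", "marked_count", "unmarked_count"):
            _as_count(raw[col], col, row_no)
    return df.astype(
        {"transect_index": int, "marked_count": int, "unmarked_count": int}
    )


def write_transect_counts(obs: CRObservations, site: str, path: str | Path) -> None:
    pd.DataFrame({
        "site": site,
        "transect_index": range(1, obs.marking.n_transects + 1),
        "marked_count": obs.marked_counts,
        "unmarked_count": obs.unmarked_counts,
    }).to_csv(path, index=False)


def observations_from_counts(
    counts: pd.DataFrame, marking: MarkingSummary, site: str
) -> CRObservations:
    """Assemble one site's :class:`CRObservations` from a counts table."""
    sub = counts[counts["site"] == site].sort_values("transect_index")
    if len(sub) != marking.n_transects:
        raise SchemaError(
            f"site {site!r}: expected {marking.n_transects} transect rows, "
            f"found {len(sub)}"
        )
    expected = list(range(1, marking.n_transects + 1))
    if list(sub["transect_index"]) != expected:
        raise SchemaError(
            f"site {site!r}: transect_index must be exactly {expected}, "
            f"got {list(sub['transect_index'])}"
        )
    return CRObservations(
        marking,
        tuple(int(x) for x in sub["marked_count"]),
        tuple(int(x) for x in sub["unmarked_count"]),
    )


def read_census(path: str | Path) -> dict[str, SiteCensus]:
    df = pd.read_csv(path)
    _require_columns(df, CENSUS_COLUMNS, path)
    out = {}
    for idx, raw in df.iterrows():
        row_no = int(idx) + 1
        out[str(raw["site"])] = SiteCensus(
            site=str(raw["site"]),
            humans=_as_count(raw["humans"], "humans", row_no),
            owned_dogs=_as_count(raw["owned_dogs"], "owned_dogs", row_no),
        )
    return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def read_geojson_geometries(path: str | Path) -> list:
    """Shapely geometries from a GeoJSON FeatureCollection (or single
    Feature/geometry); coordinates are taken as-is (projected metres)."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in gj["features"]]
    if gj.get("type") == "Feature":
        return [shape(gj["geometry"])]
    return [shape(gj)]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report: dict, path: str | Path) -> None:
    report = dict(report)
    report.setdefault("schema_version", SCHEMA_VERSION)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj).__name__}")
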