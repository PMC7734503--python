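"""Standardisation of heterogeneous sample metadata.

Raw sample annotations from sequence archives mix free-text dates,
country spellings and coordinate notations.  This module converts them
into comparable curated fields (ISO dates, decimal degrees, canonical
country + continent, ENVO habitat terms) while keeping every original
value as provenance, so curation is non-destructive.
"""

from __future__ import annotations

import csv
import datetime
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .gazetteer import Gazetteer, load_gazetteer

logger = logging.getLogger(__name__)


class CoordSource(str, Enum):
    REPORTED = "REPORTED"
    CENTROID_FALLBACK = "CENTROID_FALLBACK"
    CORRECTED = "CORRECTED"


@dataclass
class RawSample:
    """A sample record as deposited: free text permitted everywhere."""

    srs: str
    collection_date_raw: Optional[str] = None
    country_raw: Optional[str] = None
    lat_lon_raw: Optional[str] = None
    habitat_raw: Optional[str] = None
    material_raw: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.srs:
            raise ValueError("srs must be non-empty")


@dataclass
class CuratedSample:
    srs: str
    collection_date_iso: Optional[str] = None
    country: Optional[str] = None
    geoname_id: Optional[int] = None
    continent: Optional[str] = None
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    coord_source: CoordSource = CoordSource.REPORTED
    biome_term: Optional[tuple[str, str]] = None  # (label, ENVO id)
    provenance: dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.latitude is None) != (self.longitude is None):
            raise ValueError("latitude/longitude must both be present or both absent")
        if self.coord_source is CoordSource.CENTROID_FALLBACK and self.country is None:
            raise ValueError("centroid fallback requires a country")


# --------------------------------------------------------------------------
# dates

_MONTHS = {
    name: i
    for i, name in enumerate(
        ["jan", "feb", "mar", "apr", "may", "jun",
         "jul", "aug", "sep", "oct", "nov", "dec"],
        start=1,
    )
}

_RE_ISO = re.compile(r"(\d{4})-(\d{2})-(\d{2})$")
_RE_DMY = re.compile(r"(\d{1,2})-([A-Za-z]{3})-(\d{4})$")
_RE_MY = re.compile(r"([A-Za-z]{3})-(\d{4})$")
_RE_Y = re.compile(r"(\d{4})$")
_RE_MDY = re.compile(r"(\d{1,2})/(\d{1,2})/(\d{4})$")


def standardize_date(raw: Optional[str]) -> Optional[str]:
    """Convert a raw date string to ISO 8601.

    Recognised dialects: YYYY-MM-DD, DD-Mon-YYYY, Mon-YYYY, YYYY and
    MM/DD/YYYY.  Partial dates keep only the known precision (YYYY or
    YYYY-MM).  Anything else fails soft with a logged warning.
    """
    if raw is None:
        return None
    s = raw.strip()
    if not s:
        return None
    if m := _RE_ISO.fullmatch(s):
        y, mo, d = map(int, m.groups())
        try:
            datetime.date(y, mo, d)
        except ValueError:
            logger.warning("invalid calendar date %r", raw)
            return None
        return f"{y:04d}-{mo:02d}-{d:02d}"
    if m := _RE_DMY.fullmatch(s):
        d, mon, y = int(m.group(1)), m.group(2).lower(), int(m.group(3))
        if mon not in _MONTHS:
            logger.warning("unknown month in %r", raw)
            return None
        try:
            datetime.date(y, _MONTHS[mon], d)
        except ValueError:
            logger.warning("invalid calendar date %r", raw)
            return None
        return f"{y:04d}-{_MONTHS[mon]:02d}-{d:02d}"
    if m := _RE_MY.fullmatch(s):
        mon, y = m.group(1).lower(), int(m.group(2))
        if mon not in _MONTHS:
            logger.warning("unknown month in %r", raw)
            return None
        return f"{y:04d}-{_MONTHS[mon]:02d}"
    if m := _RE_Y.fullmatch(s):
        return m.group(1)
    if m := _RE_MDY.fullmatch(s):
        mo, d, y = map(int, m.groups())
        try:
            datetime.date(y, mo, d)
        except ValueError:
            logger.warning("invalid calendar date %r", raw)
            return None
        return f"{y:04d}-{mo:02d}-{d:02d}"
    logger.warning("unparseable date %r", raw)
    return None


# --------------------------------------------------------------------------
# coordinates

_DMS_PART = (
    r"(?P<deg{i}>\d+(?:\.\d+)?)\s*°\s*"
    r"(?:(?P<min{i}>\d+(?:\.\d+)?)\s*[′'])?\s*"
    r"(?:(?P<sec{i}>\d+(?:\.\d+)?)\s*[″\"])?\s*"
    r"(?P<hem{i}>[{hems}])"
)
_RE_DMS = re.compile(
    _DMS_PART.format(i=1, hems="NS") + r"[\s,;]+" + _DMS_PART.format(i=2, hems="EW")
)
_RE_DEC_HEM = re.compile(
    r"(\d+(?:\.\d+)?)\s*([NS])[\s,;]+(\d+(?:\.\d+)?)\s*([EW])"
)
_RE_SIGNED = re.compile(
    r"(-?\d+(?:\.\d+)?)\s*[,;\s]\s*(-?\d+(?:\.\d+)?)"
)


def _dms_value(deg: str, minute: Optional[str], sec: Optional[str], hem: str) -> float:
    value = float(deg) + float(minute or 0) / 60.0 + float(sec or 0) / 3600.0
    return -value if hem in "SW" else value


def parse_coordinates(raw: Optional[str]) -> Optional[tuple[float, float]]:
    """Parse a coordinate string to decimal (latitude, longitude).

    Accepts decimal-with-hemisphere ("52.15 N 4.48 E"), signed decimal
    ("52.15, 4.48") and DMS ("52°09′36″N 4°29′E").  Values are rounded
    to 6 decimal places; out-of-range or malformed input yields None.
    """
    if raw is None:
        return None
    s = raw.strip()
    if not s:
        return None
    lat = lon = None
    if "°" in s:
        if m := _RE_DMS.fullmatch(s):
            lat = _dms_value(m.group("deg1"), m.group("min1"), m.group("sec1"), m.group("hem1"))
            lon = _dms_value(m.group("deg2"), m.group("min2"), m.group("sec2"), m.group("hem2"))
    elif m := _RE_DEC_HEM.fullmatch(s):
        lat = float(m.group(1)) * (-1 if m.group(2) == "S" else 1)
        lon = float(m.group(3)) * (-1 if m.group(4) == "W" else 1)
    elif m := _RE_SIGNED.fullmatch(s):
        lat, lon = float(m.group(1)), float(m.group(2))
    if lat is None or lon is None:
        logger.warning("unparseable coordinates %r", raw)
        return None
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        logger.warning("coordinates out of range %r", raw)
        return None
    return (round(lat, 6), round(lon, 6))


def format_decimal(lat: float, lon: float) -> str:
    """Canonical signed-decimal rendering; round-trips through
    :func:`parse_coordinates` within 1e-6 degrees."""
    return f"{lat:.6f}, {lon:.6f}"


# --------------------------------------------------------------------------
# geography

@dataclass(frozen=True)
class Geography:
    country: str
    geoname_id: int
    continent: str
    latitude: float
    longitude: float
    coord_source: CoordSource


def assign_geography(
    country_raw: Optional[str],
    coords: Optional[tuple[float, float]],
    gazetteer: Gazetteer,
) -> Optional[Geography]:
    """Resolve the country and final coordinates for a sample.

    Reported coordinates are kept when they fall inside the country's
    bounding box; otherwise they are replaced by the country centroid
    (coordinate repair).  Samples without coordinates fall back to the
    centroid.  Unknown countries yield None (logged).
    """
    entry = gazetteer.lookup(country_raw or "")
    if entry is None:
        logger.warning("unknown country %r", country_raw)
        return None
    if coords is None:
        lat, lon, source = entry.centroid_lat, entry.centroid_lon, CoordSource.CENTROID_FALLBACK
    elif not entry.contains(*coords):
        logger.warning(
            "coordinates %s outside bbox of %s: replaced by centroid",
            coords,
            entry.country_name,
        )
        lat, lon, source = entry.centroid_lat, entry.centroid_lon, CoordSource.CORRECTED
    else:
        (lat, lon), source = coords, CoordSource.REPORTED
    return Geography(
        country=entry.country_name,
        geoname_id=entry.geoname_id,
        continent=entry.continent,
        latitude=lat,
        longitude=lon,
        coord_source=source,
    )


# --------------------------------------------------------------------------
# environment terms

def bundled_envo_path() -> Path:
    return Path(str(resources.files("zotukit.data") / "envo_terms.tsv"))


def load_envo_dictionary(path: Union[str, Path, None] = None) -> dict[str, str]:
    """Load the label -> ENVO id dictionary (bundled TSV by default)."""
    path = bundled_envo_path() if path is None else Path(path)
    with open(path, newline="") as handle:
        return {row["label"]: row["envo_id"] for row in csv.DictReader(handle, delimiter="\t")}


def tag_environment(
    habitat_raw: Optional[str], envo_dictionary: dict[str, str]
) -> Optional[tuple[str, str]]:
    """Longest case-insensitive dictionary label contained in the text wins."""
    if not habitat_raw:
        return None
    haystack = habitat_raw.casefold()
    best: Optional[tuple[str, str]] = None
    for label, envo_id in envo_dictionary.items():
        if label.casefold() in haystack:
            if best is None or len(label) > len(best[0]):
                best = (label, envo_id)
    return best


# --------------------------------------------------------------------------
# full-record curation

def curate_sample(
    raw: RawSample,
    gazetteer: Gazetteer,
    envo_dictionary: dict[str, str],
) -> CuratedSample:
    """Curate one raw sample, recording provenance for every curated field."""
    date_iso = standardize_date(raw.collection_date_raw)
    coords = parse_coordinates(raw.lat_lon_raw)
    geo = assign_geography(raw.country_raw, coords, gazetteer) if raw.country_raw else None
    biome = tag_environment(raw.habitat_raw, envo_dictionary)

    if geo is not None:
        country, geoname_id, continent = geo.country, geo.geoname_id, geo.continent
        latitude, longitude, coord_source = geo.latitude, geo.longitude, geo.coord_source
    else:
        country = geoname_id = continent = None
        # no country to validate against: keep parsed coordinates as reported
        latitude, longitude = coords if coords else (None, None)
        coord_source = CoordSource.REPORTED

    provenance: dict[str, Optional[str]] = {
        "collection_date_iso": raw.collection_date_raw,
        "country": raw.country_raw,
        "geoname_id": raw.country_raw,
        "continent": raw.country_raw,
        "latitude": raw.lat_lon_raw,
        "longitude": raw.lat_lon_raw,
        "coord_source": raw.lat_lon_raw,
        "biome_term": raw.habitat_raw,
        "material": raw.material_raw,
    }
    return CuratedSample(
        srs=raw.srs,
        collection_date_iso=date_iso,
        country=country,
        geoname_id=geoname_id,
        continent=continent,
        latitude=latitude,
        longitude=longitude,
        coord_source=coord_source,
        biome_term=biome,
        provenance=provenance,
    )


def reconstruct_raw(curated: CuratedSample) -> RawSample:
    """Invert curation via the provenance mapping (byte-for-byte)."""
    p = curated.provenance
    return RawSample(
        srs=curated.srs,
        collection_date_raw=p["collection_date_iso"],
        country_raw=p["country"],
        lat_lon_raw=p["latitude"],
        habitat_raw=p["biome_term"],
        material_raw=p["material"],
    )


_CSV_COLUMNS = [
    "srs",
    "collection_date_iso",
    "country",
    "geoname_id",
    "continent",
    "latitude",
    "longitude",
    "coord_source",
    "biome_label",
    "biome_envo",
    "collection_date_raw",
    "country_raw",
    "lat_lon_raw",
    "habitat_raw",
    "material_raw",
]


def curate_table(
    samples: pd.DataFrame,
    gazetteer: Optional[Gazetteer] = None,
    envo_dictionary: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Curate a raw-sample table (columns srs, collection_date,
    geo_loc_name, lat_lon, env_biome, env_material) into a table with
    both curated and provenance columns."""
    gazetteer = gazetteer if gazetteer is not None else load_gazetteer()
    envo_dictionary = (
        envo_dictionary if envo_dictionary is not None else load_envo_dictionary()
    )

    def _get(row: pd.Series, col: str) -> Optional[str]:
        value = row.get(col)
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        return str(value)

    rows = []
    for _, row in samples.iterrows():
        raw = RawSample(
            srs=str(row["srs"]),
            collection_date_raw=_get(row, "collection_date"),
            country_raw=_get(row, "geo_loc_name"),
            lat_lon_raw=_get(row, "lat_lon"),
            habitat_raw=_get(row, "env_biome"),
            material_raw=_get(row, "env_material"),
        )
        cur = curate_sample(raw, gazetteer, envo_dictionary)
        rows.append(
            {
                "srs": cur.srs,
                "collection_date_iso": cur.collection_date_iso,
                "country": cur.country,
                "geoname_id": cur.geoname_id,
                "continent": cur.continent,
                "latitude": cur.latitude,
                "longitude": cur.longitude,
                "coord_source": cur.coord_source.value,
                "biome_label": cur.biome_term[0] if cur.biome_term else None,
                "biome_envo": cur.biome_term[1] if cur.biome_term else None,
                "collection_date_raw": raw.collection_date_raw,
                "country_raw": raw.country_raw,
                "lat_lon_raw": raw.lat_lon_raw,
                "habitat_raw": raw.habitat_raw,
                "material_raw": raw.material_raw,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)
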