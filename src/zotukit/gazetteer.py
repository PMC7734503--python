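"""Country gazetteer: canonical names, continents, centroids, bboxes.

Ships as a versioned TSV so that geography assignment needs no network.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

CONTINENTS = (
    "Africa",
    "Asia",
    "Europe",
    "North America",
    "Oceania",
    "South America",
    "Antarctica",
)


@dataclass(frozen=True)
class GazetteerEntry:
    country_name: str
    aliases: tuple[str, ...]
    geoname_id: int
    continent: str
    centroid_lat: float
    centroid_lon: float
    bbox: tuple[float, float, float, float]  # min_lat, min_lon, max_lat, max_lon

    def __post_init__(self) -> None:
        if self.continent not in CONTINENTS:
            raise ValueError(f"unknown continent {self.continent!r}")
        if not self.contains(self.centroid_lat, self.centroid_lon):
            raise ValueError(f"centroid outside bbox for {self.country_name}")

    def contains(self, lat: float, lon: float) -> bool:
        min_lat, min_lon, max_lat, max_lon = self.bbox
        return min_lat <= lat <= max_lat and min_lon <= lon <= max_lon


class Gazetteer:
    """Case-insensitive lookup over country names and aliases."""

    def __init__(self, entries: list[GazetteerEntry]):
        self.entries = entries
        self._index: dict[str, GazetteerEntry] = {}
        for entry in entries:
            self._index[entry.country_name.casefold()] = entry
            for alias in entry.aliases:
                self._index[alias.casefold()] = entry

    def lookup(self, name: str) -> Optional[GazetteerEntry]:
        if not name:
            return None
        return self._index.get(name.strip().casefold())

    def __len__(self) -> int:
        return len(self.entries)


def bundled_gazetteer_path() -> Path:
    return Path(str(resources.files("zotukit.data") / "gazetteer.tsv"))


def load_gazetteer(path: Union[str, Path, None] = None) -> Gazetteer:
    path = bundled_gazetteer_path() if path is None else Path(path)
    entries: list[GazetteerEntry] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            aliases = tuple(
                a.strip() for a in (row.get("aliases") or "").split(";") if a.strip()
            )
            entries.append(
                GazetteerEntry(
                    country_name=row["country_name"],
                    aliases=aliases,
                    geoname_id=int(row["geoname_id"]),
                    continent=row["continent"],
                    centroid_lat=float(row["centroid_lat"]),
                    centroid_lon=float(row["centroid_lon"]),
                    bbox=(
                        float(row["min_lat"]),
                        float(row["min_lon"]),
                        float(row["max_lat"]),
                        float(row["max_lon"]),
                    ),
                )
            )
    return Gazetteer(entries)
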