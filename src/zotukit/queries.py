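"""Biogeographic presence/absence queries over the reference store.

All queries work on presence (distinct reference sequences), never on
abundance: a ZOTU observed in any sample of a geographic unit counts
once for that unit.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .pipeline.taxonomy import Lineage
from .store import ZotuStore

#: Latitude of the tropics (Cancer/Capricorn), standard astronomical value.
TROPIC_LATITUDE = 23.43651

#: Phyla shown by name in phylum-by-continent tables; anything else
#: resolved-but-unlisted is bucketed as "Other", unresolved as
#: "Unidentified".  Configurable per call.
DEFAULT_DISPLAY_PHYLA = (
    "Basidiomycota",
    "Ascomycota",
    "Mortierellomycota",
    "Mucoromycota",
    "Chytridiomycota",
    "Rozellomycota",
    "Glomeromycota",
)

VALID_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def _presence(store: ZotuStore) -> pd.DataFrame:
    """(ref_id, srs, continent, latitude, longitude) for located samples."""
    contains = store.table("contains")
    sample = store.table("sample")[
        ["srs", "continent", "latitude", "longitude"]
    ]
    return contains.merge(sample, on="srs", how="left")


def _phylum_bucket(lineage_text: Optional[str], display: Sequence[str]) -> str:
    if not lineage_text or pd.isna(lineage_text):
        return "Unidentified"
    phylum = Lineage.from_string(lineage_text).phylum
    if not phylum or phylum.lower() in ("", "unidentified"):
        return "Unidentified"
    return phylum if phylum in display else "Other"


def phylum_by_continent(
    store: ZotuStore, display_phyla: Sequence[str] = DEFAULT_DISPLAY_PHYLA
) -> pd.DataFrame:
    """Distinct-ZOTU counts per (phylum, continent).

    A ZOTU present on two continents is counted once per continent.
    """
    presence = _presence(store)
    presence = presence[presence["continent"].notna()]
    if presence.empty:
        return pd.DataFrame(columns=["phylum", "continent", "zotu_count"])
    taxa = store.table("assign_taxa")[["ref_id", "lineage"]]
    merged = presence.merge(taxa, on="ref_id", how="left")
    merged["phylum"] = merged["lineage"].map(
        lambda text: _phylum_bucket(text, display_phyla)
    )
    counts = (
        merged.drop_duplicates(["ref_id", "continent"])
        .groupby(["phylum", "continent"])["ref_id"]
        .nunique()
        .reset_index(name="zotu_count")
        .sort_values(["phylum", "continent"], ignore_index=True)
    )
    return counts


def _unit_sets(store: ZotuStore, unit_column: str = "continent") -> dict[str, set[int]]:
    presence = _presence(store)
    presence = presence[presence[unit_column].notna()]
    return {
        unit: set(group["ref_id"])
        for unit, group in presence.groupby(unit_column)
    }


def shared_zotus(store: ZotuStore, unit: str, unit_column: str = "continent") -> int:
    """Count of ``unit``'s ZOTUs also present in at least one other unit."""
    sets = _unit_sets(store, unit_column)
    own = sets.get(unit, set())
    others: set[int] = set()
    for name, refs in sets.items():
        if name != unit:
            others |= refs
    return len(own & others)


def pairwise_overlap(store: ZotuStore, unit_column: str = "continent") -> pd.DataFrame:
    """Symmetric unit x unit shared-ZOTU counts; the diagonal holds each
    unit's own distinct-ZOTU count."""
    sets = _unit_sets(store, unit_column)
    units = sorted(sets)
    data = [
        [len(sets[u] & sets[v]) for v in units]
        for u in units
    ]
    return pd.DataFrame(data, index=units, columns=units)


def taxon_in_latitude_band(
    store: ZotuStore,
    rank: str,
    name: str,
    band: tuple[float, float] = (-TROPIC_LATITUDE, TROPIC_LATITUDE),
) -> pd.DataFrame:
    """Per-sample distinct-ZOTU counts for a taxon inside a latitude band.

    Returns columns (srs, latitude, longitude, zotu_count) for samples
    with curated coordinates whose latitude lies within ``band``.
    """
    if rank not in VALID_RANKS:
        raise ValueError(f"unknown rank {rank!r}; valid ranks: {list(VALID_RANKS)}")
    lat_min, lat_max = band
    presence = _presence(store)
    presence = presence[
        presence["latitude"].notna()
        & (presence["latitude"] >= lat_min)
        & (presence["latitude"] <= lat_max)
    ]
    if presence.empty:
        return pd.DataFrame(columns=["srs", "latitude", "longitude", "zotu_count"])
    taxa = store.table("assign_taxa")[["ref_id", "lineage"]]
    merged = presence.merge(taxa, on="ref_id", how="inner")
    wanted = merged["lineage"].map(
        lambda text: Lineage.from_string(text).rank(rank).casefold() == name.casefold()
    )
    merged = merged[wanted]
    if merged.empty:
        return pd.DataFrame(columns=["srs", "latitude", "longitude", "zotu_count"])
    return (
        merged.groupby(["srs", "latitude", "longitude"])["ref_id"]
        .nunique()
        .reset_index(name="zotu_count")
        .sort_values("srs", ignore_index=True)
    )


def band_points_geojson(points: pd.DataFrame) -> dict:
    """Render a latitude-band result as a GeoJSON FeatureCollection."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [row["longitude"], row["latitude"]],
            },
            "properties": {"srs": row["srs"], "zotu_count": int(row["zotu_count"])},
        }
        for _, row in points.iterrows()
    ]
    return {
        "type": "FeatureCollection",
        "features": features,
        "metadata": {"band_definition": "sample latitude within [lat_min, lat_max]"},
    }
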