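from __future__ import annotations

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zotukit.curation import (
    CoordSource,
    CuratedSample,
    RawSample,
    assign_geography,
    curate_sample,
    curate_table,
    format_decimal,
    parse_coordinates,
    reconstruct_raw,
    standardize_date,
    tag_environment,
)
from zotukit.fixtures import make_metadata


# --------------------------------------------------------------------------
# dates

@pytest.mark.parametrize(
    "raw,expected",
    [
        ("12-Aug-2014", "2014-08-12"),
        ("2014-08-12", "2014-08-12"),
        ("Aug-2014", "2014-08"),
        ("2014", "2014"),
        ("08/12/2014", "2014-08-12"),
        ("1-Jan-2000", "2000-01-01"),
    ],
)
def test_date_dialects(raw, expected):
    assert standardize_date(raw) == expected


@pytest.mark.parametrize(
    "raw",
    ["sometime in summer", "32-Jan-2014", "2014-13-40", "13/32/2014", "not applicable", ""],
)
def test_unparseable_dates_fail_soft(raw):
    assert standardize_date(raw) is None


def test_date_none_passthrough():
    assert standardize_date(None) is None


# --------------------------------------------------------------------------
# coordinates

def test_dms_minutes_only():
    assert parse_coordinates("52°09′N 4°29′E") == (
        round(52 + 9 / 60, 6),
        round(4 + 29 / 60, 6),
    )


def test_dms_with_seconds():
    lat, lon = parse_coordinates("52°09′36″N 4°29′E")
    assert lat == pytest.approx(52.16, abs=1e-6)
    assert lon == pytest.approx(4.483333, abs=1e-6)


def test_origin():
    assert parse_coordinates("0 N 0 E") == (0.0, 0.0)


def test_southern_western_hemispheres():
    assert parse_coordinates("25.27 S 133.78 E") == (-25.27, 133.78)
    assert parse_coordinates("10.5 N 20.25 W") == (10.5, -20.25)


def test_signed_decimal():
    assert parse_coordinates("52.15, 4.48") == (52.15, 4.48)
    assert parse_coordinates("-33.9 151.2") == (-33.9, 151.2)


@pytest.mark.parametrize("raw", ["95 N 10 E", "10 N 190 E", "-95, 10", "garbage", ""])
def test_malformed_or_out_of_range(raw):
    assert parse_coordinates(raw) is None


@settings(max_examples=300, deadline=None)
@given(
    lat=st.floats(min_value=-90, max_value=90, allow_nan=False),
    lon=st.floats(min_value=-180, max_value=180, allow_nan=False),
)
def test_format_parse_round_trip(lat, lon):
    parsed = parse_coordinates(format_decimal(lat, lon))
    assert parsed is not None
    assert math.isclose(parsed[0], lat, abs_tol=1e-6)
    assert math.isclose(parsed[1], lon, abs_tol=1e-6)


# --------------------------------------------------------------------------
# geography

def test_centroid_fallback_exact(gazetteer):
    geo = assign_geography("Netherlands", None, gazetteer)
    entry = gazetteer.lookup("Netherlands")
    assert geo.coord_source is CoordSource.CENTROID_FALLBACK
    assert (geo.latitude, geo.longitude) == (entry.centroid_lat, entry.centroid_lon)
    assert geo.continent == "Europe"
    assert geo.geoname_id == entry.geoname_id


def test_in_bbox_coordinates_kept(gazetteer):
    geo = assign_geography("Netherlands", (52.1, 4.5), gazetteer)
    assert geo.coord_source is CoordSource.REPORTED
    assert (geo.latitude, geo.longitude) == (52.1, 4.5)


def test_out_of_bbox_coordinates_corrected(gazetteer):
    geo = assign_geography("Netherlands", (-33.9, 151.2), gazetteer)
    entry = gazetteer.lookup("Netherlands")
    assert geo.coord_source is CoordSource.CORRECTED
    assert (geo.latitude, geo.longitude) == (entry.centroid_lat, entry.centroid_lon)


def test_unknown_country_absent(gazetteer):
    assert assign_geography("Atlantis", (1.0, 2.0), gazetteer) is None


def test_alias_and_case_insensitive_lookup(gazetteer):
    assert gazetteer.lookup("usa").country_name == "United States"
    assert gazetteer.lookup("THE NETHERLANDS").country_name == "Netherlands"


def test_gazetteer_invariants(gazetteer):
    assert len(gazetteer) >= 38
    for entry in gazetteer.entries:
        assert entry.contains(entry.centroid_lat, entry.centroid_lon)
        assert entry.continent


@settings(max_examples=100, deadline=None)
@given(
    lat=st.one_of(st.none(), st.floats(min_value=-90, max_value=90, allow_nan=False)),
    lon=st.floats(min_value=-180, max_value=180, allow_nan=False),
    idx=st.integers(min_value=0, max_value=51),
)
def test_geography_output_always_in_range(gazetteer, lat, lon, idx):
    entry = gazetteer.entries[idx % len(gazetteer.entries)]
    coords = None if lat is None else (lat, lon)
    geo = assign_geography(entry.country_name, coords, gazetteer)
    assert -90 <= geo.latitude <= 90
    assert -180 <= geo.longitude <= 180
    if geo.coord_source is CoordSource.CENTROID_FALLBACK:
        assert (geo.latitude, geo.longitude) == (entry.centroid_lat, entry.centroid_lon)


# --------------------------------------------------------------------------
# environment tagging

def test_longest_label_wins():
    d = {"forest soil": "ENVO:00002261", "soil": "ENVO:00001998"}
    assert tag_environment("temperate broadleaf forest soil", d) == (
        "forest soil",
        "ENVO:00002261",
    )


def test_empty_habitat():
    assert tag_environment("", {"soil": "x"}) is None


def test_environment_case_folding():
    d = {"forest soil": "ENVO:00002261"}
    assert tag_environment("FOREST SOIL", d) == tag_environment("forest soil", d)


# --------------------------------------------------------------------------
# whole-record curation and provenance

_raw_text = st.one_of(st.none(), st.text(max_size=30))


@settings(max_examples=100, deadline=None)
@given(
    date=_raw_text,
    country=_raw_text,
    lat_lon=_raw_text,
    habitat=_raw_text,
    material=_raw_text,
)
def test_provenance_reconstructs_raw_byte_for_byte(
    gazetteer, envo_dict, date, country, lat_lon, habitat, material
):
    raw = RawSample(
        srs="SRS1",
        collection_date_raw=date,
        country_raw=country,
        lat_lon_raw=lat_lon,
        habitat_raw=habitat,
        material_raw=material,
    )
    curated = curate_sample(raw, gazetteer, envo_dict)
    assert reconstruct_raw(curated) == raw
    assert set(curated.provenance) >= {
        "collection_date_iso",
        "country",
        "continent",
        "latitude",
        "longitude",
        "coord_source",
        "biome_term",
    }


def test_curated_invariants():
    with pytest.raises(ValueError):
        CuratedSample(srs="S", latitude=1.0, longitude=None)
    with pytest.raises(ValueError):
        CuratedSample(
            srs="S", country=None, coord_source=CoordSource.CENTROID_FALLBACK
        )


def test_curate_table_matches_generator_truth(gazetteer, envo_dict):
    truth = make_metadata(seed=0)
    curated = curate_table(truth.raw, gazetteer, envo_dict)
    merged = curated.merge(truth.expected, on="srs")
    assert len(merged) == len(truth.raw)
    for _, row in merged.iterrows():
        assert row["collection_date_iso"] == row["expected_date"] or (
            row["collection_date_iso"] is None and row["expected_date"] is None
        )
        assert row["country"] == row["expected_country"] or (
            row["country"] is None and row["expected_country"] is None
        )
        assert row["continent"] == row["expected_continent"] or (
            row["continent"] is None and row["expected_continent"] is None
        )
        if pd.isna(row["expected_lat"]):
            assert row["latitude"] is None or math.isnan(row["latitude"])
        else:
            assert row["latitude"] == pytest.approx(row["expected_lat"], abs=1e-6)
            assert row["longitude"] == pytest.approx(row["expected_lon"], abs=1e-6)
        assert row["coord_source"] == row["expected_coord_source"]
        assert row["biome_label"] == row["expected_biome_label"] or (
            row["biome_label"] is None and row["expected_biome_label"] is None
        )
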