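from __future__ import annotations

import numpy as np
import pytest

from conftest import make_assignment, make_zotu
from oracles import presence_sets
from zotukit.curation import CoordSource, CuratedSample
from zotukit.queries import (
    TROPIC_LATITUDE,
    band_points_geojson,
    pairwise_overlap,
    phylum_by_continent,
    shared_zotus,
    taxon_in_latitude_band,
)
from zotukit.store import SraExperiment, SraHierarchy, ZotuStore

PHYLA = ["Basidiomycota", "Ascomycota", "Mortierellomycota", "Weirdomycota"]
CONTINENTS = ["Africa", "Asia", "Europe", "North America", "Oceania", "South America"]


def blank_provenance():
    return {
        key: None
        for key in [
            "collection_date_iso", "country", "geoname_id", "continent",
            "latitude", "longitude", "coord_source", "biome_term", "material",
        ]
    }


def located_sample(srs, continent, lat, lon):
    return CuratedSample(
        srs=srs, country="X", continent=continent, latitude=lat, longitude=lon,
        coord_source=CoordSource.REPORTED, provenance=blank_provenance(),
    )


def build_store(observations, samples):
    """observations: list of (srs, srr, [(seq, phylum, family)])."""
    store = ZotuStore()
    batches = []
    for srs, srr, zotus in observations:
        batch = []
        for seq, phylum, family in zotus:
            batch.append(
                (make_zotu(seq), make_assignment(phylum=phylum, family=family))
            )
        batches.append((srs, srr, batch))
    store.update_store(batches)
    hierarchy = SraHierarchy(
        study="SRP1",
        experiments=[
            SraExperiment(srx=f"SRX{i}", platform="P", sample=s.srs)
            for i, s in enumerate(samples)
        ],
        runs=[],
    )
    store.import_curated(samples, hierarchy)
    return store


def test_single_observation():
    store = build_store(
        [("S1", "R1", [("AAAA", "Basidiomycota", "Russulaceae")])],
        [located_sample("S1", "Europe", 52.0, 5.0)],
    )
    table = phylum_by_continent(store)
    assert table.values.tolist() == [["Basidiomycota", "Europe", 1]]


def test_zotu_on_two_continents_counted_once_per_continent():
    store = build_store(
        [
            ("S1", "R1", [("AAAA", "Basidiomycota", "Russulaceae")]),
            ("S2", "R2", [("AAAA", "Basidiomycota", "Russulaceae")]),
        ],
        [
            located_sample("S1", "Europe", 52.0, 5.0),
            located_sample("S2", "Asia", 35.0, 105.0),
        ],
    )
    table = phylum_by_continent(store)
    assert sorted(table["continent"]) == ["Asia", "Europe"]
    assert table["zotu_count"].tolist() == [1, 1]


def test_empty_store():
    store = ZotuStore()
    assert phylum_by_continent(store).empty
    assert pairwise_overlap(store).empty
    assert shared_zotus(store, "Europe") == 0


def test_unlisted_phylum_bucketed_as_other_and_missing_as_unidentified():
    store = ZotuStore()
    store.update_store(
        [
            ("S1", "R1", [
                (make_zotu("AAAA"), make_assignment(phylum="Weirdomycota")),
                (make_zotu("CCCC"), None),
            ]),
        ]
    )
    store.import_curated(
        [located_sample("S1", "Europe", 52.0, 5.0)],
        SraHierarchy(study="SRP1", experiments=[], runs=[]),
    )
    table = phylum_by_continent(store)
    buckets = dict(zip(table["phylum"], table["zotu_count"]))
    assert buckets == {"Other": 1, "Unidentified": 1}


def test_shared_and_pairwise_example():
    # continent A holds {a, b}; continent B holds {b, c}
    store = build_store(
        [
            ("S1", "R1", [("AAAA", "Basidiomycota", "F"), ("CCCC", "Basidiomycota", "F")]),
            ("S2", "R2", [("CCCC", "Basidiomycota", "F"), ("GGGG", "Basidiomycota", "F")]),
        ],
        [
            located_sample("S1", "Africa", 0.0, 20.0),
            located_sample("S2", "Asia", 35.0, 100.0),
        ],
    )
    assert shared_zotus(store, "Africa") == 1
    assert shared_zotus(store, "Asia") == 1
    table = pairwise_overlap(store)
    assert table.loc["Africa", "Asia"] == 1
    assert table.loc["Asia", "Africa"] == 1
    assert table.loc["Africa", "Africa"] == 2  # diagonal = own distinct count


def test_disjoint_sets_share_nothing():
    store = build_store(
        [
            ("S1", "R1", [("AAAA", "Basidiomycota", "F")]),
            ("S2", "R2", [("CCCC", "Basidiomycota", "F")]),
        ],
        [
            located_sample("S1", "Africa", 0.0, 20.0),
            located_sample("S2", "Asia", 35.0, 100.0),
        ],
    )
    assert shared_zotus(store, "Africa") == 0
    assert shared_zotus(store, "Asia") == 0


def test_single_continent_shares_zero_by_definition():
    store = build_store(
        [("S1", "R1", [("AAAA", "Basidiomycota", "F")])],
        [located_sample("S1", "Europe", 52.0, 5.0)],
    )
    assert shared_zotus(store, "Europe") == 0


def test_band_query_example():
    store = build_store(
        [
            ("S1", "R1", [
                ("AAAA", "Basidiomycota", "Russulaceae"),
                ("CCCC", "Basidiomycota", "Russulaceae"),
                ("GGGG", "Basidiomycota", "Russulaceae"),
                ("TTTT", "Ascomycota", "Nectriaceae"),
            ]),
            ("S2", "R2", [("AAAA", "Basidiomycota", "Russulaceae")]),
        ],
        [
            located_sample("S1", "South America", -10.0, -60.0),
            located_sample("S2", "Europe", 45.0, 5.0),  # outside the band
        ],
    )
    points = taxon_in_latitude_band(
        store, "family", "Russulaceae", band=(-TROPIC_LATITUDE, TROPIC_LATITUDE)
    )
    assert points["srs"].tolist() == ["S1"]
    assert points["zotu_count"].tolist() == [3]
    geojson = band_points_geojson(points)
    assert geojson["features"][0]["geometry"]["coordinates"] == [-60.0, -10.0]


def test_band_query_unknown_rank():
    store = ZotuStore()
    with pytest.raises(ValueError, match="valid ranks"):
        taxon_in_latitude_band(store, "tribe", "X")


def test_band_query_absent_taxon():
    store = build_store(
        [("S1", "R1", [("AAAA", "Basidiomycota", "Russulaceae")])],
        [located_sample("S1", "Europe", 10.0, 5.0)],
    )
    assert taxon_in_latitude_band(store, "genus", "Tuber").empty


def _random_store(rng, n_refs=60, n_samples=12, n_obs=300):
    """Randomized store plus plain-python shadow records."""
    sequences = {}
    samples = []
    sample_meta = {}
    for i in range(n_samples):
        srs = f"S{i}"
        continent = CONTINENTS[rng.integers(0, len(CONTINENTS))]
        lat = float(rng.uniform(-60, 60))
        lon = float(rng.uniform(-180, 180))
        samples.append(located_sample(srs, continent, lat, lon))
        sample_meta[srs] = (continent, lat, lon)
    observations = []
    shadow = []  # (ref_seq, srs, phylum, family)
    for i in range(n_samples):
        srs = f"S{i}"
        chosen = rng.choice(n_refs, size=min(n_obs // n_samples, n_refs), replace=False)
        zotus = []
        for ref_idx in chosen:
            seq = "".join("ACGT"[(int(ref_idx) >> (2 * k)) & 3] for k in range(6))
            phylum = PHYLA[int(ref_idx) % len(PHYLA)]
            family = ["Russulaceae", "Nectriaceae"][int(ref_idx) % 2]
            zotus.append((seq, phylum, family))
            shadow.append((seq, srs, phylum, family))
            sequences[seq] = (phylum, family)
        observations.append((srs, f"R{i}", zotus))
    store = build_store(observations, samples)
    return store, shadow, sample_meta


def test_queries_equal_brute_force_on_random_stores(rng):
    for trial in range(8):
        store, shadow, sample_meta = _random_store(rng)
        units = {srs: meta[0] for srs, meta in sample_meta.items()}
        contains = store.table("contains")
        ref_seq = dict(
            zip(store.table("reference_sequence")["ref_id"],
                store.table("reference_sequence")["sequence"])
        )
        rows = [(ref_seq[r], s) for r, s in zip(contains["ref_id"], contains["srs"])]
        sets = presence_sets(rows, units)

        # pairwise overlap and shared counts
        table = pairwise_overlap(store)
        for u in sets:
            others = set().union(*(sets[v] for v in sets if v != u)) if len(sets) > 1 else set()
            assert shared_zotus(store, u) == len(sets[u] & others)
            for v in sets:
                seq_ids_u, seq_ids_v = sets[u], sets[v]
                assert table.loc[u, v] == len(seq_ids_u & seq_ids_v)
        assert (table.values == table.values.T).all()

        # double-counting law
        global_distinct = len(set().union(*sets.values()))
        assert sum(len(s) for s in sets.values()) >= global_distinct

        # phylum x continent
        expected = {}
        for seq, srs, phylum, family in shadow:
            bucket = phylum if phylum != "Weirdomycota" else "Other"
            expected.setdefault((bucket, units[srs]), set()).add(seq)
        got = phylum_by_continent(store)
        got_map = {
            (row["phylum"], row["continent"]): row["zotu_count"]
            for _, row in got.iterrows()
        }
        assert got_map == {k: len(v) for k, v in expected.items()}

        # latitude band
        band = (-23.43651, 23.43651)
        expected_band = {}
        for seq, srs, phylum, family in shadow:
            lat = sample_meta[srs][1]
            if band[0] <= lat <= band[1] and family == "Russulaceae":
                expected_band.setdefault(srs, set()).add(seq)
        points = taxon_in_latitude_band(store, "family", "Russulaceae", band=band)
        got_band = dict(zip(points["srs"], points["zotu_count"]))
        assert got_band == {k: len(v) for k, v in expected_band.items()}
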